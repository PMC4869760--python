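"""Two-stage phenotypic analysis of multi-environment trials.

Stage 1 analyses each trial (location-by-cycle combination) separately:
candidate mixed models with and without random row/column effects are
compared by AIC, line BLUEs and their standard errors are extracted from
the winning model, and a trial heritability is computed from the genetic
variance of a companion random-line fit and the mean variance of a
difference of BLUEs (Piepho-Moehring entry-mean heritability).

Stage 2 combines the per-trial BLUEs of one breeding cycle in a weighted
mixed model ``y_ij = mu + g_i + t_j + gt_ij + e`` with fixed trial
effects, random line and line-by-trial effects, weights ``1/se^2`` from
stage 1, and the residual variance fixed to a trait-specific constant
(1 for grain yield, 0.1 for the protein traits) so the interaction
variance is separable from the residual even though every line-by-trial
cell holds a single adjusted mean.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._lmm import gls, reml_fit
from .simdata import GRAIN_YIELD, PROTEIN_CONTENT, PROTEIN_YIELD, TRAITS

__all__ = [
    "TrialResult",
    "CycleBLUEs",
    "STAGE2_FIXED_RESID",
    "fit_trial_model",
    "piepho_moehring_h2",
    "select_trials",
    "fit_stage2",
    "across_trial_h2",
    "analyze_cycles",
    "line_mean_blues",
    "variance_component_table",
]

logger = logging.getLogger(__name__)

#: residual variance constants of the weighted stage-2 model, per trait
STAGE2_FIXED_RESID = {GRAIN_YIELD: 1.0, PROTEIN_CONTENT: 0.1, PROTEIN_YIELD: 0.1}

_MODEL_ORDER = ("baseline", "row", "col", "row+col")


@dataclass
class TrialResult:
    """Stage-1 output for one trial and one trait."""

    trial_id: str
    cycle: int
    trait: str
    blues: pd.Series  # all entries, checks included
    se: pd.Series
    test_lines: np.ndarray  # genotyped (non-check) entries
    sigma2_G: float
    MVD: float
    h2: float
    model_tag: str
    converged: bool = True


@dataclass
class CycleBLUEs:
    """Stage-2 output: across-trial adjusted means for one cycle/trait."""

    cycle: int
    trait: str
    blues: pd.Series
    se: pd.Series
    sigma2_G: float
    sigma2_GT: float
    n_trials: int
    h2: float


def piepho_moehring_h2(sigma2_G: float, MVD: float) -> float:
    """Entry-mean heritability ``s2_G / (s2_G + MVD/2)``, clamped to [0,1]."""
    if sigma2_G < 0 or MVD < 0:
        raise ValueError("variance inputs must be non-negative")
    if sigma2_G == 0 and MVD == 0:
        raise ValueError("heritability undefined: both inputs zero")
    return float(np.clip(sigma2_G / (sigma2_G + 0.5 * MVD), 0.0, 1.0))


def across_trial_h2(sigma2_G: float, sigma2_GT: float, t: int) -> float:
    """Across-trial heritability ``s2_G / (s2_G + s2_GT / t)``, clamped to [0,1]."""
    if t is None or int(t) < 1:
        raise ValueError("number of trials t must be >= 1")
    if sigma2_G < 0 or sigma2_GT < 0:
        raise ValueError("variance inputs must be non-negative")
    if sigma2_G == 0 and sigma2_GT == 0:
        raise ValueError("heritability undefined: both inputs zero")
    return float(np.clip(sigma2_G / (sigma2_G + sigma2_GT / int(t)), 0.0, 1.0))


def _mean_variance_of_difference(C: np.ndarray) -> float:
    """Mean over entry pairs of ``var(BLUE_i - BLUE_j)`` from the BLUE
    covariance matrix."""
    n = C.shape[0]
    if n < 2:
        return 0.0
    tr = float(np.trace(C))
    s = float(C.sum())
    return 2.0 * (n * tr - s) / (n * (n - 1))


def fit_trial_model(plots: pd.DataFrame, trait: str) -> TrialResult:
    """Stage-1 analysis of a single trial.

    ``plots`` must contain exactly one trial.  Candidate models share the
    fixed part (line as fixed effect) and differ in random row and/or
    column effects; the smallest REML AIC wins.  The genetic variance
    for the heritability comes from a companion fit with line random.
    """
    df = plots.loc[plots["trait"] == trait]
    if df.empty:
        raise ValueError(f"trait {trait!r} not present in plot table")
    if df["trial"].nunique() != 1:
        raise ValueError("fit_trial_model expects plots from a single trial")
    trial_id = df["trial"].iloc[0]
    cycle = int(df["cycle"].iloc[0])

    entries = pd.Index(pd.unique(df["line"]))
    if entries.size < 2:
        raise ValueError("need at least two lines")
    if len(df) <= entries.size:
        raise ValueError("no replication in trial: error variance not estimable")
    y = df["value"].to_numpy(dtype=float)
    X = pd.get_dummies(pd.Categorical(df["line"], categories=entries)).to_numpy(dtype=float)

    def onehot(col):
        return pd.get_dummies(df[col].astype("category")).to_numpy(dtype=float)

    Z_row = onehot("row") if df["row"].nunique() > 1 else None
    Z_col = onehot("col") if df["col"].nunique() > 1 else None
    candidates = {"baseline": {}}
    if Z_row is not None:
        candidates["row"] = {"row": Z_row}
    if Z_col is not None:
        candidates["col"] = {"col": Z_col}
    if Z_row is not None and Z_col is not None:
        candidates["row+col"] = {"row": Z_row, "col": Z_col}

    fits = {}
    for tag in _MODEL_ORDER:
        if tag in candidates:
            fits[tag] = reml_fit(y, X, randoms=candidates[tag])
    best_tag = min(fits, key=lambda k: (fits[k].aic, _MODEL_ORDER.index(k)))
    best = fits[best_tag]

    blues = pd.Series(best.beta, index=entries, name="blue")
    se = pd.Series(np.sqrt(np.diag(best.beta_cov)), index=entries, name="se")
    MVD = _mean_variance_of_difference(best.beta_cov)

    companion = reml_fit(
        y,
        np.ones((len(df), 1)),
        randoms={"line": X, **candidates[best_tag]},
    )
    sigma2_G = companion.varcomps["line"]
    if sigma2_G == 0 and MVD == 0:
        h2 = 0.0
    else:
        h2 = piepho_moehring_h2(sigma2_G, MVD)

    is_check = df.groupby("line", sort=False)["is_check"].first().reindex(entries)
    test_lines = entries[~is_check.astype(bool)].to_numpy(dtype=object)
    return TrialResult(
        trial_id=trial_id,
        cycle=cycle,
        trait=trait,
        blues=blues,
        se=se,
        test_lines=test_lines,
        sigma2_G=float(sigma2_G),
        MVD=float(MVD),
        h2=h2,
        model_tag=best_tag,
        converged=best.converged and companion.converged,
    )


def select_trials(results: list[TrialResult], min_h2: float = 0.3) -> list[TrialResult]:
    """Keep trials with heritability strictly above ``min_h2``."""
    kept = [r for r in results if r.h2 > min_h2]
    dropped = [r.trial_id for r in results if r.h2 <= min_h2]
    if dropped:
        logger.info("select_trials dropped %d trial(s): %s", len(dropped), ", ".join(map(str, dropped)))
    if not kept:
        raise ValueError(f"no usable trials: all heritabilities <= {min_h2}")
    return kept


def fit_stage2(
    trials: list[TrialResult],
    trait: str | None = None,
    fixed_resid: float | None = None,
    blues_from_fixed_fit: bool = True,
) -> CycleBLUEs:
    """Weighted across-trial mixed model for one breeding cycle.

    Only genotyped (non-check) lines enter; observations are weighted by
    the inverse squared stage-1 standard errors and the residual
    variance is fixed to the trait constant.  Line BLUEs come from a GLS
    refit with line fixed at the estimated variance components (set
    ``blues_from_fixed_fit=False`` for a random-effect back-solve).
    """
    if len(trials) < 2:
        raise ValueError("stage 2 needs >= 2 trials (interaction variance inestimable)")
    trait = trait or trials[0].trait
    if any(t.trait != trait for t in trials):
        raise ValueError("mixed traits in stage-2 input")
    if fixed_resid is None:
        fixed_resid = STAGE2_FIXED_RESID.get(trait, 1.0)
    cycle = trials[0].cycle

    rows = []
    for tr in trials:
        sub = pd.DataFrame(
            {
                "line": tr.test_lines,
                "blue": tr.blues.reindex(tr.test_lines).to_numpy(),
                "se": tr.se.reindex(tr.test_lines).to_numpy(),
                "trial": tr.trial_id,
            }
        )
        rows.append(sub.dropna(subset=["blue", "se"]))
    data = pd.concat(rows, ignore_index=True)
    lines = pd.Index(pd.unique(data["line"]))
    trial_ids = pd.Index(pd.unique(data["trial"]))
    t = trial_ids.size

    y = data["blue"].to_numpy(dtype=float)
    w = 1.0 / data["se"].to_numpy(dtype=float) ** 2
    Zg = pd.get_dummies(pd.Categorical(data["line"], categories=lines)).to_numpy(dtype=float)
    T = pd.get_dummies(pd.Categorical(data["trial"], categories=trial_ids)).to_numpy(dtype=float)
    X_vc = np.column_stack([np.ones(len(data)), T[:, 1:]])
    n = len(data)

    fit = reml_fit(
        y,
        X_vc,
        randoms={"line": Zg, "gxt": np.eye(n)},
        weights=w,
        fixed_resid=fixed_resid,
    )
    sigma2_G = fit.varcomps["line"]
    sigma2_GT = fit.varcomps["gxt"]
    h2 = 0.0 if (sigma2_G == 0 and sigma2_GT == 0) else across_trial_h2(sigma2_G, sigma2_GT, t)

    V = sigma2_GT * np.eye(n) + np.diag(fixed_resid / w)
    if blues_from_fixed_fit:
        X_b = np.column_stack([Zg, T[:, 1:]])
        beta, cov = gls(y, X_b, V)
        blues = pd.Series(beta[: lines.size], index=lines, name="blue")
        se = pd.Series(np.sqrt(np.diag(cov)[: lines.size]), index=lines, name="se")
    else:
        Vg = V + sigma2_G * (Zg @ Zg.T)
        beta, _ = gls(y, X_vc, Vg)
        resid = y - X_vc @ beta
        u = sigma2_G * (Zg.T @ np.linalg.solve(Vg, resid))
        blues = pd.Series(beta[0] + u, index=lines, name="blue")
        se = pd.Series(np.full(lines.size, np.nan), index=lines, name="se")
    return CycleBLUEs(
        cycle=cycle,
        trait=trait,
        blues=blues,
        se=se,
        sigma2_G=float(sigma2_G),
        sigma2_GT=float(sigma2_GT),
        n_trials=int(t),
        h2=float(h2),
    )


def analyze_cycles(
    plots: pd.DataFrame,
    traits=TRAITS,
    min_h2: float = 0.3,
    skip_trial_filter: bool = False,
) -> dict[tuple[int, str], CycleBLUEs]:
    """Run the full two-stage pipeline for every cycle and trait.

    Returns a mapping ``(cycle, trait) -> CycleBLUEs``.  Set
    ``skip_trial_filter=True`` to keep all trials regardless of their
    stage-1 heritability (useful in calibration studies at very low
    target heritability, where the >0.3 rule would empty the cycle).
    """
    out = {}
    for cycle, cyc_df in plots.groupby("cycle", sort=True):
        for trait in traits:
            results = [
                fit_trial_model(trial_df, trait)
                for _, trial_df in cyc_df.groupby("trial", sort=True)
            ]
            kept = results if skip_trial_filter else select_trials(results, min_h2=min_h2)
            out[(int(cycle), trait)] = fit_stage2(kept, trait)
    return out


def line_mean_blues(plots: pd.DataFrame, traits=TRAITS) -> pd.DataFrame:
    """Across-trial line means of the candidate lines, per cycle and trait.

    In the orthogonal design simulated here (every candidate grown once
    in every trial of its cycle) the simple across-trial mean is the
    ordinary least-squares adjusted mean, so this is a fast, exact
    stand-in for the two-stage pipeline wherever the downstream
    cross-validation machinery, not the stage models themselves, is
    under study.
    """
    test = plots.loc[~plots["is_check"] & plots["trait"].isin(traits)]
    out = (
        test.groupby(["cycle", "trait", "line"], sort=True)["value"]
        .mean()
        .rename("blue")
        .reset_index()
    )
    return out


def variance_component_table(cycle_blues: list[CycleBLUEs]) -> pd.DataFrame:
    """Variance-component report, one row per trait-by-cycle cell."""
    rows = [
        {
            "trait": cb.trait,
            "cycle": cb.cycle,
            "n_trials": cb.n_trials,
            "sigma2_G": cb.sigma2_G,
            "sigma2_GT": cb.sigma2_GT,
            "h2": cb.h2,
            "n_lines": cb.blues.size,
        }
        for cb in cycle_blues
    ]
    return pd.DataFrame(rows)
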