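"""Cross-validation schemes, bias, outlier handling, and accuracy analysis.

Three cross-validation designs cover different questions about a
multi-cycle breeding program:

* ``within_cycle_cv`` — classical fivefold CV inside one breeding cycle
  (80 % of the cycle's lines train, the left-out fold is predicted);
* ``between_cycle_bias`` — the *same* training folds predict every other
  cycle, quantifying how much within-cycle CV overstates the accuracy a
  breeder actually gets on next year's material;
* ``across_cycle_cv`` — the breeding cycles themselves are the folds: an
  equal number of lines is sampled from every other cycle, a fixed year
  (cycle) effect absorbs the different yield levels, and the entire
  held-out cycle is predicted.

Accuracy is the Pearson correlation between GEBVs and adjusted means
(``r_GS``); on synthetic data the correlation with true breeding values
(``r_MT``) is reported alongside.  Replicate sampling uses per-
(scheme, replicate, unit) substreams of one master seed, so the
between-cycle scheme reuses the within-cycle folds bit-exactly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .gsmodel import GBLUP, RRBLUP, line_accuracy_rpev
from .markers import KinshipMatrix, MarkerMatrix
from .pheno import CycleBLUEs, line_mean_blues

__all__ = [
    "GSData",
    "CVResult",
    "BiasResult",
    "within_cycle_cv",
    "between_cycle_bias",
    "bias_percent",
    "across_cycle_cv",
    "outlier_corrected_cv",
    "pairwise_cycle_matrix",
    "identify_outliers",
    "identify_outlier_trials",
    "independent_validation",
    "selection_proportion",
    "relatedness_accuracy_correlation",
    "dataset_from_simulation",
    "dataset_from_cycle_blues",
]

# scheme labels -> substream ids of the master seed
_SCHEME_STREAM = {"within": 11, "between": 11, "across": 13, "diag": 17}


def _rng(seed: int, scheme: str, rep: int, unit: int) -> np.random.Generator:
    return np.random.default_rng([int(seed), _SCHEME_STREAM[scheme], int(rep), int(unit)])


@dataclass
class GSData:
    """Genotypes plus cycle-level adjusted means, aligned by line id."""

    markers: MarkerMatrix
    blues: pd.DataFrame  # columns: cycle, trait, line, blue
    validation_cycle: int | None = None
    tbv: pd.DataFrame | None = None  # index line, one column per trait

    def __post_init__(self):
        self._geno_index = pd.Index(self.markers.line_ids)
        genotyped = self.blues["line"].isin(self._geno_index)
        self.blues = self.blues.loc[genotyped].reset_index(drop=True)

    @property
    def cycles(self) -> list[int]:
        return sorted(int(c) for c in self.blues["cycle"].unique())

    @property
    def breeding_cycles(self) -> list[int]:
        return [c for c in self.cycles if c != self.validation_cycle]

    def lines(self, cycle: int, trait) -> np.ndarray:
        """Lines of a cycle with adjusted means for every requested trait."""
        traits = [trait] if isinstance(trait, str) else list(trait)
        sub = self.blues[(self.blues["cycle"] == cycle) & (self.blues["trait"].isin(traits))]
        counts = sub.groupby("line", sort=True)["trait"].nunique()
        return counts.index[counts == len(traits)].to_numpy(dtype=object)

    def blue_vector(self, trait: str, lines) -> np.ndarray:
        sub = self.blues[self.blues["trait"] == trait].set_index("line")["blue"]
        return sub.reindex(list(lines)).to_numpy(dtype=float)

    def tbv_vector(self, trait: str, lines) -> np.ndarray | None:
        if self.tbv is None or trait not in self.tbv.columns:
            return None
        return self.tbv[trait].reindex(list(lines)).to_numpy(dtype=float)

    def codes(self, lines) -> np.ndarray:
        idx = self._geno_index.get_indexer(list(lines))
        if np.any(idx < 0):
            raise KeyError("line without genotype requested")
        return self.markers.codes[idx]

    def cycle_labels(self, lines) -> np.ndarray:
        cyc = self.blues.drop_duplicates("line").set_index("line")["cycle"]
        return cyc.reindex(list(lines)).to_numpy()


def dataset_from_simulation(pop, plots: pd.DataFrame, cycle_blues=None) -> GSData:
    """Assemble a :class:`GSData` from a simulated program.

    If ``cycle_blues`` (the output of :func:`cyclegs.pheno.analyze_cycles`)
    is omitted, balanced across-trial line means stand in for the
    stage-2 adjusted means (exact for the orthogonal design simulated
    here).  Genotypes are used as simulated; run the markers QC/impute
    pipeline beforehand for a full-fidelity analysis.
    """
    from .markers import impute_missing

    if cycle_blues is None:
        blues = line_mean_blues(plots)
    else:
        blues = dataset_from_cycle_blues_frame(cycle_blues)
    geno = pop.genotypes
    if geno.missing_mask.any():
        geno = impute_missing(geno)
    return GSData(
        markers=geno,
        blues=blues,
        validation_cycle=pop.validation_cycle,
        tbv=pop.tbv,
    )


def dataset_from_cycle_blues_frame(cycle_blues: dict) -> pd.DataFrame:
    rows = []
    for (cycle, trait), cb in cycle_blues.items():
        rows.append(
            pd.DataFrame(
                {"cycle": cycle, "trait": trait, "line": cb.blues.index, "blue": cb.blues.to_numpy()}
            )
        )
    return pd.concat(rows, ignore_index=True)


def dataset_from_cycle_blues(
    markers: MarkerMatrix,
    cycle_blues: dict[tuple[int, str], CycleBLUEs],
    validation_cycle: int | None = None,
    tbv: pd.DataFrame | None = None,
) -> GSData:
    """Build a dataset from stage-2 results keyed by (cycle, trait)."""
    return GSData(
        markers=markers,
        blues=dataset_from_cycle_blues_frame(cycle_blues),
        validation_cycle=validation_cycle,
        tbv=tbv,
    )


@dataclass
class CVResult:
    """Replicate-level accuracies for one validation scheme."""

    scheme: str
    trait: str
    train_size: int
    replicates: np.ndarray
    replicates_mt: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    @property
    def mean(self) -> float:
        return float(np.nanmean(self.replicates))

    @property
    def sd(self) -> float:
        return float(np.nanstd(self.replicates, ddof=1)) if len(self.replicates) > 1 else 0.0

    @property
    def mean_mt(self) -> float | None:
        return None if self.replicates_mt is None else float(np.nanmean(self.replicates_mt))

    def to_frame(self) -> pd.DataFrame:
        out = pd.DataFrame(
            {
                "scheme": self.scheme,
                "trait": self.trait,
                "train_size": self.train_size,
                "replicate": np.arange(len(self.replicates)),
                "r_GS": self.replicates,
            }
        )
        if self.replicates_mt is not None:
            out["r_MT"] = self.replicates_mt
        return out


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 3:
        raise ValueError("correlation needs at least 3 lines")
    if a.std() == 0 or b.std() == 0:
        return np.nan
    return float(np.corrcoef(a, b)[0, 1])


def _make_folds(rng: np.random.Generator, ids: np.ndarray, n_folds: int) -> list[np.ndarray]:
    """Random partition into near-equal folds (remainder spread one per fold)."""
    ids = np.asarray(ids, dtype=object)
    perm = rng.permutation(ids.size)
    return [ids[chunk] for chunk in np.array_split(perm, n_folds)]


def _fit_training(data: GSData, train_lines, trait: str, with_year_effect: bool = False) -> RRBLUP:
    y = data.blue_vector(trait, train_lines)
    Z = data.codes(train_lines)
    fixed = None
    if with_year_effect:
        labels = data.cycle_labels(train_lines)
        if np.unique(labels).size > 1:
            fixed = pd.get_dummies(pd.Series(labels)).to_numpy(dtype=float)[:, 1:]
    return RRBLUP().fit(Z, y, fixed=fixed)


def _default_predictor(trait: str):
    def predictor(data, train_lines, test_lines, with_year_effect):
        model = _fit_training(data, train_lines, trait, with_year_effect)
        return model.predict(data.codes(test_lines))

    return predictor


def within_cycle_cv(
    data: GSData,
    cycle: int,
    trait: str,
    n_folds: int = 5,
    reps: int = 100,
    seed: int = 0,
    pooled: bool = False,
) -> CVResult:
    """Fivefold CV inside one breeding cycle.

    Per replicate the cycle's lines are randomly partitioned into
    ``n_folds`` near-equal folds; each fold is predicted from the
    remaining folds and the per-fold accuracies are averaged (set
    ``pooled=True`` to correlate all pooled out-of-fold predictions
    instead).
    """
    lines = data.lines(cycle, trait)
    if lines.size < n_folds:
        raise ValueError(f"cycle {cycle} has fewer lines than folds")
    if lines.size // n_folds < 3:
        raise ValueError("folds would hold fewer than 3 lines; correlation undefined")
    tbv_avail = data.tbv_vector(trait, lines[:1]) is not None
    rs = np.empty(reps)
    rs_mt = np.empty(reps) if tbv_avail else None
    for rep in range(reps):
        rng = _rng(seed, "within", rep, cycle)
        folds = _make_folds(rng, lines, n_folds)
        fold_r, fold_mt, pooled_pred, pooled_obs, pooled_tbv = [], [], [], [], []
        for k, fold in enumerate(folds):
            train = np.concatenate([f for j, f in enumerate(folds) if j != k])
            model = _fit_training(data, train, trait)
            pred = model.predict(data.codes(fold))
            obs = data.blue_vector(trait, fold)
            fold_r.append(_pearson(pred, obs))
            pooled_pred.append(pred)
            pooled_obs.append(obs)
            if tbv_avail:
                tv = data.tbv_vector(trait, fold)
                fold_mt.append(_pearson(pred, tv))
                pooled_tbv.append(tv)
        if pooled:
            rs[rep] = _pearson(np.concatenate(pooled_pred), np.concatenate(pooled_obs))
            if tbv_avail:
                rs_mt[rep] = _pearson(np.concatenate(pooled_pred), np.concatenate(pooled_tbv))
        else:
            rs[rep] = float(np.nanmean(fold_r))
            if tbv_avail:
                rs_mt[rep] = float(np.nanmean(fold_mt))
    return CVResult(
        scheme="within_cycle",
        trait=trait,
        train_size=int(round(lines.size * (n_folds - 1) / n_folds)),
        replicates=rs,
        replicates_mt=rs_mt,
        meta={"cycle": cycle, "n_folds": n_folds, "seed": seed},
    )


@dataclass
class BiasResult:
    within: CVResult
    between: dict[int, CVResult]
    bias_pct: dict[int, float]  # NaN where undefined (r_between <= 0)

    @property
    def defined(self) -> dict[int, bool]:
        return {c: np.isfinite(v) for c, v in self.bias_pct.items()}


def bias_percent(r_within: float, r_between: float) -> float:
    """Relative bias ``(r_within - r_between) / r_between * 100``.

    Positive values mean within-cycle CV overestimates.  Undefined
    (NaN) when the between-cycle accuracy is not positive.
    """
    if not np.isfinite(r_between) or r_between <= 0:
        return np.nan
    return (r_within - r_between) / r_between * 100.0


def between_cycle_bias(
    data: GSData,
    train_cycle: int,
    trait: str,
    n_folds: int = 5,
    reps: int = 100,
    seed: int = 0,
) -> BiasResult:
    """Within- vs between-cycle accuracy using identical training folds.

    The training populations of :func:`within_cycle_cv` (same master
    seed, bit-identical folds) additionally predict every other breeding
    cycle; the bias per target cycle is the relative excess of the
    within-cycle accuracy.
    """
    others = [c for c in data.breeding_cycles if c != train_cycle]
    if not others:
        raise ValueError("between-cycle bias needs >= 2 cycles")
    lines = data.lines(train_cycle, trait)
    if lines.size // n_folds < 3:
        raise ValueError("folds would hold fewer than 3 lines")
    other_lines = {c: data.lines(c, trait) for c in others}
    other_obs = {c: data.blue_vector(trait, other_lines[c]) for c in others}
    r_within = np.empty(reps)
    r_between = {c: np.empty(reps) for c in others}
    for rep in range(reps):
        rng = _rng(seed, "within", rep, train_cycle)
        folds = _make_folds(rng, lines, n_folds)
        fold_within = []
        fold_between = {c: [] for c in others}
        for k, fold in enumerate(folds):
            train = np.concatenate([f for j, f in enumerate(folds) if j != k])
            model = _fit_training(data, train, trait)
            fold_within.append(_pearson(model.predict(data.codes(fold)), data.blue_vector(trait, fold)))
            for c in others:
                pred = model.predict(data.codes(other_lines[c]))
                fold_between[c].append(_pearson(pred, other_obs[c]))
        r_within[rep] = float(np.nanmean(fold_within))
        for c in others:
            r_between[c][rep] = float(np.nanmean(fold_between[c]))
    within = CVResult(
        "within_cycle", trait, int(round(lines.size * (n_folds - 1) / n_folds)), r_within,
        meta={"cycle": train_cycle, "seed": seed},
    )
    between = {
        c: CVResult(
            "between_cycle", trait, within.train_size, r_between[c],
            meta={"train_cycle": train_cycle, "target_cycle": c, "seed": seed},
        )
        for c in others
    }
    bias = {c: bias_percent(within.mean, between[c].mean) for c in others}
    return BiasResult(within=within, between=between, bias_pct=bias)


def across_cycle_cv(
    data: GSData,
    trait: str,
    train_size_total: int,
    reps: int = 100,
    seed: int = 0,
    with_year_effect: bool = True,
    exclude: tuple[int, ...] = (),
    predictor=None,
    predictor_traits=None,
) -> CVResult:
    """Cross-validation with the breeding cycles as folds.

    Per replicate and held-out cycle, ``train_size_total / n_training``
    lines are sampled from every other (non-excluded) cycle, a model
    with fixed cycle effects is trained, and the entire held-out cycle
    is predicted.  The replicate value is the mean accuracy over the
    held-out cycles.  ``exclude`` removes cycles from both the training
    and the held-out role (the outlier-corrected scheme).
    """
    if train_size_total <= 0:
        raise ValueError("train_size_total must be positive")
    cycles = [c for c in data.breeding_cycles if c not in exclude]
    if len(cycles) < 2:
        raise ValueError("across-cycle CV needs >= 2 usable cycles")
    n_train_cycles = len(cycles) - 1
    if train_size_total % n_train_cycles:
        raise ValueError(
            f"train_size_total={train_size_total} not divisible by {n_train_cycles} training cycles"
        )
    quota = train_size_total // n_train_cycles
    sample_traits = predictor_traits or [trait]
    cycle_lines = {c: data.lines(c, sample_traits) for c in cycles}
    for c in cycles:
        if cycle_lines[c].size < quota:
            raise ValueError(f"cycle {c} has {cycle_lines[c].size} lines, fewer than the quota {quota}")
    predictor = predictor or _default_predictor(trait)
    tbv_avail = data.tbv is not None and trait in getattr(data.tbv, "columns", [])
    rs = np.empty(reps)
    rs_mt = np.empty(reps) if tbv_avail else None
    for rep in range(reps):
        fold_r, fold_mt = [], []
        for held in cycles:
            rng = _rng(seed, "across", rep, held)
            train = np.concatenate(
                [rng.choice(cycle_lines[c], size=quota, replace=False) for c in cycles if c != held]
            )
            test = data.lines(held, trait)
            pred = predictor(data, train, test, with_year_effect)
            fold_r.append(_pearson(pred, data.blue_vector(trait, test)))
            if tbv_avail:
                fold_mt.append(_pearson(pred, data.tbv_vector(trait, test)))
        rs[rep] = float(np.nanmean(fold_r))
        if tbv_avail:
            rs_mt[rep] = float(np.nanmean(fold_mt))
    return CVResult(
        scheme="across_cycle" if not exclude else "outlier_corrected",
        trait=trait,
        train_size=train_size_total,
        replicates=rs,
        replicates_mt=rs_mt,
        meta={"seed": seed, "exclude": tuple(exclude), "with_year_effect": with_year_effect},
    )


def outlier_corrected_cv(
    data: GSData,
    excluded_units: tuple[int, ...],
    train_size_total: int,
    trait: str,
    reps: int = 100,
    seed: int = 0,
    **kwargs,
) -> CVResult:
    """Across-cycle CV with outlier cycles dropped, total size unchanged.

    The per-cycle quota is re-divided equally over the remaining
    training cycles.  Excluded cycles are removed from both the
    training and the validation role.
    """
    return across_cycle_cv(
        data, trait, train_size_total, reps=reps, seed=seed, exclude=tuple(excluded_units), **kwargs
    )


def pairwise_cycle_matrix(
    data: GSData,
    trait: str,
    reps_diag: int = 20,
    n_folds: int = 5,
    seed: int = 0,
) -> pd.DataFrame:
    """Train-on-cycle-a, predict-cycle-b accuracy matrix.

    Off-diagonal entries use all lines of the training cycle
    (deterministic); the diagonal holds the within-cycle CV mean.  The
    matrix is not symmetric in general.
    """
    cycles = data.breeding_cycles
    if len(cycles) < 2:
        raise ValueError("need >= 2 cycles")
    M = pd.DataFrame(np.nan, index=cycles, columns=cycles, dtype=float)
    models = {}
    for a in cycles:
        try:
            models[a] = _fit_training(data, data.lines(a, trait), trait)
        except Exception as exc:  # keep going, flag the cell
            warnings.warn(f"training on cycle {a} failed: {exc}", UserWarning, stacklevel=2)
    for a in cycles:
        if a not in models:
            continue
        for b in cycles:
            if a == b:
                continue
            test = data.lines(b, trait)
            M.loc[a, b] = _pearson(models[a].predict(data.codes(test)), data.blue_vector(trait, test))
    for a in cycles:
        M.loc[a, a] = within_cycle_cv(data, a, trait, n_folds=n_folds, reps=reps_diag, seed=seed).mean
    return M


def identify_outliers(matrix: pd.DataFrame, rule_threshold_sd: float = 1.0) -> list:
    """Flag units whose mean off-diagonal accuracy as a *training* set
    falls below (overall mean - ``rule_threshold_sd`` x sd) of the
    row means."""
    if matrix.shape[0] < 3:
        raise ValueError("need >= 3 units to define an outlier distribution")
    M = matrix.to_numpy(dtype=float).copy()
    np.fill_diagonal(M, np.nan)
    row_means = np.nanmean(M, axis=1)
    cutoff = np.nanmean(row_means) - rule_threshold_sd * np.nanstd(row_means, ddof=1)
    return [u for u, rm in zip(matrix.index, row_means) if rm < cutoff]


def identify_outlier_trials(matrix: pd.DataFrame, rule_threshold_sd: float = 1.0) -> list:
    """Trial-level variant: additionally flags trials whose mean accuracy
    as a training set is negative."""
    flagged = set(identify_outliers(matrix, rule_threshold_sd))
    M = matrix.to_numpy(dtype=float).copy()
    np.fill_diagonal(M, np.nan)
    row_means = np.nanmean(M, axis=1)
    for u, rm in zip(matrix.index, row_means):
        if rm < 0:
            flagged.add(u)
    return sorted(flagged, key=list(matrix.index).index)


def selection_proportion(gebv: pd.Series, blue: pd.Series, q: float, direction: str = "best") -> float:
    """Share of the truly best (or worst) fraction ``q`` recovered by GEBV.

    ``|top_q(GEBV) ∩ top_q(BLUE)| / |top_q(BLUE)|``; ties broken by
    line id so the result is deterministic.
    """
    if not 0 < q <= 1:
        raise ValueError("q must lie in (0, 1]")
    if direction not in {"best", "worst"}:
        raise ValueError("direction must be 'best' or 'worst'")
    idx = gebv.index.intersection(blue.index)
    gebv, blue = gebv.loc[idx], blue.loc[idx]
    n_sel = max(1, int(round(q * len(idx))))
    asc = direction == "worst"

    def top(s: pd.Series) -> set:
        order = s.to_frame("v").reset_index(names="line").sort_values(
            ["v", "line"], ascending=[asc, True]
        )
        return set(order["line"].head(n_sel))

    return len(top(gebv) & top(blue)) / n_sel


def independent_validation(
    data: GSData,
    training_cycles,
    validation_cycle: int,
    trait: str,
    corrections: dict[str, tuple] | None = None,
    q_grid: tuple[float, ...] = (0.1, 0.2, 0.3),
    with_year_effect: bool = True,
) -> pd.DataFrame:
    """Predict an untouched validation cycle from full and corrected
    training sets; report accuracy and selection proportions.

    ``corrections`` maps a label to the cycles excluded from training;
    the full training set is always reported under label ``"full"``.
    """
    training_cycles = [c for c in training_cycles]
    if validation_cycle in training_cycles:
        raise ValueError("validation cycle overlaps the training cycles")
    val_lines = data.lines(validation_cycle, trait)
    train_all = {c: data.lines(c, trait) for c in training_cycles}
    overlap = set(np.concatenate(list(train_all.values()))) & set(val_lines)
    if overlap:
        raise ValueError(f"lines shared between training and validation: {sorted(overlap)[:5]}")
    blue_val = pd.Series(data.blue_vector(trait, val_lines), index=val_lines)
    arms = {"full": tuple()}
    arms.update({k: tuple(v) for k, v in (corrections or {}).items()})
    rows = []
    for label, excluded in arms.items():
        keep = [c for c in training_cycles if c not in excluded]
        train = np.concatenate([train_all[c] for c in keep])
        model = _fit_training(data, train, trait, with_year_effect=with_year_effect)
        gebv = pd.Series(model.predict(data.codes(val_lines)), index=val_lines)
        row = {
            "correction": label,
            "n_train": train.size,
            "r_GS": _pearson(gebv.to_numpy(), blue_val.to_numpy()),
        }
        tv = data.tbv_vector(trait, val_lines)
        if tv is not None:
            row["r_MT"] = _pearson(gebv.to_numpy(), tv)
        for q in q_grid:
            for direction in ("best", "worst"):
                row[f"prop_{direction}_q{int(round(q * 100))}"] = selection_proportion(
                    gebv, blue_val, q, direction
                )
        rows.append(row)
    return pd.DataFrame(rows)


def relatedness_accuracy_correlation(
    data: GSData,
    K: KinshipMatrix,
    trait: str,
    k_values=(1, 2, 5, 10, 20, 50, 70, 100, 200, 500),
    with_year_effect: bool = True,
) -> pd.DataFrame:
    """Correlate top-k relatedness with per-line accuracy ``r_PEV``.

    Leave-one-cycle-out: for every validation line, the mean of its k
    largest kinship coefficients to the training lines is correlated
    (across validation lines) with the PEV-based accuracy of that line
    under a G-BLUP fit on the training cycles.
    """
    rows = []
    for held in data.breeding_cycles:
        train = np.concatenate([data.lines(c, trait) for c in data.breeding_cycles if c != held])
        val = data.lines(held, trait)
        idx_t = K.indexer(train)
        idx_v = K.indexer(val)
        K_tt = K.K[np.ix_(idx_t, idx_t)]
        K_vt = K.K[np.ix_(idx_v, idx_t)]
        k_diag_v = K.diagonal[idx_v]
        y = data.blue_vector(trait, train)
        fixed = None
        labels = data.cycle_labels(train)
        if with_year_effect and np.unique(labels).size > 1:
            fixed = pd.get_dummies(pd.Series(labels)).to_numpy(dtype=float)[:, 1:]
        model = GBLUP(compute_pev=True).fit(K_tt, y, fixed=fixed)
        _, pev_v = model.predict_with_pev(K_vt, k_diag_v)
        r_pev = line_accuracy_rpev(pev_v, k_diag_v, model.sigma2_G_)
        sorted_kin = -np.sort(-K_vt, axis=1)  # descending per validation line
        for k in k_values:
            kk = int(k)
            if kk > train.size:
                warnings.warn(f"k={kk} exceeds training size {train.size}; truncated", UserWarning, stacklevel=2)
                kk = train.size
            topk = sorted_kin[:, :kk].mean(axis=1)
            rows.append(
                {
                    "held_cycle": held,
                    "k": int(k),
                    "k_used": kk,
                    "pearson_r": _pearson(topk, r_pev),
                    "sigma2_G": model.sigma2_G_,
                }
            )
    return pd.DataFrame(rows)
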