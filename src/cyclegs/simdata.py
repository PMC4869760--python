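"""Synthetic multi-cycle breeding program generator.

Emulates the data structure of a commercial winter-wheat line breeding
program: several breeding cycles (cohorts entering yield testing in
successive years) of inbred lines derived by selfing or doubled
haploids, genotyped with biallelic SNP markers, and phenotyped in
multi-location trials where unreplicated candidate lines are grown
alongside replicated check varieties.

Key statistical features reproduced:

* cycles are genetically linked (parents drawn preferentially from the
  previous cycle) so within-cycle kinship exceeds between-cycle kinship;
* three traits — grain yield (dt/ha), protein content (%), and the
  derived trait protein yield = grain yield x protein content / 100 —
  with a configurable negative genetic correlation between yield and
  protein realised through overlapping QTL;
* per-cycle year effects, trial main effects, genotype-by-trial
  interaction calibrated to hit a target across-trial heritability,
  optional row/column spatial trends, and plot residual noise;
* designated outlier trials whose genetic signal is sign-flipped,
  producing a negative phenotypic correlation with sibling trials;
* true breeding values (TBV) retained for every line so prediction
  accuracy against truth is computable.

Everything is deterministic given the config seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .markers import MarkerMatrix

__all__ = [
    "TRAITS",
    "ProgramConfig",
    "TruePopulation",
    "default_config",
    "small_config",
    "simulate_genotypes",
    "simulate_phenotypes",
    "simulate_program",
    "write_phenotypes_csv",
    "write_truth_csv",
]

GRAIN_YIELD = "grain_yield"
PROTEIN_CONTENT = "protein_content"
PROTEIN_YIELD = "protein_yield"
TRAITS = (GRAIN_YIELD, PROTEIN_CONTENT, PROTEIN_YIELD)

#: component traits simulated from QTL; protein yield is derived per plot
_COMPONENT_TRAITS = (GRAIN_YIELD, PROTEIN_CONTENT)

# stage-2 fixed residual constants of the companion analysis; used here to
# account for the share of plot error that the across-trial model will
# attribute to genotype-by-trial interaction (see pheno.fit_stage2)
_STAGE2_RESID_SCALE = {GRAIN_YIELD: 1.0, PROTEIN_CONTENT: 0.1, PROTEIN_YIELD: 0.1}

# substream labels for the single master seed
_S_GENO, _S_QTL, _S_PHENO, _S_MISSING = 1, 2, 3, 4


class ConfigError(ValueError):
    """Invalid simulation configuration; the message names the field."""


@dataclass
class ProgramConfig:
    """Configuration of the simulated breeding program.

    Defaults describe a five-cycle program of 659 lines (64-176 per
    cycle) with an independent 178-line validation cycle, 2-8 trials per
    cycle and per-trait heritability targets spanning roughly 0.14-0.84
    across cycles — the magnitudes typical of multi-environment wheat
    trials.  ``target_h2`` entries may be scalars (all cycles) or one
    value per cycle including the validation cycle.
    """

    n_cycles: int = 5
    lines_per_cycle: tuple[int, ...] = (94, 64, 165, 160, 176)
    n_validation_lines: int = 178
    n_founders: int = 30
    n_markers: int = 1000
    n_qtl_per_trait: int = 100
    family_size: int = 8
    trait_means: dict = field(default_factory=lambda: {GRAIN_YIELD: 80.0, PROTEIN_CONTENT: 14.0})
    genetic_var: dict = field(default_factory=lambda: {GRAIN_YIELD: 6.0, PROTEIN_CONTENT: 0.30})
    target_h2: dict = field(
        default_factory=lambda: {
            GRAIN_YIELD: (0.32, 0.54, 0.53, 0.45, 0.84, 0.57),
            PROTEIN_CONTENT: (0.72, 0.84, 0.80, 0.69, 0.50, 0.70),
        }
    )
    trials_per_cycle: tuple[int, ...] = (5, 6, 4, 5, 8, 4)
    gxe_variance_ratio: float | None = None
    residual_sd: dict = field(default_factory=lambda: {GRAIN_YIELD: 2.0, PROTEIN_CONTENT: 0.45})
    year_effect_sd: dict = field(default_factory=lambda: {GRAIN_YIELD: 5.0, PROTEIN_CONTENT: 0.8})
    trial_effect_sd: dict = field(default_factory=lambda: {GRAIN_YIELD: 3.0, PROTEIN_CONTENT: 0.5})
    spatial_sd: dict = field(default_factory=lambda: {GRAIN_YIELD: 1.0, PROTEIN_CONTENT: 0.15})
    n_checks: int = 3
    check_reps: int = 3
    outlier_trial_spec: tuple[tuple[int, int, int], ...] = ()
    cycle_specific_genetic_frac: float = 0.4
    genetic_corr_gy_pc: float = -0.3
    qtl_overlap: float = 0.5
    missing_rate: float = 0.05
    selfing_generations: int = 6
    doubled_haploid: bool = False
    prev_cycle_parent_frac: float = 0.7
    seed: int = 42

    @property
    def n_total_cycles(self) -> int:
        """Breeding cycles plus the validation cycle, if any."""
        return self.n_cycles + (1 if self.n_validation_lines > 0 else 0)

    @property
    def all_cycle_sizes(self) -> tuple[int, ...]:
        sizes = tuple(self.lines_per_cycle)
        if self.n_validation_lines > 0:
            sizes = sizes + (self.n_validation_lines,)
        return sizes

    def h2_for(self, trait: str, cycle: int) -> float:
        v = self.target_h2.get(trait, 0.5)
        if np.isscalar(v):
            return float(v)
        v = tuple(v)
        return float(v[min(cycle, len(v) - 1)])

    def validate(self) -> None:
        if len(self.lines_per_cycle) != self.n_cycles:
            raise ConfigError("lines_per_cycle: length must equal n_cycles")
        if len(self.trials_per_cycle) < self.n_total_cycles:
            raise ConfigError("trials_per_cycle: need one entry per cycle (incl. validation)")
        if self.n_founders < 4:
            raise ConfigError("n_founders: must be >= 4")
        if self.n_markers < 10:
            raise ConfigError("n_markers: must be >= 10")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ConfigError("missing_rate: must lie in [0, 1)")
        if not -1.0 <= self.genetic_corr_gy_pc <= 1.0:
            raise ConfigError("genetic_corr_gy_pc: must lie in [-1, 1]")
        if not 0.0 <= self.qtl_overlap <= 1.0:
            raise ConfigError("qtl_overlap: must lie in [0, 1]")
        if any(t < 1 for t in self.trials_per_cycle[: self.n_total_cycles]):
            raise ConfigError("trials_per_cycle: every entry must be positive")
        if self.gxe_variance_ratio is not None and self.gxe_variance_ratio < 0:
            raise ConfigError("gxe_variance_ratio: must be >= 0")
        for trait, v in self.target_h2.items():
            arr = np.atleast_1d(np.asarray(v, dtype=float))
            if np.any((arr < 0) | (arr > 1)):
                raise ConfigError(f"target_h2[{trait}]: values must lie in [0, 1]")


def default_config(**overrides) -> ProgramConfig:
    """Full-size program (659 lines + 178 validation lines)."""
    return replace(ProgramConfig(), **overrides)


def small_config(**overrides) -> ProgramConfig:
    """Desk-scale program for tests and quick studies.

    Five cycles of 32 lines plus a 36-line validation cycle, 240
    markers, 3 trials per cycle.
    """
    base = ProgramConfig(
        n_cycles=5,
        lines_per_cycle=(32, 32, 32, 32, 32),
        n_validation_lines=36,
        n_founders=16,
        n_markers=240,
        n_qtl_per_trait=40,
        family_size=8,
        trials_per_cycle=(3, 3, 3, 3, 3, 3),
        target_h2={GRAIN_YIELD: 0.5, PROTEIN_CONTENT: 0.8},
    )
    return replace(base, **overrides)


@dataclass
class TruePopulation:
    """Simulated genotypes with the truth needed for validation.

    ``tbv`` holds per-line true breeding values: deviations for the
    component traits, and for protein yield the product
    ``(mean_gy + tbv_gy) * (mean_pc + tbv_pc) / 100`` on the natural
    scale.  ``qtl`` maps each component trait to its (marker indices,
    scaled effects, offset) so TBV is reproducible from the genotypes.
    """

    genotypes: MarkerMatrix
    cycle_of: pd.Series
    family_of: pd.Series
    tbv: pd.DataFrame
    qtl: dict
    check_values: pd.DataFrame
    true_codes: np.ndarray  # unmasked genotype codes (lines x markers)
    config: ProgramConfig

    def lines_in_cycle(self, cycle: int) -> np.ndarray:
        return self.cycle_of.index[self.cycle_of.to_numpy() == cycle].to_numpy(dtype=object)

    @property
    def validation_cycle(self) -> int | None:
        return self.config.n_cycles if self.config.n_validation_lines > 0 else None


def _self_down(f1: np.ndarray, rng: np.random.Generator, generations: int, dh: bool) -> np.ndarray:
    """Collapse heterozygous F1 loci by selfing (marginal distribution).

    After ``g`` selfing generations a locus heterozygous in the F1 is
    still heterozygous with probability ``2^-g`` and otherwise fixed for
    either allele with equal probability; doubled haploids fix
    immediately.  Loci are unlinked, so per-locus sampling is exact.
    """
    out = f1.copy()
    het = out == 0.0
    n_het = int(het.sum())
    if n_het == 0:
        return out
    if dh:
        stay = np.zeros(n_het, dtype=bool)
    else:
        stay = rng.random(n_het) < 0.5**generations
    fixed = np.where(rng.random(n_het) < 0.5, -1.0, 1.0)
    resolved = np.where(stay, 0.0, fixed)
    out[het] = resolved
    return out


def simulate_genotypes(config: ProgramConfig) -> TruePopulation:
    """Simulate genotypes and true breeding values for all cycles.

    Founder lines are fully inbred with allele frequencies drawn from
    Uniform(0.1, 0.9).  Each later line descends from a biparental cross
    whose parents come preferentially from the previous cycle, followed
    by single-seed descent (or DH) to near-homozygosity.  Missing calls
    are masked at ``missing_rate``.
    """
    config.validate()
    rng_g = np.random.default_rng([config.seed, _S_GENO])
    rng_q = np.random.default_rng([config.seed, _S_QTL])
    rng_m = np.random.default_rng([config.seed, _S_MISSING])
    M = config.n_markers

    p0 = rng_g.uniform(0.1, 0.9, size=M)
    founders = np.where(rng_g.random((config.n_founders, M)) < p0, 1.0, -1.0)

    sizes = config.all_cycle_sizes
    codes, line_ids, cyc_idx, fam_ids = [], [], [], []
    prev_pool = founders
    for c, n_lines in enumerate(sizes):
        n_fam = max(1, int(np.ceil(n_lines / config.family_size)))
        fam_sizes = np.full(n_fam, n_lines // n_fam)
        fam_sizes[: n_lines % n_fam] += 1
        cycle_rows = []
        for f, fs in enumerate(fam_sizes):
            if c == 0:
                pool1 = pool2 = founders
            else:
                pool1 = prev_pool if rng_g.random() < config.prev_cycle_parent_frac else founders
                pool2 = prev_pool if rng_g.random() < config.prev_cycle_parent_frac else founders
            par1 = pool1[rng_g.integers(pool1.shape[0])]
            par2 = pool2[rng_g.integers(pool2.shape[0])]
            for _ in range(fs):
                a1 = np.where(par1 == 0.0, np.where(rng_g.random(M) < 0.5, -1.0, 1.0), par1)
                a2 = np.where(par2 == 0.0, np.where(rng_g.random(M) < 0.5, -1.0, 1.0), par2)
                f1 = np.sign(a1 + a2)  # equal alleles keep sign, unequal -> 0
                child = _self_down(f1, rng_g, config.selfing_generations, config.doubled_haploid)
                cycle_rows.append(child)
                fam_ids.append(f"C{c}F{f}")
        block = np.vstack(cycle_rows)
        codes.append(block)
        line_ids.extend(f"C{c}_L{i:03d}" for i in range(n_lines))
        cyc_idx.extend([c] * n_lines)
        prev_pool = block

    true_codes = np.vstack(codes)
    line_ids = np.asarray(line_ids, dtype=object)

    # trait architecture: overlapping QTL with correlated effects
    n_qtl = min(config.n_qtl_per_trait, M)
    n_shared = int(round(config.qtl_overlap * n_qtl))
    all_idx = rng_q.permutation(M)
    shared = all_idx[:n_shared]
    own_gy = all_idx[n_shared : n_shared + (n_qtl - n_shared)]
    own_pc = all_idx[n_shared + (n_qtl - n_shared) : n_shared + 2 * (n_qtl - n_shared)]
    # only shared QTL contribute covariance, so the effect-draw correlation
    # is inflated by the overlap fraction to realise the target genome-wide
    rho = config.genetic_corr_gy_pc
    if config.qtl_overlap > 0:
        rho = float(np.clip(rho / config.qtl_overlap, -0.99, 0.99))
    cov = np.array([[1.0, rho], [rho, 1.0]])
    eff_shared = rng_q.multivariate_normal(np.zeros(2), cov, size=n_shared)
    qtl = {}
    tbv = {}
    for t, (own, col) in {GRAIN_YIELD: (own_gy, 0), PROTEIN_CONTENT: (own_pc, 1)}.items():
        idx = np.concatenate([shared, own]).astype(int)
        eff = np.concatenate([eff_shared[:, col], rng_q.standard_normal(own.size)])
        raw = true_codes[:, idx] @ eff
        sd = raw.std()
        scale = np.sqrt(config.genetic_var[t]) / sd if sd > 0 else 0.0
        eff = eff * scale
        offset = -float(raw.mean() * scale)
        qtl[t] = {"indices": idx, "effects": eff, "offset": offset}
        tbv[t] = true_codes[:, idx] @ eff + offset

    tbv_df = pd.DataFrame(tbv, index=line_ids)
    tbv_df[PROTEIN_YIELD] = (
        (config.trait_means[GRAIN_YIELD] + tbv_df[GRAIN_YIELD])
        * (config.trait_means[PROTEIN_CONTENT] + tbv_df[PROTEIN_CONTENT])
        / 100.0
    )
    tbv_df.index.name = "line"

    check_ids = [f"CHK{i+1}" for i in range(config.n_checks)]
    chk = {
        t: rng_q.normal(0.0, np.sqrt(config.genetic_var[t]), size=config.n_checks)
        for t in _COMPONENT_TRAITS
    }
    check_values = pd.DataFrame(chk, index=pd.Index(check_ids, name="line"))

    observed = true_codes.copy()
    if config.missing_rate > 0:
        mask = rng_m.random(observed.shape) < config.missing_rate
        observed[mask] = np.nan

    marker_ids = np.asarray([f"M{k:04d}" for k in range(M)], dtype=object)
    geno = MarkerMatrix(line_ids, marker_ids, observed)
    return TruePopulation(
        genotypes=geno,
        cycle_of=pd.Series(cyc_idx, index=line_ids, name="cycle"),
        family_of=pd.Series(fam_ids, index=line_ids, name="family"),
        tbv=tbv_df,
        qtl=qtl,
        check_values=check_values,
        true_codes=true_codes,
        config=config,
    )


def _gxt_variance(config: ProgramConfig, trait: str, cycle: int, sigma2_g: float, n_trials: int) -> float:
    """Interaction variance that realises the target across-trial h2.

    Solves ``h2 = s2_G / (s2_G + s2_GT_eff / t)`` for the effective
    interaction variance seen by the weighted stage-2 analysis, then
    subtracts the share of plot error that the fixed stage-2 residual
    constant leaves to be absorbed by the interaction term.
    """
    if config.gxe_variance_ratio is not None:
        return config.gxe_variance_ratio * sigma2_g
    h2 = config.h2_for(trait, cycle)
    sigma2_e = config.residual_sd.get(trait, 0.0) ** 2
    leak = (1.0 - _STAGE2_RESID_SCALE[trait]) * sigma2_e
    if h2 <= 0.0:
        return sigma2_g  # genetic effect is dropped; keep a noise floor
    if h2 >= 1.0:
        return 0.0
    target = n_trials * sigma2_g * (1.0 / h2 - 1.0)
    return max(target - leak, 0.0)


def simulate_phenotypes(pop: TruePopulation, config: ProgramConfig | None = None) -> pd.DataFrame:
    """Simulate plot-level phenotypes for every cycle and trial.

    Returns a long-format plot table with columns ``cycle, trial, line,
    is_check, row, col, trait, value``.  Candidate lines are grown once
    per trial, checks ``check_reps`` times.  Protein yield is derived
    per plot as grain yield x protein content / 100.
    """
    config = config or pop.config
    for t in _COMPONENT_TRAITS:
        if t not in config.trait_means:
            raise ConfigError(f"trait_means[{t}]: unknown trait or missing mean")
    rng = np.random.default_rng([config.seed, _S_PHENO])
    outliers = {(int(c), int(j)): int(s) for c, j, s in config.outlier_trial_spec}
    records = []
    for c in range(config.n_total_cycles):
        lines = pop.lines_in_cycle(c)
        n_trials = config.trials_per_cycle[c]
        checks = pop.check_values.index.to_numpy(dtype=object)
        entry_ids = np.concatenate([lines, np.repeat(checks, config.check_reps)])
        is_check = np.concatenate(
            [np.zeros(lines.size, dtype=bool), np.ones(checks.size * config.check_reps, dtype=bool)]
        )
        n_plots = entry_ids.size
        n_col = int(np.ceil(np.sqrt(n_plots)))
        n_row = int(np.ceil(n_plots / n_col))

        line_rows = pd.Index(pop.tbv.index).get_indexer(lines)
        per_trait = {}
        for t in _COMPONENT_TRAITS:
            g_line = pop.tbv[t].reindex(lines).to_numpy()
            sigma2_g = float(np.var(g_line))
            h2 = config.h2_for(t, c)
            gmult = 0.0 if h2 <= 0.0 else 1.0
            s2_gt = _gxt_variance(config, t, c, sigma2_g, n_trials)
            year = rng.normal(0.0, config.year_effect_sd.get(t, 0.0))
            # cycle-specific heritable deviation: marker-driven genetic
            # effects expressed in every trial of this cycle but not
            # transferable to other cycles (genetically structured
            # genotype-by-year interaction)
            frac = config.cycle_specific_genetic_frac
            if frac > 0 and gmult > 0:
                q = pop.qtl[t]
                a_c = rng.standard_normal(q["indices"].size)
                g_cyc = pop.true_codes[np.ix_(line_rows, q["indices"])] @ a_c
                sd = g_cyc.std()
                g_cyc = g_cyc * (frac * np.sqrt(sigma2_g) / sd) if sd > 0 else g_cyc
                g_cyc_chk = rng.normal(0.0, frac * np.sqrt(sigma2_g), size=config.n_checks)
            else:
                g_cyc = np.zeros(lines.size)
                g_cyc_chk = np.zeros(config.n_checks)
            g_all = np.concatenate([g_line + g_cyc, np.repeat(pop.check_values[t].to_numpy() + g_cyc_chk, config.check_reps)])
            per_trait[t] = (g_all, gmult, s2_gt, year)

        for j in range(n_trials):
            sign = outliers.get((c, j), 1)
            perm = rng.permutation(n_plots)
            rows = perm // n_col
            cols = perm % n_col
            vals = {}
            for t in _COMPONENT_TRAITS:
                g_all, gmult, s2_gt, year = per_trait[t]
                tau = rng.normal(0.0, config.trial_effect_sd.get(t, 0.0))
                # one interaction draw per entry (replicated checks share it)
                gxt_entry = rng.normal(0.0, np.sqrt(s2_gt), size=lines.size + config.n_checks)
                gxt = np.concatenate(
                    [gxt_entry[: lines.size], np.repeat(gxt_entry[lines.size :], config.check_reps)]
                )
                ssd = config.spatial_sd.get(t, 0.0)
                row_eff = rng.normal(0.0, ssd, size=n_row) if ssd > 0 else np.zeros(n_row)
                col_eff = rng.normal(0.0, ssd, size=n_col) if ssd > 0 else np.zeros(n_col)
                eps = rng.normal(0.0, config.residual_sd.get(t, 0.0), size=n_plots)
                genetic = sign * (gmult * g_all + gxt)
                vals[t] = (
                    config.trait_means[t] + year + tau + genetic + row_eff[rows] + col_eff[cols] + eps
                )
            vals[PROTEIN_YIELD] = vals[GRAIN_YIELD] * vals[PROTEIN_CONTENT] / 100.0
            trial_id = f"C{c}T{j}"
            for t in TRAITS:
                records.append(
                    pd.DataFrame(
                        {
                            "cycle": c,
                            "trial": trial_id,
                            "line": entry_ids,
                            "is_check": is_check,
                            "row": rows,
                            "col": cols,
                            "trait": t,
                            "value": vals[t],
                        }
                    )
                )
    return pd.concat(records, ignore_index=True)


def simulate_program(config: ProgramConfig) -> tuple[TruePopulation, pd.DataFrame]:
    """Convenience wrapper: genotypes + phenotypes in one call."""
    pop = simulate_genotypes(config)
    return pop, simulate_phenotypes(pop, config)


def write_phenotypes_csv(plots: pd.DataFrame, path) -> None:
    plots.to_csv(path, index=False)


def write_truth_csv(pop: TruePopulation, path) -> None:
    long = pop.tbv.reset_index().melt(id_vars="line", var_name="trait", value_name="tbv")
    long.to_csv(path, index=False)
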