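# Methods

## Scope and model overview

`cyclegs` analyses genomic selection in a line breeding program whose
material arrives in *breeding cycles*: non-overlapping cohorts of inbred
lines entering multi-environment yield testing in successive years.  The
pipeline has four statistical layers:

1. **Stage-1 trial analysis.**  Each trial (one location-by-cycle
   combination) is analysed separately with line as a fixed effect.
   Candidate models {baseline, +random row, +random column, +random
   row+column} share the fixed part and are compared by REML AIC; the
   winner supplies line BLUEs and standard errors.  The trial
   heritability is the entry-mean form h² = σ²G / (σ²G + MVD/2), where
   σ²G comes from a companion fit with line random and MVD is the mean
   variance of a difference of BLUEs.  Autoregressive (AR1×AR1)
   residual structures are out of scope; the row/column random-effect
   family exercises the same AIC-selection and weighting flow and is a
   documented limitation.
2. **Stage-2 across-trial analysis.**  Per cycle and trait, stage-1
   BLUEs enter y_ij = μ + g_i + t_j + gt_ij + e with trial fixed, line
   and line-by-trial random, per-observation weights 1/se², and the
   residual variance *fixed* to 1 (grain yield) or 0.1 (protein
   content, protein yield).  Fixing the residual is what separates σ²GT
   from the residual when each line-by-trial cell holds one adjusted
   mean.  The across-trial heritability is h² = σ²G / (σ²G + σ²GT/t).
   Trials with stage-1 h² ≤ 0.3 are dropped (strict inequality).
   Stage-2 adjusted means come from a GLS refit with line fixed at the
   estimated variance components; a random-effect back-solve is
   available behind a flag.
3. **Genomic prediction.**  RR-BLUP (y = Xb + Zu + e, u ~ N(0, Iσ²u),
   markers coded −1/0/+1) and G-BLUP (y = Xb + g + e, g ~ N(0, Kσ²G))
   with K = WWᵀ / (2Σ p_k(1−p_k)) from column-centered markers.  REML
   uses the spectral decomposition of the kernel with the residual
   variance profiled out, so a single bounded 1-D search over the
   log variance ratio gives the exact restricted-likelihood optimum.
   Per-line accuracies come from the prediction error variance:
   r_PEV = √(1 − PEV/(G_ii σ²G)).
4. **Validation schemes.**  Fivefold within-cycle CV; between-cycle
   prediction reusing the *same* training folds (bias = relative excess
   of the within-cycle accuracy, undefined when the between-cycle
   accuracy is not positive); across-cycle CV with the cycles as folds,
   equal per-cycle sampling quotas and a fixed cycle (year) effect;
   pairwise train-on-a/predict-b accuracy matrices with outlier
   flagging; independent validation with selection proportions; and the
   top-k relatedness vs r_PEV correlation.

## Synthetic breeding program

No public multi-cycle wheat dataset with plot-level phenotypes and
genotypes exists at this design, so the package ships a generator whose
defaults describe a realistic five-cycle commercial program: cycles of
94/64/165/160/176 lines (659 total) plus an independent 178-line
validation cycle, 5/6/4/5/8 trials per cycle, and per-trait,
per-cycle heritability targets spanning 0.32–0.84 (grain yield) and
0.50–0.84 (protein content) — the magnitudes seen in published
multi-environment wheat trials.  Key mechanisms:

* **Genomes.**  Unlinked biallelic markers; fully inbred founders with
  allele frequencies ~ Uniform(0.1, 0.9); biparental crosses with
  parents drawn preferentially (default 70 %) from the previous cycle,
  then single-seed descent for 6 generations (residual heterozygosity
  < 2 %) or doubled haploids.  This yields within-cycle kinship above
  between-cycle kinship, the structure the cycle-aware CV schemes probe.
* **Traits.**  Grain yield (dt/ha) and protein content (%) from
  overlapping QTL with correlated effect draws; the draw correlation is
  inflated by the overlap fraction so the realised genome-wide genetic
  correlation matches the configured value (default −0.3).  Protein
  yield is derived *per plot* as grain yield × protein content / 100;
  its TBV is stored as the natural-scale product including trait means.
* **Phenotypes.**  Plot value = trait mean + year effect + trial effect
  + genetic value + cycle-specific genetic deviation + genotype-by-trial
  noise + optional row/column trends + residual.  The cycle-specific
  deviation (default 0.4 × genetic SD) is marker-driven but redrawn per
  cycle: heritable within a cycle, non-transferable across cycles — the
  mechanism that makes within-cycle CV genuinely optimistic.  The
  genotype-by-trial variance is calibrated from the target across-trial
  h² (solving the stage-2 formula, including the share of plot error
  the fixed stage-2 residual constant leaves to the interaction term);
  a target of exactly 0 drops the genetic effect, since no finite
  interaction variance reaches h² = 0.  Candidate lines are grown once
  per trial, checks three times.  Outlier trials have their genetic
  signal sign-flipped.
* **What it does not emulate.**  Linkage and recombination hotspots,
  dominance/epistasis, reaction-norm G×E, selection during line
  development, genotyping error.  Passing tests therefore demonstrate
  that the *analysis machinery* behaves as designed under the assumed
  variance structure, not that real wheat data would give the same
  numbers.

## Numerical choices

* Stage-1/stage-2 REML maximises the restricted likelihood on dense
  matrices over log-variances (L-BFGS-B with a short Nelder–Mead
  polish); boundary components below 1e-8 × var(y) are reported as 0.
  AIC = 2k − 2ℓ_REML with k the number of estimated variance
  parameters, compared only among models sharing the fixed part.
* The kernel REML search is bounded on log ratio ∈ [−14, 14] with
  xatol 1e-10.  RR-BLUP scales its marker kernel by 2Σ p_k(1−p_k) — the
  same normaliser as the kinship — so the RR-BLUP and G-BLUP profiles
  coincide exactly and the fitted GEBVs agree to machine precision,
  including at boundary optima.
* Kinship eigenvalues are clipped at zero for the spectral solve
  instead of adding a diagonal ridge; a ridge of 1e-6 would perturb
  GEBVs by the same order as the equivalence tolerance.  Explicit
  inversions (PEV path) operate on V = σ²G K + σ²e I, which the
  residual term already regularises.
* MVN-EM imputation treats each marker column as a draw from N(μ, Σ)
  over lines; the line covariance is shrunk toward its diagonal
  (weight 0.1) for N-near-M stability; imputed dosages are clipped to
  [−1, 1]; convergence is a max-change rule (tol 1e-4, 50 iterations)
  with a warning on non-convergence.
* Allele frequencies count heterozygotes as half a copy; MAF uses
  non-missing calls only.
* Fold/replicate randomness derives from one master seed through
  per-(scheme, replicate, unit) substreams, so the between-cycle scheme
  reuses the within-cycle folds bit-exactly and reruns are
  deterministic.
* Within-replicate CV accuracy is the mean of per-fold Pearson
  correlations (a pooled-prediction flag exists); ties in selection
  fractions break by line id.

## Study problem sizes

The shipped studies run at desk scale, chosen so the full suite
completes in minutes while keeping each effect detectable: five 32-line
cycles (64-line cycles for the bias study, matching the smallest
real-world cycle), 240 markers, 3 trials per cycle, 10 CV replicates,
and 20 simulation seeds for every averaged quantity; the equivalence
and REML-recovery checks use one 200-line cycle with 500 markers.  The
bias study reports one bias value per trait × training cycle, with the
between-cycle accuracy averaged over target cycles before the ratio is
taken, and uses a grain-yield target h² of 0.35 with a −0.6 yield–
protein genetic correlation so the derived protein yield lands in the
low-heritability regime where its bias is expected to be most extreme.
The two-stage recovery study runs a single cycle and therefore sets the
cycle-specific genetic fraction to zero (in a one-cycle design that
variance is confounded with the main genetic effect).

## Open design choices made here

* Stage-2 adjusted means from a fixed-line refit (the accuracy measure
  correlates GEBVs with adjusted means, which random-effect shrinkage
  would distort); flag to switch.
* The unknown year effect of a predicted cycle is taken as the mean of
  the training-cycle effects; correlations are unaffected, ranked
  selections are.
* Derived-trait GEBVs add trait means back before multiplying
  ((mean_gy + gebv_gy)(mean_pc + gebv_pc)/100): GEBVs are deviations
  and a product of raw deviations distorts the ranking.  A
  deviation-product mode exists behind a flag.
* Outlier cycles are excluded from both the training and the held-out
  role in corrected CV (the alternative is a constructor flag).
* Family sizes and crossing designs of real programs are not published;
  the generator exposes them as configuration without claiming
  fidelity.

## Known limitations

Spatial modelling is limited to random row/column effects; the
imputation has no reference-panel mode; variance-component standard
errors are not reported; the pairwise accuracy matrix approximates
genetic correlation only up to heritability-driven attenuation; CV
accuracy against adjusted means (r_GS) is itself attenuated relative to
accuracy against true breeding values (r_MT) — on synthetic data both
are reported.
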