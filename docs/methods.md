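# qpcrkit — methods note

This note records the exact algorithmic conventions ("dialects"), default
parameters, and the scope of the synthetic-data generators.  Where a published
method family admits several reasonable parameterizations, the concrete choice
committed here is stated explicitly; all of them are also logged in result
metadata at run time.

## 1. Scales and conventions

* **Cq** (quantification cycle): cycles to reach threshold; lower Cq = more
  template.  One Cq unit = one doubling only at perfect efficiency.
* **Amplification factor E** ∈ (1, 2]: per-cycle fold change of product.
  Internally everything is stored as E; *efficiency %* = 100·(E − 1) appears
  only at the reporting layer, avoiding the classic "90% vs 1.90" ambiguity.
* Stability values: lower = more stable, for every method.

## 2. Synthetic Cq generator (`simdata.simulate_cq_dataset`)

Cq values are drawn directly on the cycle scale as a sum of components:

```
Cq(sample s, gene g, replicate r) =
      baseline_g                     per-gene expected Cq
    + loading_s                      N(0, loading_sd), shared by all genes of s
    + biology_{g,s}                  N(0, gene_sample_sd_g), shared by replicates
    + group_offset_g[(age, temp)]    deterministic regulation
    + sex_offset_g[sex]              deterministic sex dimorphism
    + Σ coreg effects                shared latent N(0, sd) for listed gene pairs
    + plate_offset_{plate(s)}        fixed between-run shift
    + tech_{g,s,r}                   N(0, tech_sd_g) replicate noise
```

plus a failure process: with probability `failure_rate` per replicate the read
fails, becoming either a missing Cq or a wild value 1.2–3 cycles off (split by
`failure_missing_frac`).  These are exactly the events the replicate filter is
designed to catch.

Default design: 8 ages (30–135 dpf) × 3 temperatures × 10 fish = 240 samples,
24 groups; 6 reference + 6 target genes, duplicates, 3 plates; 3 interplate
calibrator samples run in triplicate on every plate with a fixed latent value.
`default_truth()` places reference baselines at realistic gonad-panel scales
(mean Cq ≈ 15.9–21.2), makes B2M temperature-regulated and co-regulated with
VASA, gives UBQ/RPS4 a shared latent effect, and makes several targets
temperature- and sex-regulated (e.g. CYP19a strongly female-biased).

**Scope / limitations.** Purely additive Gaussian components on the Cq scale;
no amplification inhibition, no probe-chemistry differences, no
heteroscedasticity with expression level, no sample degradation structure.
Sample-to-plate assignment is deterministic (consecutive thirds).

## 3. Mechanistic amplification-curve generator (`simdata.simulate_amp_curve`)

Product follows the recursion `N_c = N_{c−1}·E_c` with

```
E_c = 1 + (E0 − 1)·(1 − N_{c−1}/Nmax)
```

so growth is geometric at `E0` while product is scarce and stalls at the
plateau `Nmax`.  Observed fluorescence adds an optical baseline with linear
drift and Gaussian read noise:

```
F_c = N_c + baseline + drift·c + N(0, noise_sd)
```

Defaults: `E0 = 1.9`, `F0 = 0.05`, `Nmax = 30000`, `baseline = 3000`,
`drift = 5`/cycle, `noise_sd = 30`, 40 cycles.  Note a useful consequence of
the recursion: per-cycle efficiency is **exactly linear in the previous
cycle's product**, which the LRE estimator exploits.

**Scope.** Single-reaction resource-depletion kinetics only; no multi-phase
plateaus, no probe bleaching, no early-cycle drift curvature.

## 4. Preprocessing

Order: **calibrate → filter → average** (plate offsets are removed at
replicate level first, so they cannot inflate within-pair Cq ranges).

* **Interplate calibration**: per gene and plate, offset = plate mean of the
  calibrator Cqs − overall calibrator mean; subtracted from every Cq of that
  gene on that plate.  Idempotent; preserves within-plate differences exactly;
  errors if a plate lacks calibrator Cqs for a gene.
* **Replicate filter** (default `max_delta = 1.0`): a sample is dropped
  *whole* as soon as (a) any gene of the QC panel has a replicate Cq range
  strictly greater than one cycle, or (b) any gene at all has a missing
  replicate Cq — a reaction without a Cq is unusable no matter which panel the
  consistency rule covers.  Calibrator rows pass through untouched; the report
  lists each removed sample with the offending gene and reason.
* **Averaging**: duplicate mean per (sample, gene) into a complete
  samples × genes matrix (`CqMatrix`); incomplete matrices are rejected.
* **Descriptives**: per-gene N, mean, SD (n−1), min, max and a normality
  p-value from the Lilliefors variant of the Kolmogorov–Smirnov test
  (parameters estimated from the data; `statsmodels`).  Constant columns and
  n < 4 give NaN p-values.  The test variant is recorded in the table's
  metadata.

## 5. Stability methods

All four consume the calibrated, averaged matrix; experimental group =
age × temperature.

* **Comparative delta-Ct**: gene value = mean over all other genes of the
  across-sample SD (n−1) of the pairwise Cq difference.
* **BestKeeper** (descriptive dialect): per-gene raw SD and CV% = 100·SD/mean,
  plus all-pairs Pearson r/p.  Genes with SD > 1 cycle are flagged against the
  method's recommended cutoff.  Ranking is by SD.
* **NormFinder** (model-based decomposition; committed parameterization):
  per-sample means are removed (they carry loading/RT effects common to all
  genes).  With groups j of size n_j: `d_gj` = group mean − overall mean of
  the centered values; `σ_gj` = within-group SD.  Deviations are shrunken by
  signal-to-noise, `d̃ = d·γ²/(γ² + σ²/n)` with `γ²` the across-group variance
  of d (0/0 → 0).  Stability `ρ_g = mean_j(|d̃_gj| + σ_gj/√n_j)`.  Reported
  intra-/inter-group variations are `mean_j σ_gj` and `mean_j |d̃_gj|`.  Best
  pair minimizes the analogous quantity with pair deviation `(d̃_g + d̃_h)/2`
  and pair variance `(σ_g² + σ_h²)/4`.  Rankings and limiting behavior are
  asserted in tests, not third-party decimal equality.
* **GeNorm**: M_g = mean pairwise SD over the *current* gene set (round 1
  equals the delta-Ct values exactly); the worst gene is excluded (ties broken
  by removing the gene later in input order, logged) and M recomputed until
  two remain.  The never-excluded final pair is placed jointly first in the
  ranking, ordered by input gene order.  Final-pair M is compared with the
  accepted cutoff 1.5.
* **Normalization-factor comparison**: for each reference combo, the
  normalization factor is the arithmetic mean of the combo's (optionally
  efficiency-corrected) Cqs — the Cq-scale equivalent of a geometric mean of
  linear quantities — subtracted from each target Cq; reported are the mean
  within-group SD, the SD of group means, and per-sex SDs, averaged over
  targets.

## 6. Single-reaction efficiency estimators

All consume one raw curve and return E with window, R², warnings and reasons.
Pre-condition for all: the signal must rise at least 10 early-cycle spreads
above the early median ("no exponential phase" otherwise).  Estimates E ≤ 1
are invalid; E > 2 is kept but flagged `above_doubling` (a chemistry cannot
more than double per cycle).  Estimation is always per reaction; per-gene
means are taken afterwards, never from pooled curves.

* **linreg (window of linearity)**: background (level + linear drift) is
  fitted to the pre-lift-off cycles (lift-off = early median + 10·early SD);
  on the subtracted signal the best 4–6-cycle window of log S vs cycle is
  selected inside the band (0.02, 0.2)·Smax — clear of the noise floor,
  before plateau curvature — requiring slope > ln 1.25 (flatter "windows" are
  residual background).  If the narrow band holds no window it widens to
  (0.01, 1/3)·Smax with a `relaxed_window` warning.  E = exp(slope).
  *Why not a constant-baseline search*: selecting a constant baseline by
  maximizing window R² is systematically biased under realistic noise
  (slight under-subtraction compresses the log-scale noise of the lowest
  window points and wins the R² contest while flattening the slope); the
  pre-lift-off fit removes the bias and also absorbs linear drift.
* **dart**: baseline from a saturation fit `a·c/(b + c) + d` to cycles 2–10
  (mean fallback with warning on divergence); lift-off threshold = 10 × early
  residual SD; exponential-phase midpoint signal = geometric mean of lift-off
  and the maximal subtracted signal; log-linear regression over the cycles
  within a √10-fold band around the midpoint (10-fold total range).
* **miner**: four-parameter logistic `Fb + Fmax/(1 + exp(−(c − c½)/k))` fitted
  with three deterministic starts (k₀ ∈ {1, 2, 4}); the exponential phase is
  the cycles whose signal lies between 1% and 10% of the fitted plateau
  (extended downward to ≥ 4 cycles) — ending safely before the curvature that
  the logistic's second-derivative maximum (≈ 21% of plateau) marks; then a
  three-parameter exponential `Fb′ + F0·E^c` is fitted on that phase
  (log-linear start, E bounded in (1, 4]).
* **lre**: baseline = mean fluorescence of cycles 6–12; per-cycle ratios
  `E_c = S_c/S_{c−1}` are regressed linearly on the *previous* cycle's signal
  `S_{c−1}` (under depletion kinetics the decline is exactly linear in prior
  product); the window grows cycle-by-cycle from the maximal-ΔS seed while
  window R² ≥ 0.99 (constant ratios count as perfectly linear), up to 8
  cycles; E = intercept — the efficiency extrapolated to zero product.  A
  positive slope is flagged `efficiency_not_declining`.

Expected behavior on realistic noisy curves (defaults above, 100 curves per
E0): every method recovers |mean Ê − E0| < 0.10 at E0 ∈ {1.80, 1.90, 2.00};
dart and miner sit slightly low (depletion inside their windows), lre is
nearly unbiased, linreg within ≈ 0.03.  Signed biases are reported, not tuned.

**Aggregation**: invalid estimates are excluded with counts; per-gene
arithmetic mean E per method; Pearson r/p across gene means per method pair
(≥ 3 common genes with spread required, else NaN).

## 7. Normalization

* Efficiency correction: `Cq_corr = Cq·log(E)/log 2`, defined for E ∈ (1, 2];
  E = 2 is the identity.
* Delta-Cq: `ΔCq = corr(target) − mean_r corr(reference combo)`, then per-
  target mean-centering across samples (so group means are contrasts; the
  per-gene mean-zero invariant is enforced to 1e-9).
* With all E = 2 the pipeline reduces to classic delta-Cq normalization.
* Group summaries: mean/SD per (target, group); singleton groups get NaN SD.

## 8. Robustness of rankings

Stratified subsets (k samples per experimental group, without replacement;
default k ∈ {3, 2}, 25 draws each) are re-ranked by each method and compared
with the full-data ranking: `identical` (same sequence), `top3_reordered`
(top-3 set preserved but order or tail differs), `different` (top-3 set
changed).  Method failures on a subset (e.g. degenerate groups) are recorded
and excluded from percentages rather than raised.

## 9. Pipeline

`RunConfig(seed=...)` → `run_pipeline` executes simulate → preprocess →
stability (all four) → normalization-factor comparison → efficiency (per-gene
curve batches with per-gene true E0 ~ N(1.90, 0.03) clipped to [1.8, 2.0]) →
target normalization (target genes receive the method's mean reference
efficiency as a documented fallback; E = 2 with no information) → robustness,
writing one CSV per result table plus `config.yaml` and `manifest.json`.
Identical seeds give byte-identical outputs.

## 10. Reproducibility parameters (summary table)

| Parameter | Default |
|---|---|
| replicate QC rule | range > 1.0 cycle, or any missing Cq |
| BestKeeper SD cutoff | 1.0 cycle |
| GeNorm M cutoff | 1.5 |
| linreg window | 4–6 cycles in (0.02, 0.2)·Smax |
| linreg minimum slope | ln 1.25 |
| dart early cycles / lift-off | 2–10 / 10·early SD |
| miner phase | 1%–10% of fitted plateau, ≥ 4 cycles |
| lre baseline / window R² / max window | cycles 6–12 / 0.99 / 8 cycles |
| robustness strata | 3 and 2 per group × 25 subsets |
| curve defaults | E0 1.9, Nmax 30000, baseline 3000, drift 5, noise SD 30 |
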