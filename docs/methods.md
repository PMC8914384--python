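# Methods

## Model and assumptions

`ipenrich` calls specific bait interactors from a single bait/control
immunoprecipitation pair quantified by MaxQuant LFQ. The underlying model
is empirical rather than parametric: within a bait-intensity stratum, the
log2 bait/control ratios of nonspecifically bound proteins form a unimodal
null cloud, and specific interactors are boxplot outliers of that cloud.
Binning by intensity matters because LFQ ratio variance shrinks with
abundance; a global fence would over-call low-abundance proteins and
under-call abundant ones. The procedure assumes one bait column and one
control column — replicate-aware statistics are out of scope by design.

Missing control intensities are informative, not ignorable: a prey pulled
down only by the bait has no control value. They are imputed at the
detection baseline — draws from a normal with mean at the 5% quantile of
the pooled (bait + control, observed only) log10 intensities and SD 0.1
log10 units — so such preys receive large finite ratios instead of being
dropped. The stated imputation law ("a standard normal distribution with a
mean of ... and an SD of 0.1") is internally contradictory as written; the
only reading consistent with "values close to the baseline" is an ordinary
normal with that mean and SD, which is what is implemented.

## Pipeline parameters (`AnalysisConfig`)

| parameter | default | meaning |
|---|---|---|
| `min_peptides_observed` | 2 | razor+unique peptides required for any protein |
| `min_peptides_imputed` | 3 | stricter evidence floor for imputed proteins |
| `imputation_quantile_level` | 0.05 | pooled log10 quantile used as baseline |
| `imputation_sd` | 0.1 | SD of imputation draws, log10 units |
| `min_bin_size` | 300 | minimum proteins per intensity bin |
| `iqr_multiplier_sig1` | 1.5 | fence multiple for significance 1 |
| `iqr_multiplier_sig2` | 3.0 | fence multiple for significance 2 |
| `rng_seed` | 0 | seed of the imputation RNG |
| `drop_site_only` | true | remove "only identified by site" entries |

Numerical conventions, chosen where the procedure is open:

- **Quantiles** use linear interpolation between order statistics (the
  default of mainstream statistical environments, `numpy.quantile`'s
  `linear`); the test suite checks every quartile against an independent
  sort-and-interpolate oracle.
- **Binning** sorts by log10 bait intensity (the control may be imputed,
  hence artificial) and partitions into k = max(1, ⌊N/300⌋) consecutive
  disjoint bins whose sizes differ by at most one; N < 300 gives a single
  bin; ties are broken by stable input order. Sliding windows would be an
  alternative reading of "bins of at least 300"; the disjoint partition was
  chosen and `min_bin_size` is configurable.
- **Outlier test** is strict (`>` the upper fence, `<` the lower), so with
  IQR = 0 any distinct value is an outlier. A protein's own ratio is
  included in its bin's quartiles — the simplest reading of a boxplot over
  a bin; with ≥ 300 proteins per bin, one ratio moves the quartiles
  negligibly.
- **Direction**: both fences are computed and depleted outliers are
  labelled, but ranking and scoring consider the enriched side only — the
  scientific question is which preys the bait pulls down.
- **Missing bait** intensities are dismissed at filtering: imputation is
  defined for controls only, and a protein absent from the bait IP cannot
  be an enriched interactor.
- The pooled quantile is computed after filtering and before imputation.
- Every dismissed protein is logged with stage and reason, so the input is
  always partitioned into survivors and audited dismissals.

## Synthetic experiments (`SimulationConfig`)

The generator emulates the structure the procedure relies on, with a known
truth labelling:

- log10 control intensity ~ N(6.5, 1.0) — a realistic LFQ dynamic range of
  roughly four orders of magnitude;
- log2 bait/control ratio ~ N(0, 0.35) for background proteins and
  N(4.0, 0.35) for spiked interactors (defaults: 2,000 background, 30
  interactors), giving a dense null cloud and a separated enriched arm;
- razor+unique peptides ~ 1 + Poisson(3·max(0, log10 bait − (μ − 2σ))), so
  peptide evidence grows with abundance and the faintest proteins fail the
  evidence filters, as in real searches;
- missing controls by **left-censoring**: the control is missing iff its
  log10 value falls below a detection threshold placed at the
  class-specific normal quantile (μ + σ·Φ⁻¹(p), p = 0.05 for background,
  0.6 for interactors). Each protein's marginal missing probability is
  exactly p — missing-control counts are Binomial — while missingness
  concentrates at the low-intensity baseline for background proteins and is
  frequent for interactors depleted from the control IP. A uniformly random
  missingness mechanism would instead scatter baseline-imputed controls
  under high-abundance background proteins and manufacture false
  enrichment that no real censoring process produces.

What the generator does **not** emulate: correlated protein abundances,
shared-peptide protein-group ambiguity, intensity-dependent ratio variance
beyond the censoring mechanism, contaminant/decoy rows (flags are all
false), or spectrum-level effects. Passing recovery tests therefore show
that the caller separates a shifted arm from a log-normal null under
censored missingness — not that any particular biological screen is
error-free.

With the default spike-in conditions the pipeline reaches recall ≥ 0.9 at
significance ≥ 1 and precision ≥ 0.9 at significance 2 averaged over ten
seeds, and with zero interactors and no missingness produces no
significance-2 call in ≥ 95% of a hundred seeded experiments; both are
recomputed by the test suite, not quoted from elsewhere.

## Problem sizes

The test and acceptance workloads use 1,000–2,030-protein tables, ten-seed
recovery averages, a hundred-seed null calibration, 1,000 random bins for
the oracle cross-check and 100,000 imputation draws — sizes at which every
quantity under test (bin partitions, fence switch points, Monte-Carlo
moments within ±0.002) is stable, while the whole suite runs in seconds.

## Known limitations

- Exactly one bait and one control column; no replicates, no
  condition-level variance moderation, no FDR across proteins.
- The significance classes are descriptive outlier labels, not calibrated
  error rates; class-1 calls in particular inherit the ~0.7% two-sided
  normal boxplot-outlier rate per bin.
- Imputed ratios depend on the pooled 5% quantile, which shifts with the
  experiment's intensity distribution; comparing significance calls across
  experiments with very different depth is not meaningful.
- The ranking key (significance class before ratio) is a convention;
  `rank_top_enriched(..., class_first=False)` ranks by ratio alone.
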