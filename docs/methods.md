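# Methods

## Background model

Read depth for target `i` in sample `j` is modeled as
`Y_ij ~ Poisson(λ_ij)` with

```
λ_ij = N_j · f_j(GC_i) · β_i · exp(Σ_{k=1..K} g_ik h_jk)
```

* `N_j` — library size, fixed at the observed column total.
* `f_j(·)` — sample-specific GC-bias curve. Represented as values on a
  grid of GC bins (default width 2 percentage points; bins holding fewer
  than 10 targets are merged with a neighbor), linearly interpolated
  between bin centers and held flat beyond them. Estimated per iteration
  from per-bin medians of the ratios `Y_ij / (N_j β_i e^{gh})`; a per-bin
  Poisson MLE (`f_estimator="mle"`) is available but the median is the
  default because it is robust to residual aberrant targets. The curve
  keeps its per-sample scale: `β` is per-target and `N` is fixed, so the
  sample-level depth correction has nowhere else to live. (Normalizing
  the curve to mean one, an earlier design, silently removed that degree
  of freedom, left a ~3% per-sample bias, slowed convergence by an order
  of magnitude, and made information criteria prefer one spurious extra
  factor.)
* `β_i` — target-specific capture/length factor, closed-form Poisson MLE
  given everything else: `β_i = Σ_j Y_ij / Σ_j N_j f_j(GC_i) e^{gh}`.
* `g, h` — rank-`K` latent loadings, updated by batched per-target and
  per-sample Poisson log-linear regressions (Newton steps with a shared
  design, clipped for stability) with `log(N_j f_j β_i)` as offset;
  initialized from an SVD of the log-ratio matrix. After convergence the
  fitted log-bias matrix `g hᵀ` is refactorized by a rank-`K` SVD so the
  `g` columns are orthogonal (identifiability).

The outer loop iterates f-step, β-step, g-step, h-step until the relative
log-likelihood change falls below `tol` (default 1e-6, cap 100
iterations); on data drawn from the model it converges in under ten
iterations. The log-likelihood is monitored and is non-decreasing up to
the small slack introduced by the median-based f-step.

## Negative-control normalization

**Control samples.** The full model is fitted on the control submatrix,
fixing `β` and `g`. Each non-control sample keeps its observed `N_j` and
receives its own GC curve (binned medians against the control-derived
`β, g`) and loading `h_j` (one Poisson regression on `g`); curve and
loading are refined over three passes. GC bias is sample-specific, so it
is never borrowed from the controls.

**Control regions.** Targets are split into putative common-CNV targets
`I*` and the complement. The complement fit supplies `N, f, h` (and
`β, g` for complement targets). For each target in `I*` a two-component
Poisson mixture is fitted by EM: sample `j` is a carrier with probability
`π`, and carriers' means are multiplied by `e^μ`. The M-step is a
weighted Poisson regression in which every sample contributes one
carrier and one non-carrier pseudo-observation; the E-step updates the
posterior carrier probabilities. `μ` may be estimated or pre-fixed
(`log(1/2)` for a known heterozygous-deletion analysis). The EM runs
from two starts when `μ` is fixed — seeding carriers from the
displaced-low group, or from everyone except the displaced-high group
(which rescues events carried by most of the cohort, where a pooled fit
anchors on the carriers) — and the winning solution must beat the
single-component likelihood, which guards against mis-anchored local
optima on noise-flagged targets. Convergence: relative observed-data
log-likelihood change below 1e-8, cap 500 iterations; degenerate
posteriors (π within 1e-3 of 0 or 1) collapse to the single-component
fit. With free `μ` the label-swapped solution has identical likelihood;
the branch with `π ≤ 0.5` is reported (flip `β ← β e^μ, μ ← −μ,
π ← 1−π` for the other). The background returned for `I*` targets
excludes `μ`, so carrier signal survives normalization.

**Empirical identification of control regions.** A first pass fits all
samples; target `i` is flagged when the across-sample SD of
`z_ij = log(Y_ij/λ̂_ij)` exceeds 0.3, or any `z` exceeds 0.8 or falls
below −0.8. Because these rules act per target while a CNV spans
consecutive targets, the flag mask is then made spatially coherent:
each flag drags in 2 neighbors, runs separated by at most 6 unflagged
targets are joined, and flagged runs grow outward while the adjacent
target shows the run's carrier-vs-noncarrier mean-z contrast (threshold
0.15 — well above the null contrast noise of ~0.03 and below the
attenuated one-copy contrast left after a contaminated first pass; the
first-pass latent factors absorb part of the signal, so the raw
contrast of ~0.69 is not available). On CNV-free simulated cohorts the
flagged fraction stays near 2–3%. All thresholds are configurable, and a
known common-CNV list can be supplied instead.

## Segmentation

Within each scope unit (chromosome, or gene for sparse panels) all
intervals `[s, e]` are scored by the Poisson log-likelihood ratio of
`λ·ĉ/2` against `λ`, with `ĉ = 2 Σy / Σλ̂` the MLE fractional copy
number:

```
L(s,e) = Σ_i [ y_i log(ĉ/2) − λ̂_i (ĉ/2 − 1) ]
```

The maximal interval is accepted if `L ≥ lratio_min`, and the search
recurses on both flanks (greedy top-down; verified against an exhaustive
O(n²) oracle). Integer mode rounds `ĉ` and rescores. `lratio_min`
defaults to 15, calibrated on CNV-free simulated cohorts (n = 800–2000,
m = 60–90) where it yields essentially zero false segments per sample
(≈0.02 at threshold 10, 0 at 15); it is exposed in the options. States:
copy number below 0.7 two-copy deletion, [0.7, 1.7) one-copy deletion,
[1.7, 2.3] diploid, (2.3, 3.3] gain, above 3.3 high gain — boundaries are
assigned to the diploid side, a conservative deterministic choice.
Diploid segments are retained in memory and suppressed in written output.

## Simulation engine

`generate_null` draws: library sizes log-uniform over a mean per-target
depth of 100–400; target lengths 60–500 bp and GC ~ Normal(47, 8) clipped
to [30, 70]%; capture factors proportional to length times a lognormal
(σ = 0.4); per-sample GC curves `exp(a·u + b·u²)` with `u = (GC−50)/20`,
`a ~ N(0, 0.25)`, `b ~ N(−0.2, 0.1)`; orthogonal latent loadings scaled
to a per-entry log-bias SD of 0.15 per factor, with the first factor
shifted by ±0.5 between two interleaved sequencing batches; Poisson
counts with column sums matching the library sizes. Expected per-target
median coverage is floored at 45, matching the convention that the
spike-in background is a post-QC matrix — without the floor,
low-coverage targets produce heavy-tailed log-ratios that are flagged and
mis-modeled for reasons unrelated to CNV signal.

`spike_in` thins carriers' counts binomially to expectation `y·c/2` for
losses and superposes `Poisson(y(c/2−1))` extra reads for gains, keeping
counts integer with the correct noise; `c ~ Normal(c_mean, c_sd)`
truncated at 0 (defaults: deletions mean 1, duplications mean 3, SD 0.1
for both — the duplication SD mirrors the deletion one). Tumor-mixture
events use the multiplier `(p·c + (1−p)·2)/2` for tumor fraction `p`.
Carrier–batch correlation is induced by shifting per-batch carrier
probabilities to hit a requested point-biserial correlation. Control-role
samples are never carriers.

**Scoring.** Exon-sample cells are the unit; a truth cell is recovered
when covered by a non-diploid call of the correct direction. Copy-number
events are defined relative to the population average, so an event
carried by more than half the cohort is equivalently the complementary
event in the non-carriers (a 90%-frequency deletion is a 10%-frequency
relative duplication); scoring uses whichever representation the calls
recover better, precision accepts either, and an event carried by every
sample is unscorable and skipped. With no emitted calls precision is 1
by convention (no false positives) — this matters for sparse callers.

**What the generator does not emulate:** overdispersion beyond Poisson,
mappability artifacts, GC curves outside the smooth-quadratic family,
allele-specific signal, and correlated carrier status across distinct
regions. Passing benchmarks here demonstrate correct behavior under the
stated noise model, not performance on real sequencing data.

## Model selection

`AIC = 2ℓ − 2·df` and `BIC = 2ℓ − df·log(nm)` on a larger-is-better
scale with `df = K(n + m − K)` counting only the factor parameters
(`β, f, N` are common to all `K`, so criterion differences depend on `K`
alone); variance reduction is `1 − Var(z_K)/Var(z_0)`, with the elbow
defined as the smallest `K` reaching 95% of the maximal reduction. Ties
take the smallest `K`.

## Desk-scale study sizes

The acceptance suite runs: z-score centering and baseline contrasts on
one cohort of 2000 targets × 90 samples (20 regions of 5–40 exons at
10–50% frequency, `μ` fixed at `log(1/2)` as for a known
heterozygous-deletion analysis); the frequency sweep at 600 targets × 90
samples, K = 3, frequencies 5–95% in steps of 5%, 5 replicates;
deletion/duplication symmetry at 500 × 60 with 20 replicates;
EM recovery at one target × 200 samples with the carrier count fixed at
exactly 40% (isolating estimator error from binomial sampling of the
carrier draw); model selection at 1000 × 90 with three true factors; and
robustness to `K` in control-sample mode on a cohort with one dominant
batch factor, the regime of sparse targeted panels where that robustness
claim applies. The tumor-fraction sweep in `scripts/acceptance.py`
supplies the spiked regions as known common-CNV regions — the
prior-knowledge route appropriate for recurrent somatic events — because
mixture shifts of `|log ratio| ≤ 0.22` are invisible to the empirical
dispersion rules at their standard thresholds.

## Known limitations

* Copy numbers near a category boundary are split across the two states
  by estimation noise; in particular a clonal one-copy deletion at 30%
  tumor fraction has expected fractional copy number exactly 1.7, the
  diploid/one-copy-deletion boundary, so roughly half of such segments
  are categorized diploid however good the normalization.
* One CNV type per target in the mixture (no multi-component extension);
  no sex-chromosome ploidy adjustment; no allele-frequency modeling.
* The per-exon EM treats contiguous exons of one event independently;
  region-level pooling of `π` would share strength but is not
  implemented.
* Coverage computation from BAM/CRAM is out of scope; inputs are count
  matrices.
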