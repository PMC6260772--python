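# cnvfactor

Full-spectrum copy-number variant (CNV) detection from sequencing read
depth — common and rare, germline and somatic — for whole-exome, targeted
panel, and binned whole-genome data.

Read-depth CNV callers must separate true copy-number signal from
target- and sample-specific technical noise (GC bias, capture efficiency,
library size, batch effects). Background models fitted on *all* samples
and *all* regions absorb recurrent CNV signal into the background, which
is why classical normalization loses sensitivity precisely for common
variants. `cnvfactor` fits a Poisson latent-factor background that is
guarded by negative controls, so recurrent signal survives normalization.

## Model

Raw counts follow

```
Y_ij ~ Poisson(λ_ij),    λ_ij = N_j · f_j(GC_i) · β_i · exp(Σ_k g_ik h_jk)
```

where `N_j` is the library size of sample `j`, `f_j(·)` a smooth
sample-specific GC-bias curve, `β_i` a target-specific capture factor, and
`g, h` rank-`K` latent-factor loadings (`g` columns orthogonal). Two modes
keep CNV signal out of the fit:

* **control samples** — copy-number-neutral samples estimate `β` and `g`;
  each remaining sample then gets its own `f_j` and loading `h_j` by a
  single Poisson regression (case/control and tumor/normal designs);
* **control regions** — targets free of *common* CNVs estimate `N, f, h`;
  for each flagged common-CNV target an EM over the latent carrier status
  `Z_ij ~ Bernoulli(π_i)` estimates `β_i, g_i` together with the carrier
  rate `π_i` and log-scale effect `μ_i` (free, or pre-fixed, e.g.
  `log(1/2)` for a heterozygous deletion). The returned background
  excludes `μ`, so carriers keep their signal. Control regions can be
  supplied (known common CNVs) or flagged empirically from a first-pass
  fit via z-score dispersion.

Samples are then segmented against their background by recursive Poisson
likelihood-ratio search with fractional copy numbers
(`ĉ = 2·Σy/Σλ̂`), categorized as two-copy deletion / one-copy deletion /
diploid / gain / high gain at the boundaries 0.7 / 1.7 / 2.3 / 3.3. The
number of latent factors is chosen by AIC, BIC, or variance reduction.

A spike-in simulation engine (`cnvfactor.simulate`) generates CNV-free
cohorts from the model, spikes deletions, duplications, or tumor-mixture
events of configurable length, frequency, and batch correlation, and
scores calls at exon level.

## Worked example

`examples/03_negative_control_normalization.py` spikes a 50%-frequency
heterozygous deletion into a simulated 1000-target × 90-sample cohort and
normalizes three ways:

```
flagged common-CNV targets: 132 of 1000
mean z-score over true carrier exons (target log(1/2) = -0.693):
  pooled null fit:     -0.412
  SVD baseline:        -0.429
  control-region mode: -0.702
segmentation on the control-region background: precision 1.000, recall 0.998
```

The normalized z-score `log(Y/λ̂)` of a heterozygous deletion should sit
at `log(1/2) = -0.693`. The pooled fit and the SVD baseline absorb part of
the common deletion into the background (carriers attenuated to ≈ −0.41),
while control-region normalization preserves the full signal (−0.70) and
segmentation recovers the spiked exons almost perfectly. The other
examples cover cohort simulation, model selection (AIC/BIC/variance
reduction agree on the true `K`), and a frequency sweep in which the
pooled fit's accuracy collapses for common CNVs while the
control-guarded fit stays accurate.

## Command line

A thin CLI wraps the library for shell pipelines:

```
cnvfactor simulate  --n 2000 --m 90 --k 3 --seed 7 --out-prefix sim
cnvfactor qc        --targets sim.targets.tsv --counts sim.counts.tsv \
                    --samples sim.samples.tsv --out-prefix qc
cnvfactor normalize --targets qc.targets.tsv --counts qc.counts.tsv \
                    --samples sim.samples.tsv --mode auto --k-range 1:5 \
                    --criterion bic --out-prefix norm
cnvfactor segment   --targets qc.targets.tsv --counts qc.counts.tsv \
                    --samples sim.samples.tsv --model norm.model.json \
                    --out segments.tsv
```

`--mode auto` uses control samples when the sample sheet contains them
and control regions otherwise. Every subcommand writes a JSON run
manifest (version, options hash, seed).

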