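"""Simulate a WES-like cohort and spike in CNVs.

Draws a CNV-free read-depth matrix from the background model (library
sizes, per-sample GC bias, capture efficiencies, three latent factors,
Poisson counts), spikes heterozygous deletions at 20% carrier frequency,
and writes the standard TSV inputs a real analysis would start from.
"""

import numpy as np

import cnvfactor as cf

cohort = cf.generate_null(n=1000, m=60, K=3, seed=7)
plan = cf.SpikeInPlan(
    regions=cf.default_regions(1000, 6, 10),
    cnv_type="het_del",
    frequency=0.2,
    seed=8,
)
spiked, truth = cf.spike_in(cohort.counts, plan)

cf.write_targets(spiked.targets, "cohort.targets.tsv")
cf.write_samples(spiked.samples, "cohort.samples.tsv")
cf.write_counts(spiked, "cohort.counts.tsv")
truth.to_frame(spiked.samples).to_csv("cohort.truth.tsv", sep="\t", index=False)

carriers = truth.carrier.sum(axis=1)
print(f"cohort: {spiked.n_targets} targets x {spiked.n_samples} samples")
print(f"median per-target coverage: {np.median(spiked.values):.0f} reads")
print(f"spiked regions: {len(plan.regions)} x 10 exons, carriers per region: {[int(c) for c in carriers]}")
print("wrote cohort.targets.tsv / cohort.samples.tsv / cohort.counts.tsv / cohort.truth.tsv")
# Carrier counts fluctuate binomially around 20% of 60 samples; every
# carrier's depth in its region was thinned to c/2 of expectation (c~N(1,0.1)).
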