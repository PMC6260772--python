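"""Target- and sample-level quality control applied before model fitting.

A target is kept when its median coverage across samples lies in
[median_min, median_max], its length in [length_min, length_max] bp, its GC
content in [gc_min, gc_max] percent, and its mappability is at least
mapp_min. All intervals are closed; ties pass. The mappability rule keeps
high-mappability targets (low-mappability ones are the unreliable ones);
the threshold is configurable.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
import yaml

from .data import CountMatrix, ValidationError


@dataclass
class QCThresholds:
    median_min: float = 40.0
    median_max: float = 4000.0
    length_min: float = 30.0
    length_max: float = 2000.0
    gc_min: float = 30.0
    gc_max: float = 70.0
    mapp_min: float = 0.9

    @classmethod
    def from_yaml(cls, path: str) -> "QCThresholds":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {k: v for k, v in raw.items() if k in cls.__dataclass_fields__}
        return cls(**known)

    def to_dict(self) -> dict:
        return asdict(self)


def filter_targets(
    counts: CountMatrix, thresholds: QCThresholds | None = None
) -> tuple[CountMatrix, pd.DataFrame]:
    """Apply the target QC rules; return (passing CountMatrix, report).

    The report has one row per input target with pass/fail and a
    comma-separated list of reason codes among {median_coverage, length,
    gc, mappability} for every rule the target violates.
    """
    thr = thresholds or QCThresholds()
    t = counts.targets
    med = np.median(counts.values, axis=1)
    fails = {
        "median_coverage": (med < thr.median_min) | (med > thr.median_max),
        "length": (t.lengths < thr.length_min) | (t.lengths > thr.length_max),
        "gc": (t.gc < thr.gc_min) | (t.gc > thr.gc_max),
        "mappability": t.mappability < thr.mapp_min,
    }
    fail_any = np.zeros(len(t), dtype=bool)
    reasons = [[] for _ in range(len(t))]
    for code, mask in fails.items():
        fail_any |= mask
        for i in np.flatnonzero(mask):
            reasons[i].append(code)
    report = pd.DataFrame(
        {
            "chrom": t.chrom,
            "start": t.start,
            "end": t.end,
            "median_coverage": med,
            "pass": ~fail_any,
            "reasons": [",".join(r) for r in reasons],
        }
    )
    keep = np.flatnonzero(~fail_any)
    if keep.size == 0:
        raise ValidationError("no usable targets: every target failed QC")
    return counts.subset_targets(keep), report


def filter_samples(counts: CountMatrix, min_total: int = 0) -> CountMatrix:
    """Drop samples whose total depth is below ``min_total`` (0 keeps all)."""
    totals = counts.values.sum(axis=0)
    keep = np.flatnonzero(totals >= min_total)
    if keep.size == 0:
        raise ValidationError("no usable samples: all totals below min_total")
    if keep.size == counts.n_samples:
        return counts
    return counts.subset_samples(keep)
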