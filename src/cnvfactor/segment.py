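"""Recursive Poisson likelihood-ratio segmentation against the background.

Within each scope unit (chromosome, or gene for sparse targeted panels)
every contiguous interval [s, e] of targets is scored by the generalized
likelihood ratio of Poisson(lam * c/2) against Poisson(lam), where the
fractional copy number c maximizing the likelihood is 2 * sum(y) / sum(lam):

    L(s, e) = sum_i [ y_i log(c/2) - lam_i (c/2 - 1) ]

The interval with maximal L is accepted if L reaches ``lratio_min``; the
search then recurses on both flanks. Fractional mode keeps c continuous
(attenuated mixtures, tumor purity); integer mode rounds c and rescores.
Copy numbers map to five states: below 0.7 two-copy deletion, [0.7, 1.7)
one-copy deletion, [1.7, 2.3] diploid, (2.3, 3.3] gain, above 3.3 high
gain (boundaries assigned toward diploid).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data import BackgroundModel, CountMatrix, SegmentCall, ValidationError


@dataclass
class SegmentationOptions:
    mode: str = "fraction"  # or "integer"
    lratio_min: float = 15.0  # calibrated on null simulations (see docs)
    max_seg_targets: int | None = None
    scope: str = "per_chromosome"  # or "per_gene"

    def __post_init__(self):
        if self.lratio_min <= 0:
            raise ValidationError("lratio_min must be positive")
        if self.mode not in ("fraction", "integer"):
            raise ValidationError(f"unknown mode {self.mode!r}")
        if self.scope not in ("per_chromosome", "per_gene"):
            raise ValidationError(f"unknown scope {self.scope!r}")


def categorize_state(copy_number: float) -> str:
    """Map a fractional copy number to the five-state CNV categorization."""
    c = float(copy_number)
    if c < 0:
        raise ValidationError("copy number must be >= 0")
    if c < 0.7:
        return "two_copy_del"
    if c < 1.7:
        return "one_copy_del"
    if c <= 2.3:
        return "diploid"
    if c <= 3.3:
        return "gain"
    return "high_gain"


def _interval_scores(y: np.ndarray, lam: np.ndarray, max_len: int | None):
    """Score every interval; returns (s_idx, e_idx_exclusive, c_hat, L)."""
    L0 = y.size
    cy = np.concatenate([[0.0], np.cumsum(y)])
    cl = np.concatenate([[0.0], np.cumsum(lam)])
    s, e = np.triu_indices(L0 + 1, k=1)
    if max_len is not None:
        keep = (e - s) <= max_len
        s, e = s[keep], e[keep]
    Sy = cy[e] - cy[s]
    Sl = cl[e] - cl[s]
    r = Sy / Sl  # c_hat / 2
    with np.errstate(divide="ignore", invalid="ignore"):
        term = np.where(Sy > 0, Sy * np.log(np.where(r > 0, r, 1.0)), 0.0)
    L = term - Sl * (r - 1.0)
    return s, e, 2.0 * r, L


def _rescore_integer(y, lam, s, e, c_frac):
    """Round the copy number and recompute L at the integer value."""
    cy = np.concatenate([[0.0], np.cumsum(y)])
    cl = np.concatenate([[0.0], np.cumsum(lam)])
    Sy, Sl = cy[e] - cy[s], cl[e] - cl[s]
    c_int = max(0.0, np.floor(c_frac + 0.5))
    r = c_int / 2.0
    if r == 0.0:
        L = -np.inf if Sy > 0 else Sl
    else:
        L = Sy * np.log(r) - Sl * (r - 1.0)
    return c_int, L


def segment_sample(
    y: np.ndarray, lam: np.ndarray, opts: SegmentationOptions | None = None
) -> list[tuple[int, int, float, float]]:
    """Segment one sample's counts within one scope unit.

    Returns (first, last, copy_number, lratio) tuples with inclusive target
    indices relative to the input arrays; every returned segment met the
    acceptance threshold. Greedy top-down: the globally best interval is
    accepted first, then both flanks are searched independently.
    """
    opts = opts or SegmentationOptions()
    y = np.asarray(y, dtype=float)
    lam = np.asarray(lam, dtype=float)
    if y.shape != lam.shape:
        raise ValidationError("y and lam must have the same length")
    if y.size == 0:
        return []
    if np.any(lam <= 0) or lam.sum() == 0:
        raise ValidationError("lam must be strictly positive")
    segs: list[tuple[int, int, float, float]] = []
    stack = [(0, y.size)]
    while stack:
        lo, hi = stack.pop()
        if hi - lo < 1:
            continue
        s, e, c, L = _interval_scores(y[lo:hi], lam[lo:hi], opts.max_seg_targets)
        best = int(np.argmax(L))
        c_best, L_best = c[best], L[best]
        if opts.mode == "integer":
            c_best, L_best = _rescore_integer(
                y[lo:hi], lam[lo:hi], s[best], e[best], c_best
            )
        if not np.isfinite(L_best) or L_best < opts.lratio_min:
            continue
        fs, fe = lo + int(s[best]), lo + int(e[best])  # [fs, fe)
        segs.append((fs, fe - 1, float(c_best), float(L_best)))
        stack.append((lo, fs))
        stack.append((fe, hi))
    segs.sort()
    return segs


def _scope_units(counts: CountMatrix, scope: str):
    """Yield (key, index array) for contiguous runs of the scope key."""
    if scope == "per_gene":
        keys = np.array(
            [g if g else c for g, c in zip(counts.targets.gene, counts.targets.chrom)]
        )
    else:
        keys = counts.targets.chrom
    n = len(keys)
    start = 0
    for i in range(1, n + 1):
        if i == n or keys[i] != keys[start]:
            yield keys[start], np.arange(start, i)
            start = i


def call_cnvs(
    counts: CountMatrix,
    model: BackgroundModel | None,
    opts: SegmentationOptions | None = None,
    lam: np.ndarray | None = None,
) -> list[SegmentCall]:
    """Segment every sample against its background; return all segments.

    Diploid-state segments are kept in the returned list (writers suppress
    them). ``lam`` may be passed directly to segment against an arbitrary
    background matrix (e.g. an SVD reconstruction baseline).
    """
    opts = opts or SegmentationOptions()
    if lam is None:
        if model is None:
            raise ValidationError("either a model or a lam matrix is required")
        lam = model.fitted_mean()
    if lam.shape != counts.values.shape:
        raise ValidationError("lam shape does not match the count matrix")
    targets = counts.targets
    calls: list[SegmentCall] = []
    units = list(_scope_units(counts, opts.scope))
    for j, sid in enumerate(counts.samples.sample_id):
        yj = counts.values[:, j].astype(float)
        for _, idx in units:
            for fs, fe, c, L in segment_sample(yj[idx], lam[idx, j], opts):
                gfs, gfe = int(idx[fs]), int(idx[fe])
                calls.append(
                    SegmentCall(
                        sample_id=str(sid),
                        chrom=str(targets.chrom[gfs]),
                        start=int(targets.start[gfs]),
                        end=int(targets.end[gfe]),
                        first_target=gfs,
                        last_target=gfe,
                        copy_number=max(c, 0.0),
                        lratio=L,
                        state=categorize_state(max(c, 0.0)),
                    )
                )
    calls.sort(key=lambda c: (c.sample_id, c.chrom, c.start))
    return calls
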