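"""Domain containers and TSV readers/writers shared by the whole pipeline.

The containers mirror the objects a read-depth CNV workflow passes around:
an ordered set of genomic targets (exons or bins), a sample sheet, the raw
target-by-sample count matrix, the fitted multiplicative background model,
per-target mixture fits over carrier status, and segment-level CNV calls.

All genomic intervals are held internally in BED convention (0-based,
half-open); 1-based inclusive input is converted on read and back on write
via the ``dialect`` flag.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

STATES = ("two_copy_del", "one_copy_del", "diploid", "gain", "high_gain")
DEL_STATES = frozenset({"two_copy_del", "one_copy_del"})
GAIN_STATES = frozenset({"gain", "high_gain"})
ROLES = ("case", "control", "unlabeled")

TARGET_COLUMNS = ["chrom", "start", "end", "gc", "mappability", "gene"]


class ValidationError(ValueError):
    """Raised when an input violates a container invariant."""


def _as_key(chrom, start, end) -> str:
    return f"{chrom}:{start}-{end}"


class TargetSet:
    """Ordered genomic targets with GC%, mappability and optional gene label.

    Parameters
    ----------
    df : DataFrame with columns chrom, start, end, gc, mappability and an
        optional gene column. Coordinates must already be 0-based half-open.
    """

    def __init__(self, df: pd.DataFrame, dialect: str = "bed"):
        df = df.copy()
        if "gene" not in df.columns:
            df["gene"] = ""
        missing = [c for c in TARGET_COLUMNS if c not in df.columns]
        if missing:
            raise ValidationError(f"target table missing columns: {missing}")
        df = df[TARGET_COLUMNS]
        df["start"] = df["start"].astype(np.int64)
        df["end"] = df["end"].astype(np.int64)
        df["gene"] = df["gene"].fillna("").astype(str)
        if (df["end"] <= df["start"]).any():
            bad = int(np.argmax((df["end"] <= df["start"]).to_numpy()))
            raise ValidationError(f"target row {bad}: end must exceed start")
        if ((df["gc"] < 0) | (df["gc"] > 100)).any():
            raise ValidationError("gc must be a percentage in [0, 100]")
        if ((df["mappability"] < 0) | (df["mappability"] > 1)).any():
            raise ValidationError("mappability must lie in [0, 1]")
        order = np.lexsort((df["start"].to_numpy(), df["chrom"].to_numpy()))
        if not np.array_equal(order, np.arange(len(df))):
            warnings.warn("targets were not sorted by (chrom, start); sorting")
            df = df.iloc[order]
        dup = df.duplicated(subset=["chrom", "start", "end"])
        if dup.any():
            raise ValidationError(
                f"duplicate target interval at row {int(np.argmax(dup.to_numpy()))}"
            )
        df = df.reset_index(drop=True)
        self.df = df
        self.dialect = dialect  # convention the input file used

    # -- convenience accessors -------------------------------------------
    def __len__(self) -> int:
        return len(self.df)

    @property
    def chrom(self) -> np.ndarray:
        return self.df["chrom"].to_numpy()

    @property
    def start(self) -> np.ndarray:
        return self.df["start"].to_numpy()

    @property
    def end(self) -> np.ndarray:
        return self.df["end"].to_numpy()

    @property
    def gc(self) -> np.ndarray:
        return self.df["gc"].to_numpy(dtype=float)

    @property
    def mappability(self) -> np.ndarray:
        return self.df["mappability"].to_numpy(dtype=float)

    @property
    def gene(self) -> np.ndarray:
        return self.df["gene"].to_numpy()

    @property
    def lengths(self) -> np.ndarray:
        return (self.df["end"] - self.df["start"]).to_numpy()

    def keys(self) -> np.ndarray:
        return np.array(
            [_as_key(c, s, e) for c, s, e in zip(self.chrom, self.start, self.end)]
        )

    def subset(self, idx) -> "TargetSet":
        """Restrict to the given positional indices (order-preserving)."""
        idx = np.asarray(idx)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        sub = self.df.iloc[np.sort(idx)].reset_index(drop=True)
        return TargetSet(sub, dialect=self.dialect)

    def __eq__(self, other) -> bool:
        return isinstance(other, TargetSet) and self.df.equals(other.df)


class SampleTable:
    """Sample sheet: unique ids, case/control/unlabeled role, optional batch."""

    def __init__(self, df: pd.DataFrame):
        df = df.copy()
        if "sample_id" not in df.columns:
            raise ValidationError("sample table needs a sample_id column")
        if "role" not in df.columns:
            df["role"] = "unlabeled"
        if "batch" not in df.columns:
            df["batch"] = ""
        df["sample_id"] = df["sample_id"].astype(str)
        df["role"] = df["role"].fillna("unlabeled").astype(str)
        df["batch"] = df["batch"].fillna("").astype(str)
        bad = ~df["role"].isin(ROLES)
        if bad.any():
            raise ValidationError(f"unknown role(s): {sorted(df.loc[bad, 'role'].unique())}")
        if df["sample_id"].duplicated().any():
            raise ValidationError("sample_id values must be unique")
        self.df = df[["sample_id", "role", "batch"]].reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def sample_id(self) -> np.ndarray:
        return self.df["sample_id"].to_numpy()

    @property
    def role(self) -> np.ndarray:
        return self.df["role"].to_numpy()

    @property
    def batch(self) -> np.ndarray:
        return self.df["batch"].to_numpy()

    @property
    def control_indices(self) -> np.ndarray:
        return np.flatnonzero(self.role == "control")

    def subset(self, idx) -> "SampleTable":
        idx = np.asarray(idx)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return SampleTable(self.df.iloc[idx].reset_index(drop=True))

    def __eq__(self, other) -> bool:
        return isinstance(other, SampleTable) and self.df.equals(other.df)


@dataclass
class CountMatrix:
    """Targets x samples raw read-depth counts tied to a TargetSet/SampleTable."""

    values: np.ndarray
    targets: TargetSet
    samples: SampleTable

    def __post_init__(self):
        v = np.asarray(self.values)
        if v.ndim != 2:
            raise ValidationError("count matrix must be 2-D")
        if v.shape != (len(self.targets), len(self.samples)):
            raise ValidationError(
                f"count matrix shape {v.shape} does not match "
                f"{len(self.targets)} targets x {len(self.samples)} samples"
            )
        if not np.issubdtype(v.dtype, np.integer):
            if not np.all(np.isfinite(v)) or np.any(v != np.round(v)):
                raise ValidationError("counts must be finite integers")
            v = v.astype(np.int64)
        if (v < 0).any():
            raise ValidationError("counts must be non-negative")
        self.values = v.astype(np.int64)

    @property
    def n_targets(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def subset_targets(self, idx) -> "CountMatrix":
        idx = np.asarray(idx)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        idx = np.sort(idx)
        return CountMatrix(self.values[idx], self.targets.subset(idx), self.samples)

    def subset_samples(self, idx) -> "CountMatrix":
        idx = np.asarray(idx)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return CountMatrix(self.values[:, idx], self.targets, self.samples.subset(idx))


@dataclass
class BackgroundModel:
    """Fitted multiplicative null model for read depth.

    The expected count for target i in sample j is

        lam_ij = N_j * f_j(GC_i) * beta_i * exp(sum_k g_ik h_jk)

    with N the per-sample library size, f_j a smooth per-sample GC-bias
    curve stored on a common GC grid (linear interpolation, flat beyond the
    grid), beta the per-target capture efficiency, and g, h the rank-K
    latent-factor loadings (g columns orthogonalized).
    """

    library_size: np.ndarray  # (m,)
    gc_grid: np.ndarray  # (B,)
    gc_curves: np.ndarray  # (m, B) per-sample multiplier at each grid point
    beta: np.ndarray  # (n,)
    g: np.ndarray  # (n, K)
    h: np.ndarray  # (m, K)
    K: int
    target_gc: np.ndarray  # (n,) GC% of the targets the model covers
    converged: bool = True
    loglik: float = np.nan
    n_iter: int = 0

    def f_matrix(self) -> np.ndarray:
        """Per-sample GC multiplier evaluated at every target: (n, m)."""
        n, m = len(self.target_gc), len(self.library_size)
        F = np.empty((n, m))
        for j in range(m):
            F[:, j] = np.interp(self.target_gc, self.gc_grid, self.gc_curves[j])
        return F

    def log_bias(self) -> np.ndarray:
        return self.g @ self.h.T

    def fitted_mean(self) -> np.ndarray:
        """The lam-hat matrix (n, m); finite and strictly positive."""
        lam = (
            self.library_size[None, :]
            * self.f_matrix()
            * self.beta[:, None]
            * np.exp(self.log_bias())
        )
        if not np.all(np.isfinite(lam)) or np.any(lam <= 0):
            raise ValidationError("fitted means must be finite and positive")
        return lam

    # -- serialization: JSON header + npz matrix sidecar ------------------
    def save(self, path: str) -> None:
        meta = {"K": int(self.K), "converged": bool(self.converged),
                "loglik": float(self.loglik), "n_iter": int(self.n_iter),
                "sidecar": str(path) + ".npz"}
        with open(path, "w") as fh:
            json.dump(meta, fh, indent=1)
        np.savez(
            str(path) + ".npz",
            library_size=self.library_size, gc_grid=self.gc_grid,
            gc_curves=self.gc_curves, beta=self.beta, g=self.g, h=self.h,
            target_gc=self.target_gc,
        )

    @classmethod
    def load(cls, path: str) -> "BackgroundModel":
        with open(path) as fh:
            meta = json.load(fh)
        arrs = np.load(meta["sidecar"])
        return cls(
            library_size=arrs["library_size"], gc_grid=arrs["gc_grid"],
            gc_curves=arrs["gc_curves"], beta=arrs["beta"], g=arrs["g"],
            h=arrs["h"], K=meta["K"], target_gc=arrs["target_gc"],
            converged=meta["converged"], loglik=meta["loglik"],
            n_iter=meta["n_iter"],
        )


@dataclass
class MixtureFit:
    """Two-component Poisson mixture result for one common-CNV target.

    pi is the carrier incidence rate, mu the log-scale copy-number shift of
    carriers relative to the null, z_posterior the per-sample posterior
    carrier probabilities.
    """

    target_index: int
    pi: float
    mu: float
    z_posterior: np.ndarray
    converged: bool = True
    n_iter: int = 0

    def __post_init__(self):
        if not 0.0 <= self.pi <= 1.0:
            raise ValidationError("pi must lie in [0, 1]")
        z = np.asarray(self.z_posterior, dtype=float)
        if ((z < 0) | (z > 1)).any():
            raise ValidationError("posteriors must lie in [0, 1]")
        self.z_posterior = z


@dataclass
class SegmentCall:
    """One contiguous constant-copy-number segment for one sample."""

    sample_id: str
    chrom: str
    start: int
    end: int
    first_target: int
    last_target: int
    copy_number: float
    lratio: float
    state: str

    def __post_init__(self):
        if self.state not in STATES:
            raise ValidationError(f"unknown state {self.state!r}")
        if self.copy_number < 0:
            raise ValidationError("copy_number must be >= 0")

    @property
    def n_targets(self) -> int:
        return self.last_target - self.first_target + 1


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------

def read_targets(path: str, dialect: str = "bed") -> TargetSet:
    """Read a BED-plus TSV of targets.

    Columns: chrom, start, end, gc, mappability[, gene]; a header line is
    required. ``dialect`` is "bed" (0-based half-open, default) or
    "one-based" (1-based inclusive; converted on read).
    """
    if dialect not in ("bed", "one-based"):
        raise ValidationError(f"unknown coordinate dialect {dialect!r}")
    try:
        df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    except Exception as exc:  # surface the parser's line info
        raise ValidationError(f"failed to parse {path}: {exc}") from exc
    required = ["chrom", "start", "end", "gc", "mappability"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing columns {missing}")
    for col in ("start", "end", "gc", "mappability"):
        bad = pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()
        if bad.any():
            raise ValidationError(
                f"{path}: malformed value in column {col!r} at line {int(bad.idxmax()) + 2}"
            )
        df[col] = pd.to_numeric(df[col])
    if dialect == "one-based":
        df["start"] = df["start"] - 1
    return TargetSet(df, dialect=dialect)


def write_targets(targets: TargetSet, path: str, dialect: str | None = None) -> None:
    dialect = dialect or targets.dialect
    df = targets.df.copy()
    if dialect == "one-based":
        df["start"] = df["start"] + 1
    df.to_csv(path, sep="\t", index=False)


def read_samples(path: str) -> SampleTable:
    return SampleTable(pd.read_csv(path, sep="\t", dtype=str))


def write_samples(samples: SampleTable, path: str) -> None:
    samples.df.to_csv(path, sep="\t", index=False)


def read_counts(path: str, targets: TargetSet, samples: SampleTable) -> CountMatrix:
    """Read a count TSV (first column the target key, one column per sample).

    Rows may be keyed by ``chrom:start-end`` (matched against ``targets``) or
    simply aligned by order with a ``target`` index column.
    """
    df = pd.read_csv(path, sep="\t")
    if df.shape[0] != len(targets):
        raise ValidationError(
            f"{path}: {df.shape[0]} rows but {len(targets)} targets"
        )
    key_col = df.columns[0]
    keys = df[key_col].astype(str).to_numpy()
    expected = targets.keys()
    if not np.array_equal(keys, expected):
        if set(keys) == set(expected):
            df = df.set_index(key_col).loc[expected].reset_index()
        else:
            raise ValidationError(f"{path}: target keys do not match the TargetSet")
    missing = [s for s in samples.sample_id if s not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing sample column(s) {missing}")
    vals = df[list(samples.sample_id)].to_numpy()
    return CountMatrix(vals, targets, samples)


def write_counts(counts: CountMatrix, path: str) -> None:
    df = pd.DataFrame(counts.values, columns=counts.samples.sample_id)
    df.insert(0, "target", counts.targets.keys())
    df.to_csv(path, sep="\t", index=False)


SEGMENT_HEADER = [
    "sample_id", "chrom", "start", "end", "n_targets",
    "copy_number", "lratio", "state",
]


def write_segments(calls: list[SegmentCall], path: str) -> None:
    """Write non-diploid calls as TSV, sorted by (sample, chrom, start).

    Diploid-state segments are suppressed on output (they remain available
    in the in-memory segmentation result).
    """
    rows = [
        (c.sample_id, c.chrom, c.start, c.end, c.n_targets,
         round(c.copy_number, 4), round(c.lratio, 4), c.state)
        for c in calls if c.state != "diploid"
    ]
    rows.sort(key=lambda r: (r[0], r[1], r[2]))
    df = pd.DataFrame(rows, columns=SEGMENT_HEADER)
    df.to_csv(path, sep="\t", index=False)


def segments_to_bed(calls: list[SegmentCall], path: str) -> None:
    """Optional BED export: name=sample:state, score=lratio."""
    rows = [
        (c.chrom, c.start, c.end, f"{c.sample_id}:{c.state}", round(c.lratio, 3))
        for c in calls if c.state != "diploid"
    ]
    rows.sort(key=lambda r: (r[0], r[1]))
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, header=False)
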