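"""Background estimation guarded by negative controls.

Two modes keep common CNV signal out of the fitted background:

* **control samples** — samples known to be copy-number neutral fit the
  target-side parameters (beta, g); each remaining sample then gets its own
  GC curve and sample loading by a single Poisson regression against the
  control-derived target factors.

* **control regions** — targets free of *common* CNVs fit the sample-side
  parameters (N, f, h); for each flagged common-CNV target an EM over the
  unknown per-sample carrier status estimates the target factors (beta, g)
  together with the carrier incidence rate pi and log-scale effect mu. The
  returned background deliberately excludes the carrier effect, so true
  CNV signal survives normalization.

Control regions can be supplied (e.g. known common CNVs as BED) or flagged
empirically from a first-pass fit via the dispersion of normalized
z-scores.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln

from .background import (
    FitOptions,
    _fit_components,
    batched_poisson_regression,
    fit_null,
    zscores,
)
from .data import BackgroundModel, CountMatrix, MixtureFit, ValidationError

_ETA_MAX = 30.0


def _interp_curves(gc, centers, curves):
    """Evaluate per-sample GC curves (m, B) at target GC values -> (n, m)."""
    n, m = len(gc), curves.shape[0]
    F = np.empty((n, m))
    for j in range(m):
        F[:, j] = np.interp(gc, centers, curves[j])
    return F


def _poisson_logpmf(y, lam):
    return y * np.log(lam) - lam - gammaln(y + 1.0)


def _weighted_poisson_newton(y, X, w, offset, b0, steps=8, ridge=1e-9):
    """Weighted Poisson regression (single response vector), Newton steps."""
    b = b0.copy()
    eye = np.eye(X.shape[1])
    for _ in range(steps):
        eta = np.clip(offset + X @ b, -_ETA_MAX, _ETA_MAX)
        mu = np.exp(eta)
        grad = X.T @ (w * (y - mu))
        H = (X * (w * mu)[:, None]).T @ X
        H += ridge * np.trace(H) * eye + 1e-12 * eye
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            step = grad / (np.diag(H) + 1e-12)
        step = np.clip(step, -1.0, 1.0)
        b = b + step
        if np.max(np.abs(step)) < 1e-11:
            break
    return b


# ---------------------------------------------------------------------------
# mode A: negative-control samples
# ---------------------------------------------------------------------------

def normalize_with_control_samples(
    counts: CountMatrix,
    K: int,
    opts: FitOptions | None = None,
    controls=None,
    case_refine_iters: int = 3,
) -> BackgroundModel:
    """Fit the background on control samples; predict it for everyone else.

    ``controls`` is an index array; by default samples with role 'control'
    in the sample table are used. The control submatrix fixes beta and g
    (and the control samples' own N, f, h); each non-control sample keeps
    its observed library size, gets a GC curve from its own binned depth
    ratios, and a sample loading from one Poisson regression on g.
    """
    opts = opts or FitOptions()
    if controls is None:
        controls = counts.samples.control_indices
    controls = np.asarray(controls, dtype=int)
    if controls.size < 2:
        raise ValidationError(
            "need at least 2 negative-control samples; "
            "use control-region mode when no controls are available"
        )
    Y = counts.values.astype(float)
    gc = counts.targets.gc
    n, m = Y.shape
    parts = _fit_components(counts.values[:, controls], gc, K, opts)
    beta, G = parts["beta"], parts["G"]
    centers = parts["centers"]

    cases = np.setdiff1d(np.arange(m), controls)
    N = np.empty(m)
    H = np.empty((m, max(K, 0)))
    curves = np.empty((m, len(centers)))
    N[controls] = parts["N"]
    H[controls] = parts["H"]
    curves[controls] = parts["curves"]

    if cases.size:
        Yc = Y[:, cases]
        Nc = Yc.sum(axis=0)
        if np.any(Nc == 0):
            raise ValidationError("case sample with zero total depth")
        Hc = np.zeros((cases.size, K))
        curves_c = np.ones((cases.size, len(centers)))
        # re-use the control fit's GC bin layout
        from .background import _gc_bin_assign

        _, groups = _gc_bin_assign(gc, opts.gc_bin_width, opts.min_bin_targets)
        Fc = np.ones((n, cases.size))
        for _ in range(case_refine_iters):
            E = np.exp(np.clip(G @ Hc.T, -_ETA_MAX, _ETA_MAX))
            R = Yc / (Nc[None, :] * beta[:, None] * E)
            for b, gidx in enumerate(groups):
                curves_c[:, b] = np.median(R[gidx, :], axis=0)
            curves_c = np.maximum(curves_c, 1e-8)
            for jj in range(cases.size):
                Fc[:, jj] = np.interp(gc, centers, curves_c[jj])
            if K > 0:
                offset = np.log(Nc)[None, :] + np.log(Fc) + np.log(beta)[:, None]
                Hc = batched_poisson_regression(Yc.T, G, offset.T, Hc)
        N[cases] = Nc
        H[cases] = Hc
        curves[cases] = curves_c

    return BackgroundModel(
        library_size=N, gc_grid=centers, gc_curves=curves, beta=beta,
        g=G, h=H, K=K, target_gc=gc, converged=parts["converged"],
        loglik=parts["loglik"], n_iter=parts["n_iter"],
    )


# ---------------------------------------------------------------------------
# control-region identification
# ---------------------------------------------------------------------------

@dataclass
class ControlRegions:
    """Split of targets into putative common-CNV targets and the rest."""

    istar: np.ndarray  # indices flagged as harboring common CNVs
    complement: np.ndarray  # negative-control region indices
    zstats: "object" = None  # per-target z dispersion table (DataFrame)
    first_pass: BackgroundModel | None = None


def _spatial_close(flag: np.ndarray, chrom: np.ndarray, pad: int, max_gap: int):
    """Dilate the flag mask and close short gaps within each chromosome.

    Common CNVs span consecutive targets, while the per-target dispersion
    rules fire stochastically near their thresholds; padding each flagged
    target by ``pad`` neighbors and filling gaps up to ``max_gap`` targets
    turns patchy per-target flags into coherent regions.
    """
    out = flag.copy()
    n = flag.size
    boundaries = np.flatnonzero(np.r_[True, chrom[1:] != chrom[:-1], True])
    for lo, hi in zip(boundaries[:-1], boundaries[1:]):
        seg = flag[lo:hi]
        if not seg.any():
            continue
        mask = seg.copy()
        if pad > 0:
            for i in np.flatnonzero(seg):
                mask[max(i - pad, 0) : i + pad + 1] = True
        if max_gap > 0:
            on = np.flatnonzero(mask)
            gaps = np.diff(on)
            for k in np.flatnonzero((gaps > 1) & (gaps <= max_gap + 1)):
                mask[on[k] : on[k + 1]] = True
        out[lo:hi] = mask
    return out


def _grow_regions(z: np.ndarray, flag: np.ndarray, chrom: np.ndarray, min_diff: float):
    """Extend flagged runs while neighbors share the run's carrier split.

    A CNV has one carrier set across all the targets it spans, so a run of
    flagged targets defines a consensus split of the samples (low vs high
    mean z over the run); adjacent targets whose carrier-vs-noncarrier
    mean-z contrast exceeds ``min_diff`` belong to the same event and are
    pulled into I*. Runs flagged by noise produce an uninformative split
    whose contrast vanishes off the run, so they do not grow.
    """
    out = flag.copy()
    n = flag.size
    boundaries = np.flatnonzero(np.r_[True, chrom[1:] != chrom[:-1], True])
    for lo, hi in zip(boundaries[:-1], boundaries[1:]):
        seg = flag[lo:hi]
        if not seg.any():
            continue
        edges = np.flatnonzero(np.diff(np.r_[0, seg.view(np.int8), 0]))
        for a, b in zip(edges[::2], edges[1::2]):
            s = z[lo + a : lo + b].mean(axis=0)
            mid = (s.max() + s.min()) / 2.0
            C = s < mid
            if C.sum() == 0 or C.sum() == C.size:
                continue

            def contrast(i):
                return abs(z[i, C].mean() - z[i, ~C].mean())

            i = lo + a - 1
            while i >= lo and not out[i] and contrast(i) > min_diff:
                out[i] = True
                i -= 1
            i = lo + b
            while i < hi and not out[i] and contrast(i) > min_diff:
                out[i] = True
                i += 1
    return out


def identify_control_regions(
    counts: CountMatrix,
    K: int,
    opts: FitOptions | None = None,
    sd_max: float = 0.3,
    z_max: float = 0.8,
    z_min: float = -0.8,
    neighbor_pad: int = 2,
    max_gap: int = 6,
    grow_diff: float = 0.15,
    min_control_targets: int = 200,
    istar=None,
) -> ControlRegions:
    """Flag common-CNV targets from a first-pass fit of all samples.

    A target enters I* when the across-sample SD of its normalized z-scores
    exceeds ``sd_max``, or any z exceeds ``z_max`` / falls below ``z_min``
    (defaults 0.3 / 0.8 / -0.8). Because common CNVs span consecutive
    targets, the raw flags are then made spatially coherent: each flagged
    target drags in ``neighbor_pad`` neighbors and runs separated by at
    most ``max_gap`` unflagged targets are joined (set both to 0 for the
    bare per-target rules). Alternatively pass explicit indices ``istar``
    (e.g. known common CNVs from a BED file) to skip the first pass.
    """
    import pandas as pd

    n = counts.n_targets
    if istar is not None:
        istar = np.unique(np.asarray(istar, dtype=int))
        comp = np.setdiff1d(np.arange(n), istar)
        if comp.size < min_control_targets:
            raise ValidationError(
                f"only {comp.size} negative-control targets remain "
                f"(floor {min_control_targets})"
            )
        return ControlRegions(istar=istar, complement=comp)
    opts = opts or FitOptions()
    model = fit_null(counts, K, opts)
    z = zscores(counts, model)
    sd = z.std(axis=1)
    zmx = z.max(axis=1)
    zmn = z.min(axis=1)
    flag = (sd > sd_max) | (zmx > z_max) | (zmn < z_min)
    flag = _spatial_close(flag, counts.targets.chrom, neighbor_pad, max_gap)
    if grow_diff > 0:
        flag = _grow_regions(z, flag, counts.targets.chrom, grow_diff)
    istar = np.flatnonzero(flag)
    comp = np.flatnonzero(~flag)
    if comp.size < min_control_targets:
        raise ValidationError(
            f"only {comp.size} negative-control targets remain "
            f"(floor {min_control_targets}); relax thresholds or supply I*"
        )
    stats = pd.DataFrame({"sd": sd, "z_max": zmx, "z_min": zmn, "flagged": flag})
    return ControlRegions(istar=istar, complement=comp, zstats=stats, first_pass=model)


# ---------------------------------------------------------------------------
# mode B: negative-control regions with EM over carrier status
# ---------------------------------------------------------------------------

def fit_mixture(
    y: np.ndarray,
    offset: np.ndarray,
    h: np.ndarray,
    mu_fixed: float | None = None,
    max_iter: int = 500,
    tol: float = 1e-8,
    target_index: int = -1,
):
    """EM fit of the two-component Poisson mixture for one target.

    Observed counts y (one per sample) follow Poisson(lam_j e^{mu Z_j})
    with lam_j = exp(offset_j + log beta + g . h_j) and latent carrier
    indicators Z_j ~ Bernoulli(pi). Returns (log_beta, g, MixtureFit); the
    coefficients describe the *null* component, i.e. the background with
    the carrier effect excluded.

    mu may be fixed (e.g. log(1/2) for a heterozygous deletion) or free;
    with free mu the label-swapped solution has identical likelihood, so
    the orientation with pi <= 0.5 is reported.
    """
    y = np.asarray(y, dtype=float)
    m = y.size
    K = h.shape[1] if h.ndim == 2 else 0
    Xnull = np.column_stack([np.ones(m), h]) if K else np.ones((m, 1))

    def null_fit():
        b = np.zeros(K + 1)
        b[0] = np.log(max(y.mean(), 1e-8)) - np.mean(offset)
        b = _weighted_poisson_newton(y, Xnull, np.ones(m), offset, b, steps=12)
        return b

    b = null_fit()
    lam0 = np.exp(np.clip(offset + Xnull @ b, -_ETA_MAX, _ETA_MAX))
    resid = np.log(np.maximum(y, 1.0) / lam0)

    def null_result(conv=True, iters=0):
        fit = MixtureFit(
            target_index=target_index, pi=0.0, mu=0.0,
            z_posterior=np.zeros(m), converged=conv, n_iter=iters,
        )
        return b[0], b[1:], fit

    # stacked design: each sample appears once per carrier state
    y2 = np.concatenate([y, y])
    off2 = np.concatenate([offset, offset])
    zcol = np.concatenate([np.zeros(m), np.ones(m)])

    def run_em(w0, mu0):
        """EM from a starting posterior; returns (ll, result tuple)."""
        w = w0.copy()
        mu = float(mu0)
        if mu_fixed is None:
            X2 = np.column_stack([np.vstack([Xnull, Xnull]), zcol])
            coef = np.concatenate([b, [mu]])
        else:
            X2 = np.vstack([Xnull, Xnull])
            coef = b.copy()
        bb = b.copy()
        ll_prev = -np.inf
        ll = -np.inf
        ll_trace = []
        converged = False
        it = 0
        for it in range(1, max_iter + 1):
            # M-step (uses current posteriors w)
            pi = float(np.mean(w))
            if pi < 1e-3 or pi > 1 - 1e-3:
                return None  # degenerate: collapse to the null fit
            w2 = np.concatenate([1 - w, w])
            if mu_fixed is None:
                coef = _weighted_poisson_newton(y2, X2, w2, off2, coef, steps=5)
                bb, mu = coef[:-1], float(coef[-1])
            else:
                coef = _weighted_poisson_newton(
                    y2, X2, w2, off2 + mu * zcol, coef, steps=5
                )
                bb = coef
            # E-step
            lam = np.exp(np.clip(offset + Xnull @ bb, -_ETA_MAX, _ETA_MAX))
            l0 = _poisson_logpmf(y, lam) + np.log1p(-pi)
            l1 = _poisson_logpmf(y, lam * np.exp(mu)) + np.log(pi)
            tot = np.logaddexp(l0, l1)
            w = np.exp(l1 - tot)
            ll = float(tot.sum())
            ll_trace.append(ll)
            if np.isfinite(ll_prev) and abs(ll - ll_prev) <= tol * max(abs(ll_prev), 1.0):
                converged = True
                break
            ll_prev = ll
        return ll, bb, mu, w, converged, it, ll_trace

    # candidate starts: the displaced-low group as carriers, or everyone
    # but the displaced-high group (misanchored null at high incidence)
    lo, hi = resid < -0.2, resid > 0.2
    starts = []
    if mu_fixed is not None:
        want_lo = mu_fixed < 0
        direct = lo if want_lo else hi
        flipped = ~hi if want_lo else ~lo
        if direct.sum() > 0:
            starts.append((direct, mu_fixed))
        if 0 < flipped.sum() < m:
            starts.append((flipped, mu_fixed))
    else:
        if lo.sum() or hi.sum():
            cand = lo if lo.sum() >= hi.sum() else hi
            starts.append((cand, float(np.median(resid[cand]))))
    if not starts:
        return null_result()

    # a mixture solution must beat the single-component fit; local optima
    # that mis-anchor the null (e.g. everyone a carrier) fall below it
    ll_null = float(np.sum(_poisson_logpmf(y, lam0)))
    best = None
    for cand, mu0 in starts:
        w0 = np.where(cand, 0.9, 0.1)
        res = run_em(w0, mu0)
        if res is not None and (best is None or res[0] > best[0]):
            best = res
    if best is None or best[0] <= ll_null:
        return null_result()
    _, bfit, mu, w, converged, it, ll_trace = best

    pi = float(np.clip(np.mean(w), 0.0, 1.0))
    if mu_fixed is None and pi > 0.5:  # label-swap: report the minority branch
        bfit = bfit.copy()
        bfit[0] += mu
        mu = -mu
        pi = 1.0 - pi
        w = 1.0 - w
    fit = MixtureFit(
        target_index=target_index, pi=pi, mu=float(mu),
        z_posterior=np.clip(w, 0.0, 1.0), converged=converged, n_iter=it,
    )
    fit.ll_trace = np.array(ll_trace)  # EM monotonicity diagnostics
    return bfit[0], bfit[1:], fit


def normalize_with_control_regions(
    counts: CountMatrix,
    istar,
    K: int,
    opts: FitOptions | None = None,
    mu_fixed: float | None = None,
    em_max_iter: int = 500,
    em_tol: float = 1e-8,
) -> tuple[BackgroundModel, list[MixtureFit]]:
    """Fit the background with sample-side parameters from control regions.

    N, f and h come from a full fit restricted to the complement of
    ``istar``; beta and g for each flagged target come from the EM mixture
    over carrier status. The returned background excludes the carrier
    effect mu, so carriers keep their signal after normalization.
    """
    opts = opts or FitOptions()
    n, m = counts.values.shape
    istar = np.unique(np.asarray(istar, dtype=int)) if len(np.atleast_1d(istar)) else np.empty(0, int)
    comp = np.setdiff1d(np.arange(n), istar)
    if comp.size < max(K + 2, 10):
        raise ValidationError("too few negative-control targets to fit the background")
    gc = counts.targets.gc
    parts = _fit_components(counts.values[comp], gc[comp], K, opts)
    N, Hm, centers = parts["N"], parts["H"], parts["centers"]
    F_all = _interp_curves(gc, centers, parts["curves"])

    beta = np.empty(n)
    G = np.zeros((n, max(K, 0)))
    beta[comp] = parts["beta"]
    if K > 0:
        G[comp] = parts["G"]
    fits: list[MixtureFit] = []
    Yf = counts.values.astype(float)
    logN = np.log(N)
    for i in istar:
        off = logN + np.log(F_all[i])
        blog, gvec, fit = fit_mixture(
            Yf[i], off, Hm, mu_fixed=mu_fixed,
            max_iter=em_max_iter, tol=em_tol, target_index=int(i),
        )
        beta[i] = np.exp(blog)
        if K > 0:
            G[i] = gvec
        fits.append(fit)

    model = BackgroundModel(
        library_size=N, gc_grid=centers, gc_curves=parts["curves"],
        beta=beta, g=G, h=Hm, K=K, target_gc=gc,
        converged=parts["converged"] and all(f.converged for f in fits),
        loglik=parts["loglik"], n_iter=parts["n_iter"],
    )
    return model, fits


def posterior_carriers(fits: list[MixtureFit], cutoff: float = 0.5) -> np.ndarray:
    """Threshold posterior carrier probabilities (strictly above cutoff).

    For reporting only — segmentation works on z-scores, not these labels.
    """
    if not fits:
        return np.zeros((0, 0), dtype=bool)
    return np.vstack([f.z_posterior > cutoff for f in fits])


def mixture_table(fits: list[MixtureFit]):
    """Summarize per-target mixture fits as a DataFrame (TSV-friendly)."""
    import pandas as pd

    return pd.DataFrame(
        {
            "target": [f.target_index for f in fits],
            "pi": [f.pi for f in fits],
            "mu": [f.mu for f in fits],
            "converged": [f.converged for f in fits],
            "n_iter": [f.n_iter for f in fits],
        }
    )
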