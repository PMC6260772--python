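"""Poisson latent-factor background model for read-depth count matrices.

The null model for the count of target i in sample j is

    Y_ij ~ Poisson(lam_ij),   lam_ij = N_j f_j(GC_i) beta_i exp(sum_k g_ik h_jk)

with N_j the library size (column total, held fixed), f_j a smooth
sample-specific GC-bias curve, beta_i a target-specific capture factor, and
g, h rank-K latent loadings capturing unmeasured systematic variation
(batch, capture chemistry). Fitting alternates closed-form / generalized
linear model updates for each block and finishes with a rank-K SVD of the
fitted log-bias matrix so the g columns are mutually orthogonal.

The module also provides normalized z-scores log(Y / lam_hat), model
selection over K by AIC / BIC / variance reduction, and the SVD baseline
normalization used by PCA-style callers for comparison.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data import BackgroundModel, CountMatrix, ValidationError

_ETA_MAX = 30.0


@dataclass
class FitOptions:
    """Tuning knobs for the iterative fit.

    gc_bin_width is in GC percentage points; bins holding fewer than
    min_bin_targets targets are merged with a neighbor before the per-bin
    medians are taken. tol is the relative log-likelihood change declaring
    convergence. seed only matters for randomized restarts (none by
    default); the standard initialization is deterministic.
    """

    max_iter: int = 100
    tol: float = 1e-6
    gc_bin_width: float = 2.0
    min_bin_targets: int = 10
    f_estimator: str = "median"  # or "mle" (per-bin Poisson MLE)
    newton_steps: int = 4
    seed: int = 0


# ---------------------------------------------------------------------------
# small numerical helpers
# ---------------------------------------------------------------------------

def _gc_bin_assign(gc: np.ndarray, width: float, min_targets: int):
    """Assign targets to GC bins of the given width, merging sparse bins.

    Returns (bin centers, list of index arrays), ordered by GC.
    """
    lo = np.floor(gc.min() / width) * width
    hi = np.ceil(gc.max() / width) * width
    edges = np.arange(lo, hi + width, width)
    if len(edges) < 2:
        edges = np.array([lo, lo + width])
    idx = np.clip(np.digitize(gc, edges) - 1, 0, len(edges) - 2)
    groups = [np.flatnonzero(idx == b) for b in range(len(edges) - 1)]
    groups = [g for g in groups if g.size > 0]
    # merge sparse bins into their (left) neighbor
    merged: list[np.ndarray] = []
    for g in groups:
        if merged and (g.size < min_targets or merged[-1].size < min_targets):
            merged[-1] = np.concatenate([merged[-1], g])
        else:
            merged.append(g)
    if len(merged) > 1 and merged[0].size < min_targets:
        merged[1] = np.concatenate([merged[0], merged[1]])
        merged = merged[1:]
    centers = np.array([gc[g].mean() for g in merged])
    order = np.argsort(centers)
    return centers[order], [merged[o] for o in order]


def batched_poisson_regression(
    Y: np.ndarray,
    X: np.ndarray,
    offset: np.ndarray,
    B0: np.ndarray,
    steps: int = 4,
    ridge: float = 1e-8,
) -> np.ndarray:
    """Fit R independent Poisson log-linear regressions sharing one design.

    Y, offset: (R, C); X: (C, K); B0: (R, K) starting coefficients.
    Newton-Raphson with clipped steps; exact per-row MLE is not required
    because the caller iterates the outer loop to convergence.
    """
    B = B0.copy()
    K = X.shape[1]
    if K == 0:
        return B
    eye = np.eye(K)
    for _ in range(steps):
        eta = np.clip(offset + B @ X.T, -_ETA_MAX, _ETA_MAX)
        mu = np.exp(eta)
        grad = (Y - mu) @ X  # (R, K)
        H = np.einsum("rc,ck,cl->rkl", mu, X, X)
        H += ridge * np.trace(H, axis1=1, axis2=2)[:, None, None] * eye + 1e-12 * eye
        try:
            step = np.linalg.solve(H, grad[..., None])[..., 0]
        except np.linalg.LinAlgError:
            step = grad / (np.einsum("rkk->rk", H) + 1e-12)
        step = np.clip(step, -1.0, 1.0)
        B = B + step
        if np.max(np.abs(step)) < 1e-10:
            break
    return B


def poisson_loglik(Y: np.ndarray, lam: np.ndarray) -> float:
    """Poisson log-likelihood up to the additive log(Y!) constant."""
    return float(np.sum(Y * np.log(lam) - lam))


# ---------------------------------------------------------------------------
# the fit
# ---------------------------------------------------------------------------

def _fit_components(Y: np.ndarray, gc: np.ndarray, K: int, opts: FitOptions):
    """Alternating fit on raw arrays. Returns a dict of fitted blocks."""
    n, m = Y.shape
    if np.any(Y.sum(axis=0) == 0):
        raise ValidationError("sample with zero total depth; run filter_samples first")
    if K >= min(n, m) or K < 0:
        raise ValidationError(f"K={K} must satisfy 0 <= K < min(n, m)")

    Yf = Y.astype(float)
    N = Yf.sum(axis=0)
    centers, groups = _gc_bin_assign(gc, opts.gc_bin_width, opts.min_bin_targets)
    beta = Yf.sum(axis=1) / N.sum()
    F = np.ones((n, m))
    curves = np.ones((m, len(centers)))
    G = np.zeros((n, K))
    H = np.zeros((m, K))
    ll_prev = -np.inf
    ll_trace: list[float] = []
    converged = False
    it = 0

    for it in range(1, opts.max_iter + 1):
        E = np.exp(np.clip(G @ H.T, -_ETA_MAX, _ETA_MAX))
        # --- f-step: per-sample GC curve from binned medians of ratios ---
        base = N[None, :] * beta[:, None] * E
        if opts.f_estimator == "mle":
            for b, gidx in enumerate(groups):
                curves[:, b] = Yf[gidx, :].sum(axis=0) / base[gidx, :].sum(axis=0)
        else:
            R = Yf / base
            for b, gidx in enumerate(groups):
                curves[:, b] = np.median(R[gidx, :], axis=0)
        curves = np.maximum(curves, 1e-8)
        # f keeps its per-sample scale: beta is per-target and N is fixed,
        # so the sample-level correction has nowhere else to live
        for j in range(m):
            F[:, j] = np.interp(gc, centers, curves[j])
        # --- beta-step: closed-form Poisson MLE given everything else ---
        denom = (N[None, :] * F * E).sum(axis=1)
        beta = Yf.sum(axis=1) / denom
        offset = np.log(N)[None, :] + np.log(F) + np.log(beta)[:, None]
        # --- latent factors ---
        if K > 0:
            if it == 1:
                Lr = np.log((Yf + 0.5) / np.exp(offset))
                U, s, Vt = np.linalg.svd(Lr - Lr.mean(), full_matrices=False)
                G = U[:, :K] * s[:K]
                H = Vt[:K].T
            G = batched_poisson_regression(Yf, H, offset, G, opts.newton_steps)
            H = batched_poisson_regression(Yf.T, G, offset.T, H, opts.newton_steps)
            # keep the g/h scale split well-conditioned between iterations
            norms = np.linalg.norm(H, axis=0) / np.sqrt(m)
            norms = np.where(norms > 0, norms, 1.0)
            H /= norms[None, :]
            G *= norms[None, :]
        lam = np.exp(np.clip(offset + G @ H.T, -_ETA_MAX, _ETA_MAX))
        ll = poisson_loglik(Yf, lam)
        ll_trace.append(ll)
        if np.isfinite(ll_prev) and abs(ll - ll_prev) <= opts.tol * abs(ll_prev):
            converged = True
            break
        ll_prev = ll

    if K > 0:  # orthogonalize: rank-K SVD of the fitted log-bias matrix
        M = G @ H.T
        U, s, Vt = np.linalg.svd(M, full_matrices=False)
        G = U[:, :K] * s[:K]
        H = Vt[:K].T
    return {
        "N": N, "beta": beta, "curves": curves, "centers": centers,
        "F": F, "G": G, "H": H, "loglik": ll_trace[-1],
        "ll_trace": np.array(ll_trace), "converged": converged, "n_iter": it,
    }


def fit_null(counts: CountMatrix, K: int, opts: FitOptions | None = None) -> BackgroundModel:
    """Fit the Poisson latent-factor null model with K latent factors."""
    opts = opts or FitOptions()
    parts = _fit_components(counts.values, counts.targets.gc, K, opts)
    model = BackgroundModel(
        library_size=parts["N"], gc_grid=parts["centers"],
        gc_curves=parts["curves"], beta=parts["beta"], g=parts["G"],
        h=parts["H"], K=K, target_gc=counts.targets.gc,
        converged=parts["converged"], loglik=parts["loglik"],
        n_iter=parts["n_iter"],
    )
    model.ll_trace = parts["ll_trace"]  # iteration diagnostics
    return model


def zscores(
    counts: CountMatrix, model: BackgroundModel, pseudocount: float = 1.0
) -> np.ndarray:
    """Normalized z-scores log(Y / lam_hat); zero counts get the pseudocount."""
    lam = model.fitted_mean()
    if lam.shape != counts.values.shape:
        raise ValidationError("model shape does not match counts")
    Y = counts.values.astype(float)
    Y = np.where(Y == 0, pseudocount, Y)
    return np.log(Y / lam)


def model_selection(
    counts: CountMatrix,
    K_range,
    opts: FitOptions | None = None,
    elbow_fraction: float = 0.95,
):
    """Fit every K in K_range; report AIC, BIC and variance reduction.

    AIC = 2 loglik - 2 df and BIC = 2 loglik - df log(nm) with
    df = K (n + m - K) counting the factor parameters only, both on a
    larger-is-better scale. Variance reduction compares the z-score
    variance at K factors with the factor-free fit. The variance-reduction
    choice takes the smallest K reaching ``elbow_fraction`` of the maximal
    reduction (the elbow); AIC/BIC choices maximize, smallest K on ties.
    """
    import pandas as pd

    opts = opts or FitOptions()
    K_range = sorted(set(int(k) for k in K_range))
    n, m = counts.values.shape
    if any(k < 1 or k >= min(n, m) for k in K_range):
        raise ValidationError("K_range must satisfy 1 <= K < min(n, m)")
    base = fit_null(counts, 0, opts)
    var0 = float(np.var(zscores(counts, base)))
    rows = []
    models = {}
    for K in K_range:
        mod = fit_null(counts, K, opts)
        models[K] = mod
        df = K * (n + m - K)
        ll = mod.loglik
        varK = float(np.var(zscores(counts, mod)))
        rows.append(
            {
                "K": K,
                "loglik": ll,
                "df": df,
                "AIC": 2 * ll - 2 * df,
                "BIC": 2 * ll - df * np.log(n * m),
                "variance_reduction": 1.0 - varK / var0,
            }
        )
    table = pd.DataFrame(rows)
    chosen = {
        "aic": int(table.loc[table["AIC"].idxmax(), "K"]),
        "bic": int(table.loc[table["BIC"].idxmax(), "K"]),
    }
    vr = table["variance_reduction"].to_numpy()
    target = elbow_fraction * vr.max()
    chosen["varred"] = int(table["K"].iloc[int(np.argmax(vr >= target))])
    return table, chosen, models


def svd_normalize(counts: CountMatrix, K: int) -> np.ndarray:
    """SVD baseline: remove the rank-K reconstruction, standardize columns.

    This is the normalization style of PCA/SVD read-depth callers:
    Y* = Y - U_K D_K V_K^T followed by column standardization.
    """
    Y = counts.values.astype(float)
    n, m = Y.shape
    if not 0 <= K < min(n, m):
        raise ValidationError(f"K={K} must satisfy 0 <= K < min(n, m)")
    if K > 0:
        U, s, Vt = np.linalg.svd(Y, full_matrices=False)
        resid = Y - (U[:, :K] * s[:K]) @ Vt[:K]
    else:
        resid = Y.copy()
    sd = resid.std(axis=0)
    zero = np.flatnonzero(sd <= 1e-9 * max(1.0, np.abs(Y).max()))
    if zero.size:
        ids = counts.samples.sample_id[zero]
        raise ValidationError(f"constant residual column for sample(s) {list(ids)}")
    return (resid - resid.mean(axis=0)) / sd
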