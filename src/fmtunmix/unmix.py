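"""Temporal unmixing engines: convex extreme-point separation (CAMNS),
eigenvalue source counting, and PCA/ICA baselines.

The convex route treats the K sum-normalized frames as points in the
(P-1)-dimensional affine hull of the P source patterns.  Under local
dominance (every source owns at least one pure pixel) the sources are
exactly the extreme points of the polyhedron

    { s = H beta + d : s >= 0 } ,

where d is the mean observation and H an orthonormal basis of the
centered observation span.  Each extreme point is found by minimizing and
maximizing a random linear functional r^T s over the polyhedron (two
linear programs per draw); directions are projected orthogonal to the
extreme points already found so every draw explores a new face.

Orientation convention: sources are the N-pixel spatial patterns and the
K frames are the observations, so the polyhedron lives in pixel space and
its vertices are images.  For source counting the K x K correlation
matrix of the row-centered stack (each frame minus its own pixel mean) is
eigendecomposed; its number of nonnegligible eigenvalues equals the
number of sources.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linprog, nnls
from scipy.stats import chi2

from .errors import (
    DegenerateStackError,
    DimensionError,
    EmptyFrameError,
    InfeasibleGeometryError,
    InsufficientFramesError,
    InvalidParameterError,
    NonIdentifiableError,
)
from .scenes import MeasurementStack


@dataclass(frozen=True)
class EigenReport:
    """Eigenspectrum of the frame correlation matrix and the source count
    read off it."""

    eigenvalues: np.ndarray  # descending, length K
    estimated_P: int
    threshold_used: float
    method_tag: str  # "ratio" | "log-gap"


@dataclass(frozen=True)
class AffineSetModel:
    """Affine hull of the observations: x ~ d + H beta."""

    d: np.ndarray            # (N,) mean observation
    H: np.ndarray            # (N, P-1) orthonormal basis
    P: int
    fit_residual: float      # worst relative energy outside the affine set
    noise_std: float = 0.0   # per-pixel noise scale from the residual


@dataclass
class UnmixResult:
    """Separated sources (max-normalized spatial patterns) and their
    estimated time courses."""

    sources: np.ndarray          # (P, N)
    mixing: np.ndarray           # (K, P)
    method_tag: str
    sources_raw: np.ndarray = None  # before max-normalization
    lp_diagnostics: list = field(default_factory=list)
    has_negative: bool = False
    converged: tuple = ()
    rng_seed: int | None = None


def _maxnorm(v: np.ndarray) -> np.ndarray:
    m = v.max()
    return v / m if m > 0 else v.copy()


def estimate_source_count(stack: MeasurementStack, threshold_ratio: float = 1e-6,
                          method: str = "ratio") -> EigenReport:
    """Count sources from the eigenspectrum of C = (1/N) Xc Xc^T, where Xc
    is the stack with each frame's pixel mean removed.

    ``ratio``: eigenvalues above ``threshold_ratio * lambda_1`` are
    nonnegligible (suited to noise-free data, where the spectrum drops to
    round-off beyond the true rank).  ``log-gap``: the count is placed at
    the largest gap of the log-eigenvalue sequence (suited to noisy data,
    where the trailing eigenvalues sit on a noise floor).
    """
    if stack.K < 2:
        raise InsufficientFramesError("need at least two frames")
    if not stack.background_subtracted:
        raise InvalidParameterError("subtract the background before counting sources")
    Psi = stack.frames
    d = Psi.mean(axis=1)
    Xc = Psi - d[:, None]
    C = (Xc @ Xc.T) / stack.N
    evals = np.linalg.eigvalsh(C)[::-1]
    lam1 = max(evals[0], 0.0)
    if method == "ratio":
        est = int(np.sum(evals > threshold_ratio * lam1)) if lam1 > 0 else 0
        thr = threshold_ratio
    elif method == "log-gap":
        floor = max(lam1, np.finfo(float).tiny) * 1e-40
        logs = np.log(np.maximum(evals, floor))
        gaps = logs[:-1] - logs[1:]
        est = int(np.argmax(gaps)) + 1
        thr = float(np.exp(logs[est - 1]))
    else:
        raise InvalidParameterError(f"unknown method {method!r}")
    est = min(max(est, 1), stack.K)
    return EigenReport(eigenvalues=evals, estimated_P=est,
                       threshold_used=thr, method_tag=method)


def sum_normalize_frames(stack: MeasurementStack):
    """Divide each frame by its pixel sum so that mixing weights sum to one
    and the observation affine hull coincides with the source affine hull.

    Returns (normalized stack, frame_sums); de-normalizing with the sums
    restores the input.
    """
    sums = stack.frames.sum(axis=1)
    if np.any(sums <= 0):
        raise EmptyFrameError("every frame must have positive total intensity")
    out = MeasurementStack(frames=stack.frames / sums[:, None],
                           times=stack.times.copy(),
                           background_subtracted=stack.background_subtracted,
                           sum_normalized=True,
                           meta=dict(stack.meta))
    return out, sums


def affine_set_fit(stack: MeasurementStack, P: int) -> AffineSetModel:
    """Fit the (P-1)-dimensional affine hull of the K frames.

    The basis is obtained through the K x K Gram eigendecomposition of the
    centered frames (cheap: K << N) and mapped back to pixel space, giving
    orthonormal columns.
    """
    if not 2 <= P <= stack.K:
        raise DimensionError(f"need 2 <= P <= K={stack.K}, got P={P}")
    Psi = stack.frames
    d = Psi.mean(axis=0)
    Xc = Psi - d[None, :]
    G = (Xc @ Xc.T) / stack.N
    evals, evecs = np.linalg.eigh(G)
    evals, evecs = evals[::-1], evecs[:, ::-1]
    lam1 = max(evals[0], 0.0)
    if lam1 <= 0 or evals[P - 2] <= 1e-12 * lam1:
        raise DegenerateStackError(
            f"centered stack rank < P-1={P - 1}; cannot span the affine hull")
    H = Xc.T @ (evecs[:, :P - 1] / np.sqrt(stack.N * evals[:P - 1]))
    # worst-case relative energy of any frame outside the fitted affine set
    resid = Xc - (Xc @ H) @ H.T
    norms = np.linalg.norm(Xc, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        rel = np.where(norms > 0, np.linalg.norm(resid, axis=1) / norms, 0.0)
    # the K-(P-1) directions outside the fitted subspace carry only noise;
    # their energy yields a per-pixel noise-scale estimate
    dof = stack.K - (P - 1)
    noise_std = float(np.sqrt((resid**2).sum() / (stack.N * max(dof, 1))))
    return AffineSetModel(d=d, H=H, P=P, fit_residual=float(rel.max()),
                          noise_std=noise_std)


def _weighted_affine_fit(stack: MeasurementStack, P: int, weights: np.ndarray):
    """Affine-hull fit with per-frame inverse-variance weights.

    After sum normalization the noise level of frame k is sigma/sum_k, so
    dim frames are noisier; weighting by sum_k^2 restores statistical
    efficiency.  On noise-free data the fitted affine set is identical to
    the unweighted one (any weighting spans the same hull).
    """
    if not 2 <= P <= stack.K:
        raise DimensionError(f"need 2 <= P <= K={stack.K}, got P={P}")
    w = np.asarray(weights, dtype=float)
    w = w / w.sum()
    Psi = stack.frames
    d = w @ Psi
    Xc = Psi - d[None, :]
    Xw = np.sqrt(w)[:, None] * Xc
    G = (Xw @ Xw.T) / stack.N
    evals, evecs = np.linalg.eigh(G)
    evals, evecs = evals[::-1], evecs[:, ::-1]
    lam1 = max(evals[0], 0.0)
    if lam1 <= 0 or evals[P - 2] <= 1e-12 * lam1:
        raise DegenerateStackError(
            f"centered stack rank < P-1={P - 1}; cannot span the affine hull")
    H = Xw.T @ (evecs[:, :P - 1] / np.sqrt(stack.N * evals[:P - 1]))
    return AffineSetModel(d=d, H=H, P=P, fit_residual=np.nan)


def _solve_lp(c, H, d, slack):
    """min c^T beta subject to H beta + d >= -slack."""
    res = linprog(c, A_ub=-H, b_ub=d + slack, bounds=[(None, None)] * H.shape[1],
                  method="highs")
    if res.status == 2:
        raise InfeasibleGeometryError("observation polyhedron is empty")
    if res.status != 0:
        raise InfeasibleGeometryError(
            f"linear program failed (status {res.status}: {res.message})")
    return res.x


def camns_lp(stack: MeasurementStack, P: int, rng_seed: int = 0,
             max_iters: int | None = None, lp_slack: float = 1e-9,
             novelty_rtol: float = 1e-6) -> UnmixResult:
    """Convex extreme-point separation.

    Sum-normalizes the frames, fits the affine set, then repeatedly draws
    a random direction (projected orthogonal to the extreme points already
    accepted), solves the minimizing and maximizing linear programs over
    the nonnegativity polyhedron, and accepts optimizers that are
    measurably distinct from the points found so far.  Stops when P
    extreme points are found; each is a source pattern up to positive
    scale.  Estimated time courses come from nonnegative least squares of
    the frames on the sources, rescaled by the frame sums.
    """
    if not stack.background_subtracted:
        raise InvalidParameterError("subtract the background before unmixing")
    if stack.sum_normalized:
        nstack, sums = stack, np.ones(stack.K)
    else:
        nstack, sums = sum_normalize_frames(stack)
    rng = np.random.default_rng(rng_seed)
    diagnostics = []

    if P == 1:
        src_raw = nstack.frames.mean(axis=0)[None, :]
        return _finish("camns", src_raw, stack, sums, diagnostics,
                       rng_seed=rng_seed)

    model = _weighted_affine_fit(nstack, P, weights=sums**2)
    H, d = model.H, model.d
    # Noise handling.  The mean observation carries noise of scale
    # sigma/sqrt(K); the polyhedron is relaxed by a few of those sigmas so
    # noise-driven negative pixels do not empty it.  Pixels with no
    # evidence of signal (mean below a few noise sigmas) are dropped from
    # the constraint set: in exact arithmetic their constraints are never
    # active (no source is positive there), while under noise they cut the
    # feasible set at spurious random positions.  For noise-free stacks
    # both devices reduce to the float-round-off slack and the full
    # constraint set.
    # Pixel screening, done on the raw stack where the noise is
    # homoscedastic: a pure-background pixel carries chi^2_K noise energy
    # across the K frames, a signal pixel carries energy far above it.
    # The noise scale comes from the energy outside the rank-P subspace of
    # the raw frames.  A Bonferroni-corrected chi-square cut keeps
    # essentially every signal pixel while rejecting noise-only pixels,
    # whose nonnegativity constraints are never active in exact arithmetic
    # but cut the feasible set at random positions under noise.
    svals = np.linalg.svd(stack.frames, compute_uv=False)
    dof = stack.N * max(stack.K - P, 1)
    sigma_raw = np.sqrt(np.sum(svals[P:] ** 2) / dof)
    energy = (stack.frames**2).sum(axis=0)
    active = energy > sigma_raw**2 * chi2.isf(1e-3 / stack.N, stack.K)
    if not active.any():
        active = np.ones_like(d, dtype=bool)
    # noise level of the weighted mean observation sets the polyhedron slack
    sigma_d = sigma_raw / np.sqrt(np.sum(sums**2))
    slack = lp_slack + 3.0 * sigma_d
    Hc, dc = H[active], d[active]
    novelty_tol = novelty_rtol * np.linalg.norm(d)
    found: list[np.ndarray] = []
    max_iters = max_iters if max_iters is not None else 10 * P
    for draw in range(max_iters):
        w = rng.standard_normal(stack.N)
        if found:
            Q, _ = np.linalg.qr(np.stack(found, axis=1))
            r = w - Q @ (Q.T @ w)
        else:
            r = w
        if np.linalg.norm(r) < 1e-12:
            continue
        entry = {"draw": draw, "accepted": []}

        def _vertex(beta):
            # undo the deliberate slack inflation: shrink the vertex along
            # the ray from the mean until its binding constraint sits at
            # zero rather than at -slack (no-op when slack is round-off)
            v = Hc @ beta + dc
            n_star = int(np.argmin(v))
            if v[n_star] < 0 and dc[n_star] > 0:
                beta = beta * (dc[n_star] / (dc[n_star] - v[n_star]))
            return H @ beta + d

        cands = []
        beta_min = _solve_lp(H.T @ r, Hc, dc, slack)
        cands.append(("p_star", _vertex(beta_min)))
        beta_max = _solve_lp(-(H.T @ r), Hc, dc, slack)
        cands.append(("q_star", _vertex(beta_max)))
        entry["p_star"] = float(r @ cands[0][1])
        entry["q_star"] = float(r @ cands[1][1])
        for tag, s in cands:
            if len(found) >= P:
                break
            if all(np.linalg.norm(s - f) > novelty_tol for f in found):
                found.append(s)
                entry["accepted"].append(tag)
        diagnostics.append(entry)
        if len(found) >= P:
            break
    if len(found) < P:
        raise NonIdentifiableError(
            f"found only {len(found)} of {P} extreme points in "
            f"{max_iters} draws", diagnostics=diagnostics)
    return _finish("camns", np.stack(found), stack, sums, diagnostics,
                   rng_seed=rng_seed)


def _finish(tag, src_raw, stack, sums, diagnostics, rng_seed=None,
            converged=()):
    sources = np.stack([_maxnorm(s) for s in src_raw])
    K, P = stack.K, src_raw.shape[0]
    mixing = np.empty((K, P))
    for k in range(K):
        mixing[k], _ = nnls(sources.T, stack.frames[k])
    return UnmixResult(sources=sources, mixing=mixing, method_tag=tag,
                       sources_raw=src_raw, lp_diagnostics=diagnostics,
                       has_negative=bool((sources < 0).any()),
                       converged=converged, rng_seed=rng_seed)


def _sign_align(S: np.ndarray) -> np.ndarray:
    out = S.copy()
    for i, s in enumerate(out):
        if s[np.argmax(np.abs(s))] < 0:
            out[i] = -s
    return out


def pca_unmix(stack: MeasurementStack, P: int) -> UnmixResult:
    """Principal-component baseline: sources are the top-P principal
    directions of the frame set (centered over frames), sign-aligned and
    max-normalized.  Recovers the true sources only when they are
    spatially orthogonal and their centered courses are uncorrelated."""
    if P > stack.K:
        raise DimensionError(f"P={P} exceeds frame count K={stack.K}")
    Xc = stack.frames - stack.frames.mean(axis=0)
    U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    signs = np.array([np.sign(s[np.argmax(np.abs(s))]) or 1.0 for s in Vt[:P]])
    src_raw = Vt[:P] * signs[:, None]
    sources = np.stack([_maxnorm(s) for s in src_raw])
    mixing = (U[:, :P] * S[:P]) * signs[None, :]
    return UnmixResult(sources=sources, mixing=mixing, method_tag="pca",
                       sources_raw=src_raw,
                       has_negative=bool((sources < 0).any()))


def _fastica_deflation(Z, P, rng, max_iter, tol):
    """One deflation pass of the fixed-point negentropy iteration (log-cosh
    contrast) on whitened data Z (P x N).  Returns (W, flags, contrast)."""
    n = Z.shape[1]
    W = np.zeros((P, P))
    flags = []
    for i in range(P):
        w = rng.standard_normal(P)
        w -= W[:i].T @ (W[:i] @ w)
        w /= np.linalg.norm(w)
        ok = False
        for _ in range(max_iter):
            u = w @ Z
            g = np.tanh(u)
            gp = 1.0 - g**2
            w_new = (Z @ g) / n - gp.mean() * w
            w_new -= W[:i].T @ (W[:i] @ w_new)
            nrm = np.linalg.norm(w_new)
            if nrm < 1e-12:
                w_new = rng.standard_normal(P)
                w_new -= W[:i].T @ (W[:i] @ w_new)
                nrm = np.linalg.norm(w_new)
            w_new /= nrm
            if abs(abs(w_new @ w) - 1.0) < tol:
                w = w_new
                ok = True
                break
            w = w_new
        W[i] = w
        flags.append(ok)
    # negentropy proxy: (E[G(y)] - E[G(gauss)])^2 summed over components,
    # with G(y) = log cosh y
    g_gauss = 0.3745  # E[log cosh z], z standard normal
    proj = W @ Z
    contrast = float(np.sum((np.mean(np.log(np.cosh(proj)), axis=1) - g_gauss) ** 2))
    return W, flags, contrast


def ica_unmix(stack: MeasurementStack, P: int, rng_seed: int = 0,
              max_iter: int = 500, tol: float = 1e-6,
              n_restarts: int = 3) -> UnmixResult:
    """Independent-component baseline: whitening to P components followed
    by fixed-point negentropy maximization (deflation, log-cosh contrast).

    The deflation pass is restarted ``n_restarts`` times from fresh random
    initializations and the solution with the highest total negentropy is
    kept, guarding against occasional convergence to a poor fixed point.
    Deterministic under a fixed seed; non-convergence of a component is
    recorded, not fatal.
    """
    if P > stack.K:
        raise DimensionError(f"P={P} exceeds frame count K={stack.K}")
    rng = np.random.default_rng(rng_seed)
    X = stack.frames
    Xc = X - X.mean(axis=1, keepdims=True)  # center each frame over pixels
    C = (Xc @ Xc.T) / stack.N
    evals, evecs = np.linalg.eigh(C)
    evals, evecs = evals[::-1], evecs[:, ::-1]
    if evals[P - 1] <= 1e-15 * max(evals[0], 1.0):
        raise DegenerateStackError("stack rank below requested component count")
    Wwhite = evecs[:, :P].T / np.sqrt(evals[:P])[:, None]  # (P, K)
    Z = Wwhite @ Xc  # (P, N), identity covariance

    W, flags, best = None, (), -np.inf
    for _ in range(max(1, n_restarts)):
        W_r, flags_r, contrast = _fastica_deflation(Z, P, rng, max_iter, tol)
        if contrast > best:
            W, flags, best = W_r, flags_r, contrast

    Y = W @ Z  # components of the row-centered data
    # The centering step shifts every component image by a constant; the
    # source images are therefore re-derived by regressing the original
    # (uncentered) frames on the estimated mixing courses.
    A_mix, *_ = np.linalg.lstsq(Y.T, X.T, rcond=None)  # (P, K) -> mixing^T
    src_raw, *_ = np.linalg.lstsq(A_mix.T, X, rcond=None)
    src_raw = _sign_align(src_raw)
    sources = np.stack([_maxnorm(s) for s in src_raw])
    mixing, *_ = np.linalg.lstsq(sources.T, X.T, rcond=None)
    return UnmixResult(sources=sources, mixing=mixing.T, method_tag="ica",
                       sources_raw=src_raw,
                       has_negative=bool((sources < 0).any()),
                       converged=tuple(flags), rng_seed=rng_seed)


def brute_force_segment_vertices(stack: MeasurementStack):
    """Independent two-source oracle: for P = 2 the polyhedron
    {beta h + d >= 0} is a segment of the real line; its endpoints (the
    extreme points) follow from a direct sweep of the N one-variable
    constraints.  Returns the two vertex images."""
    if stack.sum_normalized:
        nstack = stack
    else:
        nstack, _ = sum_normalize_frames(stack)
    model = affine_set_fit(nstack, 2)
    h, d = model.H[:, 0], model.d
    lo, hi = -np.inf, np.inf
    for hn, dn in zip(h, d):
        if hn > 0:
            lo = max(lo, -dn / hn)
        elif hn < 0:
            hi = min(hi, -dn / hn)
    if not np.isfinite(lo) or not np.isfinite(hi) or lo > hi:
        raise InfeasibleGeometryError("segment sweep found no bounded segment")
    return np.stack([h * lo + d, h * hi + d])
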