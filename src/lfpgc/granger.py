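"""MVAR-based Granger causality over a multichannel LFP montage.

The pipeline models each analysis segment as a vector autoregression
(VAR): ``x(t) = sum_j A_j x(t-j) + e(t)``, ``Cov(e) = Sigma``.  Granger
causality (GC) from channel *y* to channel *x* is the log-ratio of the
innovation variance of a *reduced* predictor of ``x`` (one that never
sees the past of ``y``) to that of the *full* predictor::

    F_{y->x} = ln( Sigma_reduced[x, x] / Sigma_full[x, x] )

Two reduced-model conventions are provided:

``conditional``
    the reduced model retains every channel except the source; the
    default for time-domain GC matrices.
``bivariate``
    full and reduced models involve the (source, target) pair alone;
    the default for spectral (Geweke) GC.

Reduced models are never refitted to data; they are solved from the
fitted full model's autocovariance sequence with Whittle's multivariate
Levinson-Durbin recursion, so that full and reduced quantities are
consistent with a single estimated model.

Frequency-domain GC uses Geweke's decomposition, whose average over
[0, Nyquist] equals the time-domain statistic in the bivariate case.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg

__all__ = [
    "VARModel",
    "ModelOrderResult",
    "VARFit",
    "GCResult",
    "select_order",
    "fit_var",
    "fit_segment",
    "var_to_autocov",
    "whittle_var",
    "time_gc",
    "spectral_gc",
    "band_gc",
    "analyze_segment",
]

#: spectral-radius margin below 1 that a model must satisfy to count as stable
STABILITY_MARGIN = 1e-6

#: relative tolerance on (reduced - full) innovation variance: small negative
#: excursions (autocovariance truncation, rounding) are clamped to zero GC,
#: anything worse raises
_NEG_REL_TOL = 1e-6


@dataclass
class VARModel:
    """A fitted (or constructed) vector autoregression.

    coeffs : (p, n, n) array, ``coeffs[j-1]`` multiplies lag ``j``
    sigma : (n, n) innovation covariance
    fs : sampling rate in Hz
    """

    coeffs: np.ndarray
    sigma: np.ndarray
    fs: float

    def __post_init__(self) -> None:
        self.coeffs = np.atleast_3d(np.asarray(self.coeffs, dtype=float))
        self.sigma = np.asarray(self.sigma, dtype=float)
        if self.coeffs.ndim != 3 or self.coeffs.shape[1] != self.coeffs.shape[2]:
            raise ValueError("coeffs must have shape (p, n, n)")
        if self.sigma.shape != self.coeffs.shape[1:]:
            raise ValueError("sigma shape does not match coefficient matrices")
        if not np.allclose(self.sigma, self.sigma.T, atol=1e-10):
            raise ValueError("sigma must be symmetric")

    @property
    def order(self) -> int:
        return self.coeffs.shape[0]

    @property
    def n_channels(self) -> int:
        return self.coeffs.shape[1]

    def companion(self) -> np.ndarray:
        return companion_matrix(self.coeffs)

    def spectral_radius(self) -> float:
        return float(np.max(np.abs(np.linalg.eigvals(self.companion()))))

    def is_stable(self, margin: float = STABILITY_MARGIN) -> bool:
        return self.spectral_radius() < 1.0 - margin


def companion_matrix(coeffs: np.ndarray) -> np.ndarray:
    """Block-companion form of a (p, n, n) coefficient stack."""
    coeffs = np.asarray(coeffs, dtype=float)
    p, n, _ = coeffs.shape
    C = np.zeros((n * p, n * p))
    C[:n, :] = np.concatenate(list(coeffs), axis=1)
    if p > 1:
        C[n:, :-n] = np.eye(n * (p - 1))
    return C


@dataclass
class ModelOrderResult:
    order: int
    criterion: np.ndarray  # curve over orders 1..p_max
    orders: np.ndarray
    name: str = "BIC"


@dataclass
class VARFit:
    """Full-model fit context: the estimated VAR, its autocovariance
    sequence, and (optionally) the data it was fitted to."""

    model: VARModel
    autocov: np.ndarray  # (q+1, n, n)
    data: np.ndarray | None = None


@dataclass
class GCResult:
    """Per-segment GC output: time-domain matrix, spectral array, bands.

    Matrices are indexed ``[target, source]`` (``F[i, j]`` is the GC from
    channel j to channel i); diagonals are NaN.
    """

    order: int
    model: VARModel
    time_gc: np.ndarray  # (n, n), NaN diagonal
    freqs: np.ndarray
    spectral: np.ndarray  # (n, n, F), NaN diagonal
    bands: dict[str, np.ndarray] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# estimation


def _lag_gram(data: np.ndarray, p_max: int):
    """Gram matrices of the stacked-lag regression over a fixed sample span.

    Returns (G, C, S0, T_eff) with G = X'X for the order-p_max design,
    C = X'Y, S0 = Y'Y, so any order p <= p_max is solvable from leading
    sub-blocks on the identical effective span.
    """
    T, n = data.shape
    Y = data[p_max:]
    cols = [data[p_max - j:T - j] for j in range(1, p_max + 1)]
    X = np.concatenate(cols, axis=1)
    G = X.T @ X
    C = X.T @ Y
    S0 = Y.T @ Y
    return G, C, S0, Y.shape[0]


def _ols_from_gram(G, C, S0, p, n):
    k = p * n
    Gp = G[:k, :k]
    Cp = C[:k]
    try:
        cf = scipy.linalg.cho_factor(Gp)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - defensive
        raise np.linalg.LinAlgError(
            "rank-deficient lag matrix; lower the model order or provide "
            "more samples"
        ) from exc
    except scipy.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            "rank-deficient lag matrix; lower the model order or provide "
            "more samples"
        ) from exc
    B = scipy.linalg.cho_solve(cf, Cp)  # (k, n)
    rss = S0 - Cp.T @ B  # (n, n) residual cross-products
    rss = (rss + rss.T) / 2.0
    coeffs = np.stack([B[j * n:(j + 1) * n].T for j in range(p)])
    return coeffs, rss


def select_order(data: np.ndarray, p_max: int, fs: float = 1.0) -> ModelOrderResult:
    """Choose the VAR order by the Bayesian information criterion.

    All candidate orders 1..p_max are scored on the same effective sample
    span (the last ``T - p_max`` samples), with

        BIC(p) = ln det Sigma_hat(p) + p n^2 ln(T_eff) / T_eff

    where Sigma_hat is the maximum-likelihood residual covariance.
    """
    data = np.asarray(data, dtype=float)
    T, n = data.shape
    if p_max < 1:
        raise ValueError("p_max must be >= 1")
    if p_max > T / (n**2 + 1):
        raise ValueError(
            f"p_max={p_max} too large for T={T} samples of {n} channels; "
            f"need p_max <= T/(n^2+1) = {T / (n**2 + 1):.1f}"
        )
    G, C, S0, T_eff = _lag_gram(data, p_max)
    bic = np.empty(p_max)
    for p in range(1, p_max + 1):
        _, rss = _ols_from_gram(G, C, S0, p, n)
        sigma_ml = rss / T_eff
        sign, logdet = np.linalg.slogdet(sigma_ml)
        if sign <= 0:
            bic[p - 1] = np.inf
            continue
        bic[p - 1] = logdet + p * n**2 * np.log(T_eff) / T_eff
    order = int(np.argmin(bic)) + 1
    return ModelOrderResult(order=order, criterion=bic,
                            orders=np.arange(1, p_max + 1))


def fit_var(data: np.ndarray, p: int, fs: float = 1.0) -> VARModel:
    """OLS fit of a VAR(p): each sample regressed on p stacked lags.

    The residual covariance uses the small-sample denominator
    ``T_eff - n p - 1``.
    """
    data = np.asarray(data, dtype=float)
    T, n = data.shape
    if T <= n * p + 1:
        raise ValueError(
            f"need more than n*p+1 = {n * p + 1} samples to fit VAR({p}) "
            f"on {n} channels; got {T}"
        )
    G, C, S0, T_eff = _lag_gram(data, p)
    coeffs, rss = _ols_from_gram(G, C, S0, p, n)
    dof = T_eff - n * p - 1
    if dof < 1:
        raise ValueError("not enough residual degrees of freedom")
    sigma = rss / dof
    return VARModel(coeffs=coeffs, sigma=sigma, fs=fs)


def fit_segment(data: np.ndarray, fs: float, p: int | None = None,
                p_max: int = 30, decay_tol: float = 1e-8,
                q_max: int = 500) -> tuple[VARFit, int]:
    """Order-select (unless p given), fit, and precompute the autocovariance."""
    if p is None:
        p = select_order(data, p_max=p_max, fs=fs).order
    model = fit_var(data, p, fs=fs)
    if not model.is_stable():
        raise ValueError(
            f"fitted VAR({p}) is unstable (spectral radius "
            f"{model.spectral_radius():.6f}); segment unusable for GC"
        )
    G = var_to_autocov(model, decay_tol=decay_tol, q_max=q_max)
    return VARFit(model=model, autocov=G, data=data), p


# ---------------------------------------------------------------------------
# autocovariance and Whittle recursion


def var_to_autocov(model: VARModel, q: int | None = None,
                   decay_tol: float = 1e-8, q_max: int = 500) -> np.ndarray:
    """Autocovariance sequence Gamma_0..Gamma_q implied by a stable VAR.

    Gamma_k = E[x(t) x(t-k)'].  Lags 0..p-1 come from the companion-form
    discrete Lyapunov equation; further lags from the Yule-Walker
    recursion Gamma_k = sum_j A_j Gamma_{k-j}.  When ``q`` is None the
    sequence is extended until ||Gamma_q|| / ||Gamma_0|| < decay_tol or
    ``q_max`` is reached.
    """
    if not model.is_stable():
        raise ValueError(
            "unstable VAR model: the Lyapunov autocovariance solution is "
            "invalid (spectral radius "
            f"{model.spectral_radius():.6f})"
        )
    p, n = model.order, model.n_channels
    C = model.companion()
    Q = np.zeros_like(C)
    Q[:n, :n] = model.sigma
    big = scipy.linalg.solve_discrete_lyapunov(C, Q)
    # first block row: Cov(X_t, x_{t-k}) for the companion state
    gammas = [big[:n, k * n:(k + 1) * n] for k in range(p)]
    gammas[0] = (gammas[0] + gammas[0].T) / 2.0

    A = model.coeffs
    g0 = np.linalg.norm(gammas[0])

    def extend_one():
        k = len(gammas)
        acc = np.zeros((n, n))
        for j in range(1, p + 1):
            lag = k - j
            G_lag = gammas[lag] if lag >= 0 else gammas[-lag].T
            acc += A[j - 1] @ G_lag
        gammas.append(acc)

    if q is not None:
        while len(gammas) <= q:
            extend_one()
        return np.stack(gammas[:q + 1])

    while len(gammas) <= max(p, 1):
        extend_one()
    while (np.linalg.norm(gammas[-1]) / g0 >= decay_tol
           and len(gammas) - 1 < q_max):
        extend_one()
    return np.stack(gammas)


def _whittle_batched(G: np.ndarray, p: int | None = None):
    """Whittle's multivariate Levinson-Durbin recursion, batched.

    G : (B, q+1, n, n) autocovariance stacks, G[:, k] = Gamma_k.
    Solves the order-p Yule-Walker system for each batch member,
    returning forward coefficients (B, p, n, n) and innovation
    covariances (B, n, n).
    """
    G = np.asarray(G, dtype=float)
    Bn, qp1, n, _ = G.shape
    q = qp1 - 1
    if p is None:
        p = q
    if p > q:
        raise ValueError(f"autocovariance only available to lag {q} < order {p}")
    A = np.zeros((Bn, p, n, n))  # forward coefficients
    Bk = np.zeros((Bn, p, n, n))  # backward coefficients
    V = G[:, 0].copy()  # forward innovation cov
    W = G[:, 0].copy()  # backward innovation cov
    try:
        np.linalg.cholesky(V)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError("Gamma_0 is singular") from exc
    if _whittle_jit is not None:
        return _whittle_jit(np.ascontiguousarray(G), p)
    # Grev[:, q-m:] == [Gamma_m, ..., Gamma_1], precomputed once
    Grev = G[:, 1:][:, ::-1].copy() if q > 0 else G[:, 1:]
    for m in range(p):
        # Delta = Gamma_{m+1} - sum_{j=1..m} A_j Gamma_{m+1-j}
        delta = G[:, m + 1].copy()
        if m > 0:
            delta -= np.matmul(A[:, :m], Grev[:, q - m:]).sum(axis=1)
        deltaT = np.swapaxes(delta, 1, 2)
        KA = np.linalg.solve(np.swapaxes(W, 1, 2), deltaT)
        KA = np.swapaxes(KA, 1, 2)  # delta @ inv(W)
        KB = np.linalg.solve(np.swapaxes(V, 1, 2), delta)
        KB = np.swapaxes(KB, 1, 2)  # delta' @ inv(V)
        if m > 0:
            A_old = A[:, :m].copy()
            # A_j <- A_j - K_A B_{m+1-j};  B_j <- B_j - K_B A_{m+1-j}
            A[:, :m] = A_old - np.matmul(KA[:, None], Bk[:, :m][:, ::-1])
            Bk[:, :m] = Bk[:, :m] - np.matmul(KB[:, None], A_old[:, ::-1])
        A[:, m] = KA
        Bk[:, m] = KB
        V = V - KA @ deltaT
        W = W - KB @ delta
        V = (V + np.swapaxes(V, 1, 2)) / 2.0
        W = (W + np.swapaxes(W, 1, 2)) / 2.0
    return A, V


def _whittle_core(G: np.ndarray, p: int):
    """Scalar-loop Whittle recursion (jit-compiled when numba is present).

    Same contract as :func:`_whittle_batched`.  Matrix products and the
    symmetric solves are written as explicit loops over the (small)
    channel dimension so the jit compiles them to straight machine code
    instead of per-iteration BLAS/LAPACK calls.
    """
    Bn, qp1, n, _ = G.shape
    A = np.zeros((Bn, p, n, n))
    V = np.zeros((Bn, n, n))
    L = np.zeros((n, n))
    tmp = np.zeros((n, n))
    for b in range(Bn):
        Gb = G[b]
        Ab = np.zeros((p, n, n))
        Bb = np.zeros((p, n, n))
        A_old = np.zeros((p, n, n))
        B_old = np.zeros((p, n, n))
        Vb = Gb[0].copy()
        Wb = Gb[0].copy()
        delta = np.zeros((n, n))
        KA = np.zeros((n, n))
        KB = np.zeros((n, n))
        for m in range(p):
            for r in range(n):
                for c in range(n):
                    acc = Gb[m + 1, r, c]
                    for j in range(m):
                        for k in range(n):
                            acc -= Ab[j, r, k] * Gb[m - j, k, c]
                    delta[r, c] = acc
            # KA = delta W^{-1}; KB = delta' V^{-1}; both via Cholesky
            _chol_lower(Wb, L)
            _right_solve_spd(delta, L, KA, tmp)
            _chol_lower(Vb, L)
            for r in range(n):
                for c in range(n):
                    tmp[r, c] = delta[c, r]
            _right_solve_spd(tmp.copy(), L, KB, tmp)
            if m > 0:
                A_old[:m] = Ab[:m]
                B_old[:m] = Bb[:m]
                for j in range(m):
                    for r in range(n):
                        for c in range(n):
                            sa = A_old[j, r, c]
                            sb = B_old[j, r, c]
                            for k in range(n):
                                sa -= KA[r, k] * B_old[m - 1 - j, k, c]
                                sb -= KB[r, k] * A_old[m - 1 - j, k, c]
                            Ab[j, r, c] = sa
                            Bb[j, r, c] = sb
            Ab[m] = KA
            Bb[m] = KB
            for r in range(n):
                for c in range(n):
                    sa = 0.0
                    sb = 0.0
                    for k in range(n):
                        sa += KA[r, k] * delta[c, k]
                        sb += KB[r, k] * delta[k, c]
                    tmp[r, c] = Vb[r, c] - sa
                    Wb[r, c] = Wb[r, c] - sb
            for r in range(n):
                for c in range(n):
                    Vb[r, c] = 0.5 * (tmp[r, c] + tmp[c, r])
            for r in range(n):
                for c in range(r):
                    s = 0.5 * (Wb[r, c] + Wb[c, r])
                    Wb[r, c] = s
                    Wb[c, r] = s
        A[b] = Ab
        V[b] = Vb
    return A, V


def _chol_lower(M: np.ndarray, L: np.ndarray) -> None:
    """Lower Cholesky factor of a small SPD matrix, written into L."""
    n = M.shape[0]
    for i in range(n):
        for j in range(i + 1):
            s = M[i, j]
            for k in range(j):
                s -= L[i, k] * L[j, k]
            if i == j:
                L[i, j] = np.sqrt(max(s, 1e-300))
            else:
                L[i, j] = s / L[j, j]
        for j in range(i + 1, n):
            L[i, j] = 0.0


def _right_solve_spd(R: np.ndarray, L: np.ndarray, X: np.ndarray,
                     work: np.ndarray) -> None:
    """Solve X (L L') = R for X (rows of R solved independently)."""
    n = L.shape[0]
    for r in range(R.shape[0]):
        # forward: y L' = R_r  -> solve L y' = R_r'
        for i in range(n):
            s = R[r, i]
            for k in range(i):
                s -= L[i, k] * work[r, k]
            work[r, i] = s / L[i, i]
        # backward: x L = y (L lower) -> solve L' x' = y'
        for i in range(n - 1, -1, -1):
            s = work[r, i]
            for k in range(i + 1, n):
                s -= L[k, i] * X[r, k]
            X[r, i] = s / L[i, i]


try:
    import numba

    _chol_lower = numba.njit(cache=False, inline="always")(_chol_lower)
    _right_solve_spd = numba.njit(cache=False, inline="always")(_right_solve_spd)
    _whittle_jit = numba.njit(cache=False)(_whittle_core)
except Exception:  # pragma: no cover - numba genuinely absent
    _whittle_jit = None


def whittle_var(autocov: np.ndarray, p: int | None = None,
                fs: float = 1.0) -> VARModel:
    """Best linear predictor of order p from an autocovariance sequence.

    Solves the multivariate Yule-Walker equations by Whittle's recursion
    and returns the predictor as a :class:`VARModel` whose ``sigma`` is
    the innovation covariance.
    """
    autocov = np.asarray(autocov, dtype=float)
    if autocov.ndim == 1:  # univariate convenience
        autocov = autocov[:, None, None]
    A, V = _whittle_batched(autocov[None], p=p)
    return VARModel(coeffs=A[0], sigma=V[0], fs=fs)


# ---------------------------------------------------------------------------
# GC computation


def _check_ratio(v_red: np.ndarray, v_full: np.ndarray) -> np.ndarray:
    """ln(v_red / v_full) with the nonnegativity contract enforced."""
    rel = (v_red - v_full) / v_full
    if np.any(rel < -_NEG_REL_TOL):
        raise FloatingPointError(
            "reduced-model innovation variance fell below the full model's "
            f"by {float(np.min(rel)):.3e} (relative); numerical failure"
        )
    return np.log(np.maximum(v_red, v_full) / v_full)


def _pair_index_sets(n: int):
    """Unordered channel pairs (i < j) covering all off-diagonal entries."""
    return [(i, j) for i in range(n) for j in range(i + 1, n)]


def time_gc(fit: VARFit, pair_mode: str = "conditional") -> np.ndarray:
    """Time-domain GC matrix F with F[target, source]; NaN diagonal.

    ``conditional``: the reduced model for source y is the order-q Whittle
    solution on the full model's autocovariance restricted to the other
    channels.  ``bivariate``: full and reduced models are fitted by OLS on
    the (target, source) pair alone at the full model's order (requires
    the fit context to carry its data).
    """
    n = fit.model.n_channels
    F = np.full((n, n), np.nan)
    if pair_mode == "conditional":
        sig_full = np.diag(fit.model.sigma)
        G = fit.autocov
        # one reduced model per excluded source: all other channels retained
        Gsub = np.stack([
            G[:, [c for c in range(n) if c != y]][:, :, [c for c in range(n) if c != y]]
            for y in range(n)
        ])
        _, V = _whittle_batched(Gsub)
        for y in range(n):
            keep = [c for c in range(n) if c != y]
            for xi, x in enumerate(keep):
                F[x, y] = _check_ratio(V[y, xi, xi], sig_full[x])
        return F
    if pair_mode == "bivariate":
        if fit.data is None:
            raise ValueError("bivariate time GC requires the fitted data")
        p = fit.model.order
        fs = fit.model.fs
        for (i, j) in _pair_index_sets(n):
            pair = fit.data[:, [i, j]]
            m_pair = fit_var(pair, p, fs=fs)
            m_i = fit_var(fit.data[:, [i]], p, fs=fs)
            m_j = fit_var(fit.data[:, [j]], p, fs=fs)
            F[i, j] = _check_ratio(m_i.sigma[0, 0], m_pair.sigma[0, 0])
            F[j, i] = _check_ratio(m_j.sigma[0, 0], m_pair.sigma[1, 1])
        return F
    raise ValueError(f"unknown pair_mode {pair_mode!r}")


def _pair_models_from_autocov(fit: VARFit):
    """Order-q bivariate models for every unordered pair, via Whittle."""
    n = fit.model.n_channels
    pairs = _pair_index_sets(n)
    G = fit.autocov
    Gp = np.stack([G[:, [i, j]][:, :, [i, j]] for (i, j) in pairs])
    A, V = _whittle_batched(Gp)
    return pairs, A, V


def _geweke_pairs(A: np.ndarray, V: np.ndarray, freqs: np.ndarray, fs: float):
    """Geweke spectral GC for a batch of bivariate models, both directions.

    A : (P, q, 2, 2) coefficients, V : (P, 2, 2) innovation covariances.
    Returns (f_10, f_01), each (P, F): GC from channel 1 into channel 0
    and the reverse, over ``freqs``.
    """
    q = A.shape[1]
    lags = np.arange(1, q + 1)
    phase = np.exp(-2j * np.pi * np.outer(lags, freqs) / fs)  # (q, F)
    Af = np.eye(2)[None, None] - np.einsum("pjxy,jf->pfxy", A, phase)
    det = Af[..., 0, 0] * Af[..., 1, 1] - Af[..., 0, 1] * Af[..., 1, 0]
    H = np.empty_like(Af)
    H[..., 0, 0] = Af[..., 1, 1]
    H[..., 1, 1] = Af[..., 0, 0]
    H[..., 0, 1] = -Af[..., 0, 1]
    H[..., 1, 0] = -Af[..., 1, 0]
    H /= det[..., None, None]

    out = []
    for tgt, src in ((0, 1), (1, 0)):
        v_tt = V[:, tgt, tgt][:, None]
        v_ss = V[:, src, src][:, None]
        v_ts = V[:, tgt, src][:, None]
        h_tt = H[..., tgt, tgt]
        h_ts = H[..., tgt, src]
        s_tt = (np.abs(h_tt) ** 2 * v_tt
                + 2 * np.real(h_tt * np.conj(h_ts)) * v_ts
                + np.abs(h_ts) ** 2 * v_ss)
        # partial source variance after removing its correlation with the
        # target innovation (Geweke's normalization transform leaves
        # H[tgt, src] unchanged)
        sig_src_part = v_ss - v_ts**2 / v_tt
        denom = s_tt - sig_src_part * np.abs(h_ts) ** 2
        rel = denom / np.maximum(s_tt, 1e-300)
        if np.any(rel < -_NEG_REL_TOL):
            raise FloatingPointError(
                "non-positive spectral log-argument beyond tolerance"
            )
        denom = np.maximum(denom, 1e-12 * np.maximum(s_tt, 1e-300))
        out.append(np.maximum(np.log(s_tt / denom), 0.0))
    return out


def spectral_gc(fit: VARFit, freqs: np.ndarray,
                pair_mode: str = "bivariate") -> np.ndarray:
    """Spectral GC array (n, n, F) indexed [target, source, freq].

    Bivariate mode (default): each unordered pair's order-q model is
    solved from the full fit's autocovariance, then decomposed with
    Geweke's formula.  Conditional spectral GC is not provided; the
    conditional option applies to the time-domain matrix.
    """
    if pair_mode != "bivariate":
        raise NotImplementedError(
            "spectral GC is computed with bivariate pair models"
        )
    freqs = np.asarray(freqs, dtype=float)
    fs = fit.model.fs
    if np.any(freqs < 0) or np.any(freqs > fs / 2 + 1e-9):
        raise ValueError("frequency grid must lie within [0, fs/2]")
    n = fit.model.n_channels
    pairs, A, V = _pair_models_from_autocov(fit)
    S = np.full((n, n, freqs.size), np.nan)
    f_ji, f_ij = _geweke_pairs(A, V, freqs, fs)
    for k, (i, j) in enumerate(pairs):
        S[i, j] = f_ji[k]  # j -> i
        S[j, i] = f_ij[k]  # i -> j
    return S


def band_gc(spectra: np.ndarray, freqs: np.ndarray, bands) -> dict[str, np.ndarray]:
    """Band-limited GC matrices: arithmetic mean over grid points inside
    each band (edges inclusive)."""
    from .spectra import band_mean

    return {b.name: band_mean(freqs, spectra, b, axis=-1) for b in bands}


def analyze_segment(data: np.ndarray, fs: float, p: int | None = None,
                    p_max: int = 30, freqs: np.ndarray | None = None,
                    bands=None, time_mode: str = "conditional",
                    decay_tol: float = 1e-8, q_max: int = 500) -> GCResult:
    """Full per-segment GC analysis: order selection, OLS fit,
    autocovariance, time-domain GC, spectral GC, band-limited GC."""
    from .spectra import GC_BANDS

    if freqs is None:
        freqs = np.arange(0.0, fs / 2 + 1e-9, 0.5)
    if bands is None:
        bands = GC_BANDS
    fit, order = fit_segment(data, fs, p=p, p_max=p_max,
                             decay_tol=decay_tol, q_max=q_max)
    tgc = time_gc(fit, pair_mode=time_mode)
    sgc = spectral_gc(fit, freqs)
    bmats = band_gc(sgc, freqs, bands)
    return GCResult(order=order, model=fit.model, time_gc=tgc,
                    freqs=freqs, spectral=sgc, bands=bmats)
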