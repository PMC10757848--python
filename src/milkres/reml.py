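"""Animal-model REML: variance components, heritability, genetic and
phenotypic correlations.

Univariate model:  y = Xβ + Za + e,  a ~ N(0, A σ²a),  e ~ N(0, I σ²e),
with A the pedigree numerator relationship matrix.  The restricted
likelihood is maximized by projecting y onto the orthogonal complement
of the fixed-effect column space, eigendecomposing the projected
relationship structure once, and profiling the total variance so only a
one-dimensional search over the heritability remains.

Bivariate model: the two traits share the additive relationship
structure through A ⊗ G and residual structure I ⊗ R (G, R the 2×2
genetic and residual covariance matrices).  When both traits are
measured on the same cows with the same design matrix the same
projection/eigen trick reduces every likelihood evaluation to O(n);
otherwise a dense-covariance fallback is used.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg, optimize, stats

__all__ = [
    "VarianceComponents",
    "BivariateComponents",
    "RemlError",
    "UnivariateREML",
    "BivariateREML",
    "reml_univariate",
    "reml_bivariate",
    "lrt_variance",
    "gcv",
    "fisher_r_to_z",
]

_EIG_TOL = 1e-9


class RemlError(RuntimeError):
    """Non-convergence or invalid model setup in a REML fit."""


@dataclass
class VarianceComponents:
    """Univariate animal-model REML estimates."""

    sigma2_a: float
    sigma2_e: float
    h2: float
    se_h2: float
    logl: float
    logl_null: float
    n_records: int
    converged: bool
    boundary: bool = False  # σ²a pinned at 0

    @property
    def sigma2_p(self) -> float:
        return self.sigma2_a + self.sigma2_e

    def lrt_p(self, mixture: bool = False) -> float:
        """p-value that σ²a > 0 by likelihood ratio against the
        no-animal-effect model (χ²₁ reference by default; 50:50
        χ²₀/χ²₁ boundary mixture behind the flag)."""
        stat, p = lrt_variance(self.logl, self.logl_null, mixture=mixture)
        return p


@dataclass
class BivariateComponents:
    """Bivariate animal-model REML estimates."""

    G: np.ndarray  # 2x2 additive covariance
    R: np.ndarray  # 2x2 residual covariance
    rg: float
    rp: float
    se_rg: float
    logl: float
    n_records: int
    converged: bool
    boundary: bool = False  # |rg| pinned near 1

    @property
    def P(self) -> np.ndarray:
        return self.G + self.R


def _design_projection(X: np.ndarray) -> tuple[np.ndarray, int]:
    """Orthonormal basis Q2 of the complement of col(X) and rank(X).

    Rank-deficient X (aliased levels) is handled by dropping dependent
    directions; Q2 has n − rank columns.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n = X.shape[0]
    q, r, _ = linalg.qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    rank = int(np.sum(diag > max(n, X.shape[1]) * np.finfo(float).eps * diag.max()))
    Qfull, _ = linalg.qr(X, mode="full")
    return Qfull[:, rank:], rank


class UnivariateREML:
    """Reusable univariate REML solver for a fixed design X and
    relationship kernel K = Z A Z' (n×n over the records).

    The projection and eigendecomposition are computed once; each call
    to :meth:`fit` on a new response is then a 1-D optimization, which
    makes Monte-Carlo replication over phenotypes cheap.
    """

    def __init__(self, X: np.ndarray, K: np.ndarray):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.ndim == 1:
            X = X[:, None]
        n = K.shape[0]
        if X.shape[0] != n:
            raise RemlError(f"X has {X.shape[0]} rows but K is {n}x{n}")
        Q2, rank = _design_projection(X)
        self.n = n
        self.rank_x = rank
        self.df = n - rank
        if self.df < 2:
            raise RemlError("fewer than 2 residual degrees of freedom")
        S = Q2.T @ K @ Q2
        d, U = linalg.eigh((S + S.T) / 2.0)
        d[d < _EIG_TOL] = 0.0
        self.d = d
        self.T = U.T @ Q2.T  # maps y -> rotated residual contrasts

    # -- likelihood pieces ----------------------------------------------
    def _logl(self, w: np.ndarray, sigma2_a: float, sigma2_e: float) -> float:
        v = sigma2_a * self.d + sigma2_e
        if np.any(v <= 0):
            return -np.inf
        return -0.5 * float(np.sum(np.log(v)) + np.sum(w * w / v))

    def fit(self, y: np.ndarray, max_h2: float = 0.999) -> VarianceComponents:
        """Estimate (σ²a, σ²e) for one response vector.

        Profiles the total variance in closed form and searches the
        heritability on (0, ``max_h2``) by bounded scalar minimization;
        a boundary estimate σ²a → 0 is reported as 0 with a flag.
        """
        y = np.asarray(y, dtype=float)
        w = self.T @ y
        ww = w * w
        df = self.df
        d = self.d

        def profiled_neg2(h2: float) -> float:
            # λ = σ²a/σ²e = h2/(1-h2); v_i = λ d_i + 1
            lam = h2 / (1.0 - h2)
            v = lam * d + 1.0
            s2e = float(np.sum(ww / v)) / df
            return float(np.sum(np.log(v))) + df * math.log(s2e)

        res = optimize.minimize_scalar(
            profiled_neg2, bounds=(0.0, max_h2), method="bounded",
            options={"xatol": 1e-10},
        )
        h2_hat = float(res.x)
        # bounded Brent never returns the exact boundary; check it explicitly
        if profiled_neg2(0.0) <= res.fun:
            h2_hat = 0.0
        lam = h2_hat / (1.0 - h2_hat)
        v = lam * d + 1.0
        s2e = float(np.sum(ww / v)) / df
        s2a = lam * s2e
        logl = self._logl(w, s2a, s2e) - 0.5 * df * math.log(2 * math.pi)
        s2e0 = float(np.sum(ww)) / df
        logl0 = self._logl(w, 0.0, s2e0) - 0.5 * df * math.log(2 * math.pi)
        boundary = h2_hat <= 1e-8 or h2_hat >= max_h2 - 1e-6

        se_h2 = self._se_h2(w, s2a, s2e) if not boundary else math.nan
        return VarianceComponents(
            sigma2_a=s2a if not boundary or h2_hat > 0 else 0.0,
            sigma2_e=s2e,
            h2=h2_hat,
            se_h2=se_h2,
            logl=logl,
            logl_null=logl0,
            n_records=self.n,
            converged=True,
            boundary=boundary,
        )

    def _se_h2(self, w: np.ndarray, s2a: float, s2e: float) -> float:
        """Delta-method SE of h² from the observed information in
        (σ²a, σ²e), by central-difference Hessian of the restricted
        log-likelihood."""
        theta = np.array([s2a, s2e])
        h = np.maximum(1e-5, 1e-4 * np.abs(theta))

        def f(t):
            return self._logl(w, t[0], t[1])

        H = np.zeros((2, 2))
        for i in range(2):
            for j in range(i, 2):
                ei = np.zeros(2); ei[i] = h[i]
                ej = np.zeros(2); ej[j] = h[j]
                H[i, j] = H[j, i] = (
                    f(theta + ei + ej) - f(theta + ei - ej)
                    - f(theta - ei + ej) + f(theta - ei - ej)
                ) / (4 * h[i] * h[j])
        try:
            cov = linalg.inv(-H)
        except linalg.LinAlgError:
            return math.nan
        s2p = s2a + s2e
        grad = np.array([s2e, -s2a]) / s2p**2
        var = float(grad @ cov @ grad)
        return math.sqrt(var) if var > 0 else math.nan


def reml_univariate(
    y: np.ndarray,
    X: np.ndarray,
    A: np.ndarray,
    record_animal_index: np.ndarray | None = None,
) -> VarianceComponents:
    """One-shot univariate animal-model REML.

    ``record_animal_index`` maps each record to its row in ``A`` (the
    identity mapping — one record per animal, pedigree order — when
    omitted).  See :class:`UnivariateREML` for the algorithm.
    """
    y = np.asarray(y, dtype=float)
    if record_animal_index is None:
        K = A
    else:
        idx = np.asarray(record_animal_index)
        K = A[np.ix_(idx, idx)]
    return UnivariateREML(X, K).fit(y)


def _chol_from_theta(theta3: np.ndarray) -> np.ndarray:
    L = np.zeros((2, 2))
    L[0, 0] = math.exp(theta3[0])
    L[1, 0] = theta3[1]
    L[1, 1] = math.exp(theta3[2])
    return L


class BivariateREML:
    """Bivariate REML for two traits on the *same* cows with the *same*
    fixed-effect design (the fast, eigendecomposed path).

    Every likelihood evaluation costs O(n) after a single
    eigendecomposition, so replicated simulations and LRTs with the
    genetic covariance pinned at zero are cheap.
    """

    _LOGD_LO, _LOGD_HI = -8.0, 8.0

    def __init__(self, X: np.ndarray, K: np.ndarray):
        self._uni = UnivariateREML(X, K)
        self.d = self._uni.d
        self.n = self._uni.n

    def _nll(
        self, theta: np.ndarray, W: np.ndarray, fix_rg_zero: bool,
        fix_re_zero: bool = False,
    ) -> float:
        tG = theta[:3].copy()
        tR = theta[3:].copy()
        if fix_rg_zero:
            tG[1] = 0.0
        if fix_re_zero:
            tR[1] = 0.0
        LG = _chol_from_theta(tG)
        LR = _chol_from_theta(tR)
        G = LG @ LG.T
        R = LR @ LR.T
        d = self.d
        C11 = G[0, 0] * d + R[0, 0]
        C12 = G[0, 1] * d + R[0, 1]
        C22 = G[1, 1] * d + R[1, 1]
        det = C11 * C22 - C12 * C12
        if np.any(det <= 0) or np.any(C11 <= 0):
            return 1e12
        w1, w2 = W
        quad = (C22 * w1 * w1 - 2 * C12 * w1 * w2 + C11 * w2 * w2) / det
        return 0.5 * float(np.sum(np.log(det)) + np.sum(quad))

    def fit(
        self, y1: np.ndarray, y2: np.ndarray, fix_rg_zero: bool = False,
        fix_re_zero: bool = False,
    ) -> BivariateComponents:
        """Estimate (G, R) for a pair of responses.

        Cholesky-log parameterization keeps both matrices positive
        definite; starting values come from the two univariate fits.
        ``fix_rg_zero`` pins the genetic covariance at 0 (the reduced
        model of the genetic-correlation LRT); ``fix_re_zero`` pins the
        residual covariance too, under which the fit decomposes into
        the two univariate problems.
        """
        W = np.vstack([self._uni.T @ np.asarray(y1, float),
                       self._uni.T @ np.asarray(y2, float)])
        u1 = self._uni.fit(y1)
        u2 = self._uni.fit(y2)
        ga = [max(u.sigma2_a, 1e-4 * u.sigma2_p) for u in (u1, u2)]
        re = [max(u.sigma2_e, 1e-4 * u.sigma2_p) for u in (u1, u2)]
        x0 = np.array([
            0.5 * math.log(ga[0]), 0.0, 0.5 * math.log(ga[1]),
            0.5 * math.log(re[0]), 0.0, 0.5 * math.log(re[1]),
        ])
        lo, hi = self._LOGD_LO, self._LOGD_HI
        bounds = [(lo, hi), (-50.0, 50.0), (lo, hi)] * 2
        res = optimize.minimize(
            self._nll, x0, args=(W, fix_rg_zero, fix_re_zero), method="L-BFGS-B",
            bounds=bounds, options={"maxiter": 500, "ftol": 1e-12, "gtol": 1e-8},
        )
        # polish with Nelder-Mead if L-BFGS-B stalls on the numeric gradient
        if not res.success or res.nit < 2:
            res2 = optimize.minimize(
                self._nll, res.x, args=(W, fix_rg_zero, fix_re_zero),
                method="Nelder-Mead",
                options={"maxiter": 4000, "xatol": 1e-10, "fatol": 1e-10},
            )
            if res2.fun <= res.fun:
                res = res2
        theta = res.x.copy()
        if fix_rg_zero:
            theta[1] = 0.0
        if fix_re_zero:
            theta[4] = 0.0
        LG = _chol_from_theta(theta[:3])
        LR = _chol_from_theta(theta[3:])
        G = LG @ LG.T
        R = LR @ LR.T
        P = G + R
        rg = G[0, 1] / math.sqrt(G[0, 0] * G[1, 1]) if G[0, 0] * G[1, 1] > 0 else math.nan
        rp = P[0, 1] / math.sqrt(P[0, 0] * P[1, 1])
        boundary = math.isfinite(rg) and abs(rg) > 0.999
        df = self._uni.df
        logl = -res.fun - df * math.log(2 * math.pi)
        se_rg = math.nan
        if not fix_rg_zero and not boundary:
            se_rg = self._se_rg(G, R, W)
        return BivariateComponents(
            G=G, R=R, rg=rg, rp=rp, se_rg=se_rg, logl=logl,
            n_records=2 * self.n, converged=bool(res.success or res.fun < 1e11),
            boundary=boundary,
        )

    def _nll_cov(self, p6: np.ndarray, W: np.ndarray) -> float:
        """NLL parameterized directly by (G11, G12, G22, R11, R12, R22)."""
        G = np.array([[p6[0], p6[1]], [p6[1], p6[2]]])
        R = np.array([[p6[3], p6[4]], [p6[4], p6[5]]])
        d = self.d
        C11 = G[0, 0] * d + R[0, 0]
        C12 = G[0, 1] * d + R[0, 1]
        C22 = G[1, 1] * d + R[1, 1]
        det = C11 * C22 - C12 * C12
        if np.any(det <= 0) or np.any(C11 <= 0):
            return 1e12
        w1, w2 = W
        quad = (C22 * w1 * w1 - 2 * C12 * w1 * w2 + C11 * w2 * w2) / det
        return 0.5 * float(np.sum(np.log(det)) + np.sum(quad))

    def _se_rg(self, G: np.ndarray, R: np.ndarray, W: np.ndarray) -> float:
        """Delta-method SE of rg from the numeric observed information in
        the covariance parameterization."""
        p = np.array([G[0, 0], G[0, 1], G[1, 1], R[0, 0], R[0, 1], R[1, 1]])
        h = np.maximum(1e-6, 1e-4 * np.abs(p))
        k = 6
        H = np.zeros((k, k))
        for i in range(k):
            for j in range(i, k):
                ei = np.zeros(k); ei[i] = h[i]
                ej = np.zeros(k); ej[j] = h[j]
                H[i, j] = H[j, i] = (
                    self._nll_cov(p + ei + ej, W) - self._nll_cov(p + ei - ej, W)
                    - self._nll_cov(p - ei + ej, W) + self._nll_cov(p - ei - ej, W)
                ) / (4 * h[i] * h[j])
        try:
            cov = linalg.inv(H)
        except linalg.LinAlgError:
            return math.nan
        g11, g12, g22 = p[0], p[1], p[2]
        s = math.sqrt(g11 * g22)
        grad = np.zeros(k)
        grad[0] = -0.5 * g12 / (g11 * s)
        grad[1] = 1.0 / s
        grad[2] = -0.5 * g12 / (g22 * s)
        var = float(grad @ cov @ grad)
        return math.sqrt(var) if var > 0 else math.nan


def reml_bivariate(
    y1: np.ndarray,
    y2: np.ndarray,
    X1: np.ndarray,
    X2: np.ndarray,
    A: np.ndarray,
    idx1: np.ndarray | None = None,
    idx2: np.ndarray | None = None,
    fix_rg_zero: bool = False,
) -> BivariateComponents:
    """Bivariate animal-model REML, general entry point.

    When the two traits share the cow set (``idx1 == idx2``) and design
    matrix, the fast eigendecomposed path is used; otherwise a dense
    stacked-covariance REML is maximized directly (suitable for moderate
    record counts, e.g. indicator × longevity pairs).
    """
    y1 = np.asarray(y1, float)
    y2 = np.asarray(y2, float)
    n1, n2 = len(y1), len(y2)
    if idx1 is None:
        idx1 = np.arange(n1)
    if idx2 is None:
        idx2 = np.arange(n2)
    idx1 = np.asarray(idx1)
    idx2 = np.asarray(idx2)
    X1 = np.atleast_2d(np.asarray(X1, float))
    X2 = np.atleast_2d(np.asarray(X2, float))
    same = (
        n1 == n2
        and np.array_equal(idx1, idx2)
        and X1.shape == X2.shape
        and np.allclose(X1, X2)
    )
    if same:
        K = A[np.ix_(idx1, idx1)]
        return BivariateREML(X1, K).fit(y1, y2, fix_rg_zero=fix_rg_zero)
    return _reml_bivariate_dense(y1, y2, X1, X2, A, idx1, idx2, fix_rg_zero)


def _reml_bivariate_dense(y1, y2, X1, X2, A, idx1, idx2, fix_rg_zero):
    """Dense stacked-covariance bivariate REML for unequal cow sets.

    Residual covariance applies only where the same animal carries both
    traits (each cow has one record per trait at most).
    """
    n1, n2 = len(y1), len(y2)
    n = n1 + n2
    K11 = A[np.ix_(idx1, idx1)]
    K22 = A[np.ix_(idx2, idx2)]
    K12 = A[np.ix_(idx1, idx2)]
    # overlap indicator for the residual cross-covariance
    J12 = (idx1[:, None] == idx2[None, :]).astype(float)
    X = linalg.block_diag(X1, X2)
    y = np.concatenate([y1, y2])
    Q2, rank = _design_projection(X)
    df = n - rank
    w = Q2.T @ y

    def nll(theta):
        tG = theta[:3].copy()
        tR = theta[3:]
        if fix_rg_zero:
            tG[1] = 0.0
        LG = _chol_from_theta(tG)
        LR = _chol_from_theta(tR)
        G = LG @ LG.T
        R = LR @ LR.T
        V = np.empty((n, n))
        V[:n1, :n1] = G[0, 0] * K11 + R[0, 0] * np.eye(n1)
        V[n1:, n1:] = G[1, 1] * K22 + R[1, 1] * np.eye(n2)
        V12 = G[0, 1] * K12 + R[0, 1] * J12
        V[:n1, n1:] = V12
        V[n1:, :n1] = V12.T
        S = Q2.T @ V @ Q2
        try:
            c, low = linalg.cho_factor(S, check_finite=False)
        except linalg.LinAlgError:
            return 1e12
        logdet = 2.0 * float(np.sum(np.log(np.diag(c))))
        quad = float(w @ linalg.cho_solve((c, low), w, check_finite=False))
        return 0.5 * (logdet + quad)

    # start from univariate components of each trait
    u1 = UnivariateREML(X1, K11).fit(y1)
    u2 = UnivariateREML(X2, K22).fit(y2)
    ga = [max(u.sigma2_a, 1e-4 * u.sigma2_p) for u in (u1, u2)]
    re = [max(u.sigma2_e, 1e-4 * u.sigma2_p) for u in (u1, u2)]
    x0 = np.array([
        0.5 * math.log(ga[0]), 0.0, 0.5 * math.log(ga[1]),
        0.5 * math.log(re[0]), 0.0, 0.5 * math.log(re[1]),
    ])
    res = optimize.minimize(
        nll, x0, method="Nelder-Mead",
        options={"maxiter": 3000, "xatol": 1e-8, "fatol": 1e-9},
    )
    theta = res.x.copy()
    if fix_rg_zero:
        theta[1] = 0.0
    LG = _chol_from_theta(theta[:3])
    LR = _chol_from_theta(theta[3:])
    G = LG @ LG.T
    R = LR @ LR.T
    P = G + R
    rg = G[0, 1] / math.sqrt(G[0, 0] * G[1, 1]) if G[0, 0] * G[1, 1] > 0 else math.nan
    rp = P[0, 1] / math.sqrt(P[0, 0] * P[1, 1])
    logl = -res.fun - 0.5 * df * math.log(2 * math.pi)
    return BivariateComponents(
        G=G, R=R, rg=rg, rp=rp, se_rg=math.nan, logl=logl,
        n_records=n, converged=bool(res.success),
        boundary=math.isfinite(rg) and abs(rg) > 0.999,
    )


def lrt_variance(
    logl_full: float, logl_reduced: float, mixture: bool = False
) -> tuple[float, float]:
    """Likelihood-ratio test of a variance parameter (h² or rg).

    Statistic 2·(logL_full − logL_reduced), clipped at 0; the reference
    distribution is χ²₁ (the study's choice).  ``mixture=True`` uses the
    boundary-corrected 50:50 χ²₀/χ²₁ mixture appropriate when the null
    pins a variance at the edge of its space.
    """
    stat = max(0.0, 2.0 * (logl_full - logl_reduced))
    if mixture:
        p = 0.5 * stats.chi2.sf(stat, df=1) if stat > 0 else 1.0
    else:
        p = float(stats.chi2.sf(stat, df=1))
    return stat, p


def gcv(sigma2_a: float, mean: float | None = None, log_scale: bool = False) -> float:
    """Genetic coefficient of variation: √σ²a / |mean|, or plain √σ²a
    for traits already on a log scale (the LnVar/RawVar family), where
    the additive SD is itself unitless."""
    if sigma2_a < 0:
        raise ValueError("additive variance must be non-negative")
    sd = math.sqrt(sigma2_a)
    if log_scale:
        return sd
    if mean is None or mean == 0:
        raise ValueError("a non-zero mean is required unless log_scale=True")
    return sd / abs(mean)


def fisher_r_to_z(r: float, n: int) -> tuple[float, float]:
    """Fisher r-to-z test that a correlation differs from zero.

    z = 0.5·ln((1+r)/(1−r)); under H0 z is normal with SD 1/√(n−3).
    Returns (z, two-sided p).
    """
    if not -1.0 < r < 1.0:
        raise ValueError("|r| must be < 1")
    if n <= 3:
        raise ValueError("n must exceed 3")
    z = 0.5 * math.log((1.0 + r) / (1.0 - r))
    p = 2.0 * stats.norm.sf(abs(z) * math.sqrt(n - 3))
    return z, min(p, 1.0)
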