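"""Linear mixed models with crossed random intercepts, fit by REML.

The model is

    y = X beta + sum_k Z_k u_k + e,   u_k ~ N(0, sigma_k^2 I),  e ~ N(0, sigma^2 I)

where each Z_k is the indicator matrix of a grouping factor (participant,
stimulus, ROI, ...).  Random factors may be fully crossed; only random
intercepts are supported.  The profiled REML criterion is optimised over the
variance ratios gamma_k = sigma_k^2 / sigma^2 using the Woodbury identity, so
each objective evaluation costs O(q^3) in the total number of random levels q
rather than O(n^3) in observations.

Denominator degrees of freedom for t and F statistics use the Satterthwaite
approximation: the covariance of the variance-component estimates is taken
from the (finite-difference) Hessian of the REML deviance, and each contrast's
df is 2*phi^2 / Var(phi) with phi = l' C(theta) l.  Multi-df F tests combine
per-eigenvector one-df values the way lmerTest does.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, optimize, sparse
from scipy import stats as sps

logger = logging.getLogger(__name__)

__all__ = ["RandomStructure", "LMMFit", "fit_reml"]


class RankError(ValueError):
    """Raised when the fixed-effect design is rank deficient."""


@dataclass
class RandomStructure:
    """Integer-coded crossed grouping factors."""

    names: list[str]
    codes: list[np.ndarray]        # each in {0..n_levels-1}, length n
    n_levels: list[int]

    @classmethod
    def from_frame(cls, data: pd.DataFrame, columns: list[str]) -> "RandomStructure":
        names, codes, nlev = [], [], []
        for col in columns:
            c, levels = pd.factorize(data[col], sort=True)
            if len(levels) < 2:
                raise ValueError(f"random factor {col!r} has fewer than 2 levels")
            names.append(col)
            codes.append(np.asarray(c, dtype=np.int64))
            nlev.append(len(levels))
        return cls(names, codes, nlev)


def _build_z(struct: RandomStructure, n: int) -> tuple[sparse.csr_matrix, np.ndarray]:
    """Sparse indicator matrix for all factors stacked, plus block index."""
    blocks = []
    block_of_col = []
    for k, (codes, q) in enumerate(zip(struct.codes, struct.n_levels)):
        zk = sparse.csr_matrix(
            (np.ones(n), (np.arange(n), codes)), shape=(n, q)
        )
        blocks.append(zk)
        block_of_col.append(np.full(q, k))
    return sparse.hstack(blocks, format="csr"), np.concatenate(block_of_col)


@dataclass
class _CrossProducts:
    ZtZ: np.ndarray
    ZtX: np.ndarray
    Zty: np.ndarray
    XtX: np.ndarray
    Xty: np.ndarray
    yty: float
    n: int
    p: int
    block: np.ndarray  # block index of each Z column


def _profiled_pieces(cp: _CrossProducts, gamma: np.ndarray):
    """Solve the Woodbury system for a given vector of variance ratios.

    Returns (beta, XtWinvX, r2, logdetM, logdetXtWinvX).
    """
    lam = np.sqrt(gamma[cp.block])
    M = np.eye(len(lam)) + (lam[:, None] * cp.ZtZ) * lam[None, :]
    cf = linalg.cho_factor(M, lower=True)
    A = lam[:, None] * cp.ZtX            # q x p
    b = lam * cp.Zty                     # q
    MiA = linalg.cho_solve(cf, A)
    Mib = linalg.cho_solve(cf, b)
    XtWinvX = cp.XtX - A.T @ MiA
    XtWinvy = cp.Xty - A.T @ Mib
    yWinvy = cp.yty - b @ Mib
    sign, logdetX = np.linalg.slogdet(XtWinvX)
    if sign <= 0:
        raise RankError("X'V^-1 X is not positive definite (rank-deficient design)")
    beta = linalg.solve(XtWinvX, XtWinvy, assume_a="pos")
    r2 = float(yWinvy - beta @ XtWinvy)
    logdetM = 2.0 * np.sum(np.log(np.diag(cf[0])))
    return beta, XtWinvX, max(r2, 1e-300), logdetM, logdetX


def _profiled_deviance(cp: _CrossProducts, s: np.ndarray) -> float:
    """-2 REML log-likelihood profiled over beta and sigma^2; s = sqrt(gamma)."""
    _, _, r2, logdetM, logdetX = _profiled_pieces(cp, s**2)
    return (cp.n - cp.p) * np.log(r2) + logdetM + logdetX


def _full_deviance(cp: _CrossProducts, theta: np.ndarray) -> float:
    """-2 REML log-likelihood (up to constant) in variance units.

    theta = (sigma_1^2, ..., sigma_K^2, sigma^2).
    """
    sigma2 = theta[-1]
    if sigma2 <= 0 or np.any(theta[:-1] < 0):
        return np.inf
    gamma = theta[:-1] / sigma2
    _, _, r2, logdetM, logdetX = _profiled_pieces(cp, gamma)
    return (cp.n - cp.p) * np.log(sigma2) + r2 / sigma2 + logdetM + logdetX


@dataclass
class LMMFit:
    """A fitted crossed random-intercepts model."""

    beta: np.ndarray
    cov_beta: np.ndarray
    fixed_names: list[str]
    sigma2: float
    re_var: dict[str, float]
    loglik_reml: float
    converged: bool
    n: int
    p: int
    theta: np.ndarray = field(repr=False)          # variance components + residual
    theta_cov: np.ndarray = field(repr=False)      # asymptotic cov of theta-hat
    _cp: _CrossProducts = field(repr=False, default=None)
    df_fallback_used: bool = False

    # -- Satterthwaite machinery -------------------------------------------

    def _cov_beta_at(self, theta: np.ndarray) -> np.ndarray:
        sigma2 = theta[-1]
        gamma = np.clip(theta[:-1], 0.0, None) / sigma2
        _, XtWinvX, _, _, _ = _profiled_pieces(self._cp, gamma)
        return sigma2 * linalg.inv(XtWinvX)

    def _phi_grad(self, ell: np.ndarray) -> tuple[float, np.ndarray]:
        """phi = l' C(theta) l and its finite-difference gradient in theta."""
        phi0 = float(ell @ self.cov_beta @ ell)
        grad = np.zeros_like(self.theta)
        for k in range(len(self.theta)):
            h = max(abs(self.theta[k]), self.theta[-1]) * 1e-4
            tp = self.theta.copy()
            tm = self.theta.copy()
            tp[k] += h
            tm[k] = max(tm[k] - h, 0.0 if k < len(self.theta) - 1 else tm[k] * 0.5)
            dp = float(ell @ self._cov_beta_at(tp) @ ell)
            dm = float(ell @ self._cov_beta_at(tm) @ ell)
            grad[k] = (dp - dm) / (tp[k] - tm[k])
        return phi0, grad

    def satterthwaite_df(self, ell: np.ndarray) -> float:
        """Effective denominator df for the scalar contrast l' beta."""
        phi, g = self._phi_grad(np.asarray(ell, dtype=float))
        denom = float(g @ self.theta_cov @ g)
        if denom <= 0 or not np.isfinite(denom):
            self.df_fallback_used = True
            logger.warning("Satterthwaite variance not estimable; falling back to residual df")
            return float(self.n - self.p)
        df = 2.0 * phi**2 / denom
        if not np.isfinite(df) or df <= 0:
            self.df_fallback_used = True
            return float(self.n - self.p)
        return min(df, float(self.n - self.p))

    def contrast(self, ell: np.ndarray):
        """t test of a single contrast: (estimate, se, df, t, p)."""
        ell = np.asarray(ell, dtype=float)
        est = float(ell @ self.beta)
        se = float(np.sqrt(ell @ self.cov_beta @ ell))
        df = self.satterthwaite_df(ell)
        t = est / se
        p = 2.0 * sps.t.sf(abs(t), df)
        return est, se, df, t, p

    def ftest(self, L: np.ndarray):
        """F test of L beta = 0 with Satterthwaite denominator df.

        Per-eigenvector one-df values nu_i of Q = L C L' are pooled as in
        lmerTest: E = sum nu_i/(nu_i - 2), df = 2E/(E - rank).
        Returns (F, df_num, df_den, p).
        """
        L = np.atleast_2d(np.asarray(L, dtype=float))
        Q = L @ self.cov_beta @ L.T
        rank = np.linalg.matrix_rank(Q)
        if rank < L.shape[0]:
            raise RankError("contrast matrix is rank deficient")
        vals, vecs = linalg.eigh(Q)
        order = np.argsort(vals)[::-1][:rank]
        vals, vecs = vals[order], vecs[:, order]
        t2 = 0.0
        nus = []
        for i in range(rank):
            ell = vecs[:, i] @ L
            est = float(ell @ self.beta)
            t2 += est**2 / vals[i]
            nus.append(self.satterthwaite_df(ell))
        F = t2 / rank
        nus = np.asarray(nus)
        usable = nus > 2.0
        if usable.all():
            E = float(np.sum(nus / (nus - 2.0)))
            df_den = 2.0 * E / (E - rank) if E > rank else float(self.n - self.p)
        else:
            df_den = float(self.n - self.p)
            self.df_fallback_used = True
        p = sps.f.sf(F, rank, df_den)
        return float(F), int(rank), float(df_den), float(p)


def fit_reml(
    y: np.ndarray,
    X: np.ndarray,
    struct: RandomStructure,
    fixed_names: list[str] | None = None,
    maxiter: int = 200,
) -> LMMFit:
    """Fit the crossed random-intercepts model by profiled REML.

    Raises :class:`RankError` if X is rank deficient.
    """
    y = np.asarray(y, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n, p = X.shape
    if np.linalg.matrix_rank(X) < p:
        raise RankError("fixed-effect design matrix is rank deficient")
    if not np.all(np.isfinite(y)):
        raise ValueError("response contains non-finite values")
    Z, block = _build_z(struct, n)
    K = len(struct.names)
    cp = _CrossProducts(
        ZtZ=np.asarray((Z.T @ Z).todense()),
        ZtX=np.asarray(Z.T @ X),
        Zty=np.asarray(Z.T @ y).ravel(),
        XtX=X.T @ X,
        Xty=X.T @ y,
        yty=float(y @ y),
        n=n,
        p=p,
        block=block,
    )

    res = optimize.minimize(
        lambda s: _profiled_deviance(cp, s),
        x0=np.full(K, 0.5),
        method="L-BFGS-B",
        bounds=[(0.0, None)] * K,
        options={"maxiter": maxiter},
    )
    gamma = res.x**2
    beta, XtWinvX, r2, logdetM, logdetX = _profiled_pieces(cp, gamma)
    sigma2 = r2 / (n - p)
    theta = np.append(gamma * sigma2, sigma2)
    cov_beta = sigma2 * linalg.inv(XtWinvX)
    loglik = -0.5 * (
        (n - p) * np.log(2 * np.pi * sigma2) + (n - p) + logdetM + logdetX
    )

    # covariance of theta-hat from the finite-difference Hessian of the
    # REML deviance (Var = 2 H^-1); boundary components get a pseudo-inverse
    H = _fd_hessian(lambda t: _full_deviance(cp, t), theta)
    try:
        theta_cov = 2.0 * linalg.inv(H)
        if not np.all(np.isfinite(theta_cov)):
            raise linalg.LinAlgError
    except linalg.LinAlgError:
        theta_cov = 2.0 * linalg.pinvh(H)

    fit = LMMFit(
        beta=beta,
        cov_beta=cov_beta,
        fixed_names=fixed_names or [f"x{i}" for i in range(p)],
        sigma2=float(sigma2),
        re_var={nm: float(v) for nm, v in zip(struct.names, theta[:-1])},
        loglik_reml=float(loglik),
        converged=bool(res.success and np.isfinite(loglik)),
        n=n,
        p=p,
        theta=theta,
        theta_cov=theta_cov,
    )
    fit._cp = cp
    return fit


def _fd_hessian(f, x0: np.ndarray) -> np.ndarray:
    """Central finite-difference Hessian with parameter-scaled steps."""
    k = len(x0)
    scale = max(x0[-1], 1e-8)
    h = np.maximum(np.abs(x0), 0.05 * scale) * 1e-3
    H = np.zeros((k, k))
    f0 = f(x0)

    def ev(dx):
        x = x0 + dx
        # keep variances nonnegative; reflect tiny negatives
        x[:-1] = np.clip(x[:-1], 0.0, None)
        x[-1] = max(x[-1], 1e-12)
        return f(x)

    for i in range(k):
        ei = np.zeros(k)
        ei[i] = h[i]
        fpp = ev(ei)
        fmm = ev(-ei)
        H[i, i] = (fpp - 2 * f0 + fmm) / h[i] ** 2
        for j in range(i):
            ej = np.zeros(k)
            ej[j] = h[j]
            H[i, j] = H[j, i] = (
                ev(ei + ej) - ev(ei - ej) - ev(-ei + ej) + ev(-ei - ej)
            ) / (4 * h[i] * h[j])
    return H
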