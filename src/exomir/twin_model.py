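"""Per-miR Poisson-lognormal regression with twin-correlated random effects.

Counts are modeled as y_ij ~ Poisson(exp(x_ij' beta + u_ij + offset_ij)) where
u is a normally distributed per-subject random effect: variance sigma2 (the
reported "overdispersion"), correlation rho between members of a monozygotic
twin pair, independent for singletons.  The marginal likelihood integrates u
out by adaptive Gauss-Hermite quadrature — exactly for sigma2=0, a 1-D rule
per singleton and a Cholesky-transformed 2-D tensor rule per pair otherwise.

Maximum-likelihood fits are obtained per miR on the unconstrained scale
(beta, log sigma2, atanh rho); Wald tests of the three pairwise group
contrasts (No-HRT vs PRE, HRT vs PRE, HRT vs No-HRT) use standard errors from
the numerically differentiated observed information, and Benjamini-Hochberg
FDR is applied per comparison across miRs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import gammaln
from scipy.stats import norm
from statsmodels.stats.multitest import multipletests

from .datatypes import (
    COMPARISONS,
    GROUP_HRT,
    GROUP_NOHRT,
    GROUP_PRE,
    CountMatrix,
    SampleTable,
)

logger = logging.getLogger(__name__)

_LOG_SIGMA2_MIN = -15.0  # effectively sigma2 = 0
_LOG_SIGMA2_MAX = 5.0
_ATANH_RHO_MAX = 5.0  # |rho| <= tanh(5) ~ 0.9999
_BETA_MAX = 30.0


@dataclass
class ModelConfig:
    n_nodes: int = 20  # quadrature nodes per dimension
    rho_mode: str = "per_mir"  # "per_mir" | "zero"
    use_offset: bool = False  # log library-size offset
    max_iter: int = 500
    tol: float = 1e-8  # relative log-likelihood tolerance
    test: str = "wald"  # "wald" | "lrt"
    fdr_scope: str = "per_comparison"  # "per_comparison" | "joint"
    min_detect: int = 1  # minimum total count for a miR to be tested


@dataclass
class PoissonNormalFit:
    """Maximum-likelihood fit of one miR.

    beta0 is the log mean count of the PRE reference group; beta_nohrt and
    beta_hrt are group log fold-changes.  sigma2 is the random-effect
    variance (overdispersion), rho the within-pair correlation.  cov is the
    inverse observed information over the free parameters.
    """

    mir_id: str
    beta0: float
    beta_nohrt: float
    beta_hrt: float
    sigma2: float
    rho: float
    loglik: float
    converged: bool
    n_quad: int
    se: np.ndarray  # SEs of (beta0, beta_nohrt, beta_hrt)
    cov: np.ndarray  # covariance of (beta0, beta_nohrt, beta_hrt)
    sigma2_at_boundary: bool = False
    rho_identified: bool = True
    n_iter: int = 0


# ---------------------------------------------------------------------------
# cluster bookkeeping
# ---------------------------------------------------------------------------

def design_matrices(samples: SampleTable, library_sizes: pd.Series | None = None):
    """Split samples into singleton and pair clusters with design rows.

    Returns (sample order used, singleton dict, pair dict) where the dicts
    hold index arrays, design matrices and offsets.  Columns of X are
    (intercept, POST_NOHRT, POST_HRT) with PRE the reference level.
    """
    df = samples.table
    x_of = {GROUP_PRE: (1, 0, 0), GROUP_NOHRT: (1, 1, 0), GROUP_HRT: (1, 0, 1)}
    offs = (
        np.log(library_sizes.reindex(df["sample_id"]).to_numpy(float))
        if library_sizes is not None
        else np.zeros(len(df))
    )
    pos = {s: i for i, s in enumerate(df["sample_id"])}

    singles = df[df["pair_id"].isna()]
    s_idx = np.array([pos[s] for s in singles["sample_id"]], dtype=int)
    X_s = np.array([x_of[g] for g in singles["group"]], dtype=float).reshape(-1, 3)

    pairs = samples.pairs()
    p_idx = np.array(
        [[pos[r[GROUP_NOHRT]], pos[r[GROUP_HRT]]] for _, r in pairs.iterrows()], dtype=int
    ).reshape(-1, 2)
    X_p = np.tile(np.array([x_of[GROUP_NOHRT], x_of[GROUP_HRT]], dtype=float), (len(pairs), 1, 1))

    return (
        list(df["sample_id"]),
        {"idx": s_idx, "X": X_s, "offset": offs[s_idx] if len(s_idx) else np.zeros(0)},
        {"idx": p_idx, "X": X_p, "offset": offs[p_idx] if len(p_idx) else np.zeros((0, 2))},
    )


# ---------------------------------------------------------------------------
# marginal likelihood via adaptive Gauss-Hermite quadrature
# ---------------------------------------------------------------------------

class _Quadrature:
    """Gauss-Hermite rule with adjusted weights w_k exp(|z_k|^2) precomputed
    for the adaptive transform (1-D rule plus 2-D tensor grid)."""

    def __init__(self, n_nodes: int):
        self.n_nodes = n_nodes
        z, w = np.polynomial.hermite.hermgauss(n_nodes)
        self.z = z
        self.aw1 = w * np.exp(z**2)
        zz1, zz2 = np.meshgrid(z, z, indexing="ij")
        self.z2a = zz1.ravel()
        self.z2b = zz2.ravel()
        self.aw2 = np.outer(w, w).ravel() * np.exp(self.z2a**2 + self.z2b**2)


def _wlse(hk, aw):
    """Row-wise log sum of aw * exp(hk), stabilised by the row max."""
    m = hk.max(axis=1)
    return m + np.log(np.exp(hk - m[:, None]) @ aw)


def _loglik_singletons(y, eta, sigma2, quad: _Quadrature):
    """Vectorized adaptive 1-D GH marginal log-likelihood per singleton.

    y, eta: (n,) arrays; returns (n,) cluster log-likelihoods.
    """
    n = len(y)
    if n == 0:
        return np.zeros(0)
    # mode of h(u) = y(eta+u) - exp(eta+u) - u^2/(2 sigma2) by Newton
    u = np.zeros(n)
    for _ in range(50):
        lam = np.exp(eta + u)
        g = y - lam - u / sigma2
        h = -lam - 1.0 / sigma2
        step = np.clip(-g / h, -5.0, 5.0)
        u = u + step
        if np.max(np.abs(step)) < 1e-10:
            break
    lam = np.exp(eta + u)
    L = 1.0 / np.sqrt(lam + 1.0 / sigma2)  # from -h''(u*)
    # u_k = u* + sqrt(2) L z_k
    uk = u[:, None] + (np.sqrt(2.0) * L)[:, None] * quad.z[None, :]
    ek = eta[:, None] + uk
    hk = y[:, None] * ek - np.exp(ek) - uk**2 / (2 * sigma2)
    val = _wlse(hk, quad.aw1)
    const = -gammaln(y + 1.0) - 0.5 * np.log(2 * np.pi * sigma2)
    return val + 0.5 * np.log(2.0) + np.log(L) + const


def _loglik_pairs(y, eta, sigma2, rho, quad: _Quadrature):
    """Vectorized adaptive 2-D GH marginal log-likelihood per twin pair.

    y, eta: (n, 2); a tensor-product rule is applied after shifting to the
    joint mode and rescaling by the Cholesky factor of the inverse negative
    Hessian there.
    """
    n = len(y)
    if n == 0:
        return np.zeros(0)
    det = sigma2**2 * (1.0 - rho**2)
    # precision matrix of the bivariate random effect
    p11 = 1.0 / (sigma2 * (1.0 - rho**2))
    p12 = -rho * p11

    u1 = np.zeros(n)
    u2 = np.zeros(n)
    y1, y2 = y[:, 0], y[:, 1]
    for _ in range(50):
        lam1 = np.exp(eta[:, 0] + u1)
        lam2 = np.exp(eta[:, 1] + u2)
        g1 = y1 - lam1 - (p11 * u1 + p12 * u2)
        g2 = y2 - lam2 - (p12 * u1 + p11 * u2)
        h11 = lam1 + p11
        h22 = lam2 + p11
        dt = h11 * h22 - p12 * p12
        s1 = np.clip((h22 * g1 - p12 * g2) / dt, -5.0, 5.0)
        s2 = np.clip((h11 * g2 - p12 * g1) / dt, -5.0, 5.0)
        u1 += s1
        u2 += s2
        if max(np.max(np.abs(s1)), np.max(np.abs(s2))) < 1e-10:
            break

    # negative Hessian M at the mode and Cholesky of its inverse C = M^-1
    m11 = np.exp(eta[:, 0] + u1) + p11
    m22 = np.exp(eta[:, 1] + u2) + p11
    dt = m11 * m22 - p12 * p12
    l11 = np.sqrt(m22 / dt)
    l21 = -p12 / dt / l11
    l22 = np.sqrt(np.maximum(m11 / dt - l21**2, 1e-300))

    # transformed nodes u_k = u* + sqrt(2) L z_k
    s2_ = np.sqrt(2.0)
    uk1 = u1[:, None] + (s2_ * l11)[:, None] * quad.z2a[None, :]
    uk2 = u2[:, None] + (s2_ * l21)[:, None] * quad.z2a[None, :] + (s2_ * l22)[:, None] * quad.z2b[None, :]
    e1 = eta[:, 0:1] + uk1
    e2 = eta[:, 1:2] + uk2
    hk = (
        y1[:, None] * e1
        - np.exp(e1)
        + y2[:, None] * e2
        - np.exp(e2)
        - 0.5 * (p11 * uk1**2 + 2 * p12 * uk1 * uk2 + p11 * uk2**2)
    )
    val = _wlse(hk, quad.aw2)
    const = -gammaln(y + 1.0).sum(axis=1) - np.log(2 * np.pi) - 0.5 * np.log(det)
    return val + np.log(2.0) + np.log(l11) + np.log(l22) + const


def marginal_loglik(y, X, offset, beta, sigma2, rho, n_nodes: int = 20) -> float:
    """Marginal log-likelihood of one cluster (singleton or twin pair).

    log Integral prod_j Poisson(y_j | exp(x_j beta + u_j + offset_j))
    phi(u; 0, Sigma) du with Sigma = sigma2 [[1, rho], [rho, 1]] for pairs
    (sigma2 for singletons), by adaptive Gauss-Hermite quadrature.
    sigma2 = 0 degenerates exactly to the Poisson log-pmf.
    """
    y = np.atleast_1d(np.asarray(y, float))
    X = np.atleast_2d(np.asarray(X, float))
    offset = np.broadcast_to(np.asarray(offset, float), y.shape)
    beta = np.asarray(beta, float)
    if sigma2 < 0:
        raise ValueError("sigma2 must be nonnegative")
    if abs(rho) >= 1:
        raise ValueError("|rho| must be < 1")
    if (y < 0).any():
        raise ValueError("negative counts")
    if n_nodes < 5:
        raise ValueError("n_nodes must be >= 5")
    eta = X @ beta + offset
    if sigma2 == 0.0:
        return float(np.sum(y * eta - np.exp(eta) - gammaln(y + 1.0)))
    quad = _Quadrature(n_nodes)
    if len(y) == 1:
        return float(_loglik_singletons(y, eta, sigma2, quad)[0])
    if len(y) == 2:
        return float(_loglik_pairs(y[None, :], eta[None, :], sigma2, rho, quad)[0])
    raise ValueError("clusters are singletons or pairs")


# ---------------------------------------------------------------------------
# per-miR fitting
# ---------------------------------------------------------------------------

def _cluster_loglik(beta, sigma2, rho, y_s, singles, y_p, pairs, quad):
    ll = 0.0
    if len(y_s):
        eta = singles["X"] @ beta + singles["offset"]
        ll += _loglik_singletons(y_s, eta, sigma2, quad).sum()
    if len(y_p):
        eta = pairs["X"] @ beta + pairs["offset"]
        ll += _loglik_pairs(y_p, eta, sigma2, rho, quad).sum()
    return ll


def _total_loglik(theta, y_s, singles, y_p, pairs, quad, rho_mode):
    beta = theta[:3]
    sigma2 = np.exp(theta[3])
    rho = 0.0 if rho_mode == "zero" else np.tanh(theta[4])
    return _cluster_loglik(beta, sigma2, rho, y_s, singles, y_p, pairs, quad)


def _poisson_glm_start(y, X, offset):
    """Poisson regression MLE by iteratively reweighted least squares."""
    beta = np.zeros(X.shape[1])
    ybar = max(y.mean(), 0.1)
    beta[0] = np.log(ybar) - offset.mean()
    for _ in range(100):
        eta = X @ beta + offset
        lam = np.exp(np.clip(eta, -30, 30))
        W = lam
        score = X.T @ (y - lam)
        info = (X * W[:, None]).T @ X
        try:
            step = np.linalg.solve(info + 1e-10 * np.eye(len(beta)), score)
        except np.linalg.LinAlgError:
            break
        step = np.clip(step, -5, 5)
        beta = beta + step
        if np.max(np.abs(step)) < 1e-10:
            break
    return np.clip(beta, -_BETA_MAX, _BETA_MAX)


def fit_mir(
    y: np.ndarray | pd.Series,
    samples: SampleTable,
    config: ModelConfig | None = None,
    mir_id: str = "",
    library_sizes: pd.Series | None = None,
) -> PoissonNormalFit | None:
    """Maximum marginal-likelihood fit of the twin model to one miR.

    Returns None for an all-zero miR (skip signal).  The covariance of beta
    comes from the inverse of the numerically differentiated observed
    information of the full parameter vector.
    """
    config = config or ModelConfig()
    if isinstance(y, pd.Series):
        y = y.reindex(samples.sample_ids).to_numpy(float)
    else:
        y = np.asarray(y, float)
    if y.sum() == 0:
        return None

    order, singles, pairs = design_matrices(
        samples, library_sizes if config.use_offset else None
    )
    y_s = y[singles["idx"]] if len(singles["idx"]) else np.zeros(0)
    y_p = y[pairs["idx"]] if len(pairs["idx"]) else np.zeros((0, 2))

    quad = _Quadrature(config.n_nodes)
    # coarse rule for the warm-start pass: much cheaper per evaluation and
    # already accurate enough to land next to the full-rule optimum
    quad_coarse = _Quadrature(min(9, config.n_nodes)) if config.n_nodes > 9 else None

    X_all = np.vstack([singles["X"], pairs["X"].reshape(-1, 3)])
    off_all = np.concatenate([singles["offset"], pairs["offset"].ravel()])
    y_all = np.concatenate([y_s, y_p.ravel()])
    beta0 = _poisson_glm_start(y_all, X_all, off_all)

    rho_mode = config.rho_mode if len(y_p) else "zero"
    n_free = 4 if rho_mode == "zero" else 5

    def unpack(t):
        theta = np.empty(5)
        theta[:4] = t[:4]
        theta[4] = t[4] if n_free == 5 else 0.0
        return theta

    def make_nll(q):
        def nll(t):
            val = _total_loglik(unpack(t), y_s, singles, y_p, pairs, q, rho_mode)
            return -val if np.isfinite(val) else 1e12

        return nll

    nll = make_nll(quad)

    t0 = np.concatenate([beta0, [np.log(0.1)], [0.0]])[:n_free]
    bounds = [(-_BETA_MAX, _BETA_MAX)] * 3 + [(_LOG_SIGMA2_MIN, _LOG_SIGMA2_MAX)]
    if n_free == 5:
        bounds.append((-_ATANH_RHO_MAX, _ATANH_RHO_MAX))
    opts = {"maxiter": config.max_iter, "ftol": config.tol, "gtol": 1e-7}

    t_start = t0
    nit = 0
    pre_ok = False
    if quad_coarse is not None:
        pre = minimize(make_nll(quad_coarse), t0, method="L-BFGS-B", bounds=bounds, options=opts)
        nit += pre.nit
        if np.isfinite(pre.fun):
            t_start = pre.x
            pre_ok = bool(pre.success)
    res = minimize(nll, t_start, method="L-BFGS-B", bounds=bounds, options=opts)
    res.nit = nit + res.nit
    if not res.success and pre_ok and res.fun <= nll(t_start) + 1e-6:
        # the polish started at the coarse-rule optimum; a stalled line
        # search there is convergence, not failure
        res.success = True
    # monotone acceptance: never report a point worse than the start
    if res.fun > nll(t0) + 1e-9:
        res.x, res.fun, res.success = t0, nll(t0), False

    t_hat = res.x
    theta_hat = unpack(t_hat)
    sigma2_hat = np.exp(theta_hat[3])
    at_boundary = theta_hat[3] <= _LOG_SIGMA2_MIN + 1e-6
    rho_hat = 0.0 if (rho_mode == "zero" or at_boundary) else np.tanh(theta_hat[4])

    cov_beta, se_beta = _beta_covariance(nll, t_hat, n_free)
    converged = bool(res.success) and np.all(np.isfinite(se_beta))

    return PoissonNormalFit(
        mir_id=mir_id,
        beta0=float(theta_hat[0]),
        beta_nohrt=float(theta_hat[1]),
        beta_hrt=float(theta_hat[2]),
        sigma2=float(0.0 if at_boundary else sigma2_hat),
        rho=float(rho_hat),
        loglik=float(-res.fun),
        converged=converged,
        n_quad=config.n_nodes,
        se=se_beta,
        cov=cov_beta,
        sigma2_at_boundary=bool(at_boundary),
        rho_identified=not (rho_mode == "zero" or at_boundary),
        n_iter=int(res.nit),
    )


def _beta_covariance(nll, t_hat, n_free):
    """Covariance of beta from the numerically differentiated observed information."""
    d = len(t_hat)
    H = np.zeros((d, d))
    h = np.maximum(1e-4, 1e-4 * np.abs(t_hat))
    f0 = nll(t_hat)
    fp = np.empty(d)
    fm = np.empty(d)
    for i in range(d):
        ei = np.zeros(d)
        ei[i] = h[i]
        fp[i] = nll(t_hat + ei)
        fm[i] = nll(t_hat - ei)
        H[i, i] = (fp[i] - 2 * f0 + fm[i]) / h[i] ** 2
    for i in range(d):
        for j in range(i + 1, d):
            ei = np.zeros(d)
            ej = np.zeros(d)
            ei[i] = h[i]
            ej[j] = h[j]
            fpp = nll(t_hat + ei + ej)
            fmm = nll(t_hat - ei - ej)
            H[i, j] = H[j, i] = (fpp - fp[i] - fp[j] + 2 * f0 - fm[i] - fm[j] + fmm) / (
                2 * h[i] * h[j]
            )
    try:
        cov = np.linalg.inv(H)
        cov_beta = cov[:3, :3]
        var = np.diag(cov_beta).copy()
        if (var <= 0).any():
            raise np.linalg.LinAlgError
        se = np.sqrt(var)
    except np.linalg.LinAlgError:
        # fall back to the beta block alone (information for beta given
        # variance parameters fixed at their MLEs)
        try:
            cov_beta = np.linalg.inv(H[:3, :3])
            var = np.diag(cov_beta).copy()
            se = np.sqrt(np.where(var > 0, var, np.nan))
        except np.linalg.LinAlgError:
            cov_beta = np.full((3, 3), np.nan)
            se = np.full(3, np.nan)
    return cov_beta, se


# ---------------------------------------------------------------------------
# contrasts and FDR
# ---------------------------------------------------------------------------

def test_contrasts(fit: PoissonNormalFit) -> pd.DataFrame:
    """Wald tests of the three pairwise group contrasts of one fit."""
    C = np.array([[0, 1, 0], [0, 0, 1], [0, -1, 1]], dtype=float)
    est = C @ np.array([fit.beta0, fit.beta_nohrt, fit.beta_hrt])
    var = np.einsum("ij,jk,ik->i", C, fit.cov, C)
    se = np.sqrt(np.where(var > 0, var, np.nan))
    with np.errstate(invalid="ignore", divide="ignore"):
        zstat = est / se
        p = 2.0 * norm.sf(np.abs(zstat))
    p = np.where(np.isfinite(se), p, np.nan)  # non-finite SE -> missing p
    p = np.where(est == 0.0, 1.0, p)  # exactly-null contrast
    return pd.DataFrame(
        {
            "mir_id": fit.mir_id,
            "comparison": list(COMPARISONS),
            "estimate": est,
            "se": se,
            "p": p,
        }
    )


def fdr_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values; NaNs are passed through."""
    p = np.asarray(pvals, float)
    out = np.full(p.shape, np.nan)
    ok = np.isfinite(p)
    if ((p[ok] < 0) | (p[ok] > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    if ok.sum():
        out[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return out


# null-hypothesis design transforms beta = T gamma for each contrast:
# dropping a group effect, or forcing the two postmenopausal effects equal
_CONTRAST_NULLS = {
    "NOHRT_vs_PRE": np.array([[1.0, 0.0], [0.0, 0.0], [0.0, 1.0]]),
    "HRT_vs_PRE": np.array([[1.0, 0.0], [0.0, 1.0], [0.0, 0.0]]),
    "HRT_vs_NOHRT": np.array([[1.0, 0.0], [0.0, 1.0], [0.0, 1.0]]),
}


def _max_constrained_loglik(y, samples, config, T, library_sizes=None):
    """Maximum marginal log-likelihood with beta restricted to the column
    space of T (beta = T gamma)."""
    order, singles, pairs = design_matrices(
        samples, library_sizes if config.use_offset else None
    )
    y = np.asarray(y, float)
    y_s = y[singles["idx"]] if len(singles["idx"]) else np.zeros(0)
    y_p = y[pairs["idx"]] if len(pairs["idx"]) else np.zeros((0, 2))
    singles = {**singles, "X": singles["X"] @ T}
    pairs = {**pairs, "X": pairs["X"] @ T}
    k = T.shape[1]

    X_all = np.vstack([singles["X"], pairs["X"].reshape(-1, k)])
    off_all = np.concatenate([singles["offset"], pairs["offset"].ravel()])
    gamma0 = _poisson_glm_start(np.concatenate([y_s, y_p.ravel()]), X_all, off_all)
    rho_mode = config.rho_mode if len(y_p) else "zero"
    n_free = k + (1 if rho_mode == "zero" else 2)
    quad = _Quadrature(config.n_nodes)

    def nll(t):
        beta = t[:k]
        sigma2 = np.exp(t[k])
        rho = 0.0 if rho_mode == "zero" else np.tanh(t[k + 1])
        val = _cluster_loglik(beta, sigma2, rho, y_s, singles, y_p, pairs, quad)
        return -val if np.isfinite(val) else 1e12

    t0 = np.concatenate([gamma0, [np.log(0.1)], [0.0]])[:n_free]
    bounds = [(-_BETA_MAX, _BETA_MAX)] * k + [(_LOG_SIGMA2_MIN, _LOG_SIGMA2_MAX)]
    if n_free == k + 2:
        bounds.append((-_ATANH_RHO_MAX, _ATANH_RHO_MAX))
    res = minimize(
        nll, t0, method="L-BFGS-B", bounds=bounds,
        options={"maxiter": config.max_iter, "ftol": config.tol, "gtol": 1e-7},
    )
    return -min(res.fun, nll(t0))


def lrt_contrasts(
    y, samples: SampleTable, fit: PoissonNormalFit, config: ModelConfig | None = None,
    library_sizes: pd.Series | None = None,
) -> pd.DataFrame:
    """Likelihood-ratio tests of the three contrasts (chi-square, 1 df).

    Each null refits the model with the corresponding group effect removed
    (or the two postmenopausal effects tied); estimates and SEs still come
    from the unconstrained fit.
    """
    from scipy.stats import chi2

    config = config or ModelConfig()
    if isinstance(y, pd.Series):
        y = y.reindex(samples.sample_ids).to_numpy(float)
    table = test_contrasts(fit)
    ps = []
    for comp in COMPARISONS:
        ll0 = _max_constrained_loglik(y, samples, config, _CONTRAST_NULLS[comp], library_sizes)
        stat = max(0.0, 2.0 * (fit.loglik - ll0))
        ps.append(float(chi2.sf(stat, df=1)))
    table["p"] = ps
    return table


def fits_to_records(fits: list[PoissonNormalFit]) -> list[dict]:
    """JSON-serializable per-miR fit summaries."""
    return [
        {
            "mir_id": f.mir_id,
            "beta0": f.beta0,
            "beta_nohrt": f.beta_nohrt,
            "beta_hrt": f.beta_hrt,
            "se_beta": [float(s) for s in f.se],
            "sigma2": f.sigma2,
            "rho": f.rho,
            "rho_identified": bool(f.rho_identified),
            "sigma2_at_boundary": bool(f.sigma2_at_boundary),
            "loglik": f.loglik,
            "converged": bool(f.converged),
            "n_quad": int(f.n_quad),
            "n_iter": int(f.n_iter),
        }
        for f in fits
    ]


def group_mean_counts(counts: CountMatrix, samples: SampleTable) -> pd.DataFrame:
    """Arithmetic mean count per group, rounded to integer for reporting."""
    df = counts.counts
    out = {}
    for g in (GROUP_PRE, GROUP_NOHRT, GROUP_HRT):
        cols = samples.group_samples(g)
        out[f"mean_{g}"] = np.rint(df[cols].mean(axis=1)).astype(int) if cols else np.nan
    return pd.DataFrame(out, index=df.index)


def run_de_analysis(
    counts: CountMatrix,
    samples: SampleTable,
    config: ModelConfig | None = None,
    library_sizes: pd.Series | None = None,
) -> tuple[list[PoissonNormalFit], pd.DataFrame]:
    """Fit every detected miR and build the full contrast table.

    Filters miRs below ``min_detect`` total counts, fits the twin model to
    each, Wald-tests the three group contrasts, applies BH-FDR (per
    comparison by default), and attaches per-group mean counts and the
    up/down direction in the first-named group.  Non-converged fits are
    excluded from the FDR family and logged.
    """
    config = config or ModelConfig()
    if set(counts.sample_ids) != set(samples.sample_ids):
        raise ValueError("count matrix and sample table cover different samples")
    n_groups = samples.table["group"].nunique()
    if n_groups < 2:
        raise ValueError("differential expression needs >= 2 groups")

    totals = counts.counts.sum(axis=1)
    tested = totals[totals >= config.min_detect].index
    skipped = totals[totals < config.min_detect].index.tolist()
    if skipped:
        logger.info("skipping %d miRs below min_detect=%d", len(skipped), config.min_detect)

    fits: list[PoissonNormalFit] = []
    rows = []
    for mir in tested:
        fit = fit_mir(
            counts.counts.loc[mir], samples, config, mir_id=mir, library_sizes=library_sizes
        )
        if fit is None:
            continue
        fits.append(fit)
        if config.test == "lrt":
            ct = lrt_contrasts(counts.counts.loc[mir], samples, fit, config, library_sizes)
        else:
            ct = test_contrasts(fit)
        if not fit.converged:
            logger.warning("miR %s did not converge; excluded from FDR", mir)
            ct["p"] = np.nan
        rows.append(ct)
    if not rows:
        raise ValueError("no miRs passed the detection filter")
    table = pd.concat(rows, ignore_index=True)

    if config.fdr_scope == "joint":
        table["q"] = fdr_adjust(table["p"])
    else:
        table["q"] = np.nan
        for comp in COMPARISONS:
            m = table["comparison"] == comp
            table.loc[m, "q"] = fdr_adjust(table.loc[m, "p"])
    table["direction"] = np.where(table["estimate"] > 0, "up", np.where(table["estimate"] < 0, "down", "none"))

    means = group_mean_counts(counts, samples)
    table = table.merge(means, left_on="mir_id", right_index=True, how="left")
    sig2 = {f.mir_id: f.sigma2 for f in fits}
    table["overdispersion"] = table["mir_id"].map(sig2)
    table = table.sort_values(
        ["comparison", "q", "mir_id"], kind="mergesort", na_position="last"
    ).reset_index(drop=True)
    return fits, table
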