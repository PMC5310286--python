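"""Two-level normal mixture model for K-dataset z-score rows, fitted by EM.

The model treats each gene's row of K signed z-scores as a draw from a
convex combination of two multivariate components:

* a *complete concordance* (CC) component in which the gene occupies the
  same regulation state (null / up / down) in every dataset, with state
  probabilities ``pi``; and
* a *complete independence* (CI) component in which the state is drawn
  independently per dataset with per-dataset probabilities ``rho[:, k]``.

Both components share the per-dataset state densities
``N(mu[j, k], sigma2[j, k])``.  State 0 is the theoretical null and is
pinned at N(0, 1); state 1 is up-regulation (positive mean) and state 2
down-regulation (negative mean).  The full density for a row z is

    f(z) = lam * f_CC(z) + (1 - lam) * f_CI(z)

so the free-parameter count grows linearly in K (lam; two of pi; per
dataset two of rho, two means and two variances) rather than as 3**K.

All densities and responsibilities are computed in log space with
log-sum-exp so that rows with extreme tail z-scores do not underflow.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp
from scipy.stats import norm

# numerical guards used by the M-step
VARIANCE_FLOOR = 1e-4
PROPORTION_FLOOR = 1e-8
MEAN_SIGN_CLAMP = 0.01  # |mu| floor keeping component identity (up/down)

NULL, UP, DOWN = 0, 1, 2


class DiscosetError(Exception):
    """Base class for user-facing errors raised by this package."""


class DegenerateFitError(DiscosetError):
    """EM encountered a non-finite log-likelihood or an empty/degenerate fit."""


@dataclass
class MixtureParams:
    """Parameters of the two-level mixture over K datasets.

    Attributes
    ----------
    lam : float
        Weight of the complete-concordance component, in [0, 1].
    pi : (3,) array
        CC state probabilities (null, up, down); sums to 1.
    rho : (3, K) array
        CI state probabilities per dataset; each column sums to 1.
    mu : (3, K) array
        State means; row 0 fixed at 0, row 1 positive, row 2 negative.
    sigma2 : (3, K) array
        State variances; row 0 fixed at 1 unless the null variance is
        explicitly freed during fitting.
    """

    lam: float
    pi: np.ndarray
    rho: np.ndarray
    mu: np.ndarray
    sigma2: np.ndarray

    def __post_init__(self) -> None:
        self.pi = np.asarray(self.pi, dtype=float)
        self.rho = np.asarray(self.rho, dtype=float)
        self.mu = np.asarray(self.mu, dtype=float)
        self.sigma2 = np.asarray(self.sigma2, dtype=float)

    @property
    def K(self) -> int:
        return self.rho.shape[1]

    def validate(self) -> None:
        if not (0.0 <= self.lam <= 1.0):
            raise ValueError(f"lam must lie in [0, 1], got {self.lam}")
        if self.pi.shape != (3,):
            raise ValueError("pi must have shape (3,)")
        K = self.K
        for name, arr in (("rho", self.rho), ("mu", self.mu), ("sigma2", self.sigma2)):
            if arr.shape != (3, K):
                raise ValueError(f"{name} must have shape (3, {K})")
        if not np.isclose(self.pi.sum(), 1.0):
            raise ValueError("pi must sum to 1")
        if not np.allclose(self.rho.sum(axis=0), 1.0):
            raise ValueError("each rho column must sum to 1")
        if np.any(self.pi < 0) or np.any(self.rho < 0):
            raise ValueError("pi and rho must be nonnegative")
        if np.any(self.sigma2 <= 0):
            raise ValueError("variances must be positive")
        if np.any(self.mu[UP] <= 0) or np.any(self.mu[DOWN] >= 0):
            raise ValueError("mu[1,:] must be positive and mu[2,:] negative")

    def n_free_parameters(self) -> int:
        # lam; two free pi entries; per dataset: two free rho, two means,
        # two variances (state 0 pinned at N(0, 1))
        return 1 + 2 + self.K * 6

    def copy(self) -> "MixtureParams":
        return MixtureParams(self.lam, self.pi.copy(), self.rho.copy(),
                             self.mu.copy(), self.sigma2.copy())

    def to_dict(self) -> dict:
        return {
            "lambda": float(self.lam),
            "pi": self.pi.tolist(),
            "rho": self.rho.tolist(),
            "mu": self.mu.tolist(),
            "sigma2": self.sigma2.tolist(),
            "K": self.K,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MixtureParams":
        return cls(d["lambda"], np.array(d["pi"]), np.array(d["rho"]),
                   np.array(d["mu"]), np.array(d["sigma2"]))


@dataclass
class PosteriorMemberships:
    """Posterior expectations of the latent indicators, per gene.

    ``omega[i]`` is E(omega_i), the probability the gene follows the CC
    component.  ``xi[i, j]`` is E(omega_i * xi_{i,j}) so its row sum equals
    ``omega[i]``.  ``eta[i, j, k]`` is E((1-omega_i) * eta_{i,j,k}) so for
    each dataset k the sum over j equals ``1 - omega[i]``.
    """

    omega: np.ndarray
    xi: np.ndarray
    eta: np.ndarray


@dataclass
class EMFitReport:
    params: MixtureParams
    loglik_trace: np.ndarray
    n_iter: int
    converged: bool
    init: MixtureParams = field(repr=False, default=None)


# ---------------------------------------------------------------------------
# densities

def _component_logpdf(z: np.ndarray, params: MixtureParams) -> np.ndarray:
    """(m, 3, K) array of log N(z[i,k]; mu[j,k], sigma2[j,k])."""
    z = np.atleast_2d(np.asarray(z, dtype=float))
    return norm.logpdf(z[:, None, :], loc=params.mu[None, :, :],
                       scale=np.sqrt(params.sigma2)[None, :, :])


def _log_ci_rows(logpdf: np.ndarray, params: MixtureParams) -> np.ndarray:
    """log f_CI per gene: sum_k log sum_j rho[j,k] phi_jk(z_k)."""
    with np.errstate(divide="ignore"):
        a = logpdf + np.log(params.rho)[None, :, :]
    return logsumexp(a, axis=1).sum(axis=1)


def _log_cc_rows(logpdf: np.ndarray, params: MixtureParams) -> np.ndarray:
    """log f_CC per gene: log sum_j pi[j] prod_k phi_jk(z_k)."""
    with np.errstate(divide="ignore"):
        return logsumexp(logpdf.sum(axis=2) + np.log(params.pi)[None, :], axis=1)


def _log_two_level_rows(log_cc: np.ndarray, log_ci: np.ndarray,
                        lam: float) -> np.ndarray:
    with np.errstate(divide="ignore"):
        stacked = np.stack([np.log(lam) + log_cc, np.log1p(-lam) + log_ci])
    return logsumexp(stacked, axis=0)


def ci_density(z_row: np.ndarray, params: MixtureParams, log: bool = False):
    """Complete-independence density of one K-vector of z-scores."""
    params.validate()
    val = _log_ci_rows(_component_logpdf(z_row, params), params)[0]
    return val if log else float(np.exp(val))


def cc_density(z_row: np.ndarray, params: MixtureParams, log: bool = False):
    """Complete-concordance density of one K-vector of z-scores."""
    params.validate()
    val = _log_cc_rows(_component_logpdf(z_row, params), params)[0]
    return val if log else float(np.exp(val))


def two_level_density(z_row: np.ndarray, params: MixtureParams,
                      log: bool = False):
    """Full density lam*f_CC + (1-lam)*f_CI of one z-score row."""
    params.validate()
    logpdf = _component_logpdf(z_row, params)
    val = _log_two_level_rows(_log_cc_rows(logpdf, params),
                              _log_ci_rows(logpdf, params), params.lam)[0]
    return val if log else float(np.exp(val))


def loglik(z: np.ndarray, params: MixtureParams) -> float:
    """Total log-likelihood sum_i log f(z_i) of an (m, K) z-score matrix."""
    params.validate()
    logpdf = _component_logpdf(z, params)
    rows = _log_two_level_rows(_log_cc_rows(logpdf, params),
                               _log_ci_rows(logpdf, params), params.lam)
    return float(rows.sum())


# ---------------------------------------------------------------------------
# EM

def e_step(z: np.ndarray, params: MixtureParams) -> PosteriorMemberships:
    """Posterior expectations of the latent indicators given ``params``."""
    params.validate()
    post, _ = _e_step_impl(np.asarray(z, dtype=float), params)
    return post


def _e_step_impl(z, params):
    """Shared E-step core; also returns the per-row log density."""
    logpdf = _component_logpdf(z, params)  # (m, 3, K)
    with np.errstate(divide="ignore"):
        log_rho_phi = logpdf + np.log(params.rho)[None, :, :]
    log_ci_cols = logsumexp(log_rho_phi, axis=1)          # (m, K)
    log_ci = log_ci_cols.sum(axis=1)                      # (m,)
    with np.errstate(divide="ignore"):
        log_cc_terms = logpdf.sum(axis=2) + np.log(params.pi)[None, :]
    log_cc = logsumexp(log_cc_terms, axis=1)              # (m,)
    log_f = _log_two_level_rows(log_cc, log_ci, params.lam)
    if not np.all(np.isfinite(log_f)):
        raise DegenerateFitError("zero density row encountered in E-step")

    with np.errstate(divide="ignore"):
        log_lam, log_1mlam = np.log(params.lam), np.log1p(-params.lam)
    omega = np.exp(log_lam + log_cc - log_f)
    # E(omega_i xi_ij): lam * pi_j * prod_k phi_jk / f
    xi = np.exp(log_lam + log_cc_terms - log_f[:, None])
    # E((1-omega) eta_ijk): (1-lam) rho_jk phi_jk * prod_{h != k} ci_col_h / f
    log_prod_except = log_ci[:, None] - log_ci_cols       # (m, K)
    eta = np.exp(log_1mlam + log_rho_phi + log_prod_except[:, None, :]
                 - log_f[:, None, None])
    return PosteriorMemberships(omega=omega, xi=xi, eta=eta), log_f


def m_step(z: np.ndarray, post: PosteriorMemberships,
           free_null_variance: bool = False) -> MixtureParams:
    """Closed-form parameter updates from posterior memberships.

    The null state (j=0) is held at N(0, 1) — z-scores of truly null genes
    are standard normal by construction — unless ``free_null_variance`` is
    set, in which case its variance (but never its mean) is re-estimated.
    """
    z = np.asarray(z, dtype=float)
    m, K = z.shape
    omega, xi, eta = post.omega, post.xi, post.eta

    lam = float(np.mean(omega))

    pi_num = xi.sum(axis=0)
    pi = _floored_simplex(pi_num)

    rho_num = eta.sum(axis=0)                # (3, K)
    rho = np.empty_like(rho_num)
    for k in range(K):
        rho[:, k] = _floored_simplex(rho_num[:, k])

    # per-state, per-dataset responsibility: CC share + CI share
    w = xi.T[:, :, None] + np.transpose(eta, (1, 0, 2))   # (3, m, K)
    w_tot = w.sum(axis=1)                                 # (3, K)
    mu = np.zeros((3, K))
    sigma2 = np.ones((3, K))
    for j in (UP, DOWN):
        denom = np.maximum(w_tot[j], np.finfo(float).tiny)
        if np.any(w_tot[j] <= np.finfo(float).eps):
            warnings.warn(f"component {j} collapsed (zero responsibility); "
                          "applying floors", RuntimeWarning)
        mu[j] = np.einsum("mk,mk->k", np.ascontiguousarray(w[j]), z) / denom
        sigma2[j] = np.einsum("mk,mk->k", np.ascontiguousarray(w[j]),
                              (z - mu[j][None, :]) ** 2) / denom
    # clamp to preserve component identity (up stays positive, down negative)
    mu[UP] = np.maximum(mu[UP], MEAN_SIGN_CLAMP)
    mu[DOWN] = np.minimum(mu[DOWN], -MEAN_SIGN_CLAMP)
    sigma2[UP] = np.maximum(sigma2[UP], VARIANCE_FLOOR)
    sigma2[DOWN] = np.maximum(sigma2[DOWN], VARIANCE_FLOOR)

    if free_null_variance:
        denom = np.maximum(w_tot[NULL], np.finfo(float).tiny)
        s2 = np.einsum("mk,mk->k", np.ascontiguousarray(w[NULL]), z ** 2) / denom
        sigma2[NULL] = np.maximum(s2, VARIANCE_FLOOR)

    return MixtureParams(lam=lam, pi=pi, rho=rho, mu=mu, sigma2=sigma2)


def _floored_simplex(num: np.ndarray) -> np.ndarray:
    total = num.sum()
    if total <= 0:
        return np.full_like(num, 1.0 / len(num), dtype=float)
    p = np.maximum(num / total, PROPORTION_FLOOR)
    return p / p.sum()


def auto_init(z: np.ndarray) -> MixtureParams:
    """Overdispersed null-heavy starting point for EM.

    Per-dataset up/down means start at the mean of the z-scores beyond the
    90th percentile of the positive tail (mirrored for the negative tail),
    falling back to +/-2 when a tail is empty.
    """
    z = np.asarray(z, dtype=float)
    K = z.shape[1]
    mu = np.zeros((3, K))
    for k in range(K):
        col = z[:, k]
        pos = col[col > 0]
        if pos.size:
            tail = pos[pos >= np.quantile(pos, 0.9)]
            mu[UP, k] = tail.mean() if tail.size else 2.0
        else:
            mu[UP, k] = 2.0
        mu[DOWN, k] = -mu[UP, k]
    return MixtureParams(
        lam=0.5,
        pi=np.array([0.8, 0.1, 0.1]),
        rho=np.tile(np.array([0.8, 0.1, 0.1])[:, None], (1, K)),
        mu=mu,
        sigma2=np.ones((3, K)),
    )


def fit_em(z: np.ndarray, init: MixtureParams | str = "auto",
           tol: float = 1e-4, max_iter: int = 2000, seed: int | None = None,
           min_genes: int = 50, free_null_variance: bool = False) -> EMFitReport:
    """Fit the two-level mixture by EM until the log-likelihood stabilises.

    Convergence is declared when the absolute change in total
    log-likelihood between consecutive iterations drops below ``tol``.
    The fit is deterministic given (z, init); ``seed`` is accepted for
    interface uniformity and reserved for randomised restarts.
    """
    z = np.asarray(z, dtype=float)
    if z.ndim != 2:
        raise ValueError("z must be a (genes x datasets) matrix")
    if z.shape[0] < min_genes:
        raise DiscosetError(
            f"need at least {min_genes} genes for a stable fit, got {z.shape[0]}")
    if not np.all(np.isfinite(z)):
        raise ValueError("z contains non-finite entries")

    params = auto_init(z) if isinstance(init, str) else init.copy()
    params.validate()

    trace = []
    prev_ll = -np.inf
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        post, log_f = _e_step_impl(z, params)
        ll = float(log_f.sum())
        if not np.isfinite(ll):
            raise DegenerateFitError(f"non-finite log-likelihood at iteration {it}")
        trace.append(ll)
        if np.isfinite(prev_ll) and abs(ll - prev_ll) < tol:
            converged = True
            break
        prev_ll = ll
        params = m_step(z, post, free_null_variance=free_null_variance)

    return EMFitReport(params=params, loglik_trace=np.array(trace),
                       n_iter=it, converged=converged)
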