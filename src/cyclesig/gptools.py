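"""Non-stationary Gaussian-process comparison of two groups of single-cell time series.

Each cell trace is modeled as

    x_i(t) = B'(t) alpha + d(t) + noise,

where ``B(t)`` is a vector of Gaussian kernels (the mean basis), ``alpha``
a coefficient vector shared by the population, and ``d(t)`` a zero-mean
Gaussian process with a non-stationary Matern-5/2 covariance whose standard
deviation ``sigma(t)`` and length scale ``ell(t)`` vary over time.  Both are
log-linear in a second, coarser kernel basis ``C(t)``:

    sigma(t) = exp(C'(t) beta),   ell(t) = exp(C'(t) gamma),

and an i.i.d. measurement-noise term ``tau**2`` sits on the diagonal.
Time correlations make pointwise t-tests invalid for comparing two
populations of traces; instead the hyperparameters are estimated by MAP,
the posterior of the population mean is obtained on a sparse grid of J
points by conjugate Bayesian linear regression, and the two posterior
means are compared through the statistic

    T = (mu_x - mu_y)' (Sigma_x + Sigma_y)^+ (mu_x - mu_y)  ~  chi2(nu),

with ``nu`` the number of positive eigenvalues of ``Sigma_x + Sigma_y``.
The whitened effect profile ``E`` (with ``T = sum(E_k**2)``) localizes the
grid points driving the difference.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg, optimize
from scipy.special import gammaln
from scipy.stats import chi2

__all__ = [
    "BasisSet",
    "GPHyperparams",
    "MAPFit",
    "MeanPosterior",
    "ComparisonResult",
    "gaussian_basis",
    "eval_sigma_ell",
    "build_covariance",
    "neg_log_posterior",
    "fit_map",
    "posterior_alpha",
    "posterior_mean_on_grid",
    "compare_groups",
    "compare_trace_groups",
]

_SQRT5 = math.sqrt(5.0)

#: default prior variance of the mean coefficients alpha
ALPHA_PRIOR_VAR = 100.0


@dataclass(frozen=True)
class BasisSet:
    """Evenly spaced Gaussian kernels k(t; c) = exp(-(t-c)^2 / (2 h^2)).

    The bandwidth equals the center spacing, h = (t_T - t_1)/(count - 1),
    so neighboring kernels overlap substantially and the expansion can
    represent smooth functions on [t_1, t_T].
    """

    centers: np.ndarray
    bandwidth: float

    @property
    def count(self) -> int:
        return len(self.centers)

    @property
    def t_start(self) -> float:
        return float(self.centers[0])

    @property
    def t_end(self) -> float:
        return float(self.centers[-1])

    def __call__(self, t) -> np.ndarray:
        """Design matrix of kernel values, shape (len(t), count)."""
        t = np.atleast_1d(np.asarray(t, dtype=float))
        z = (t[:, None] - self.centers[None, :]) / self.bandwidth
        return np.exp(-0.5 * z * z)


def gaussian_basis(t_range, count: int) -> BasisSet:
    """Basis of `count` Gaussian kernels with centers t_1, t_1+h, ..., t_T."""
    t1, tT = float(t_range[0]), float(t_range[-1])
    if count < 2:
        raise ValueError("basis needs at least 2 kernels")
    if not tT > t1:
        raise ValueError("time range must have positive length")
    h = (tT - t1) / (count - 1)
    return BasisSet(centers=np.linspace(t1, tT, count), bandwidth=h)


@dataclass(frozen=True)
class GPHyperparams:
    """Covariance hyperparameters: log-sd coefficients ``beta``, log-length-scale
    coefficients ``gamma`` (both length L), and the measurement-noise scale
    ``tau``.  The priors place all three on (0, inf)."""

    beta: np.ndarray
    gamma: np.ndarray
    tau: float

    def __post_init__(self):
        object.__setattr__(self, "beta", np.asarray(self.beta, dtype=float))
        object.__setattr__(self, "gamma", np.asarray(self.gamma, dtype=float))
        if self.beta.shape != self.gamma.shape:
            raise ValueError("beta and gamma must have the same length")
        if not np.isfinite(self.beta).all() or not np.isfinite(self.gamma).all():
            raise ValueError("non-finite hyperparameter coefficients")

    @property
    def in_prior_support(self) -> bool:
        return bool((self.beta > 0).all() and (self.gamma > 0).all() and self.tau > 0)


def eval_sigma_ell(hyper: GPHyperparams, basis_C: BasisSet, t):
    """Time-varying sd and length scale: sigma = exp(C'beta), ell = exp(C'gamma)."""
    C = basis_C(t)
    if C.shape[1] != len(hyper.beta):
        raise ValueError(
            f"basis has {C.shape[1]} kernels but beta/gamma have length {len(hyper.beta)}"
        )
    sigma = np.exp(C @ hyper.beta)
    ell = np.exp(C @ hyper.gamma)
    return sigma, ell


def matern52(q):
    """Stationary Matern-5/2 correlation as a function of the scaled distance q."""
    q = np.asarray(q, dtype=float)
    a = _SQRT5 * q
    return (1.0 + a + 5.0 * q * q / 3.0) * np.exp(-a)


def build_covariance(
    hyper: GPHyperparams,
    basis_C: BasisSet,
    times,
    include_noise: bool = True,
    sigma_scale: float = 1.0,
) -> np.ndarray:
    """Non-stationary Matern-5/2 covariance on `times`.

    K(s,t) = sigma(s) sigma(t) * sqrt(2 ell(s) ell(t) / (ell(s)^2 + ell(t)^2))
             * M_{5/2}( sqrt(2 (s-t)^2 / (ell(s)^2 + ell(t)^2)) )
             + tau^2 * delta(s,t),

    the standard construction for inducing a valid non-stationary kernel from
    a stationary one; for constant sigma, ell it reduces exactly to the
    stationary Matern-5/2.  `sigma_scale` rescales sigma(t) (the priors force
    sigma >= 1, so simulation fixtures may need smaller amplitudes).
    """
    times = np.asarray(times, dtype=float)
    if not np.isfinite(times).all():
        raise ValueError("non-finite time points")
    with np.errstate(over="ignore"):  # overflow is checked and reported below
        sigma, ell = eval_sigma_ell(hyper, basis_C, times)
    sigma = sigma * float(sigma_scale)
    for name, arr in (("sigma", sigma), ("ell", ell)):
        if not np.isfinite(arr).all():
            bad = int(np.argmax(~np.isfinite(arr)))
            raise ValueError(
                f"{name}(t) overflowed at t={times[bad]:.4g}; "
                f"check beta/gamma coefficients"
            )
    l2 = ell * ell
    denom = l2[:, None] + l2[None, :]
    prefac = np.sqrt(2.0 * ell[:, None] * ell[None, :] / denom)
    dist2 = (times[:, None] - times[None, :]) ** 2
    q = np.sqrt(2.0 * dist2 / denom)
    K = sigma[:, None] * sigma[None, :] * prefac * matern52(q)
    K = 0.5 * (K + K.T)
    if include_noise:
        K[np.diag_indices_from(K)] += hyper.tau**2
    return K


def _chol_with_jitter(S: np.ndarray):
    """Cholesky factor, adding 1e-9*max(diag) jitter (escalating) on failure."""
    try:
        return linalg.cho_factor(S, lower=True)
    except linalg.LinAlgError:
        pass
    jitter = 1e-9 * float(np.max(np.diag(S)))
    for _ in range(6):
        try:
            return linalg.cho_factor(S + jitter * np.eye(S.shape[0]), lower=True)
        except linalg.LinAlgError:
            jitter *= 10.0
    raise linalg.LinAlgError("covariance factorization failed even with jitter")


def _prior_neg_logpdf(alpha, hyper: GPHyperparams, basis_C: BasisSet) -> float:
    """-log prior: alpha ~ N(0, 10^2); beta_l, tau ~ Gamma(1,1);
    gamma_l ~ Gamma(0.2 (t_T - t_1), 1) (shape-rate)."""
    alpha = np.asarray(alpha, dtype=float)
    if (hyper.beta <= 0).any() or (hyper.gamma <= 0).any() or hyper.tau <= 0:
        return np.inf
    J = len(alpha)
    out = 0.5 * J * math.log(2.0 * math.pi * ALPHA_PRIOR_VAR)
    out += 0.5 * float(alpha @ alpha) / ALPHA_PRIOR_VAR
    # Gamma(1,1): -log pdf = x
    out += float(np.sum(hyper.beta)) + float(hyper.tau)
    a = 0.2 * (basis_C.t_end - basis_C.t_start)
    out += float(np.sum(hyper.gamma - (a - 1.0) * np.log(hyper.gamma))) + len(
        hyper.gamma
    ) * float(gammaln(a))
    return out


def neg_log_posterior(
    alpha,
    hyper: GPHyperparams,
    data,
    times,
    basis_B: BasisSet,
    basis_C: BasisSet,
    include_priors: bool = True,
) -> float:
    """Negative log joint posterior of (alpha, beta, gamma, tau) given M cell
    traces measured on a shared time grid (`data` has shape (M, T))."""
    data = np.atleast_2d(np.asarray(data, dtype=float))
    times = np.asarray(times, dtype=float)
    M, T = data.shape
    if len(times) != T:
        raise ValueError("data columns must match the time grid")
    alpha = np.asarray(alpha, dtype=float)
    B = basis_B(times)
    Sigma = build_covariance(hyper, basis_C, times)
    c = _chol_with_jitter(Sigma)
    logdet = 2.0 * float(np.sum(np.log(np.diag(c[0]))))
    resid = data - (B @ alpha)[None, :]
    sol = linalg.cho_solve(c, resid.T)
    quad = float(np.sum(resid.T * sol))
    out = 0.5 * M * (logdet + T * math.log(2.0 * math.pi)) + 0.5 * quad
    if include_priors:
        out += _prior_neg_logpdf(alpha, hyper, basis_C)
    return out


@dataclass
class MAPFit:
    """Joint MAP estimate; alpha is a nuisance here and is re-estimated with
    proper uncertainty by `posterior_alpha` downstream."""

    alpha: np.ndarray
    hyper: GPHyperparams
    objective: float
    times: np.ndarray
    basis_B: BasisSet
    basis_C: BasisSet
    converged: bool
    restart_objectives: list = field(default_factory=list)

    def covariance(self) -> np.ndarray:
        return build_covariance(self.hyper, self.basis_C, self.times)


def _ridge_coeffs(design: np.ndarray, target: np.ndarray, lam: float = 1e-6):
    A = design.T @ design + lam * np.eye(design.shape[1])
    return linalg.solve(A, design.T @ target, assume_a="pos")


def _profiled_alpha(c, B, data_sum, M):
    """Conditional MAP of alpha given the covariance Cholesky factor `c`."""
    SinvB = linalg.cho_solve(c, B)
    A = np.eye(B.shape[1]) / ALPHA_PRIOR_VAR + M * (B.T @ SinvB)
    rhs = SinvB.T @ data_sum
    return linalg.solve(A, rhs, assume_a="pos")


def fit_map(
    data,
    times,
    J: int = 10,
    L: int = 5,
    n_restarts: int = 5,
    seed: int = 0,
    maxiter: int = 300,
) -> MAPFit:
    """MAP estimate of (alpha, beta, gamma, tau) for one population.

    The objective is jointly minimized over all parameters; alpha enters
    the posterior as a Gaussian quadratic, so for every (beta, gamma, tau)
    its conditional minimizer has a closed form and is profiled out exactly,
    leaving a bound-constrained optimization over the 2L+1 covariance
    parameters (L-BFGS-B, multi-start with seeded restarts).
    """
    data = np.atleast_2d(np.asarray(data, dtype=float))
    times = np.asarray(times, dtype=float)
    M, T = data.shape
    if M < 5:
        raise ValueError("need at least 5 cells to fit the population model")
    if T < 2 * J:
        warnings.warn(
            f"only {T} time points for J={J} mean kernels; fit may be unstable",
            stacklevel=2,
        )
    basis_B = gaussian_basis(times, J)
    basis_C = gaussian_basis(times, L)
    B = basis_B(times)
    C = basis_C(times)
    data_sum = data.sum(axis=0)

    def objective(theta):
        hyper = GPHyperparams(beta=theta[:L], gamma=theta[L : 2 * L], tau=theta[-1])
        try:
            Sigma = build_covariance(hyper, basis_C, times)
            c = _chol_with_jitter(Sigma)
        except (ValueError, linalg.LinAlgError):
            return np.inf
        alpha = _profiled_alpha(c, B, data_sum, M)
        logdet = 2.0 * float(np.sum(np.log(np.diag(c[0]))))
        resid = data - (B @ alpha)[None, :]
        quad = float(np.sum(resid.T * linalg.cho_solve(c, resid.T)))
        val = 0.5 * M * (logdet + T * math.log(2.0 * math.pi)) + 0.5 * quad
        val += _prior_neg_logpdf(alpha, hyper, basis_C)
        return val

    # initialization: beta from the log pooled sd, gamma from log of a quarter
    # of the time range, tau from the high-frequency residual sd
    pooled_sd = data.std(axis=0, ddof=1)
    beta0 = _ridge_coeffs(C, np.log(np.maximum(pooled_sd, 1e-3)))
    gamma0 = _ridge_coeffs(
        C, np.full(T, math.log(0.25 * (times[-1] - times[0])))
    )
    tau0 = float(np.median(np.std(np.diff(data, axis=1), axis=1))) / math.sqrt(2.0)
    theta0 = np.concatenate([beta0, gamma0, [tau0]])
    theta0 = np.clip(theta0, 1e-3, None)

    rng = np.random.default_rng(seed)
    bounds = [(1e-6, None)] * (2 * L + 1)
    best = None
    restart_objectives = []
    for r in range(n_restarts):
        start = theta0 if r == 0 else theta0 * np.exp(rng.normal(0.0, 0.3, theta0.shape))
        res = optimize.minimize(
            objective,
            np.clip(start, 1e-6, None),
            method="L-BFGS-B",
            bounds=bounds,
            options={"maxiter": maxiter},
        )
        restart_objectives.append(float(res.fun))
        if best is None or res.fun < best.fun:
            best = res
    if best is None or not np.isfinite(best.fun):
        raise RuntimeError("all MAP restarts failed to converge")
    theta = best.x
    hyper = GPHyperparams(beta=theta[:L].copy(), gamma=theta[L : 2 * L].copy(), tau=float(theta[-1]))
    Sigma = build_covariance(hyper, basis_C, times)
    alpha = _profiled_alpha(_chol_with_jitter(Sigma), B, data_sum, M)
    return MAPFit(
        alpha=alpha,
        hyper=hyper,
        objective=float(best.fun),
        times=times,
        basis_B=basis_B,
        basis_C=basis_C,
        converged=bool(best.success),
        restart_objectives=restart_objectives,
    )


def posterior_alpha(data, Sigma_hat, basis_B: BasisSet, times):
    """Conjugate Gaussian posterior of the mean coefficients alpha.

    With the GP part fixed at its MAP value, the model is Bayesian linear
    regression with Gaussian noise covariance Sigma_hat shared by the M
    cells:  A = 10^-2 I + M B' Sigma^-1 B, cov = A^-1,
    mu = A^-1 B' Sigma^-1 sum_i x_i.
    """
    data = np.atleast_2d(np.asarray(data, dtype=float))
    times = np.asarray(times, dtype=float)
    M = data.shape[0]
    B = basis_B(times)
    c = _chol_with_jitter(np.asarray(Sigma_hat, dtype=float))
    SinvB = linalg.cho_solve(c, B)
    A = np.eye(B.shape[1]) / ALPHA_PRIOR_VAR + M * (B.T @ SinvB)
    cov_alpha = linalg.inv(A)
    cov_alpha = 0.5 * (cov_alpha + cov_alpha.T)
    mu_alpha = cov_alpha @ (SinvB.T @ data.sum(axis=0))
    return mu_alpha, cov_alpha


@dataclass
class MeanPosterior:
    """Gaussian posterior of the population mean m(s) on a sparse grid s."""

    grid: np.ndarray
    mu_alpha: np.ndarray
    cov_alpha: np.ndarray
    mu: np.ndarray
    cov: np.ndarray


def posterior_mean_on_grid(mu_alpha, cov_alpha, basis_B: BasisSet, grid) -> MeanPosterior:
    """Posterior of m(s) = B'(s) alpha on a grid inside [t_1, t_T].

    The mean is a combination of J basis functions, so its covariance has
    rank at most J; use a sparse grid of J evenly spaced points to keep it
    full rank.
    """
    grid = np.asarray(grid, dtype=float)
    tol = 1e-9 * (basis_B.t_end - basis_B.t_start)
    if grid.min() < basis_B.t_start - tol or grid.max() > basis_B.t_end + tol:
        raise ValueError("grid must lie within the basis time range")
    Bs = basis_B(grid)
    mu = Bs @ np.asarray(mu_alpha, dtype=float)
    cov = Bs @ np.asarray(cov_alpha, dtype=float) @ Bs.T
    cov = 0.5 * (cov + cov.T)
    return MeanPosterior(
        grid=grid,
        mu_alpha=np.asarray(mu_alpha, float),
        cov_alpha=np.asarray(cov_alpha, float),
        mu=mu,
        cov=cov,
    )


@dataclass
class ComparisonResult:
    """Outcome of comparing two posterior mean distributions.

    T is chi-squared with `nu` degrees of freedom under the null of equal
    means; `epsilon` is its upper tail probability (the largest credible
    level whose region still contains zero); `effect` is the whitened
    per-grid-point profile with T = sum(effect**2).
    """

    delta: np.ndarray
    T: float
    nu: int
    epsilon: float
    effect: np.ndarray
    grid: np.ndarray


def compare_groups(
    post_x: MeanPosterior, post_y: MeanPosterior, eig_tol: float | None = None
) -> ComparisonResult:
    """Chi-squared comparison of two posterior means on a shared grid.

    S = Sigma_x + Sigma_y is eigendecomposed; nu counts eigenvalues above
    `eig_tol` (default: machine-eps * J * lambda_max, the standard numerical
    rank rule), T is the squared Mahalanobis norm of the mean difference on
    the positive eigenspace, and epsilon = P(chi2(nu) > T).
    """
    if post_x.grid.shape != post_y.grid.shape or not np.allclose(
        post_x.grid, post_y.grid
    ):
        raise ValueError("posterior grids differ; refit on a common grid")
    delta = post_x.mu - post_y.mu
    S = post_x.cov + post_y.cov
    w, V = linalg.eigh(S)
    wmax = max(float(w[-1]), 0.0)
    if eig_tol is None:
        eig_tol = np.finfo(float).eps * len(w) * wmax
    pos = w > eig_tol
    nu = int(np.count_nonzero(pos))
    if nu == 0:
        warnings.warn("covariance sum has no positive eigenvalues", stacklevel=2)
        return ComparisonResult(
            delta=delta, T=0.0, nu=0, epsilon=1.0,
            effect=np.zeros(0), grid=post_x.grid,
        )
    effect = (V[:, pos].T @ delta) / np.sqrt(w[pos])
    T = float(effect @ effect)
    epsilon = float(chi2.sf(T, nu))
    return ComparisonResult(
        delta=delta, T=T, nu=nu, epsilon=epsilon, effect=effect, grid=post_x.grid
    )


def compare_trace_groups(
    data_x,
    data_y,
    times,
    J: int = 10,
    L: int = 5,
    seed: int = 0,
    n_restarts: int = 5,
    eig_tol: float | None = None,
):
    """Full two-group procedure: MAP fit per group, posterior of each mean on
    the sparse J-point grid, chi-squared comparison.

    Returns (ComparisonResult, MeanPosterior_x, MeanPosterior_y).
    """
    times = np.asarray(times, dtype=float)
    posts = []
    for k, data in enumerate((data_x, data_y)):
        fit = fit_map(data, times, J=J, L=L, seed=seed + k, n_restarts=n_restarts)
        Sigma_hat = fit.covariance()
        mu_a, cov_a = posterior_alpha(data, Sigma_hat, fit.basis_B, times)
        grid = np.linspace(times[0], times[-1], J)
        posts.append(posterior_mean_on_grid(mu_a, cov_a, fit.basis_B, grid))
    result = compare_groups(posts[0], posts[1], eig_tol=eig_tol)
    return result, posts[0], posts[1]
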