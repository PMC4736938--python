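"""Virtual populations: density smoothing, reduced-rank ICAR spatial effects,
lognormal overdispersion and Poisson realization.

Expected abundance in unit j is

    lambda_j = a_j * exp(log(d*_j) + eta_j + eps_j)

where d*_j is a neighbourhood-smoothed density, eta is a mean-zero spatially
autocorrelated random effect drawn from a restricted spatial regression
(RSR) reduced-rank ICAR distribution with precision tau_eta, and eps_j is
iid Gaussian noise.  A population realization draws N_j ~ Poisson(lambda_j).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg

from .scenario import DensitySurface, SurveyGrid

__all__ = [
    "SmoothingMatrix",
    "SpatialEffectModel",
    "IntensitySurface",
    "PopulationRealization",
    "build_smoothing_matrix",
    "smooth_density",
    "build_rsr_basis",
    "draw_spatial_effects",
    "compute_lambda",
    "draw_population",
    "default_generation_rank",
    "simulate_intensity",
]

#: default ICAR precision of the generating spatial random effects
TAU_ETA_DEFAULT = 5.0

#: default variance of the iid lognormal overdispersion term eps_j
EPS_VARIANCE_DEFAULT = 0.1

#: floor applied to zero smoothed densities before taking logs
DENSITY_FLOOR = 1e-12


@dataclass
class SmoothingMatrix:
    """Row-stochastic neighbourhood smoother: self weight 2, rook-neighbour
    weight 1, rows standardised to sum to one."""

    W: np.ndarray  # (J, J)


@dataclass
class SpatialEffectModel:
    """Reduced-rank (Moran basis) ICAR model for spatial random effects.

    eta = K alpha with alpha ~ N(0, (tau_eta * K'QK)^(-1)), where Q is the
    ICAR precision structure (degree matrix minus adjacency) and K holds the
    leading eigenvectors of the Moran operator P A P, P projecting orthogonal
    to the fixed-effect design matrix.
    """

    Q: np.ndarray           # (J, J) ICAR structure
    K: np.ndarray           # (J, m) orthonormal basis
    m: int
    tau_eta: float = TAU_ETA_DEFAULT
    moran_eigenvalues: np.ndarray | None = None

    @property
    def prior_precision(self) -> np.ndarray:
        """Precision of the basis coefficients alpha: tau_eta * K'QK."""
        return self.tau_eta * (self.K.T @ self.Q @ self.K)

    def marginal_covariance(self) -> np.ndarray:
        """Implied covariance of eta: K (tau K'QK)^(-1) K'."""
        M = self.K.T @ self.Q @ self.K
        M = M + 1e-10 * np.eye(self.m)
        return self.K @ np.linalg.inv(self.tau_eta * M) @ self.K.T


@dataclass
class IntensitySurface:
    """Expected abundance per unit for one stochastic replicate."""

    species: str
    lam: np.ndarray      # (J,) expected animals per unit
    eta: np.ndarray
    eps: np.ndarray
    d_star: np.ndarray


@dataclass
class PopulationRealization:
    """Integer animals per unit."""

    species: str
    N_j: np.ndarray

    @property
    def N(self) -> int:
        return int(self.N_j.sum())


def build_smoothing_matrix(grid: SurveyGrid) -> SmoothingMatrix:
    """Row-stochastic smoother with self weight 2 and neighbour weight 1.

    Isolated units end up with self weight 1 after standardisation.
    """
    J = grid.n_units
    W = np.zeros((J, J))
    for i, nb in enumerate(grid.adjacency):
        W[i, i] = 2.0
        W[i, nb] = 1.0
    W /= W.sum(axis=1, keepdims=True)
    return SmoothingMatrix(W=W)


def smooth_density(W: SmoothingMatrix, D: DensitySurface) -> np.ndarray:
    """Smoothed densities d* = W d (no re-normalisation of the total)."""
    if W.W.shape[1] != D.d.size:
        raise ValueError("smoothing matrix and density surface dimensions differ")
    return W.W @ D.d


def default_generation_rank(J: int) -> int:
    """Default reduced rank for the generating spatial effects."""
    return min(50, max(1, int(np.ceil(0.1 * J))))


def build_rsr_basis(
    grid: SurveyGrid,
    X: np.ndarray | None = None,
    m: int | None = None,
    tau_eta: float = TAU_ETA_DEFAULT,
) -> SpatialEffectModel:
    """Moran-operator basis for restricted spatial regression.

    The Moran operator is P A P with A the rook adjacency and
    P = I - X (X'X)^(-1) X' (identity when ``X`` is None); its ``m`` leading
    eigenvectors form the basis K.  The ICAR structure Q = diag(degree) - A.
    """
    J = grid.n_units
    if m is None:
        m = default_generation_rank(J)
    if not 1 <= m < max(J, 2):
        raise ValueError(f"rank m={m} must satisfy 1 <= m < J={J}")
    A = grid.adjacency_matrix()
    Q = np.diag(A.sum(axis=1)) - A
    if X is None:
        B = np.eye(J)
    else:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[0] != J:
            X = X.T
        if np.linalg.matrix_rank(X) < X.shape[1]:
            raise ValueError("fixed-effect design matrix is rank deficient")
        # orthonormal basis of the complement of the column space of X;
        # the Moran operator P A P restricted to this subspace is B' A B
        B = scipy.linalg.null_space(X.T)
    if m > B.shape[1]:
        raise ValueError(
            f"rank m={m} exceeds the dimension orthogonal to the fixed effects"
        )
    omega = B.T @ A @ B
    omega = (omega + omega.T) / 2.0
    evals, evecs = scipy.linalg.eigh(omega)
    idx = np.argsort(evals)[::-1][:m]
    K = B @ evecs[:, idx]
    return SpatialEffectModel(
        Q=Q, K=K, m=m, tau_eta=tau_eta, moran_eigenvalues=evals[idx]
    )


def draw_spatial_effects(
    model: SpatialEffectModel, seed: int | np.random.Generator = 0
) -> np.ndarray:
    """Draw eta = K alpha, alpha ~ N(0, (tau_eta K'QK)^(-1))."""
    if model.tau_eta <= 0:
        raise ValueError("tau_eta must be positive")
    rng = np.random.default_rng(seed)
    M = model.prior_precision
    # jitter guards against numerically singular projected structures
    L = np.linalg.cholesky(M + 1e-10 * np.eye(model.m))
    z = rng.standard_normal(model.m)
    alpha = scipy.linalg.solve_triangular(L.T, z, lower=False)
    return model.K @ alpha


def compute_lambda(
    grid: SurveyGrid,
    d_star: np.ndarray,
    eta: np.ndarray,
    seed: int | np.random.Generator = 0,
    eps_variance: float = EPS_VARIANCE_DEFAULT,
    species: str = "seal",
) -> IntensitySurface:
    """Expected abundance lambda_j = a_j exp(log d*_j + eta_j + eps_j).

    eps_j are iid Normal(0, eps_variance).  Zero smoothed densities on
    habitat are floored at a tiny positive value so the log is finite;
    lambda is exactly zero where the habitat area is zero.
    """
    d_star = np.asarray(d_star, dtype=float)
    if (d_star < 0).any():
        raise ValueError("smoothed densities must be non-negative")
    rng = np.random.default_rng(seed)
    eps = rng.normal(0.0, np.sqrt(eps_variance), size=grid.n_units)
    a = grid.a
    lam = np.zeros(grid.n_units)
    pos = a > 0
    lam[pos] = a[pos] * np.exp(
        np.log(np.maximum(d_star[pos], DENSITY_FLOOR)) + eta[pos] + eps[pos]
    )
    return IntensitySurface(species=species, lam=lam, eta=eta, eps=eps, d_star=d_star)


def draw_population(
    intensity: IntensitySurface, seed: int | np.random.Generator = 0
) -> PopulationRealization:
    """Realize N_j ~ Poisson(lambda_j) independently per unit."""
    if (intensity.lam < 0).any():
        raise ValueError("lambda must be non-negative")
    rng = np.random.default_rng(seed)
    return PopulationRealization(
        species=intensity.species, N_j=rng.poisson(intensity.lam)
    )


def simulate_intensity(
    grid: SurveyGrid,
    density: DensitySurface,
    model: SpatialEffectModel,
    seed: int | np.random.Generator = 0,
    eps_variance: float = EPS_VARIANCE_DEFAULT,
    smoother: SmoothingMatrix | None = None,
) -> IntensitySurface:
    """Convenience pipeline: smooth the density surface, draw spatial
    effects, and assemble one stochastic intensity surface."""
    rng = np.random.default_rng(seed)
    if smoother is None:
        smoother = build_smoothing_matrix(grid)
    d_star = smooth_density(smoother, density)
    eta = draw_spatial_effects(model, rng)
    return compute_lambda(
        grid, d_star, eta, rng, eps_variance=eps_variance, species=density.species
    )
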