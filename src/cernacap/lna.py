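"""Linear noise approximation around the deterministic steady state.

Fluctuations ``dx`` of the state vector x = (m1, m2, mu, c1, c2) relax as
``d(dx)/dt = A dx + eta`` with A the Jacobian of the mass-action drift at
the fixed point and ``<eta_a(t) eta_b(t')> = Gamma_ab delta(t-t')``.  The
diffusion matrix is assembled channel by channel: each of the 14 elementary
reactions is an independent Poisson noise source of strength equal to its
stationary propensity, entering each species with its stoichiometric sign,
so ``Gamma = sum_r a_r s_r s_r^T``.  The stationary covariance solves the
fluctuation-dissipation (Lyapunov) relation ``A C + C A^T + Gamma = 0``;
both a spectral (eigen-decomposition) evaluation and a direct Lyapunov
solve are provided and agree to solver precision.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.linalg import solve_continuous_lyapunov

from .gillespie import SPECIES, build_reaction_system
from .parameters import KineticParameters, Occupancies

__all__ = [
    "LNAResult",
    "drift",
    "jacobian",
    "diffusion_matrix",
    "covariance_spectral",
    "covariance_lyapunov",
    "lna_covariance",
]


@dataclass(frozen=True)
class LNAResult:
    """Jacobian, diffusion matrix, stationary covariance and the spectrum of A."""

    A: np.ndarray
    Gamma: np.ndarray
    C: np.ndarray
    eigenvalues: np.ndarray
    species: tuple[str, ...] = SPECIES

    @property
    def stable(self) -> bool:
        return bool(np.all(self.eigenvalues.real < 0))

    def fano(self, mean: np.ndarray) -> np.ndarray:
        """Fano factors ``C_aa / mean_a`` (NaN where the mean vanishes)."""
        mean = np.asarray(mean, dtype=float)
        with np.errstate(divide="ignore", invalid="ignore"):
            return np.where(mean > 0, np.diag(self.C) / mean, np.nan)


def drift(params: KineticParameters, occ: Occupancies, x: np.ndarray) -> np.ndarray:
    """Deterministic part of the mass-action kinetics at state ``x``."""
    m1, m2, mu, c1, c2 = np.asarray(x, dtype=float)
    return np.array(
        [
            params.b1 * occ.n1 - params.d1 * m1 - params.kplus1 * mu * m1
            + params.kminus1 * c1,
            params.b2 * occ.n2 - params.d2 * m2 - params.kplus2 * mu * m2
            + params.kminus2 * c2,
            params.beta * occ.nmu - params.delta * mu
            - params.kplus1 * mu * m1 - params.kplus2 * mu * m2
            + (params.kminus1 + params.kappa1) * c1
            + (params.kminus2 + params.kappa2) * c2,
            params.kplus1 * mu * m1
            - (params.sigma1 + params.kminus1 + params.kappa1) * c1,
            params.kplus2 * mu * m2
            - (params.sigma2 + params.kminus2 + params.kappa2) * c2,
        ]
    )


def jacobian(params: KineticParameters, ss) -> np.ndarray:
    """Analytic Jacobian of the drift at the steady state (5x5)."""
    m1, m2, mu = ss.m1, ss.m2, ss.mu
    k1, k2 = params.kplus1, params.kplus2
    D1 = params.sigma1 + params.kminus1 + params.kappa1
    D2 = params.sigma2 + params.kminus2 + params.kappa2
    A = np.zeros((5, 5))
    # d(m1_dot)/dx
    A[0, 0] = -params.d1 - k1 * mu
    A[0, 2] = -k1 * m1
    A[0, 3] = params.kminus1
    # d(m2_dot)/dx
    A[1, 1] = -params.d2 - k2 * mu
    A[1, 2] = -k2 * m2
    A[1, 4] = params.kminus2
    # d(mu_dot)/dx
    A[2, 0] = -k1 * mu
    A[2, 1] = -k2 * mu
    A[2, 2] = -params.delta - k1 * m1 - k2 * m2
    A[2, 3] = params.kminus1 + params.kappa1
    A[2, 4] = params.kminus2 + params.kappa2
    # d(c1_dot)/dx
    A[3, 0] = k1 * mu
    A[3, 2] = k1 * m1
    A[3, 3] = -D1
    # d(c2_dot)/dx
    A[4, 1] = k2 * mu
    A[4, 2] = k2 * m2
    A[4, 4] = -D2
    return A


def diffusion_matrix(params: KineticParameters, ss) -> np.ndarray:
    """Diffusion matrix ``Gamma = sum_r a_r s_r s_r^T`` at the steady state.

    Each elementary reaction contributes its stationary propensity times the
    outer product of its stoichiometric vector, which reproduces the Poisson
    noise amplitudes of the individual synthesis, degradation, association,
    dissociation and complex-decay channels together with their cross-species
    sign pattern (e.g. one association event removes a free ceRNA *and* a
    free miRNA while creating a complex).
    """
    system = build_reaction_system(params, ss.occ)
    a = system.propensities(ss.as_vector())
    S = system.stoich.astype(float)
    return (S * a[:, None]).T @ S


def covariance_lyapunov(A: np.ndarray, Gamma: np.ndarray) -> np.ndarray:
    """Stationary covariance from the Lyapunov equation ``A C + C A^T = -Gamma``."""
    A = np.asarray(A, dtype=float)
    Gamma = np.asarray(Gamma, dtype=float)
    eig = np.linalg.eigvals(A)
    if np.any(eig.real >= 0):
        raise ValueError(
            f"relaxation matrix is not stable (max Re(lambda) = {eig.real.max():.3e})"
        )
    C = solve_continuous_lyapunov(A, -Gamma)
    return 0.5 * (C + C.T)


def covariance_spectral(
    A: np.ndarray, Gamma: np.ndarray, imag_tol: float = 1e-8
) -> np.ndarray:
    """Stationary covariance from the eigen-decomposition of ``A``.

    With ``A = B diag(lambda) B^-1`` and ``M = B^-1 Gamma B^-T``, the
    covariance is ``C = -B [M_pr / (lambda_p + lambda_r)] B^T``.  Requires a
    diagonalizable, strictly stable ``A``; falls back (with a warning) to
    the Lyapunov solve when the eigenbasis is numerically defective, and
    fails explicitly at marginal stability where ``lambda_p + lambda_r``
    vanishes.
    """
    A = np.asarray(A, dtype=float)
    Gamma = np.asarray(Gamma, dtype=float)
    lam, B = np.linalg.eig(A)
    if np.any(lam.real >= 0):
        raise ValueError(
            f"relaxation matrix is not stable (max Re(lambda) = {lam.real.max():.3e})"
        )
    pair_sum = lam[:, None] + lam[None, :]
    if np.min(np.abs(pair_sum)) < 1e-12 * np.max(np.abs(lam)):
        raise ValueError("marginally stable spectrum: lambda_p + lambda_r ~ 0")
    cond = np.linalg.cond(B)
    if not np.isfinite(cond) or cond > 1e12:
        warnings.warn(
            "near-defective eigenbasis; falling back to the Lyapunov solver",
            RuntimeWarning,
            stacklevel=2,
        )
        return covariance_lyapunov(A, Gamma)
    Binv = np.linalg.inv(B)
    M = Binv @ Gamma @ Binv.T
    C = -B @ (M / pair_sum) @ B.T
    scale = max(np.abs(C).max(), 1e-300)
    if np.abs(C.imag).max() > imag_tol * scale:
        raise ValueError(
            f"spectral covariance has non-negligible imaginary part "
            f"({np.abs(C.imag).max():.3e})"
        )
    C = C.real
    return 0.5 * (C + C.T)


def lna_covariance(
    params: KineticParameters, ss, method: str = "lyapunov"
) -> LNAResult:
    """Full LNA at a solved steady state: A, Gamma, C and the spectrum of A.

    ``method`` selects the covariance path: ``"lyapunov"`` (default,
    recommended) or ``"spectral"``.
    """
    A = jacobian(params, ss)
    Gamma = diffusion_matrix(params, ss)
    if method == "lyapunov":
        C = covariance_lyapunov(A, Gamma)
    elif method == "spectral":
        C = covariance_spectral(A, Gamma)
    else:
        raise ValueError("method must be 'lyapunov' or 'spectral'")
    return LNAResult(A=A, Gamma=Gamma, C=C, eigenvalues=np.linalg.eigvals(A))
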