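"""Deterministic layer: promoter occupancy, steady state and regimes.

At steady state the coupled mass-action balance for the five species
(m1, m2, mu, c1, c2) reduces exactly to a scalar problem in the free-miRNA
level ``mu``: eliminating the complexes gives the threshold-linear form

    m_i = (b_i n_i / d_i) * mu0_i / (mu0_i + mu),
    mu0_i = (d_i / k_i+) * (1 + k_i- / (sigma_i + kappa_i)),

and the miRNA balance becomes a strictly increasing function of ``mu``
whose unique root on [0, beta*nmu/delta] is found by bracketing.  ``mu0_i``
is the soft threshold separating the *free* (mu << mu0), *susceptible*
(mu ~ mu0) and *repressed* (mu >> mu0) regimes of ceRNA_i.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .parameters import KineticParameters, Occupancies

__all__ = [
    "SteadyState",
    "tf_occupancy",
    "occupancy_inverse",
    "mirna_threshold",
    "cerna_gain",
    "steady_state",
    "classify_regime",
    "rescale_omega",
    "mu_threshold_crossing",
    "steady_state_residuals",
]

#: default width (in ratio mu/mu0) of the susceptible band used by
#: :func:`classify_regime`; the regimes are qualitative, the band is a choice.
DEFAULT_REGIME_BAND = 10.0


@dataclass(frozen=True)
class SteadyState:
    """Deterministic stationary state of the network.

    Molecule numbers ``m1, m2, mu, c1, c2``, the susceptibility thresholds
    ``mu0_1, mu0_2``, regime labels for each ceRNA, and the occupancies the
    state was solved at (kept so that downstream consumers — the diffusion
    matrix, the simulator — see consistent synthesis rates).
    """

    m1: float
    m2: float
    mu: float
    c1: float
    c2: float
    mu0_1: float
    mu0_2: float
    regime1: str
    regime2: str
    occ: Occupancies
    residual: float

    def as_vector(self) -> np.ndarray:
        """State vector in the canonical species order (m1, m2, mu, c1, c2)."""
        return np.array([self.m1, self.m2, self.mu, self.c1, self.c2])


def tf_occupancy(f: float, params: KineticParameters) -> float:
    """Equilibrium fractional occupancy of a promoter at TF copy number ``f``.

    ``n = f^h / (f^h + kout/kin)``; strictly increasing in ``f``, 0 at
    ``f = 0`` and saturating at 1.
    """
    if f < 0:
        raise ValueError(f"TF copy number must be >= 0, got {f!r}")
    fh = float(f) ** params.h
    return fh / (fh + params.kout_over_kin)


def occupancy_inverse(n: float, params: KineticParameters) -> float:
    """TF copy number producing occupancy ``n`` (closed-form Hill inversion)."""
    if not (0.0 < n < 1.0):
        raise ValueError(f"occupancy must lie in (0, 1), got {n!r}")
    return (n / (1.0 - n) * params.kout_over_kin) ** (1.0 / params.h)


def mirna_threshold(params: KineticParameters, i: int) -> float:
    """Soft miRNA threshold ``mu0_i`` of ceRNA_i.

    Equals ``(d_i/k_i+) * (1 + k_i-/(sigma_i + kappa_i))``; returns ``inf``
    when ``k_i+ = 0`` (the ceRNA is decoupled from the miRNA pool).
    """
    kp = params.kplus(i)
    if kp == 0.0:
        return math.inf
    denom = params.sigma(i) + params.kappa(i)
    if denom == 0.0:
        # complexes only dissociate: no net miRNA-mediated decay channel
        return math.inf
    return params.d(i) / kp * (1.0 + params.kminus(i) / denom)


def cerna_gain(mu: float, params: KineticParameters, i: int) -> float:
    """Sigmoidal repression factor ``F_i = mu0_i / (mu0_i + mu)`` in (0, 1]."""
    if mu < 0:
        raise ValueError(f"miRNA level must be >= 0, got {mu!r}")
    mu0 = mirna_threshold(params, i)
    if math.isinf(mu0):
        return 1.0
    return mu0 / (mu0 + mu)


def classify_regime(
    mu: float, mu0: float, ratio_band: float = DEFAULT_REGIME_BAND
) -> str:
    """Label a ceRNA as ``free``, ``susceptible`` or ``repressed``.

    ``free`` when ``mu/mu0 < 1/ratio_band``, ``repressed`` when
    ``mu/mu0 > ratio_band``, ``susceptible`` in between.
    """
    if mu < 0:
        raise ValueError("mu must be >= 0")
    if not mu0 > 0:
        raise ValueError("mu0 must be > 0")
    if math.isinf(mu0):
        return "free"
    ratio = mu / mu0
    if ratio < 1.0 / ratio_band:
        return "free"
    if ratio > ratio_band:
        return "repressed"
    return "susceptible"


def _mu_balance(mu: float, params: KineticParameters, occ: Occupancies) -> float:
    """Net miRNA drain minus supply at free-miRNA level ``mu``.

    Strictly increasing in ``mu``: the unique zero is the stationary level.
    """
    total = params.delta * mu - params.beta * occ.nmu
    for i, n in ((1, occ.n1), (2, occ.n2)):
        kp = params.kplus(i)
        if kp == 0.0:
            continue
        D = params.sigma(i) + params.kminus(i) + params.kappa(i)
        # m_i given mu, with complexes eliminated
        m = params.b(i) * n / (params.d(i) + kp * mu * (params.sigma(i) + params.kappa(i)) / D)
        total += kp * mu * m * params.sigma(i) / D
    return total


def steady_state(
    params: KineticParameters,
    occ: Occupancies,
    ratio_band: float = DEFAULT_REGIME_BAND,
    rtol: float = 1e-12,
    max_residual: float = 1e-8,
) -> SteadyState:
    """Solve the stationary balance equations of the full network.

    The solve is exact up to root-finder tolerance: the five coupled balance
    equations are reduced to a single monotone equation for the free-miRNA
    level, bracketed on ``[0, beta*nmu/delta]`` and solved by Brent's
    method.  Raises ``RuntimeError`` if the verified residual of the full
    system exceeds ``max_residual`` (relative to the synthesis fluxes).
    """
    supply = params.beta * occ.nmu
    if supply == 0.0:
        mu = 0.0
    else:
        upper = supply / params.delta
        g0 = _mu_balance(0.0, params, occ)
        if g0 >= 0.0:
            mu = 0.0
        else:
            mu = brentq(
                _mu_balance, 0.0, upper, args=(params, occ),
                xtol=1e-14, rtol=rtol, maxiter=200,
            )

    levels = {}
    for i, n in ((1, occ.n1), (2, occ.n2)):
        kp = params.kplus(i)
        if kp == 0.0:
            m = params.b(i) * n / params.d(i)
            c = 0.0
        else:
            D = params.sigma(i) + params.kminus(i) + params.kappa(i)
            m = params.b(i) * n / (
                params.d(i) + kp * mu * (params.sigma(i) + params.kappa(i)) / D
            )
            c = kp * mu * m / D
        levels[i] = (m, c)

    mu0_1 = mirna_threshold(params, 1)
    mu0_2 = mirna_threshold(params, 2)
    ss = SteadyState(
        m1=levels[1][0], m2=levels[2][0], mu=mu,
        c1=levels[1][1], c2=levels[2][1],
        mu0_1=mu0_1, mu0_2=mu0_2,
        regime1=classify_regime(mu, mu0_1, ratio_band) if not math.isinf(mu0_1) else "free",
        regime2=classify_regime(mu, mu0_2, ratio_band) if not math.isinf(mu0_2) else "free",
        occ=occ,
        residual=0.0,
    )
    res = steady_state_residuals(params, ss)
    scale = max(params.b1 * occ.n1, params.b2 * occ.n2, supply, 1.0)
    rel = float(np.max(np.abs(res))) / scale
    if rel > max_residual:
        raise RuntimeError(
            f"steady-state solve did not converge: relative residual {rel:.3e} "
            f"(residual vector {res})"
        )
    object.__setattr__(ss, "residual", rel)
    return ss


def steady_state_residuals(params: KineticParameters, ss: SteadyState) -> np.ndarray:
    """Right-hand sides of the five balance equations at a candidate state."""
    from .lna import drift

    return drift(params, ss.occ, ss.as_vector())


def mu_threshold_crossing(
    params: KineticParameters,
    occ_base: Occupancies,
    i: int,
    f_lo: float = 0.5,
    f_hi: float = 60.0,
) -> float:
    """TF1 copy number at which the free-miRNA level crosses ``mu0_i``.

    As the competitor's activator f1 rises, titration pulls the stationary
    free-miRNA level down; where it crosses the soft threshold of ceRNA_i,
    that ceRNA transits from the repressed toward the free regime through
    maximal susceptibility.  Solved by bracketing on ``[f_lo, f_hi]``;
    raises ``ValueError`` when the level never reaches the threshold there
    (titration may saturate above ``mu0_i``, in which case the ceRNA is
    susceptible but never fully crosses over).
    """
    mu0 = mirna_threshold(params, i)
    if math.isinf(mu0):
        raise ValueError(f"ceRNA {i} is decoupled (k+ = 0); no threshold to cross")

    def gap(f1: float) -> float:
        occ = occ_base.replace(n1=tf_occupancy(f1, params))
        return steady_state(params, occ).mu - mu0

    g_lo, g_hi = gap(f_lo), gap(f_hi)
    if g_lo * g_hi > 0:
        raise ValueError(
            f"free-miRNA level does not cross mu0_{i} = {mu0:.4g} on "
            f"[{f_lo}, {f_hi}] (endpoint gaps {g_lo:.4g}, {g_hi:.4g})"
        )
    return brentq(gap, f_lo, f_hi, xtol=1e-10, rtol=1e-12)


def rescale_omega(params: KineticParameters, omega: float) -> KineticParameters:
    """Jointly rescale miRNA turnover and binding: ``delta -> omega*delta``,
    ``k_i+ -> omega*k_i+``.

    Shrinking ``omega`` inflates the free-miRNA pool while weakening each
    individual miRNA-ceRNA interaction; the mean target level is preserved
    whenever dissociation and complex-decay back-fluxes are negligible
    against the synthesis fluxes, so the transform tunes titration noise at
    (nearly) fixed response curve.
    """
    if not omega > 0:
        raise ValueError(f"omega must be > 0, got {omega!r}")
    return params.replace(
        delta=omega * params.delta,
        kplus1=omega * params.kplus1,
        kplus2=omega * params.kplus2,
    )
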