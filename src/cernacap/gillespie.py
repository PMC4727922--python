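"""Exact stochastic simulation (Gillespie / SSA) of the ceRNA network.

The network is represented as 14 elementary mass-action reactions over the
species vector (m1, m2, mu, c1, c2): three syntheses at the occupancy-scaled
rates ``b1*n1``, ``b2*n2``, ``beta*nmu``, three spontaneous degradations,
two complex associations, two dissociations, and — for each complex — a
stoichiometric decay (miRNA lost with the target) and a catalytic decay
(miRNA recycled).  Promoter occupancies are frozen at their fast Hill
equilibrium, so the synthesis propensities are constants and TF-binding
noise does not enter the simulation.

The inner direct-method loop is JIT-compiled; stationary moments are
accumulated on the fly (time-weighted first and second moments of the full
state vector) so that long runs need no trajectory storage.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numba import njit

from .parameters import KineticParameters, Occupancies

__all__ = [
    "SPECIES",
    "ReactionSystem",
    "Trajectory",
    "StationaryStats",
    "build_reaction_system",
    "simulate",
    "stationary_stats",
    "stationary_moments",
    "moment_scan",
    "default_burn_in",
    "default_window",
]

SPECIES = ("m1", "m2", "mu", "c1", "c2")

REACTION_LABELS = (
    "synthesis_m1", "synthesis_m2", "synthesis_mu",
    "degradation_m1", "degradation_m2", "degradation_mu",
    "association_1", "association_2",
    "dissociation_1", "dissociation_2",
    "stoichiometric_decay_c1", "stoichiometric_decay_c2",
    "catalytic_decay_c1", "catalytic_decay_c2",
)

# reactant orders (0/1 per species) and state changes, one row per reaction,
# species-ordered (m1, m2, mu, c1, c2)
_ORDERS = np.array(
    [
        [0, 0, 0, 0, 0],
        [0, 0, 0, 0, 0],
        [0, 0, 0, 0, 0],
        [1, 0, 0, 0, 0],
        [0, 1, 0, 0, 0],
        [0, 0, 1, 0, 0],
        [1, 0, 1, 0, 0],
        [0, 1, 1, 0, 0],
        [0, 0, 0, 1, 0],
        [0, 0, 0, 0, 1],
        [0, 0, 0, 1, 0],
        [0, 0, 0, 0, 1],
        [0, 0, 0, 1, 0],
        [0, 0, 0, 0, 1],
    ],
    dtype=np.int64,
)

_STOICH = np.array(
    [
        [+1, 0, 0, 0, 0],
        [0, +1, 0, 0, 0],
        [0, 0, +1, 0, 0],
        [-1, 0, 0, 0, 0],
        [0, -1, 0, 0, 0],
        [0, 0, -1, 0, 0],
        [-1, 0, -1, +1, 0],
        [0, -1, -1, 0, +1],
        [+1, 0, +1, -1, 0],
        [0, +1, +1, 0, -1],
        [0, 0, 0, -1, 0],
        [0, 0, 0, 0, -1],
        [0, 0, +1, -1, 0],
        [0, 0, +1, 0, -1],
    ],
    dtype=np.int64,
)


@dataclass(frozen=True)
class ReactionSystem:
    """Mass-action reaction network: rate constants, reactant orders and
    stoichiometry, one row per reaction in the order of ``REACTION_LABELS``."""

    rates: np.ndarray
    orders: np.ndarray = field(default_factory=lambda: _ORDERS.copy())
    stoich: np.ndarray = field(default_factory=lambda: _STOICH.copy())
    labels: tuple[str, ...] = REACTION_LABELS

    def propensities(self, state: np.ndarray) -> np.ndarray:
        """Propensity of each reaction at an integer state vector."""
        x = np.asarray(state, dtype=float)
        a = self.rates.copy()
        for r in range(len(a)):
            for s in range(len(SPECIES)):
                if self.orders[r, s]:
                    a[r] *= x[s]
        return a


def build_reaction_system(
    params: KineticParameters, occ: Occupancies
) -> ReactionSystem:
    """Assemble the 14-reaction network at frozen promoter occupancies."""
    rates = np.array(
        [
            params.b1 * occ.n1,
            params.b2 * occ.n2,
            params.beta * occ.nmu,
            params.d1,
            params.d2,
            params.delta,
            params.kplus1,
            params.kplus2,
            params.kminus1,
            params.kminus2,
            params.sigma1,
            params.sigma2,
            params.kappa1,
            params.kappa2,
        ],
        dtype=np.float64,
    )
    return ReactionSystem(rates=rates)


@dataclass(frozen=True)
class Trajectory:
    """SSA sample path: event times and piecewise-constant integer states."""

    times: np.ndarray
    states: np.ndarray  # (n_events+1, 5) integer states, states[k] holds on [times[k], times[k+1])
    t_end: float
    seed: int

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.states, columns=list(SPECIES))
        df.insert(0, "time", self.times)
        return df

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


@dataclass(frozen=True)
class StationaryStats:
    """Time-averaged stationary statistics of a sample path."""

    mean: np.ndarray
    variance: np.ndarray
    fano: np.ndarray  # NaN where the mean vanishes
    n_events: int
    burn_in: float
    duration: float

    def species(self, name: str) -> tuple[float, float, float]:
        i = SPECIES.index(name)
        return float(self.mean[i]), float(self.variance[i]), float(self.fano[i])


@njit(cache=True)
def _ssa_trajectory(rates, orders, stoich, x0, t_end, seed, max_events):
    np.random.seed(seed)
    n_r = rates.shape[0]
    n_s = x0.shape[0]
    x = x0.copy()
    times = np.empty(max_events + 1, dtype=np.float64)
    states = np.empty((max_events + 1, n_s), dtype=np.int64)
    times[0] = 0.0
    states[0] = x
    k = 0
    t = 0.0
    a = np.empty(n_r, dtype=np.float64)
    while t < t_end and k < max_events:
        atot = 0.0
        for r in range(n_r):
            p = rates[r]
            for s in range(n_s):
                if orders[r, s] == 1:
                    p *= x[s]
            a[r] = p
            atot += p
        if atot <= 0.0:
            break
        dt = -math.log(np.random.random()) / atot
        t_next = t + dt
        if t_next > t_end:
            break
        u = np.random.random() * atot
        acc = 0.0
        r_sel = n_r - 1
        for r in range(n_r):
            acc += a[r]
            if u < acc:
                r_sel = r
                break
        for s in range(n_s):
            x[s] += stoich[r_sel, s]
        k += 1
        t = t_next
        times[k] = t
        states[k] = x
    return times[: k + 1], states[: k + 1], k


@njit(cache=True)
def _ssa_moments(rates, orders, stoich, x0, burn_in, t_end, seed):
    np.random.seed(seed)
    n_r = rates.shape[0]
    n_s = x0.shape[0]
    x = x0.copy()
    s1 = np.zeros(n_s, dtype=np.float64)
    s2 = np.zeros((n_s, n_s), dtype=np.float64)
    w_sum = 0.0
    n_events = 0
    t = 0.0
    a = np.empty(n_r, dtype=np.float64)
    while t < t_end:
        atot = 0.0
        for r in range(n_r):
            p = rates[r]
            for s in range(n_s):
                if orders[r, s] == 1:
                    p *= x[s]
            a[r] = p
            atot += p
        if atot <= 0.0:
            t_next = t_end
        else:
            t_next = t + (-math.log(np.random.random()) / atot)
        lo = t if t > burn_in else burn_in
        hi = t_next if t_next < t_end else t_end
        if hi > lo:
            w = hi - lo
            w_sum += w
            for i in range(n_s):
                s1[i] += w * x[i]
                for j in range(n_s):
                    s2[i, j] += w * x[i] * x[j]
        if t_next >= t_end or atot <= 0.0:
            break
        u = np.random.random() * atot
        acc = 0.0
        r_sel = n_r - 1
        for r in range(n_r):
            acc += a[r]
            if u < acc:
                r_sel = r
                break
        for s in range(n_s):
            x[s] += stoich[r_sel, s]
        n_events += 1
        t = t_next
    return s1, s2, w_sum, n_events


def default_burn_in(params: KineticParameters) -> float:
    """Ten times the slowest spontaneous relaxation time (min)."""
    return 10.0 / min(params.d1, params.d2, params.delta)


def default_window(params: KineticParameters) -> float:
    """Default sampling window: 100x the slowest relaxation time (min)."""
    return 100.0 / min(params.d1, params.d2, params.delta)


def _initial_state(
    params: KineticParameters, occ: Occupancies, initial_state=None
) -> np.ndarray:
    if initial_state is not None:
        x0 = np.asarray(initial_state, dtype=np.int64)
        if x0.shape != (5,) or np.any(x0 < 0):
            raise ValueError("initial_state must be 5 non-negative integers")
        return x0
    from .core import steady_state

    ss = steady_state(params, occ)
    return np.maximum(np.rint(ss.as_vector()), 0).astype(np.int64)


def simulate(
    system: ReactionSystem,
    t_end: float,
    seed: int,
    initial_state,
    max_events: int = 5_000_000,
) -> Trajectory:
    """Run the direct-method SSA until ``t_end`` and return the sample path.

    Bit-identical for identical seeds.  Raises ``RuntimeError`` if the event
    buffer fills before ``t_end`` (increase ``max_events`` or use
    :func:`stationary_moments`, which stores nothing).
    """
    if not t_end > 0:
        raise ValueError("t_end must be > 0")
    x0 = np.asarray(initial_state, dtype=np.int64)
    if x0.shape != (5,) or np.any(x0 < 0):
        raise ValueError("initial_state must be 5 non-negative integers")
    times, states, k = _ssa_trajectory(
        system.rates, system.orders, system.stoich, x0,
        float(t_end), int(seed), int(max_events),
    )
    if k >= max_events and times[-1] < t_end:
        raise RuntimeError(
            f"event buffer exhausted at t={times[-1]:.1f} < t_end={t_end}; "
            "raise max_events"
        )
    return Trajectory(times=times, states=states, t_end=float(t_end), seed=int(seed))


def stationary_stats(traj: Trajectory, burn_in: float) -> StationaryStats:
    """Time-weighted stationary mean, variance and Fano factor of a path.

    Each recorded state is weighted by the length of the interval on which
    it held, restricted to ``[burn_in, t_end]``.
    """
    if burn_in >= traj.t_end:
        raise ValueError("burn_in must be smaller than the trajectory duration")
    edges = np.append(traj.times, traj.t_end)
    lo = np.maximum(edges[:-1], burn_in)
    hi = np.minimum(edges[1:], traj.t_end)
    w = np.maximum(hi - lo, 0.0)
    w_sum = w.sum()
    x = traj.states.astype(float)
    mean = (w[:, None] * x).sum(axis=0) / w_sum
    var = (w[:, None] * (x - mean) ** 2).sum(axis=0) / w_sum
    with np.errstate(divide="ignore", invalid="ignore"):
        fano = np.where(mean > 0, var / mean, np.nan)
    n_events = int(np.sum((traj.times >= burn_in) & (traj.times <= traj.t_end)))
    return StationaryStats(
        mean=mean, variance=var, fano=fano,
        n_events=n_events, burn_in=burn_in, duration=float(w_sum),
    )


def _child_seeds(seed: int, n: int) -> np.ndarray:
    ss = np.random.SeedSequence(seed)
    return (ss.generate_state(n, dtype=np.uint32) & 0x7FFFFFFF).astype(np.int64)


def stationary_moments(
    params: KineticParameters,
    occ: Occupancies,
    seed: int,
    replicates: int = 4,
    burn_in: float | None = None,
    window: float | None = None,
    initial_state=None,
):
    """Pooled stationary mean vector and covariance matrix from SSA replicates.

    Runs ``replicates`` independent chains (seeds derived from the master
    seed), accumulates time-weighted first/second moments in each, and pools
    them.  Returns ``(mean, cov, se_mean, se_var, n_events)`` where the
    standard errors are across-replicate standard errors of the per-species
    mean and variance.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    if burn_in is None:
        burn_in = default_burn_in(params)
    if window is None:
        window = default_window(params)
    system = build_reaction_system(params, occ)
    x0 = _initial_state(params, occ, initial_state)
    seeds = _child_seeds(seed, replicates)
    means = np.empty((replicates, 5))
    variances = np.empty((replicates, 5))
    covs = np.empty((replicates, 5, 5))
    n_events = 0
    for r in range(replicates):
        s1, s2, w, k = _ssa_moments(
            system.rates, system.orders, system.stoich, x0,
            float(burn_in), float(burn_in + window), int(seeds[r]),
        )
        m = s1 / w
        c = s2 / w - np.outer(m, m)
        means[r] = m
        variances[r] = np.diag(c)
        covs[r] = c
        n_events += k
    mean = means.mean(axis=0)
    cov = covs.mean(axis=0)
    if replicates > 1:
        se_mean = means.std(axis=0, ddof=1) / math.sqrt(replicates)
        se_var = variances.std(axis=0, ddof=1) / math.sqrt(replicates)
    else:
        se_mean = np.full(5, np.nan)
        se_var = np.full(5, np.nan)
    return mean, cov, se_mean, se_var, n_events


def moment_scan(
    params: KineticParameters,
    channel: str,
    f_grid: np.ndarray,
    replicates: int,
    seed: int,
    occ_base: Occupancies,
    burn_in: float | None = None,
    window: float | None = None,
) -> pd.DataFrame:
    """Stationary statistics of ``m2`` and ``mu`` (and ``m1``) along an input grid.

    ``channel`` selects which TF copy number is swept: ``"miRNA"`` varies
    ``f1`` (the competitor's activator), ``"TF"`` varies ``f2`` (the
    target's own activator); the remaining occupancies are held at
    ``occ_base``.  Per-point statistics are pooled over ``replicates``
    independent chains with seeds derived from the master seed and the grid
    index.
    """
    from .core import tf_occupancy

    f_grid = np.asarray(f_grid, dtype=float)
    if f_grid.size == 0:
        raise ValueError("f_grid must be non-empty")
    if channel not in {"miRNA", "TF"}:
        raise ValueError("channel must be 'miRNA' or 'TF'")
    point_seeds = _child_seeds(seed, f_grid.size)
    rows = []
    for g, f in enumerate(f_grid):
        n = tf_occupancy(f, params)
        occ = occ_base.replace(n1=n) if channel == "miRNA" else occ_base.replace(n2=n)
        mean, cov, se_mean, se_var, n_events = stationary_moments(
            params, occ, int(point_seeds[g]), replicates=replicates,
            burn_in=burn_in, window=window,
        )
        row = {"f": f, "channel": channel, "n_events": n_events, "seed": int(point_seeds[g])}
        for name in ("m1", "m2", "mu"):
            i = SPECIES.index(name)
            row[f"mean_{name}"] = mean[i]
            row[f"var_{name}"] = cov[i, i]
            row[f"fano_{name}"] = cov[i, i] / mean[i] if mean[i] > 0 else np.nan
            row[f"se_mean_{name}"] = se_mean[i]
            row[f"se_var_{name}"] = se_var[i]
        rows.append(row)
    return pd.DataFrame(rows)
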