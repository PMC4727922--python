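"""Packaged kinetic-parameter presets for the published study conditions.

Each preset bundles the kinetic constants, the fixed promoter occupancies
and the occupancy range of the swept input for one figure-level scenario.
Where a scenario distinguishes the post-transcriptional channel (input
``f1``) from the transcriptional one (input ``f2``), both variants are
packaged.  All presets share d1 = d2 = delta = 0.1 /min, h = 5 and
kout/kin = 63300 molecules^5, so half promoter saturation sits at
f = 63300^(1/5) ~ 9.1 molecules and n(30) ~ 0.997.

The occupancy sweep bounds drive the input grids; the nominal TF ceiling
f_max = 30 of the source tables is retained as metadata.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .core import occupancy_inverse, rescale_omega, steady_state
from .parameters import KineticParameters, Occupancies

__all__ = ["Preset", "preset", "available_presets", "input_grid",
           "matched_tf_occupancy_range"]

#: highest occupancy an input grid is allowed to reach; keeps the Hill
#: inversion finite when a matched range would demand full saturation
OCC_CEILING = 0.9995


@dataclass(frozen=True)
class Preset:
    """One study condition: parameters, operating occupancies, input range."""

    name: str
    channel: str  # "miRNA" or "TF"
    params: KineticParameters
    occ: Occupancies  # occupancies of the non-swept TFs (swept one set to 0 here)
    input_range: tuple[float, float]  # occupancy range of the swept input
    f_max: float = 30.0
    sweep_ranges: dict | None = None  # figure-specific parameter sweep bounds

    def with_params(self, **changes) -> "Preset":
        return replace(self, params=self.params.replace(**changes))


def _base(**over) -> KineticParameters:
    defaults = dict(
        b1=100.0, b2=100.0, beta=100.0,
        d1=0.1, d2=0.1, delta=0.1,
        kplus1=math.e ** 2, kplus2=math.e ** -3,
        kminus1=0.001, kminus2=0.001,
        kappa1=0.002, kappa2=0.002,
        sigma1=1.0, sigma2=1.0,
        kout_over_kin=63300.0, h=5,
    )
    defaults.update(over)
    return KineticParameters(**defaults)


def _fig2() -> dict[str, Preset]:
    p = _base(
        b1=120.0, b2=100.0, beta=100.0,
        kplus1=0.002, kplus2=0.001,
        kminus1=0.0005, kminus2=0.001,
        kappa1=0.0003, kappa2=0.0004,
        sigma1=0.5, sigma2=1.0,
    )
    occ = Occupancies(n1=0.0, n2=0.71, nmu=0.9)
    return {"miRNA": Preset("fig2", "miRNA", p, occ, (0.0, 0.99))}


def _fig5() -> dict[str, Preset]:
    p = _base(kplus1=0.01, kplus2=0.01)  # grid centre; swept over the ranges below
    sweep = {"kplus1": (math.e ** -10, math.e ** 2),
             "kplus2": (math.e ** -10, math.e ** 2)}
    return {
        "miRNA": Preset("fig5", "miRNA", p,
                        Occupancies(n1=0.0, n2=0.99, nmu=0.99), (0.0, 0.99),
                        sweep_ranges=sweep),
        "TF": Preset("fig5", "TF", p,
                     Occupancies(n1=0.99, n2=0.0, nmu=0.99), (0.0, 0.99),
                     sweep_ranges=sweep),
    }


def _fig6() -> dict[str, Preset]:
    p = _base()
    sweep = {"kappa1": (math.e ** -5, math.e ** 5),
             "kappa2": (math.e ** -5, math.e ** 5)}
    return {
        "miRNA": Preset("fig6", "miRNA", p,
                        Occupancies(n1=0.0, n2=0.21, nmu=0.99), (0.0, 0.99),
                        sweep_ranges=sweep),
        "TF": Preset("fig6", "TF", p,
                     Occupancies(n1=0.21, n2=0.0, nmu=0.99), (0.0, 0.99),
                     sweep_ranges=sweep),
    }


def _fig7(variant: str) -> dict[str, Preset]:
    if variant == "A":
        p = _base()
        nmu = 0.99
    else:
        p = _base(kappa1=math.e ** -8, kappa2=math.e ** 5)
        nmu = 0.5
    sweep = {"n1": (0.1, 0.9), "n2": (0.1, 0.9)}
    name = f"fig7{variant}"
    return {
        "miRNA": Preset(name, "miRNA", p, Occupancies(0.0, 0.0, nmu), (0.0, 0.9),
                        sweep_ranges=sweep),
        "TF": Preset(name, "TF", p, Occupancies(0.0, 0.0, nmu), (0.0, 0.9),
                     sweep_ranges=sweep),
    }


def _fig8() -> dict[str, Preset]:
    p_mirna = _base(b1=100.0, b2=110.2, beta=100.0,
                    kplus1=math.e ** 3, kplus2=1.0)
    p_tf = _base(b1=0.0, b2=50.0, beta=0.0, kplus1=0.0, kplus2=0.0)
    return {
        "miRNA": Preset("fig8", "miRNA", p_mirna,
                        Occupancies(n1=0.0, n2=0.99, nmu=0.99), (0.0, 0.99),
                        sweep_ranges={"b1": (1.0, 147.0)}),
        "TF": Preset("fig8", "TF", p_tf,
                     Occupancies(n1=0.0, n2=0.0, nmu=0.0), (0.0, 0.99),
                     sweep_ranges={"b2": (10.0, 98.0)}),
    }


def _fig9(omega: float) -> dict[str, Preset]:
    p_mirna = rescale_omega(
        _base(b1=90.0, b2=22.3, beta=80.0,
              kplus1=math.e ** 3.39, kplus2=math.e ** -5.77),
        omega,
    )
    p_tf = _base(b1=0.0, b2=22.0, beta=0.0, kplus1=0.0, kplus2=0.0)
    return {
        "miRNA": Preset("fig9", "miRNA", p_mirna,
                        Occupancies(n1=0.0, n2=0.99, nmu=0.99), (0.0, 0.99)),
        # the TF-channel input range is reconstructed at run time so that the
        # output range matches the miRNA channel's; see
        # :func:`matched_tf_occupancy_range`
        "TF": Preset("fig9", "TF", p_tf,
                     Occupancies(n1=0.0, n2=0.0, nmu=0.0), (0.05, OCC_CEILING)),
    }


_BUILDERS = {
    "fig2": lambda omega: _fig2(),
    "fig5": lambda omega: _fig5(),
    "fig6": lambda omega: _fig6(),
    "fig7A": lambda omega: _fig7("A"),
    "fig7B": lambda omega: _fig7("B"),
    "fig8": lambda omega: _fig8(),
    "fig9": _fig9,
}


def available_presets() -> tuple[str, ...]:
    return tuple(_BUILDERS)


def preset(name: str, channel: str | None = None, omega: float = 1.0) -> Preset:
    """Look up a packaged study condition.

    ``channel`` selects the miRNA- or TF-channel variant where the scenario
    distinguishes them (defaults to ``"miRNA"``); ``omega`` applies the
    joint miRNA-turnover/binding rescaling (meaningful for ``fig9``).
    """
    if name not in _BUILDERS:
        raise KeyError(
            f"unknown preset {name!r}; available: {', '.join(available_presets())}"
        )
    variants = _BUILDERS[name](omega)
    if channel is None:
        channel = "miRNA"
    if channel not in variants:
        raise KeyError(f"preset {name!r} has no {channel!r} variant")
    return variants[channel]


def input_grid(
    params: KineticParameters,
    occ_range: tuple[float, float],
    n_points: int = 40,
    floor_occupancy: float = 1e-3,
) -> np.ndarray:
    """TF copy-number grid spanning an occupancy range.

    Log-spaced in ``f`` (the response curves live on a log input axis) with
    the ``f = 0`` endpoint prepended when the range starts at zero
    occupancy; ``floor_occupancy`` sets the first positive grid point in
    that case.
    """
    lo, hi = occ_range
    if not (0.0 <= lo < hi <= 1.0):
        raise ValueError("need 0 <= lo < hi <= 1")
    f_hi = occupancy_inverse(min(hi, OCC_CEILING), params)
    if lo <= 0.0:
        f_lo = occupancy_inverse(floor_occupancy, params)
        return np.concatenate([[0.0], np.geomspace(f_lo, f_hi, n_points - 1)])
    return np.geomspace(occupancy_inverse(lo, params), f_hi, n_points)


def matched_tf_occupancy_range(
    mirna_preset: Preset, tf_params: KineticParameters, n_grid: int = 33
) -> tuple[float, float]:
    """Occupancy range of a decoupled TF channel whose output range matches
    the miRNA channel's.

    The miRNA channel's minimal and maximal target levels are computed from
    the deterministic steady state at the ends of its input range; the TF
    channel (a pure birth-death response ``m2 = b2 n2 / d2``) is then given
    the occupancy window mapping onto the same ``[m2_min, m2_max]``,
    clipped to the representable ceiling when ``b2/d2`` cannot quite reach
    ``m2_max``.
    """
    grid = input_grid(mirna_preset.params, mirna_preset.input_range, n_grid)
    m2 = []
    for f in (grid[0], grid[-1]):
        from .core import tf_occupancy

        occ = mirna_preset.occ.replace(n1=tf_occupancy(f, mirna_preset.params))
        m2.append(steady_state(mirna_preset.params, occ).m2)
    m2_lo, m2_hi = min(m2), max(m2)
    scale = tf_params.d2 / tf_params.b2
    lo = min(max(m2_lo * scale, 1e-6), OCC_CEILING / 2)
    hi = min(m2_hi * scale, OCC_CEILING)
    return (lo, hi)
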