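"""Kinetic parameters and transcription-factor inputs of the ceRNA network.

The network couples two ceRNA species (copy numbers ``m1``, ``m2``) and one
miRNA species (``mu``) through reversible miRNA-ceRNA complexes (``c1``,
``c2``).  Each RNA species is transcribed under the control of its own
transcription factor; promoter occupancy follows a cooperative Hill
equilibrium.  Complexes decay either *stoichiometrically* (rate ``sigma_i``,
the bound miRNA is lost together with the target) or *catalytically* (rate
``kappa_i``, the miRNA is recycled back into the free pool).

All rates are expressed per minute, bimolecular rates per molecule per
minute, and all abundances are absolute molecule counts.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Any

import yaml

__all__ = [
    "KineticParameters",
    "Occupancies",
    "load_parameters",
    "save_parameters",
]


@dataclass(frozen=True)
class KineticParameters:
    """Rate constants and Hill parameters of the 3-TF / 2-ceRNA / 1-miRNA network.

    Attributes
    ----------
    b1, b2 : float
        Maximal transcription rates of ceRNA1 / ceRNA2 (molecules/min); the
        effective synthesis rate is ``b_i * n_i`` with ``n_i`` the promoter
        occupancy.
    beta : float
        Maximal miRNA transcription rate (molecules/min).
    d1, d2, delta : float
        Spontaneous degradation rates of ceRNA1, ceRNA2 and the free miRNA
        (1/min).  Must be strictly positive.
    kplus1, kplus2 : float
        miRNA-ceRNA complex association rates (1/(molecule min)).
    kminus1, kminus2 : float
        Complex dissociation rates (1/min).
    sigma1, sigma2 : float
        Stoichiometric complex-decay rates (1/min); no miRNA recycling.
    kappa1, kappa2 : float
        Catalytic complex-decay rates (1/min); the miRNA is recycled.
    kout_over_kin : float
        Ratio of TF-DNA unbinding to binding rates, in molecules**h.  Only
        the ratio enters the equilibrium occupancy; a nominal ``kin = 1`` is
        implied throughout.
    h : int
        Hill cooperativity (number of TF molecules binding the promoter).
    """

    b1: float
    b2: float
    beta: float
    d1: float
    d2: float
    delta: float
    kplus1: float
    kplus2: float
    kminus1: float
    kminus2: float
    kappa1: float
    kappa2: float
    sigma1: float
    sigma2: float
    kout_over_kin: float = 63300.0
    h: int = 5

    def __post_init__(self) -> None:
        for name in (
            "b1", "b2", "beta", "d1", "d2", "delta",
            "kplus1", "kplus2", "kminus1", "kminus2",
            "kappa1", "kappa2", "sigma1", "sigma2",
        ):
            v = getattr(self, name)
            if not (v >= 0.0):
                raise ValueError(f"rate {name} must be >= 0, got {v!r}")
        for name in ("d1", "d2", "delta"):
            if getattr(self, name) <= 0.0:
                raise ValueError(f"degradation rate {name} must be > 0")
        if self.kout_over_kin <= 0.0:
            raise ValueError("kout_over_kin must be > 0")
        if self.h < 1 or int(self.h) != self.h:
            raise ValueError("Hill coefficient h must be an integer >= 1")

    def replace(self, **changes: Any) -> "KineticParameters":
        """Return a copy with the given fields replaced."""
        return dataclasses.replace(self, **changes)

    # per-ceRNA views used throughout the deterministic layer
    def kplus(self, i: int) -> float:
        return (self.kplus1, self.kplus2)[i - 1]

    def kminus(self, i: int) -> float:
        return (self.kminus1, self.kminus2)[i - 1]

    def kappa(self, i: int) -> float:
        return (self.kappa1, self.kappa2)[i - 1]

    def sigma(self, i: int) -> float:
        return (self.sigma1, self.sigma2)[i - 1]

    def b(self, i: int) -> float:
        return (self.b1, self.b2)[i - 1]

    def d(self, i: int) -> float:
        return (self.d1, self.d2)[i - 1]

    def to_dict(self) -> dict[str, float]:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "KineticParameters":
        return cls(**d)


@dataclass(frozen=True)
class Occupancies:
    """Equilibrium fractional occupancies of the three TF binding sites.

    The promoter on/off dynamics is assumed fast compared with
    transcription, so each occupancy sits at its Hill equilibrium
    ``n = f^h / (f^h + kout/kin)`` and enters the kinetics only through the
    effective synthesis rates ``b_i * n_i`` and ``beta * n_mu``.
    """

    n1: float
    n2: float
    nmu: float

    def __post_init__(self) -> None:
        for name in ("n1", "n2", "nmu"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"occupancy {name} must lie in [0, 1], got {v!r}")

    @classmethod
    def from_tf_counts(
        cls, f1: float, f2: float, fmu: float, params: KineticParameters
    ) -> "Occupancies":
        from .core import tf_occupancy

        return cls(
            n1=tf_occupancy(f1, params),
            n2=tf_occupancy(f2, params),
            nmu=tf_occupancy(fmu, params),
        )

    def replace(self, **changes: Any) -> "Occupancies":
        return dataclasses.replace(self, **changes)


def save_parameters(params: KineticParameters, path: str | Path) -> None:
    """Write a parameter set to a JSON or YAML file (chosen by suffix)."""
    path = Path(path)
    d = params.to_dict()
    if path.suffix in {".yaml", ".yml"}:
        path.write_text(yaml.safe_dump(d, sort_keys=False))
    else:
        path.write_text(json.dumps(d, indent=2) + "\n")


def load_parameters(path: str | Path) -> KineticParameters:
    """Read a parameter set from a JSON or YAML file."""
    path = Path(path)
    text = path.read_text()
    if path.suffix in {".yaml", ".yml"}:
        d = yaml.safe_load(text)
    else:
        d = json.loads(text)
    return KineticParameters.from_dict(d)
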