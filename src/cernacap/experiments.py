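"""Configuration-driven parameter sweeps over the packaged study conditions.

Each sweep evaluates the two regulatory channels (post-transcriptional,
input f1; transcriptional, input f2) on a grid of kinetic parameters and
returns a long-format table with one row per grid point: capacities,
capacity difference, amplitudes of variation, the worst-case Fano factor of
the target, regime labels and the seed used.  Grid points are independent;
a non-convergent point is recorded with a ``status`` flag rather than
aborting the sweep.  Default grids are reduced (desk-scale) versions of the
published scans; the swept ranges themselves follow the packaged presets.
"""

from __future__ import annotations

import dataclasses
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .capacity import aov, capacity, optimal_input, poisson_limit_capacity, response_curve
from .core import steady_state, tf_occupancy
from .gillespie import SPECIES
from .lna import lna_covariance
from .parameters import Occupancies
from .presets import Preset, input_grid, matched_tf_occupancy_range, preset

__all__ = [
    "SweepConfig",
    "fano_peak",
    "channel_capacity",
    "binding_rate_sweep",
    "recycling_sweep",
    "occupancy_sweep",
    "aov_capacity_curve",
    "omega_sweep",
    "run_sweep",
    "write_manifest",
]

_M2 = SPECIES.index("m2")


@dataclass(frozen=True)
class SweepConfig:
    """Sweep specification: which scan, at what resolution, how estimated."""

    sweep: str  # binding | recycling | occupancy | aov | omega
    preset: str = ""
    estimator: str = "lna"
    replicates: int = 4
    seed: int = 0
    grid_points: int = 5  # points per swept-parameter axis
    input_points: int = 40  # points of the input (TF copy-number) grid
    omega_grid: tuple[float, ...] = ()
    out: str | None = None

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SweepConfig":
        d = dict(d)
        if "omega_grid" in d and d["omega_grid"] is not None:
            d["omega_grid"] = tuple(d["omega_grid"])
        return cls(**d)

    @classmethod
    def from_file(cls, path: str | Path) -> "SweepConfig":
        path = Path(path)
        text = path.read_text()
        if path.suffix in {".yaml", ".yml"}:
            return cls.from_dict(yaml.safe_load(text))
        return cls.from_dict(json.loads(text))


def channel_capacity(
    ps: Preset,
    estimator: str = "lna",
    seed: int = 0,
    input_points: int = 40,
    replicates: int = 4,
    input_range: tuple[float, float] | None = None,
    occ: Occupancies | None = None,
    with_fano: bool = False,
) -> dict:
    """Capacity, AOV and diagnostics of a single channel at one parameter point."""
    grid = input_grid(ps.params, input_range or ps.input_range, input_points)
    curve = response_curve(
        ps.params, ps.channel, grid, estimator, seed=seed,
        occ_base=occ or ps.occ, replicates=replicates,
    )
    opt = optimal_input(curve)
    out = {
        "I": capacity(opt),
        "Z": opt.Z,
        "aov": aov(curve),
        "m2_min": float(curve.mean[0]),
        "m2_max": float(curve.mean[-1]),
        "curve": curve,
    }
    if with_fano:
        # worst-case (largest) target Fano factor along the input grid, LNA
        ff = []
        for f in grid:
            n = tf_occupancy(f, ps.params)
            o = (ps.occ if occ is None else occ)
            o = o.replace(n1=n) if ps.channel == "miRNA" else o.replace(n2=n)
            ss = steady_state(ps.params, o)
            if ss.m2 > 0:
                ff.append(lna_covariance(ps.params, ss).C[_M2, _M2] / ss.m2)
        out["fano_max"] = max(ff) if ff else float("nan")
    return out


def fano_peak(
    params,
    occ_base: Occupancies,
    species: str = "m2",
    f_lo: float = 2.0,
    f_hi: float = 40.0,
    n_points: int = 200,
) -> tuple[float, float]:
    """Input f1 at which the LNA Fano factor of a species peaks.

    Stochastic fluctuations are maximal where supply and consumption of the
    shared miRNA pool are balanced, so the Fano-factor peak along the f1
    axis is the operational signature of a ceRNA passing through its
    susceptible window.  Returns ``(f1_peak, fano_peak)`` from a log-spaced
    scan.
    """
    idx = SPECIES.index(species)
    grid = np.geomspace(f_lo, f_hi, n_points)
    best_f, best_ff = np.nan, -np.inf
    for f in grid:
        occ = occ_base.replace(n1=tf_occupancy(f, params))
        ss = steady_state(params, occ)
        mean = ss.as_vector()[idx]
        if mean <= 0:
            continue
        ff = lna_covariance(params, ss).C[idx, idx] / mean
        if ff > best_ff:
            best_f, best_ff = f, ff
    return float(best_f), float(best_ff)


def _point_seeds(seed: int, n: int) -> np.ndarray:
    ss = np.random.SeedSequence(seed)
    return (ss.generate_state(n, dtype=np.uint32) & 0x7FFFFFFF).astype(np.int64)


def _two_channel_rows(
    grid_values: list[dict],
    make_presets,
    config: SweepConfig,
) -> pd.DataFrame:
    """Evaluate both channels at every grid point of a 2-D parameter scan."""
    seeds = _point_seeds(config.seed, len(grid_values))
    rows = []
    for g, overrides in enumerate(grid_values):
        row = dict(overrides)
        row["seed"] = int(seeds[g])
        try:
            ps_mirna, ps_tf = make_presets(overrides)
            res_m = channel_capacity(
                ps_mirna, config.estimator, int(seeds[g]),
                config.input_points, config.replicates,
            )
            res_t = channel_capacity(
                ps_tf, config.estimator, int(seeds[g]) + 1,
                config.input_points, config.replicates,
            )
            row.update(
                I_miRNA=res_m["I"], I_TF=res_t["I"],
                delta_I=res_t["I"] - res_m["I"],
                aov_miRNA=res_m["aov"], aov_TF=res_t["aov"],
                status="ok",
            )
        except Exception as exc:  # failure policy: flag, do not abort
            row.update(
                I_miRNA=np.nan, I_TF=np.nan, delta_I=np.nan,
                aov_miRNA=np.nan, aov_TF=np.nan, status=f"failed: {exc}",
            )
        rows.append(row)
    return pd.DataFrame(rows)


def binding_rate_sweep(config: SweepConfig) -> pd.DataFrame:
    """Channel capacities over a log grid of complex association rates
    (k1+, k2+), all other parameters held at the binding-scan preset."""
    base = preset("fig5", "miRNA")
    lo1, hi1 = base.sweep_ranges["kplus1"]
    lo2, hi2 = base.sweep_ranges["kplus2"]
    k1s = np.geomspace(lo1, hi1, config.grid_points)
    k2s = np.geomspace(lo2, hi2, config.grid_points)
    grid = [{"kplus1": k1, "kplus2": k2} for k1 in k1s for k2 in k2s]

    def make(ov):
        return (
            preset("fig5", "miRNA").with_params(**ov),
            preset("fig5", "TF").with_params(**ov),
        )

    df = _two_channel_rows(grid, make, config)
    df.insert(0, "ln_kplus2", np.log(df.pop("kplus2")))
    df.insert(0, "ln_kplus1", np.log(df.pop("kplus1")))
    return df


def recycling_sweep(config: SweepConfig) -> pd.DataFrame:
    """Channel capacities over a log grid of miRNA-recycling (catalytic
    complex-decay) rates (kappa1, kappa2)."""
    base = preset("fig6", "miRNA")
    lo1, hi1 = base.sweep_ranges["kappa1"]
    lo2, hi2 = base.sweep_ranges["kappa2"]
    kap1 = np.geomspace(lo1, hi1, config.grid_points)
    kap2 = np.geomspace(lo2, hi2, config.grid_points)
    grid = [{"kappa1": a, "kappa2": b} for a in kap1 for b in kap2]

    def make(ov):
        return (
            preset("fig6", "miRNA").with_params(**ov),
            preset("fig6", "TF").with_params(**ov),
        )

    df = _two_channel_rows(grid, make, config)
    df.insert(0, "ln_kappa2", np.log(df.pop("kappa2")))
    df.insert(0, "ln_kappa1", np.log(df.pop("kappa1")))
    return df


def occupancy_sweep(config: SweepConfig) -> pd.DataFrame:
    """Capacity difference over a grid of operating occupancies (n1, n2).

    The grid pins the occupancy each channel does *not* control: the
    post-transcriptional channel sweeps its input f1 over the full range
    with the target's promoter held at ``n2``, and the transcriptional
    channel sweeps f2 with the competitor's promoter held at ``n1``.  The
    grid therefore sets the effective transcription rates ``b1*n1`` (as
    seen by the TF channel) and ``b2*n2`` (as seen by the miRNA channel)
    whose balance against each other and against the miRNA influx
    ``beta*nmu`` decides which channel wins.
    """
    name = config.preset or "fig7A"
    base = preset(name, "miRNA")
    lo, hi = base.sweep_ranges["n1"]
    n1s = np.linspace(lo, hi, config.grid_points)
    n2s = np.linspace(*base.sweep_ranges["n2"], config.grid_points)
    grid = [{"n1": a, "n2": b} for a in n1s for b in n2s]
    seeds = _point_seeds(config.seed, len(grid))
    rows = []
    for g, pt in enumerate(grid):
        row = dict(pt, seed=int(seeds[g]))
        try:
            ps_m = preset(name, "miRNA")
            ps_t = preset(name, "TF")
            res_m = channel_capacity(
                ps_m, config.estimator, int(seeds[g]), config.input_points,
                config.replicates,
                occ=ps_m.occ.replace(n2=pt["n2"]),
            )
            res_t = channel_capacity(
                ps_t, config.estimator, int(seeds[g]) + 1, config.input_points,
                config.replicates,
                occ=ps_t.occ.replace(n1=pt["n1"]),
            )
            row.update(
                I_miRNA=res_m["I"], I_TF=res_t["I"],
                delta_I=res_t["I"] - res_m["I"],
                aov_miRNA=res_m["aov"], aov_TF=res_t["aov"], status="ok",
            )
        except Exception as exc:
            row.update(I_miRNA=np.nan, I_TF=np.nan, delta_I=np.nan,
                       aov_miRNA=np.nan, aov_TF=np.nan, status=f"failed: {exc}")
        rows.append(row)
    return pd.DataFrame(rows)


def aov_capacity_curve(config: SweepConfig) -> pd.DataFrame:
    """Capacity versus amplitude of variation at a pinned minimal target level.

    The miRNA channel's maximal transcription rate ``b1`` and the (miRNA-
    free) TF channel's ``b2`` are swept over the packaged ranges; for the
    TF channel the lower input endpoint is re-matched at every ``b2`` so
    that both channels share the same minimal output, making capacity a
    function of the AOV alone.  The Poissonian-channel ceiling is tabulated
    alongside.
    """
    ps_m0 = preset("fig8", "miRNA")
    ps_t0 = preset("fig8", "TF")
    # minimal output of the miRNA channel (f1 = 0; independent of b1)
    m2_min = steady_state(ps_m0.params, ps_m0.occ.replace(n1=0.0)).m2
    b1s = np.geomspace(*ps_m0.sweep_ranges["b1"], config.grid_points)
    b2s = np.geomspace(*ps_t0.sweep_ranges["b2"], config.grid_points)
    seeds = _point_seeds(config.seed, 2 * config.grid_points)
    rows = []
    for g, b1 in enumerate(b1s):
        row = {"channel": "miRNA", "swept_param": "b1", "value": float(b1),
               "seed": int(seeds[g])}
        try:
            res = channel_capacity(
                ps_m0.with_params(b1=float(b1)), config.estimator,
                int(seeds[g]), config.input_points, config.replicates,
            )
            row.update(I=res["I"], aov=res["aov"], m2_min=res["m2_min"],
                       m2_max=res["m2_max"],
                       I_poisson=poisson_limit_capacity(res["m2_min"], res["m2_max"])
                       if res["m2_max"] > res["m2_min"] else 0.0,
                       status="ok")
        except Exception as exc:
            row.update(I=np.nan, aov=np.nan, m2_min=np.nan, m2_max=np.nan,
                       I_poisson=np.nan, status=f"failed: {exc}")
        rows.append(row)
    for g, b2 in enumerate(b2s):
        row = {"channel": "TF", "swept_param": "b2", "value": float(b2),
               "seed": int(seeds[config.grid_points + g])}
        n_lo = m2_min * ps_t0.params.d2 / b2
        if n_lo >= 0.98:  # b2 too small to clear the pinned minimal level
            row.update(I=0.0, aov=0.0, m2_min=m2_min, m2_max=m2_min,
                       I_poisson=0.0, status="degenerate")
            rows.append(row)
            continue
        try:
            res = channel_capacity(
                ps_t0.with_params(b2=float(b2)), config.estimator,
                int(seeds[config.grid_points + g]), config.input_points,
                config.replicates, input_range=(n_lo, 0.99),
            )
            row.update(I=res["I"], aov=res["aov"], m2_min=res["m2_min"],
                       m2_max=res["m2_max"],
                       I_poisson=poisson_limit_capacity(res["m2_min"], res["m2_max"])
                       if res["m2_max"] > res["m2_min"] else 0.0,
                       status="ok")
        except Exception as exc:
            row.update(I=np.nan, aov=np.nan, m2_min=np.nan, m2_max=np.nan,
                       I_poisson=np.nan, status=f"failed: {exc}")
        rows.append(row)
    return pd.DataFrame(rows)


def omega_sweep(config: SweepConfig) -> pd.DataFrame:
    """Channel capacities and target noise versus the rescaling factor omega.

    Shrinking omega jointly weakens miRNA turnover and binding while
    inflating the miRNA pool; the mean response (hence the AOV) is
    preserved, so the scan isolates the titration-noise contribution.  The
    TF channel's input window is matched once to the omega = 1 output
    range and does not depend on omega.
    """
    omegas = np.asarray(
        config.omega_grid if config.omega_grid else np.geomspace(1e-3, 2.0, 8)
    )
    ps_tf = preset("fig9", "TF")
    tf_range = matched_tf_occupancy_range(preset("fig9", "miRNA"), ps_tf.params)
    seeds = _point_seeds(config.seed, omegas.size + 1)
    res_t = channel_capacity(
        ps_tf, config.estimator, int(seeds[-1]), config.input_points,
        config.replicates, input_range=tf_range, with_fano=True,
    )
    rows = []
    for g, om in enumerate(omegas):
        row = {"omega": float(om), "seed": int(seeds[g])}
        try:
            ps_m = preset("fig9", "miRNA", omega=float(om))
            res_m = channel_capacity(
                ps_m, config.estimator, int(seeds[g]), config.input_points,
                config.replicates, with_fano=True,
            )
            row.update(
                I_miRNA=res_m["I"], I_TF=res_t["I"],
                delta_I=res_t["I"] - res_m["I"],
                aov_miRNA=res_m["aov"], aov_TF=res_t["aov"],
                fano_max_miRNA=res_m["fano_max"], fano_max_TF=res_t["fano_max"],
                status="ok",
            )
        except Exception as exc:
            row.update(I_miRNA=np.nan, I_TF=np.nan, delta_I=np.nan,
                       aov_miRNA=np.nan, aov_TF=np.nan,
                       fano_max_miRNA=np.nan, fano_max_TF=np.nan,
                       status=f"failed: {exc}")
        rows.append(row)
    return pd.DataFrame(rows)


_SWEEPS = {
    "binding": binding_rate_sweep,
    "recycling": recycling_sweep,
    "occupancy": occupancy_sweep,
    "aov": aov_capacity_curve,
    "omega": omega_sweep,
}


def run_sweep(config: SweepConfig) -> pd.DataFrame:
    """Dispatch a sweep by name and optionally write the CSV + run manifest."""
    if config.sweep not in _SWEEPS:
        raise KeyError(f"unknown sweep {config.sweep!r}; available: {tuple(_SWEEPS)}")
    t0 = time.monotonic()
    df = _SWEEPS[config.sweep](config)
    elapsed = time.monotonic() - t0
    if config.out:
        out = Path(config.out)
        out.parent.mkdir(parents=True, exist_ok=True)
        df.to_csv(out, index=False)
        write_manifest(out.with_suffix(".manifest.json"), config, elapsed)
    return df


def write_manifest(path: str | Path, config: SweepConfig, runtime_s: float) -> None:
    """Write a JSON run manifest (config echo, package version, wall-clock)."""
    manifest = {
        "config": config.to_dict(),
        "version": __version__,
        "runtime_s": round(runtime_s, 3),
    }
    Path(path).write_text(json.dumps(manifest, indent=2) + "\n")
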