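"""End-to-end experiments: channel-diameter and electrode-displacement sweeps.

Each configuration runs the full chain: build head -> carve channel ->
place montage -> solve the conduction problem -> field metrics -> sample
potentials at the ROI neuron compartments -> steady-state polarization ->
population statistics.  The ROI population is built once on the pristine
head (the CSF/GM surface is unaffected by channel or montage) and reused
across configurations, as the ROI is anchored to the fixed channel.

Displacement moves all five electrodes rigidly while the channel stays on
the target; retention curves are normalized to the zero-displacement
configuration of the same sweep.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import map_coordinates

from . import __version__
from .cable import (MembraneParams, PolarizationProfile, coupling_constant,
                    coupling_summary, refine, steady_state_polarization)
from .config import Scenario
from .geometry import ChannelSpec, MontageSpec, build_head_model, carve_channel, place_montage
from .grid import LabeledGrid
from .metrics import FocalityReport, focality_volumes, surface_normals, column_normals
from .morphology import PlacedNeuron, populate_roi
from .solver import compute_efield, sample_potential, solve_potential

log = logging.getLogger(__name__)

QUANTILE_METHOD = "linear"  # interpolation convention for Q1/Q3


@dataclass
class SweepConfig:
    """One experiment: a list of (channel, displacement) configurations."""

    base: Scenario
    configurations: list[dict]
    neuron_kinds: tuple[str, ...] = ("L5", "L3")

    def __post_init__(self) -> None:
        if not self.configurations:
            raise ValueError("sweep needs at least one configuration")


def diameter_sweep(
    base: Scenario,
    shapes: tuple[str, ...] = ("NONE", "I", "T"),
    diameters: tuple[float, ...] = (1, 3, 5, 7, 9),
    neuron_kinds: tuple[str, ...] = ("L5", "L3"),
) -> SweepConfig:
    """The channel-dimension experiment: shapes x shaft diameters (+ none)."""
    configs = []
    for shape in shapes:
        if shape.upper() == "NONE":
            configs.append({"name": "none", "shape": "NONE", "diameter": np.nan,
                            "displacement": 0.0})
        else:
            for d in diameters:
                configs.append({"name": f"{shape}{d:g}", "shape": shape.upper(),
                                "diameter": float(d), "displacement": 0.0})
    return SweepConfig(base, configs, neuron_kinds)


def displacement_sweep(
    base: Scenario,
    displacements: tuple[float, ...] = (0, 5, 10, 15, 20),
    neuron_kinds: tuple[str, ...] = ("L5", "L3"),
) -> SweepConfig:
    """Rigid montage displacement with the channel fixed on the target."""
    chan = base.channel
    if chan.shape == "NONE":
        raise ValueError("displacement sweep requires a channel at the target")
    configs = [
        {"name": f"disp{d:g}", "shape": chan.shape, "diameter": chan.shaft_diameter,
         "displacement": float(d)}
        for d in displacements
    ]
    return SweepConfig(base, configs, neuron_kinds)


@dataclass
class ConfigResult:
    name: str
    shape: str
    diameter: float
    displacement: float
    focality: FocalityReport | None = None
    stats: dict = dc_field(default_factory=dict)      # kind -> landmark -> stats
    coupling: dict = dc_field(default_factory=dict)   # kind -> (mean, sd)
    peak_soma_mV: dict = dc_field(default_factory=dict)
    labels_sha256: str = ""
    solve_info: dict = dc_field(default_factory=dict)
    error: str | None = None


@dataclass
class SweepResult:
    config: SweepConfig
    results: list[ConfigResult]
    retention: dict = dc_field(default_factory=dict)  # kind -> {displacement: frac}

    def by_name(self, name: str) -> ConfigResult:
        for r in self.results:
            if r.name == name:
                return r
        raise KeyError(name)


def roi_statistics(profiles: list[PolarizationProfile]) -> dict[str, dict[str, float]]:
    """Median, Q1, Q3 (linear interpolation), min, max per landmark."""
    if not profiles:
        raise ValueError("need at least one polarization profile")
    keys = set(profiles[0].morphology.landmarks)
    for p in profiles[1:]:
        if set(p.morphology.landmarks) != keys:
            raise ValueError("profiles carry inconsistent landmark sets")
    out: dict[str, dict[str, float]] = {}
    for k in sorted(keys):
        vals = np.array([p.landmark_values()[k] for p in profiles])
        q1, med, q3 = np.percentile(vals, [25, 50, 75], method=QUANTILE_METHOD)
        out[k] = {
            "median": float(med), "q1": float(q1), "q3": float(q3),
            "min": float(vals.min()), "max": float(vals.max()),
        }
    return out


def _local_field_magnitude(E, points_mm: np.ndarray) -> np.ndarray:
    spec = E.spec
    loc = (np.atleast_2d(points_mm) - np.asarray(spec.origin)) / spec.spacing - 0.5
    loc = np.clip(loc.T, 0, np.asarray(spec.shape)[:, None] - 1.0)
    return map_coordinates(E.magnitude, loc, order=1, mode="nearest")


def _polarize_population(
    phi, E, population: list[PlacedNeuron], membrane: MembraneParams
) -> tuple[list[PolarizationProfile], tuple[float, float], float]:
    """Solve every neuron; returns (profiles, coupling mean/sd, peak |soma dV|)."""
    profiles, couplings = [], []
    for pn in population:
        centers = pn.morphology.centers_mm()
        e_mV = sample_potential(phi, centers) * 1e3
        prof = steady_state_polarization(pn, e_mV, membrane)
        profiles.append(prof)
        localE = float(_local_field_magnitude(E, pn.morphology.pos[0][None, :])[0])
        if localE > 0:
            couplings.append(coupling_constant(prof, localE))
    peak = max(abs(p.soma_mV) for p in profiles)
    return profiles, coupling_summary(couplings), peak


def build_population(
    head_grid: LabeledGrid, scenario: Scenario, kinds: tuple[str, ...]
) -> dict[str, list[PlacedNeuron]]:
    """Place and refine the ROI neurons on the channel-free head."""
    lookup = column_normals(head_grid)
    pops: dict[str, list[PlacedNeuron]] = {}
    for kind in kinds:
        placed = populate_roi(head_grid, scenario.roi, kind, scenario.morphology,
                              normals_lookup=lookup)
        for pn in placed:
            pn.morphology = refine(pn.morphology, scenario.membrane)
        pops[kind] = placed
        log.info("ROI population %s: %d neurons", kind, len(placed))
    return pops


def run_sweep(cfg: SweepConfig, populations=None) -> SweepResult:
    """Run every configuration; stage errors abort only that configuration."""
    base = cfg.base
    spec = base.grid_spec()
    head_grid = build_head_model(spec, base.head)
    surface_normals(head_grid)  # fail early if the geometry is degenerate
    if populations is None:
        populations = build_population(head_grid, base, cfg.neuron_kinds)

    results = []
    for conf in cfg.configurations:
        res = ConfigResult(name=conf["name"], shape=conf["shape"],
                           diameter=conf["diameter"],
                           displacement=conf["displacement"])
        t0 = time.perf_counter()
        try:
            if conf["shape"] == "NONE":
                chan = ChannelSpec(shape="NONE")
            else:
                chan = dataclasses.replace(base.channel, shape=conf["shape"],
                                           shaft_diameter=conf["diameter"],
                                           hat_diameter=None)
            montage = dataclasses.replace(
                base.montage,
                displacement=(conf["displacement"], base.montage.displacement[1]),
            )
            g = carve_channel(head_grid, chan)
            g, faces = place_montage(g, montage)
            res.labels_sha256 = hashlib.sha256(g.labels.tobytes()).hexdigest()
            phi = solve_potential(g, base.conductivity, faces, base.solver)
            res.solve_info = {"iterations": phi.iterations, "residual": phi.residual}
            E = compute_efield(phi, g)
            res.focality = focality_volumes(E)
            for kind, pop in populations.items():
                profiles, coup, peak = _polarize_population(phi, E, pop, base.membrane)
                res.stats[kind] = roi_statistics(profiles)
                res.coupling[kind] = coup
                res.peak_soma_mV[kind] = peak
        except Exception as exc:  # noqa: BLE001 - stage errors are recorded
            res.error = f"{type(exc).__name__}: {exc}"
            log.error("configuration %s failed: %s", conf["name"], res.error)
        log.info("configuration %s done in %.1f s", conf["name"],
                 time.perf_counter() - t0)
        results.append(res)

    sweep = SweepResult(cfg, results)
    zero = next((r for r in results
                 if r.displacement == 0 and r.error is None and r.peak_soma_mV), None)
    if zero is not None and any(r.displacement != 0 for r in results):
        for kind in cfg.neuron_kinds:
            sweep.retention[kind] = {
                r.displacement: r.peak_soma_mV[kind] / zero.peak_soma_mV[kind]
                for r in results if r.error is None
            }
    return sweep


# ---------------------------------------------------------------------------
# reports

_FMT = "%.10g"


def write_report(result: SweepResult, outdir) -> dict[str, Path]:
    """focality.csv, polarization_stats.csv, retention.csv, run_manifest.json.

    Output is byte-reproducible for identical configurations: every number
    is computed deterministically and formatted with a fixed float format.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    rows = []
    for r in result.results:
        row = {"config": r.name, "shape": r.shape, "shaft_diameter_mm": r.diameter,
               "displacement_mm": r.displacement, "error": r.error or ""}
        if r.focality:
            row["peak_EF_V_per_m"] = r.focality.peak_V_per_m
            for p in (50, 60, 70, 80):
                row[f"vol{p}_mm3"] = r.focality.vol_mm3[p]
        rows.append(row)
    paths["focality"] = outdir / "focality.csv"
    pd.DataFrame(rows).to_csv(paths["focality"], index=False, float_format=_FMT)

    rows = []
    for r in result.results:
        for kind, stats in r.stats.items():
            for lm, s in stats.items():
                rows.append({"config": r.name, "kind": kind, "landmark": lm, **s})
    paths["polarization_stats"] = outdir / "polarization_stats.csv"
    pd.DataFrame(rows).to_csv(paths["polarization_stats"], index=False,
                              float_format=_FMT)

    rows = []
    for r in result.results:
        if r.error:
            continue
        for kind, peak in r.peak_soma_mV.items():
            ret = result.retention.get(kind, {}).get(r.displacement, np.nan)
            rows.append({"config": r.name, "displacement_mm": r.displacement,
                         "kind": kind, "peak_soma_mV": peak, "retention": ret})
    paths["retention"] = outdir / "retention.csv"
    pd.DataFrame(rows).to_csv(paths["retention"], index=False, float_format=_FMT)

    manifest = {
        "version": __version__,
        "quantile_method": QUANTILE_METHOD,
        "scenario": result.config.base.to_dict(),
        "neuron_kinds": list(result.config.neuron_kinds),
        "configurations": result.config.configurations,
        "labels_sha256": {r.name: r.labels_sha256 for r in result.results},
        "solve_info": {r.name: r.solve_info for r in result.results},
    }
    paths["manifest"] = outdir / "run_manifest.json"
    paths["manifest"].write_text(json.dumps(manifest, indent=2, sort_keys=True,
                                            default=float))
    return paths


def load_manifest_scenario(path) -> Scenario:
    """Re-resolve the Scenario recorded in a run manifest."""
    from .config import scenario_from_dict

    doc = json.loads(Path(path).read_text())["scenario"]
    doc = {k: v for k, v in doc.items()
           if k in {"spacing", "head", "channel", "montage", "conductivity",
                    "solver", "roi", "membrane", "morphology"}}
    spacing = doc.pop("spacing", 0.5)
    doc["grid"] = {"spacing": spacing}
    return scenario_from_dict(doc)
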