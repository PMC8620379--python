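"""End-to-end scenario runs: simulate, segment, score, validate, report.

``reproduce`` runs the four neuropathological scenarios (Control, ADI/II,
ADIII/IV, ADV/VI) with replicate simulations, collects raft statistics,
domain compositions, peroxidability indexes and the random-ensemble
validation, and returns a JSON-serialisable report.  Two presets are
provided: ``paper`` (200x200 lattice, 1000 iterations, 10 replicates,
ensemble of 100) and ``desk`` (100x100, 300 iterations, 3 replicates,
ensemble of 20) for quick runs on one CPU.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Any

import numpy as np

from .classes import MembraneComposition
from .forcefield import ForceField
from .io import CONDITIONS, ScenarioSet, load_scenarios
from .peroxidability import domain_pi, pi_patch_map
from .rafts import (
    RaftStats,
    auto_threshold,
    domain_composition,
    raft_mask,
    raft_stats,
    scenario_threshold,
)
from .simulate import SimulationConfig, SimulationResult, run_simulation
from .validation import random_reference_ensemble, validate_solution

__all__ = ["PRESETS", "preset_config", "run_scenario", "reproduce", "export_heatmaps"]

PRESETS: dict[str, dict[str, Any]] = {
    "paper": {"dims": (200, 200), "iterations": 1000, "replicates": 10, "ensemble": 100},
    "desk": {"dims": (100, 100), "iterations": 300, "replicates": 3, "ensemble": 20},
}


def preset_config(name: str = "paper", seed: int = 0, **overrides: Any) -> SimulationConfig:
    """Simulation config for a named preset, with keyword overrides."""
    if name not in PRESETS:
        raise ValueError(f"unknown preset {name!r}; choose from {sorted(PRESETS)}")
    params = {k: v for k, v in PRESETS[name].items() if k != "ensemble"}
    params.update(overrides)
    return SimulationConfig(seed=seed, **params)


@dataclass
class ScenarioResult:
    """Replicate-level outputs of one condition."""

    condition: str
    replicates: list[SimulationResult]
    stats: list[RaftStats]
    inside: list[MembraneComposition]
    outside: list[MembraneComposition]
    pi: list[tuple[float, float, float]]  # (inside, outside, whole)
    thresholds: list[float]
    seeds: list[int]


def run_scenario(
    condition: str,
    composition: MembraneComposition,
    force_field: ForceField,
    config: SimulationConfig,
    seeds: list[int] | None = None,
    tau: float | None = None,
    results: list[SimulationResult] | None = None,
) -> ScenarioResult:
    """Run the replicate simulations of one condition and analyse each.

    ``tau`` fixes the raft mobility threshold (use
    :func:`~raftsim.rafts.scenario_threshold` for cross-condition
    comparability); ``None`` falls back to the per-map
    :func:`~raftsim.rafts.auto_threshold`.  Pre-computed ``results`` (e.g.
    the Control runs used to calibrate ``tau``) are analysed instead of
    re-simulating.
    """
    if seeds is None:
        root = np.random.default_rng(config.seed)
        seeds = [int(s) for s in root.integers(0, 2**31 - 1, size=config.replicates)]
    reps, stats, ins, outs, pis, taus = [], [], [], [], [], []
    for i, seed in enumerate(seeds):
        if results is not None:
            result = results[i]
        else:
            result = run_simulation(composition, force_field, config, seed=seed)
        rep_tau = auto_threshold(result.mobility) if tau is None else tau
        mask = raft_mask(result.mobility, rep_tau).mask
        stat = raft_stats(result.mobility, tau=rep_tau)
        inside, outside = domain_composition(result.lattice, mask)
        pi = domain_pi(result.lattice, mask)
        reps.append(result)
        stats.append(stat)
        ins.append(inside)
        outs.append(outside)
        pis.append(pi)
        taus.append(rep_tau)
    return ScenarioResult(
        condition=condition,
        replicates=reps,
        stats=stats,
        inside=ins,
        outside=outs,
        pi=pis,
        thresholds=taus,
        seeds=seeds,
    )


def _mean_sd(values: list[float]) -> dict[str, float]:
    arr = np.asarray(values, dtype=float)
    return {"mean": float(arr.mean()), "sd": float(arr.std(ddof=1)) if arr.size > 1 else 0.0}


def _scenario_report(sc: ScenarioResult) -> dict[str, Any]:
    return {
        "condition": sc.condition,
        "seeds": sc.seeds,
        "thresholds": sc.thresholds,
        "raft_mean_size": _mean_sd([s.mean_size for s in sc.stats]),
        "raft_count": _mean_sd([s.count for s in sc.stats]),
        "raft_area_fraction": _mean_sd([s.area_fraction for s in sc.stats]),
        "composition_inside": {
            k: v
            for k, v in zip(
                sc.inside[0].to_dict(),
                np.mean([c.percent for c in sc.inside], axis=0).tolist(),
            )
        },
        "composition_outside": {
            k: v
            for k, v in zip(
                sc.outside[0].to_dict(),
                np.mean([c.percent for c in sc.outside], axis=0).tolist(),
            )
        },
        "pi_inside": _mean_sd([p[0] for p in sc.pi]),
        "pi_outside": _mean_sd([p[1] for p in sc.pi]),
        "pi_whole": _mean_sd([p[2] for p in sc.pi]),
    }


def reproduce(
    preset: str = "paper",
    seed: int = 0,
    scenarios: ScenarioSet | None = None,
    conditions: tuple[str, ...] = CONDITIONS,
    validate: bool = True,
    outdir: str | Path | None = None,
) -> dict[str, Any]:
    """Run the full four-scenario analysis and return the consolidated report.

    Per condition: replicate simulations, raft size/count/area statistics
    (mean +/- SD over replicates), domain compositions, domain PI, and the
    Delta^2 validation against the experimental raft composition using a
    shared random-membrane ensemble.  Partial failures are reported per
    condition and do not abort the run.
    """
    if scenarios is None:
        scenarios = load_scenarios()
    force_field = scenarios.force_field()
    config = preset_config(preset, seed=seed)
    ensemble_n = PRESETS[preset]["ensemble"]
    report: dict[str, Any] = {
        "preset": preset,
        "seed": seed,
        "config": {
            "dims": list(config.dims),
            "iterations": config.iterations,
            "replicates": config.replicates,
            "swap_rule": config.swap_rule,
            "theta_mode": config.theta_mode,
            "hamaker": scenarios.settings.hamaker,
            "distance": scenarios.settings.distance,
        },
        "conditions": {},
    }
    ensemble = None
    if validate:
        ensemble = random_reference_ensemble(
            force_field, config, n=ensemble_n, seed=seed + 1
        )
    # one fixed raft threshold for all conditions, calibrated on Control
    control_cfg = replace(config, seed=seed + 1000)
    control_rng = np.random.default_rng(control_cfg.seed)
    control_seeds = [
        int(s) for s in control_rng.integers(0, 2**31 - 1, size=config.replicates)
    ]
    control_results = [
        run_simulation(scenarios.membranes["Control"], force_field, config, seed=s)
        for s in control_seeds
    ]
    tau = scenario_threshold([r.mobility for r in control_results])
    report["tau"] = tau
    for i, condition in enumerate(conditions):
        try:
            if condition == "Control":
                sc = run_scenario(
                    condition,
                    scenarios.membranes[condition],
                    force_field,
                    control_cfg,
                    seeds=control_seeds,
                    tau=tau,
                    results=control_results,
                )
            else:
                sc = run_scenario(
                    condition,
                    scenarios.membranes[condition],
                    force_field,
                    replace(config, seed=seed + 1000 * (i + 1)),
                    tau=tau,
                )
            entry = _scenario_report(sc)
            if ensemble is not None:
                # validate the replicate-mean simulated raft composition
                mean_inside = MembraneComposition(
                    np.mean([c.percent for c in sc.inside], axis=0)
                )
                vr = validate_solution(
                    scenarios.membranes[condition],
                    mean_inside,
                    scenarios.reference_rafts[condition],
                    ensemble,
                )
                entry["validation"] = {
                    "d2_membrane_vs_simulated": vr.d2_membrane_vs_simulated,
                    "d2_simulated_vs_experimental": vr.d2_simulated_vs_experimental,
                    "ci_membrane": list(vr.ci_membrane),
                    "ci_experimental": list(vr.ci_experimental),
                    "ensemble_size": vr.ensemble_size,
                    "supported": vr.supported,
                }
            report["conditions"][condition] = entry
        except Exception as err:  # keep going; report the failure
            report["conditions"][condition] = {"error": f"{type(err).__name__}: {err}"}
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        with open(outdir / "report.json", "w") as fh:
            json.dump(report, fh, indent=2)
    return report


def export_heatmaps(
    result: SimulationResult, outdir: str | Path, prefix: str = "run"
) -> list[Path]:
    """Export mobility and PI heatmaps of a simulation as PNG images.

    Color limits are fixed (mobility 0-1, PI 0-600) so images from
    different conditions are directly comparable.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    maps = {
        "mobility": (result.mobility, 0.0, 1.0, "gray"),
        "pi": (pi_patch_map(result.lattice), 0.0, 600.0, "viridis"),
    }
    for name, (data, vmin, vmax, cmap) in maps.items():
        fig, ax = plt.subplots(figsize=(4, 4))
        im = ax.imshow(data, vmin=vmin, vmax=vmax, cmap=cmap, interpolation="nearest")
        fig.colorbar(im, ax=ax, shrink=0.8)
        ax.set_title(f"{prefix} {name} ({data.shape[0]}x{data.shape[1]})")
        path = outdir / f"{prefix}_{name}.png"
        fig.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(fig)
        written.append(path)
    return written
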