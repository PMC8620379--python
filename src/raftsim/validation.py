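"""Significance check of simulated raft compositions against random membranes.

The validation statistic is the quadratic difference between two
percentage compositions,

    Delta^2 = sum_over_classes (pa_k - pb_k)^2,

in squared percentage points.  An ensemble of membranes with random
lipid-class proportions (symmetric Dirichlet on the 7-class simplex) is
simulated with the standard pipeline, and empirical 95% confidence
intervals of two Delta^2 measurements are formed:

  (i)  membrane composition vs the raft composition simulated from it;
  (ii) simulated raft composition vs an experimental raft composition.

A data-driven solution is supported when its measurement (i) falls outside
the random interval and its measurement (ii) falls below the random
ensemble's values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .classes import MembraneComposition
from .forcefield import ForceField
from .rafts import auto_threshold, domain_composition, raft_mask
from .simulate import SimulationConfig, run_simulation

__all__ = [
    "quadratic_difference",
    "random_composition",
    "random_reference_ensemble",
    "validate_solution",
    "EnsembleDraw",
    "ValidationResult",
]


def quadratic_difference(
    comp_a: MembraneComposition, comp_b: MembraneComposition
) -> float:
    """Delta^2 between two compositions: sum of squared percent differences."""
    return float(np.sum((comp_a.percent - comp_b.percent) ** 2))


def random_composition(
    rng: np.random.Generator, alpha: float = 1.0
) -> MembraneComposition:
    """Random 7-class composition summing to 100.

    Sampled from a symmetric Dirichlet(alpha); alpha = 1 is uniform on the
    simplex.
    """
    return MembraneComposition(100.0 * rng.dirichlet(np.full(7, alpha)))


@dataclass(frozen=True)
class EnsembleDraw:
    """One random-membrane simulation of the reference ensemble."""

    membrane: MembraneComposition
    simulated_raft: MembraneComposition
    d2_membrane_vs_raft: float


@dataclass
class ValidationResult:
    """Observed Delta^2 values against the random-ensemble intervals."""

    d2_membrane_vs_simulated: float
    d2_simulated_vs_experimental: float
    ci_membrane: tuple[float, float]
    ci_experimental: tuple[float, float]
    ensemble_size: int
    membrane_outside_ci: bool
    experimental_below_upper: bool

    @property
    def supported(self) -> bool:
        """The acceptance logic: (i) outside its CI and (ii) below the
        random interval's upper bound."""
        return self.membrane_outside_ci and self.experimental_below_upper


def _simulated_raft_composition(
    composition: MembraneComposition,
    force_field: ForceField,
    config: SimulationConfig,
    seed: int,
) -> MembraneComposition | None:
    """Run one simulation and return the raft-region composition.

    Returns None when the segmented raft region is empty or covers the
    whole lattice (composition undefined for a region).
    """
    result = run_simulation(composition, force_field, config, seed=seed)
    tau = auto_threshold(result.mobility)
    mask = raft_mask(result.mobility, tau).mask
    if not mask.any() or mask.all():
        return None
    inside, _ = domain_composition(result.lattice, mask)
    return inside


def random_reference_ensemble(
    force_field: ForceField,
    config: SimulationConfig,
    n: int = 100,
    seed: int = 0,
    alpha: float = 1.0,
    max_resamples: int | None = None,
) -> list[EnsembleDraw]:
    """Simulate ``n`` random-composition membranes with the standard pipeline.

    Draws whose segmented raft region is degenerate (empty or full) are
    resampled; the number of resamples is bounded by ``max_resamples``
    (default ``10 * n``).
    """
    if n < 2:
        raise ValueError(f"ensemble size must be >= 2, got {n}")
    if max_resamples is None:
        max_resamples = 10 * n
    rng = np.random.default_rng(seed)
    draws: list[EnsembleDraw] = []
    attempts = 0
    while len(draws) < n:
        if attempts > n + max_resamples:
            raise RuntimeError(
                f"too many degenerate raft regions: {attempts} attempts for {n} draws"
            )
        attempts += 1
        membrane = random_composition(rng, alpha=alpha)
        sim_seed = int(rng.integers(0, 2**31 - 1))
        raft = _simulated_raft_composition(membrane, force_field, config, sim_seed)
        if raft is None:
            continue
        draws.append(
            EnsembleDraw(
                membrane=membrane,
                simulated_raft=raft,
                d2_membrane_vs_raft=quadratic_difference(membrane, raft),
            )
        )
    return draws


def validate_solution(
    membrane_comp: MembraneComposition,
    simulated_raft_comp: MembraneComposition,
    experimental_raft_comp: MembraneComposition,
    ensemble: list[EnsembleDraw],
) -> ValidationResult:
    """Compare a data-driven solution's Delta^2 values with the random ensemble.

    Measurement (i): ``membrane_comp`` vs ``simulated_raft_comp``, compared
    with the ensemble's membrane-vs-own-raft interval.  Measurement (ii):
    ``simulated_raft_comp`` vs ``experimental_raft_comp``, compared with
    the interval of the same quantity computed for every random draw.
    """
    d2_mem = quadratic_difference(membrane_comp, simulated_raft_comp)
    d2_exp = quadratic_difference(simulated_raft_comp, experimental_raft_comp)
    ens_mem = np.array([d.d2_membrane_vs_raft for d in ensemble])
    ens_exp = np.array(
        [
            quadratic_difference(d.simulated_raft, experimental_raft_comp)
            for d in ensemble
        ]
    )
    ci_mem = (float(np.percentile(ens_mem, 2.5)), float(np.percentile(ens_mem, 97.5)))
    ci_exp = (float(np.percentile(ens_exp, 2.5)), float(np.percentile(ens_exp, 97.5)))
    return ValidationResult(
        d2_membrane_vs_simulated=d2_mem,
        d2_simulated_vs_experimental=d2_exp,
        ci_membrane=ci_mem,
        ci_experimental=ci_exp,
        ensemble_size=len(ensemble),
        membrane_outside_ci=bool(d2_mem < ci_mem[0] or d2_mem > ci_mem[1]),
        experimental_below_upper=bool(d2_exp < ci_exp[1]),
    )
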