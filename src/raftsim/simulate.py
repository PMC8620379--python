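"""Stochastic swap dynamics on the membrane lattice.

Each iteration visits every site once in a fresh random permutation.  A
visited site proposes to exchange with one uniformly chosen von Neumann
neighbour.  Two acceptance rules are provided; both satisfy "the more
strongly bound, the less likely to move":

``"binding"`` (default) -- inverse-force law

    p(move) = exp(-(B_cur - B_ref) / theta)

where ``B_cur`` is the summed neighbour binding of the two participating
sites in the current configuration and ``B_ref`` the weakest possible
two-site binding (8x the smallest pair energy), so the least-bound pair
moves with probability ~1.  Strongly bound neighbourhoods freeze and
accrete more strongly bound lipids, which is what nucleates and grows the
low-mobility domains segmented as rafts.

``"metropolis"`` -- p = min(1, exp((B_swap - B_cur)/theta)) on the binding
change of the exchange.  Kept for sensitivity checks: with the mean-length
LVW convention the pair-energy matrix is nearly additive, so the energy
change of an exchange is almost zero everywhere and this rule produces
near-free diffusion (no rafts).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np

from . import _kernels
from .classes import MembraneComposition
from .forcefield import ForceField
from .lattice import binding_field, class_counts, initialize_lattice

__all__ = ["SimulationConfig", "SimulationResult", "step", "run_simulation"]


class ConfigurationError(ValueError):
    """Raised for invalid simulation settings."""


@dataclass(frozen=True)
class SimulationConfig:
    """Settings of one lattice simulation.

    Parameters
    ----------
    dims
        Lattice height and width; 200 x 200 by default.
    iterations
        Number of full sweeps; 1000 reaches a steady distribution of
        low-mobility regions at the default scale.
    replicates
        Number of independently seeded repeats averaged in scenario runs.
    theta
        Energy scale of the acceptance rule (J).  ``None`` auto-calibrates
        from the force field at startup: for the binding rule, 4x the
        standard deviation of the pair energies (half the natural spread
        of the two-site 8-bond binding sum, keeping acceptance in a
        dynamic range); for Metropolis, according to ``theta_mode``.
    theta_mode
        Metropolis auto-calibration: ``"median"`` = median off-diagonal
        pair energy; ``"spread"`` = standard deviation of the pair
        energies.
    swap_rule
        ``"binding"`` (default, inverse-force law) or ``"metropolis"``.
    count_identical
        Whether exchanges between same-class sites count as accepted moves
        in the mobility map (default True: any exchange is a change of
        position of the elements involved).
    track_rmsd
        Record the per-iteration RMSD of the binding-energy field relative
        to the initial configuration.
    """

    dims: tuple[int, int] = (200, 200)
    iterations: int = 1000
    replicates: int = 10
    theta: float | None = None
    theta_mode: Literal["median", "spread"] = "median"
    swap_rule: Literal["metropolis", "binding"] = "binding"
    count_identical: bool = True
    track_rmsd: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.iterations < 1:
            raise ConfigurationError(f"iterations must be >= 1, got {self.iterations}")
        if self.replicates < 1:
            raise ConfigurationError(f"replicates must be >= 1, got {self.replicates}")
        if self.theta is not None and not self.theta > 0:
            raise ConfigurationError(f"theta must be positive, got {self.theta}")
        if self.swap_rule not in ("metropolis", "binding"):
            raise ConfigurationError(f"unknown swap rule {self.swap_rule!r}")

    def resolve_theta(self, force_field: ForceField) -> float:
        if self.theta is not None:
            return self.theta
        if self.swap_rule == "binding":
            # half the natural spread of the two-site 8-bond binding sum:
            # weakly bound neighbourhoods stay fluid, the most strongly
            # bound freeze within the simulated window
            return 4.0 * force_field.bond_spread()
        if self.theta_mode == "median":
            return force_field.median_bond()
        if self.theta_mode == "spread":
            return force_field.bond_spread()
        raise ConfigurationError(f"unknown theta mode {self.theta_mode!r}")


@dataclass
class SimulationResult:
    """Final lattice, mobility map and noise series of one simulation."""

    lattice: np.ndarray
    mobility: np.ndarray
    rmsd_series: np.ndarray
    config: SimulationConfig
    seed: int
    theta: float = field(default=0.0)

    @property
    def dims(self) -> tuple[int, int]:
        return self.lattice.shape  # type: ignore[return-value]


def step(
    grid: np.ndarray,
    force_field: ForceField,
    rng: np.random.Generator,
    theta: float,
    swap_rule: str = "metropolis",
    count_identical: bool = True,
) -> np.ndarray:
    """Advance the lattice by one full sweep in place.

    Returns the boolean mask of sites that changed position (both partners
    of every accepted exchange) during this sweep.
    """
    if not theta > 0:
        raise ConfigurationError(f"theta must be positive, got {theta}")
    n = grid.size
    order = rng.permutation(n)
    nbr_choice = rng.integers(0, 4, size=n, dtype=np.int8)
    urand = rng.random(n)
    accepted = np.zeros(grid.shape, dtype=np.bool_)
    rule = _kernels.RULE_BINDING if swap_rule == "binding" else _kernels.RULE_METROPOLIS
    b_ref = 8.0 * float(force_field.energy.min())
    _kernels.sweep(
        grid,
        force_field.energy,
        order,
        nbr_choice,
        urand,
        theta,
        b_ref,
        rule,
        count_identical,
        accepted,
    )
    return accepted


def run_simulation(
    composition: MembraneComposition,
    force_field: ForceField,
    config: SimulationConfig | None = None,
    seed: int | None = None,
) -> SimulationResult:
    """Initialize a lattice from the composition and run the swap dynamics.

    The mobility of a site is the fraction of iterations in which it
    changed position; ``rmsd_series[t]`` is the root-mean-square deviation
    over sites of the binding-energy field after ``t`` iterations relative
    to the initial field (so the first entry is 0).
    """
    if config is None:
        config = SimulationConfig()
    if seed is not None:
        config = replace(config, seed=seed)
    rng = np.random.default_rng(config.seed)
    grid = initialize_lattice(composition, config.dims, rng)
    counts_before = class_counts(grid)
    theta = config.resolve_theta(force_field)

    moved_total = np.zeros(config.dims, dtype=np.int64)
    rmsd = np.zeros(config.iterations)
    if config.track_rmsd:
        field0 = binding_field(grid, force_field)
    for t in range(config.iterations):
        if config.track_rmsd and t > 0:
            diff = binding_field(grid, force_field) - field0
            rmsd[t] = float(np.sqrt(np.mean(diff**2)))
        moved = step(
            grid,
            force_field,
            rng,
            theta,
            swap_rule=config.swap_rule,
            count_identical=config.count_identical,
        )
        moved_total += moved

    if not np.array_equal(class_counts(grid), counts_before):
        raise RuntimeError("class counts changed during the simulation")
    mobility = moved_total / config.iterations
    return SimulationResult(
        lattice=grid,
        mobility=mobility,
        rmsd_series=rmsd,
        config=config,
        seed=config.seed,
        theta=theta,
    )
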