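"""Lattice construction and neighbour binding energies.

The membrane monolayer is a periodic H x W grid (default 200 x 200) of
lipid-class codes.  Sites interact with their four von Neumann neighbours
through the LVW force field.
"""

from __future__ import annotations

import numpy as np

from .classes import CompositionError, MembraneComposition, N_CLASSES
from .forcefield import ForceField

__all__ = [
    "allocate_counts",
    "initialize_lattice",
    "class_counts",
    "neighbor_binding",
    "binding_field",
]


def allocate_counts(composition: MembraneComposition, n_sites: int) -> np.ndarray:
    """Integer per-class site counts for ``n_sites`` lattice cells.

    Uses largest-remainder rounding of ``percent * n_sites / 100`` so the
    counts sum exactly to ``n_sites`` while staying as close as possible
    to the requested proportions.
    """
    if n_sites < N_CLASSES:
        raise CompositionError(f"need at least {N_CLASSES} sites, got {n_sites}")
    # normalize so quotas sum exactly to n_sites even when the validated
    # percentages sum to 100 +/- 0.5
    quota = composition.percent * n_sites / composition.percent.sum()
    counts = np.floor(quota).astype(np.int64)
    short = n_sites - int(counts.sum())
    if short > 0:
        remainders = quota - counts
        # ties broken by class code order (stable argsort)
        for idx in np.argsort(-remainders, kind="stable")[:short]:
            counts[idx] += 1
    return counts


def initialize_lattice(
    composition: MembraneComposition,
    dims: tuple[int, int] = (200, 200),
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Random initial lattice matching the composition's class proportions.

    The allocated multiset of class codes is shuffled uniformly; the same
    seed always yields the same grid.
    """
    h, w = dims
    if h <= 0 or w <= 0:
        raise ValueError(f"lattice dims must be positive, got {dims}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    counts = allocate_counts(composition, h * w)
    flat = np.repeat(np.arange(N_CLASSES, dtype=np.int8), counts)
    rng.shuffle(flat)
    return flat.reshape(h, w)


def class_counts(grid: np.ndarray) -> np.ndarray:
    """Per-class site counts of a lattice."""
    return np.bincount(grid.ravel(), minlength=N_CLASSES)


def neighbor_binding(
    grid: np.ndarray, site: tuple[int, int], force_field: ForceField
) -> float:
    """Summed LVW energy between one site and its 4 periodic neighbours (J)."""
    h, w = grid.shape
    r, c = site
    code = grid[r, c]
    e = force_field.energy
    return float(
        e[code, grid[(r - 1) % h, c]]
        + e[code, grid[(r + 1) % h, c]]
        + e[code, grid[r, (c - 1) % w]]
        + e[code, grid[r, (c + 1) % w]]
    )


def binding_field(grid: np.ndarray, force_field: ForceField) -> np.ndarray:
    """Per-site summed neighbour binding energy over the whole lattice (J).

    Vectorised equivalent of calling :func:`neighbor_binding` at every site.
    """
    e = force_field.energy
    out = np.zeros(grid.shape)
    for axis, shift in ((0, 1), (0, -1), (1, 1), (1, -1)):
        out += e[grid, np.roll(grid, shift, axis=axis)]
    return out
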