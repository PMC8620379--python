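"""Pairwise London-Van der Waals interactions between lipid cylinders.

Each lipid class is represented as a cylinder of radius ``R`` and length
``L`` (angstrom).  The non-retarded, additive London-Van der Waals (LVW)
attraction between two parallel cylinders held at surface separation ``D``
is

    LVW_ij = A * L / (12 * sqrt(2) * D**(3/2)) * sqrt(Ri*Rj / (Ri + Rj))

with ``A`` the Hamaker constant (J).  The 7x7 matrix of these energies
over all lipid-class pairs is the force field that drives the lattice
swap dynamics: the more strongly a site is bound to its neighbours, the
less likely it is to move.

For a heterogeneous pair the single length ``L`` in the formula is taken
as the arithmetic mean of the two class lengths, which makes the matrix
symmetric by construction and reduces to the plain formula for
within-class pairs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .classes import CLASS_CODES, CLASS_NAMES, N_CLASSES, _canonical_name

__all__ = [
    "CylinderParams",
    "InteractionSettings",
    "ForceField",
    "lvw_energy",
    "build_force_field",
    "read_cylinder_table",
]


class ForceFieldError(ValueError):
    """Raised for invalid cylinder geometry or interaction settings."""


@dataclass(frozen=True)
class CylinderParams:
    """Cylinder geometry of one lipid class: radius and length in angstrom."""

    radius: float
    length: float

    def __post_init__(self) -> None:
        if not self.radius > 0:
            raise ForceFieldError(f"radius must be positive, got {self.radius}")
        if not self.length > 0:
            raise ForceFieldError(f"length must be positive, got {self.length}")


@dataclass(frozen=True)
class InteractionSettings:
    """Hamaker constant (J) and intermolecular surface distance (angstrom).

    The Hamaker constant for lipids in vacuum is of order 1e-20 to 1e-19 J;
    the default is 1e-19 J.  Only the ratio of interaction energies to the
    swap-rule scale theta affects the dynamics, so the absolute value is a
    units choice more than a physical fit.
    """

    hamaker: float = 1e-19
    distance: float = 1.50

    def __post_init__(self) -> None:
        if not self.hamaker > 0:
            raise ForceFieldError(f"hamaker must be positive, got {self.hamaker}")
        if not self.distance > 0:
            raise ForceFieldError(f"distance must be positive, got {self.distance}")


def lvw_energy(
    params_i: CylinderParams,
    params_j: CylinderParams,
    settings: InteractionSettings,
) -> float:
    """Non-retarded additive LVW attraction between two lipid cylinders (J).

    Uses the arithmetic mean of the two cylinder lengths as the common
    length ``L``, so the result is symmetric in its arguments.
    """
    length = 0.5 * (params_i.length + params_j.length)
    reduced = params_i.radius * params_j.radius / (params_i.radius + params_j.radius)
    return (
        settings.hamaker
        * length
        / (12.0 * math.sqrt(2.0) * settings.distance**1.5)
        * math.sqrt(reduced)
    )


@dataclass(frozen=True)
class ForceField:
    """Symmetric 7x7 matrix of pairwise LVW interaction energies (J)."""

    energy: np.ndarray
    settings: InteractionSettings

    def __post_init__(self) -> None:
        arr = np.asarray(self.energy, dtype=float)
        if arr.shape != (N_CLASSES, N_CLASSES):
            raise ForceFieldError(f"force field must be 7x7, got {arr.shape}")
        if not np.array_equal(arr, arr.T):
            raise ForceFieldError("force field matrix must be symmetric")
        # zero entries are allowed (free-diffusion limit); negative are not
        if np.any(arr < 0):
            raise ForceFieldError("interaction energies must be non-negative")
        object.__setattr__(self, "energy", arr)

    def median_bond(self) -> float:
        """Median of the 21 off-diagonal pair energies."""
        iu = np.triu_indices(N_CLASSES, k=1)
        return float(np.median(self.energy[iu]))

    def bond_spread(self) -> float:
        """Standard deviation of the 28 distinct pair energies."""
        iu = np.triu_indices(N_CLASSES)
        return float(np.std(self.energy[iu]))


def build_force_field(
    params: Mapping[str, CylinderParams],
    settings: InteractionSettings | None = None,
) -> ForceField:
    """Assemble the 7x7 LVW force field from per-class cylinder geometry.

    Parameters
    ----------
    params
        Mapping of lipid-class name to :class:`CylinderParams`; all seven
        classes must be present (alias spellings accepted).
    settings
        Hamaker constant and intermolecular distance; defaults to
        ``InteractionSettings()``.
    """
    if settings is None:
        settings = InteractionSettings()
    canonical = {_canonical_name(name): p for name, p in params.items()}
    missing = [name for name in CLASS_NAMES if name not in canonical]
    if missing:
        raise ForceFieldError(f"missing cylinder parameters for: {', '.join(missing)}")
    energy = np.empty((N_CLASSES, N_CLASSES))
    for i, name_i in enumerate(CLASS_NAMES):
        for j, name_j in enumerate(CLASS_NAMES):
            energy[i, j] = lvw_energy(canonical[name_i], canonical[name_j], settings)
    # enforce exact symmetry against float noise in the double loop
    energy = np.minimum(energy, energy.T)
    return ForceField(energy=energy, settings=settings)


def read_cylinder_table(path: str | Path) -> dict[str, CylinderParams]:
    """Read a cylinder-parameter CSV with columns
    ``class,width_radius_angstrom,length_angstrom``."""
    df = pd.read_csv(path)
    required = {"class", "width_radius_angstrom", "length_angstrom"}
    if not required.issubset(df.columns):
        raise ForceFieldError(
            f"cylinder table must have columns {sorted(required)}, got {list(df.columns)}"
        )
    out: dict[str, CylinderParams] = {}
    for _, row in df.iterrows():
        name = _canonical_name(str(row["class"]))
        out[name] = CylinderParams(
            radius=float(row["width_radius_angstrom"]),
            length=float(row["length_angstrom"]),
        )
    return out
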