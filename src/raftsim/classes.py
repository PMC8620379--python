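"""Lipid classes and membrane compositions.

The model coarse-grains membrane lipids into seven structural classes.
Each class has a stable integer code used to encode lattice sites.
Compositions are mole percentages of total lipids and must sum to 100.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np

#: Canonical class order; the index is the lattice code for the class.
CLASS_NAMES: tuple[str, ...] = (
    "cholesterol",
    "sterol_esters",
    "dha",
    "n6_lcpufa",
    "monoenes",
    "saturates",
    "sphingolipids",
)

N_CLASSES = len(CLASS_NAMES)

CLASS_CODES: dict[str, int] = {name: i for i, name in enumerate(CLASS_NAMES)}

#: Tolerance on the percentage sum of a valid composition.
SUM_TOLERANCE = 0.5


class CompositionError(ValueError):
    """Raised when a lipid composition is invalid."""


def _canonical_name(name: str) -> str:
    key = name.strip().lower().replace(" ", "_").replace("-", "_")
    aliases = {
        "sterol_ester": "sterol_esters",
        "n_6_lcpufa": "n6_lcpufa",
        "n6lcpufa": "n6_lcpufa",
        "monoenoic_fatty_acids": "monoenes",
        "monoenoic": "monoenes",
        "saturated_fatty_acids": "saturates",
        "saturated": "saturates",
        "sphingolipid": "sphingolipids",
    }
    key = aliases.get(key, key)
    if key not in CLASS_CODES:
        raise CompositionError(
            f"unknown lipid class {name!r}; expected one of {', '.join(CLASS_NAMES)}"
        )
    return key


@dataclass(frozen=True)
class MembraneComposition:
    """Mole percentages of the seven lipid classes, summing to 100.

    Parameters
    ----------
    percent
        Length-7 array of percentages in canonical class order
        (:data:`CLASS_NAMES`).
    """

    percent: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.percent, dtype=float)
        if arr.shape != (N_CLASSES,):
            raise CompositionError(
                f"composition must have {N_CLASSES} entries, got shape {arr.shape}"
            )
        if np.any(arr < 0):
            bad = [CLASS_NAMES[i] for i in np.flatnonzero(arr < 0)]
            raise CompositionError(f"negative percentage for class(es): {', '.join(bad)}")
        total = float(arr.sum())
        if abs(total - 100.0) > SUM_TOLERANCE:
            raise CompositionError(
                f"percentages must sum to 100 +/- {SUM_TOLERANCE}, got {total:.4f}"
            )
        object.__setattr__(self, "percent", arr)

    @classmethod
    def from_dict(cls, mapping: Mapping[str, float]) -> "MembraneComposition":
        """Build a composition from a name -> percent mapping.

        Missing classes default to 0; alias spellings of the class names
        (e.g. ``"Saturated fatty acids"``) are accepted.
        """
        arr = np.zeros(N_CLASSES)
        for name, value in mapping.items():
            arr[CLASS_CODES[_canonical_name(name)]] = float(value)
        return cls(arr)

    def to_dict(self) -> dict[str, float]:
        return {name: float(self.percent[i]) for i, name in enumerate(CLASS_NAMES)}

    def __getitem__(self, name: str) -> float:
        return float(self.percent[CLASS_CODES[_canonical_name(name)]])

    def __eq__(self, other: object) -> bool:  # dataclass eq breaks on arrays
        if not isinstance(other, MembraneComposition):
            return NotImplemented
        return bool(np.array_equal(self.percent, other.percent))


def composition_from_counts(counts: Iterable[int]) -> MembraneComposition:
    """Convert per-class site counts into a percentage composition."""
    arr = np.asarray(list(counts), dtype=float)
    total = arr.sum()
    if total <= 0:
        raise CompositionError("cannot form a composition from zero total count")
    return MembraneComposition(100.0 * arr / total)
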