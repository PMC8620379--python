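"""Peroxidability index (PI) of compositions, lattice patches and domains.

PI scores a lipid composition's susceptibility to peroxidation as a linear
combination of the mole percentages of the unsaturated classes:

    PI = 0.025 * %monoenes + 5 * %n-6 LCPUFA + 6 * %DHA

Cholesterol, sterol esters, saturates and sphingolipids contribute nothing.
The coefficients are restricted to the lipid classes resolved by this
model; a pure-DHA composition bounds PI at 600.
"""

from __future__ import annotations

import numpy as np

from .classes import CLASS_CODES, MembraneComposition, N_CLASSES, composition_from_counts
from .lattice import class_counts
from .rafts import domain_composition

__all__ = ["PI_COEFFICIENTS", "peroxidability_index", "pi_patch_map", "domain_pi"]

PI_COEFFICIENTS = np.zeros(N_CLASSES)
PI_COEFFICIENTS[CLASS_CODES["monoenes"]] = 0.025
PI_COEFFICIENTS[CLASS_CODES["n6_lcpufa"]] = 5.0
PI_COEFFICIENTS[CLASS_CODES["dha"]] = 6.0

#: Upper bound of PI: a composition of 100% DHA.
PI_MAX = 600.0


def peroxidability_index(composition: MembraneComposition) -> float:
    """PI of a percentage composition (dimensionless, in [0, 600])."""
    return float(PI_COEFFICIENTS @ composition.percent)


def pi_patch_map(lattice: np.ndarray, patch_size: int = 5) -> np.ndarray:
    """PI computed on non-overlapping ``patch_size`` x ``patch_size`` tiles.

    Each patch's 25 cells are converted to a percentage composition and
    scored; a 200 x 200 lattice yields a 40 x 40 map.
    """
    h, w = lattice.shape
    if h % patch_size or w % patch_size:
        raise ValueError(
            f"lattice dims {lattice.shape} not divisible by patch size {patch_size};"
            " crop the lattice first"
        )
    ph, pw = h // patch_size, w // patch_size
    patches = lattice.reshape(ph, patch_size, pw, patch_size).swapaxes(1, 2)
    counts = (
        patches.reshape(ph, pw, patch_size * patch_size)[..., None]
        == np.arange(N_CLASSES)
    ).sum(axis=2)
    percent = 100.0 * counts / (patch_size * patch_size)
    return percent @ PI_COEFFICIENTS


def domain_pi(lattice: np.ndarray, mask: np.ndarray) -> tuple[float, float, float]:
    """PI inside rafts, outside rafts, and of the whole lattice.

    An empty region (inside or outside) yields NaN for that region's PI as
    an explicit "undefined" signal rather than a silent zero.
    """
    mask = np.asarray(mask, dtype=bool)
    pi_whole = peroxidability_index(composition_from_counts(class_counts(lattice)))
    if mask.all():
        return pi_whole, float("nan"), pi_whole
    if not mask.any():
        return float("nan"), pi_whole, pi_whole
    inside, outside = domain_composition(lattice, mask)
    return (
        peroxidability_index(inside),
        peroxidability_index(outside),
        pi_whole,
    )
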