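"""Composition-table I/O and bundled human frontal-cortex datasets.

The package ships the experimental lipid-class composition tables for
human frontal cortex at four neuropathological conditions (Control and
Braak stages ADI/II, ADIII/IV, ADV/VI):

* ``frontal_cortex_membrane.csv`` -- whole cell-membrane composition, the
  simulation input (this fraction is also referred to as "non-rafts" in
  parts of the source data; it is stored once, under the membrane name);
* ``frontal_cortex_rafts.csv`` -- lipid-raft composition, the experimental
  reference the simulated rafts are validated against;
* ``cylinder_params.csv`` -- per-class cylinder geometry (mouse frontal
  cortex calibration) plus the intermolecular distance of 1.50 angstrom.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import pandas as pd

from .classes import (
    CLASS_NAMES,
    CompositionError,
    MembraneComposition,
    _canonical_name,
)
from .forcefield import (
    CylinderParams,
    ForceField,
    InteractionSettings,
    build_force_field,
    read_cylinder_table,
)

__all__ = [
    "CONDITIONS",
    "ScenarioSet",
    "read_composition_table",
    "write_composition_table",
    "load_scenarios",
    "data_path",
]

#: Neuropathological conditions in order of increasing severity.
CONDITIONS: tuple[str, ...] = ("Control", "ADI/II", "ADIII/IV", "ADV/VI")

#: Intermolecular distance (angstrom) bundled with the cylinder table.
INTERMOLECULAR_DISTANCE = 1.50


@dataclass(frozen=True)
class ScenarioSet:
    """Bundled inputs for the four neuropathological scenarios."""

    membranes: dict[str, MembraneComposition]
    reference_rafts: dict[str, MembraneComposition]
    cylinders: dict[str, CylinderParams]
    settings: InteractionSettings

    def __post_init__(self) -> None:
        for table in (self.membranes, self.reference_rafts):
            missing = [c for c in CONDITIONS if c not in table]
            if missing:
                raise CompositionError(f"missing condition(s): {', '.join(missing)}")

    def force_field(self) -> ForceField:
        return build_force_field(self.cylinders, self.settings)


def data_path(name: str) -> Path:
    """Path of a bundled data file."""
    return Path(str(resources.files("raftsim.data").joinpath(name)))


def read_composition_table(path: str | Path) -> dict[str, MembraneComposition]:
    """Read a composition CSV into one composition per condition.

    Accepts either a long table with columns ``class,percent`` (returned
    under the single key ``"composition"``) or a wide table with a
    ``class`` column and one column per condition.  Every composition is
    validated; a column that does not sum to 100 +/- 0.5 raises a
    :class:`~raftsim.classes.CompositionError` naming the condition.
    """
    df = pd.read_csv(path)
    if "class" not in df.columns:
        raise CompositionError(f"{path}: composition table needs a 'class' column")
    classes = [_canonical_name(str(c)) for c in df["class"]]
    value_cols = [c for c in df.columns if c != "class"]
    if not value_cols:
        raise CompositionError(f"{path}: no composition columns found")
    if value_cols == ["percent"]:
        value_cols = ["percent"]
    out: dict[str, MembraneComposition] = {}
    for col in value_cols:
        mapping = dict(zip(classes, df[col].astype(float)))
        try:
            comp = MembraneComposition.from_dict(mapping)
        except CompositionError as err:
            label = "composition" if col == "percent" else col
            raise CompositionError(f"{path}: condition {label!r}: {err}") from err
        out["composition" if col == "percent" else col] = comp
    return out


def write_composition_table(
    compositions: dict[str, MembraneComposition], path: str | Path
) -> None:
    """Write compositions as a wide CSV (inverse of :func:`read_composition_table`)."""
    df = pd.DataFrame({"class": list(CLASS_NAMES)})
    for name, comp in compositions.items():
        df[name] = comp.percent
    df.to_csv(path, index=False)


def load_scenarios(
    hamaker: float = 1e-19,
    distance: float = INTERMOLECULAR_DISTANCE,
) -> ScenarioSet:
    """Load the bundled frontal-cortex scenario set."""
    membranes = read_composition_table(data_path("frontal_cortex_membrane.csv"))
    rafts = read_composition_table(data_path("frontal_cortex_rafts.csv"))
    cylinders = read_cylinder_table(data_path("cylinder_params.csv"))
    return ScenarioSet(
        membranes=membranes,
        reference_rafts=rafts,
        cylinders=cylinders,
        settings=InteractionSettings(hamaker=hamaker, distance=distance),
    )
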