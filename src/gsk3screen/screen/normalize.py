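"""Percent-of-control normalization of well readouts.

Raw percent p-CRMP2/MAP2 values are expressed relative to a reference
set at 100: vehicle (DMSO) wells, the average of all wells (the primary
screen's convention), or lithium reference wells (used when ranking
candidate modulators against a therapeutically relevant lithium dose).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from ..imaging.wells import WellResult

ROLES = ("DMSO", "positive_control", "lithium_ref", "test")

MODE_ROLE = {"dmso": "DMSO", "lithium_1mM": "lithium_ref"}


class ReferenceError(ValueError):
    """The reference mean for the requested mode is missing or zero."""


@dataclass
class PlateLayout:
    """Well -> (compound, dose, role) assignment of one plate."""

    wells: dict[str, tuple[str, float, str]] = field(default_factory=dict)

    def role(self, well: str) -> str:
        return self.wells[well][2]

    def compound(self, well: str) -> str:
        return self.wells[well][0]

    def wells_with_role(self, role: str) -> list[str]:
        return [w for w, (_, _, r) in self.wells.items() if r == role]

    @classmethod
    def from_csv(cls, path: str | Path) -> "PlateLayout":
        wells = {}
        with open(path) as fh:
            for row in csv.DictReader(fh):
                wells[row["well"]] = (
                    row["compound"], float(row["dose"]), row["role"]
                )
        return cls(wells=wells)


@dataclass
class NormalizedWell:
    """One well's readout on the percent-of-reference scale."""

    well: str
    raw_percent: float | None
    normalized_percent: float | None
    mode: str
    neuron_count: int


def normalize_to_reference(
    wells: list[WellResult],
    layout: PlateLayout,
    mode: str = "dmso",
) -> list[NormalizedWell]:
    """Normalize raw well percents so the reference averages 100.

    ``mode`` is one of ``dmso``, ``all_well_average`` or ``lithium_1mM``.
    Wells with an undefined raw percent stay undefined. Raises
    :class:`ReferenceError` when the reference mean is missing or zero.
    """
    if mode not in ("dmso", "all_well_average", "lithium_1mM"):
        raise ReferenceError(f"unknown normalization mode {mode!r}")
    by_well = {w.well: w for w in wells}
    if mode == "all_well_average":
        ref_values = [w.percent_pcrmp2 for w in wells if w.percent_pcrmp2 is not None]
    else:
        role = MODE_ROLE[mode]
        ref_wells = layout.wells_with_role(role)
        ref_values = [
            by_well[w].percent_pcrmp2
            for w in ref_wells
            if w in by_well and by_well[w].percent_pcrmp2 is not None
        ]
    if not ref_values:
        raise ReferenceError(f"no reference wells with a defined readout for "
                             f"mode {mode!r}")
    ref_mean = float(np.mean(ref_values))
    if ref_mean == 0:
        raise ReferenceError(f"reference mean is zero for mode {mode!r}")

    return [
        NormalizedWell(
            well=w.well,
            raw_percent=w.percent_pcrmp2,
            normalized_percent=(
                100.0 * w.percent_pcrmp2 / ref_mean
                if w.percent_pcrmp2 is not None
                else None
            ),
            mode=mode,
            neuron_count=w.neuron_count,
        )
        for w in wells
    ]
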