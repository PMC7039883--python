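"""End-to-end screen pipeline: plate images -> well readouts -> hit calls.

Thin orchestration over :mod:`gsk3screen.imaging` and
:mod:`gsk3screen.screen`; every computation lives in those modules.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .imaging.wells import HCIConfig, WellResult, analyze_field, measure_well
from .screen.hits import BandConfig, HitCall, call_hits
from .screen.normalize import PlateLayout, normalize_to_reference
from .synth.plate_sim import SyntheticPlate, SyntheticPlateSpec, generate_plate


def layout_from_spec(spec: SyntheticPlateSpec) -> PlateLayout:
    """Plate layout (compound, dose, role per well) of a synthetic spec."""
    return PlateLayout(
        wells={
            well: (w.compound, w.dose, w.role) for well, w in spec.wells.items()
        }
    )


def analyze_plate(
    plate: SyntheticPlate, config: HCIConfig | None = None, mode: str = "high-content"
) -> list[WellResult]:
    """Run the image-analysis pipeline on every well of a plate."""
    config = config or HCIConfig(pixel_size_um=plate.spec.pixel_size_um)
    results = []
    for well in sorted(plate.spec.wells):
        fields = [
            analyze_field(f.image, config) for f in plate.well_fields(well)
        ]
        results.append(measure_well(well, fields, mode=mode))
    return results


@dataclass
class ScreenReport:
    """Normalized readouts and hit calls of one screened plate."""

    well_results: list[WellResult]
    layout: PlateLayout
    hits: list[HitCall]
    normalization_mode: str

    def calls_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "compound": h.compound,
                    "mean_percent": h.mean_percent,
                    "sd_percent": h.sd_percent,
                    "n": h.n_replicates,
                    "neuron_count_ratio": h.neuron_count_ratio,
                    "band": h.band,
                }
                for h in self.hits
            ]
        )


def run_screen(
    spec: SyntheticPlateSpec,
    config: HCIConfig | None = None,
    mode: str = "dmso",
    bands: BandConfig | None = None,
) -> ScreenReport:
    """Simulate, analyze and band-call a whole synthetic plate."""
    plate = generate_plate(spec)
    well_results = analyze_plate(plate, config)
    layout = layout_from_spec(spec)
    normalized = normalize_to_reference(well_results, layout, mode=mode)

    by_compound: dict[str, list[float]] = {}
    counts: dict[str, list[int]] = {}
    for nw in normalized:
        compound = layout.compound(nw.well)
        if layout.role(nw.well) != "test":
            continue
        by_compound.setdefault(compound, []).append(nw.normalized_percent)
        counts.setdefault(compound, []).append(nw.neuron_count)

    ref_wells = layout.wells_with_role("DMSO") or list(layout.wells)
    by_well = {w.well: w for w in well_results}
    ref_count = float(
        np.mean([by_well[w].neuron_count for w in ref_wells if w in by_well])
    )
    count_ratios = {
        compound: (float(np.mean(c)) / ref_count if ref_count > 0 else 1.0)
        for compound, c in counts.items()
    }
    hits = call_hits(by_compound, count_ratios, bands)
    return ScreenReport(
        well_results=well_results, layout=layout, hits=hits,
        normalization_mode=mode,
    )
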