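"""Per-field analysis and per-well aggregation.

The well readout is the percent p-CRMP2(T514)/MAP2: 100 times the ratio
of the well-averaged neurite p-CRMP2 intensity to the well-averaged
neurite MAP2 intensity, measured on neurites anchored to MAP2-positive
neurons (high-content mode) or on whole-field integrated signal above
background with no per-cell gating (whole-field mode, emulating a
laser-scanning cytometer). The MAP2-positive neuron count, summed over
fields, is the toxicity readout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .classify import CellRecord, ClassifierThresholds, classify_cells
from .neurites import NeuriteMeasurement, NeuriteParams, trace_neurites
from .segment import NucleiSegmentation, SegmentationParams, segment_nuclei


@dataclass
class HCIConfig:
    """End-to-end configuration of the image-analysis pipeline."""

    pixel_size_um: float = 0.65
    channel_order: tuple[str, str, str] = ("nuclear", "map2", "pcrmp2")
    segmentation: SegmentationParams = field(default_factory=SegmentationParams)
    thresholds: ClassifierThresholds = field(default_factory=ClassifierThresholds)
    neurites: NeuriteParams = field(default_factory=NeuriteParams)


@dataclass
class FieldAnalysis:
    """All measurements of one field."""

    segmentation: NucleiSegmentation
    cells: list[CellRecord]
    neurites: NeuriteMeasurement

    @property
    def neuron_count(self) -> int:
        return sum(1 for c in self.cells if c.is_neuron)


@dataclass
class WellResult:
    """Aggregated readout of one well.

    ``percent_pcrmp2`` is None (typed missing) when no field of the well
    contributed a measurable neurite signal.
    """

    well: str
    n_fields: int
    neuron_count: int
    percent_pcrmp2: float | None


def analyze_field(image: np.ndarray, config: HCIConfig | None = None) -> FieldAnalysis:
    """Run segmentation, classification and neurite tracing on one field.

    ``image`` is (3, H, W) in the configured channel order.
    """
    config = config or HCIConfig()
    ch = {name: image[i] for i, name in enumerate(config.channel_order)}
    seg = segment_nuclei(ch["nuclear"], config.pixel_size_um, config.segmentation)
    cells = classify_cells(seg, ch["nuclear"], ch["map2"], config.thresholds)
    neuron_labels = {c.nucleus.label for c in cells if c.is_neuron}
    neurites = trace_neurites(
        ch["map2"], seg, pcrmp2=ch["pcrmp2"], params=config.neurites,
        restrict_labels=neuron_labels,
    )
    return FieldAnalysis(segmentation=seg, cells=cells, neurites=neurites)


def measure_well(
    well: str,
    fields: list[FieldAnalysis],
    mode: str = "high-content",
) -> WellResult:
    """Aggregate field analyses into the per-well readout.

    high-content mode averages background-subtracted neurite p-CRMP2 and
    MAP2 means over fields with at least one neuron and measurable
    neurites, then takes their ratio x100. whole-field mode ratios the
    total above-background intensities with no per-cell gating.
    """
    if not fields:
        raise ValueError("measure_well needs at least one field")
    if mode not in ("high-content", "whole-field"):
        raise ValueError(f"unknown mode {mode!r}")

    neuron_count = sum(f.neuron_count for f in fields)
    if mode == "high-content":
        p_means = [
            f.neurites.pcrmp2_mean_bgsub
            for f in fields
            if f.neuron_count > 0 and f.neurites.n_pixels > 0
        ]
        m_means = [
            f.neurites.map2_mean_bgsub
            for f in fields
            if f.neuron_count > 0 and f.neurites.n_pixels > 0
        ]
        if not m_means or np.mean(m_means) <= 0:
            return WellResult(well, len(fields), neuron_count, None)
        percent = 100.0 * float(np.mean(p_means)) / float(np.mean(m_means))
    else:
        p_tot = sum(f.neurites.pcrmp2_total_bgsub for f in fields)
        m_tot = sum(f.neurites.map2_total_bgsub for f in fields)
        if m_tot <= 0:
            return WellResult(well, len(fields), neuron_count, None)
        percent = 100.0 * p_tot / m_tot
    return WellResult(well, len(fields), neuron_count, percent)


def cells_frame(well: str, fields: list[FieldAnalysis]) -> pd.DataFrame:
    """One row per segmented cell across the fields of a well."""
    rows = []
    for fi, f in enumerate(fields):
        for cell in f.cells:
            rows.append(
                {
                    "well": well,
                    "field": fi,
                    "label": cell.nucleus.label,
                    "area_um2": cell.nucleus.area_um2,
                    "nuclear_mean": cell.nucleus.mean_intensity,
                    "ring_map2_mean": cell.ring_map2_mean,
                    "ring_map2_cv": cell.ring_map2_cv,
                    "size_ok": cell.size_ok,
                    "nuclear_intensity_ok": cell.nuclear_intensity_ok,
                    "map2_ok": cell.map2_ok,
                    "cv_ok": cell.cv_ok,
                    "class": cell.cell_class,
                }
            )
    return pd.DataFrame(rows)
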