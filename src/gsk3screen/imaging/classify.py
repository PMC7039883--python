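"""Collar-ring classification of segmented nuclei into neurons and rejects.

A collar ring (an annulus dilated outward from the nuclear boundary)
samples the perinuclear MAP2 staining, and four criteria are applied in
order:

1. nuclear size inside the [50, 160] um2 band (small = debris, large =
   clump; boundaries inclusive);
2. nuclear staining bright enough (mean >= 2197 camera counts by
   default);
3. ring MAP2 above a floor (background mean + 3 sd by default) —
   otherwise not a neuron;
4. ring MAP2 coefficient of variation above 1 — neurites crossing the
   ring make neuronal MAP2 patchy, so high CV marks neurons.

A cell is a neuron iff all four pass; each rejection is labelled by its
first failing criterion in the numbered order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from skimage.morphology import dilation, disk as disk_footprint

from .segment import NucleiSegmentation, NuclearObject

logger = logging.getLogger(__name__)


@dataclass
class ClassifierThresholds:
    """The four-criterion thresholds and ring geometry.

    ``size_unit`` selects whether the size band is nuclear area in um2
    (default) or equivalent diameter in um. ``map2_floor`` of None
    estimates the floor per image as background mean + 3 background sd
    (robustly, from the median and MAD). ``cv_neuron_above`` implements
    the printed rule (CV > threshold marks neurons); set it False to
    invert the criterion.
    """

    size_min: float = 50.0
    size_max: float = 160.0
    size_unit: str = "area"  # "area" (um2) or "diameter" (um)
    nuclear_min: float = 2197.0
    map2_floor: float | None = None
    cv_threshold: float = 1.0
    cv_neuron_above: bool = True
    ring_width_um: float = 2.0


@dataclass
class CellRecord:
    """One nucleus with its collar-ring statistics and classification."""

    nucleus: NuclearObject
    ring_map2_mean: float
    ring_map2_cv: float
    size_ok: bool
    nuclear_intensity_ok: bool
    map2_ok: bool
    cv_ok: bool
    cell_class: str  # neuron | non-neuron | rejected-debris | rejected-clump | rejected-dim

    @property
    def is_neuron(self) -> bool:
        return self.cell_class == "neuron"


def estimate_map2_floor(map2: np.ndarray) -> float:
    """Background mean + 3 sd, estimated robustly from median and MAD."""
    med = float(np.median(map2))
    mad = float(np.median(np.abs(map2 - med)))
    if mad == 0.0:
        # noise-free background: anything at background level is not MAP2+
        return med + 1.0
    return med + 3.0 * 1.4826 * mad


def classify_cells(
    seg: NucleiSegmentation,
    nuclear: np.ndarray,
    map2: np.ndarray,
    thresholds: ClassifierThresholds | None = None,
) -> list[CellRecord]:
    """Apply the four classification criteria to every segmented nucleus.

    Rings are clipped at the image border (logged); ring pixels belonging
    to any nucleus are excluded so the ring samples cytoplasm only.
    """
    thresholds = thresholds or ClassifierThresholds()
    map2 = np.asarray(map2, dtype=float)
    floor = (
        thresholds.map2_floor
        if thresholds.map2_floor is not None
        else estimate_map2_floor(map2)
    )
    ring_px = max(1, int(round(thresholds.ring_width_um / seg.pixel_size_um)))
    footprint = disk_footprint(ring_px)
    any_nucleus = seg.labels > 0

    height, width = seg.labels.shape
    records = []
    for obj in seg.objects:
        rows, cols = obj.coords[:, 0], obj.coords[:, 1]
        if (
            rows.min() <= ring_px or cols.min() <= ring_px
            or rows.max() >= height - 1 - ring_px
            or cols.max() >= width - 1 - ring_px
        ):
            logger.info("object %d: collar ring clipped at image border",
                        obj.label)
        # dilate within the padded bounding box only
        r0 = max(int(rows.min()) - ring_px - 1, 0)
        r1 = min(int(rows.max()) + ring_px + 2, height)
        c0 = max(int(cols.min()) - ring_px - 1, 0)
        c1 = min(int(cols.max()) + ring_px + 2, width)
        own = np.zeros((r1 - r0, c1 - c0), dtype=bool)
        own[rows - r0, cols - c0] = True
        ring = dilation(own, footprint) & ~any_nucleus[r0:r1, c0:c1]
        ring_values = map2[r0:r1, c0:c1][ring]
        ring_mean = float(ring_values.mean()) if ring_values.size else 0.0
        ring_cv = (
            float(ring_values.std() / ring_mean)
            if ring_values.size and ring_mean > 0
            else 0.0
        )

        size = (
            obj.area_um2
            if thresholds.size_unit == "area"
            else 2.0 * np.sqrt(obj.area_um2 / np.pi)
        )
        size_ok = thresholds.size_min <= size <= thresholds.size_max
        nuclear_ok = obj.mean_intensity >= thresholds.nuclear_min
        map2_ok = ring_mean >= floor
        cv_ok = (
            ring_cv > thresholds.cv_threshold
            if thresholds.cv_neuron_above
            else ring_cv <= thresholds.cv_threshold
        )

        if not size_ok:
            cls = "rejected-debris" if size < thresholds.size_min else "rejected-clump"
        elif not nuclear_ok:
            cls = "rejected-dim"
        elif not map2_ok or not cv_ok:
            cls = "non-neuron"
        else:
            cls = "neuron"

        records.append(
            CellRecord(
                nucleus=obj,
                ring_map2_mean=ring_mean,
                ring_map2_cv=ring_cv,
                size_ok=size_ok,
                nuclear_intensity_ok=nuclear_ok,
                map2_ok=map2_ok,
                cv_ok=cv_ok,
                cell_class=cls,
            )
        )
    return records
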