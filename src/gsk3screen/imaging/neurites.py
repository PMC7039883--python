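"""Neurite tracing from the MAP2 channel.

The MAP2-positive mask (global Otsu by default) is stripped of soma
regions (nuclei dilated by the soma margin) and skeletonized; only
skeleton components connected to a soma are retained, so free-floating
MAP2 debris does not contribute. p-CRMP2 and MAP2 intensities are then
measured on the retained skeleton pixels, both raw and with the
per-channel background (image median) subtracted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage.filters import threshold_otsu
from skimage.morphology import dilation, disk as disk_footprint, skeletonize

from .segment import NucleiSegmentation

logger = logging.getLogger(__name__)


@dataclass
class NeuriteParams:
    """Tunables for neurite tracing."""

    map2_threshold: float | None = None  # None = Otsu per image
    soma_margin_um: float = 2.0
    max_foreground_fraction: float = 0.4


@dataclass
class NeuriteMeasurement:
    """Pooled neurite skeleton of one field with channel intensities."""

    skeleton: np.ndarray  # bool mask
    length_um: float
    map2_mean: float
    pcrmp2_mean: float
    map2_mean_bgsub: float
    pcrmp2_mean_bgsub: float
    map2_total_bgsub: float
    pcrmp2_total_bgsub: float

    @property
    def n_pixels(self) -> int:
        return int(self.skeleton.sum())


def _empty(shape: tuple[int, int]) -> NeuriteMeasurement:
    return NeuriteMeasurement(
        skeleton=np.zeros(shape, dtype=bool), length_um=0.0,
        map2_mean=0.0, pcrmp2_mean=0.0,
        map2_mean_bgsub=0.0, pcrmp2_mean_bgsub=0.0,
        map2_total_bgsub=0.0, pcrmp2_total_bgsub=0.0,
    )


def trace_neurites(
    map2: np.ndarray,
    seg: NucleiSegmentation,
    pcrmp2: np.ndarray | None = None,
    params: NeuriteParams | None = None,
    restrict_labels: set[int] | None = None,
) -> NeuriteMeasurement:
    """Trace neurites and measure channel intensities on the skeleton.

    ``restrict_labels`` limits the somata that anchor skeleton components
    (e.g. the labels classified as MAP2-positive neurons); by default all
    nuclei anchor. No MAP2-positive pixels gives a zero-length
    measurement, not a failure.
    """
    params = params or NeuriteParams()
    map2 = np.asarray(map2, dtype=float)
    shape = map2.shape
    if map2.std() < 1e-9:
        return _empty(shape)

    thr = (
        params.map2_threshold
        if params.map2_threshold is not None
        else threshold_otsu(map2)
    )
    mask = map2 > thr
    if not mask.any() or mask.mean() > params.max_foreground_fraction:
        if mask.mean() > params.max_foreground_fraction:
            logger.warning(
                "MAP2 foreground fraction %.2f implausible; treating field "
                "as empty", mask.mean(),
            )
        return _empty(shape)

    soma_px = max(1, int(round(params.soma_margin_um / seg.pixel_size_um)))
    if restrict_labels is None:
        soma_nuclei = seg.labels > 0
    else:
        soma_nuclei = np.isin(seg.labels, sorted(restrict_labels))
    soma = dilation(soma_nuclei, disk_footprint(soma_px))

    neurite_mask = mask & ~soma
    skeleton = skeletonize(neurite_mask)
    if not skeleton.any():
        return _empty(shape)

    # retain only skeleton components that touch a soma
    comp_labels, n_comp = ndi.label(skeleton, structure=np.ones((3, 3)))
    touch = dilation(soma, disk_footprint(1))
    touching = np.unique(comp_labels[touch & (comp_labels > 0)])
    skeleton = np.isin(comp_labels, touching) & skeleton
    if not skeleton.any():
        return _empty(shape)

    map2_bg = float(np.median(map2))
    map2_vals = map2[skeleton]
    if pcrmp2 is not None:
        pcr = np.asarray(pcrmp2, dtype=float)
        pcr_bg = float(np.median(pcr))
        pcr_vals = pcr[skeleton]
    else:
        pcr_bg = 0.0
        pcr_vals = np.zeros_like(map2_vals)

    return NeuriteMeasurement(
        skeleton=skeleton,
        length_um=float(skeleton.sum()) * seg.pixel_size_um,
        map2_mean=float(map2_vals.mean()),
        pcrmp2_mean=float(pcr_vals.mean()),
        map2_mean_bgsub=float((map2_vals - map2_bg).mean()),
        pcrmp2_mean_bgsub=float((pcr_vals - pcr_bg).mean()),
        map2_total_bgsub=float(np.clip(map2 - map2_bg, 0, None).sum()),
        pcrmp2_total_bgsub=(
            float(np.clip(np.asarray(pcrmp2, dtype=float) - pcr_bg, 0, None).sum())
            if pcrmp2 is not None
            else 0.0
        ),
    )
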