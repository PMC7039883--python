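"""Seeded generator of three-channel plate images with ground truth.

Each field emulates a mixed hiPSC-derived neuronal culture imaged in three
channels (0: nuclear stain, 1: MAP2, 2: p-CRMP2 at T514):

* **neurons** — a bright nucleus plus several smoothed random-walk
  neurites radiating from the soma; neurites carry MAP2 signal, and
  p-CRMP2 signal proportional to MAP2 scaled by the well's suppression
  factor ``f`` (GSK3 inhibition lowers ``f``);
* **non-neuronal cells** — normally sized, bright nuclei with no MAP2;
* **debris** — nuclear blobs below the 50 um2 size band;
* **clumps** — nuclear blobs above the 160 um2 size band.

Suppression follows a Hill dose–response whose default is calibrated so
that lithium-like doses of 1 and 2.5 mM give 87.2% and 68.4% of control.
Toxic wells thin the neuron count via a per-dose multiplier. All output
is a pure function of the spec and its seed.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile
from skimage.draw import disk as draw_disk

CHANNEL_ORDER = ("nuclear", "map2", "pcrmp2")


class PlacementError(RuntimeError):
    """Objects could not be placed without overlap within the retry budget."""


@dataclass
class HillModel:
    """Dose–response factor f(dose) in (0, 1], decreasing with dose."""

    top: float = 1.0
    bottom: float = 0.0
    ec50: float = 4.634
    hill: float = 1.251

    def factor(self, dose: float) -> float:
        if dose <= 0:
            return self.top
        return self.bottom + (self.top - self.bottom) / (
            1.0 + (dose / self.ec50) ** self.hill
        )

    @classmethod
    def from_two_points(
        cls, d1: float, f1: float, d2: float, f2: float
    ) -> "HillModel":
        """Solve ec50 and hill exactly from two (dose, factor) anchors
        with top = 1 and bottom = 0."""
        r1 = 1.0 / f1 - 1.0
        r2 = 1.0 / f2 - 1.0
        hill = math.log(r2 / r1) / math.log(d2 / d1)
        ec50 = d1 * r1 ** (-1.0 / hill)
        return cls(top=1.0, bottom=0.0, ec50=ec50, hill=hill)


#: Default suppression model, anchored to 87.2% at 1 mM and 68.4% at 2.5 mM.
LITHIUM_SUPPRESSION = HillModel.from_two_points(1.0, 0.872, 2.5, 0.684)


@dataclass
class WellSpec:
    """Treatment of one well.

    ``suppression`` overrides the dose–response model when given;
    ``toxicity`` multiplies the expected neuron count (1 = benign).
    """

    compound: str
    dose: float
    role: str  # DMSO | positive_control | lithium_ref | test
    suppression: float | None = None
    toxicity: float = 1.0

    def __post_init__(self) -> None:
        if self.suppression is not None and not 0.0 < self.suppression <= 1.0:
            raise ValueError(f"suppression must be in (0, 1], got {self.suppression}")
        if not 0.0 <= self.toxicity <= 1.0:
            raise ValueError(f"toxicity must be in [0, 1], got {self.toxicity}")


@dataclass
class SyntheticPlateSpec:
    """Study conditions for a synthetic imaging plate.

    Intensities are on the 16-bit camera scale; MAP2/p-CRMP2 amplitudes
    are signal above the constant background. Object areas are drawn so
    debris falls below 50 um2, clumps above 160 um2 and cells inside the
    [50, 160] um2 band of the classifier.
    """

    wells: dict[str, WellSpec] = field(default_factory=dict)
    fields_per_well: int = 4
    image_shape: tuple[int, int] = (256, 256)
    pixel_size_um: float = 0.65
    n_neurons: int = 7
    n_nonneurons: int = 3
    n_debris: int = 2
    n_clumps: int = 1
    background: float = 200.0
    noise_sd: float = 20.0
    nuclear_mean: float = 3000.0
    nuclear_jitter: float = 0.1
    map2_amplitude: float = 1800.0
    neurites_per_neuron: int = 4
    neurite_steps: tuple[int, int] = (30, 60)
    neurite_width_px: int = 1  # dilation radius; width = 2*r + 1
    suppression_model: HillModel = field(
        default_factory=lambda: LITHIUM_SUPPRESSION
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if not 4 <= self.fields_per_well <= 6:
            raise ValueError(
                f"fields_per_well must be in [4, 6], got {self.fields_per_well}"
            )
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be > 0")
        for name in ("n_neurons", "n_nonneurons", "n_debris", "n_clumps"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    def well_suppression(self, well: WellSpec) -> float:
        if well.role == "DMSO":
            return 1.0
        if well.suppression is not None:
            return well.suppression
        return self.suppression_model.factor(well.dose)


@dataclass
class GroundTruthObject:
    """Per-object ground truth of one synthetic cell or artifact."""

    object_class: str  # neuron | non-neuron | debris | clump
    area_um2: float
    centroid: tuple[float, float]
    neurite_paths: list[np.ndarray] = field(default_factory=list)
    suppression: float = 1.0

    @property
    def neurite_length_px(self) -> int:
        return sum(len(p) for p in self.neurite_paths)


@dataclass
class FieldTruth:
    """Ground truth for one imaged field."""

    well: str
    field_index: int
    objects: list[GroundTruthObject]
    suppression: float

    def count(self, object_class: str) -> int:
        return sum(1 for o in self.objects if o.object_class == object_class)


@dataclass
class SyntheticField:
    image: np.ndarray  # (3, H, W) uint16
    truth: FieldTruth


# area bands (um2): debris < 50, cells in [50, 160], clumps > 160
_AREA_RANGES = {
    "neuron": (75.0, 145.0),
    "non-neuron": (75.0, 145.0),
    "debris": (15.0, 35.0),
    "clump": (210.0, 330.0),
}


def _radius_px(area_um2: float, pixel_size_um: float) -> int:
    area_px = area_um2 / pixel_size_um**2
    return max(2, int(round(math.sqrt(area_px / math.pi))))


def _place_centers(
    rng: np.random.Generator,
    shape: tuple[int, int],
    radii: list[int],
    max_tries: int = 400,
) -> list[tuple[int, int]]:
    centers: list[tuple[int, int]] = []
    for i, r in enumerate(radii):
        margin = r + 8
        for _ in range(max_tries):
            row = int(rng.integers(margin, shape[0] - margin))
            col = int(rng.integers(margin, shape[1] - margin))
            ok = all(
                math.hypot(row - cr, col - cc) >= r + radii[j] + 10
                for j, (cr, cc) in enumerate(centers)
            )
            if ok:
                centers.append((row, col))
                break
        else:
            raise PlacementError(
                f"could not place object {i} (radius {r}px) after "
                f"{max_tries} tries; image too crowded"
            )
    return centers


def _walk_neurite(
    rng: np.random.Generator,
    start: tuple[float, float],
    angle: float,
    n_steps: int,
    shape: tuple[int, int],
    forbidden: np.ndarray,
) -> np.ndarray:
    """Smoothed random walk; stops at the border or near a foreign nucleus."""
    path = []
    row, col = start
    for _ in range(n_steps):
        angle += rng.normal(0.0, 0.25)
        row += math.sin(angle)
        col += math.cos(angle)
        ir, ic = int(round(row)), int(round(col))
        if not (1 <= ir < shape[0] - 1 and 1 <= ic < shape[1] - 1):
            break
        if forbidden[ir, ic]:
            break
        path.append((ir, ic))
    return np.array(path, dtype=int).reshape(-1, 2)


def generate_field(
    spec: SyntheticPlateSpec,
    suppression: float,
    n_neurons: int,
    rng: np.random.Generator,
    well: str = "",
    field_index: int = 0,
) -> SyntheticField:
    """Render one field and its ground truth.

    p-CRMP2 signal on neurite pixels is ``suppression`` times the MAP2
    signal amplitude there; at zero camera noise the background-subtracted
    p-CRMP2/MAP2 ratio on true neurite pixels is exactly ``suppression``.
    """
    shape = spec.image_shape
    classes = (
        ["neuron"] * n_neurons
        + ["non-neuron"] * spec.n_nonneurons
        + ["debris"] * spec.n_debris
        + ["clump"] * spec.n_clumps
    )
    areas = [float(rng.uniform(*_AREA_RANGES[c])) for c in classes]
    radii = [_radius_px(a, spec.pixel_size_um) for a in areas]
    centers = _place_centers(rng, shape, radii)

    nuc_sig = np.zeros(shape, dtype=float)
    map2_sig = np.zeros(shape, dtype=float)
    pcr_sig = np.zeros(shape, dtype=float)
    nuclei_mask = np.zeros(shape, dtype=bool)

    # keep-out zones (nucleus + collar ring + margin) so neurites never
    # contaminate another cell's collar ring
    ring_px = max(1, int(round(2.0 / spec.pixel_size_um)))
    disks = []
    zones = []
    keepout = np.zeros(shape, dtype=bool)
    for (row, col), r in zip(centers, radii):
        rr, cc = draw_disk((row, col), r + 0.5, shape=shape)
        disks.append((rr, cc))
        nuclei_mask[rr, cc] = True
        zr, zc = draw_disk((row, col), r + ring_px + 3.5, shape=shape)
        zones.append((zr, zc))
        keepout[zr, zc] = True

    # offsets for stamping a (2w+1)-wide neurite around each path pixel
    w = spec.neurite_width_px
    stamp = np.array(
        [(dr, dc) for dr in range(-w, w + 1) for dc in range(-w, w + 1)
         if dr * dr + dc * dc <= w * w],
        dtype=int,
    )

    objects = []
    for i, (cls, (row, col), r, (rr, cc)) in enumerate(
        zip(classes, centers, radii, disks)
    ):
        level = spec.nuclear_mean * (
            1.0 + rng.uniform(-spec.nuclear_jitter, spec.nuclear_jitter)
        )
        nuc_sig[rr, cc] = level
        paths: list[np.ndarray] = []
        if cls == "neuron":
            forbidden = keepout.copy()
            forbidden[zones[i]] = False
            amp = spec.map2_amplitude * rng.uniform(0.9, 1.1)
            base_angle = rng.uniform(0, 2 * math.pi)
            for k in range(spec.neurites_per_neuron):
                angle = base_angle + 2 * math.pi * k / spec.neurites_per_neuron
                angle += rng.normal(0.0, 0.2)
                start = (row + (r - 1) * math.sin(angle),
                         col + (r - 1) * math.cos(angle))
                n_steps = int(rng.integers(*spec.neurite_steps))
                path = _walk_neurite(rng, start, angle, n_steps, shape, forbidden)
                if len(path) == 0:
                    continue
                paths.append(path)
                pr = np.clip(path[:, 0, None] + stamp[:, 0], 0, shape[0] - 1)
                pc = np.clip(path[:, 1, None] + stamp[:, 1], 0, shape[1] - 1)
                map2_sig[pr, pc] = np.maximum(map2_sig[pr, pc], amp)
                pcr_sig[pr, pc] = np.maximum(
                    pcr_sig[pr, pc], suppression * amp
                )
        area_um2 = float(len(rr)) * spec.pixel_size_um**2
        objects.append(
            GroundTruthObject(
                object_class=cls,
                area_um2=area_um2,
                centroid=(float(row), float(col)),
                neurite_paths=paths,
                suppression=suppression,
            )
        )

    image = np.empty((3, *shape), dtype=np.uint16)
    for ch, sig in enumerate((nuc_sig, map2_sig, pcr_sig)):
        plane = spec.background + sig
        if spec.noise_sd > 0:
            plane = plane + rng.normal(0.0, spec.noise_sd, size=shape)
        image[ch] = np.clip(plane, 0, 65535).astype(np.uint16)

    truth = FieldTruth(
        well=well, field_index=field_index, objects=objects,
        suppression=suppression,
    )
    return SyntheticField(image=image, truth=truth)


@dataclass
class SyntheticPlate:
    """All fields of a simulated plate plus its layout."""

    spec: SyntheticPlateSpec
    fields: dict[tuple[str, int], SyntheticField]

    def well_fields(self, well: str) -> list[SyntheticField]:
        return [
            f for (w, _), f in sorted(self.fields.items()) if w == well
        ]


def generate_plate(spec: SyntheticPlateSpec) -> SyntheticPlate:
    """Render every field of every well, deterministically from the seed."""
    root = np.random.SeedSequence(spec.seed)
    wells = sorted(spec.wells)
    children = root.spawn(len(wells) * spec.fields_per_well)
    fields: dict[tuple[str, int], SyntheticField] = {}
    idx = 0
    for well in wells:
        wspec = spec.wells[well]
        f = spec.well_suppression(wspec)
        for fi in range(spec.fields_per_well):
            rng = np.random.default_rng(children[idx])
            idx += 1
            n_neurons = (
                int(rng.binomial(spec.n_neurons, wspec.toxicity))
                if wspec.toxicity < 1.0
                else spec.n_neurons
            )
            fields[(well, fi)] = generate_field(
                spec, f, n_neurons, rng, well=well, field_index=fi
            )
    return SyntheticPlate(spec=spec, fields=fields)


def make_screen_layout(
    n_strong: int = 8,
    n_candidate: int = 8,
    n_inactive: int = 64,
    n_toxic: int = 8,
    n_dmso: int = 8,
    f_strong: float = 0.6,
    f_candidate: float = 0.85,
    toxic_multiplier: float = 0.2,
) -> dict[str, WellSpec]:
    """A 96-well single-plate screen layout with planted hit classes."""
    total = n_strong + n_candidate + n_inactive + n_toxic + n_dmso
    if total > 96:
        raise ValueError(f"layout needs {total} wells, a plate has 96")
    wells = [f"{r}{c:02d}" for r in "ABCDEFGH" for c in range(1, 13)]
    layout: dict[str, WellSpec] = {}
    specs = (
        [("DMSO", "DMSO", 1.0, 1.0)] * n_dmso
        + [("strong", "test", f_strong, 1.0)] * n_strong
        + [("candidate", "test", f_candidate, 1.0)] * n_candidate
        + [("inactive", "test", 1.0, 1.0)] * n_inactive
        + [("toxic", "test", 1.0, toxic_multiplier)] * n_toxic
    )
    for well, (group, role, f, tox) in zip(wells, specs):
        layout[well] = WellSpec(
            compound=f"{group}_{well}", dose=10.0, role=role,
            suppression=f, toxicity=tox,
        )
    return layout


def write_plate(plate: SyntheticPlate, outdir: str | Path) -> None:
    """Write per-field multi-channel TIFFs, a layout CSV and truth JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for (well, fi), fld in sorted(plate.fields.items()):
        tifffile.imwrite(
            outdir / f"{well}_f{fi}.tif", fld.image,
            photometric="minisblack", planarconfig="separate",
        )
    with open(outdir / "layout.csv", "w") as fh:
        fh.write("well,compound,dose,role\n")
        for well in sorted(plate.spec.wells):
            w = plate.spec.wells[well]
            fh.write(f"{well},{w.compound},{w.dose},{w.role}\n")
    truth = {
        f"{well}_f{fi}": {
            "suppression": fld.truth.suppression,
            "objects": [
                {
                    "class": o.object_class,
                    "area_um2": o.area_um2,
                    "centroid": list(o.centroid),
                    "neurite_length_px": o.neurite_length_px,
                }
                for o in fld.truth.objects
            ],
        }
        for (well, fi), fld in sorted(plate.fields.items())
    }
    with open(outdir / "ground_truth.json", "w") as fh:
        json.dump(truth, fh, indent=1)
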