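"""Neurite tracing and the per-well percent p-CRMP2/MAP2 readout."""

import numpy as np
import pytest
from skimage.draw import disk

from gsk3screen.imaging.neurites import trace_neurites
from gsk3screen.imaging.segment import segment_nuclei
from gsk3screen.imaging.wells import (
    HCIConfig,
    analyze_field,
    measure_well,
)
from gsk3screen.synth.plate_sim import (
    SyntheticPlateSpec,
    WellSpec,
    generate_field,
)

PX = 0.65


def _nucleus_image(center=(50, 20), radius=8, shape=(100, 160)):
    img = np.full(shape, 200.0)
    rr, cc = disk(center, radius, shape=shape)
    img[rr, cc] = 3000.0
    return img


def test_somata_without_processes_give_zero_length():
    nuclear = _nucleus_image()
    map2 = np.full(nuclear.shape, 200.0)
    rr, cc = disk((50, 20), 10, shape=nuclear.shape)
    map2[rr, cc] = 2000.0  # MAP2 confined to the soma
    seg = segment_nuclei(nuclear, PX)
    m = trace_neurites(map2, seg)
    assert m.n_pixels == 0
    assert m.length_um == 0.0


def test_straight_neurite_skeleton_length_and_containment():
    nuclear = _nucleus_image()
    map2 = np.full(nuclear.shape, 200.0)
    # 100 px straight neurite, 3 px wide, starting just past the soma margin
    map2[49:52, 31:131] = 2000.0
    seg = segment_nuclei(nuclear, PX)
    m = trace_neurites(map2, seg)
    assert m.n_pixels == pytest.approx(100, abs=2)
    from skimage.filters import threshold_otsu

    mask = map2 > threshold_otsu(map2)
    assert not (m.skeleton & ~mask).any()  # skeleton inside MAP2 mask


def test_disconnected_map2_fragments_are_discarded():
    nuclear = _nucleus_image()
    map2 = np.full(nuclear.shape, 200.0)
    map2[49:52, 28:60] = 2000.0  # attached neurite
    map2[10:13, 100:140] = 2000.0  # free-floating fragment
    seg = segment_nuclei(nuclear, PX)
    m = trace_neurites(map2, seg)
    assert m.skeleton[11, 100:140].sum() == 0
    assert m.skeleton[50, 30:55].sum() > 0


def test_blank_map2_gives_zero_measurement_not_failure():
    nuclear = _nucleus_image()
    rng = np.random.default_rng(0)
    map2 = 200.0 + rng.normal(0, 20, size=nuclear.shape)
    seg = segment_nuclei(nuclear, PX)
    m = trace_neurites(map2, seg)
    assert m.n_pixels == 0


def _analyzed_fields(spec, f, n_fields, seed0=0, transform=None):
    config = HCIConfig(pixel_size_um=spec.pixel_size_um)
    fields = []
    for s in range(n_fields):
        rng = np.random.default_rng(seed0 + s)
        field = generate_field(spec, f, spec.n_neurons, rng)
        img = field.image.astype(float)
        if transform is not None:
            img = transform(img)
        fields.append(analyze_field(img, config))
    return fields


@pytest.fixture(scope="module")
def noise_free_spec():
    return SyntheticPlateSpec(
        wells={"A01": WellSpec("d", 0.0, "DMSO")}, noise_sd=0.0
    )


def test_identical_channels_give_percent_100(noise_free_spec):
    def equalize(img):
        img[2] = img[1]
        return img

    fields = _analyzed_fields(noise_free_spec, 1.0, 2, transform=equalize)
    result = measure_well("A01", fields)
    assert result.percent_pcrmp2 == pytest.approx(100.0, abs=1e-6)


def test_halved_pcrmp2_gives_percent_50(noise_free_spec):
    fields = _analyzed_fields(noise_free_spec, 0.5, 2)
    result = measure_well("A01", fields)
    assert result.percent_pcrmp2 == pytest.approx(50.0, abs=1.0)


def test_scale_invariance_of_the_percent_readout(noise_free_spec):
    fields = _analyzed_fields(noise_free_spec, 0.8, 2)
    base = measure_well("A01", fields).percent_pcrmp2

    def scale_both(img):
        img[1] *= 3.0
        img[2] *= 3.0
        return img

    scaled = measure_well(
        "A01", _analyzed_fields(noise_free_spec, 0.8, 2, transform=scale_both)
    ).percent_pcrmp2
    assert scaled == pytest.approx(base, rel=0.02)

    def scale_pcrmp2(img):
        img[2] = 200.0 + 0.5 * (img[2] - 200.0)  # halve the signal only
        return img

    halved = measure_well(
        "A01", _analyzed_fields(noise_free_spec, 0.8, 2, transform=scale_pcrmp2)
    ).percent_pcrmp2
    assert halved == pytest.approx(0.5 * base, rel=0.05)


def test_zero_neurons_gives_typed_missing_percent():
    spec = SyntheticPlateSpec(
        wells={"A01": WellSpec("d", 0.0, "DMSO")},
        n_nonneurons=2, n_debris=1, n_clumps=0,
    )
    config = HCIConfig()
    fields = [
        analyze_field(
            generate_field(spec, 1.0, 0, np.random.default_rng(s)).image, config
        )
        for s in range(2)
    ]
    result = measure_well("A01", fields)
    assert result.percent_pcrmp2 is None
    assert result.neuron_count == 0


def test_neuron_counts_match_ground_truth_within_one(single_well_spec):
    config = HCIConfig()
    for seed in range(5):
        rng = np.random.default_rng(seed)
        field = generate_field(single_well_spec, 1.0, 7, rng)
        fa = analyze_field(field.image, config)
        assert abs(fa.neuron_count - field.truth.count("neuron")) <= 1


def test_suppression_monotonicity_in_expectation(single_well_spec):
    """Well percent decreases as the planted suppression factor drops."""
    config = HCIConfig()
    percents = []
    for f in (1.0, 0.8, 0.6, 0.4):
        fields = []
        for s in range(3):
            rng = np.random.default_rng(100 + s)
            fields.append(
                analyze_field(
                    generate_field(single_well_spec, f, 7, rng).image, config
                )
            )
        percents.append(measure_well("W", fields).percent_pcrmp2)
    assert percents == sorted(percents, reverse=True)
    slope = np.polyfit([1.0, 0.8, 0.6, 0.4], percents, 1)[0]
    assert slope > 0  # percent rises with f, i.e. falls with dose


def test_whole_field_mode_needs_no_gating(noise_free_spec):
    fields = _analyzed_fields(noise_free_spec, 0.5, 2)
    result = measure_well("A01", fields, mode="whole-field")
    assert result.percent_pcrmp2 == pytest.approx(50.0, abs=3.0)
    with pytest.raises(ValueError):
        measure_well("A01", fields, mode="bogus")
    with pytest.raises(ValueError):
        measure_well("A01", [])
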