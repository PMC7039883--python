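"""Plate-level analytics: normalization, Z', hit bands, t-test stars."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gsk3screen.imaging.wells import WellResult
from gsk3screen.screen import (
    BandConfig,
    PlateLayout,
    ReferenceError,
    call_hits,
    normalize_to_reference,
    stars_from_p,
    unpaired_ttest,
    zprime,
)


def _layout():
    wells = {}
    for i in range(1, 5):
        wells[f"A{i:02d}"] = ("DMSO", 0.0, "DMSO")
    for i in range(5, 9):
        wells[f"A{i:02d}"] = ("cmpd", 10.0, "test")
    wells["B01"] = ("lithium", 1.0, "lithium_ref")
    wells["B02"] = ("lithium", 1.0, "lithium_ref")
    return PlateLayout(wells=wells)


def _wells(values, counts=None):
    counts = counts or [40] * len(values)
    return [
        WellResult(well=w, n_fields=4, neuron_count=c, percent_pcrmp2=v)
        for (w, v), c in zip(values.items(), counts)
    ]


def test_well_equal_to_dmso_mean_normalizes_to_100():
    wells = _wells({"A01": 60.0, "A02": 60.0, "A03": 60.0, "A04": 60.0,
                    "A05": 60.0})
    normalized = normalize_to_reference(wells, _layout(), mode="dmso")
    assert normalized[4].normalized_percent == pytest.approx(100.0)


def test_raw_30_against_dmso_mean_60_gives_50():
    wells = _wells({"A01": 60.0, "A02": 60.0, "A03": 60.0, "A04": 60.0,
                    "A05": 30.0})
    normalized = normalize_to_reference(wells, _layout(), mode="dmso")
    assert normalized[4].normalized_percent == pytest.approx(50.0)


def test_all_well_average_mode_averages_to_100_exactly():
    rng = np.random.default_rng(1)
    values = {f"A{i:02d}": float(v) for i, v in
              enumerate(rng.uniform(20, 90, size=8), start=1)}
    normalized = normalize_to_reference(_wells(values), _layout(),
                                        mode="all_well_average")
    mean = np.mean([n.normalized_percent for n in normalized])
    assert mean == pytest.approx(100.0, abs=1e-12)


def test_lithium_reference_mode_uses_lithium_wells():
    values = {"A01": 80.0, "B01": 40.0, "B02": 60.0}
    normalized = normalize_to_reference(_wells(values), _layout(),
                                        mode="lithium_1mM")
    assert normalized[0].normalized_percent == pytest.approx(160.0)


def test_normalization_is_idempotent():
    values = {"A01": 60.0, "A02": 80.0, "A05": 40.0}
    once = normalize_to_reference(_wells(values), _layout(), mode="dmso")
    again = normalize_to_reference(
        [
            WellResult(n.well, 4, 40, n.normalized_percent)
            for n in once
        ],
        _layout(),
        mode="dmso",
    )
    for a, b in zip(once, again):
        assert b.normalized_percent == pytest.approx(a.normalized_percent)


def test_missing_reference_is_a_typed_error():
    wells = _wells({"A05": 50.0})  # no DMSO wells measured
    with pytest.raises(ReferenceError, match="dmso"):
        normalize_to_reference(wells, _layout(), mode="dmso")
    with pytest.raises(ReferenceError):
        normalize_to_reference(wells, _layout(), mode="nonsense")


def test_zprime_closed_forms():
    rng = np.random.default_rng(0)
    neg = list(100.0 + 4.0 * _unit_sd(rng, 24))
    pos = list(20.0 + 2.0 * _unit_sd(rng, 24))
    assert zprime(pos, neg).value == pytest.approx(1 - 18 / 80, abs=1e-12)

    assert zprime([20.0, 20.0], [100.0, 100.0]).value == 1.0

    neg = list(100.0 + 20.0 * _unit_sd(rng, 16))
    pos = list(80.0 + 20.0 * _unit_sd(rng, 16))
    assert zprime(pos, neg).value == pytest.approx(-5.0, abs=1e-12)


def _unit_sd(rng, n):
    """Samples rescaled to mean 0 and sample sd exactly 1."""
    x = rng.normal(size=n)
    x = x - x.mean()
    return x / x.std(ddof=1)


def test_zprime_equal_means_is_typed_undefined():
    result = zprime([50.0, 51.0], [50.5, 50.5])
    assert not result.defined
    assert result.value is None
    with pytest.raises(ValueError):
        zprime([1.0], [2.0, 3.0])


@settings(deadline=None, max_examples=50, derandomize=True)
@given(
    sd_pos=st.floats(0.0, 30.0),
    sd_neg=st.floats(0.0, 30.0),
)
def test_zprime_is_at_most_one_and_decreases_with_spread(sd_pos, sd_neg):
    rng = np.random.default_rng(7)
    pos = 20.0 + sd_pos * _unit_sd(rng, 12)
    neg = 100.0 + sd_neg * _unit_sd(rng, 12)
    value = zprime(list(pos), list(neg)).value
    assert value <= 1.0 + 1e-12
    if sd_pos == 0.0 and sd_neg == 0.0:
        assert value == 1.0
    wider = zprime(list(20.0 + (sd_pos + 1.0) * _unit_sd(rng, 12)), list(neg))
    assert wider.value < value + 1e-9


def test_hit_bands_and_toxicity_override():
    calls = call_hits(
        {"inert": [100.0, 99.0], "cand": [85.0, 86.0], "strong": [60.0],
         "tox": [85.0]},
        {"inert": 1.0, "cand": 0.9, "strong": 0.9, "tox": 0.3},
    )
    bands = {c.compound: c.band for c in calls}
    assert bands == {"inert": "inactive", "cand": "candidate",
                     "strong": "strong", "tox": "toxic"}


def test_every_nontoxic_compound_gets_exactly_one_monotone_band():
    means = np.linspace(40, 120, 33)
    calls = call_hits(
        {f"c{i}": [float(m)] for i, m in enumerate(means)},
        {f"c{i}": 1.0 for i in range(len(means))},
    )
    by_mean = sorted(calls, key=lambda c: c.mean_percent)
    order = {"strong": 0, "candidate": 1, "inactive": 2}
    ranks = [order[c.band] for c in by_mean]
    assert ranks == sorted(ranks)
    assert {c.band for c in by_mean if c.mean_percent < 80} == {"strong"}
    assert {c.band for c in by_mean if 80 <= c.mean_percent < 90} == {"candidate"}
    assert {c.band for c in by_mean if c.mean_percent >= 90} == {"inactive"}


def test_band_config_rejects_non_increasing_edges():
    with pytest.raises(ValueError):
        BandConfig(strong_below=90.0, candidate_below=80.0)


def test_identical_groups_give_t0_p1_no_stars():
    result = unpaired_ttest([5.0, 5.0, 5.0], [5.0, 5.0, 5.0])
    assert result.t == 0.0
    assert result.p == 1.0
    assert result.stars == ""


def test_pooled_t_on_123_vs_456_gives_one_star():
    result = unpaired_ttest([1.0, 2.0, 3.0], [4.0, 5.0, 6.0])
    assert abs(result.t) == pytest.approx(3.674, abs=1e-3)
    assert result.df == 4
    assert result.p == pytest.approx(0.0213, abs=5e-4)
    assert result.stars == "*"


def test_star_bands_match_printed_boundaries():
    assert stars_from_p(0.06) == ""
    assert stars_from_p(0.05) == ""
    assert stars_from_p(0.049) == "*"
    assert stars_from_p(0.01) == "*"  # inclusive lower edge of the * band
    assert stars_from_p(0.001) == "**"
    assert stars_from_p(5e-4) == "***"
    assert stars_from_p(1e-4) == "***"
    assert stars_from_p(5e-5) == "****"


@settings(deadline=None, max_examples=100, derandomize=True)
@given(st.floats(1e-12, 1.0))
def test_star_mapping_is_a_nonincreasing_step_function(p):
    smaller = stars_from_p(p * 0.5)
    assert len(smaller) >= len(stars_from_p(p))


def test_welch_option_changes_df():
    a = [1.0, 2.0, 3.0, 4.0]
    b = [10.0, 30.0, 50.0]
    pooled = unpaired_ttest(a, b)
    welch = unpaired_ttest(a, b, equal_var=False)
    assert pooled.df == 5
    assert welch.df < pooled.df
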