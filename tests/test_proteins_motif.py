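"""Per-protein summaries, site queries and motif extraction."""

import numpy as np
import pytest

from gsk3screen.phospho import (  # noqa: F401
    count_regulated_per_protein,
    extract_motif_matrix,
    filter_phosphopeptides,
    normalize_ratios,
    site_ratio_query,
)
from gsk3screen.phospho.regulation import (
    test_regulation as score_regulation,
)
from gsk3screen.phospho.records import PhosphoSite
from gsk3screen.synth.phospho_sim import (
    SyntheticPhosphoSpec,
    generate_phospho_table,
)

from conftest import make_record


def _scored_table(records, **kwargs):
    return score_regulation(normalize_ratios(records), "CHIR_10uM", **kwargs)


def test_empty_regulated_set_gives_empty_summary():
    table = _scored_table([make_record("p1")])
    assert count_regulated_per_protein(table, [make_record("p1")]) == []


def test_counts_merge_groups_and_sort_by_count_then_key():
    down = {("CHIR_10uM", 1): 0.25, ("CHIR_10uM", 2): 0.26,
            ("CHIR_1uM", 1): 1.0, ("CHIR_1uM", 2): 1.0}
    flat = {("CHIR_10uM", 1): 1.0, ("CHIR_10uM", 2): 1.0,
            ("CHIR_1uM", 1): 1.0, ("CHIR_1uM", 2): 1.0}
    records = [
        make_record("a1", protein="GSK3B", gene="GSK3B", ratios=down),
        make_record("a2", protein="GSK3A", gene="GSK3A", ratios=down),
        make_record("b1", protein="MAP1B", gene="MAP1B", ratios=down),
        make_record("b2", protein="MAP1B", gene="MAP1B", ratios=down),
        make_record("b3", protein="MAP1B", gene="MAP1B", ratios=down),
        make_record("c1", protein="AAA1", gene="AAA1", ratios=down),
        make_record("c2", protein="AAA1", gene="AAA1", ratios=down),
        make_record("null", protein="MAP1B", gene="MAP1B", ratios=flat),
    ]
    table = _scored_table(records)
    regulated = {"a1", "a2", "b1", "b2", "b3", "c1", "c2"}
    summaries = count_regulated_per_protein(
        table, records, min_peptides=2, regulated_ids=regulated
    )
    assert [(s.protein_key, s.n_regulated_peptides) for s in summaries] == [
        ("MAP1B", 3),
        ("AAA1", 2),
        ("GSK3A/GSK3B", 2),  # the paralogs count as one protein
    ]


def test_min_peptides_threshold_filters_and_validates():
    table = _scored_table([make_record("p1")])
    with pytest.raises(ValueError):
        count_regulated_per_protein(table, [make_record("p1")], min_peptides=0)


def test_site_query_missing_site_is_typed_not_found():
    records = [make_record("p1")]
    table = _scored_table(records)
    result = site_ratio_query(table, records, "GSK3B", "S9")
    assert not result.found
    assert len(result.channels) == 0


def test_site_query_returns_normalized_ratio():
    # three peptides keep channel medians at 0 so the hit stays at -0.5
    records = [
        make_record("hit", protein="GSK3B", gene="GSK3B", position=9,
                    ratios={("CHIR_10uM", 1): 2.0 ** -0.5}),
        make_record("n1", ratios={("CHIR_10uM", 1): 1.0}),
        make_record("n2", ratios={("CHIR_10uM", 1): 1.0}),
        make_record("n3", ratios={("CHIR_10uM", 1): 1.0}),
    ]
    table = _scored_table(records)
    result = site_ratio_query(table, records, "GSK3B", "S9")
    assert result.found
    assert result.channels.loc["hit", "log2_CHIR_10uM_r1"] == pytest.approx(-0.5)
    assert result.mean_log2("CHIR_10uM") == pytest.approx(-0.5)


def test_single_window_has_unit_frequencies():
    seq = "AAAASGGGTPAAA"
    records = [
        make_record("p1", protein="P1", sequence=seq, position=5, residue="S")
    ]
    matrix = extract_motif_matrix(records, {"p1"}, {"P1": seq}, window=13)
    assert matrix.n_windows == 1
    freq = matrix.frequencies
    assert freq.loc["S", 0] == 1.0
    assert freq.loc["T", 4] == 1.0
    assert freq.loc["A", -1] == 1.0
    # window is centred: position -4 holds the first A of the sequence
    assert freq.loc["A", -4] == 1.0


def test_two_windows_split_only_at_the_differing_position():
    seq_g = "AAAAAASAAAGAAA"
    seq_p = "AAAAAASAAAPAAA"  # differs at offset +4 from the S at pos 7
    records = [
        make_record("g", protein="PG", sequence=seq_g, position=7, residue="S"),
        make_record("p", protein="PP", sequence=seq_p, position=7, residue="S"),
    ]
    matrix = extract_motif_matrix(
        records, {"g", "p"}, {"PG": seq_g, "PP": seq_p}, window=13
    )
    freq = matrix.frequencies
    assert freq.loc["G", 4] == 0.5
    assert freq.loc["P", 4] == 0.5
    assert freq.loc["A", 3] == 1.0
    assert freq.loc["S", 0] == 1.0


def test_windows_at_termini_are_gap_padded_and_gaps_excluded():
    seq = "SAAAT"  # site at position 1: 6 leading gaps in a 13-window
    records = [
        make_record("p1", protein="P1", sequence=seq, position=1, residue="S")
    ]
    matrix = extract_motif_matrix(records, {"p1"}, {"P1": seq}, window=13)
    assert matrix.counts.loc["-", -6] == 1
    assert matrix.frequencies[-6].isna().all()  # gap-only column
    assert matrix.frequencies.loc["T", 4] == 1.0


def test_out_of_range_site_is_skipped_and_counted():
    records = [
        make_record("bad", protein="P1", position=50, residue="S"),
        make_record("good", protein="P1", sequence="AAAASAAAA", position=5),
    ]
    sequences = {"P1": "AAAASAAAA"}
    matrix = extract_motif_matrix(records, {"bad", "good"}, sequences)
    assert matrix.n_windows == 1
    assert matrix.n_skipped == 1


def test_column_sums_and_center_residue_invariants():
    table = generate_phospho_table(SyntheticPhosphoSpec(n_peptides=400, seed=13))
    kept = filter_phosphopeptides(table.records)
    reg = score_regulation(normalize_ratios(kept), "CHIR_10uM",
                          method="moderated")
    down = {
        pid for pid in reg.significant_ids
        if reg.data.loc[pid, "direction"] == "down"
    }
    matrix = extract_motif_matrix(kept, down, table.protein_sequences)
    assert matrix.n_windows > 10
    sums = matrix.frequencies.sum(axis=0, skipna=True)
    for off, total in sums.items():
        if matrix.counts.loc["-", off] < matrix.n_windows:
            assert total == pytest.approx(1.0)
    center = matrix.frequencies[0]
    assert center.loc["S"] + center.loc["T"] == pytest.approx(1.0)


def test_planted_consensus_is_recovered_at_offsets_0_and_4():
    table = generate_phospho_table(SyntheticPhosphoSpec(n_peptides=600, seed=2))
    kept = filter_phosphopeptides(table.records)
    reg = score_regulation(normalize_ratios(kept), "CHIR_10uM",
                          method="moderated")
    down = {
        pid for pid in reg.significant_ids
        if reg.data.loc[pid, "direction"] == "down"
    }
    matrix = extract_motif_matrix(kept, down, table.protein_sequences)
    assert matrix.modal_residue(0) in ("S", "T")
    assert matrix.modal_residue(4) in ("S", "T")
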