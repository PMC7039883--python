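"""The four-rule phosphopeptide filter cascade.

A phosphopeptide is retained only if it satisfies all of:

1. identified in both SILAC experiments;
2. not a decoy;
3. carries at least one fully localized phosphosite;
4. quantified in both replicates for at least one treatment condition.

The rules are conjunctive, so the retained set is invariant to the order
in which they are applied. Rule 1 concerns identification evidence
(``experiment_ids``); rule 4 concerns ratio quantification — a peptide can
be identified in an experiment without yielding a usable ratio there.
"""

from __future__ import annotations

from collections.abc import Iterable

from .records import CONDITIONS, PhosphoPeptideRecord


def filter_phosphopeptides(
    records: list[PhosphoPeptideRecord],
    required_experiments: Iterable[str] | None = None,
) -> list[PhosphoPeptideRecord]:
    """Apply the filter cascade; input order is preserved.

    Parameters
    ----------
    records
        Validated phosphopeptide records.
    required_experiments
        Experiments a peptide must have been identified in. Defaults to
        the union of experiment IDs observed across the whole table.
    """
    if required_experiments is None:
        required: set[str] = set()
        for rec in records:
            required |= rec.experiment_ids
    else:
        required = set(required_experiments)

    kept = []
    for rec in records:
        if not required <= rec.experiment_ids:
            continue
        if rec.decoy:
            continue
        if not rec.has_localized_site():
            continue
        if not any(rec.quantified_in_both_replicates(c) for c in CONDITIONS):
            continue
        kept.append(rec)
    return kept
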