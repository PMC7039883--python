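"""Per-protein regulation summaries and site-level ratio queries."""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .records import CHANNELS, PhosphoPeptideRecord
from .regulation import RegulationTable, log2_column

#: Paralogs whose phosphopeptides are indistinguishable and counted as one
#: protein: GSK3 alpha and beta share the regulated peptides here.
DEFAULT_MERGE_GROUPS: tuple[frozenset[str], ...] = (
    frozenset({"GSK3A", "GSK3B"}),
)


@dataclass(frozen=True)
class ProteinSummary:
    """A (possibly merged) protein with its regulated-peptide count."""

    protein_key: str
    gene_symbol: str
    n_regulated_peptides: int


def _protein_key(
    rec: PhosphoPeptideRecord, merge_groups: tuple[frozenset[str], ...]
) -> tuple[str, str]:
    """Assign a record to a merged group label or its first accession."""
    names = set(rec.protein_ids) | {rec.gene_symbol}
    for group in merge_groups:
        if names & group:
            label = "/".join(sorted(group))
            return label, label
    return rec.protein_ids[0] if rec.protein_ids else rec.gene_symbol, rec.gene_symbol


def count_regulated_per_protein(
    table: RegulationTable,
    records: list[PhosphoPeptideRecord],
    min_peptides: int = 1,
    merge_groups: tuple[frozenset[str], ...] | None = DEFAULT_MERGE_GROUPS,
    regulated_ids: set[str] | None = None,
    alpha: float = 0.05,
) -> list[ProteinSummary]:
    """Count distinct regulated phosphopeptides per (merged) protein.

    ``regulated_ids`` defaults to the nominally regulated set
    (p_nom < ``alpha``), the set the per-protein rankings are built from.
    Only proteins with at least ``min_peptides`` regulated peptides are
    returned, sorted by count descending, ties broken lexicographically
    by protein key.
    """
    if min_peptides < 1:
        raise ValueError(f"min_peptides must be >= 1, got {min_peptides}")
    merge_groups = merge_groups or ()
    if regulated_ids is None:
        regulated_ids = table.nominally_regulated_ids(alpha)

    counts: dict[str, set[str]] = {}
    genes: dict[str, str] = {}
    for rec in records:
        if rec.peptide_id not in regulated_ids:
            continue
        key, gene = _protein_key(rec, merge_groups)
        counts.setdefault(key, set()).add(rec.peptide_id)
        genes.setdefault(key, gene)

    summaries = [
        ProteinSummary(key, genes[key], len(pids))
        for key, pids in counts.items()
        if len(pids) >= min_peptides
    ]
    summaries.sort(key=lambda s: (-s.n_regulated_peptides, s.protein_key))
    return summaries


@dataclass
class SiteRatioResult:
    """Normalized log2 ratios of all peptides covering a queried site.

    An empty query is a typed not-found outcome (``found`` is False),
    never an error.
    """

    protein_key: str
    site: str
    channels: pd.DataFrame = field(default_factory=pd.DataFrame)

    @property
    def found(self) -> bool:
        return len(self.channels) > 0

    def mean_log2(self, condition: str) -> float:
        cols = [c for c in self.channels.columns if c.startswith(f"log2_{condition}_")]
        return float(self.channels[cols].stack().mean())


def site_ratio_query(
    table: RegulationTable,
    records: list[PhosphoPeptideRecord],
    protein_key: str,
    site: str,
) -> SiteRatioResult:
    """Look up per-channel normalized log2 ratios for one phosphosite.

    ``site`` is residue + 1-based position, e.g. ``"S9"`` or ``"Y216"``.
    Matches any peptide mapped to ``protein_key`` (accession or gene
    symbol) carrying that phosphosite.
    """
    residue, position = site[0], int(site[1:])
    hits = []
    for rec in records:
        if protein_key not in rec.protein_ids and protein_key != rec.gene_symbol:
            continue
        if not any(
            s.residue == residue and s.position == position for s in rec.phosphosites
        ):
            continue
        if rec.peptide_id in table.data.index:
            hits.append(rec.peptide_id)
    cols = [log2_column(c, r) for c, r in CHANNELS]
    channels = table.data.loc[hits, cols] if hits else pd.DataFrame(columns=cols)
    return SiteRatioResult(protein_key=protein_key, site=site, channels=channels)
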