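"""Domain records for quantified phosphopeptides.

A :class:`PhosphoPeptideRecord` is one row of a searched, quantified
phosphopeptide table: the peptide sequence, the proteins it maps to, its
phosphosite assignments (with per-site localization confidence), a decoy
flag, the SILAC experiments in which it was identified, and its
treated/control abundance ratios per treatment condition and replicate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

#: SILAC treatment conditions quantified against the vehicle control.
CONDITIONS: tuple[str, ...] = ("CHIR_1uM", "CHIR_10uM")

#: Biological replicate experiments (one SILAC label swap each).
REPLICATES: tuple[int, ...] = (1, 2)

#: All quantification channels, as (condition, replicate) keys.
CHANNELS: tuple[tuple[str, int], ...] = tuple(
    (c, r) for c in CONDITIONS for r in REPLICATES
)

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
GAP = "-"


class ValidationError(ValueError):
    """A record violates a structural invariant of the table."""


@dataclass(frozen=True)
class PhosphoSite:
    """One phosphorylated residue on a protein.

    Parameters
    ----------
    residue
        Single-letter code, one of S/T/Y.
    position
        1-based position in the protein sequence.
    localized
        Whether the site assignment passed the search engine's
        localization criterion ("fully localized").
    """

    residue: str
    position: int
    localized: bool

    def __post_init__(self) -> None:
        if self.residue not in "STY":
            raise ValidationError(
                f"phosphosite residue must be S, T or Y, got {self.residue!r}"
            )
        if self.position < 1:
            raise ValidationError(
                f"phosphosite position must be >= 1, got {self.position}"
            )


@dataclass
class PhosphoPeptideRecord:
    """One quantified phosphopeptide with per-channel SILAC ratios.

    ``ratios`` maps ``(condition, replicate)`` to the treated/control
    abundance ratio; missing channels are simply absent from the map
    (never stored as zero). ``experiment_ids`` collects the SILAC
    experiments in which the peptide was identified, which is distinct
    from (and weaker than) being *quantified* in a channel.
    """

    peptide_id: str
    sequence: str
    protein_ids: tuple[str, ...]
    gene_symbol: str
    phosphosites: tuple[PhosphoSite, ...]
    decoy: bool
    experiment_ids: frozenset[str]
    ratios: dict[tuple[str, int], float] = field(default_factory=dict)

    def validate(self) -> None:
        """Raise :class:`ValidationError` on any invariant violation."""
        if not self.sequence or any(a not in AMINO_ACIDS for a in self.sequence):
            raise ValidationError(
                f"peptide {self.peptide_id}: sequence must be uppercase "
                f"single-letter amino acids, got {self.sequence!r}"
            )
        for key, value in self.ratios.items():
            if key not in CHANNELS:
                raise ValidationError(
                    f"peptide {self.peptide_id}: unknown channel {key!r}"
                )
            if not value > 0:
                raise ValidationError(
                    f"peptide {self.peptide_id}: ratio for {key} must be "
                    f"positive, got {value}"
                )

    def has_localized_site(self) -> bool:
        return any(s.localized for s in self.phosphosites)

    def quantified_in_both_replicates(self, condition: str) -> bool:
        return all((condition, r) in self.ratios for r in REPLICATES)


def validate_table(records: list[PhosphoPeptideRecord]) -> None:
    """Validate every record and the table-level uniqueness invariant."""
    seen: set[str] = set()
    for rec in records:
        rec.validate()
        if rec.peptide_id in seen:
            raise ValidationError(f"duplicate peptide_id {rec.peptide_id!r}")
        seen.add(rec.peptide_id)
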