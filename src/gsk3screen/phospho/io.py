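"""Reading and writing phosphopeptide tables.

The on-disk format is a plain TSV/CSV with one row per phosphopeptide. A
*dialect* maps the logical fields to the concrete column names of a given
export (a search-engine site-comparison export, or the synthetic
generator's own table), so both load through the same code path.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from .records import CHANNELS, PhosphoPeptideRecord, PhosphoSite, ValidationError


class MissingColumnError(KeyError):
    """A required column is absent from the table."""


@dataclass
class TableDialect:
    """Column mapping for a phosphopeptide table.

    ``ratio_columns`` maps each ``(condition, replicate)`` channel to its
    column name. ``list_sep`` separates multi-valued cells (protein IDs,
    experiment IDs, phosphosites).
    """

    peptide_id: str = "peptide_id"
    sequence: str = "sequence"
    protein_ids: str = "protein_ids"
    gene_symbol: str = "gene_symbol"
    phosphosites: str = "phosphosites"
    decoy: str = "decoy"
    experiment_ids: str = "experiment_ids"
    ratio_columns: dict[tuple[str, int], str] = field(default_factory=dict)
    list_sep: str = ";"

    def __post_init__(self) -> None:
        if not self.ratio_columns:
            self.ratio_columns = {
                (cond, rep): f"ratio_{cond}_r{rep}" for cond, rep in CHANNELS
            }

    @classmethod
    def from_file(cls, path: str | Path) -> "TableDialect":
        """Load a dialect from a YAML or JSON mapping file.

        Ratio columns are given under ``ratio_columns`` as
        ``"<condition>/<replicate>": "<column>"`` entries.
        """
        path = Path(path)
        with open(path) as fh:
            raw = json.load(fh) if path.suffix == ".json" else yaml.safe_load(fh)
        ratio_raw = raw.pop("ratio_columns", {})
        ratio_columns = {}
        for key, col in ratio_raw.items():
            cond, rep = key.rsplit("/", 1)
            ratio_columns[(cond, int(rep))] = col
        return cls(ratio_columns=ratio_columns, **raw)


def _parse_sites(cell: str, sep: str) -> tuple[PhosphoSite, ...]:
    # serialized as e.g. "S45:1;T52:0" (residue, 1-based position, localized)
    sites = []
    for token in str(cell).split(sep):
        token = token.strip()
        if not token:
            continue
        body, loc = token.rsplit(":", 1)
        sites.append(PhosphoSite(body[0], int(body[1:]), loc == "1"))
    return tuple(sites)


def _format_sites(sites: tuple[PhosphoSite, ...], sep: str) -> str:
    return sep.join(
        f"{s.residue}{s.position}:{1 if s.localized else 0}" for s in sites
    )


def load_phosphopeptide_table(
    path: str | Path, dialect: TableDialect | None = None
) -> list[PhosphoPeptideRecord]:
    """Load a TSV/CSV phosphopeptide table into validated records.

    Missing ratio cells become absent map entries, never zeros. Raises
    :class:`MissingColumnError` naming the first absent required column,
    and :class:`~gsk3screen.phospho.records.ValidationError` (naming the
    peptide) for non-positive ratios or malformed sites.
    """
    dialect = dialect or TableDialect()
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)

    required = [
        dialect.peptide_id,
        dialect.sequence,
        dialect.protein_ids,
        dialect.gene_symbol,
        dialect.phosphosites,
        dialect.decoy,
        dialect.experiment_ids,
        *dialect.ratio_columns.values(),
    ]
    for col in required:
        if col not in df.columns:
            raise MissingColumnError(f"required column {col!r} not found in {path}")

    records = []
    for _, row in df.iterrows():
        pid = row[dialect.peptide_id]
        ratios: dict[tuple[str, int], float] = {}
        for channel, col in dialect.ratio_columns.items():
            cell = row[col].strip()
            if cell == "" or cell.upper() in ("NA", "NAN"):
                continue
            try:
                value = float(cell)
            except ValueError as exc:
                raise ValidationError(
                    f"peptide {pid}: unparseable ratio {cell!r} in column {col}"
                ) from exc
            if not value > 0:
                raise ValidationError(
                    f"peptide {pid}: ratio in column {col} must be positive, "
                    f"got {value}"
                )
            ratios[channel] = value
        rec = PhosphoPeptideRecord(
            peptide_id=pid,
            sequence=row[dialect.sequence],
            protein_ids=tuple(
                p for p in row[dialect.protein_ids].split(dialect.list_sep) if p
            ),
            gene_symbol=row[dialect.gene_symbol],
            phosphosites=_parse_sites(row[dialect.phosphosites], dialect.list_sep),
            decoy=str(row[dialect.decoy]).strip() in ("1", "True", "true", "TRUE"),
            experiment_ids=frozenset(
                e for e in row[dialect.experiment_ids].split(dialect.list_sep) if e
            ),
            ratios=ratios,
        )
        rec.validate()
        records.append(rec)
    return records


def write_phosphopeptide_table(
    records: list[PhosphoPeptideRecord],
    path: str | Path,
    dialect: TableDialect | None = None,
) -> None:
    """Write records to TSV/CSV in the given dialect (round-trip safe)."""
    dialect = dialect or TableDialect()
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    rows = []
    for rec in records:
        row = {
            dialect.peptide_id: rec.peptide_id,
            dialect.sequence: rec.sequence,
            dialect.protein_ids: dialect.list_sep.join(rec.protein_ids),
            dialect.gene_symbol: rec.gene_symbol,
            dialect.phosphosites: _format_sites(rec.phosphosites, dialect.list_sep),
            dialect.decoy: int(rec.decoy),
            dialect.experiment_ids: dialect.list_sep.join(sorted(rec.experiment_ids)),
        }
        for channel, col in dialect.ratio_columns.items():
            row[col] = repr(rec.ratios[channel]) if channel in rec.ratios else ""
        rows.append(row)
    if not rows:
        # header-only table: keep the full column set so it reloads
        d = dialect
        columns = [
            d.peptide_id, d.sequence, d.protein_ids, d.gene_symbol,
            d.phosphosites, d.decoy, d.experiment_ids,
            *d.ratio_columns.values(),
        ]
        pd.DataFrame(columns=columns).to_csv(path, sep=sep, index=False)
        return
    pd.DataFrame(rows).to_csv(path, sep=sep, index=False)
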