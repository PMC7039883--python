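"""Phospho-motif extraction around regulated sites.

GSK3 phosphorylates Ser/Thr residues four positions N-terminal of a primed
phospho-Ser/Thr (the S/T-X-X-X-pS/T consensus). To recover this signature,
sequence windows are cut from the parent protein around every fully
localized down-regulated S/T site and stacked into a position frequency
matrix. Windows extending past a protein terminus are padded with a gap
symbol; gaps are excluded from the per-column frequencies.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .records import AMINO_ACIDS, GAP, PhosphoPeptideRecord

logger = logging.getLogger(__name__)


@dataclass
class MotifMatrix:
    """Position count and frequency matrices for aligned site windows.

    Rows are amino acids (plus the gap row in ``counts``); columns are
    positions relative to the phosphosite, ``-w .. +w`` for a window of
    length ``2w + 1``. ``frequencies`` excludes gaps, so each column with
    any non-gap observation sums to 1.
    """

    window_length: int
    counts: pd.DataFrame
    frequencies: pd.DataFrame
    n_windows: int
    n_skipped: int

    def modal_residue(self, offset: int) -> str:
        """Most frequent residue at a position offset from the site."""
        return str(self.frequencies[offset].idxmax())

    def to_tsv(self, path) -> None:
        self.frequencies.to_csv(path, sep="\t", index_label="residue")

    def plot(self, ax=None):
        """Render the frequency matrix as a stacked bar chart."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(8, 3))
        bottom = np.zeros(self.frequencies.shape[1])
        for residue, row in self.frequencies.iterrows():
            ax.bar(self.frequencies.columns, row.values, bottom=bottom,
                   label=residue, width=0.8)
            bottom += row.values
        ax.set_xlabel("position relative to phosphosite")
        ax.set_ylabel("frequency")
        return ax


def extract_motif_matrix(
    records: list[PhosphoPeptideRecord],
    regulated_down: set[str],
    protein_sequences: dict[str, str],
    window: int = 13,
) -> MotifMatrix:
    """Build the position frequency matrix of down-regulated S/T sites.

    One window per fully localized S/T phosphosite on a peptide in
    ``regulated_down``, centered on the site in its parent protein
    sequence (first mapped accession with a known sequence). Sites whose
    position falls outside the protein sequence are skipped with a
    warning and counted in ``n_skipped``.
    """
    if window < 9 or window % 2 == 0:
        raise ValueError(f"window must be an odd integer >= 9, got {window}")
    half = window // 2
    offsets = list(range(-half, half + 1))
    rows = list(AMINO_ACIDS) + [GAP]
    counts = pd.DataFrame(0, index=rows, columns=offsets, dtype=int)

    n_windows = 0
    n_skipped = 0
    for rec in records:
        if rec.peptide_id not in regulated_down:
            continue
        seq = next(
            (protein_sequences[p] for p in rec.protein_ids if p in protein_sequences),
            None,
        )
        if seq is None:
            n_skipped += 1
            logger.warning("peptide %s: no protein sequence available", rec.peptide_id)
            continue
        for site in rec.phosphosites:
            if not site.localized or site.residue not in "ST":
                continue
            idx = site.position - 1
            if idx < 0 or idx >= len(seq) or seq[idx] != site.residue:
                n_skipped += 1
                logger.warning(
                    "peptide %s: site %s%d outside or inconsistent with its "
                    "protein sequence; skipped", rec.peptide_id, site.residue,
                    site.position,
                )
                continue
            for off in offsets:
                j = idx + off
                aa = seq[j] if 0 <= j < len(seq) else GAP
                counts.loc[aa, off] += 1
            n_windows += 1

    nongap = counts.loc[list(AMINO_ACIDS)]
    col_totals = nongap.sum(axis=0)
    frequencies = nongap.div(col_totals.where(col_totals > 0, other=np.nan), axis=1)
    return MotifMatrix(
        window_length=window,
        counts=counts,
        frequencies=frequencies,
        n_windows=n_windows,
        n_skipped=n_skipped,
    )
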