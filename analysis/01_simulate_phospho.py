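"""Simulate the SILAC phosphoproteomics dataset.

Writes the default synthetic phosphopeptide table (1,000 peptides, 20%
true GSK3 substrates with the planted S/T-X-X-X-S/T context and
dose-dependent log2 down-shifts) plus its ground truth, ready for the
regulation analysis in the next step.
"""

import json
from pathlib import Path

from gsk3screen import phospho
from gsk3screen.synth.phospho_sim import (
    SyntheticPhosphoSpec,
    generate_phospho_table,
)

ROOT = Path(__file__).resolve().parents[1]
OUT = ROOT / "results"
SEED = 20260930


def main() -> None:
    OUT.mkdir(exist_ok=True)
    spec = SyntheticPhosphoSpec(seed=SEED)
    table = generate_phospho_table(spec)
    phospho.write_phosphopeptide_table(
        table.records, OUT / "phospho_table.tsv"
    )
    with open(OUT / "phospho_truth.json", "w") as fh:
        json.dump(
            {
                "true_substrates": sorted(table.true_substrates),
                "protein_sequences": table.protein_sequences,
                "seed": SEED,
            },
            fh,
        )
    n_decoy = sum(r.decoy for r in table.records)
    print(
        f"wrote {len(table.records)} phosphopeptides "
        f"({len(table.true_substrates)} true substrates, {n_decoy} decoys) "
        f"to {OUT / 'phospho_table.tsv'}"
    )


if __name__ == "__main__":
    main()
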