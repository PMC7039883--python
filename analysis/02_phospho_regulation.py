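"""Filter, normalize and test the simulated phosphoproteome.

Reproduces the discovery arm end to end: the four-rule filter cascade,
per-channel median normalization in log2 space, the moderated one-sample
regulation test with Benjamini–Hochberg correction, per-protein
regulated-peptide counts (GSK3 paralogs merged), the phospho-motif
position frequency matrix of down-regulated sites, and connected
components of a planted interaction network over the top proteins.
"""

import json
from pathlib import Path

from gsk3screen import phospho
from gsk3screen.phospho.regulation import test_regulation
from gsk3screen.synth.edges import plant_interaction_edges, write_edge_list

ROOT = Path(__file__).resolve().parents[1]
OUT = ROOT / "results"
SEED = 20260930


def main() -> None:
    records = phospho.load_phosphopeptide_table(OUT / "phospho_table.tsv")
    truth = json.loads((OUT / "phospho_truth.json").read_text())

    kept = phospho.filter_phosphopeptides(records)
    table = test_regulation(
        phospho.normalize_ratios(kept), "CHIR_10uM", alpha=0.05,
        method="moderated",
    )
    table.to_tsv(OUT / "regulation.tsv")
    table.volcano_frame().to_csv(OUT / "volcano.tsv", sep="\t")

    true_set = set(truth["true_substrates"])
    called = table.significant_ids
    kept_truth = true_set & {r.peptide_id for r in kept}
    sens = len(called & kept_truth) / len(kept_truth)
    fdr = len(called - true_set) / max(1, len(called))
    print(
        f"{len(records)} loaded -> {len(kept)} retained by the cascade; "
        f"{len(called)} significant at BH 0.05 "
        f"(sensitivity {sens:.2f}, FDR {fdr:.3f} vs planted truth)"
    )

    summaries = phospho.count_regulated_per_protein(
        table, kept, min_peptides=3,
        regulated_ids=called,
    )
    with open(OUT / "proteins_min3.tsv", "w") as fh:
        fh.write("protein\tgene_symbol\tn_regulated_peptides\n")
        for s in summaries:
            fh.write(
                f"{s.protein_key}\t{s.gene_symbol}\t{s.n_regulated_peptides}\n"
            )
    print(f"{len(summaries)} proteins carry >= 3 regulated phosphopeptides")

    down = {
        pid for pid in called
        if table.data.loc[pid, "direction"] == "down"
    }
    matrix = phospho.extract_motif_matrix(
        kept, down, truth["protein_sequences"]
    )
    matrix.to_tsv(OUT / "motif_pfm.tsv")
    print(
        f"motif PFM from {matrix.n_windows} windows: modal residue "
        f"{matrix.modal_residue(0)} at the site, "
        f"{matrix.modal_residue(4)} at +4 (GSK3 priming consensus)"
    )

    proteins = [s.protein_key for s in phospho.count_regulated_per_protein(
        table, kept, min_peptides=2, regulated_ids=called
    )]
    edges = plant_interaction_edges(
        proteins, n_connected=max(2, int(round(0.41 * len(proteins)))),
        n_components=3, seed=SEED,
    )
    edge_path = OUT / "ppi_edges.tsv"
    write_edge_list(edges, edge_path)
    net = phospho.build_interaction_network(set(proteins), edge_path)
    net.components_frame().to_csv(
        OUT / "network_components.tsv", sep="\t", index=False
    )
    print(
        f"interaction network: {len(net.connected_nodes)}/{len(proteins)} "
        f"proteins connected ({100 * net.fraction_connected:.0f}%) in "
        f"{len(net.components)} submodules"
    )


if __name__ == "__main__":
    main()
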