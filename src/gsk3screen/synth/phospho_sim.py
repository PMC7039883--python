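"""Seeded generator of SILAC phosphopeptide tables with planted truth.

The generator emulates the statistical structure the downstream pipeline
assumes: a minority of peptides are true kinase substrates carrying the
GSK3 consensus context (S/T-X-X-X-S/T around the phosphosite) and a
dose-dependent negative log2 ratio shift; the rest are centred at zero.
Decoys, peptides without a fully localized site, peptides seen in only
one SILAC experiment, and per-channel missing ratios are injected at
configurable rates so the filter cascade has real work to do.

Everything is a pure function of the spec (including its seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..phospho.records import (
    AMINO_ACIDS,
    CHANNELS,
    CONDITIONS,
    PhosphoPeptideRecord,
    PhosphoSite,
)


@dataclass
class SyntheticPhosphoSpec:
    """Study conditions for a synthetic SILAC phosphopeptide table.

    Effect sizes are mean log2 down-shifts per condition for true
    substrates; noise is per-replicate Gaussian on the log2 scale.
    """

    n_peptides: int = 1000
    fraction_true_substrates: float = 0.2
    effect_size: dict[str, float] = field(
        default_factory=lambda: {"CHIR_1uM": -0.8, "CHIR_10uM": -1.5}
    )
    noise_sd: float = 0.3
    decoy_rate: float = 0.05
    unlocalized_rate: float = 0.10
    single_experiment_rate: float = 0.05
    missingness: float = 0.05
    motif_plant_rate: float = 0.9
    peptides_per_protein: int = 5
    protein_length: int = 80
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("fraction_true_substrates", "decoy_rate", "unlocalized_rate",
                     "single_experiment_rate", "missingness", "motif_plant_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.noise_sd < 0:
            raise ValueError(f"noise_sd must be >= 0, got {self.noise_sd}")
        if self.n_peptides < 0:
            raise ValueError(f"n_peptides must be >= 0, got {self.n_peptides}")


@dataclass
class SyntheticPhosphoTable:
    """Generator output: records plus ground truth."""

    records: list[PhosphoPeptideRecord]
    true_substrates: set[str]
    protein_sequences: dict[str, str]


_AA = np.array(list(AMINO_ACIDS))
_ST = np.array(["S", "T"])

EXPERIMENTS = ("EXP1", "EXP2")


def _random_sequence(rng: np.random.Generator, length: int) -> list[str]:
    return list(rng.choice(_AA, size=length))


def generate_phospho_table(spec: SyntheticPhosphoSpec) -> SyntheticPhosphoTable:
    """Generate a phosphopeptide table with planted true substrates.

    True substrates receive the consensus context (S/T at the site, S/T
    at +4, planted at ``motif_plant_rate``) and condition-specific log2
    down-shifts; every peptide's per-channel log2 ratio is the effect
    plus N(0, noise_sd) noise, exponentiated back to a positive ratio.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_peptides
    if n == 0:
        return SyntheticPhosphoTable([], set(), {})

    n_proteins = max(1, n // spec.peptides_per_protein)
    proteins = {}
    for p in range(n_proteins):
        proteins[f"SYNP{p:05d}"] = _random_sequence(rng, spec.protein_length)

    protein_ids = sorted(proteins)
    records: list[PhosphoPeptideRecord] = []
    truth: set[str] = set()

    is_substrate = rng.random(n) < spec.fraction_true_substrates
    is_decoy = rng.random(n) < spec.decoy_rate
    is_unlocalized = rng.random(n) < spec.unlocalized_rate
    is_single_exp = rng.random(n) < spec.single_experiment_rate

    for i in range(n):
        acc = protein_ids[int(rng.integers(0, n_proteins))]
        seq = proteins[acc]
        # site away from the termini so most windows need no gap padding
        pos = int(rng.integers(8, spec.protein_length - 8))  # 0-based
        substrate = bool(is_substrate[i]) and not bool(is_decoy[i])
        if substrate:
            seq[pos] = str(rng.choice(_ST))
            if rng.random() < spec.motif_plant_rate:
                seq[pos + 4] = str(rng.choice(_ST))
        else:
            # non-substrate phosphosites are still S/T/Y, mostly S/T
            seq[pos] = str(rng.choice(np.array(["S", "T", "Y"]),
                                      p=[0.55, 0.35, 0.10]))

        ratios: dict[tuple[str, int], float] = {}
        for cond in CONDITIONS:
            effect = spec.effect_size[cond] if substrate else 0.0
            for rep in (1, 2):
                log2r = effect + (
                    rng.normal(0.0, spec.noise_sd) if spec.noise_sd > 0 else 0.0
                )
                ratios[(cond, rep)] = float(2.0 ** log2r)
        for channel in list(ratios):
            if rng.random() < spec.missingness:
                del ratios[channel]

        pep_start = max(0, pos - 7)
        pep_end = min(spec.protein_length, pos + 8)
        pid = f"pep{i:05d}"
        site = PhosphoSite(
            residue=seq[pos],
            position=pos + 1,
            localized=not bool(is_unlocalized[i]),
        )
        experiments = (
            frozenset({EXPERIMENTS[int(rng.integers(0, 2))]})
            if is_single_exp[i]
            else frozenset(EXPERIMENTS)
        )
        rec = PhosphoPeptideRecord(
            peptide_id=pid,
            sequence="".join(seq[pep_start:pep_end]),
            protein_ids=(acc,),
            gene_symbol=acc,
            phosphosites=(site,),
            decoy=bool(is_decoy[i]),
            experiment_ids=experiments,
            ratios=ratios,
        )
        records.append(rec)
        if substrate:
            truth.add(pid)

    sequences = {acc: "".join(seq) for acc, seq in proteins.items()}
    return SyntheticPhosphoTable(
        records=records, true_substrates=truth, protein_sequences=sequences
    )
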