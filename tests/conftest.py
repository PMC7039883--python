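import numpy as np
import pytest

from gsk3screen.phospho.records import PhosphoPeptideRecord, PhosphoSite
from gsk3screen.synth.phospho_sim import (
    SyntheticPhosphoSpec,
    generate_phospho_table,
)
from gsk3screen.synth.plate_sim import SyntheticPlateSpec, WellSpec


def make_record(
    pid,
    decoy=False,
    experiments=("EXP1", "EXP2"),
    localized=True,
    ratios=None,
    protein="PROT1",
    gene="GENE1",
    sequence="AAASPAAK",
    position=4,
    residue="S",
):
    """Minimal valid record with the given deviations."""
    if ratios is None:
        ratios = {
            ("CHIR_1uM", 1): 1.0,
            ("CHIR_1uM", 2): 1.0,
            ("CHIR_10uM", 1): 1.0,
            ("CHIR_10uM", 2): 1.0,
        }
    return PhosphoPeptideRecord(
        peptide_id=pid,
        sequence=sequence,
        protein_ids=(protein,),
        gene_symbol=gene,
        phosphosites=(PhosphoSite(residue, position, localized),),
        decoy=decoy,
        experiment_ids=frozenset(experiments),
        ratios=dict(ratios),
    )


@pytest.fixture
def synthetic_table():
    return generate_phospho_table(SyntheticPhosphoSpec(n_peptides=500, seed=3))


@pytest.fixture
def single_well_spec():
    return SyntheticPlateSpec(
        wells={"A01": WellSpec(compound="DMSO", dose=0.0, role="DMSO")},
        seed=5,
    )


@pytest.fixture
def field_rng():
    return np.random.default_rng(17)
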