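import numpy as np
import pytest

from snrnatail.readproc import Molecule
from snrnatail.refmodel import GeneModel, GeneRegistry


@pytest.fixture
def u1toy() -> GeneModel:
    """Tiny gene model with known bases at every position around the mature end."""
    return GeneModel(
        gene_id="U1toy",
        mature_seq="GGAAGCAUCUG",
        downstream_seq="GUUUCAAAG",
        anchor_len=6,
        category="major_snRNA",
    )


@pytest.fixture
def toy_reg(u1toy) -> GeneRegistry:
    other = GeneModel(
        gene_id="U2toy",
        mature_seq="CCGUACGUUACG",
        downstream_seq="CGCGCGCG",
        anchor_len=6,
        category="major_snRNA",
    )
    return GeneRegistry([u1toy, other])


def make_molecule(model: GeneModel, end: int, tail: str = "") -> Molecule:
    """Error-free molecule with a given true end and tail."""
    from snrnatail.simulate import molecule_insert

    return Molecule(
        gene_id=model.gene_id,
        insert=molecule_insert(model, end, tail),
        umi="ACGUACGUAC",
        barcode="ACGU",
        n_reads=1,
    )


def random_gene_model(rng: np.random.Generator, gene_id: str, downstream_alphabet="ACGU"):
    mature = "".join(rng.choice(list("ACGU"), size=int(rng.integers(20, 45))))
    downstream = "".join(
        rng.choice(list(downstream_alphabet), size=int(rng.integers(6, 16)))
    )
    return GeneModel(
        gene_id=gene_id,
        mature_seq=mature,
        downstream_seq=downstream,
        anchor_len=8,
        category="major_snRNA",
    )
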