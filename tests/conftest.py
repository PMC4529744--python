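import numpy as np
import pandas as pd
import pytest

from messi.model_io import (
    GenotypeMatrix,
    MetaboliteTable,
    PathwayDefinition,
    StrainSet,
    VariantRecord,
)


def make_genotypes(G, chrom="chr1", positions=None, spacing=100, gene_ids=None,
                   effects=None):
    """Small GenotypeMatrix from a variants x strains 0/1 (or -1) array."""
    G = np.asarray(G, dtype=np.int8)
    m, n = G.shape
    if positions is None:
        positions = [1000 + spacing * i for i in range(m)]
    strains = StrainSet(tuple(f"S{i:02d}" for i in range(n)))
    variants = [
        VariantRecord(
            chromosome=chrom,
            position=positions[i],
            variant_type="SNP",
            ref_allele="A",
            alt_allele="T",
            gene_id=None if gene_ids is None else gene_ids[i],
            effect_class="other" if effects is None else effects[i],
        )
        for i in range(m)
    ]
    return GenotypeMatrix(strains=strains, variants=variants, presence=G)


def make_metabolites(values, compounds=None):
    """MetaboliteTable from a strains x compounds array (NaN = missing)."""
    arr = np.asarray(values, dtype=float)
    n, k = arr.shape
    strains = StrainSet(tuple(f"S{i:02d}" for i in range(n)))
    if compounds is None:
        compounds = [f"C{j:05d}" for j in range(1, k + 1)]
    df = pd.DataFrame(arr, index=list(strains.strain_ids), columns=compounds)
    return MetaboliteTable(strains=strains, abundance=df)


def make_pathway(pid, compounds, universal=False, name=None):
    return PathwayDefinition(
        pathway_id=pid,
        name=name or pid,
        compounds=frozenset(compounds),
        universal=universal,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(42)
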