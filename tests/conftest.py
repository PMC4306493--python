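import numpy as np
import pandas as pd
import pytest

from enzatlas.simulate import SimConfig, generate
from enzatlas.types import CPCMatrix, PathwayMap, ReactionNetwork


@pytest.fixture(scope="session")
def default_dataset():
    """One default-condition synthetic dataset shared across tests."""
    return generate(SimConfig(seed=11))


@pytest.fixture(scope="session")
def small_config():
    """A small, fast configuration without the glycolysis block."""
    return SimConfig(
        n_proteins=80, n_cell_lines=10, metabolic_fraction=0.5,
        planted_pathways=(("PW_A", 6, 4.0),),
        n_metabolites=30, n_reactions=16,
        planted_branches=(("B1", 2, 0.9), ("B2", 3, 0.1)),
        include_glycolysis=False, rare_fraction=0.05, seed=7,
    )


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return generate(small_config)


def make_cpc(values: dict, cell_lines, tissues) -> CPCMatrix:
    """Tiny CPCMatrix from a {protein: [row values]} dict (None = absent)."""
    df = pd.DataFrame(
        {cl: [np.nan if row[j] is None else float(row[j])
              for row in values.values()]
         for j, cl in enumerate(cell_lines)},
        index=pd.Index(list(values), name="protein_id"),
    )
    return CPCMatrix(df, pd.Series(tissues, index=list(cell_lines)))


def make_network(reactions: dict, meta: dict | None = None) -> ReactionNetwork:
    """Network from {rid: ([reactants], [products])} plus optional metadata
    {rid: (reversible, enzyme_id, pathway_id)}."""
    rows = []
    for rid, (reac, prod) in reactions.items():
        rows += [{"reaction_id": rid, "metabolite_id": m, "coefficient": -1.0}
                 for m in reac]
        rows += [{"reaction_id": rid, "metabolite_id": m, "coefficient": 1.0}
                 for m in prod]
    meta = meta or {}
    meta_rows = [
        {"reaction_id": rid,
         "reversible": meta.get(rid, (0, "", ""))[0],
         "enzyme_id": meta.get(rid, (0, "", ""))[1],
         "pathway_id": meta.get(rid, (0, "", ""))[2]}
        for rid in reactions
    ]
    return ReactionNetwork(pd.DataFrame(rows), pd.DataFrame(meta_rows))


def make_pathway_map(pairs) -> PathwayMap:
    return PathwayMap(pd.DataFrame(pairs, columns=["pathway_id", "protein_id"]))
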