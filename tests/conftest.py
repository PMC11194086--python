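import numpy as np
import pandas as pd
import pytest

from senoscore import qc, syndata


@pytest.fixture(scope="session")
def small_population():
    """A modest population with planted modules, shared across tests."""
    cfg = syndata.SimConfig(
        seed=42,
        n_cells=600,
        n_genes=500,
        module_sizes={"maturation": 60, "isg": 30, "sasp": 20},
        module_loadings={"maturation": 0.9, "isg": 0.6, "sasp": 0.0},
    )
    return syndata.generate_cell_population(cfg)


@pytest.fixture(scope="session")
def small_landscape():
    return syndata.generate_regulatory_landscape(
        syndata.LandscapeConfig(
            seed=7,
            n_promoter_sites=10,
            n_intervening_sites=14,
            n_boundary_sites=8,
            n_other_sites=8,
            n_extra_promoters=8,
            n_extra_enhancers=8,
            n_inactive_tss=10,
            n_null_regions=60,
        )
    )


@pytest.fixture(scope="session")
def null_population():
    """No planted signal: every module loading is zero."""
    cfg = syndata.SimConfig(
        seed=9,
        n_cells=500,
        n_genes=400,
        module_sizes={"maturation": 30, "isg": 20, "sasp": 10},
        module_loadings={"maturation": 0.0, "isg": 0.0, "sasp": 0.0},
    )
    return syndata.generate_cell_population(cfg)


def toy_counts(matrix, genes=None, cells=None, meta=None) -> qc.CountMatrix:
    matrix = np.asarray(matrix)
    g, c = matrix.shape
    genes = genes if genes is not None else [f"g{i}" for i in range(g)]
    cells = cells if cells is not None else [f"c{i}" for i in range(c)]
    if meta is None:
        meta = pd.DataFrame(
            {"donor": ["d1"] * c, "tech": ["t1"] * c},
            index=pd.Index(cells, name="cell_id"),
        )
    return qc.CountMatrix(counts=matrix, gene_names=genes, cell_ids=cells, cell_meta=meta)
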