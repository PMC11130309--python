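import numpy as np
import pandas as pd
import pytest

from tamscreen import qc, simulate

MYELOID_TYPES = {"TAM_C0", "TAM_C1", "TAM_C3", "TAM_C4", "Mono_C2", "Mono_C5"}

#: generator truth cell type -> lineage label the rule table should produce
LINEAGE_OF_TYPE = {
    "malignant": "malignant",
    "T_cm": "Tcm", "T_reg": "Treg", "CD8_naive": "CD8_naive",
    "T_prolif": "T_prolif", "NK": "NK", "B": "B", "pDC": "pDC",
    "fibroblast": "fibroblast", "endothelial": "endothelial",
    **{t: "monocyte/macrophage" for t in MYELOID_TYPES},
}


@pytest.fixture(scope="session")
def small_experiment():
    """One sample per arm, 400 cells each: fast substrate for unit tests."""
    cfg = simulate.default_config(seed=11, cells_per_sample=400,
                                  n_samples_per_arm=1)
    return simulate.generate_experiment(cfg)


@pytest.fixture(scope="session")
def small_normalized(small_experiment):
    keep = qc.filter_cells(small_experiment.counts, small_experiment.genes)
    counts = small_experiment.counts[np.flatnonzero(keep)]
    meta = small_experiment.cell_meta.loc[keep]
    norm = qc.normalize_log(counts, genes=small_experiment.genes)
    return norm, meta


def lineage_truth(cell_meta: pd.DataFrame) -> pd.Series:
    return cell_meta["cell_type"].map(LINEAGE_OF_TYPE)
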