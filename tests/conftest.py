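import numpy as np
import pandas as pd
import pytest

from myoaging import simulate as sim


@pytest.fixture(scope="session")
def small_composition_truth():
    """5 cell types, 10 donors x 2 libraries, one real age effect."""
    rng = np.random.default_rng(1)
    cts = [f"CT{i}" for i in range(5)]
    return sim.CompositionTruth(
        cell_types=cts,
        n_donors=10,
        ages=[float(a) for a in np.concatenate([rng.uniform(20, 40, 5), rng.uniform(60, 75, 5)])],
        baseline_log_abundance={c: np.log(100.0) for c in cts},
        age_logfc={cts[0]: 0.5},
        libraries_per_donor=2,
    )


@pytest.fixture(scope="session")
def expression_design():
    """4 donors per age group, 2 libraries each."""
    rng = np.random.default_rng(2)
    truth = sim.CompositionTruth(
        cell_types=["a", "b"],
        n_donors=8,
        ages=[float(a) for a in np.concatenate([rng.uniform(20, 40, 4), rng.uniform(60, 75, 4)])],
        baseline_log_abundance={"a": 0.0, "b": 0.0},
        age_logfc={},
        libraries_per_donor=2,
    )
    return sim._library_design(truth)


@pytest.fixture(scope="session")
def small_expression(expression_design):
    """60-gene panel, 3 spiked aging DEGs, MYH programs on 3 clusters."""
    truth = sim.ExpressionTruth(
        n_genes=60,
        n_cells_per_sample=50,
        deg_indices=(0, 1, 2),
        deg_log2fc={0: 1.5, 1: 1.5, 2: -1.5},
        dispersion=2.0,
        donor_re_sd=0.1,
        myh_profile={0: (0.0, 0.0, 5.0), 1: (0.0, 5.0, 0.0), 2: (5.0, 0.0, 0.0)},
    )
    return sim.simulate_expression(truth, expression_design, seed=11), truth
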