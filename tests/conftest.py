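import numpy as np
import pandas as pd
import pytest

from oilcomm.core_io import AbundanceTable, SampleMetadata, tree_from_newick


@pytest.fixture
def two_leaf_tree():
    return tree_from_newick("(A:1,B:1):0;")


@pytest.fixture
def star_tree4():
    return tree_from_newick("(A:1,B:1,C:1,D:1):0;")


def make_metadata(sample_ids, treatments, days, replicates=None):
    if replicates is None:
        replicates = list(range(1, len(sample_ids) + 1))
    return SampleMetadata(
        pd.DataFrame(
            {
                "sample_id": sample_ids,
                "treatment": treatments,
                "day": days,
                "replicate": replicates,
            }
        ).set_index("sample_id")
    )


def make_table(values, taxa=None, samples=None, mode="counts"):
    values = np.asarray(values, dtype=float)
    taxa = taxa or [f"t{i}" for i in range(values.shape[0])]
    samples = samples or [f"s{j}" for j in range(values.shape[1])]
    return AbundanceTable(
        pd.DataFrame(values, index=taxa, columns=samples), mode=mode
    )


@pytest.fixture
def design_metadata():
    """6 samples: two treatments x one day x 3 replicates."""
    return make_metadata(
        [f"s{j}" for j in range(6)],
        ["WAF"] * 3 + ["CEWAF"] * 3,
        [0] * 6,
        [1, 2, 3, 1, 2, 3],
    )


def random_proportions_table(rng, n_taxa, n_samples, taxa=None):
    X = rng.dirichlet(np.ones(n_taxa), size=n_samples).T
    return make_table(X, taxa=taxa, mode="proportions")
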