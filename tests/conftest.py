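import numpy as np
import pandas as pd
import pytest

from pathlmm import GeneratorSpec, QuantTable, filter_pathways, generate_dataset


def make_design(n_ind=4, T=3, conditions=("A", "B")):
    rows = []
    for t in range(T):
        for i in range(n_ind):
            rows.append((
                f"i{i}_t{t}", f"i{i}", f"t{t}",
                conditions[i % len(conditions)],
            ))
    return pd.DataFrame(
        rows, columns=["sample_id", "individual", "time", "condition"]
    ).set_index("sample_id")


def make_quant_table(n_ind=4, T=3, n_met=6, seed=0, conditions=("A", "B")):
    rng = np.random.default_rng(seed)
    design = make_design(n_ind, T, conditions)
    values = pd.DataFrame(
        rng.lognormal(1.0, 0.4, size=(len(design), n_met)),
        index=design.index,
        columns=[f"m{j + 1}" for j in range(n_met)],
    )
    return QuantTable(values, design)


@pytest.fixture
def toy_qt():
    return make_quant_table()


@pytest.fixture(scope="session")
def base_dataset():
    """Default-sized synthetic base with filtered pathways (seed 1)."""
    qt, ps = generate_dataset(GeneratorSpec(seed=1))
    return qt, filter_pathways(ps, qt)


@pytest.fixture(scope="session")
def small_dataset():
    """Small, quick dataset for end-to-end tests."""
    spec = GeneratorSpec(
        n_individuals=10, n_metabolites=40, n_pathways=12,
        size_range=(2, 10), seed=3,
    )
    qt, ps = generate_dataset(spec)
    return qt, filter_pathways(ps, qt)
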