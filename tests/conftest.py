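import numpy as np
import pandas as pd
import pytest

from sedshift import synthetic, tables_io


@pytest.fixture(scope="session")
def scenario():
    """One deterministic two-regime sediment-core scenario shared by the suite."""
    return synthetic.transition_scenario(seed=11)


@pytest.fixture(scope="session")
def scenario_community(scenario):
    _, table = scenario
    return tables_io.to_relative(table)


def make_table(counts, ages, taxonomy=None, sample_prefix="s"):
    counts = np.asarray(counts)
    samples = [f"{sample_prefix}{i}" for i in range(counts.shape[0])]
    taxa = [f"t{j}" for j in range(counts.shape[1])]
    tax = None if taxonomy is None else pd.Series(taxonomy, index=taxa)
    return tables_io.TaxonTable(
        counts=pd.DataFrame(counts, index=samples, columns=taxa),
        ages=pd.Series(np.asarray(ages, dtype=float), index=samples),
        taxonomy=tax,
    )


@pytest.fixture
def two_by_two():
    return make_table([[3, 1], [2, 2]], [1300.0, 1400.0])
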