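import numpy as np
import pandas as pd
import pytest

from phlike import (
    DEFAULT_PANEL,
    ExpressionMatrix,
    SimulationConfig,
    simulate_cohort,
)


@pytest.fixture(scope="session")
def panel():
    return DEFAULT_PANEL


@pytest.fixture(scope="session")
def default_cohort():
    """One default synthetic cohort shared by read-only tests."""
    return simulate_cohort(SimulationConfig(), seed=1)


@pytest.fixture()
def small_counts(panel):
    """Small deterministic counts matrix over the full panel."""
    rng = np.random.default_rng(42)
    samples = [f"S{i}" for i in range(6)]
    vals = rng.integers(10, 2000, size=(len(panel.panel_genes), len(samples)))
    df = pd.DataFrame(vals, index=list(panel.panel_genes), columns=samples)
    return ExpressionMatrix(values=df, stage="counts")


def write_counts_tsv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index_label="gene")
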