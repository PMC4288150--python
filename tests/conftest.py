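import numpy as np
import pandas as pd
import pytest

from mutrscan import (ExpressionMatrix, SimConfig, generate_dataset,
                      standard_sample_sheet)


@pytest.fixture(scope="session")
def dataset():
    """One deterministic synthetic dataset shared across tests."""
    return generate_dataset(SimConfig(seed=1))


@pytest.fixture(scope="session")
def genome(dataset):
    return dataset[0]


@pytest.fixture(scope="session")
def expr(dataset):
    return dataset[1]


def make_expr(rows: dict[str, float | dict[str, float]],
              default: float = 4.0) -> ExpressionMatrix:
    """Build an ExpressionMatrix over the standard 45-sample design.

    Each entry of ``rows`` is either a constant level for the whole row or a
    dict of per-sample-id overrides applied on top of ``default``.
    """
    sheet = standard_sample_sheet()
    values = {}
    for row_id, spec in rows.items():
        if isinstance(spec, dict):
            base = pd.Series(default, index=sheet.index, dtype=float)
            for sample_id, v in spec.items():
                base[sample_id] = v
        else:
            base = pd.Series(float(spec), index=sheet.index)
        values[row_id] = base
    return ExpressionMatrix(values=pd.DataFrame(values).T, samples=sheet)
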