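import numpy as np
import pandas as pd
import pytest

import gainvar as gv


def make_table(counts_by_condition, window_ms=1000.0, neuron="n0", family="f0"):
    """Assemble a single-window spike-count table from per-condition arrays."""
    rows = []
    for cond, counts in enumerate(counts_by_condition):
        counts = np.asarray(counts)
        rows.append(
            pd.DataFrame(
                {
                    "neuron_id": neuron,
                    "family_id": family,
                    "condition_id": cond,
                    "trial": np.arange(len(counts)),
                    "window_ms": window_ms,
                    "count": counts,
                }
            )
        )
    return pd.concat(rows, ignore_index=True)


@pytest.fixture(scope="session")
def small_population():
    """A fixed 60-unit heterogeneous population and its normalization model."""
    bank = gv.make_population(n_neurons=60, seed=101)
    return gv.NormalizationModel(bank=bank)


@pytest.fixture(scope="session")
def standard_population():
    """The 250-unit population used by the decoding analyses."""
    bank = gv.make_population(n_neurons=250, seed=202)
    return gv.NormalizationModel(bank=bank)
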