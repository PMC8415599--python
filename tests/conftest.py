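import numpy as np
import pandas as pd
import pytest

from mixqc import SyntheticParams, fit_mixture, prefilter, simulate_qc_metrics


def make_cells(x, y, ids=None):
    """Metrics table from raw arrays, for hand-built fixtures."""
    x = np.asarray(x)
    y = np.asarray(y, dtype=float)
    return pd.DataFrame(
        {
            "cell_id": ids if ids is not None else [f"c{i}" for i in range(x.size)],
            "total_counts": (x * 4).astype(np.int64),
            "detected_genes": x.astype(np.int64),
            "pct_mito": y,
            "zero_total_flag": False,
        }
    )


@pytest.fixture(scope="session")
def default_cells():
    """One draw of the default well-separated synthetic sample."""
    return simulate_qc_metrics(SyntheticParams(seed=11))


@pytest.fixture(scope="session")
def default_fit(default_cells):
    kept, _ = prefilter(default_cells)
    return kept, fit_mixture(kept, seed=11)
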