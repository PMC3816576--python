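import numpy as np
import pandas as pd
import pytest


@pytest.fixture()
def rng():
    return np.random.default_rng(20130101)


@pytest.fixture()
def small_ct_table():
    """Two genes, HC at t0 + LC at three timepoints, two replicates."""
    rows = []
    for gene, base in (("cah1", 24.0), ("actin", 20.0)):
        for tp, cond in ((0.0, "HC"), (60.0, "LC"), (120.0, "LC"), (180.0, "LC")):
            shift = -2.0 if (gene == "cah1" and tp > 0) else 0.0
            for rep in (1, 2):
                rows.append((gene, cond, tp, rep, base + shift))
    return pd.DataFrame(
        rows, columns=["gene_id", "condition", "timepoint_min", "replicate", "ct"]
    )
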