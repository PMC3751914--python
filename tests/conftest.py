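import numpy as np
import pandas as pd
import pytest

import pwfrank as pw


@pytest.fixture(scope="session")
def small_dataset():
    """300 genes, 12 samples, mixed effect classes; fixed seed."""
    cfg = pw.SimulationConfig(n_genes=300, seed=1)
    return pw.simulate_expression(cfg)


@pytest.fixture(scope="session")
def small_ranking(small_dataset):
    expr, design, truth = small_dataset
    stats = pw.fit_all_transcripts(expr, design, method="blocked")
    return pw.compute_pwf(stats)


@pytest.fixture()
def design12():
    """Bare 12-sample design sheet: 3 experiments x 2x2 cells."""
    rows = []
    for e in (1, 2, 3):
        for s in ("pos", "neg"):
            for t in ("treated", "untreated"):
                rows.append({"sample": f"E{e}_{s}_{t}", "experiment": f"E{e}",
                             "sorted": s, "treatment": t})
    return pd.DataFrame(rows).set_index("sample")


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
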