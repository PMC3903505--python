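import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def binned_table():
    """Small hand-built binned count table: 3 taxa, 2 conditions x 3 bins x 3 reps."""
    from pyrosip.containers import CountTable

    taxa = ["pantoea", "citrobacter", "enterococcus"]
    cols = {}
    rows = []
    rng = np.random.default_rng(7)
    base = {
        ("labeled", "heavy"): [600, 300, 100],
        ("labeled", "middle"): [100, 100, 800],
        ("labeled", "light"): [200, 200, 600],
        ("control", "heavy"): [50, 50, 900],
        ("control", "middle"): [150, 150, 700],
        ("control", "light"): [250, 250, 500],
    }
    for (cond, bin_), mean in base.items():
        for rep in (1, 2, 3):
            sid = f"{cond}:{bin_}:r{rep}"
            cols[sid] = rng.poisson(mean)
            rows.append({"sample_id": sid, "condition": cond, "bin": bin_,
                         "fraction": pd.NA, "replicate": rep})
    lineages = pd.DataFrame(
        {"phylum": ["Proteobacteria", "Proteobacteria", "Firmicutes"],
         "genus": ["Pantoea", "Citrobacter", "Enterococcus"]},
        index=taxa,
    )
    return CountTable(
        counts=pd.DataFrame(cols, index=taxa),
        samples=pd.DataFrame(rows).set_index("sample_id"),
        lineages=lineages,
    )


@pytest.fixture(scope="session")
def demo_experiment():
    """One simulated demonstration experiment, shared across tests."""
    from pyrosip.scenarios import demo_community, demo_scenario
    from pyrosip.sipsim import simulate_experiment

    return simulate_experiment(
        demo_community(), demo_scenario("48h"), depth=2000, n_replicates=3, seed=11
    )
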