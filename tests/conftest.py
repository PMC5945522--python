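import numpy as np
import pandas as pd
import pytest

from mirpanel.counts import CohortMetadata, CountMatrix
from mirpanel.simulate import SimulationConfig, generate_counts


def make_metadata(classes, seed=0, batch=None):
    rng = np.random.default_rng(seed)
    n = len(classes)
    df = pd.DataFrame(
        {
            "class": list(classes),
            "age": rng.uniform(45, 75, n).round(1),
            "smoking": rng.choice(["never", "former", "current"], n),
        },
        index=pd.Index([f"S{i:03d}" for i in range(n)], name="sample_id"),
    )
    if batch is not None:
        df["batch"] = list(batch)
    return CohortMetadata(df)


def make_counts(array, mirna_ids=None, sample_ids=None):
    array = np.asarray(array)
    m, n = array.shape
    return CountMatrix(
        pd.DataFrame(
            array,
            index=mirna_ids or [f"miR-{i}" for i in range(m)],
            columns=sample_ids or [f"S{j:03d}" for j in range(n)],
        )
    )


@pytest.fixture(scope="session")
def small_cohort():
    """60-sample two-class NB cohort with three planted effects."""
    cfg = SimulationConfig(
        n_per_class={"control": 30, "MIBC": 30},
        n_mirna=80,
        baseline_log2_mean_range=(6, 12),
        planted_de=[
            ("miR-up", "MIBC", 2.0),
            ("miR-down", "MIBC", -1.8),
            ("miR-big", "MIBC", 3.4),
        ],
        planted_stable=["miR-hk-a", "miR-hk-b"],
        seed=101,
    )
    cm, meta = generate_counts(cfg)
    return cfg, cm, meta
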