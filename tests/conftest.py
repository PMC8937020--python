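import numpy as np
import pandas as pd
import pytest

from methpipe.io_formats import SiteScoreTable
from methpipe.synthetic import SimulationConfig, simulate_cohort

PAIR_SAMPLES = {
    "P1_T": ("P1", "tumor"),
    "P1_N": ("P1", "normal"),
    "P2_T": ("P2", "tumor"),
    "P2_N": ("P2", "normal"),
}


def make_site_table(pairs, mark="5mC", samples=None):
    """Build a SiteScoreTable from (tumor, normal) aggregated score pairs,
    one single-pair sample per condition (aggregation = identity)."""
    pairs = np.asarray(pairs, dtype=float)
    data = pd.DataFrame(
        {
            "chrom": "chr1",
            "pos0": np.arange(len(pairs), dtype=np.int64) * 10,
            "P1_T": pairs[:, 0],
            "P1_N": pairs[:, 1],
        }
    )
    return SiteScoreTable(
        mark=mark, data=data, samples=samples or {"P1_T": ("P1", "tumor"), "P1_N": ("P1", "normal")}
    )


@pytest.fixture(scope="session")
def small_cohort():
    """A modest noiseless-ish cohort shared by read-only tests."""
    cfg = SimulationConfig(
        seed=11,
        n_genes=120,
        n_patients=120,
        dispersion=0.0,
        hazard_log_hr=2.0,
        de_base_rate=0.3,
        n_survival_genes=2,
    )
    return simulate_cohort(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
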