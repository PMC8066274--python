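import numpy as np
import pandas as pd
import pytest

from virotyper.synthetic import CommunitySpec, emit_hit_tables, simulate_community

# Published per-sample family percentages (seven virome samples) used as
# printed-table inputs for the aggregation arithmetic checks.
FAMILY_PERCENTAGES = pd.DataFrame(
    {
        "V1": [40.14, 36.49, 13.44, 1.11, 2.26, 0.96],
        "V2": [49.54, 26.90, 13.37, 2.39, 1.65, 0.57],
        "V3": [37.70, 52.04, 5.79, 0.57, 0.49, 0.15],
        "V4": [45.99, 28.42, 12.90, 1.04, 1.75, 0.75],
        "6C": [42.53, 16.80, 30.33, 3.57, 1.65, 0.50],
        "BVP1": [56.57, 14.54, 11.45, 12.73, 0.78, 0.33],
        "BVP2": [47.61, 22.06, 15.62, 7.48, 1.88, 0.78],
    },
    index=["Siphoviridae", "Podoviridae", "Myoviridae", "Lavidaviridae",
           "Phycodnaviridae", "Mimiviridae"],
)

# (total reads, viral reads) per sample from the same published summary table
READ_TALLIES = {
    "V1": (3_393_068, 324_715),
    "V2": (2_218_572, 168_557),
    "V3": (2_817_492, 423_054),
    "V4": (3_573_602, 296_176),
}


@pytest.fixture(scope="session")
def small_spec():
    return CommunitySpec(
        n_virotypes=25, n_samples=3, reads_per_sample=3000,
        unidentifiable_fraction=0.5, stage2_fraction=0.15, seed=11,
    )


@pytest.fixture(scope="session")
def small_community(small_spec):
    truth, metadata = simulate_community(small_spec)
    return truth, metadata


@pytest.fixture(scope="session")
def small_hit_tables(small_spec, small_community):
    truth, _ = small_community
    return emit_hit_tables(truth, small_spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)
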