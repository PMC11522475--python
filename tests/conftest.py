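import numpy as np
import pandas as pd
import pytest

from nccall.genomic_io import FragmentSet, count_bp_overlap
from nccall.model import ModelConfig, score_sample
from nccall.simulate import SimConfig, simulate_sample


def frame(rows):
    """Shorthand: list of (chrom, start, end) -> fragment/interval frame."""
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def sites_frame(rows):
    df = frame(rows)
    df["id"] = df["chrom"] + ":" + df["start"].astype(str) + "-" + df["end"].astype(str)
    return df


def count_sample(sim, config: ModelConfig, exclude_artifacts: bool = True):
    """Count bp per planted site and score the N/C model (test helper)."""
    sites = sim.sites
    if exclude_artifacts:
        sites = sites[sites["class"] != "igg_artifact"].reset_index(drop=True)
    counts = pd.DataFrame(
        {
            "interval_id": sites["id"].to_numpy(),
            "bp_n": count_bp_overlap(sim.fragments_n, sites).to_numpy(),
            "bp_c": count_bp_overlap(sim.fragments_c, sites).to_numpy(),
        }
    )
    return score_sample(counts, config, sim.sample_id)


@pytest.fixture(scope="session")
def small_sim():
    """A small planted-enrichment sample shared across tests (8-fold, level 1)."""
    cfg = SimConfig(
        genome=(("chr1", 1_000_000),), n_wt_sites=60, n_onco_sites=15,
        site_length=800, depth=40_000, igg_artifacts=3, seed=7,
    )
    return simulate_sample(cfg, "small"), cfg


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
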