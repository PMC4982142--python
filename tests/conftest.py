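import numpy as np
import pandas as pd
import pytest

from dopseg import decontam, positions, regions, segmentation, simulate


def run_pipeline(cfg: simulate.SimConfig, cbs_seed: int = 0):
    """Full pipeline on a simulated experiment; returns (result, positions, calls)."""
    res = simulate.simulate_experiment(cfg)
    kept, _ = decontam.filter_contaminant_reads(res.alignments)
    pos = positions.merge_reads_to_positions(
        list(
            zip(
                kept["target_chrom"],
                kept["target_start"].astype(int),
                kept["target_end"].astype(int),
            )
        )
    )
    series = positions.compute_pd(pos, cfg.chrom_lengths)
    segs = segmentation.segment_chromosomes(
        series, cbs_cfg=segmentation.CbsConfig(seed=cbs_seed)
    )
    labeled = regions.classify_segments(segs, chrom_lengths=cfg.chrom_lengths)
    calls = regions.call_regions(labeled, pos)
    return res, pos, calls


@pytest.fixture(scope="session")
def roe_pipeline():
    """One roe-like simulated experiment run through the whole pipeline."""
    cfg = simulate.roe_like_config(seed=11)
    return run_pipeline(cfg, cbs_seed=11)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
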