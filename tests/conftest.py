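import numpy as np
import pytest

from strandrepair import (GroundTruth, SimulationConfig,
                          generate_genome_and_genes, simulate_timecourse)


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    """Desk-scale study conditions: 50 kb, 20 genes."""
    return SimulationConfig(seed=11, n_chroms=1, chrom_length=50_000,
                            n_genes=20, depth=50_000)


@pytest.fixture(scope="session")
def small_gt(small_config) -> GroundTruth:
    return generate_genome_and_genes(small_config)


def clone_gt(gt: GroundTruth) -> GroundTruth:
    """A fresh GroundTruth over the same genome/annotation, with no cached
    lesion state (so each test controls its own induction seed)."""
    return GroundTruth(config=gt.config, genome=gt.genome, genes=gt.genes,
                       dyads=gt.dyads)


@pytest.fixture(scope="session")
def wt_tracks(small_gt):
    """Observed WT tracks at 0 and 2 hr on the small ground truth."""
    return simulate_timecourse(clone_gt(small_gt), "WT", [2.0], seed=3)
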