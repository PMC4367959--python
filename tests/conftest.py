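"""Shared fixtures: simulated studies reused across test modules."""

import pytest

from nucrnai.simulate import SimulationConfig, simulate


@pytest.fixture(scope="session")
def sim_default():
    """Full default-scale study (6 x 1 Mb chromosomes, all libraries)."""
    return simulate(SimulationConfig(seed=11))


@pytest.fixture(scope="session")
def sim_small():
    """Compact study for stage-level tests (3 autosomes + chrX)."""
    cfg = SimulationConfig(
        seed=7,
        chromosome_lengths=(
            ("chrI", 400_000),
            ("chrII", 400_000),
            ("chrIII", 400_000),
            ("chrX", 200_000),
        ),
        n_grts_regions=8,
        n_grh_regions=10,
        n_overlap_regions=4,
    )
    return simulate(cfg)
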