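import numpy as np
import pytest

from peeprd.pipeline import AnalysisOptions, run_study
from peeprd.synthetic_data import (
    PhantomConfig,
    SimConfig,
    simulate_breathing,
    simulate_ct_sequence,
)


@pytest.fixture(scope="session")
def clean_cfg():
    """Noise- and jitter-free simulator configuration."""
    return SimConfig(noise_sd_frac=0.0, tv_jitter_frac=0.0, seed=101)


@pytest.fixture(scope="session")
def clean_waves_p6(clean_cfg):
    """Clean 30 s record at PEEP 6 plus its ground truth."""
    return simulate_breathing(clean_cfg, 6.0, 30.0)


@pytest.fixture(scope="session")
def noisy_waves_p6():
    """Default-noise 30 s record at PEEP 6 plus its ground truth."""
    cfg = SimConfig(seed=202)
    return simulate_breathing(cfg, 6.0, 30.0)


@pytest.fixture(scope="session")
def phantom_run_p6(noisy_waves_p6):
    """Default phantom (20 s) driven by the PEEP 6 record."""
    waves, gt = noisy_waves_p6
    pcfg = PhantomConfig(duration=20.0, seed=303)
    frames, mask, gt_ct = simulate_ct_sequence(pcfg, waves, gt)
    return pcfg, waves, frames, mask, gt_ct


@pytest.fixture(scope="session")
def default_study():
    """The full default PEEP-ramp study (100 s acquisitions, 11 steps)."""
    return run_study(SimConfig(), PhantomConfig(), AnalysisOptions(), seed=1)
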