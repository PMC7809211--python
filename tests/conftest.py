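import numpy as np
import pytest

from cricketgait.synth import EMGChannelSpec, EMGSynthSpec, GaitConfig, generate_emg, generate_gait


@pytest.fixture(scope="session")
def noise_free_tetrapod():
    """Jitter-free tetrapod gait: events, traces and ground truth."""
    cfg = GaitConfig("tetrapod", n_cycles=20, jitter_kappa=float("inf"))
    return generate_gait(cfg)


@pytest.fixture(scope="session")
def jittered_tetrapod():
    """Tetrapod gait with von Mises touchdown jitter (kappa=50, 100 cycles)."""
    cfg = GaitConfig("tetrapod", n_cycles=100, jitter_kappa=50.0, seed=1)
    return generate_gait(cfg)


@pytest.fixture(scope="session")
def trot_emg():
    """Trot-gait EMG bundle at 3.5 Hz: records, ground-truth phase table, gait."""
    gcfg = GaitConfig("trot", n_cycles=30, cycle_frequency=3.5, jitter_kappa=50.0, seed=7)
    events, _, truth = generate_gait(gcfg)
    channels = [
        EMGChannelSpec("LM_levator", burst_phase=2 * np.pi * 0.5),
        EMGChannelSpec("RM_levator", burst_phase=2 * np.pi * 0.5),
        EMGChannelSpec("RH_retractor", burst_phase=2 * np.pi * 0.05),
    ]
    records, phase_truth = generate_emg(events, EMGSynthSpec(channels=channels, seed=7))
    return records, phase_truth, events, truth
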