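import pytest

from hepflow.core import Recording
from hepflow.synth import HepEffect, SynthConfig, gen_ecg, gen_eeg


@pytest.fixture(scope="session")
def small_channels():
    """Compact montage: the fronto-central target set plus flankers."""
    return ["Fz", "FC1", "FC2", "Cz", "F3", "F4", "C3", "C4"]


@pytest.fixture(scope="session")
def clean_ecg_truth():
    """Noise-free metronomic ECG: 1 Hz beats for 10 s at 250 Hz."""
    cfg = SynthConfig(
        seed=1, fs=250.0, duration=10.0, mean_ibi=1000.0, ibi_sd=0.0,
        lf_mod=(0.1, 0.0), hf_mod=(0.25, 0.0), ecg_noise_sd=0.0,
    )
    return gen_ecg(cfg)


@pytest.fixture(scope="session")
def bump_recording():
    """Noise-free EEG with a 2 µV heartbeat-locked bump on Fz only."""
    cfg = SynthConfig(
        seed=6, fs=250.0, duration=60.0, mean_ibi=800.0, ibi_sd=0.0,
        lf_mod=(0.1, 0.0), hf_mod=(0.25, 0.0), ecg_noise_sd=0.0,
        eeg_channels=["Fz", "Cz", "Pz"], alpha_amp=0.0, noise_amp=0.0,
        cfa_amp=0.0,
        hep_effect=HepEffect(window=(0.4, 0.5), amplitude=2.0,
                             weights={"Fz": 1.0}),
    )
    ecg, truth = gen_ecg(cfg)
    eeg = gen_eeg(cfg, truth)
    rec = Recording(data=eeg, fs=cfg.fs, labels=cfg.eeg_channels,
                    roles=["eeg"] * 3)
    return rec, truth
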