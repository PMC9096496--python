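"""Synthetic multimodal recordings with known ground truth.

The generator produces the three signal modalities the analysis consumes —
single-lead ECG, multichannel EEG, and a respiration-belt trace — plus a
behavioral table, all with explicit ground truth so every downstream stage
can be validated without real data.

Model choices (deliberately simple, with closed-form expectations):

* the inter-beat-interval (IBI) series is mean IBI plus a low-frequency
  sinusoidal modulation, a respiratory-frequency sinusoidal modulation, and
  white jitter — which gives exact LF/HF spectral-power expectations;
* each beat is rendered as a parametric sum-of-Gaussians PQRST template
  (the detector must not be tuned to any particular measured beat shape);
* EEG channels are 1/f-shaped Gaussian noise, a 10 Hz alpha sinusoid on
  parieto-occipital channels, a cardiac-field artifact locked to each
  R-peak, and an injectable heartbeat-locked evoked bump with a per-channel
  scalp weight map;
* respiration is a rate-modulated oscillation with optional large movement
  spikes; behavioral scores come from a Gaussian copula with requested rank
  correlations.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .core import (
    CHANNELS_32,
    FRONTOCENTRAL_CHANNELS,
    PARIETAL_CHANNELS,
    Recording,
    canonical_label,
)

__all__ = [
    "SynthConfig",
    "GroundTruth",
    "gen_ecg",
    "gen_eeg",
    "gen_respiration",
    "gen_behavior",
    "gen_recording",
]

#: Minimum physiologically plausible IBI (refractory floor), ms.
MIN_IBI_MS = 250.0


@dataclass
class HepEffect:
    """Injected heartbeat-locked component.

    window : (start, end) in seconds after the R-peak, within [-0.2, 0.6].
    amplitude : peak amplitude in µV (a Hann bump over the window).
    weights : per-channel scalp weight map (labels must be EEG channels).
    """

    window: tuple[float, float] = (0.4, 0.5)
    amplitude: float = 0.0
    weights: dict[str, float] = field(
        default_factory=lambda: {ch: 1.0 for ch in FRONTOCENTRAL_CHANNELS}
    )

    def __post_init__(self) -> None:
        w0, w1 = self.window
        if not (-0.2 <= w0 < w1 <= 0.6):
            raise ValueError(
                f"hep window {self.window} must lie within [-0.2, 0.6] s"
            )
        self.weights = {canonical_label(k): v for k, v in self.weights.items()}


@dataclass
class SynthConfig:
    """Parameters of one synthetic recording segment.

    Defaults emulate a resting adult: 800 ms mean IBI with 25 ms jitter,
    0.1 Hz LF and respiratory-frequency HF modulation, 15 breaths/min,
    1 mV QRS, 10 µV 1/f EEG background with 5 µV parietal alpha and a 5 µV
    cardiac-field artifact.
    """

    seed: int = 0
    fs: float = 250.0
    duration: float = 300.0
    # --- cardiac ---
    mean_ibi: float = 800.0          # ms
    ibi_sd: float = 25.0             # ms white jitter
    lf_mod: tuple[float, float] = (0.1, 20.0)    # (Hz, depth ms)
    hf_mod: tuple[float, float] = (0.25, 15.0)   # (Hz, depth ms)
    qrs_amp: float = 1.0             # mV
    qrs_width: float = 0.08          # s, full QRS extent
    ecg_noise_sd: float = 0.02       # mV additive white noise
    # --- EEG ---
    eeg_channels: list[str] = field(default_factory=lambda: list(CHANNELS_32))
    alpha_amp: float = 5.0           # µV, on parieto-occipital channels
    noise_amp: float = 10.0          # µV SD of 1/f background
    noise_exponent: float = 1.0      # 1/f^a slope
    cfa_amp: float = 5.0             # µV cardiac-field artifact
    hep_effect: HepEffect = field(default_factory=HepEffect)
    # --- respiration ---
    resp_rate: float = 15.0          # cycles/min
    resp_rate_sd: float = 1.0        # cycles/min between-breath SD
    resp_amp: float = 1.0            # arbitrary belt units
    artifact_rate: float = 0.0       # movement spikes per minute

    def __post_init__(self) -> None:
        if self.mean_ibi <= 0:
            raise ValueError("mean_ibi must be positive")
        if self.fs <= 0 or self.duration <= 0:
            raise ValueError("fs and duration must be positive")
        self.eeg_channels = [canonical_label(c) for c in self.eeg_channels]

    def with_(self, **kw) -> "SynthConfig":
        """Copy with fields replaced (convenience for per-condition configs)."""
        return replace(self, **kw)


@dataclass
class GroundTruth:
    """Exact event times underlying one generated segment."""

    rpeak_times: np.ndarray            # s, strictly increasing
    ibi_series: np.ndarray             # ms, = diff(rpeak_times) * 1000
    resp_peak_times: np.ndarray | None = None
    hep_waveform: dict[str, np.ndarray] | None = None  # per-channel bump
    lf_depth: float = 0.0
    hf_depth: float = 0.0

    def __post_init__(self) -> None:
        t = np.asarray(self.rpeak_times, dtype=float)
        if np.any(np.diff(t) <= 0):
            raise ValueError("rpeak_times must be strictly increasing")
        self.rpeak_times = t
        self.ibi_series = np.asarray(self.ibi_series, dtype=float)


def _gauss(t: np.ndarray, mu: float, sigma: float) -> np.ndarray:
    return np.exp(-0.5 * ((t - mu) / sigma) ** 2)


def qrs_template(t: np.ndarray, amp: float, width: float = 0.08) -> np.ndarray:
    """Parametric PQRST beat: biphasic QRS spike plus smooth P/T bumps.

    ``t`` is time relative to the R-peak in seconds; the QRS complex spans
    roughly ``width`` seconds.  Slight Q/S asymmetry keeps the shape from
    matching any analysis wavelet exactly.
    """
    w = width / 0.08
    beat = (
        amp * _gauss(t, 0.0, 0.011 * w)
        - 0.16 * amp * _gauss(t, -0.026 * w, 0.008 * w)
        - 0.24 * amp * _gauss(t, 0.028 * w, 0.010 * w)
        + 0.12 * amp * _gauss(t, -0.180, 0.025)
        + 0.30 * amp * _gauss(t, 0.250, 0.045)
    )
    return beat


def _ibi_ms(cfg: SynthConfig, t: float, rng: np.random.Generator) -> float:
    lf_f, lf_d = cfg.lf_mod
    hf_f, hf_d = cfg.hf_mod
    ibi = (
        cfg.mean_ibi
        + lf_d * np.sin(2 * np.pi * lf_f * t)
        + hf_d * np.sin(2 * np.pi * hf_f * t)
    )
    if cfg.ibi_sd > 0:
        ibi += rng.normal(0.0, cfg.ibi_sd)
    return max(ibi, MIN_IBI_MS)


def gen_ecg(cfg: SynthConfig) -> tuple[np.ndarray, GroundTruth]:
    """Generate a single-lead ECG trace (mV) and its ground truth.

    Beat times are laid down sequentially from the modulated IBI model and
    each beat is rendered with :func:`qrs_template`; the returned ground
    truth records the exact R-peak times.
    """
    rng = np.random.default_rng(cfg.seed)
    t0 = 0.5 * cfg.mean_ibi / 1000.0
    times = [t0]
    while True:
        nxt = times[-1] + _ibi_ms(cfg, times[-1], rng) / 1000.0
        if nxt >= cfg.duration - 0.05:
            break
        times.append(nxt)
    if len(times) < 2:
        raise ValueError(
            f"duration {cfg.duration} s too short for 2 beats at "
            f"mean IBI {cfg.mean_ibi} ms"
        )
    times = np.array(times)
    n = int(round(cfg.duration * cfg.fs))
    tax = np.arange(n) / cfg.fs
    ecg = np.zeros(n)
    half = 0.45  # template support, s, either side of the R-peak
    for tr in times:
        i0 = max(0, int((tr - half) * cfg.fs))
        i1 = min(n, int((tr + half) * cfg.fs) + 1)
        ecg[i0:i1] += qrs_template(tax[i0:i1] - tr, cfg.qrs_amp, cfg.qrs_width)
    if cfg.ecg_noise_sd > 0:
        ecg += rng.normal(0.0, cfg.ecg_noise_sd, size=n)
    truth = GroundTruth(
        rpeak_times=times,
        ibi_series=np.diff(times) * 1000.0,
        lf_depth=cfg.lf_mod[1],
        hf_depth=cfg.hf_mod[1],
    )
    return ecg, truth


def _one_over_f_noise(
    n: int, fs: float, exponent: float, sd: float, rng: np.random.Generator
) -> np.ndarray:
    """Gaussian noise with a 1/f^exponent amplitude spectrum, unit-SD scaled."""
    white = rng.normal(size=n)
    if exponent == 0 or sd == 0:
        return sd * white
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n, 1.0 / fs)
    shaping = np.ones_like(f)
    nz = f > 0
    shaping[nz] = f[nz] ** (-exponent / 2.0)
    shaping[0] = 0.0  # no DC drift
    x = np.fft.irfft(spec * shaping, n)
    s = x.std()
    return sd * x / s if s > 0 else x


def hep_bump(tax: np.ndarray, window: tuple[float, float]) -> np.ndarray:
    """Unit-amplitude Hann bump over ``window`` (s, relative to the R-peak)."""
    w0, w1 = window
    out = np.zeros_like(tax)
    inside = (tax >= w0) & (tax < w1)
    out[inside] = 0.5 - 0.5 * np.cos(2 * np.pi * (tax[inside] - w0) / (w1 - w0))
    return out


def gen_eeg(cfg: SynthConfig, truth: GroundTruth) -> np.ndarray:
    """Generate the EEG matrix [channels × samples] in µV.

    Each channel = 1/f background + parietal alpha + cardiac-field artifact
    locked to the true R-peaks + the injected heartbeat-locked bump scaled
    by the per-channel weight map.
    """
    labels = cfg.eeg_channels
    if cfg.hep_effect.amplitude != 0:
        missing = [c for c in cfg.hep_effect.weights if c not in labels]
        if missing:
            raise ValueError(
                f"hep_effect weight channel(s) {missing} absent from "
                "eeg_channels"
            )
    rng = np.random.default_rng(cfg.seed + 104729)  # distinct stream from ECG
    n = int(round(cfg.duration * cfg.fs))
    tax = np.arange(n) / cfg.fs
    data = np.zeros((len(labels), n))

    for i in range(len(labels)):
        if cfg.noise_amp > 0:
            data[i] = _one_over_f_noise(
                n, cfg.fs, cfg.noise_exponent, cfg.noise_amp, rng
            )
    if cfg.alpha_amp > 0:
        alpha = cfg.alpha_amp * np.sin(2 * np.pi * 10.0 * tax)
        for i, lab in enumerate(labels):
            if lab in PARIETAL_CHANNELS:
                data[i] += alpha

    # cardiac-field artifact: attenuated beat shape, decaying within 100 ms
    if cfg.cfa_amp > 0:
        cfa = np.zeros(n)
        for tr in truth.rpeak_times:
            i0 = max(0, int((tr - 0.05) * cfg.fs))
            i1 = min(n, int((tr + 0.10) * cfg.fs) + 1)
            seg = tax[i0:i1] - tr
            shape = qrs_template(seg, 1.0) * np.exp(-np.clip(seg, 0, None) / 0.03)
            cfa[i0:i1] += shape
        data += cfg.cfa_amp * cfa[None, :]

    if cfg.hep_effect.amplitude != 0:
        w0, w1 = cfg.hep_effect.window
        for tr in truth.rpeak_times:
            i0 = int(np.ceil((tr + w0) * cfg.fs))
            i1 = int(np.ceil((tr + w1) * cfg.fs))
            if i0 < 0 or i1 > n:
                continue
            bump = cfg.hep_effect.amplitude * hep_bump(
                tax[i0:i1] - tr, (w0, w1)
            )
            for lab, wgt in cfg.hep_effect.weights.items():
                data[labels.index(lab), i0:i1] += wgt * bump

    truth.hep_waveform = {
        lab: cfg.hep_effect.amplitude
        * wgt
        * hep_bump(
            np.arange(-0.2, 0.6, 1 / cfg.fs), cfg.hep_effect.window
        )
        for lab, wgt in cfg.hep_effect.weights.items()
    }
    return data


def gen_respiration(cfg: SynthConfig) -> tuple[np.ndarray, np.ndarray]:
    """Generate a respiration-belt trace and the true breath-peak times.

    Instantaneous rate is drawn per breath from N(resp_rate, resp_rate_sd²);
    movement artifacts are spikes of ≥5× signal amplitude at Poisson times.
    """
    if cfg.resp_rate <= 0:
        raise ValueError("resp_rate must be positive")
    rng = np.random.default_rng(cfg.seed + 1299709)
    peaks = [60.0 / cfg.resp_rate * 0.5]
    while peaks[-1] < cfg.duration:
        rate = cfg.resp_rate
        if cfg.resp_rate_sd > 0:
            rate = max(rng.normal(cfg.resp_rate, cfg.resp_rate_sd), 1.0)
        peaks.append(peaks[-1] + 60.0 / rate)
    peaks = np.array(peaks)

    n = int(round(cfg.duration * cfg.fs))
    tax = np.arange(n) / cfg.fs
    # phase advances by 1 cycle between successive peaks; cos(2*pi*phase)
    # therefore peaks exactly at the recorded peak times
    anchor_t = np.concatenate([[peaks[0] - 60.0 / cfg.resp_rate], peaks])
    anchor_phase = np.arange(len(anchor_t), dtype=float)
    phase = np.interp(tax, anchor_t, anchor_phase)
    resp = cfg.resp_amp * np.cos(2 * np.pi * phase)

    if cfg.artifact_rate > 0:
        n_art = rng.poisson(cfg.artifact_rate * cfg.duration / 60.0)
        for _ in range(n_art):
            at = rng.uniform(0, cfg.duration)
            amp = rng.uniform(5.0, 10.0) * cfg.resp_amp * rng.choice([-1, 1])
            width = 0.05  # s; sharp movement jolt
            i0 = max(0, int((at - 3 * width) * cfg.fs))
            i1 = min(n, int((at + 3 * width) * cfg.fs))
            resp[i0:i1] += amp * _gauss(tax[i0:i1], at, width)

    keep = peaks < cfg.duration
    return resp, peaks[keep]


def gen_recording(cfg: SynthConfig, ecg_label: str = "ECG",
                  resp_label: str = "RESP") -> tuple[Recording, GroundTruth]:
    """Generate a complete multimodal Recording (EEG µV, ECG, respiration).

    The ECG trace (mV) is stored ×1000 so every channel shares the µV unit
    convention of :class:`~hepflow.core.Recording`.
    """
    ecg, truth = gen_ecg(cfg)
    eeg = gen_eeg(cfg, truth)
    resp, resp_peaks = gen_respiration(cfg)
    truth.resp_peak_times = resp_peaks
    data = np.vstack([eeg, ecg[None, :] * 1000.0, resp[None, :]])
    labels = list(cfg.eeg_channels) + [ecg_label, resp_label]
    roles = ["eeg"] * len(cfg.eeg_channels) + ["ecg", "resp"]
    rec = Recording(data=data, fs=cfg.fs, labels=labels, roles=roles)
    return rec, truth


# ---------------------------------------------------------------------------
# Behavioral table
# ---------------------------------------------------------------------------

#: Default variables of the behavioral/autonomic summary table, with the
#: marginal transform applied to the latent standard-normal score.
_BEHAVIOR_VARS: dict[str, tuple] = {
    "fss_mean": ("fss", 5.1, 0.9),
    "absorption": ("fss", 5.0, 1.0),
    "fluency": ("fss", 5.2, 0.9),
    "thinking_about_time": ("vas", None, None),
    "speed_of_time_passage": ("vas", None, None),
    "estimated_duration_s": ("lognorm", 1500.0, 0.25),
    "total_score": ("normal", 50000.0, 15000.0),
    "total_error": ("normal", 120.0, 40.0),
    "bodily_awareness": ("likert7", None, None),
    "sam_arousal_change": ("normal", 0.3, 1.0),
    "sam_valence_change": ("normal", 0.2, 1.0),
    # physiological summaries joined for correlation analyses
    "hep_amplitude_uv": ("normal", 0.5, 0.6),
    "delta_ibi_ms": ("normal", 5.0, 25.0),
    "rr_std_cpm": ("normal", 2.0, 0.8),
    "delta_hf_ms2": ("normal", 0.0, 120.0),
    "delta_lf_ms2": ("normal", 0.0, 150.0),
}


def _transform(kind: str, a, b, z: np.ndarray) -> np.ndarray:
    u = stats.norm.cdf(z)
    if kind == "fss":
        x = a + b * z
        return np.clip(x, 1.0, 7.0)
    if kind == "likert7":
        return np.clip(np.round(1 + 6 * u), 1, 7)
    if kind == "vas":
        return 10.0 * u
    if kind == "lognorm":
        return a * np.exp(b * z)
    return a + b * z  # normal


def gen_behavior(
    n_subjects: int,
    effects: dict[tuple[str, str], float] | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Generate a behavioral + autonomic summary table via a Gaussian copula.

    ``effects`` maps variable pairs to target Spearman rank correlations;
    each requested pair attains its target in expectation (latent Pearson
    r = 2·sin(πρ/6)).  Raises if the implied latent correlation matrix is
    not positive semi-definite, naming the strongest offending pair.
    """
    if n_subjects < 2:
        raise ValueError("need at least 2 subjects (correlation undefined at n=1)")
    effects = dict(effects or {})
    names = list(_BEHAVIOR_VARS)
    k = len(names)
    corr = np.eye(k)
    for (va, vb), rho in effects.items():
        if abs(rho) > 1:
            raise ValueError(f"|correlation| > 1 for pair ({va}, {vb})")
        if va not in names or vb not in names:
            raise KeyError(f"unknown behavioral variable in pair ({va}, {vb})")
        r = 2.0 * np.sin(np.pi * rho / 6.0)
        ia, ib = names.index(va), names.index(vb)
        corr[ia, ib] = corr[ib, ia] = r
    eigvals = np.linalg.eigvalsh(corr)
    if eigvals.min() < -1e-10:
        worst = max(effects.items(), key=lambda kv: abs(kv[1]))[0]
        raise ValueError(
            f"requested correlations are jointly infeasible (non-PSD matrix); "
            f"check pair {worst}"
        )
    rng = np.random.default_rng(seed)
    chol = np.linalg.cholesky(corr + 1e-12 * np.eye(k))
    z = rng.standard_normal((n_subjects, k)) @ chol.T
    cols = {
        name: _transform(*_BEHAVIOR_VARS[name], z[:, i])
        for i, name in enumerate(names)
    }
    df = pd.DataFrame(cols)
    df.insert(0, "subject", [f"s{i + 1:02d}" for i in range(n_subjects)])
    df.insert(1, "group", ["gamer" if i % 2 == 0 else "non_gamer"
                           for i in range(n_subjects)])
    return df
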