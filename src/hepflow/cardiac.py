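"""ECG analysis: wavelet R-peak detection, IBI artifact correction, HRV.

The R-peak detector decomposes the ECG with a shift-invariant (stationary)
``sym4`` discrete wavelet transform, reconstructs the signal from the detail
levels whose passband covers QRS energy (~10–40 Hz; levels 4–5 at 1000 Hz,
scaled automatically with the sampling rate), squares the reconstruction and
applies adaptive-threshold peak picking with a 250 ms refractory period.
Each detection is then refined to the local maximum of the raw ECG.

HRV band powers follow standard practice: the IBI series is cubic-spline
resampled to a uniform 4 Hz series, linearly detrended, and Welch-integrated
over LF (0.04–0.15 Hz) and HF (0.15–0.4 Hz).  HF power is physiologically
interpretable only for breathing rates within 9–24 cycles/min, so metrics
carry a respiration-rate gate flag.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pywt
from scipy import signal as sig
from scipy.interpolate import CubicSpline
from scipy.ndimage import median_filter

from .core import ConditionSegments, warn

__all__ = [
    "RPeakTrain",
    "HRVMetrics",
    "DetectorParams",
    "detect_rpeaks",
    "correct_ibi",
    "hrv_spectral",
    "ibi_summary",
]


@dataclass
class RPeakTrain:
    """Ordered R-peak times for one recording segment."""

    times: np.ndarray                  # s, strictly increasing
    source_fs: float
    corrected_flags: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        if self.times.size and np.any(np.diff(self.times) <= 0):
            raise ValueError("R-peak times must be strictly increasing")
        if not self.corrected_flags:
            self.corrected_flags = ["original"] * len(self.times)
        if len(self.corrected_flags) != len(self.times):
            raise ValueError("corrected_flags must align with times")

    @property
    def ibis_ms(self) -> np.ndarray:
        """Inter-beat intervals in ms (one fewer than beats)."""
        return np.diff(self.times) * 1000.0

    def __len__(self) -> int:
        return len(self.times)


@dataclass
class HRVMetrics:
    """Frequency-domain HRV summary for one segment."""

    ibi_mean: float                    # ms
    lf_power: float                    # ms^2, 0.04-0.15 Hz
    hf_power: float                    # ms^2, 0.15-0.4 Hz
    lf_log: float                      # ln(ms^2)
    hf_log: float                      # ln(ms^2)
    resp_gate: str = "pass"            # pass | fail_low | fail_high

    @property
    def usable(self) -> bool:
        return self.resp_gate == "pass"


@dataclass
class DetectorParams:
    wavelet: str = "sym4"
    levels: int = 5
    qrs_band: tuple[float, float] = (10.0, 40.0)   # Hz
    threshold_frac: float = 0.3        # fraction of rolling-median peak height
    refractory: float = 0.25           # s
    refine_window: float = 0.04        # s, raw-signal refinement half-width
    median_window: int = 11            # peaks, for the rolling threshold


def _qrs_levels(fs: float, band: tuple[float, float], max_level: int) -> list[int]:
    """SWT detail levels whose dyadic passband overlaps the QRS band.

    Detail level j spans roughly [fs/2^(j+1), fs/2^j] Hz; at 1000 Hz the
    QRS band selects levels 4–5, at 250 Hz levels 2–3.
    """
    lo, hi = band
    chosen = [
        j for j in range(1, max_level + 1)
        if fs / 2 ** (j + 1) < hi and fs / 2 ** j > lo
    ]
    return chosen or [max_level]


def detect_rpeaks(
    ecg: np.ndarray, fs: float, params: DetectorParams | None = None
) -> RPeakTrain:
    """Detect R-peaks in a single-lead ECG.

    Amplitude-scale invariant: thresholds are relative to a rolling median
    of detected peak heights.  Returns an empty train (with a warning) for
    flat input.
    """
    params = params or DetectorParams()
    ecg = np.asarray(ecg, dtype=float)
    if fs < 100:
        raise ValueError(f"sampling rate {fs} Hz under-resolves the QRS; need >= 100")
    if ecg.size < 2 * fs:
        raise ValueError("need at least 2 s of ECG signal")
    if np.ptp(ecg) < 1e-12:
        warn("flat ECG signal; returning empty R-peak train")
        return RPeakTrain(times=np.array([]), source_fs=fs)

    # stationary wavelet transform needs a multiple of 2^levels: edge-pad
    L = params.levels
    block = 2 ** L
    pad = (-ecg.size) % block
    x = np.pad(ecg, (0, pad), mode="edge")
    coeffs = pywt.swt(x, params.wavelet, level=L)  # [(cA_L, cD_L), ..., (cA_1, cD_1)]
    keep = set(_qrs_levels(fs, params.qrs_band, L))
    filtered = []
    for i, (ca, cd) in enumerate(coeffs):
        level = L - i
        filtered.append(
            (np.zeros_like(ca), cd if level in keep else np.zeros_like(cd))
        )
    recon = pywt.iswt(filtered, params.wavelet)[: ecg.size]
    det = recon ** 2

    min_dist = max(1, int(params.refractory * fs))
    cand, props = sig.find_peaks(det, distance=min_dist, height=0.0)
    if cand.size == 0:
        warn("no QRS-band peaks found; returning empty R-peak train")
        return RPeakTrain(times=np.array([]), source_fs=fs)
    heights = props["peak_heights"]
    local_med = median_filter(heights, size=min(params.median_window, len(heights)),
                              mode="nearest")
    ok = heights >= params.threshold_frac * local_med
    # guard against a run of noise peaks dragging the median down: also
    # require a minimal fraction of the global upper-quartile height
    ok &= heights >= 0.05 * np.quantile(heights, 0.75)
    cand = cand[ok]

    # refine to the raw-ECG local maximum within +/- refine_window
    half = int(params.refine_window * fs)
    refined = []
    for c in cand:
        i0, i1 = max(0, c - half), min(ecg.size, c + half + 1)
        refined.append(i0 + int(np.argmax(ecg[i0:i1])))
    refined = np.unique(refined)

    # enforce the refractory period after refinement (keep the taller beat)
    keep_idx: list[int] = []
    for idx in refined:
        if keep_idx and (idx - keep_idx[-1]) < min_dist:
            if ecg[idx] > ecg[keep_idx[-1]]:
                keep_idx[-1] = idx
        else:
            keep_idx.append(idx)
    times = np.array(keep_idx, dtype=float) / fs
    return RPeakTrain(times=times, source_fs=fs)


def correct_ibi(train: RPeakTrain, threshold: float = 0.25,
                median_window: int = 11) -> RPeakTrain:
    """Correct missed and spurious beats in an R-peak train.

    IBIs deviating from an 11-beat local median by more than ``threshold``
    (relative) are flagged; a gap of ~2× the local median is split by an
    interpolated beat, and a pair of successive short IBIs summing to ~one
    median is merged by removing the middle (spurious) beat.  Idempotent on
    its own output.
    """
    if len(train) < 3:
        raise ValueError("need at least 3 beats to correct IBIs")
    times = list(train.times)
    flags = list(train.corrected_flags)
    ibis = np.diff(train.times)
    med = median_filter(ibis, size=min(median_window, len(ibis)), mode="nearest")

    new_times: list[float] = [times[0]]
    new_flags: list[str] = [flags[0]]
    n_flagged = 0
    i = 0
    while i < len(ibis):
        ibi, m = ibis[i], med[i]
        nxt_t = times[i + 1]
        if abs(ibi - m) <= threshold * m:
            new_times.append(nxt_t)
            new_flags.append(flags[i + 1])
            i += 1
            continue
        n_flagged += 1
        if ibi > (2.0 - threshold) * m and ibi < (2.0 + threshold) * m:
            # missed beat: insert an interpolated beat at the gap midpoint
            new_times.append(times[i] + ibi / 2.0)
            new_flags.append("interpolated")
            new_times.append(nxt_t)
            new_flags.append(flags[i + 1])
            i += 1
            continue
        if (
            i + 1 < len(ibis)
            and ibi < (1.0 - threshold) * m
            and ibis[i + 1] < (1.0 - threshold) * med[i + 1]
            and abs(ibi + ibis[i + 1] - m) <= threshold * m
        ):
            # spurious beat between two true beats: drop the middle beat
            new_times.append(times[i + 2])
            new_flags.append(flags[i + 2])
            n_flagged += 1
            i += 2
            continue
        # flagged but not correctable by the two rules: keep as-is
        new_times.append(nxt_t)
        new_flags.append(flags[i + 1])
        i += 1

    if n_flagged > 0.2 * len(ibis):
        warn(
            f"{n_flagged}/{len(ibis)} IBIs flagged as artifacts; "
            "manual review advised"
        )
    return RPeakTrain(
        times=np.array(new_times), source_fs=train.source_fs,
        corrected_flags=new_flags,
    )


def band_power(freqs: np.ndarray, psd: np.ndarray,
               band: tuple[float, float]) -> float:
    """Trapezoid-rule integral of a PSD over a half-open frequency band."""
    mask = (freqs >= band[0]) & (freqs < band[1])
    if mask.sum() < 2:
        return 0.0
    return float(np.trapezoid(psd[mask], freqs[mask]))


def hrv_spectral(
    train: RPeakTrain,
    resp_rate: float | None = None,
    interp_fs: float = 4.0,
    lf_band: tuple[float, float] = (0.04, 0.15),
    hf_band: tuple[float, float] = (0.15, 0.4),
    resp_gate_bounds: tuple[float, float] = (9.0, 24.0),
) -> HRVMetrics:
    """Frequency-domain HRV for one segment.

    ``resp_rate`` (cycles/min) sets the gate flag: HF/LF power from segments
    breathed outside [9, 24] cycles/min is flagged unusable (inclusive
    bounds pass).  ``None`` leaves the gate at ``pass``.
    """
    span = train.times[-1] - train.times[0] if len(train) else 0.0
    if span < 120.0:
        raise ValueError(
            f"segment spans {span:.0f} s of beats; HRV needs >= 120 s"
        )
    if len(train) < 60:
        raise ValueError(f"{len(train)} beats; HRV needs >= 60")

    ibis = train.ibis_ms
    t_ibi = train.times[1:]  # each IBI timestamped at its terminating beat
    spline = CubicSpline(t_ibi, ibis)
    grid = np.arange(t_ibi[0], t_ibi[-1], 1.0 / interp_fs)
    series = sig.detrend(spline(grid), type="linear")
    nper = int(min(256.0 * interp_fs, len(series)))
    freqs, psd = sig.welch(
        series, fs=interp_fs, window="hamming", nperseg=nper,
        noverlap=nper // 2, detrend=False,
    )
    lf = band_power(freqs, psd, lf_band)
    hf = band_power(freqs, psd, hf_band)

    gate = "pass"
    if resp_rate is not None:
        if resp_rate < resp_gate_bounds[0]:
            gate = "fail_low"
        elif resp_rate > resp_gate_bounds[1]:
            gate = "fail_high"
    floor = 1e-12
    return HRVMetrics(
        ibi_mean=float(ibis.mean()),
        lf_power=lf,
        hf_power=hf,
        lf_log=float(np.log(max(lf, floor))),
        hf_log=float(np.log(max(hf, floor))),
        resp_gate=gate,
    )


def ibi_summary(train: RPeakTrain, segments: ConditionSegments) -> dict:
    """Per-segment mean IBI (ms) plus the last-minus-first game-interval delta.

    An IBI belongs to the half-open segment containing its *terminating*
    beat.  Segments with fewer than 2 beats yield NaN with a warning.
    """
    def seg_mean(t0: float, t1: float) -> float:
        mask = (train.times[1:] >= t0) & (train.times[1:] < t1)
        # both beats of the first IBI must be informative: require the
        # preceding beat too, i.e. at least 2 beats inside the segment
        inside = (train.times >= t0) & (train.times < t1)
        if inside.sum() < 2:
            warn(f"segment [{t0:g}, {t1:g}) has <2 beats; IBI mean missing")
            return float("nan")
        return float(train.ibis_ms[mask].mean())

    out: dict[str, float] = {}
    for name, (t0, t1) in segments.conditions.items():
        out[name] = seg_mean(t0, t1)
    for i, (t0, t1) in enumerate(segments.game_intervals, start=1):
        out[f"game_{i}"] = seg_mean(t0, t1)
    k = len(segments.game_intervals)
    out["delta_ibi"] = out[f"game_{k}"] - out["game_1"]
    return out
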