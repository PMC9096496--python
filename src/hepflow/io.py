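"""File I/O: BrainVision / EDF recordings, TSV result tables, JSON config.

Reading goes through MNE's readers; writing is implemented here because the
installed stack has no EDF/BrainVision writer.  Writers declare microvolt
physical units for every channel so that a write→read round trip restores
amplitudes exactly (to format precision); third-party files are likewise
assumed to carry µV signals (convert upstream otherwise).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .core import Recording, canonical_label, warn

__all__ = [
    "read_recording",
    "write_brainvision",
    "write_edf",
    "write_results_table",
    "read_results_table",
    "default_config",
    "load_config",
    "save_config",
]

#: Default mapping from channel-name patterns to roles.
DEFAULT_ROLE_MAP = {"ECG": "ecg", "EKG": "ecg", "RESP": "resp", "Resp": "resp"}


def _assign_roles(labels: list[str], role_map: dict[str, str] | None) -> list[str]:
    role_map = dict(DEFAULT_ROLE_MAP if role_map is None else role_map)
    norm_map = {canonical_label(k).lower(): v for k, v in role_map.items()}
    roles = []
    for lab in labels:
        key = canonical_label(lab).lower()
        role = norm_map.get(key)
        if role is None:
            for pat, r in norm_map.items():
                if pat in key:
                    role = r
                    break
        if role is None:
            role = "eeg"
        roles.append(role)
    return roles


def read_recording(
    path: str | Path,
    format: str = "auto",
    role_map: dict[str, str] | None = None,
    require_ecg: bool = False,
) -> Recording:
    """Read a BrainVision (.vhdr) or EDF (.edf) recording.

    Channel roles are assigned from ``role_map`` (name → role); channels not
    matching any entry default to role ``eeg`` with a warning.  Amplitudes
    are returned in µV.
    """
    import mne

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "auto":
        suffix = path.suffix.lower()
        if suffix == ".vhdr":
            format = "brainvision"
        elif suffix == ".edf":
            format = "edf"
        else:
            raise ValueError(f"cannot infer format from suffix {suffix!r}")
    try:
        if format == "brainvision":
            raw = mne.io.read_raw_brainvision(path, preload=True, verbose="error")
        elif format == "edf":
            raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
        else:
            raise ValueError(f"unknown format {format!r}")
    except (ValueError, KeyError):
        raise
    except Exception as exc:  # corrupt file: surface the reader's message
        raise ValueError(f"unreadable {format} file {path.name}: {exc}") from exc

    labels = [canonical_label(l) for l in raw.ch_names]
    roles = _assign_roles(labels, role_map)
    from .core import CHANNELS_32

    unknown = [
        lab for lab, role in zip(labels, roles)
        if role == "eeg" and lab not in CHANNELS_32
    ]
    if unknown:
        warn(f"channel(s) {unknown} not in the role map; defaulted to role 'eeg'")
    if require_ecg and "ecg" not in roles:
        raise ValueError(
            "no channel mapped to role 'ecg' but HEP analysis was requested; "
            "add the ECG channel to the role map"
        )
    data = raw.get_data() * 1e6  # MNE returns SI volts; internal unit is µV
    annotations = [
        (float(a["onset"]), float(a["duration"]), str(a["description"]))
        for a in raw.annotations
    ]
    annotations = [a for a in annotations if 0 <= a[0] <= data.shape[1] / raw.info["sfreq"]]
    return Recording(
        data=data,
        fs=float(raw.info["sfreq"]),
        labels=labels,
        roles=roles,
        annotations=annotations,
    )


# ---------------------------------------------------------------------------
# BrainVision writer (multiplexed IEEE_FLOAT_32, µV)
# ---------------------------------------------------------------------------

def write_brainvision(rec: Recording, basepath: str | Path) -> Path:
    """Write a BrainVision triplet (.vhdr/.vmrk/.eeg); returns the .vhdr path.

    Data are stored multiplexed as IEEE float32 in µV with resolution 1.
    """
    basepath = Path(basepath)
    stem = basepath.with_suffix("")
    vhdr, vmrk, eeg = (stem.with_suffix(s) for s in (".vhdr", ".vmrk", ".eeg"))

    header = [
        "Brain Vision Data Exchange Header File Version 1.0",
        "",
        "[Common Infos]",
        "Codepage=UTF-8",
        f"DataFile={eeg.name}",
        f"MarkerFile={vmrk.name}",
        "DataFormat=BINARY",
        "DataOrientation=MULTIPLEXED",
        f"NumberOfChannels={rec.n_channels}",
        f"SamplingInterval={1e6 / rec.fs:.6f}",
        "",
        "[Binary Infos]",
        "BinaryFormat=IEEE_FLOAT_32",
        "",
        "[Channel Infos]",
    ]
    for i, lab in enumerate(rec.labels, start=1):
        header.append(f"Ch{i}={lab},,1,µV")
    vhdr.write_text("\n".join(header) + "\n", encoding="utf-8")

    markers = [
        "Brain Vision Data Exchange Marker File, Version 1.0",
        "",
        "[Common Infos]",
        "Codepage=UTF-8",
        f"DataFile={eeg.name}",
        "",
        "[Marker Infos]",
        "Mk1=New Segment,,1,1,0,0",
    ]
    for k, (onset, dur, lab) in enumerate(rec.annotations, start=2):
        pos = int(round(onset * rec.fs)) + 1  # marker positions are 1-based
        pts = max(1, int(round(dur * rec.fs)))
        markers.append(f"Mk{k}=Stimulus,{lab},{pos},{pts},0")
    vmrk.write_text("\n".join(markers) + "\n", encoding="utf-8")

    eeg.write_bytes(
        np.asarray(rec.data, dtype="<f4").T.reshape(-1).tobytes()
    )
    return vhdr


# ---------------------------------------------------------------------------
# EDF writer (16-bit, 1-second data records, µV)
# ---------------------------------------------------------------------------

def write_edf(rec: Recording, path: str | Path) -> Path:
    """Write a minimal EDF file (16-bit samples, 1 s records, µV units).

    Requires an integer sampling rate; the recording is zero-padded to a
    whole number of 1-second records.
    """
    path = Path(path)
    fs = rec.fs
    if abs(fs - round(fs)) > 1e-9:
        raise ValueError(f"EDF writer requires an integer sampling rate, got {fs}")
    spr = int(round(fs))  # samples per record per channel
    nchan = rec.n_channels
    n_records = int(np.ceil(rec.n_samples / spr))
    padded = np.zeros((nchan, n_records * spr))
    padded[:, : rec.n_samples] = rec.data

    pmin = padded.min(axis=1)
    pmax = padded.max(axis=1)
    flat = pmax - pmin < 1e-12
    pmin[flat] -= 1.0
    pmax[flat] += 1.0
    dmin, dmax = -32768, 32767

    def f(x, n):  # fixed-width ASCII field
        s = str(x)[:n]
        return s.ljust(n).encode("ascii")

    hdr = b"".join([
        f("0", 8),
        f("hepflow", 80),
        f("synthetic recording", 80),
        f("01.01.00", 8),
        f("00.00.00", 8),
        f(256 * (1 + nchan), 8),
        f("", 44),
        f(n_records, 8),
        f("1", 8),
        f(nchan, 4),
    ])
    hdr += b"".join(f(lab, 16) for lab in rec.labels)
    hdr += b"".join(f("", 80) for _ in range(nchan))
    pmin_str = [f"{v:.8g}"[:8].rstrip(".") for v in pmin]
    pmax_str = [f"{v:.8g}"[:8].rstrip(".") for v in pmax]
    hdr += b"".join(f("uV", 8) for _ in range(nchan))
    hdr += b"".join(f(s, 8) for s in pmin_str)
    hdr += b"".join(f(s, 8) for s in pmax_str)
    hdr += b"".join(f(dmin, 8) for _ in range(nchan))
    hdr += b"".join(f(dmax, 8) for _ in range(nchan))
    hdr += b"".join(f("", 80) for _ in range(nchan))
    hdr += b"".join(f(spr, 8) for _ in range(nchan))
    hdr += b"".join(f("", 32) for _ in range(nchan))

    # quantize against the physical min/max exactly as written on disk
    pmin_w = np.array([float(s) for s in pmin_str])
    pmax_w = np.array([float(s) for s in pmax_str])
    scale = (pmax_w - pmin_w) / (dmax - dmin)
    digital = np.round((padded - pmin_w[:, None]) / scale[:, None] + dmin)
    digital = np.clip(digital, dmin, dmax).astype("<i2")

    with open(path, "wb") as fh:
        fh.write(hdr)
        for r in range(n_records):
            block = digital[:, r * spr : (r + 1) * spr]
            fh.write(block.tobytes())  # channel-sequential within record
    return path


# ---------------------------------------------------------------------------
# Result tables and configuration
# ---------------------------------------------------------------------------

def write_results_table(rows, path: str | Path) -> Path:
    """Write records as a UTF-8 TSV with header, '.' decimals, NaN for missing."""
    path = Path(path)
    df = rows if isinstance(rows, pd.DataFrame) else pd.DataFrame(list(rows))
    df.to_csv(path, sep="\t", index=False, na_rep="NaN", encoding="utf-8")
    return path


def read_results_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", na_values=["NaN"], encoding="utf-8")


def default_config() -> dict:
    """All analysis parameters with their package defaults.

    Every tunable stated in the pipeline's contract appears here so a run
    is fully reproducible from the serialized config alone.
    """
    return {
        "channel_roles": dict(DEFAULT_ROLE_MAP),
        "design": {"pre": 300.0, "game": 1500.0, "post": 300.0,
                   "n_game_intervals": 5},
        "rpeaks": {"wavelet": "sym4", "levels": 5, "qrs_band_hz": [10.0, 40.0],
                   "threshold_frac": 0.3, "refractory_s": 0.25,
                   "refine_window_s": 0.04},
        "ibi_correction": {"threshold": 0.25, "median_window_beats": 11},
        "hrv": {"interp_fs_hz": 4.0, "welch_window_s": 256.0,
                "welch_overlap": 0.5, "lf_band_hz": [0.04, 0.15],
                "hf_band_hz": [0.15, 0.4], "resp_gate_cpm": [9.0, 24.0]},
        "respiration": {"target_fs_hz": 25.0, "lowpass_hz": 2.0,
                        "filter_order": 8, "clip_sd": 2.0,
                        "peak_prominence_sd": 0.2, "peak_min_spacing_s": 1.5},
        "eeg": {"target_fs_hz": 250.0, "band_hz": [1.5, 70.0],
                "filter_order": 4, "alpha_band_hz": [8.0, 12.0],
                "alpha_welch_nperseg": 2000, "alpha_welch_overlap": 0.1},
        "hep": {"epoch_window_s": [-0.2, 0.6], "baseline_window_s": [-0.2, -0.1],
                "amplitude_reject_uv": None,
                "window_channels": ["Fz", "FC1", "FC2", "Cz"],
                "window_s": [0.4, 0.5]},
        "stats": {"cluster_n_perm": 10000, "cluster_alpha_thresh": 0.05,
                  "pointwise_n_perm": 1000, "fdr_q": 0.05,
                  "adjacency_factor": 1.6, "shapiro_alpha": 0.05,
                  "surrogate_n_reps": 100, "surrogate_alpha": 0.05},
    }


def load_config(path: str | Path) -> dict:
    cfg = default_config()
    user = json.loads(Path(path).read_text(encoding="utf-8"))
    for key, val in user.items():
        if isinstance(val, dict) and isinstance(cfg.get(key), dict):
            cfg[key].update(val)
        else:
            cfg[key] = val
    return cfg


def save_config(cfg: dict, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(json.dumps(cfg, indent=2) + "\n", encoding="utf-8")
    return path
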