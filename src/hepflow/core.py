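"""Shared data model: recordings, condition designs, behavioral tables.

Conventions used throughout the package:

* time in seconds, sample indices 0-based;
* every interval is half-open ``[t0, t1)`` — the sample at ``t1`` is excluded;
* EEG amplitudes in microvolts, inter-beat intervals in milliseconds,
  HRV band powers in ms^2 (natural log where "log power" is reported);
* channel names normalized to canonical 10-10 capitalization (Fz, FC1, ...).
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Recording",
    "ConditionSegments",
    "CHANNELS_32",
    "PARIETAL_CHANNELS",
    "FRONTOCENTRAL_CHANNELS",
    "canonical_label",
    "segment_conditions",
]

#: Standard 32-channel 10-10 cap layout (actiCAP-style) used by the study design.
CHANNELS_32 = [
    "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8",
    "FC5", "FC1", "FC2", "FC6",
    "T7", "C3", "Cz", "C4", "T8",
    "TP9", "CP5", "CP1", "CP2", "CP6", "TP10",
    "P7", "P3", "Pz", "P4", "P8",
    "PO9", "PO10", "O1", "Oz", "O2",
]

#: Channels treated as parietal/occipital for alpha-power summaries.
PARIETAL_CHANNELS = ["P7", "P3", "Pz", "P4", "P8", "PO9", "PO10", "O1", "Oz", "O2"]

#: Midline-anterior channels where heartbeat-evoked effects are summarized.
FRONTOCENTRAL_CHANNELS = ["Fz", "FC1", "FC2", "Cz"]

_LABEL_RE = re.compile(r"^([A-Za-z]+)(\d*)$")


def canonical_label(label: str) -> str:
    """Normalize an electrode label to canonical 10-10 capitalization.

    Vendor headers vary in case (``FZ``, ``fc1``); the canonical form
    uppercases the site letters, keeps the ``p`` of fronto-polar sites
    lowercase (``Fp1``, ``Fpz``) and a trailing midline ``z`` lowercase.
    Labels that do not look like 10-10 names are returned stripped but
    otherwise unchanged.
    """
    s = label.strip()
    m = _LABEL_RE.match(s)
    if not m:
        return s
    letters, digits = m.groups()
    up = letters.upper()
    if up.endswith("Z"):
        up = up[:-1] + "z"
    if up.startswith("FP"):
        up = "Fp" + up[2:]
    return up + digits


@dataclass
class Recording:
    """A multichannel physiological recording.

    Parameters
    ----------
    data : ndarray, shape (n_channels, n_samples)
        Signal matrix; EEG channels in µV.
    fs : float
        Sampling rate in Hz.
    labels : list of str
        Ordered channel names (normalized to canonical 10-10 form).
    roles : list of str
        Per-channel role, one of ``{"eeg", "ecg", "resp"}``.
    start_time : float
        Offset of sample 0 in seconds.
    annotations : list of (onset, duration, label)
        Event annotations, onsets in seconds relative to ``start_time``.
    """

    data: np.ndarray
    fs: float
    labels: list[str]
    roles: list[str]
    start_time: float = 0.0
    annotations: list[tuple[float, float, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D [channels x samples]")
        if self.fs <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        self.labels = [canonical_label(l) for l in self.labels]
        dupes = {l for l in self.labels if self.labels.count(l) > 1}
        if dupes:
            raise ValueError(f"duplicate channel label(s): {sorted(dupes)}")
        if len(self.labels) != self.data.shape[0]:
            raise ValueError(
                f"{len(self.labels)} labels for {self.data.shape[0]} data rows"
            )
        if len(self.roles) != len(self.labels):
            raise ValueError("roles must align with labels")
        bad = set(self.roles) - {"eeg", "ecg", "resp"}
        if bad:
            raise ValueError(f"unknown channel role(s): {sorted(bad)}")
        self.annotations = sorted(self.annotations, key=lambda a: a[0])
        for onset, dur, _ in self.annotations:
            if not (0 <= onset <= self.duration) or dur < 0:
                raise ValueError(f"annotation ({onset}, {dur}) outside recording")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        """Recording length in seconds."""
        return self.data.shape[1] / self.fs

    def index(self, label: str) -> int:
        """Row index of a channel by (case-insensitive) name."""
        lab = canonical_label(label)
        try:
            return self.labels.index(lab)
        except ValueError:
            raise KeyError(f"channel {label!r} not in recording") from None

    def channel(self, label: str) -> np.ndarray:
        return self.data[self.index(label)]

    def pick(self, labels=None, role=None) -> "Recording":
        """Sub-recording with the named channels and/or a single role."""
        idx = list(range(self.n_channels))
        if role is not None:
            idx = [i for i in idx if self.roles[i] == role]
        if labels is not None:
            want = [canonical_label(l) for l in labels]
            missing = [l for l in want if l not in self.labels]
            if missing:
                raise KeyError(f"channel(s) not in recording: {missing}")
            idx = [i for i in idx if self.labels[i] in want]
        return Recording(
            data=self.data[idx],
            fs=self.fs,
            labels=[self.labels[i] for i in idx],
            roles=[self.roles[i] for i in idx],
            start_time=self.start_time,
            annotations=list(self.annotations),
        )

    def slice_time(self, t0: float, t1: float) -> "Recording":
        """Half-open time slice ``[floor(t0*fs), floor(t1*fs))``."""
        if t1 > self.duration + 0.5 / self.fs:
            raise ValueError(
                f"requested interval end {t1:g} s exceeds recording "
                f"duration {self.duration:g} s"
            )
        i0 = int(np.floor(t0 * self.fs))
        i1 = int(np.floor(t1 * self.fs))
        keep = [
            (on - t0, du, la)
            for on, du, la in self.annotations
            if t0 <= on < t1
        ]
        return Recording(
            data=self.data[:, i0:i1],
            fs=self.fs,
            labels=list(self.labels),
            roles=list(self.roles),
            start_time=self.start_time + t0,
            annotations=keep,
        )


@dataclass
class ConditionSegments:
    """Experimental timeline: pre-game rest, gameplay, post-game rest.

    All intervals are half-open ``[t0, t1)`` in seconds.  The gameplay
    interval is additionally partitioned into ``n_game_intervals`` equal,
    non-overlapping subintervals used for within-game autonomic trends.
    """

    pre_game: tuple[float, float]
    game: tuple[float, float]
    post_game: tuple[float, float]
    game_intervals: list[tuple[float, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        order = [self.pre_game, self.game, self.post_game]
        for (a0, a1) in order:
            if a1 <= a0:
                raise ValueError(f"empty or inverted interval ({a0}, {a1})")
        for (_, a1), (b0, _) in zip(order, order[1:]):
            if b0 < a1:
                raise ValueError("condition intervals overlap or are out of order")
        if not self.game_intervals:
            g0, g1 = self.game
            edges = np.linspace(g0, g1, 6)
            self.game_intervals = [
                (float(edges[i]), float(edges[i + 1])) for i in range(5)
            ]
        g0, g1 = self.game
        iv = self.game_intervals
        if abs(iv[0][0] - g0) > 1e-9 or abs(iv[-1][1] - g1) > 1e-9:
            raise ValueError("game subintervals must span the game interval")
        for (_, a1), (b0, _) in zip(iv, iv[1:]):
            if abs(b0 - a1) > 1e-9:
                raise ValueError("game subintervals must partition without gaps")

    @classmethod
    def standard(
        cls,
        pre: float = 300.0,
        game: float = 1500.0,
        post: float = 300.0,
        t0: float = 0.0,
        n_game_intervals: int = 5,
    ) -> "ConditionSegments":
        """Sequential design: `pre` s rest, `game` s play, `post` s rest."""
        g0, g1 = t0 + pre, t0 + pre + game
        edges = np.linspace(g0, g1, n_game_intervals + 1)
        return cls(
            pre_game=(t0, g0),
            game=(g0, g1),
            post_game=(g1, g1 + post),
            game_intervals=[
                (float(edges[i]), float(edges[i + 1]))
                for i in range(n_game_intervals)
            ],
        )

    @property
    def conditions(self) -> dict[str, tuple[float, float]]:
        return {
            "pre_game": self.pre_game,
            "game": self.game,
            "post_game": self.post_game,
        }

    def scaled(self, factor: float) -> "ConditionSegments":
        """Design with every duration multiplied by ``factor`` (CI-scale runs)."""
        pre = (self.pre_game[1] - self.pre_game[0]) * factor
        game = (self.game[1] - self.game[0]) * factor
        post = (self.post_game[1] - self.post_game[0]) * factor
        return ConditionSegments.standard(
            pre=pre, game=game, post=post,
            t0=self.pre_game[0] * factor,
            n_game_intervals=len(self.game_intervals),
        )


def segment_conditions(rec: Recording, design: ConditionSegments) -> dict[str, Recording]:
    """Slice a recording into per-condition recordings.

    Returns a mapping with keys ``pre_game``, ``game``, ``post_game`` and
    ``game_1`` .. ``game_k`` for the within-game subintervals.  Slices are
    half-open sample ranges; the game subinterval slices concatenate exactly
    to the game slice (no overlap, no gap).
    """
    if design.post_game[1] > rec.duration + 0.5 / rec.fs:
        raise ValueError(
            f"design requires {design.post_game[1]:g} s but recording has "
            f"only {rec.duration:g} s"
        )
    out: dict[str, Recording] = {}
    for name, (t0, t1) in design.conditions.items():
        out[name] = rec.slice_time(t0, t1)
    for i, (t0, t1) in enumerate(design.game_intervals, start=1):
        out[f"game_{i}"] = rec.slice_time(t0, t1)
    return out


def assemble_recording(
    channels: dict[str, tuple[np.ndarray, str]],
    fs: float,
    start_time: float = 0.0,
) -> Recording:
    """Build a Recording from named (signal, role) pairs at a shared rate."""
    labels = list(channels)
    lengths = {len(sig) for sig, _ in channels.values()}
    if len(lengths) > 1:
        raise ValueError(f"channel lengths differ: {sorted(lengths)}")
    data = np.vstack([np.asarray(channels[l][0], dtype=float) for l in labels])
    roles = [channels[l][1] for l in labels]
    return Recording(data=data, fs=fs, labels=labels, roles=roles, start_time=start_time)


def warn(msg: str) -> None:
    """Package-wide analysis warning (plain UserWarning, easily filterable)."""
    warnings.warn(msg, UserWarning, stacklevel=3)
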