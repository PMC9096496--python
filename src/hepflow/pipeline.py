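"""End-to-end study pipeline on synthetic or recorded data.

``run_subject`` executes the full per-subject analysis graph — R-peak
detection, IBI correction, per-condition autonomic metrics (mean IBI,
LF/HF HRV with the respiration gate, RR-mean/RR-STD, parietal alpha) and
heartbeat-locked EEG averages — and ``run_study`` assembles subjects into
the group-level inference: cluster permutation contrasts of the HEP
between gameplay and rest, mixed repeated-measures ANOVAs over conditions,
normality-gated correlations between physiological summaries and
behavioral scores with FDR control, and (optionally) the surrogate-
heartbeat null suite.

The synthetic study conditions mirror the experiment's structure: three
sequential conditions (rest, gameplay, rest), gameplay split into five
equal intervals, heart rate slightly elevated and HRV modulation reduced
during play, and the heartbeat-locked fronto-central component suppressed
during gameplay relative to rest.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .cardiac import correct_ibi, detect_rpeaks, hrv_spectral
from .core import (
    CHANNELS_32,
    FRONTOCENTRAL_CHANNELS,
    PARIETAL_CHANNELS,
    ConditionSegments,
    Recording,
)
from .hep import (
    HEPAverage,
    alpha_power,
    average_hep,
    epoch_hep,
    preprocess_eeg,
    surrogate_suite,
)
from .io import write_results_table
from .respiration import process_respiration, respiration_metrics
from .stats import (
    bh_fdr,
    build_adjacency,
    cluster_perm_test,
    correlate_gate,
    rm_anova_gg,
    standard_montage_positions,
)
from .synth import HepEffect, SynthConfig, gen_recording

__all__ = [
    "StudyConfig",
    "SubjectBundle",
    "run_subject",
    "run_study",
    "simulate_hep_maps",
    "simulate_hep_subjects",
]

CONDITIONS = ("pre_game", "game", "post_game")


@dataclass
class StudyConfig:
    """Synthetic-study parameters (per-condition generator settings).

    Durations default to a scaled design (150 s rest, 750 s gameplay in
    five 150 s intervals) that keeps every interval long enough for
    spectral HRV while remaining fast; pass ``pre=post=300, game=1500``
    for full-length sessions.
    """

    n_subjects: int = 20
    seed: int = 0
    fs: float = 250.0
    eeg_channels: list[str] = field(default_factory=lambda: list(CHANNELS_32))
    pre: float = 150.0
    game: float = 750.0
    post: float = 150.0
    # heartbeat-locked component amplitude (µV) at rest and during play:
    # suppression during gameplay is the injected condition effect
    hep_amp_rest: float = 2.0
    hep_amp_game: float = 0.0
    hep_window: tuple[float, float] = (0.4, 0.5)
    hep_channels: list[str] = field(
        default_factory=lambda: list(FRONTOCENTRAL_CHANNELS)
    )
    # autonomic condition effects
    mean_ibi_rest: float = 820.0
    mean_ibi_game: float = 770.0
    resp_rate_rest: float = 14.0
    resp_rate_game: float = 17.0
    hf_depth_rest: float = 15.0
    hf_depth_game: float = 8.0
    lf_depth_rest: float = 20.0
    lf_depth_game: float = 12.0
    # between-subject variability
    subject_ibi_sd: float = 40.0     # ms SD of per-subject mean IBI offsets
    subject_hep_sd: float = 0.4      # µV SD of per-subject HEP amplitude
    noise_amp: float = 10.0          # µV EEG background
    cfa_amp: float = 5.0
    alpha_amp: float = 5.0
    # inference
    n_perm: int = 1000
    amplitude_reject: float | None = None

    @property
    def design(self) -> ConditionSegments:
        return ConditionSegments.standard(pre=self.pre, game=self.game,
                                          post=self.post)


@dataclass
class SubjectBundle:
    subject: str
    group: str
    hep: dict[str, HEPAverage]
    autonomic: pd.DataFrame
    summary: dict
    failed_stage: str | None = None


def _condition_cfg(
    study: StudyConfig, subject_seed: int, cond: str,
    ibi_offset: float, hep_offset: float,
) -> SynthConfig:
    is_game = cond == "game"
    dur = study.game if is_game else (study.pre if cond == "pre_game" else study.post)
    amp = (study.hep_amp_game if is_game else study.hep_amp_rest) + hep_offset
    return SynthConfig(
        seed=subject_seed + {"pre_game": 0, "game": 1, "post_game": 2}[cond],
        fs=study.fs,
        duration=dur,
        mean_ibi=(study.mean_ibi_game if is_game else study.mean_ibi_rest)
        + ibi_offset,
        lf_mod=(0.1, study.lf_depth_game if is_game else study.lf_depth_rest),
        hf_mod=(0.25, study.hf_depth_game if is_game else study.hf_depth_rest),
        eeg_channels=list(study.eeg_channels),
        noise_amp=study.noise_amp,
        cfa_amp=study.cfa_amp,
        alpha_amp=study.alpha_amp,
        resp_rate=study.resp_rate_game if is_game else study.resp_rate_rest,
        hep_effect=HepEffect(
            window=study.hep_window,
            amplitude=amp,
            weights={c: 1.0 for c in study.hep_channels},
        ),
    )


def analyze_condition_recording(
    rec: Recording,
    intervals: list[tuple[float, float]] | None = None,
    hep_window: tuple[float, float] = (0.4, 0.5),
    hep_channels: list[str] | None = None,
    amplitude_reject: float | None = None,
) -> tuple[HEPAverage | None, list[dict]]:
    """Run the per-condition analysis graph on one recording segment.

    Returns the HEP average (None when HRV/HEP preconditions fail) and one
    autonomic-metrics row per requested interval (the whole segment when
    ``intervals`` is None).
    """
    fs = rec.fs
    ecg = rec.pick(role="ecg").data[0] / 1000.0  # µV convention -> mV
    train = correct_ibi(detect_rpeaks(ecg, fs))

    resp_sig = rec.pick(role="resp").data[0]
    resp_clean, resp_fs, _ = process_respiration(resp_sig, fs)

    eeg = preprocess_eeg(rec)
    hep_avg = None
    try:
        eps = epoch_hep(eeg, train, amplitude_reject=amplitude_reject)
        hep_avg = average_hep(
            eps,
            window_channels=hep_channels,
            window=hep_window,
        )
    except ValueError:
        pass

    if intervals is None:
        intervals = [(0.0, rec.duration)]
    rows = []
    for (t0, t1) in intervals:
        row: dict = {"t0": t0, "t1": t1}
        seg_rec = rec.slice_time(t0, t1)
        sel = (train.times >= t0) & (train.times < t1)
        ib = np.diff(train.times[sel]) * 1000.0
        row["n_beats"] = int(sel.sum())
        row["ibi_mean"] = float(ib.mean()) if ib.size >= 1 else float("nan")
        resp_m = respiration_metrics(resp_clean, resp_fs, segment=(t0, t1))
        row["rr_mean"] = resp_m.rr_mean
        row["rr_std"] = resp_m.rr_std
        try:
            from .cardiac import RPeakTrain

            seg_train = RPeakTrain(times=train.times[sel], source_fs=fs)
            hrv = hrv_spectral(seg_train, resp_rate=resp_m.rr_mean)
            row.update(
                lf_power=hrv.lf_power, hf_power=hrv.hf_power,
                lf_log=hrv.lf_log, hf_log=hrv.hf_log,
                resp_gate=hrv.resp_gate,
            )
        except ValueError:
            row.update(lf_power=float("nan"), hf_power=float("nan"),
                       lf_log=float("nan"), hf_log=float("nan"),
                       resp_gate="too_short")
        par = [c for c in PARIETAL_CHANNELS if c in eeg.labels]
        try:
            row["alpha_power"] = alpha_power(
                eeg.slice_time(t0, t1), channels=par or None
            )
        except ValueError:
            row["alpha_power"] = float("nan")
        rows.append(row)
    return hep_avg, rows


def run_subject(
    study: StudyConfig, subject_index: int, out_dir: str | Path | None = None
) -> SubjectBundle:
    """Generate and analyze one synthetic subject.

    Conditions are generated from separate per-condition configs (the
    condition effect lives in the generator parameters), then each is run
    through detection → correction → autonomic metrics → HEP averaging.
    Deterministic: the bundle depends only on the study config and index.
    """
    rng = np.random.default_rng(study.seed * 1_000_003 + subject_index)
    ibi_off = float(rng.normal(0.0, study.subject_ibi_sd))
    hep_off = float(rng.normal(0.0, study.subject_hep_sd))
    subj_seed = int(rng.integers(0, 2**31 - 10))
    subject = f"s{subject_index + 1:02d}"
    group = "gamer" if subject_index % 2 == 0 else "non_gamer"

    heps: dict[str, HEPAverage] = {}
    auto_rows = []
    summary: dict = {"subject": subject, "group": group}
    failed = None
    for cond in CONDITIONS:
        cfg = _condition_cfg(study, subj_seed, cond, ibi_off, hep_off)
        try:
            rec, _truth = gen_recording(cfg)
            if cond == "game":
                k = 5
                edges = np.linspace(0, rec.duration, k + 1)
                intervals = [
                    (float(edges[i]), float(edges[i + 1])) for i in range(k)
                ]
            else:
                intervals = None
            hep_avg, rows = analyze_condition_recording(
                rec,
                intervals=intervals,
                hep_window=study.hep_window,
                hep_channels=study.hep_channels,
                amplitude_reject=study.amplitude_reject,
            )
            if hep_avg is not None:
                heps[cond] = hep_avg
                summary[f"hep_{cond}"] = hep_avg.window_mean_value
            if cond == "game":
                for i, row in enumerate(rows, start=1):
                    row["segment"] = f"game_{i}"
            else:
                rows[0]["segment"] = cond
            for row in rows:
                row.update(subject=subject, group=group)
            auto_rows.extend(rows)
        except (ValueError, RuntimeError) as exc:
            failed = f"{cond}: {exc}"
            break

    auto = pd.DataFrame(auto_rows)
    if failed is None and len(auto):
        game = auto[auto["segment"].str.startswith("game_")]
        if len(game) >= 2:
            first, last = game.iloc[0], game.iloc[-1]
            summary["delta_ibi"] = last["ibi_mean"] - first["ibi_mean"]
            summary["delta_rr"] = last["rr_mean"] - first["rr_mean"]
            summary["delta_lf"] = last["lf_power"] - first["lf_power"]
            summary["delta_hf"] = last["hf_power"] - first["hf_power"]
    bundle = SubjectBundle(
        subject=subject, group=group, hep=heps, autonomic=auto,
        summary=summary, failed_stage=failed,
    )
    if out_dir is not None:
        _write_bundle(bundle, Path(out_dir))
    return bundle


def _write_bundle(bundle: SubjectBundle, out_dir: Path) -> None:
    sdir = out_dir / bundle.subject
    sdir.mkdir(parents=True, exist_ok=True)
    write_results_table(bundle.autonomic, sdir / "autonomic.tsv")
    meta = {"subject": bundle.subject, "group": bundle.group,
            "failed_stage": bundle.failed_stage, "summary": bundle.summary,
            "hep": {}}
    for cond, avg in bundle.hep.items():
        df = pd.DataFrame(avg.data, index=avg.labels, columns=avg.times)
        df.to_csv(sdir / f"hep_{cond}.tsv", sep="\t")
        meta["hep"][cond] = {
            "n_epochs": avg.n_epochs,
            "window_mean": avg.window_mean_value,
            "window_s": list(avg.window),
            "window_channels": avg.window_channels,
        }
    (sdir / "meta.json").write_text(json.dumps(meta, indent=2, default=float))


def attach_behavior(
    summary: pd.DataFrame,
    effects: dict[str, tuple[str, float]],
    seed: int = 0,
) -> pd.DataFrame:
    """Add behavioral columns correlated with measured physiology.

    ``effects`` maps a new behavioral column to ``(physio column, rho)``:
    the column is built as ρ·z(physio) + √(1−ρ²)·noise on normal scores,
    so it attains the requested correlation with the *measured* summary in
    expectation.
    """
    rng = np.random.default_rng(seed)
    out = summary.copy()
    for name, (col, rho) in effects.items():
        if abs(rho) > 1:
            raise ValueError(f"|rho| > 1 for {name}")
        x = out[col].to_numpy(dtype=float)
        z = (x - np.nanmean(x)) / (np.nanstd(x) or 1.0)
        eps = rng.standard_normal(len(z))
        out[name] = rho * z + np.sqrt(1 - rho**2) * eps
    return out


def run_study(
    study: StudyConfig,
    out_dir: str | Path | None = None,
    contrasts: tuple[tuple[str, str], ...] = (("game", "pre_game"),
                                              ("game", "post_game")),
    behavior_effects: dict[str, tuple[str, float]] | None = None,
    run_surrogates: bool = False,
    surrogate_reps: int = 100,
) -> dict:
    """Run the full synthetic study and group-level inference.

    Returns a report dict with subject bundles, cluster-test results per
    contrast, per-measure mixed ANOVA tables, and the correlation table
    (FDR-corrected within the family).  ``out_dir`` writes the report as
    TSV/JSON files.
    """
    if study.n_subjects < 3:
        raise ValueError("need >= 3 subjects for inference")
    bundles = [run_subject(study, i, out_dir=None)
               for i in range(study.n_subjects)]
    ok = [b for b in bundles if b.failed_stage is None and len(b.hep) == 3]
    if len(ok) < 3:
        raise RuntimeError(
            f"only {len(ok)} subjects completed all conditions"
        )
    label_sets = {tuple(b.hep["game"].labels) for b in ok}
    if len(label_sets) > 1:
        common = set.intersection(*(set(s) for s in label_sets))
        raise ValueError(
            f"mixed channel sets across subjects; intersection: {sorted(common)}"
        )
    labels = ok[0].hep["game"].labels
    times = ok[0].hep["game"].times

    montage = standard_montage_positions(labels)
    adjacency = build_adjacency(montage)
    report: dict = {"n_subjects": len(ok), "labels": labels,
                    "clusters": {}, "anova": {}, "subjects": bundles}

    for cond_a, cond_b in contrasts:
        data_a = np.stack([b.hep[cond_a].data for b in ok])
        data_b = np.stack([b.hep[cond_b].data for b in ok])
        res = cluster_perm_test(
            data_a, data_b, adjacency, labels=labels,
            n_perm=study.n_perm, paired=True, seed=study.seed,
        )
        report["clusters"][f"{cond_a}_vs_{cond_b}"] = res

    auto = pd.concat([b.autonomic for b in bundles], ignore_index=True)
    report["autonomic"] = auto
    seg_map = {"pre_game": "pre_game", "game": None, "post_game": "post_game"}
    for measure in ("ibi_mean", "lf_log", "hf_log", "rr_mean", "rr_std"):
        mat, groups = [], []
        for b in ok:
            df = b.autonomic.set_index("segment")
            game_rows = df.loc[
                [f"game_{i}" for i in range(1, 6)], measure
            ].to_numpy(dtype=float)
            game_mean = (
                float(np.nanmean(game_rows))
                if np.any(np.isfinite(game_rows)) else float("nan")
            )
            vals = [df.loc["pre_game", measure], game_mean,
                    df.loc["post_game", measure]]
            if np.any(np.isnan(vals)):
                continue
            mat.append(vals)
            groups.append(b.group)
        if len(mat) >= 4 and len(set(groups)) > 1:
            report["anova"][measure] = rm_anova_gg(
                np.array(mat), np.array(groups)
            )

    summary = pd.DataFrame([b.summary for b in ok])
    if "hep_game" in summary:
        summary["hep_amplitude"] = summary["hep_game"]
    if behavior_effects:
        summary = attach_behavior(summary, behavior_effects,
                                  seed=study.seed + 77)
        entries = {}
        for name, (col, _rho) in behavior_effects.items():
            entry = correlate_gate(summary[col], summary[name])
            entries[f"{name}~{col}"] = entry
        p_adj, mask = bh_fdr(np.array([e.p for e in entries.values()]))
        for (key, entry), pa in zip(entries.items(), p_adj):
            entry.p_fdr = float(pa)
        report["correlations"] = entries
    report["summary"] = summary

    if run_surrogates:
        subjects = []
        for i in range(min(study.n_subjects, 12)):
            subj = {}
            rng_i = np.random.default_rng(study.seed * 1_000_003 + i)
            ibi_off = float(rng_i.normal(0.0, study.subject_ibi_sd))
            hep_off = float(rng_i.normal(0.0, study.subject_hep_sd))
            subj_seed = int(rng_i.integers(0, 2**31 - 10))
            for cond in ("pre_game", "game"):
                cfg = _condition_cfg(study, subj_seed, cond, ibi_off, hep_off)
                rec, _ = gen_recording(cfg)
                eeg = preprocess_eeg(rec)
                train = correct_ibi(
                    detect_rpeaks(rec.pick(role="ecg").data[0] / 1000.0, rec.fs)
                )
                subj[cond] = (eeg, train)
            subjects.append(subj)
        report["surrogates"] = surrogate_suite(
            subjects, conditions=("game", "pre_game"),
            n_reps=surrogate_reps, seed=study.seed + 13,
            window_channels=[c for c in study.hep_channels if c in labels],
            window=study.hep_window,
        )

    if out_dir is not None:
        _write_study_report(report, Path(out_dir), study)
    return report


def simulate_hep_subjects(
    n_subjects: int,
    seed: int,
    channels: list[str],
    duration: float = 120.0,
    fs: float = 250.0,
    amp_a: float = 0.0,
    amp_b: float = 0.0,
    noise_amp: float = 10.0,
    cfa_amp: float = 5.0,
    subject_hep_sd: float = 0.4,
    use_detector: bool = True,
) -> list[dict]:
    """Generate per-subject two-condition EEG + R-peak data for calibration.

    Each subject gets two independently generated segments ("a", "b") with
    heartbeat-locked fronto-central bump amplitudes ``amp_a``/``amp_b``
    (plus a shared per-subject amplitude offset).  R-peaks come from the
    wavelet detector (or ground truth when ``use_detector=False``); EEG is
    preprocessed.  Returns one ``{"a": (eeg, train), "b": ...}`` per
    subject — the input shape of :func:`~hepflow.hep.surrogate_suite`.
    """
    from .cardiac import RPeakTrain

    weights = {c: 1.0 for c in FRONTOCENTRAL_CHANNELS if c in channels}
    out = []
    for i in range(n_subjects):
        rng = np.random.default_rng(seed * 2_000_003 + i)
        hep_off = float(rng.normal(0.0, subject_hep_sd))
        base_seed = int(rng.integers(0, 2**31 - 10))
        subj = {}
        for j, (name, amp) in enumerate((("a", amp_a), ("b", amp_b))):
            cfg = SynthConfig(
                seed=base_seed + j, fs=fs, duration=duration,
                eeg_channels=list(channels), noise_amp=noise_amp,
                cfa_amp=cfa_amp,
                hep_effect=HepEffect(amplitude=amp + hep_off, weights=weights),
            )
            rec, truth = gen_recording(cfg)
            eeg = preprocess_eeg(rec)
            if use_detector:
                train = correct_ibi(
                    detect_rpeaks(rec.pick(role="ecg").data[0] / 1000.0, fs)
                )
            else:
                train = RPeakTrain(times=truth.rpeak_times, source_fs=fs)
            subj[name] = (eeg, train)
        out.append(subj)
    return out


def simulate_hep_maps(
    n_subjects: int,
    seed: int,
    channels: list[str],
    **kwargs,
) -> tuple[np.ndarray, np.ndarray, list[str], np.ndarray]:
    """Per-subject HEP average maps for the two simulated conditions.

    Runs :func:`simulate_hep_subjects` and epochs/averages each segment;
    returns ``(data_a, data_b, labels, times)`` with data shaped
    (subjects × channels × time) — the input of the cluster test.
    """
    subjects = simulate_hep_subjects(n_subjects, seed, channels, **kwargs)
    maps = {"a": [], "b": []}
    labels = times = None
    for subj in subjects:
        for name in ("a", "b"):
            eeg, train = subj[name]
            avg = average_hep(epoch_hep(eeg, train))
            maps[name].append(avg.data)
            labels, times = avg.labels, avg.times
    return np.stack(maps["a"]), np.stack(maps["b"]), labels, times


def _write_study_report(report: dict, out_dir: Path, study: StudyConfig) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    for b in report["subjects"]:
        _write_bundle(b, out_dir / "subjects")
    write_results_table(report["autonomic"], out_dir / "autonomic.tsv")
    write_results_table(report["summary"], out_dir / "summary.tsv")

    cluster_rows = []
    for contrast, res in report["clusters"].items():
        for ci, cl in enumerate(res.clusters):
            cluster_rows.append({
                "contrast": contrast, "cluster": ci, "mass": cl.mass,
                "sign": cl.sign, "p": cl.p, "n_bins": len(cl.members),
                "channels": ",".join(report["labels"][c] for c in sorted(cl.channels)),
            })
        np.savetxt(out_dir / f"null_{contrast}.txt", res.null_distribution)
    write_results_table(pd.DataFrame(
        cluster_rows or [{"contrast": "", "cluster": -1, "mass": 0.0,
                          "sign": 0, "p": 1.0, "n_bins": 0, "channels": ""}]),
        out_dir / "clusters.tsv")

    anova_rows = []
    for measure, effects in report["anova"].items():
        for name, r in effects.items():
            anova_rows.append({"measure": measure, "effect": name,
                               "F": r.F, "df1": r.df1, "df2": r.df2,
                               "p": r.p, "eta_sq": r.eta_sq,
                               "epsilon": r.epsilon})
    if anova_rows:
        write_results_table(pd.DataFrame(anova_rows), out_dir / "anova.tsv")

    if "correlations" in report:
        corr_rows = [
            {"pair": key, "method": e.method, "coefficient": e.coefficient,
             "p": e.p, "p_fdr": e.p_fdr, "n": e.n}
            for key, e in report["correlations"].items()
        ]
        write_results_table(pd.DataFrame(corr_rows), out_dir / "correlations.tsv")

    meta = {"study": {k: v for k, v in asdict(study).items()},
            "n_subjects_ok": report["n_subjects"]}
    if "surrogates" in report:
        s = report["surrogates"]
        meta["surrogates"] = {
            "fraction_significant": s.fraction_significant,
            "n_reps": s.n_reps, "alpha": s.alpha,
        }
    (out_dir / "run_meta.json").write_text(
        json.dumps(meta, indent=2, default=str)
    )
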