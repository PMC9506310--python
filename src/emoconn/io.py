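"""Readers, writers, manifests and the umbrella pipeline runner.

On-disk formats are deliberately plain: long-format CSV for EEG
(time_s, channel, value_uV), CSV for gaze and every tabular output, TSV for
state segments, JSON for configs and manifests.  EDF reading is supported
through mne when a recording arrives in that format.  Every pipeline run
writes a manifest recording the seed, all parameters and the SHA-256 of each
output, and contains no timestamps, so identical configs produce
byte-identical results.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import connectivity as conn
from . import eyetrack as eye
from . import states as st
from . import stats_report as sr
from .montage import Montage, build_montage, montage_from_frame, montage_to_frame
from .preprocess import EEGRecording, InputError, broadband_filter, mask_artifacts, resample
from .synth import StudyBundle, EMOTIONAL

__all__ = [
    "read_eeg",
    "write_eeg_csv",
    "read_gaze_csv",
    "write_gaze_csv",
    "read_montage",
    "write_montage",
    "write_study",
    "RunConfig",
    "run_pipeline",
    "PipelineError",
]

_FLOAT_FMT = "%.6f"

#: Column contracts every output table is validated against before a run
#: is reported successful.
OUTPUT_SCHEMAS = {
    "eigenvalues.csv": ["participant", "condition", "window_start", "band",
                        "e_LD_OF", "e_LD_PF", "e_SD",
                        "abs_LD_OF", "abs_LD_PF", "abs_SD"],
    "state_labels.csv": ["participant", "condition", "window_start", "cluster",
                         "emotional"],
    "state_segments.tsv": ["participant", "condition", "start_s", "end_s",
                           "emotional"],
    "eye_features.csv": ["participant", "condition", "state",
                         "mean_fixation_duration_s", "fixation_count",
                         "saccade_rate_hz", "mean_saccade_amplitude_deg",
                         "pupil_change_left_pct", "pupil_change_right_pct"],
    "tukey_arousal.csv": ["condition_1", "condition_2", "mean_difference",
                          "lower", "upper", "p_adj", "reject"],
    "tukey_valence.csv": ["condition_1", "condition_2", "mean_difference",
                          "lower", "upper", "p_adj", "reject"],
    "anova.csv": ["feature", "F", "p", "df_between", "df_within"],
    "profile_concordance.csv": ["eigenvalue_feature", "eye_feature",
                                "spearman_rho"],
}


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage and cause."""


# ---------------------------------------------------------------- readers

def read_eeg(path: str | Path, fmt: str | None = None,
             montage: Montage | None = None) -> EEGRecording:
    """Read EEG from long-format CSV or EDF; channels matched case-insensitively."""
    path = Path(path)
    if fmt is None:
        fmt = "edf" if path.suffix.lower() == ".edf" else "csv"
    if fmt == "edf":
        return _read_eeg_edf(path, montage)
    if fmt != "csv":
        raise InputError(f"unknown EEG format {fmt!r}")
    df = pd.read_csv(path)
    required = {"time_s", "channel", "value_uV"}
    if not required <= set(df.columns):
        raise InputError(f"EEG CSV must have columns {sorted(required)}")
    return _frame_to_recording(df, montage)


def _frame_to_recording(df: pd.DataFrame, montage: Montage | None) -> EEGRecording:
    channels = list(dict.fromkeys(df["channel"]))
    if montage is not None:
        canon = {c.lower(): c for c in montage.channels}
        unknown = [c for c in channels if str(c).lower() not in canon]
        if unknown:
            raise InputError(f"channels not in montage: {unknown}")
        channels_out = [canon[str(c).lower()] for c in channels]
    else:
        channels_out = [str(c) for c in channels]
    wide = df.pivot_table(index="time_s", columns="channel", values="value_uV",
                          sort=False)
    wide = wide[channels].sort_index()
    t = wide.index.to_numpy(dtype=float)
    if t.size < 2:
        raise InputError("EEG CSV has fewer than 2 time points")
    rate = 1.0 / float(np.median(np.diff(t)))
    return EEGRecording(data=wide.to_numpy(dtype=float).T, rate=round(rate, 6),
                        channels=tuple(channels_out), t0=float(t[0]))


def _read_eeg_edf(path: Path, montage: Montage | None) -> EEGRecording:
    try:
        import mne
    except ImportError as exc:  # pragma: no cover
        raise InputError("EDF support requires mne (pip install mne)") from exc
    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    data = raw.get_data() * 1e6  # volts -> microvolts
    channels = tuple(raw.ch_names)
    if montage is not None:
        canon = {c.lower(): c for c in montage.channels}
        unknown = [c for c in channels if c.lower() not in canon]
        if unknown:
            raise InputError(f"channels not in montage: {unknown}")
        channels = tuple(canon[c.lower()] for c in channels)
    return EEGRecording(data=data, rate=float(raw.info["sfreq"]),
                        channels=channels)


def write_eeg_csv(rec: EEGRecording, path: str | Path) -> None:
    n = rec.n_samples
    t = np.round(rec.times(), 6)
    df = pd.DataFrame({
        "time_s": np.tile(t, len(rec.channels)),
        "channel": np.repeat(rec.channels, n),
        "value_uV": rec.data.ravel(),
    })
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_gaze_csv(path: str | Path) -> eye.GazeRecording:
    df = pd.read_csv(path)
    required = {"time_s", "x_deg", "y_deg", "pupil_left_mm", "pupil_right_mm",
                "valid"}
    if not required <= set(df.columns):
        raise InputError(f"gaze CSV must have columns {sorted(required)}")
    return eye.GazeRecording(
        t=df["time_s"].to_numpy(float), x=df["x_deg"].to_numpy(float),
        y=df["y_deg"].to_numpy(float),
        pupil_left=df["pupil_left_mm"].to_numpy(float),
        pupil_right=df["pupil_right_mm"].to_numpy(float),
        valid=df["valid"].to_numpy(bool))


def write_gaze_csv(g: eye.GazeRecording, path: str | Path) -> None:
    pd.DataFrame({
        "time_s": g.t, "x_deg": g.x, "y_deg": g.y,
        "pupil_left_mm": g.pupil_left, "pupil_right_mm": g.pupil_right,
        "valid": g.valid.astype(int),
    }).to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_montage(path: str | Path) -> Montage:
    return montage_from_frame(pd.read_csv(path))


def write_montage(m: Montage, path: str | Path) -> None:
    montage_to_frame(m).to_csv(path, index=False, float_format=_FLOAT_FMT)


# ------------------------------------------------------------ study bundle

def write_study(bundle: StudyBundle, outdir: str | Path) -> Path:
    """Write a simulated study as one directory per participant x condition."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    files = []
    for pid, cond in bundle.sessions:
        d = outdir / pid / cond
        d.mkdir(parents=True, exist_ok=True)
        rec, gaze, _truth = bundle.materialize(pid, cond)
        write_eeg_csv(rec, d / "eeg.csv")
        write_gaze_csv(gaze, d / "gaze.csv")
        files.append([pid, cond, str(Path(pid) / cond / "eeg.csv"),
                      str(Path(pid) / cond / "gaze.csv")])
    bundle.scores.to_csv(outdir / "scores.csv", index=False,
                         float_format=_FLOAT_FMT)
    manifest = {
        "kind": "emoconn-study",
        "seed": bundle.seed,
        "n_participants": bundle.n_participants,
        "sessions": files,
        "durations_s": {f"{p}/{c}": bundle.session_configs[(p, c)].duration
                        for p, c in bundle.sessions},
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                     sort_keys=True))
    return outdir


# ---------------------------------------------------------------- pipeline

@dataclass(frozen=True)
class RunConfig:
    """Everything a full pipeline run depends on, centralized and logged."""

    input_dir: str
    output_dir: str
    band: str = "beta"
    rate: float = 500.0
    window: float = 1.0
    hop: float = 0.5
    amp_thresh: float = 100.0
    artifact_pad: float = 0.2
    k_max: int = 6
    vel_thresh: float = 30.0
    min_fix: float = 0.1
    alpha: float = 0.05
    seed: int = 0
    montage_file: str | None = None

    @classmethod
    def from_json(cls, path: str | Path, **overrides) -> "RunConfig":
        cfg = json.loads(Path(path).read_text())
        cfg.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**cfg)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _validate_schema(path: Path, name: str) -> None:
    cols = OUTPUT_SCHEMAS[name]
    sep = "\t" if name.endswith(".tsv") else ","
    got = list(pd.read_csv(path, sep=sep, nrows=0).columns)
    if got != cols:
        raise PipelineError(
            f"schema check failed for {name}: expected {cols}, got {got}")


def run_pipeline(cfg: RunConfig) -> Path:
    """preprocess -> connectivity -> states -> eyetrack -> stats over a study dir.

    The input directory must be a study bundle as written by
    :func:`write_study`.  Outputs land in ``cfg.output_dir`` with a JSON
    manifest (parameters, seed, checksums); reruns with the same config are
    byte-identical.
    """
    indir = Path(cfg.input_dir)
    outdir = Path(cfg.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest_path = indir / "manifest.json"
    if not manifest_path.exists():
        raise PipelineError(f"stage=load: missing study manifest {manifest_path}")
    study = json.loads(manifest_path.read_text())
    montage = (read_montage(cfg.montage_file) if cfg.montage_file
               else build_montage())

    eig_rows, label_rows, seg_rows, eye_rows = [], [], [], []
    for pid, cond, eeg_rel, gaze_rel in study["sessions"]:
        eeg_path, gaze_path = indir / eeg_rel, indir / gaze_rel
        for p, stage in ((eeg_path, "preprocess"), (gaze_path, "eyetrack")):
            if not p.exists():
                raise PipelineError(f"stage={stage}: missing input file {p}")
        try:
            rec = read_eeg(eeg_path, montage=montage)
            rec = resample(rec, cfg.rate)
            rec = broadband_filter(rec)
            rec = mask_artifacts(rec, cfg.amp_thresh, cfg.artifact_pad)
        except Exception as exc:
            raise PipelineError(f"stage=preprocess [{pid}/{cond}]: {exc}") from exc
        try:
            _frame, eig = conn.band_connectivity(
                rec, montage, band=cfg.band, window=cfg.window, hop=cfg.hop)
        except Exception as exc:
            raise PipelineError(f"stage=connectivity [{pid}/{cond}]: {exc}") from exc
        try:
            labels = st.incremental_kmeans(eig, k_max=cfg.k_max, seed=cfg.seed)
            baseline_n = max(3, int(0.2 * labels.window_starts.size))
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                labels = st.label_emotional(labels, baseline_windows=baseline_n)
            segments = st.state_segments(labels)
        except Exception as exc:
            raise PipelineError(f"stage=states [{pid}/{cond}]: {exc}") from exc
        try:
            gaze = read_gaze_csv(gaze_path)
            events = eye.detect_events(gaze, cfg.vel_thresh, cfg.min_fix)
            feats = eye.aggregate_by_state(events, gaze, labels, cond)
        except Exception as exc:
            raise PipelineError(f"stage=eyetrack [{pid}/{cond}]: {exc}") from exc

        eigp = eig.copy()
        eigp.insert(0, "participant", pid)
        eigp.insert(1, "condition", cond)
        eig_rows.append(eigp)
        label_rows.append(pd.DataFrame({
            "participant": pid, "condition": cond,
            "window_start": labels.window_starts,
            "cluster": labels.labels,
            "emotional": labels.emotional.astype(int),
        }))
        seg_rows.extend([pid, cond, s0, s1, int(flag)]
                        for s0, s1, flag in segments)
        featp = feats.copy()
        featp.insert(0, "participant", pid)
        eye_rows.append(featp)

    try:
        outputs = _write_reports(cfg, outdir, study, eig_rows, label_rows,
                                 seg_rows, eye_rows, indir)
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(f"stage=stats_report: {exc}") from exc

    for name in outputs:
        _validate_schema(outdir / name, name)
    manifest = {
        "kind": "emoconn-run",
        "parameters": asdict(cfg),
        "seed": cfg.seed,
        "checksums": {name: _sha256(outdir / name) for name in outputs},
    }
    (outdir / "run_manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True))
    return outdir


def _write_reports(cfg, outdir, study, eig_rows, label_rows, seg_rows,
                   eye_rows, indir) -> list[str]:
    eig_all = pd.concat(eig_rows, ignore_index=True)
    eig_all.to_csv(outdir / "eigenvalues.csv", index=False,
                   float_format=_FLOAT_FMT)
    lab = pd.concat(label_rows, ignore_index=True)
    lab = lab[OUTPUT_SCHEMAS["state_labels.csv"]]
    lab.to_csv(outdir / "state_labels.csv", index=False, float_format=_FLOAT_FMT)
    pd.DataFrame(seg_rows, columns=OUTPUT_SCHEMAS["state_segments.tsv"]).to_csv(
        outdir / "state_segments.tsv", sep="\t", index=False,
        float_format=_FLOAT_FMT)
    eye_all = pd.concat(eye_rows, ignore_index=True)
    eye_all = eye_all[OUTPUT_SCHEMAS["eye_features.csv"]]
    eye_all.to_csv(outdir / "eye_features.csv", index=False,
                   float_format=_FLOAT_FMT)

    scores = pd.read_csv(indir / "scores.csv")
    anova_rows = []
    for feature in ("arousal", "valence"):
        groups = {c: scores.loc[scores.condition == c, feature].to_numpy()
                  for c in sr.CONDITIONS}
        f, p, (dfb, dfw) = sr.one_way_anova(list(groups.values()))
        anova_rows.append({"feature": feature, "F": f, "p": p,
                           "df_between": dfb, "df_within": dfw})
        res = sr.tukey_hsd(groups, family_alpha=cfg.alpha)
        res.table.to_csv(outdir / f"tukey_{feature}.csv", index=False,
                         float_format=_FLOAT_FMT)
    for g in conn.EIG_GROUPS:
        pc = sr.participant_condition_means(eig_all, f"e_{g}")
        groups = [pc.loc[pc.condition == c, f"e_{g}"].to_numpy()
                  for c in sr.CONDITIONS]
        if all(len(x) >= 2 for x in groups):
            f, p, (dfb, dfw) = sr.one_way_anova(groups)
            anova_rows.append({"feature": f"e_{g}", "F": f, "p": p,
                               "df_between": dfb, "df_within": dfw})
    pd.DataFrame(anova_rows).to_csv(outdir / "anova.csv", index=False,
                                    float_format=_FLOAT_FMT)

    # condition-profile concordance: eigenvalues vs emotional-state eye features
    eig_cond = (eig_all.groupby("condition")[[f"e_{g}" for g in conn.EIG_GROUPS]]
                .mean())
    emo = eye_all[eye_all.state == "emotional"]
    eye_cols = ["mean_fixation_duration_s", "saccade_rate_hz",
                "pupil_change_left_pct", "pupil_change_right_pct"]
    conc_name = []
    if not emo.empty and set(sr.CONDITIONS) <= set(emo.condition):
        eye_cond = emo.groupby("condition")[eye_cols].mean()
        sr.compare_profiles(eig_cond, eye_cond).to_csv(
            outdir / "profile_concordance.csv", index=False,
            float_format=_FLOAT_FMT)
        conc_name = ["profile_concordance.csv"]

    return ["eigenvalues.csv", "state_labels.csv", "state_segments.tsv",
            "eye_features.csv", "tukey_arousal.csv", "tukey_valence.csv",
            "anova.csv"] + conc_name
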