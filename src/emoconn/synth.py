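"""Synthetic study generator with known ground truth.

Emulates the structure the pipeline measures, without claiming biophysical
realism:

* EEG: per-channel 1/f background plus band-limited oscillations; coupled
  channel pairs share a common narrowband source mixed as
  ``sqrt(strength) * common + sqrt(1 - strength) * private`` so the planted
  phase-locking has a closed-form expectation, with an imposed phase lag and
  power ratio, gated by a two-state (non-emotional / emotional) schedule.
* Gaze: fixations with slow AR(1) positional jitter (sd 0.2 deg),
  minimum-jerk saccades at scheduled times, pupil diameter as baseline +
  scheduled percent excursions + AR(1) noise (phi = 0.95, mimicking slow
  pupil dynamics).
* Study: per-participant sessions for all four valence-arousal conditions
  with participant-level random effects, plus subjective arousal/valence
  scores on a 9-point scale.

Everything is deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.signal import butter, hilbert, sosfiltfilt

from .montage import Montage, build_montage, classify_pairs
from .preprocess import BANDS, EEGRecording, InputError
from .eyetrack import GazeRecording
from .stats_report import CONDITIONS

__all__ = [
    "CouplingEntry",
    "SaccadeSpec",
    "SessionConfig",
    "GroundTruth",
    "generate_eeg",
    "generate_gaze",
    "generate_study",
    "generate_eigenvalue_schedule",
    "StudyBundle",
    "ConditionEffects",
    "default_effect_profile",
    "default_session_couplings",
    "null_effect_profile",
]

NON_EMOTIONAL = "non-emotional"
EMOTIONAL = "emotional"

#: Leading region per pair-group: its channels carry sqrt(power_ratio) and
#: zero lag; the other side of each pair carries the phase lag.
_LEAD_REGION = {"LD_OF": "occipital", "LD_PF": "prefrontal", "SD": "frontal"}


class ConfigurationError(ValueError):
    """Invalid synthetic-session configuration."""


@dataclass(frozen=True)
class CouplingEntry:
    """One planted coupling: a pair-group name or an explicit (a, b) pair."""

    target: str | tuple[str, str]
    band: str = "beta"
    phase_lag: float = 0.0  # rad, phase of the leading side minus the other
    strength: float = 0.8  # shared-source mixing weight in [0, 1]
    power_ratio: float = 1.0  # leading-side power / other-side power
    active_states: tuple[str, ...] = (EMOTIONAL,)
    #: uV RMS of the coupled band component.  The default matches the band
    #: power an uncoupled channel carries in beta (private oscillation plus
    #: 1/f background), so power_ratio -- not coupling itself -- controls
    #: every power asymmetry the pipeline measures.
    amplitude: float = 5.4

    def __post_init__(self) -> None:
        if not (0.0 <= self.strength <= 1.0):
            raise ConfigurationError("coupling strength must be in [0, 1]")
        if self.power_ratio <= 0:
            raise ConfigurationError("power_ratio must be positive")
        if self.band not in BANDS:
            raise ConfigurationError(f"unknown band {self.band!r}")


@dataclass(frozen=True)
class SaccadeSpec:
    time: float  # onset, s
    amplitude: float  # deg
    direction: float = 0.0  # rad
    duration: float = 0.05  # s


@dataclass(frozen=True)
class SessionConfig:
    """One recording session of the 2x2 design."""

    condition: str = "pleasant-aroused"
    duration: float = 360.0  # s; a 6-minute video viewing
    eeg_rate: float = 500.0
    gaze_rate: float = 60.0
    state_schedule: tuple[tuple[float, float, str], ...] = ()
    gaze_events: tuple[SaccadeSpec, ...] = ()
    pupil_excursions: tuple[tuple[float, float, float, float], ...] = ()
    pupil_baseline: tuple[float, float] = (3.5, 3.5)  # mm
    pupil_noise_sd: float = 0.03  # mm, stationary sd of the AR(1) noise
    fixation_jitter_sd: float = 0.2  # deg
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration <= 0 or self.eeg_rate <= 0 or self.gaze_rate <= 0:
            raise ConfigurationError("duration and rates must be positive")
        sched = self.state_schedule
        if not sched:
            sched = ((0.0, self.duration, NON_EMOTIONAL),)
            object.__setattr__(self, "state_schedule", sched)
        pos = 0.0
        for s0, s1, _state in sched:
            if abs(s0 - pos) > 1e-9 or s1 <= s0:
                raise ConfigurationError("state schedule must tile [0, duration]")
            pos = s1
        if abs(pos - self.duration) > 1e-9:
            raise ConfigurationError("state schedule must end at duration")

    def state_at(self, t: float) -> str:
        for s0, s1, state in self.state_schedule:
            if s0 <= t < s1:
                return state
        return self.state_schedule[-1][2]


@dataclass(frozen=True)
class GroundTruth:
    """Planted structure of one session, derivable from (config, seed)."""

    config: SessionConfig
    couplings: tuple[CouplingEntry, ...] = ()
    coupling_pairs: dict = field(default_factory=dict)  # entry idx -> pairs
    gaze_events: tuple[SaccadeSpec, ...] = ()
    pupil_excursions: tuple[tuple[float, float, float, float], ...] = ()

    def true_window_states(self, window_starts: np.ndarray,
                           window: float) -> np.ndarray:
        """State of each analysis window, decided at the window center."""
        centers = np.asarray(window_starts) + window / 2.0
        return np.array([self.config.state_at(t) for t in centers])


def _state_indicator(cfg: SessionConfig, t: np.ndarray,
                     states: tuple[str, ...]) -> np.ndarray:
    g = np.zeros(t.size)
    for s0, s1, state in cfg.state_schedule:
        if state in states:
            g[(t >= s0) & (t < s1)] = 1.0
    return g


def _pink_noise(rng: np.random.Generator, n: int, rate: float,
                rms: float) -> np.ndarray:
    """1/f-power noise band-limited to 0.5-45 Hz."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n, d=1.0 / rate)
    shape = np.zeros_like(f)
    sel = (f >= 0.5) & (f <= 45.0)
    shape[sel] = 1.0 / np.sqrt(f[sel])
    x = np.fft.irfft(spec * shape, n)
    sd = x.std()
    return x * (rms / sd) if sd > 0 else x


def _narrowband_analytic(rng: np.random.Generator, n: int, rate: float,
                         lo: float, hi: float) -> np.ndarray:
    """Unit-RMS analytic (complex) narrowband noise in [lo, hi] Hz."""
    sos = butter(4, [max(lo, 0.3), hi], btype="bandpass", fs=rate, output="sos")
    x = sosfiltfilt(sos, rng.standard_normal(n))
    z = hilbert(x)
    sd = np.real(z).std()
    return z / (sd if sd > 0 else 1.0)


def _oscillator_analytic(rng: np.random.Generator, n: int, rate: float,
                         lo: float, hi: float) -> np.ndarray:
    """Constant-envelope analytic oscillator wandering inside [lo, hi] Hz.

    Instantaneous frequency follows an AR(1) (correlation time ~0.5 s) around
    the band center, staying in the central half of the band where the
    band-power estimator's response is flat.  |z| = 1 everywhere, so a
    planted power ratio shows up in windowed band power with minimal
    estimator noise; the result is scaled to unit real RMS.
    """
    fc = 0.5 * (lo + hi)
    f_sd = (hi - lo) / 8.0
    phi = np.exp(-1.0 / (0.5 * rate))
    half = (hi - lo) / 4.0
    f = fc + np.clip(_ar1(rng, n, phi, f_sd), -half, half)
    phase = 2 * np.pi * np.cumsum(f) / rate + rng.uniform(0, 2 * np.pi)
    return np.sqrt(2.0) * np.exp(1j * phase)


def _entry_roles(entry: CouplingEntry, montage: Montage) -> tuple[list, list]:
    """(leading channels, lagging channels) for a coupling entry."""
    if isinstance(entry.target, tuple):
        a, b = entry.target
        for ch in (a, b):
            if ch not in montage.channels:
                raise ConfigurationError(f"coupling channel {ch!r} not in montage")
        return [a], [b]
    pairs = [pg for pg in classify_pairs(montage) if pg.group == entry.target]
    if not pairs:
        raise ConfigurationError(f"unknown or empty pair-group {entry.target!r}")
    lead_region = _LEAD_REGION[entry.target]
    chans = sorted({ch for pg in pairs for ch in pg.pair},
                   key=montage.channels.index)
    lead = [ch for ch in chans if montage.regions[ch] == lead_region]
    lag = [ch for ch in chans if montage.regions[ch] != lead_region]
    return lead, lag


def _bandstop(x: np.ndarray, rate: float, lo: float, hi: float) -> np.ndarray:
    sos = butter(4, [max(lo, 0.3), hi], btype="bandstop", fs=rate, output="sos")
    return sosfiltfilt(sos, x)


def generate_eeg(cfg: SessionConfig, coupling: tuple[CouplingEntry, ...] = (),
                 montage: Montage | None = None,
                 background_rms: float = 10.0,
                 private_band_rms: float = 3.0,
                 ) -> tuple[EEGRecording, GroundTruth]:
    """Coupled multichannel EEG per the session config; deterministic in seed.

    A coupling entry *owns* its band on the channels it touches: their 1/f
    background is band-stopped there and the band content is exactly

        amp(t) * (sqrt(s * g(t)) * common  +  sqrt(1 - s * g(t)) * private),

    where g(t) gates the entry's active states, so the planted phase-locking
    has the closed-form expectation plv ~ strength while active and ~0 while
    inactive, and amp(t) carries sqrt(power_ratio) on the leading side only
    while active.  Uncoupled channels keep background plus independent
    band-limited oscillations in all four bands.
    """
    montage = montage or build_montage()
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 101]))
    n = int(round(cfg.duration * cfg.eeg_rate))
    t = np.arange(n) / cfg.eeg_rate
    n_ch = len(montage.channels)
    ch_idx = {c: i for i, c in enumerate(montage.channels)}

    # which (channel, band) slots are owned by a coupling entry
    roles: list[tuple[list, list]] = [_entry_roles(e, montage) for e in coupling]
    owned: dict[str, set[str]] = {}
    for entry, (lead, lag) in zip(coupling, roles):
        for ch in lead + lag:
            owned.setdefault(ch, set()).add(entry.band)

    data = np.empty((n_ch, n))
    for ch, i in ch_idx.items():
        x = _pink_noise(rng, n, cfg.eeg_rate, background_rms)
        for band_name in owned.get(ch, ()):
            band = BANDS[band_name]
            x = _bandstop(x, cfg.eeg_rate, band.lo, band.hi)
        for band in BANDS.values():
            if band.name in owned.get(ch, ()):
                continue
            z = _narrowband_analytic(rng, n, cfg.eeg_rate,
                                     band.lo if band.lo > 0 else 0.5, band.hi)
            x = x + private_band_rms * np.real(z)
        data[i] = x

    coupling_pairs: dict[int, tuple] = {}
    for k, (entry, (lead, lag)) in enumerate(zip(coupling, roles)):
        coupling_pairs[k] = (tuple(lead), tuple(lag))
        band = BANDS[entry.band]
        lo = band.lo if band.lo > 0 else 0.5
        common = _oscillator_analytic(rng, n, cfg.eeg_rate, lo, band.hi)
        gate = _state_indicator(cfg, t, entry.active_states)
        s_eff = entry.strength * gate
        w_common = np.sqrt(s_eff)
        w_private = np.sqrt(1.0 - s_eff)
        for ch in lead:
            private = _narrowband_analytic(rng, n, cfg.eeg_rate, lo, band.hi)
            amp = entry.amplitude * np.where(gate > 0,
                                             np.sqrt(entry.power_ratio), 1.0)
            data[ch_idx[ch]] += amp * (w_common * np.real(common)
                                       + w_private * np.real(private))
        for ch in lag:
            private = _narrowband_analytic(rng, n, cfg.eeg_rate, lo, band.hi)
            lagged = np.real(common * np.exp(-1j * entry.phase_lag))
            data[ch_idx[ch]] += entry.amplitude * (w_common * lagged
                                                   + w_private * np.real(private))

    rec = EEGRecording(data=data, rate=cfg.eeg_rate, channels=montage.channels)
    truth = GroundTruth(config=cfg, couplings=tuple(coupling),
                        coupling_pairs=coupling_pairs,
                        gaze_events=cfg.gaze_events,
                        pupil_excursions=cfg.pupil_excursions)
    return rec, truth


def _min_jerk(tau: np.ndarray) -> np.ndarray:
    return 10 * tau**3 - 15 * tau**4 + 6 * tau**5


def _ar1(rng: np.random.Generator, n: int, phi: float, sd: float) -> np.ndarray:
    """Stationary AR(1) with the given marginal sd."""
    innov_sd = sd * np.sqrt(1 - phi * phi)
    x = np.empty(n)
    x[0] = rng.normal(0, sd)
    eps = rng.normal(0, innov_sd, n)
    for i in range(1, n):
        x[i] = phi * x[i - 1] + eps[i]
    return x


def generate_gaze(cfg: SessionConfig) -> tuple[GazeRecording, GroundTruth]:
    """Gaze/pupil streams with scheduled saccades and pupil excursions.

    Gaze holds a fixation (AR(1) jitter, marginal sd ``fixation_jitter_sd``)
    except during scheduled minimum-jerk saccades; an empty event schedule
    yields a single session-long fixation.
    """
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 202]))
    n = int(round(cfg.duration * cfg.gaze_rate))
    t = np.arange(n) / cfg.gaze_rate

    events = sorted(cfg.gaze_events, key=lambda e: e.time)
    last_end = -np.inf
    for ev in events:
        if ev.time < last_end:
            raise ConfigurationError("scheduled gaze events overlap")
        if ev.duration <= 0:
            raise ConfigurationError("saccade duration must be positive")
        last_end = ev.time + ev.duration

    x = np.zeros(n)
    y = np.zeros(n)
    pos = np.array([0.0, 0.0])
    for ev in events:
        target = pos + ev.amplitude * np.array(
            [np.cos(ev.direction), np.sin(ev.direction)])
        during = (t >= ev.time) & (t < ev.time + ev.duration)
        after = t >= ev.time + ev.duration
        tau = (t[during] - ev.time) / ev.duration
        x[during] = pos[0] + (target[0] - pos[0]) * _min_jerk(tau)
        y[during] = pos[1] + (target[1] - pos[1]) * _min_jerk(tau)
        x[after] = target[0]
        y[after] = target[1]
        pos = target

    # fixation jitter: slow AR(1) drift, frozen during saccades
    in_sacc = np.zeros(n, dtype=bool)
    for ev in events:
        in_sacc |= (t >= ev.time) & (t < ev.time + ev.duration)
    jx = _ar1(rng, n, 0.8, cfg.fixation_jitter_sd)
    jy = _ar1(rng, n, 0.8, cfg.fixation_jitter_sd)
    x[~in_sacc] += jx[~in_sacc]
    y[~in_sacc] += jy[~in_sacc]

    bl, br = cfg.pupil_baseline
    pl = np.full(n, bl) + _ar1(rng, n, 0.95, cfg.pupil_noise_sd)
    pr = np.full(n, br) + _ar1(rng, n, 0.95, cfg.pupil_noise_sd)
    for s0, s1, pct_l, pct_r in cfg.pupil_excursions:
        sel = (t >= s0) & (t < s1)
        pl[sel] += bl * pct_l / 100.0
        pr[sel] += br * pct_r / 100.0

    g = GazeRecording(t=t, x=x, y=y, pupil_left=pl, pupil_right=pr,
                      valid=np.ones(n, dtype=bool))
    truth = GroundTruth(config=cfg, gaze_events=tuple(events),
                        pupil_excursions=tuple(cfg.pupil_excursions))
    return g, truth


@dataclass(frozen=True)
class ConditionEffects:
    """Per-condition generator parameters (the planted effect profile)."""

    arousal_mean: float
    valence_mean: float
    arousal_sd: float = 1.3  # residual sd backed out of the printed Tukey CIs
    valence_sd: float = 1.0
    # planted band-power multipliers of the occipital / prefrontal / frontal
    # lead channels while the emotional state is active (see _lead_couplings
    # for the eigenvalue displacements they realize)
    ld_of_ratio: float = 1.0
    ld_pf_ratio: float = 1.0
    sd_ratio: float = 1.0
    coupling_strength: float = 0.9
    phase_lag: float = np.pi / 6
    pupil_pct_left: float = 0.0  # excursion during emotional segments, %
    pupil_pct_right: float = 0.0
    fixation_mean_s: float = 0.30  # mean fixation duration while emotional
    fixation_baseline_s: float = 0.25  # while non-emotional
    saccade_rate_hz: float = 2.0
    saccade_amp_deg: float = 6.0


def default_effect_profile() -> dict[str, ConditionEffects]:
    """Condition effects reproducing the study's qualitative pattern.

    Subjective-score means are anchored at the pleasant-aroused condition
    (arousal 5.5, valence 6.2 on a 9-point scale) and offset by the pairwise
    mean differences of the printed arousal/valence comparison tables.
    Physiological effects follow the reported direction: frontal dominance
    (negative occipital-frontal eigenvalue) when unpleasant-aroused,
    prefrontal dominance under pleasant valence, short-distance connectivity
    strongest when relaxed, pupil change largest when pleasant-aroused,
    fixations longest and saccades rarest when unpleasant-relaxed.
    """
    return {
        "pleasant-aroused": ConditionEffects(
            arousal_mean=5.5, valence_mean=6.2,
            ld_of_ratio=1.6, ld_pf_ratio=1.55, sd_ratio=0.45,
            pupil_pct_left=10.0, pupil_pct_right=10.0,
            fixation_mean_s=0.30, saccade_rate_hz=2.0),
        "pleasant-relaxed": ConditionEffects(
            arousal_mean=3.2917, valence_mean=6.075,
            ld_of_ratio=1.05, ld_pf_ratio=1.5, sd_ratio=1.9,
            pupil_pct_left=7.0, pupil_pct_right=7.0,
            fixation_mean_s=0.32, saccade_rate_hz=2.5),
        "unpleasant-relaxed": ConditionEffects(
            arousal_mean=4.7917, valence_mean=3.0958,
            ld_of_ratio=1.0, ld_pf_ratio=0.35, sd_ratio=2.0,
            pupil_pct_left=5.0, pupil_pct_right=6.0,
            fixation_mean_s=0.45, saccade_rate_hz=1.2),
        "unpleasant-aroused": ConditionEffects(
            arousal_mean=6.4375, valence_mean=2.575,
            ld_of_ratio=0.35, ld_pf_ratio=0.55, sd_ratio=1.5,
            pupil_pct_left=2.0, pupil_pct_right=2.0,
            fixation_mean_s=0.28, saccade_rate_hz=1.8),
    }


def _lead_couplings(ld_of_ratio: float, ld_pf_ratio: float, sd_ratio: float,
                    phase_lag: float, strength: float,
                    ) -> tuple[CouplingEntry, ...]:
    """Couplings that raise whole region powers while the emotional state is on.

    Every occipital channel leads with ``ld_of_ratio``, every prefrontal
    channel with ``ld_pf_ratio`` and every frontal channel with ``sd_ratio``;
    lag partners are temporal/central/parietal channels, which keep matched
    (ratio-1) power, one coupling entry per channel so nothing stacks.  With
    baseline per-pair band power P0 the expected emotional displacement of
    the three eigenvalues is the linear mixture

        d_LD_OF = P0 * [(a-1) - (1/3)(b-1) - (2/3)(c-1)]
        d_LD_PF = P0 * (b-1)
        d_SD    = P0 * (10/21)(c-1)

    for (a, b, c) = (ld_of_ratio, ld_pf_ratio, sd_ratio), because prefrontal
    and frontal channels also sit on the second side of occipital-frontal
    pairs, and frontal channels lead 10 of the 21 short-distance pairs.
    """
    def _ent(pair, ratio):
        return CouplingEntry(pair, band="beta", phase_lag=phase_lag,
                             strength=strength, power_ratio=ratio)
    return (
        _ent(("O1", "T5"), ld_of_ratio), _ent(("O2", "T6"), ld_of_ratio),
        _ent(("Fp1", "C3"), ld_pf_ratio), _ent(("Fp2", "C4"), ld_pf_ratio),
        _ent(("F7", "T3"), sd_ratio), _ent(("F3", "Cz"), sd_ratio),
        _ent(("F4", "Pz"), sd_ratio), _ent(("F8", "T4"), sd_ratio),
    )


def default_session_couplings(phase_lag: float = np.pi / 6,
                              strength: float = 0.9,
                              ld_of_ratio: float = 1.0,
                              ld_pf_ratio: float = 2.2,
                              sd_ratio: float = 2.2,
                              ) -> tuple[CouplingEntry, ...]:
    """Default planted couplings for a single two-state session.

    Region-level power asymmetries (see :func:`_lead_couplings`) that
    displace all three eigenvalues well clear of their baseline noise once
    the emotional state switches on: prefrontal and frontal dominance drives
    the occipital-frontal eigenvalue negative while lifting the prefrontal
    and short-distance eigenvalues, without raising the occipital power whose
    fluctuations would otherwise dominate the LD_OF noise.
    """
    return _lead_couplings(ld_of_ratio, ld_pf_ratio, sd_ratio,
                           phase_lag, strength)


def generate_eigenvalue_schedule(n_windows: int = 60,
                                 frac_emotional: float = 0.6,
                                 separation: float = 8.0,
                                 within_sd: float = 0.02,
                                 hop: float = 0.5,
                                 seed: int = 0) -> tuple[pd.DataFrame, np.ndarray]:
    """Two-state eigenvalue series planted directly in eigenvalue space.

    The last ``frac_emotional`` of the windows is displaced by
    ``separation * within_sd`` along each of the three eigenvalue axes on
    top of isotropic Gaussian noise.  Returns the series in the layout the
    clustering consumes plus the true emotional flags.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 505]))
    n_emo = int(round(frac_emotional * n_windows))
    true = np.zeros(n_windows, dtype=bool)
    true[n_windows - n_emo:] = True
    x = rng.normal(0.0, within_sd, size=(n_windows, 3))
    x[true] += separation * within_sd
    df = pd.DataFrame({
        "window_start": np.arange(n_windows) * hop,
        "band": "beta",
        "e_LD_OF": x[:, 0], "e_LD_PF": x[:, 1], "e_SD": x[:, 2],
    })
    for g in ("LD_OF", "LD_PF", "SD"):
        df[f"abs_{g}"] = df[f"e_{g}"].abs()
    return df, true


def null_effect_profile() -> dict[str, ConditionEffects]:
    """Identical conditions: no planted effects anywhere (type-I testing)."""
    eff = ConditionEffects(arousal_mean=4.0, valence_mean=4.0)
    return {c: eff for c in CONDITIONS}


def _default_schedule(duration: float) -> tuple[tuple[float, float, str], ...]:
    """Pre-stimulus baseline for the first 30% of the session, then emotional."""
    split = round(0.3 * duration, 6)
    return ((0.0, split, NON_EMOTIONAL), (split, duration, EMOTIONAL))


def _build_gaze_schedule(rng: np.random.Generator, cfg: SessionConfig,
                         eff: ConditionEffects) -> tuple[tuple[SaccadeSpec, ...],
                                                         tuple]:
    """Alternating fixation/saccade schedule honoring per-state parameters."""
    events: list[SaccadeSpec] = []
    t_cur = 0.0
    pos = np.array([0.0, 0.0])
    while True:
        state = cfg.state_at(min(t_cur, cfg.duration - 1e-6))
        mean_fix = (eff.fixation_mean_s if state == EMOTIONAL
                    else eff.fixation_baseline_s)
        # per-state saccade spacing: rate applies while emotional
        if state == EMOTIONAL and eff.saccade_rate_hz > 0:
            mean_fix = max(mean_fix, 1.0 / eff.saccade_rate_hz - 0.05)
        fix_dur = rng.gamma(4.0, mean_fix / 4.0)
        t_next = t_cur + max(fix_dur, 0.15)
        if t_next + 0.06 >= cfg.duration:
            break
        amp = float(np.clip(rng.normal(eff.saccade_amp_deg, 1.0), 2.0, 14.0))
        # steer back toward the screen center when drifting out
        if np.hypot(*pos) > 12.0:
            direction = float(np.arctan2(-pos[1], -pos[0]) + rng.normal(0, 0.3))
        else:
            direction = float(rng.uniform(-np.pi, np.pi))
        events.append(SaccadeSpec(time=round(t_next, 4), amplitude=amp,
                                  direction=direction, duration=0.05))
        pos = pos + amp * np.array([np.cos(direction), np.sin(direction)])
        t_cur = t_next + 0.05

    excursions = tuple(
        (s0, s1, eff.pupil_pct_left, eff.pupil_pct_right)
        for s0, s1, state in cfg.state_schedule if state == EMOTIONAL)
    return tuple(events), excursions


@dataclass(frozen=True)
class StudyBundle:
    """A complete simulated study: scores now, physiology on demand."""

    n_participants: int
    seed: int
    scores: pd.DataFrame  # participant, condition, arousal, valence
    session_configs: dict  # (participant, condition) -> SessionConfig
    session_couplings: dict  # (participant, condition) -> tuple[CouplingEntry]
    montage: Montage

    @property
    def sessions(self) -> list[tuple[str, str]]:
        return sorted(self.session_configs)

    def materialize(self, participant: str, condition: str
                    ) -> tuple[EEGRecording, GazeRecording, GroundTruth]:
        cfg = self.session_configs[(participant, condition)]
        rec, truth = generate_eeg(cfg, self.session_couplings[(participant, condition)],
                                  montage=self.montage)
        gaze, gtruth = generate_gaze(cfg)
        truth = replace(truth, gaze_events=gtruth.gaze_events,
                        pupil_excursions=gtruth.pupil_excursions)
        return rec, gaze, truth


def generate_study(n_participants: int = 47,
                   effect_profile: dict[str, ConditionEffects] | None = None,
                   seed: int = 0, duration: float = 360.0,
                   montage: Montage | None = None) -> StudyBundle:
    """Simulate ``n_participants`` x 4 conditions with random effects.

    Participant-level lognormal (sd 0.1) multipliers perturb the planted
    power ratios, and N(0, 0.5 %) offsets perturb pupil excursions, so
    participants differ the way a real cohort would.  Fully reproducible
    given ``seed``.
    """
    if n_participants < 2:
        raise ConfigurationError("need at least 2 participants")
    profile = effect_profile if effect_profile is not None else default_effect_profile()
    missing = set(CONDITIONS) - set(profile)
    if missing:
        raise ConfigurationError(f"effect profile missing conditions: {sorted(missing)}")
    montage = montage or build_montage()
    root = np.random.SeedSequence([seed, 303])
    rng = np.random.default_rng(root)

    rows = []
    session_configs: dict = {}
    session_couplings: dict = {}
    for p in range(n_participants):
        pid = f"p{p + 1:02d}"
        ratio_mult = float(rng.lognormal(0.0, 0.1))
        pupil_off = float(rng.normal(0.0, 0.5))
        for ci, cond in enumerate(CONDITIONS):
            eff = profile[cond]
            rows.append({
                "participant": pid,
                "condition": cond,
                "arousal": float(rng.normal(eff.arousal_mean, eff.arousal_sd)),
                "valence": float(rng.normal(eff.valence_mean, eff.valence_sd)),
            })
            sess_seed = int((seed * 7919 + p * 17 + ci + 1) % (2**31 - 1))
            eff_p = replace(
                eff,
                ld_of_ratio=eff.ld_of_ratio * ratio_mult,
                ld_pf_ratio=eff.ld_pf_ratio * ratio_mult,
                sd_ratio=eff.sd_ratio * ratio_mult,
                pupil_pct_left=eff.pupil_pct_left + pupil_off,
                pupil_pct_right=eff.pupil_pct_right + pupil_off,
            )
            cfg = SessionConfig(condition=cond, duration=duration,
                                state_schedule=_default_schedule(duration),
                                seed=sess_seed)
            ev, exc = _build_gaze_schedule(
                np.random.default_rng(np.random.SeedSequence([sess_seed, 404])),
                cfg, eff_p)
            cfg = replace(cfg, gaze_events=ev, pupil_excursions=exc)
            session_configs[(pid, cond)] = cfg
            session_couplings[(pid, cond)] = _lead_couplings(
                eff_p.ld_of_ratio, eff_p.ld_pf_ratio, eff_p.sd_ratio,
                eff.phase_lag, eff.coupling_strength)
    scores = pd.DataFrame(rows)
    return StudyBundle(n_participants=n_participants, seed=seed, scores=scores,
                       session_configs=session_configs,
                       session_couplings=session_couplings, montage=montage)
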