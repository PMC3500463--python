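"""Synthetic TMS-EEG cohort generator with known ground truth.

Simulates 64-channel scalp EEG (plus 4 EOG channels) at 1048 Hz as an
additive model

    recording = evoked templates + 1/f noise + white noise + 50 Hz line
                + blinks + TMS pulse artifacts,

with stimulus-locked evoked components whose condition structure mirrors the
figure-ground paradigm: a peri-occipital figure-minus-homogenous negativity
supported on 137-211 ms, a stack-minus-frame positivity supported on
227-313 ms, and per-TMS-window gain factors that attenuate these components
(early TMS attenuates both; intermediate TMS leaves the surface component
untouched). Behavior is drawn from per-condition confusion matrices and a
log-normal reaction-time model. The noiseless evoked stream is retained as
ground truth for parameter-recovery tests.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from figground.stimuli import (
    STIMULUS_KINDS,
    TMS_CONDITIONS,
    TrialSchedule,
    spawn_seeds,
)

#: a priori peri-occipital analysis pool
POOL_CHANNELS = ("O1", "O2", "Oz", "POz", "PO3", "PO4", "PO5", "PO6", "PO7", "PO8")

SCALP_64 = (
    "Fp1 Fpz Fp2 AF7 AF3 AFz AF4 AF8 F7 F5 F3 F1 Fz F2 F4 F6 F8 "
    "FT7 FC5 FC3 FC1 FCz FC2 FC4 FC6 FT8 T7 C5 C3 C1 Cz C2 C4 C6 T8 "
    "TP7 CP5 CP3 CP1 CPz CP2 CP4 CP6 TP8 P7 P5 P3 P1 Pz P2 P4 P6 P8 "
    "PO7 PO5 PO3 POz PO4 PO6 PO8 O1 Oz O2 Iz"
).split()

EOG_4 = ("HEOGL", "HEOGR", "VEOGU", "VEOGL")


@dataclass(frozen=True)
class Montage:
    """64 scalp labels with unit-sphere coordinates, plus 4 EOG labels."""

    ch_names: tuple[str, ...]
    positions: np.ndarray  # (n_scalp, 3), unit norm
    eog_names: tuple[str, ...] = EOG_4

    def __post_init__(self):
        if len(set(self.ch_names)) != len(self.ch_names):
            raise ValueError("channel labels must be unique")
        norms = np.linalg.norm(self.positions, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-6):
            raise ValueError("scalp coordinates must have unit norm")
        missing = [c for c in POOL_CHANNELS if c not in self.ch_names]
        if missing:
            raise ValueError(f"montage is missing pooled channels: {missing}")

    @property
    def all_names(self) -> tuple[str, ...]:
        return self.ch_names + self.eog_names

    @property
    def n_scalp(self) -> int:
        return len(self.ch_names)

    def index(self, name: str) -> int:
        return self.all_names.index(name)

    def pool_indices(self) -> np.ndarray:
        return np.array([self.ch_names.index(c) for c in POOL_CHANNELS])

    @classmethod
    def standard(cls) -> "Montage":
        """64-channel 10-10 montage with mne's standard electrode positions."""
        import warnings

        import mne

        with warnings.catch_warnings():
            warnings.simplefilter("ignore", FutureWarning)
            std = mne.channels.make_standard_montage("standard_1005")
        pos = std.get_positions()["ch_pos"]
        pts = np.array([pos[c] for c in SCALP_64], dtype=float)
        pts /= np.linalg.norm(pts, axis=1, keepdims=True)
        return cls(ch_names=tuple(SCALP_64), positions=pts)


def occipital_weights(montage: Montage, sigma_deg: float = 38.0) -> np.ndarray:
    """Spatial profile of the evoked components: a Gaussian in angular
    distance from the peri-occipital pool centroid, normalised so the mean
    weight over the pooled channels is 1 (pooled amplitude == template
    amplitude)."""
    centre = montage.positions[montage.pool_indices()].mean(axis=0)
    centre /= np.linalg.norm(centre)
    ang = np.degrees(np.arccos(np.clip(montage.positions @ centre, -1, 1)))
    w = np.exp(-0.5 * (ang / sigma_deg) ** 2)
    return w / w[montage.pool_indices()].mean()


def half_cosine_bump(times_ms: np.ndarray, onset_ms: float, offset_ms: float) -> np.ndarray:
    """Raised-cosine window supported exactly on [onset, offset] ms."""
    out = np.zeros_like(times_ms, dtype=float)
    inside = (times_ms >= onset_ms) & (times_ms <= offset_ms)
    phase = (times_ms[inside] - onset_ms) / (offset_ms - onset_ms)
    out[inside] = 0.5 * (1.0 - np.cos(2 * np.pi * phase))
    return out


@dataclass(frozen=True)
class ERPComponent:
    """One evoked component: a raised-cosine bump with condition structure.

    ``kind_weights`` maps stimulus kind -> multiplicative weight;
    ``tms_gains`` maps TMS condition -> gain in [0, 1].
    """

    name: str
    onset_ms: float
    offset_ms: float
    amplitude_uv: float
    kind_weights: dict[str, float]
    tms_gains: dict[str, float]

    def __post_init__(self):
        if self.offset_ms <= self.onset_ms:
            raise ValueError("component offset must exceed onset")
        if any(not 0 <= g <= 1 for g in self.tms_gains.values()):
            raise ValueError("TMS gains must lie in [0, 1]")


@dataclass(frozen=True)
class ERPTemplateSet:
    """The set of injected evoked components plus their scalp profile width."""

    components: tuple[ERPComponent, ...]
    spatial_sigma_deg: float = 38.0

    @classmethod
    def default(cls) -> "ERPTemplateSet":
        """Default calibration: a -1.5 uV figure negativity (137-211 ms, on
        stack and frame), and a +1.0 uV surface positivity (227-313 ms, on
        stack only). Early TMS attenuates both (gain 0.2); intermediate TMS
        leaves both intact; late TMS halves the surface component only."""
        figure = ERPComponent(
            name="figure_negativity",
            onset_ms=137.0,
            offset_ms=211.0,
            amplitude_uv=-1.5,
            kind_weights={"stack": 1.0, "frame": 1.0, "homogenous": 0.0},
            tms_gains={"none": 1.0, "early": 0.2, "intermediate": 1.0, "late": 1.0},
        )
        surface = ERPComponent(
            name="surface_positivity",
            onset_ms=227.0,
            offset_ms=313.0,
            amplitude_uv=1.0,
            kind_weights={"stack": 1.0, "frame": 0.0, "homogenous": 0.0},
            tms_gains={"none": 1.0, "early": 0.2, "intermediate": 1.0, "late": 0.5},
        )
        return cls(components=(figure, surface))

    def waveform(self, kind: str, tms: str, times_ms: np.ndarray) -> np.ndarray:
        """Pooled-peak evoked time course for one condition (uV)."""
        out = np.zeros_like(times_ms, dtype=float)
        for c in self.components:
            w = c.kind_weights.get(kind, 0.0) * c.tms_gains.get(tms, 1.0)
            if w:
                out += w * c.amplitude_uv * half_cosine_bump(times_ms, c.onset_ms, c.offset_ms)
        return out


def ground_truth_erp(
    kind: str,
    tms: str,
    templates: ERPTemplateSet,
    times_ms: np.ndarray,
    montage: Montage | None = None,
) -> np.ndarray:
    """Noiseless injected ERP for one condition.

    With ``montage=None`` returns the pooled peri-occipital trace (the
    spatial weights are normalised so the pooled mean equals the template
    amplitude); otherwise returns the full (n_scalp, n_times) pattern.
    """
    if kind not in STIMULUS_KINDS:
        raise ValueError(f"unknown kind {kind!r}")
    if tms not in TMS_CONDITIONS:
        raise ValueError(f"unknown TMS condition {tms!r}")
    pooled = templates.waveform(kind, tms, np.asarray(times_ms, dtype=float))
    if montage is None:
        return pooled
    w = occipital_weights(montage, templates.spatial_sigma_deg)
    return w[:, None] * pooled[None, :]


#: first-pulse onsets (ms post-stimulus) of the double pulse per TMS window
TMS_WINDOWS_MS = {"early": (96.0, 119.0), "intermediate": (156.0, 179.0), "late": (236.0, 259.0)}


@dataclass(frozen=True)
class TMSArtifactModel:
    """Double-pulse TMS artifact: biexponential envelope times a damped
    oscillation, clipped at +/-``clip_uv``. The two pulses of a pair are
    separated by 23 ms (a 45 Hz double pulse)."""

    windows_ms: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(TMS_WINDOWS_MS)
    )
    peak_uv: float = 3000.0
    decay_fast_ms: float = 1.5
    decay_slow_ms: float = 7.0
    ring_hz: float = 180.0
    clip_uv: float = 5000.0
    # truncated so the second pulse's artifact (pair onset + 23 ms + tail)
    # dies inside the -2..65 ms excision window
    duration_ms: float = 40.0

    def __post_init__(self):
        for cond, (a, b) in self.windows_ms.items():
            if not np.isclose(b - a, 23.0):
                raise ValueError(f"pulse pair separation must be 23 ms, got {b - a} ({cond})")

    def pulse_waveform(self, sfreq: float) -> np.ndarray:
        """Single-pulse artifact sampled at ``sfreq`` (uV)."""
        t = np.arange(0, self.duration_ms / 1000.0, 1.0 / sfreq)
        env = np.exp(-1000 * t / self.decay_slow_ms) - np.exp(-1000 * t / self.decay_fast_ms)
        env /= env.max()
        wave = self.peak_uv * env * np.cos(2 * np.pi * self.ring_hz * t)
        return np.clip(wave, -self.clip_uv, self.clip_uv)


@dataclass(frozen=True)
class NoiseModel:
    """Background activity: 1/f^alpha 'pink' process, white sensor noise,
    50 Hz mains, and stereotyped blinks at a Poisson rate. Amplitudes are
    standard deviations in uV at the single-trial level; ``subject_sigma``
    is the log-sd of the per-subject amplitude random effect."""

    pink_exponent: float = 1.0
    pink_sigma_uv: float = 9.0
    white_sigma_uv: float = 2.0
    line_amp_uv: float = 2.0
    line_hz: float = 50.0
    blink_rate_per_min: float = 4.0
    blink_amp_uv: float = 150.0
    blink_dur_ms: float = 300.0
    subject_sigma: float = 0.1

    def __post_init__(self):
        for name in ("pink_sigma_uv", "white_sigma_uv", "line_amp_uv",
                     "blink_rate_per_min", "blink_amp_uv", "subject_sigma"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    def scaled(self, factor: float) -> "NoiseModel":
        return dataclasses.replace(
            self,
            pink_sigma_uv=self.pink_sigma_uv * factor,
            white_sigma_uv=self.white_sigma_uv * factor,
            line_amp_uv=self.line_amp_uv * factor,
        )


def pink_noise(n: int, exponent: float, rng: np.random.Generator) -> np.ndarray:
    """Unit-variance 1/f^exponent noise via spectral shaping."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n)
    f[0] = f[1] if n > 1 else 1.0
    spec *= f ** (-exponent / 2.0)
    spec[0] = 0.0
    x = np.fft.irfft(spec, n)
    sd = x.std()
    return x / sd if sd > 0 else x


_KIND_INDEX = {k: i for i, k in enumerate(STIMULUS_KINDS)}


@dataclass(frozen=True)
class BehaviorModel:
    """Per-condition response confusion and reaction-time model.

    ``confusion[tms]`` is a 3x3 row-stochastic matrix, rows and columns
    ordered (stack, frame, homogenous): P(response | stimulus). RTs are
    log-normal with a per-kind median and additive per-condition shifts.
    With ``sham=True`` the no-TMS confusion is used for every condition
    (clicks alone do not change accuracy) while RT shifts still apply.
    """

    confusion: dict[str, np.ndarray]
    rt_median_ms: dict[str, float] = field(
        default_factory=lambda: {"stack": 590.0, "frame": 625.0, "homogenous": 560.0}
    )
    rt_shift_ms: dict[str, float] = field(
        default_factory=lambda: {"none": 0.0, "early": 32.0, "intermediate": 33.0, "late": 51.0}
    )
    rt_log_sigma: float = 0.25
    sham: bool = False

    def __post_init__(self):
        for cond, mat in self.confusion.items():
            mat = np.asarray(mat, dtype=float)
            if mat.shape != (3, 3):
                raise ValueError(f"confusion[{cond}] must be 3x3")
            if np.any(mat < 0) or np.any(mat > 1):
                raise ValueError("confusion entries must be probabilities")
            if not np.allclose(mat.sum(axis=1), 1.0, atol=1e-9):
                raise ValueError(f"confusion[{cond}] rows must sum to 1")

    @classmethod
    def default(cls, sham: bool = False) -> "BehaviorModel":
        """Calibration mirroring the qualitative behavioral pattern: early
        TMS lowers frame and stack accuracy via stack<->frame mix-ups, late
        TMS selectively lowers stack accuracy via stack->frame errors,
        and TMS of any timing slightly lowers homogenous accuracy."""
        conf = {
            #              resp:  stack  frame  homog      stim:
            "none": np.array([[0.86, 0.09, 0.05],        # stack
                              [0.09, 0.85, 0.06],        # frame
                              [0.03, 0.05, 0.92]]),      # homogenous
            "early": np.array([[0.72, 0.23, 0.05],
                               [0.22, 0.72, 0.06],
                               [0.05, 0.07, 0.88]]),
            "intermediate": np.array([[0.85, 0.10, 0.05],
                                      [0.10, 0.84, 0.06],
                                      [0.05, 0.08, 0.87]]),
            "late": np.array([[0.73, 0.22, 0.05],
                              [0.11, 0.83, 0.06],
                              [0.05, 0.07, 0.88]]),
        }
        return cls(confusion=conf, sham=sham)

    @classmethod
    def poor(cls) -> "BehaviorModel":
        """A near-chance responder on stack trials (overall accuracy <= 67%),
        used to exercise the subject-exclusion rule."""
        conf = {
            cond: np.array([[0.35, 0.40, 0.25],
                            [0.30, 0.45, 0.25],
                            [0.10, 0.10, 0.80]])
            for cond in TMS_CONDITIONS
        }
        return cls(confusion=conf)

    def sample_trial(self, kind: str, tms: str, rng: np.random.Generator) -> tuple[str, float]:
        cond = "none" if self.sham else tms
        row = np.asarray(self.confusion[cond])[_KIND_INDEX[kind]]
        response = STIMULUS_KINDS[rng.choice(3, p=row)]
        rt = self.rt_median_ms[kind] * np.exp(self.rt_log_sigma * rng.standard_normal())
        rt += self.rt_shift_ms[tms]
        return response, float(rt)


@dataclass
class SessionRecording:
    """One subject's continuous synthetic recording.

    ``data`` is (n_scalp + n_eog, n_samples) in uV; ``clean`` holds the
    noiseless evoked stream on the scalp channels (the recovery oracle).
    ``events`` columns: sample, kind, tms, trial_idx. ``pulse_events``
    columns: sample, tms, trial_idx (first pulse of each pair only in
    ``pair_onset`` form; both pulses listed).
    """

    data: np.ndarray
    sfreq: float
    montage: Montage
    events: pd.DataFrame
    pulse_events: pd.DataFrame
    subject: str
    clean: np.ndarray | None = None

    def __post_init__(self):
        ev = self.events["sample"].to_numpy()
        if len(ev) and np.any(np.diff(ev) <= 0):
            raise ValueError("event samples must be strictly increasing")

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def scalp(self) -> np.ndarray:
        return self.data[: self.montage.n_scalp]

    @property
    def eog(self) -> np.ndarray:
        return self.data[self.montage.n_scalp:]


def _blink_kernel(sfreq: float, dur_ms: float) -> np.ndarray:
    n = max(3, int(round(dur_ms / 1000.0 * sfreq)))
    return 0.5 * (1 - np.cos(2 * np.pi * np.arange(n) / (n - 1)))


def blink_topography(montage: Montage) -> np.ndarray:
    """Scalp propagation of the blink potential: strongest frontally,
    decaying towards posterior sites."""
    fpz = montage.positions[montage.ch_names.index("Fpz")]
    ang = np.degrees(np.arccos(np.clip(montage.positions @ fpz, -1, 1)))
    return np.exp(-ang / 55.0)


def simulate_subject(
    schedule: TrialSchedule,
    templates: ERPTemplateSet,
    artifact: TMSArtifactModel,
    noise: NoiseModel,
    behavior: BehaviorModel,
    montage: Montage,
    seed: int,
    sfreq: float = 1048.0,
    iti_s: float = 2.0,
    subject: str = "S01",
    amp_scale: float = 1.0,
) -> tuple[SessionRecording, pd.DataFrame]:
    """Simulate one subject's continuous session and behavioral table.

    The recording is the additive sum of the stimulus-locked evoked
    templates (scaled by the per-condition TMS gains and the subject's
    amplitude factor), background noise, blinks, and the TMS double-pulse
    artifact on TMS trials. Deterministic given the seed.
    """
    if len(schedule) == 0:
        raise ValueError("schedule must be nonempty")
    if iti_s < 1.2:
        raise ValueError(f"inter-trial interval {iti_s}s too short: epochs would overlap")
    rng = np.random.default_rng(np.random.SeedSequence(entropy=int(seed), spawn_key=(ord("r"),)))
    n_scalp = montage.n_scalp
    n_eog = len(montage.eog_names)
    pad = 1.0
    n_trials = len(schedule)
    n_samp = int(round((2 * pad + n_trials * iti_s) * sfreq))
    onsets = (pad + np.arange(n_trials) * iti_s) * sfreq
    onsets = np.round(onsets).astype(int)

    # --- evoked stream (ground truth) ---
    clean = np.zeros((n_scalp, n_samp), dtype=float)
    epoch_ms = np.arange(0, int(0.6 * sfreq)) / sfreq * 1000.0
    spatial = occipital_weights(montage, templates.spatial_sigma_deg)
    wave_cache: dict[tuple[str, str], np.ndarray] = {}
    table = schedule.table.reset_index(drop=True)
    for i, row in table.iterrows():
        key = (row["kind"], row["tms"])
        if key not in wave_cache:
            wave_cache[key] = templates.waveform(*key, epoch_ms)
        w = wave_cache[key]
        s = onsets[i]
        clean[:, s : s + len(w)] += amp_scale * spatial[:, None] * w[None, :]

    data = np.zeros((n_scalp + n_eog, n_samp), dtype=float)
    data[:n_scalp] = clean

    # --- TMS artifacts ---
    pulse_rows = []
    pulse = artifact.pulse_waveform(sfreq)
    art_topo = 0.4 + 0.6 * spatial / spatial.max()
    for i, row in table.iterrows():
        if row["tms"] == "none":
            continue
        for t_ms in artifact.windows_ms[row["tms"]]:
            s = onsets[i] + int(round(t_ms / 1000.0 * sfreq))
            seg = slice(s, s + len(pulse))
            data[:n_scalp, seg] += art_topo[:, None] * pulse[None, :]
            pulse_rows.append({"sample": s, "tms": row["tms"], "trial_idx": i})

    # --- background noise ---
    for ch in range(n_scalp):
        bg = noise.pink_sigma_uv * pink_noise(n_samp, noise.pink_exponent, rng)
        bg += noise.white_sigma_uv * rng.standard_normal(n_samp)
        phase = rng.uniform(0, 2 * np.pi)
        t = np.arange(n_samp) / sfreq
        bg += noise.line_amp_uv * np.sin(2 * np.pi * noise.line_hz * t + phase)
        data[ch] += bg

    # --- blinks on EOG + scalp propagation ---
    veog = np.zeros(n_samp)
    n_blinks = rng.poisson(noise.blink_rate_per_min * n_samp / sfreq / 60.0)
    kernel = _blink_kernel(sfreq, noise.blink_dur_ms)
    for _ in range(n_blinks):
        s = int(rng.integers(0, max(1, n_samp - len(kernel))))
        veog[s : s + len(kernel)] += noise.blink_amp_uv * kernel
    topo = blink_topography(montage)
    data[:n_scalp] += 0.35 * topo[:, None] * veog[None, :]
    eog_gain = np.array([0.25, 0.25, 1.0, -0.8])[:n_eog]
    data[n_scalp:] += eog_gain[:, None] * veog[None, :]
    data[n_scalp:] += noise.white_sigma_uv * rng.standard_normal((n_eog, n_samp))

    # --- behavior ---
    beh_rng = np.random.default_rng(
        np.random.SeedSequence(entropy=int(seed), spawn_key=(ord("b"),))
    )
    beh_rows = []
    for i, row in table.iterrows():
        response, rt = behavior.sample_trial(row["kind"], row["tms"], beh_rng)
        beh_rows.append(
            {"subject": subject, "block": row["block"], "trial": row["trial"],
             "kind": row["kind"], "tms": row["tms"], "response": response,
             "rt_ms": rt, "correct": response == row["kind"]}
        )

    events = pd.DataFrame(
        {"sample": onsets, "kind": table["kind"], "tms": table["tms"],
         "trial_idx": np.arange(n_trials)}
    )
    rec = SessionRecording(
        data=data, sfreq=sfreq, montage=montage, events=events,
        pulse_events=pd.DataFrame(pulse_rows, columns=["sample", "tms", "trial_idx"]),
        subject=subject, clean=clean,
    )
    return rec, pd.DataFrame(beh_rows)


def simulate_cohort(
    n_subjects: int,
    schedule: TrialSchedule,
    templates: ERPTemplateSet | None = None,
    artifact: TMSArtifactModel | None = None,
    noise: NoiseModel | None = None,
    behavior: BehaviorModel | None = None,
    montage: Montage | None = None,
    seed: int = 0,
    n_poor: int = 0,
    **subject_kwargs,
) -> tuple[list[SessionRecording], pd.DataFrame]:
    """Simulate a cohort; subject amplitude random effects are drawn once
    per subject. The last ``n_poor`` subjects respond near chance on stack
    trials (to exercise the accuracy-based exclusion rule).
    """
    if n_subjects < 2:
        raise ValueError("n_subjects must be >= 2 (paired statistics undefined otherwise)")
    templates = templates or ERPTemplateSet.default()
    artifact = artifact or TMSArtifactModel()
    noise = noise or NoiseModel()
    behavior = behavior or BehaviorModel.default()
    montage = montage or Montage.standard()
    rng = np.random.default_rng(np.random.SeedSequence(entropy=int(seed), spawn_key=(ord("c"),)))
    amp_scales = np.exp(noise.subject_sigma * rng.standard_normal(n_subjects))
    seeds = spawn_seeds(seed, n_subjects, key="subjects")
    recs, tables = [], []
    for j in range(n_subjects):
        beh = BehaviorModel.poor() if j >= n_subjects - n_poor else behavior
        rec, tab = simulate_subject(
            schedule, templates, artifact, noise, beh, montage,
            seed=int(seeds[j]), subject=f"S{j + 1:02d}",
            amp_scale=float(amp_scales[j]), **subject_kwargs,
        )
        recs.append(rec)
        tables.append(tab)
    return recs, pd.concat(tables, ignore_index=True)


def simulate_behavior_cohort(
    n_subjects: int,
    schedule: TrialSchedule,
    behavior: BehaviorModel | None = None,
    seed: int = 0,
    n_poor: int = 0,
) -> pd.DataFrame:
    """Behavior-only cohort (no EEG): fast path for behavioral statistics."""
    if n_subjects < 2:
        raise ValueError("n_subjects must be >= 2")
    behavior = behavior or BehaviorModel.default()
    seeds = spawn_seeds(seed, n_subjects, key="behsubjects")
    tables = []
    table = schedule.table.reset_index(drop=True)
    for j in range(n_subjects):
        beh = BehaviorModel.poor() if j >= n_subjects - n_poor else behavior
        rng = np.random.default_rng(
            np.random.SeedSequence(entropy=int(seeds[j]), spawn_key=(ord("b"),))
        )
        rows = []
        for _, row in table.iterrows():
            response, rt = beh.sample_trial(row["kind"], row["tms"], rng)
            rows.append(
                {"subject": f"S{j + 1:02d}", "block": row["block"], "trial": row["trial"],
                 "kind": row["kind"], "tms": row["tms"], "response": response,
                 "rt_ms": rt, "correct": response == row["kind"]}
            )
        tables.append(pd.DataFrame(rows))
    return pd.concat(tables, ignore_index=True)


def simulate_pooled_erps(
    n_subjects: int,
    templates: ERPTemplateSet | None = None,
    noise_sd_uv: float = 0.2,
    seed: int = 0,
    sfreq: float = 256.0,
    tmin_s: float = -0.2,
    tmax_s: float = 0.5,
    subject_sigma: float = 0.1,
) -> tuple[np.ndarray, dict[tuple[str, str], np.ndarray]]:
    """ERP-level cohort: per-subject pooled peri-occipital condition ERPs.

    Each subject's (kind, tms) ERP is the injected template times the
    subject's amplitude factor plus band-limited (0.5-30 Hz) pink+white
    residual noise with per-sample standard deviation ``noise_sd_uv`` -- the
    residual left after averaging ~200 trials in the continuous simulator.
    Used for statistical parameter-recovery experiments where simulating
    full continuous cohorts for every replicate would add nothing to the
    question being asked of the statistics.

    Returns ``(times_ms, erps)`` with ``erps[(kind, tms)]`` of shape
    (n_subjects, n_times).
    """
    from scipy.signal import butter, sosfiltfilt

    templates = templates or ERPTemplateSet.default()
    times_ms = np.arange(round(tmin_s * sfreq), round(tmax_s * sfreq)) / sfreq * 1000.0
    rng = np.random.default_rng(np.random.SeedSequence(entropy=int(seed), spawn_key=(ord("e"),)))
    amp = np.exp(subject_sigma * rng.standard_normal(n_subjects))
    sos = butter(4, [0.5, 30.0], btype="bandpass", fs=sfreq, output="sos")
    n_t = len(times_ms)
    erps: dict[tuple[str, str], np.ndarray] = {}
    for kind in STIMULUS_KINDS:
        for tms in TMS_CONDITIONS:
            gt = templates.waveform(kind, tms, times_ms)
            out = np.empty((n_subjects, n_t))
            for j in range(n_subjects):
                raw = pink_noise(4 * n_t, 1.0, rng) + 0.5 * rng.standard_normal(4 * n_t)
                filt = sosfiltfilt(sos, raw)[n_t : 2 * n_t]
                sd = filt.std()
                resid = noise_sd_uv * filt / sd if sd > 0 else filt
                out[j] = amp[j] * gt + resid
            erps[(kind, tms)] = out
    return times_ms, erps
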