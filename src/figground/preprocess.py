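"""TMS-artifact-aware EEG preprocessing chain.

Stage order (the whole chain is :func:`run_preprocessing`):

1. excise the TMS-disrupted interval (-2..65 ms around each pulse-pair
   onset) and bridge it with a cubic spline fitted on 250 ms of context on
   each side, leaving every sample outside the window untouched;
2. zero-phase "mirror" filtering (forward-backward recursive filtering of
   the signal and its time-reversed copy, reflect-padded): 0.5 Hz high-pass,
   30 Hz low-pass, 50 Hz notch -- applied only after artifact excision so
   the mV-scale artifact cannot smear through the filters;
3. polyphase downsampling 1048 -> 256 Hz;
4. re-referencing to Cz;
5. regression-based ocular correction against the EOG channels;
6. epoching around stimulus onsets (-200..500 ms);
7. trial rejection on the uV epochs (+/-75 uV amplitude, 50 uV/sample step;
   interpolated TMS segments are exempt from the step criterion);
8. spherical-spline surface Laplacian;
9. baseline correction over -100..0 ms;
10. per-condition averaging and peri-occipital pooling.

Interpolated samples are tracked through every stage as a boolean mask so
that statistics can exclude them.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.signal import butter, iirnotch, resample_poly, sosfiltfilt, tf2sos

from figground.laplacian import spline_laplacian
from figground.stimuli import STIMULUS_KINDS, TMS_CONDITIONS
from figground.synth import Montage, SessionRecording

__all__ = [
    "FilterSpec",
    "ExcisionSpec",
    "EpochSet",
    "ERP",
    "BoundaryError",
    "excise_and_interpolate",
    "mirror_filter",
    "downsample",
    "rereference",
    "ocular_correct",
    "epoch_recording",
    "reject_artifacts",
    "spline_laplacian",
    "baseline_correct",
    "preprocess_to_epochs",
    "condition_erps",
    "run_preprocessing",
]


class BoundaryError(ValueError):
    """A TMS pulse lies too close to the recording edge to interpolate."""


@dataclass(frozen=True)
class FilterSpec:
    """The recursive filter cascade applied after artifact excision.

    4th-order Butterworth high/low-pass edges and a 2nd-order notch,
    each run forward-backward over reflect padding (zero phase, no edge
    ringing). ``acq_lowpass_hz`` documents the acquisition-stage anti-alias
    filter and is metadata only.
    """

    highpass_hz: float = 0.5
    lowpass_hz: float = 30.0
    notch_hz: float = 50.0
    butter_order: int = 4
    notch_q: float = 35.0
    acq_lowpass_hz: float = 100.0
    downsample_to_hz: float = 256.0

    def __post_init__(self):
        if not 0 < self.highpass_hz < self.lowpass_hz < self.downsample_to_hz / 2:
            raise ValueError(
                "need 0 < highpass < lowpass < Nyquist after downsampling, got "
                f"{self.highpass_hz}/{self.lowpass_hz} at {self.downsample_to_hz} Hz"
            )


@dataclass(frozen=True)
class ExcisionSpec:
    """The zeroed-and-interpolated window around each TMS pulse-pair onset.

    ``knot_ms`` sets the interior knot spacing of the least-squares cubic
    spline fitted on the context: fine enough to track band-limited EEG
    across the gap, coarse enough that sample noise does not make the
    bridge oscillate.
    """

    window_ms: tuple[float, float] = (-2.0, 65.0)
    context_ms: float = 250.0
    knot_ms: float = 6.0

    def __post_init__(self):
        length = self.window_ms[1] - self.window_ms[0]
        if length <= 0:
            raise ValueError("excision window must have positive length")
        if self.context_ms <= length:
            raise ValueError("interpolation context must exceed the excised window")
        if self.knot_ms <= 0:
            raise ValueError("knot spacing must be positive")

    @property
    def length_ms(self) -> float:
        return self.window_ms[1] - self.window_ms[0]


def excise_and_interpolate(
    data: np.ndarray,
    sfreq: float,
    pulse_onsets: np.ndarray,
    spec: ExcisionSpec = ExcisionSpec(),
) -> tuple[np.ndarray, np.ndarray]:
    """Replace the TMS-disrupted samples with a cubic-spline bridge.

    For each pulse-pair onset (sample index of the first pulse) the samples
    in ``spec.window_ms`` are discarded and re-estimated from a cubic
    spline fitted by least squares on 250 ms of data on each side (interior
    knots every ``spec.knot_ms``), so the bridge tracks the band-limited
    EEG without chasing sample noise. Samples outside the windows are
    bit-identical to the input.

    Returns ``(data_interpolated, mask)`` where ``mask`` flags interpolated
    samples.

    Raises
    ------
    BoundaryError
        If any pulse's context extends beyond the recording.
    """
    from scipy.interpolate import make_lsq_spline

    arr = np.asarray(data, dtype=float)
    squeeze = arr.ndim == 1
    if squeeze:
        arr = arr[None, :]
    n = arr.shape[1]
    out = arr.copy()
    mask = np.zeros(n, dtype=bool)
    w0 = int(round(spec.window_ms[0] / 1000.0 * sfreq))
    w1 = int(round(spec.window_ms[1] / 1000.0 * sfreq))
    ctx = int(round(spec.context_ms / 1000.0 * sfreq))
    step = max(2, int(round(spec.knot_ms / 1000.0 * sfreq)))
    for onset in np.atleast_1d(np.asarray(pulse_onsets, dtype=int)):
        a, b = onset + w0, onset + w1  # excised: [a, b)
        if a - ctx < 0 or b + ctx > n:
            raise BoundaryError(
                f"pulse at sample {onset}: interpolation context "
                f"[{a - ctx}, {b + ctx}) exceeds recording of {n} samples"
            )
        left = np.arange(a - ctx, a)
        right = np.arange(b, b + ctx)
        x_ctx = np.concatenate([left, right])
        # interior knots strictly inside each context block
        kl = left[step // 2 : -step // 2 : step] if len(left) > 2 * step else left[1:2]
        kr = right[step // 2 : -step // 2 : step] if len(right) > 2 * step else right[-2:-1]
        knots = np.r_[[x_ctx[0]] * 4, kl, kr, [x_ctx[-1]] * 4].astype(float)
        spl = make_lsq_spline(x_ctx, out[:, x_ctx].T, knots, k=3)
        out[:, a:b] = spl(np.arange(a, b)).T
        mask[a:b] = True
    return (out[0] if squeeze else out), mask


def _filter_cascade(spec: FilterSpec, sfreq: float) -> list[np.ndarray]:
    nyq = sfreq / 2.0
    hp = butter(spec.butter_order, spec.highpass_hz / nyq, btype="highpass", output="sos")
    lp = butter(spec.butter_order, spec.lowpass_hz / nyq, btype="lowpass", output="sos")
    b, a = iirnotch(spec.notch_hz, spec.notch_q, fs=sfreq)
    return [hp, lp, tf2sos(b, a)]


def mirror_filter(data: np.ndarray, sfreq: float, spec: FilterSpec = FilterSpec()) -> np.ndarray:
    """Zero-phase recursive filtering without onset ringing.

    Each stage filters both the signal and its time-reversed copy (the
    forward-backward scheme) over mirror ('even') padding, so the combined
    output has exactly zero phase and no start-up transient leaking into
    the data.
    """
    arr = np.asarray(data, dtype=float)
    n = arr.shape[-1]
    padlen = int(min(n - 1, round(2.0 * sfreq)))
    min_len = 3 * max(24, int(round(3 * sfreq / spec.highpass_hz / 100)))
    if n <= min_len:
        raise ValueError(f"signal of {n} samples too short for the filter cascade")
    out = arr
    for sos in _filter_cascade(spec, sfreq):
        out = sosfiltfilt(sos, out, axis=-1, padtype="even", padlen=padlen)
    return out


def downsample(
    data: np.ndarray, sfreq: float, target_hz: float = 256.0, mask: np.ndarray | None = None
) -> tuple[np.ndarray, float, np.ndarray | None]:
    """Polyphase resampling (1048 -> 256 Hz is the exact ratio 32/131).

    A boolean sample mask, if given, is mapped to the new rate by flagging
    every output sample whose source neighbourhood touches a flagged input
    sample.
    """
    from fractions import Fraction

    frac = Fraction(target_hz / sfreq).limit_denominator(1000)
    up, down = frac.numerator, frac.denominator
    out = resample_poly(np.asarray(data, dtype=float), up, down, axis=-1)
    n_out = out.shape[-1]
    new_mask = None
    if mask is not None:
        src = np.round(np.arange(n_out) * down / up).astype(int)
        half = int(np.ceil(down / up / 2)) + 1
        padded = np.pad(mask.astype(bool), half)
        windows = [padded[src + half + k] for k in range(-half, half + 1)]
        new_mask = np.any(windows, axis=0)
    return out, sfreq * up / down, new_mask


def rereference(data: np.ndarray, ch_names: tuple[str, ...], ref: str = "Cz") -> np.ndarray:
    """Subtract the reference channel from every scalp channel."""
    if ref not in ch_names:
        raise ValueError(f"reference channel {ref!r} not in montage")
    idx = ch_names.index(ref)
    return data - data[..., idx, :][..., None, :]


def ocular_correct(
    scalp: np.ndarray, eog: np.ndarray, blink_z: float = 4.0
) -> tuple[np.ndarray, np.ndarray]:
    """Regression-based ocular correction.

    Propagation coefficients of each EOG channel into each scalp channel
    are estimated by least squares on blink-rich samples (where any EOG
    channel deviates more than ``blink_z`` robust SDs from its median) and
    regressed out of the whole recording. Returns ``(corrected, coeffs)``.
    Flat EOG input is left uncorrected with a warning.
    """
    scalp = np.asarray(scalp, dtype=float)
    eog = np.atleast_2d(np.asarray(eog, dtype=float))
    sd = eog.std(axis=1)
    if np.all(sd < 1e-12):
        warnings.warn("EOG channels are flat; ocular correction skipped")
        return scalp.copy(), np.zeros((scalp.shape[0], eog.shape[0]))
    med = np.median(eog, axis=1, keepdims=True)
    mad = np.median(np.abs(eog - med), axis=1, keepdims=True) * 1.4826 + 1e-12
    rich = np.any(np.abs(eog - med) > blink_z * mad, axis=0)
    if rich.sum() < 50:
        rich = np.ones(eog.shape[1], dtype=bool)
    E = eog[:, rich] - eog[:, rich].mean(axis=1, keepdims=True)
    S = scalp[:, rich] - scalp[:, rich].mean(axis=1, keepdims=True)
    coeffs, *_ = np.linalg.lstsq(E.T, S.T, rcond=None)
    coeffs = coeffs.T  # (n_scalp, n_eog)
    corrected = scalp - coeffs @ (eog - eog.mean(axis=1, keepdims=True))
    return corrected, coeffs


@dataclass
class EpochSet:
    """Stimulus-locked trials: (n_trials, n_channels, n_times) at 256 Hz.

    ``mask`` is (n_trials, n_times): True where the sample was interpolated
    over the TMS artifact. ``metadata`` carries kind/tms/correct per trial.
    """

    data: np.ndarray
    times_ms: np.ndarray
    sfreq: float
    mask: np.ndarray
    metadata: pd.DataFrame
    ch_names: tuple[str, ...]

    def __post_init__(self):
        if self.data.shape[0] != len(self.metadata):
            raise ValueError("metadata rows must match trials")
        if self.mask.shape != (self.data.shape[0], self.data.shape[2]):
            raise ValueError("mask must be (n_trials, n_times)")

    def __len__(self) -> int:
        return self.data.shape[0]

    def select(self, idx: np.ndarray) -> "EpochSet":
        return EpochSet(
            data=self.data[idx], times_ms=self.times_ms, sfreq=self.sfreq,
            mask=self.mask[idx], metadata=self.metadata.iloc[idx].reset_index(drop=True),
            ch_names=self.ch_names,
        )


@dataclass
class ERP:
    """Condition-averaged waveform with its interpolation mask."""

    data: np.ndarray  # (n_channels, n_times)
    pooled: np.ndarray  # (n_times,)
    times_ms: np.ndarray
    sfreq: float
    n_trials: int
    mask: np.ndarray  # (n_times,) union of trial masks
    kind: str = ""
    tms: str = ""
    valid: bool = True


def epoch_recording(
    data: np.ndarray,
    sfreq: float,
    event_samples: np.ndarray,
    metadata: pd.DataFrame,
    sample_mask: np.ndarray | None = None,
    tmin_s: float = -0.2,
    tmax_s: float = 0.5,
    ch_names: tuple[str, ...] = (),
) -> EpochSet:
    """Slice a continuous array into stimulus-locked epochs."""
    if len(event_samples) == 0:
        raise ValueError("no events to epoch")
    i0 = int(round(tmin_s * sfreq))
    i1 = int(round(tmax_s * sfreq))
    rel = np.arange(i0, i1)
    times_ms = rel / sfreq * 1000.0
    n = data.shape[-1]
    trials, masks, keep_rows = [], [], []
    for row_i, ev in enumerate(np.asarray(event_samples, dtype=int)):
        lo, hi = ev + i0, ev + i1
        if lo < 0 or hi > n:
            continue
        trials.append(data[:, lo:hi])
        masks.append(sample_mask[lo:hi] if sample_mask is not None else np.zeros(len(rel), bool))
        keep_rows.append(row_i)
    if not trials:
        raise ValueError("all events fall outside the recording")
    return EpochSet(
        data=np.stack(trials), times_ms=times_ms, sfreq=sfreq,
        mask=np.stack(masks), metadata=metadata.iloc[keep_rows].reset_index(drop=True),
        ch_names=tuple(ch_names),
    )


def reject_artifacts(
    epochs: EpochSet, amp_uv: float = 75.0, step_uv: float = 50.0
) -> tuple[EpochSet, pd.DataFrame]:
    """Drop trials exceeding +/-``amp_uv`` or a per-sample step > ``step_uv``.

    Applied to epochs still in uV (before the Laplacian, whose units are
    not potentials). Steps across interpolated TMS samples are exempt.
    Returns the retained epochs and a report of dropped trials.

    Raises
    ------
    ValueError
        If every trial is rejected (the report is attached to the message).
    """
    reasons = []
    keep = np.ones(len(epochs), dtype=bool)
    for t in range(len(epochs)):
        x = epochs.data[t]
        if np.any(np.abs(x) > amp_uv):
            keep[t] = False
            reasons.append({"trial": t, "reason": "amplitude",
                            "value": float(np.max(np.abs(x)))})
            continue
        steps = np.abs(np.diff(x, axis=-1))
        m = epochs.mask[t]
        step_ok = ~(m[:-1] | m[1:])  # exempt steps touching interpolated samples
        if np.any(steps[:, step_ok] > step_uv):
            keep[t] = False
            reasons.append({"trial": t, "reason": "step",
                            "value": float(steps[:, step_ok].max())})
    report = pd.DataFrame(reasons, columns=["trial", "reason", "value"])
    if not keep.any():
        raise ValueError(f"all {len(epochs)} trials rejected: {report.to_dict('records')}")
    return epochs.select(np.where(keep)[0]), report


def baseline_correct(
    data: np.ndarray, times_ms: np.ndarray, window_ms: tuple[float, float] = (-100.0, 0.0)
) -> np.ndarray:
    """Subtract the per-channel mean over the pre-stimulus baseline window."""
    sel = (times_ms >= window_ms[0]) & (times_ms < window_ms[1])
    if not sel.any():
        raise ValueError(f"baseline window {window_ms} outside epoch")
    return data - data[..., sel].mean(axis=-1, keepdims=True)


def preprocess_to_epochs(
    recording: SessionRecording,
    filter_spec: FilterSpec = FilterSpec(),
    excision_spec: ExcisionSpec = ExcisionSpec(),
    tmin_s: float = -0.2,
    tmax_s: float = 0.5,
    baseline_ms: tuple[float, float] = (-100.0, 0.0),
    amp_uv: float = 75.0,
    step_uv: float = 50.0,
    apply_laplacian: bool = True,
    apply_excision: bool = True,
    laplacian_kwargs: dict | None = None,
) -> tuple[EpochSet, pd.DataFrame]:
    """Run the chain up to cleaned, Laplacian-transformed, baselined epochs.

    Returns the epochs and the rejection report.
    """
    if len(recording.events) == 0:
        raise ValueError("recording has no events")
    mont = recording.montage
    n_scalp = mont.n_scalp

    data = recording.data.copy()
    sample_mask = np.zeros(recording.n_samples, dtype=bool)
    if apply_excision and len(recording.pulse_events):
        # the -2..65 ms window from the pair onset spans both pulses of the
        # 45 Hz double pulse, so one excision per pair
        pair_onsets = (
            recording.pulse_events.sort_values("sample")
            .groupby("trial_idx")["sample"].min().to_numpy()
        )
        data[:n_scalp], sample_mask = excise_and_interpolate(
            data[:n_scalp], recording.sfreq, pair_onsets, excision_spec
        )

    data = mirror_filter(data, recording.sfreq, filter_spec)
    data, sfreq_ds, mask_ds = downsample(
        data, recording.sfreq, filter_spec.downsample_to_hz, sample_mask
    )
    scalp = rereference(data[:n_scalp], mont.ch_names, ref="Cz")
    scalp, _ = ocular_correct(scalp, data[n_scalp:])

    ev_ds = np.round(
        recording.events["sample"].to_numpy() * sfreq_ds / recording.sfreq
    ).astype(int)
    epochs = epoch_recording(
        scalp, sfreq_ds, ev_ds, recording.events, mask_ds,
        tmin_s=tmin_s, tmax_s=tmax_s, ch_names=mont.ch_names,
    )
    epochs, report = reject_artifacts(epochs, amp_uv=amp_uv, step_uv=step_uv)

    if apply_laplacian:
        kw = laplacian_kwargs or {}
        epochs.data = spline_laplacian(epochs.data, mont.positions, **kw)

    epochs.data = baseline_correct(epochs.data, epochs.times_ms, baseline_ms)
    return epochs, report


def condition_erps(
    epochs: EpochSet, montage: Montage, subset: np.ndarray | None = None
) -> dict[tuple[str, str], ERP]:
    """Average cleaned epochs into the 12 condition ERPs (+ pooled traces).

    ``subset`` optionally restricts trials (e.g. correct only). A condition
    left with zero trials is returned with ``valid=False`` and NaN data so
    cohort runs can report partial results.
    """
    pool = montage.pool_indices()
    n_scalp = montage.n_scalp
    md = epochs.metadata
    use = np.ones(len(epochs), dtype=bool) if subset is None else np.asarray(subset, bool)
    erps: dict[tuple[str, str], ERP] = {}
    for kind in STIMULUS_KINDS:
        for tms in TMS_CONDITIONS:
            sel = (md["kind"] == kind).to_numpy() & (md["tms"] == tms).to_numpy() & use
            idx = np.where(sel)[0]
            if len(idx) == 0:
                nan = np.full((n_scalp, len(epochs.times_ms)), np.nan)
                erps[(kind, tms)] = ERP(
                    data=nan, pooled=nan[0], times_ms=epochs.times_ms, sfreq=epochs.sfreq,
                    n_trials=0, mask=np.zeros(len(epochs.times_ms), bool),
                    kind=kind, tms=tms, valid=False,
                )
                continue
            avg = epochs.data[idx].mean(axis=0)
            mask = epochs.mask[idx].any(axis=0)
            erps[(kind, tms)] = ERP(
                data=avg, pooled=avg[pool].mean(axis=0), times_ms=epochs.times_ms,
                sfreq=epochs.sfreq, n_trials=len(idx), mask=mask, kind=kind, tms=tms,
            )
    return erps


def run_preprocessing(
    recording: SessionRecording, **kwargs
) -> dict[tuple[str, str], ERP]:
    """Full chain on one recording: cleaned epochs averaged into the 12
    condition ERPs. See :func:`preprocess_to_epochs` for the stages and
    keyword arguments."""
    epochs, _ = preprocess_to_epochs(recording, **kwargs)
    return condition_erps(epochs, recording.montage)
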