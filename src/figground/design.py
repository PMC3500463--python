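"""Design arithmetic of the figure-ground TMS-EEG experiment.

Small, exact quantities implied by the experimental design: trial-count
bookkeeping of the 3 x 4 schedule, the sham session size, the TMS
double-pulse timing, the pilot time-window count, the viewing geometry,
and the stimulus duration. Each function derives its value from the
package's own scheduler/geometry code or from first principles rather than
stating a constant.
"""

from __future__ import annotations

import numpy as np

from figground.preprocess import ExcisionSpec
from figground.stimuli import TRIAL_TYPES, StimulusParams, build_schedule


def n_trial_types() -> int:
    """Cells of the stimulus (3) x TMS window (4) design."""
    return len(TRIAL_TYPES)


def trials_per_condition(n_blocks: int = 25, trials_per_block: int = 96) -> int:
    """Trials each of the 12 types receives over the full session set,
    counted from an actually built schedule (25 x 96 -> 200)."""
    schedule = build_schedule(n_blocks, trials_per_block, seed=0)
    counts = schedule.type_counts()["count"]
    if counts.nunique() != 1:
        raise AssertionError("schedule is not balanced")
    return int(counts.iloc[0])


def sham_total_trials(per_condition: int = 48) -> int:
    """Total sham-TMS trials: 48 per trial type over the 12 types."""
    return per_condition * n_trial_types()


def excision_length_ms(spec: ExcisionSpec = ExcisionSpec()) -> float:
    """Length of the excised interval around a pulse pair (-2..65 -> 67)."""
    return spec.length_ms


def pulse_pair_interval_ms(pulse_rate_hz: float = 45.0) -> float:
    """Inter-pulse interval of the double pulse: one period of the pulse
    rate (45 Hz -> 22.2 ms, i.e. the second pulse follows within 23 ms)."""
    return 1000.0 / pulse_rate_hz


def pilot_window_count(
    first_onset_ms: float = 56.0,
    last_offset_ms: float = 339.0,
    step_ms: float = 20.0,
    window_ms: float = 23.0,
) -> int:
    """Number of double-pulse onsets spaced ``step_ms`` apart whose 23 ms
    window fits inside the piloted 56-339 ms range (-> 14)."""
    last_onset = last_offset_ms - window_ms
    return int(np.floor((last_onset - first_onset_ms) / step_ms)) + 1


def degrees_per_cm(distance_cm: float = 90.0) -> float:
    """Visual angle subtended by 1 cm at the viewing distance
    (90 cm -> 0.64 deg/cm)."""
    return float(np.degrees(2 * np.arctan(0.5 / distance_cm)))


def stimulus_duration_ms(params: StimulusParams = StimulusParams()) -> float:
    """Duration of the two-refresh motion sequence at 60 Hz (-> 33.3 ms)."""
    return params.duration_ms
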