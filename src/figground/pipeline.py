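"""End-to-end experiment orchestration: simulate -> preprocess -> stats.

:func:`run_experiment` executes the whole pipeline from a single
:class:`~figground.config.ExperimentConfig`, writes a results bundle
(behavior statistics, difference-wave intervals, cumulative tests, and a
parameter-recovery report against the simulator's injected ground truth)
and a manifest with per-stage checksums so identical (config, seed) runs
can be verified bit-for-bit.
"""

from __future__ import annotations

import hashlib
import json
import time
from pathlib import Path

import numpy as np
import pandas as pd

import figground
from figground.config import ExperimentConfig
from figground.preprocess import (
    ExcisionSpec,
    FilterSpec,
    condition_erps,
    preprocess_to_epochs,
)
from figground.stats import (
    MaskedWindowError,
    cell_means,
    contrast_wave,
    cumulative_diff_test,
    error_type_analysis,
    filter_behavior,
    rm_anova_3x4,
    samplewise_fdr_ttest,
)
from figground.stimuli import TMS_CONDITIONS, build_schedule
from figground.synth import (
    BehaviorModel,
    ERPTemplateSet,
    Montage,
    NoiseModel,
    TMSArtifactModel,
    simulate_cohort,
)

#: injected ground-truth component supports, ms
INJECTED_WINDOWS_MS = {"figure-homogenous": (137.0, 211.0), "stack-frame": (227.0, 313.0)}


def _checksum(obj) -> str:
    h = hashlib.sha256()
    if isinstance(obj, np.ndarray):
        h.update(np.ascontiguousarray(obj).tobytes())
    elif isinstance(obj, pd.DataFrame):
        h.update(obj.to_csv(index=False).encode())
    else:
        h.update(json.dumps(obj, sort_keys=True, default=str).encode())
    return h.hexdigest()


def interval_jaccard(intervals: list[dict], window_ms: tuple[float, float]) -> float:
    """Jaccard overlap between reported significant intervals and a target
    window, measured on the time axis."""
    lo, hi = window_ms
    inter = 0.0
    union_len = hi - lo
    covered = []
    for iv in intervals:
        a, b = iv["start_ms"], iv["end_ms"]
        inter += max(0.0, min(b, hi) - max(a, lo))
        covered.append((a, b))
    extra = sum(max(0.0, b - a) - max(0.0, min(b, hi) - max(a, lo)) for a, b in covered)
    union = union_len + extra
    return inter / union if union > 0 else 0.0


def run_experiment(config: ExperimentConfig, outdir=None) -> dict:
    """Run the full simulated experiment; returns the results bundle.

    The bundle holds the manifest (config hash, stage checksums), the
    filtered behavior statistics (3x4 ANOVA on accuracy and RT, error-type
    analysis), the per-condition difference-wave FDR tests, the cumulative
    stack-frame statistic (all and correct-only trials), and the recovery
    report (Jaccard overlap of the significant intervals with the injected
    component windows). If ``outdir`` is given, results are also written as
    JSON/CSV files.
    """
    t0 = time.time()
    manifest: dict = {
        "package_version": figground.__version__,
        "config": json.loads(json.dumps(config.to_yaml(), default=str)),
        "config_hash": _checksum(config.to_yaml()),
        "seed": config.seed,
        "stages": {},
    }
    results: dict = {"manifest": manifest}

    # --- stage 1: schedule -------------------------------------------------
    schedule = build_schedule(
        config.schedule.n_blocks, config.schedule.trials_per_block, seed=config.seed
    )
    manifest["stages"]["schedule"] = _checksum(schedule.table)

    # --- stage 2: cohort simulation ---------------------------------------
    sim = config.simulation
    noise = NoiseModel().scaled(sim.noise_scale)
    montage = Montage.standard()
    recordings, behavior = simulate_cohort(
        n_subjects=sim.n_subjects,
        schedule=schedule,
        templates=ERPTemplateSet.default(),
        artifact=TMSArtifactModel(),
        noise=noise,
        behavior=BehaviorModel.default(),
        montage=montage,
        seed=config.seed,
        n_poor=sim.n_poor,
        sfreq=sim.sfreq,
        iti_s=sim.iti_s,
    )
    manifest["stages"]["behavior"] = _checksum(behavior)
    manifest["stages"]["recordings"] = _checksum(
        np.concatenate([r.data[:, :1000].ravel() for r in recordings])
    )

    # --- stage 3: preprocessing -------------------------------------------
    pp = config.preprocess
    fspec = FilterSpec(
        highpass_hz=pp.highpass_hz, lowpass_hz=pp.lowpass_hz, notch_hz=pp.notch_hz,
        downsample_to_hz=pp.downsample_to_hz,
    )
    espec = ExcisionSpec(window_ms=tuple(pp.excision_window_ms),
                         context_ms=pp.excision_context_ms)
    pooled: dict[tuple[str, str], list[np.ndarray]] = {}
    pooled_correct: dict[tuple[str, str], list[np.ndarray]] = {}
    masks: dict[tuple[str, str], np.ndarray] = {}
    times_ms = None
    for rec, (subj, beh) in zip(recordings, behavior.groupby("subject", sort=True)):
        events = rec.events.merge(
            beh.reset_index(drop=True)[["correct"]].assign(
                trial_idx=np.arange(len(beh))
            ),
            on="trial_idx", how="left",
        )
        rec.events = events
        epochs, _rep = preprocess_to_epochs(
            rec, filter_spec=fspec, excision_spec=espec, tmin_s=pp.tmin_s,
            tmax_s=pp.tmax_s, baseline_ms=tuple(pp.baseline_ms), amp_uv=pp.amp_uv,
            step_uv=pp.step_uv, apply_laplacian=pp.apply_laplacian,
        )
        erps = condition_erps(epochs, montage)
        erps_c = condition_erps(
            epochs, montage, subset=epochs.metadata["correct"].fillna(False).to_numpy(bool)
        )
        times_ms = erps[("stack", "none")].times_ms
        for key, erp in erps.items():
            if erp.valid:
                pooled.setdefault(key, []).append(erp.pooled)
                masks[key] = erp.mask if key not in masks else (masks[key] | erp.mask)
        for key, erp in erps_c.items():
            if erp.valid:
                pooled_correct.setdefault(key, []).append(erp.pooled)
    pooled_arr = {k: np.stack(v) for k, v in pooled.items()}
    pooled_correct_arr = {k: np.stack(v) for k, v in pooled_correct.items()
                          if len(v) == sim.n_subjects}
    manifest["stages"]["pooled_erps"] = _checksum(
        np.concatenate([pooled_arr[k].ravel() for k in sorted(pooled_arr)])
    )

    # --- stage 4: behavioral statistics ------------------------------------
    st = config.stats
    beh_filtered, beh_log = filter_behavior(
        behavior, rt_bounds_ms=tuple(st.rt_bounds_ms), min_accuracy=st.min_accuracy
    )
    acc_cells = cell_means(beh_filtered, value="correct")
    rt_cells = cell_means(beh_filtered, value="rt_ms")
    results["behavior"] = {
        "filter_log": beh_log,
        "anova_accuracy": rm_anova_3x4(acc_cells).to_dict("records"),
        "anova_rt": rm_anova_3x4(rt_cells).to_dict("records"),
    }
    props, err_tests = error_type_analysis(beh_filtered, q=st.q)
    results["behavior"]["error_types"] = err_tests.to_dict("records")

    # --- stage 5: difference-wave statistics --------------------------------
    def subject_stack(key):
        return pooled_arr[key]

    eeg: dict = {"figure-homogenous": {}, "stack-frame": {}}
    for tms in TMS_CONDITIONS:
        keys = [("stack", tms), ("frame", tms), ("homogenous", tms)]
        if not all(k in pooled_arr for k in keys):
            continue
        mask_union = masks[keys[0]] | masks[keys[1]] | masks[keys[2]]
        fh = contrast_wave(*(pooled_arr[k] for k in keys), contrast="figure-homogenous")
        sf = contrast_wave(pooled_arr[keys[0]], pooled_arr[keys[1]], None, "stack-frame")
        for contrast, wave, window in (
            ("figure-homogenous", fh, tuple(st.early_window_ms)),
            ("stack-frame", sf, tuple(st.late_window_ms)),
        ):
            try:
                res = samplewise_fdr_ttest(wave, times_ms, window, mask=mask_union, q=st.q)
                eeg[contrast][tms] = {
                    "testable": True,
                    "intervals": res.intervals,
                    "q_threshold": res.q_threshold,
                    "n_significant": int(res.significant.sum()),
                }
            except MaskedWindowError as e:
                eeg[contrast][tms] = {"testable": False, "reason": str(e)}
    results["eeg"] = eeg

    # --- stage 6: cumulative stack-frame statistic --------------------------
    conds = tuple(c for c in ("none", "early", "intermediate")
                  if ("stack", c) in pooled_arr)
    stack_d = {c: pooled_arr[("stack", c)] for c in conds}
    frame_d = {c: pooled_arr[("frame", c)] for c in conds}
    vals, tests = cumulative_diff_test(
        stack_d, frame_d, times_ms, conditions=conds,
        window_ms=tuple(st.cumulative_window_ms),
    )
    results["cumulative"] = {"all_trials": tests.to_dict("records")}
    conds_c = tuple(c for c in conds if ("stack", c) in pooled_correct_arr
                    and ("frame", c) in pooled_correct_arr)
    if len(conds_c) >= 2:
        _, tests_c = cumulative_diff_test(
            {c: pooled_correct_arr[("stack", c)] for c in conds_c},
            {c: pooled_correct_arr[("frame", c)] for c in conds_c},
            times_ms, conditions=conds_c, window_ms=tuple(st.cumulative_window_ms),
        )
        results["cumulative"]["correct_only"] = tests_c.to_dict("records")

    # --- stage 7: recovery report -------------------------------------------
    recovery = {}
    for contrast, window in INJECTED_WINDOWS_MS.items():
        entry = eeg[contrast].get("none", {})
        if entry.get("testable"):
            recovery[contrast] = {
                "injected_window_ms": window,
                "jaccard": interval_jaccard(entry["intervals"], window),
                "intervals": entry["intervals"],
            }
    results["recovery"] = recovery
    manifest["stages"]["results"] = _checksum(
        {k: v for k, v in results.items() if k != "manifest"}
    )
    manifest["runtime_s"] = round(time.time() - t0, 2)

    if outdir is not None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        with open(out / "results.json", "w") as f:
            json.dump({k: v for k, v in results.items() if k != "manifest"},
                      f, indent=2, default=_json_default)
        with open(out / "manifest.json", "w") as f:
            json.dump(manifest, f, indent=2, default=_json_default)
        beh_filtered.to_csv(out / "behavior_filtered.csv", index=False)
        vals.to_csv(out / "cumulative_values.csv", index=False)
        props.to_csv(out / "error_proportions.csv", index=False)
    return results


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, (np.bool_,)):
        return bool(o)
    return str(o)


def make_fixtures(scale: str, outdir) -> dict:
    """Write the deterministic miniature datasets used by the test suite.

    ``tiny`` is 3 subjects x 24 trials (2 per type); ``desk`` is the
    5-subject x 48-trial profile. Regenerating with the same scale yields
    byte-identical CSV outputs.
    """
    if scale not in ("tiny", "desk"):
        raise ValueError("scale must be 'tiny' or 'desk'")
    config = ExperimentConfig.tiny() if scale == "tiny" else ExperimentConfig.desk()
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    schedule = build_schedule(
        config.schedule.n_blocks, config.schedule.trials_per_block, seed=config.seed
    )
    schedule.to_csv(out / "schedule.csv")
    from figground.synth import simulate_behavior_cohort

    behavior = simulate_behavior_cohort(
        config.simulation.n_subjects, schedule, seed=config.seed
    )
    behavior.to_csv(out / "behavior.csv", index=False)
    config.to_yaml(out / "config.yaml")
    return {
        "schedule_checksum": _checksum(schedule.table),
        "behavior_checksum": _checksum(behavior),
        "paths": [str(out / p) for p in ("schedule.csv", "behavior.csv", "config.yaml")],
    }
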