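"""Artifact excision, filtering, ocular correction, rejection, Laplacian,
and the assembled preprocessing chain checked against simulator ground truth."""

import warnings

import numpy as np
import pandas as pd
import pytest
from scipy.signal import sosfilt

from figground.laplacian import SingularGeometryError, laplacian_transform
from figground.preprocess import (
    BoundaryError,
    EpochSet,
    ExcisionSpec,
    FilterSpec,
    baseline_correct,
    condition_erps,
    downsample,
    epoch_recording,
    excise_and_interpolate,
    mirror_filter,
    ocular_correct,
    preprocess_to_epochs,
    reject_artifacts,
    rereference,
    run_preprocessing,
    spline_laplacian,
    _filter_cascade,
)

SFREQ = 1048.0


class TestExcision:
    def _gap_setup(self, signal):
        onset = len(signal) // 2
        return excise_and_interpolate(signal, SFREQ, [onset]), onset

    def test_straight_line_recovered_exactly(self):
        t = np.arange(int(3 * SFREQ)) / SFREQ
        line = 2.0 + 5.0 * t
        (out, mask), _ = self._gap_setup(line.copy())
        np.testing.assert_allclose(out, line, atol=1e-9)
        assert mask.sum() > 0

    def test_sinusoid_bridge_rmse_under_5_percent(self):
        """A 5 Hz oscillation is bridged across the 67 ms gap to < 5% of
        its amplitude (RMSE over the interpolated samples)."""
        amp = 12.0
        t = np.arange(int(3 * SFREQ)) / SFREQ
        sin = amp * np.sin(2 * np.pi * 5.0 * t)
        (out, mask), _ = self._gap_setup(sin.copy())
        rmse = np.sqrt(np.mean((out[mask] - sin[mask]) ** 2))
        assert rmse < 0.05 * amp

    def test_samples_outside_window_untouched(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal(int(3 * SFREQ))
        (out, mask), _ = self._gap_setup(x.copy())
        np.testing.assert_array_equal(out[~mask], x[~mask])

    def test_no_pulses_identity(self):
        x = np.random.default_rng(1).standard_normal((3, 2000))
        out, mask = excise_and_interpolate(x, SFREQ, [])
        np.testing.assert_array_equal(out, x)
        assert not mask.any()

    def test_pulse_near_edge_raises_boundary_error(self):
        x = np.zeros(1000)
        with pytest.raises(BoundaryError, match="context"):
            excise_and_interpolate(x, SFREQ, [100])

    def test_window_length_is_67_ms(self):
        spec = ExcisionSpec()
        assert spec.length_ms == pytest.approx(67.0)

    def test_context_must_exceed_window(self):
        with pytest.raises(ValueError, match="context"):
            ExcisionSpec(window_ms=(-2.0, 65.0), context_ms=50.0)


class TestMirrorFilter:
    def test_passband_unity_gain_zero_phase(self):
        t = np.arange(int(20 * SFREQ)) / SFREQ
        x = np.sin(2 * np.pi * 10.0 * t)
        y = mirror_filter(x, SFREQ)
        mid = slice(int(5 * SFREQ), int(15 * SFREQ))
        assert y[mid].std() / x[mid].std() == pytest.approx(1.0, abs=0.01)
        xc = np.correlate(y[mid], x[mid], "full")
        assert np.argmax(xc) == len(x[mid]) - 1  # zero-lag peak

    def test_notch_attenuates_line_frequency(self):
        t = np.arange(int(20 * SFREQ)) / SFREQ
        x = np.sin(2 * np.pi * 50.0 * t)
        y = mirror_filter(x, SFREQ)
        mid = slice(int(5 * SFREQ), int(15 * SFREQ))
        assert y[mid].std() < 0.05 * x[mid].std()

    def test_step_ringing_below_causal_filtering(self):
        """The motivating property: a step discontinuity rings less after
        zero-phase mirror filtering than after one-pass causal filtering."""
        n = int(8 * SFREQ)
        x = np.zeros(n)
        x[n // 2 :] = 50.0
        y_mirror = mirror_filter(x, SFREQ)
        y_causal = x.copy()
        for sos in _filter_cascade(FilterSpec(), SFREQ):
            y_causal = sosfilt(sos, y_causal)
        post = slice(n // 2 + int(0.05 * SFREQ), n // 2 + int(0.5 * SFREQ))
        osc_mirror = np.abs(np.diff(y_mirror[post])).max()
        osc_causal = np.abs(np.diff(y_causal[post])).max()
        assert osc_mirror < osc_causal

    def test_signal_too_short_rejected(self):
        with pytest.raises(ValueError, match="too short"):
            mirror_filter(np.zeros(10), SFREQ)

    def test_invalid_band_edges_rejected(self):
        with pytest.raises(ValueError, match="Nyquist"):
            FilterSpec(lowpass_hz=200.0)


class TestDownsample:
    def test_1048_to_256_exact_rate(self):
        x = np.random.default_rng(2).standard_normal(int(10 * SFREQ))
        y, rate, _ = downsample(x, SFREQ, 256.0)
        assert rate == pytest.approx(256.0)
        assert len(y) == pytest.approx(len(x) * 256 / 1048, abs=2)

    def test_mask_maps_to_new_rate(self):
        n = int(4 * SFREQ)
        mask = np.zeros(n, bool)
        mask[2000:2070] = True
        _, _, m2 = downsample(np.zeros(n), SFREQ, 256.0, mask)
        # flagged span maps to ~70 * 256/1048 = 17 samples, plus guard
        assert 15 <= m2.sum() <= 25
        centre = int(2035 * 256 / 1048)
        assert m2[centre]


class TestOcularCorrection:
    def test_known_blink_topography_removed(self, montage):
        rng = np.random.default_rng(3)
        n = 30_000
        clean = rng.standard_normal((64, n))
        blink = np.zeros(n)
        for s in range(2000, n - 2000, 5000):
            blink[s : s + 300] += 150 * np.hanning(300)
        topo = np.linspace(1.0, 0.1, 64)
        scalp = clean + 0.35 * topo[:, None] * blink[None, :]
        eog = np.vstack([blink + rng.standard_normal(n), -0.8 * blink])
        corrected, coeffs = ocular_correct(scalp, eog)
        resid = corrected - clean
        assert np.abs(resid).max() < 0.1 * 150 * 0.35

    def test_flat_eog_warns_and_skips(self):
        scalp = np.random.default_rng(4).standard_normal((4, 1000))
        with pytest.warns(UserWarning, match="flat"):
            out, coeffs = ocular_correct(scalp, np.zeros((2, 1000)))
        np.testing.assert_array_equal(out, scalp)
        assert np.all(coeffs == 0)

    def test_blink_free_recording_nearly_unchanged(self):
        rng = np.random.default_rng(5)
        scalp = rng.standard_normal((8, 20_000))
        eog = rng.standard_normal((2, 20_000))
        out, coeffs = ocular_correct(scalp, eog)
        assert np.abs(coeffs).max() < 0.05
        assert np.abs(out - scalp).max() < 0.5


def _epochs_from(data, mask=None):
    n_tr, n_ch, n_t = data.shape
    return EpochSet(
        data=data,
        times_ms=np.arange(n_t) * 1000.0 / 256.0,
        sfreq=256.0,
        mask=np.zeros((n_tr, n_t), bool) if mask is None else mask,
        metadata=pd.DataFrame({"kind": ["stack"] * n_tr, "tms": ["none"] * n_tr}),
        ch_names=tuple(f"ch{i}" for i in range(n_ch)),
    )


class TestRejection:
    def test_amplitude_threshold_literal(self):
        data = np.zeros((2, 3, 50))
        data[0, 1, 10] = 80.0
        kept, report = reject_artifacts(_epochs_from(data))
        assert len(kept) == 1
        assert report.iloc[0]["reason"] == "amplitude"

    def test_inside_both_bounds_retained(self):
        data = np.zeros((1, 2, 50))
        data[0, 0, ::2] = 74.0
        data[0, 0, 1::2] = 74.0 - 49.0
        kept, report = reject_artifacts(_epochs_from(data))
        assert len(kept) == 1 and report.empty

    def test_step_threshold_literal(self):
        data = np.zeros((1, 2, 50))
        data[0, 0, 25:] = 60.0
        with pytest.raises(ValueError, match="rejected"):
            reject_artifacts(_epochs_from(data))

    def test_interpolated_segment_exempt_from_step(self):
        data = np.zeros((1, 2, 50))
        data[0, 0, 25:] = 60.0
        mask = np.zeros((1, 50), bool)
        mask[0, 24:27] = True
        kept, report = reject_artifacts(_epochs_from(data, mask))
        assert len(kept) == 1

    def test_all_rejected_raises_with_report(self):
        data = np.full((2, 2, 50), 100.0)
        with pytest.raises(ValueError, match="amplitude"):
            reject_artifacts(_epochs_from(data))


class TestLaplacian:
    def test_constant_potential_maps_to_zero(self, montage):
        v = np.full((64, 7), 3.7)
        out = spline_laplacian(v, montage.positions)
        assert np.abs(out).max() < 1e-6

    def test_reference_invariance(self, montage):
        rng = np.random.default_rng(6)
        v = rng.standard_normal((64, 11))
        a = spline_laplacian(v, montage.positions)
        b = spline_laplacian(v + 7.3, montage.positions)
        np.testing.assert_allclose(a, b, atol=1e-6)

    def test_l1_harmonic_eigenrelation(self, montage):
        """P1(cos theta) = z is an eigenfunction: surface Laplacian =
        -l(l+1) z / r^2, verified within 5% away from the rim."""
        z = montage.positions[:, 2][:, None]
        lap = spline_laplacian(z, montage.positions, head_radius_m=1.0)
        interior = montage.positions[:, 2] > 0.1
        ratio = lap[interior, 0] / (-2.0 * z[interior, 0])
        assert np.all(np.abs(ratio - 1.0) < 0.05)

    def test_matches_mne_csd(self, montage):
        """Independent oracle: mne's spherical-spline CSD (its sign
        convention is the negative surface Laplacian)."""
        mne = pytest.importorskip("mne")
        mne.set_log_level("ERROR")
        rng = np.random.default_rng(7)
        data = rng.standard_normal((64, 20))
        info = mne.create_info(list(montage.ch_names), 256.0, "eeg")
        ev = mne.EvokedArray(data * 1e-6, info)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", FutureWarning)
            ev.set_montage(mne.channels.make_standard_montage("standard_1005"))
        pos = np.array([ch["loc"][:3] for ch in ev.info["chs"]])
        pos /= np.linalg.norm(pos, axis=1, keepdims=True)
        csd = mne.preprocessing.compute_current_source_density(
            ev, sphere=(0.0, 0.0, 0.0, 0.095), lambda2=1e-5, stiffness=4,
            n_legendre_terms=50,
        )
        mine = spline_laplacian(data, pos)
        np.testing.assert_allclose(mine, -csd.data * 1e6, rtol=1e-6)

    def test_duplicate_electrodes_rejected(self, montage):
        pos = montage.positions.copy()
        pos[1] = pos[0]
        with pytest.raises(SingularGeometryError, match="duplicate"):
            laplacian_transform(pos)

    def test_too_few_electrodes_rejected(self, montage):
        with pytest.raises(ValueError, match="16"):
            laplacian_transform(montage.positions[:8])


class TestChainPieces:
    def test_rereference_zeroes_reference_channel(self, montage):
        data = np.random.default_rng(8).standard_normal((64, 100))
        out = rereference(data, montage.ch_names, "Cz")
        cz = montage.ch_names.index("Cz")
        assert np.abs(out[cz]).max() == 0

    def test_baseline_mean_zero(self):
        rng = np.random.default_rng(9)
        times = np.arange(-51, 128) * 1000.0 / 256.0
        data = rng.standard_normal((3, 5, len(times))) + 4.0
        out = baseline_correct(data, times)
        sel = (times >= -100) & (times < 0)
        np.testing.assert_allclose(out[..., sel].mean(axis=-1), 0, atol=1e-12)

    def test_epoching_requires_events(self):
        with pytest.raises(ValueError, match="no events"):
            epoch_recording(np.zeros((2, 100)), 256.0, np.array([]), pd.DataFrame())


class TestFullChain:
    def test_zero_noise_pipeline_recovers_filtered_template(self, montage):
        """With no noise and no TMS, the pooled pipeline output matches the
        ground-truth template passed through the same filter cascade to
        within 2% RMS."""
        from figground.stimuli import TrialSchedule, build_schedule
        from figground.synth import (
            BehaviorModel, ERPTemplateSet, NoiseModel, TMSArtifactModel,
            simulate_subject,
        )

        sched = build_schedule(1, 12, seed=4)
        table = sched.table.copy()
        table["tms"] = "none"
        noise0 = NoiseModel(pink_sigma_uv=0, white_sigma_uv=0, line_amp_uv=0,
                            blink_rate_per_min=0, subject_sigma=0)
        rec, _ = simulate_subject(
            TrialSchedule(table), ERPTemplateSet.default(), TMSArtifactModel(),
            noise0, BehaviorModel.default(), montage, seed=1,
        )
        erps = run_preprocessing(rec, apply_laplacian=False)
        got = erps[("stack", "none")]

        # oracle: the injected pooled template (measured like the pipeline
        # does: after Cz re-referencing) through the same filters
        from figground.synth import occipital_weights

        w = occipital_weights(montage)
        cz_gain = 1.0 - w[montage.ch_names.index("Cz")]
        tpl_times = np.arange(rec.n_samples) / rec.sfreq * 1000.0
        onset0 = rec.events["sample"].iloc[0]
        tpl = cz_gain * ERPTemplateSet.default().waveform(
            "stack", "none", tpl_times - tpl_times[onset0]
        )
        filt = mirror_filter(tpl, rec.sfreq)
        ds, rate, _ = downsample(filt, rec.sfreq, 256.0)
        ev = int(round(onset0 * rate / rec.sfreq))
        i0, i1 = ev + int(round(-0.2 * rate)), ev + int(round(0.5 * rate))
        expect = ds[i0:i1]
        t_ms = (np.arange(i0, i1) - ev) / rate * 1000.0
        expect = expect - expect[(t_ms >= -100) & (t_ms < 0)].mean()
        rms_err = np.sqrt(np.mean((got.pooled - expect) ** 2))
        rms_sig = np.sqrt(np.mean(expect**2))
        assert rms_err < 0.02 * rms_sig

    def test_excision_improves_erp_recovery_in_every_tms_condition(self, montage):
        """With artifacts present, running the excision stage brings the
        pooled ERP closer to the artifact-free ground truth than skipping
        it, in every TMS condition."""
        from figground.stimuli import build_schedule
        from figground.synth import (
            BehaviorModel, ERPTemplateSet, NoiseModel, TMSArtifactModel,
            simulate_subject,
        )

        sched = build_schedule(1, 24, seed=6)
        tpl = ERPTemplateSet.default()
        noise = NoiseModel(blink_rate_per_min=0)
        rec, _ = simulate_subject(
            sched, tpl, TMSArtifactModel(), noise, BehaviorModel.default(),
            montage, seed=13,
        )
        kwargs = dict(apply_laplacian=False, amp_uv=np.inf, step_uv=np.inf)
        with_exc = run_preprocessing(rec, apply_excision=True, **kwargs)
        without = run_preprocessing(rec, apply_excision=False, **kwargs)

        clean_rec = simulate_subject(
            sched, tpl, TMSArtifactModel(peak_uv=0.0),
            NoiseModel(pink_sigma_uv=0, white_sigma_uv=0, line_amp_uv=0,
                       blink_rate_per_min=0, subject_sigma=0),
            BehaviorModel.default(), montage, seed=13,
        )[0]
        truth = run_preprocessing(clean_rec, apply_excision=False, **kwargs)

        for tms in ("early", "intermediate", "late"):
            for kind in ("stack", "frame", "homogenous"):
                gt = truth[(kind, tms)].pooled
                e_with = np.sqrt(np.mean((with_exc[(kind, tms)].pooled - gt) ** 2))
                e_without = np.sqrt(np.mean((without[(kind, tms)].pooled - gt) ** 2))
                assert e_with < e_without

    def test_no_events_rejected(self, small_recording):
        rec, _ = small_recording
        import dataclasses

        empty = dataclasses.replace(
            rec, events=rec.events.iloc[:0], pulse_events=rec.pulse_events.iloc[:0]
        )
        with pytest.raises(ValueError, match="no events"):
            run_preprocessing(empty)

    def test_erp_error_decreases_with_trial_count(self, montage):
        """Averaging more trials brings the pooled ERP closer to the
        injected template (checked at 3 trial counts)."""
        from figground.stimuli import TrialSchedule, build_schedule
        from figground.synth import (
            BehaviorModel, ERPTemplateSet, NoiseModel, TMSArtifactModel,
            simulate_subject,
        )

        tpl = ERPTemplateSet.default()
        noise = NoiseModel(blink_rate_per_min=0, subject_sigma=0)
        errs = []
        for n_trials, seed in ((12, 0), (36, 1), (108, 2)):
            sched = build_schedule(1, n_trials, seed=seed)
            table = sched.table.copy()
            table["tms"] = "none"
            rec, _ = simulate_subject(
                TrialSchedule(table), tpl, TMSArtifactModel(), noise,
                BehaviorModel.default(), montage, seed=20 + seed, iti_s=1.4,
            )
            erps = run_preprocessing(rec, apply_laplacian=False)
            t = erps[("stack", "none")].times_ms
            gt = tpl.waveform("stack", "none", t)
            gt -= gt[(t >= -100) & (t < 0)].mean()
            errs.append(np.sqrt(np.mean((erps[("stack", "none")].pooled - gt) ** 2)))
        assert errs[0] > errs[1] > errs[2]
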