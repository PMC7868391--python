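"""ASSR analysis chain: artifact detection, preprocessing, epoching,
source contrasts, thalamic pathway, subject-count curve."""

import warnings

import numpy as np
import pytest

from ratesi import assr_pipeline as ap
from ratesi import assr_synth as asyn
from ratesi import inverse as iv
from ratesi.recording import SensorRecording


@pytest.fixture(scope="module")
def subject(default_lf):
    proto = asyn.AssrProtocol(n_subjects=1, seed=9)
    rec, gt = asyn.generate_assr_subject(default_lf, proto, 0)
    return proto, rec, gt


class TestArtifactDetection:
    def test_sensitivity_on_injected_artifacts(self, subject):
        _, rec, _ = subject
        dirty, mask = asyn.inject_artifacts(rec, asyn.ArtifactSpec(), rng=4)
        bad, _ = ap.detect_artifact_segments(dirty)
        # A trial counts as contaminated when it overlaps the substantive
        # part of a burst (the Hann taper makes the outer edges of the
        # injected interval carry negligible energy).
        fs = int(rec.fs)
        truth = np.zeros(len(rec.events), dtype=bool)
        for i, on in enumerate(rec.events[:, 0]):
            for s0, s1 in mask:
                overlap = min(on + fs, s1) - max(on - fs, s0)
                if overlap > 0.25 * (s1 - s0):
                    truth[i] = True
        sens = (bad & truth).sum() / max(truth.sum(), 1)
        assert sens >= 0.95

    def test_white_noise_false_alarm_rate_low(self, rng):
        rec = SensorRecording(data=rng.standard_normal((12, 240_000)),
                              fs=1000.0,
                              events=np.column_stack([
                                  np.arange(2000, 238_000, 2000),
                                  np.full(118, 1)]))
        bad, _ = ap.detect_artifact_segments(rec, z_thresh=4.0)
        assert bad.mean() < 0.05

    def test_peak_to_peak_always_flags(self, subject):
        _, rec, _ = subject
        dirty = rec.copy()
        on = rec.events[40, 0]
        dirty.data[3, on + 100] += 50 * np.abs(rec.data).max()
        bad, reasons = ap.detect_artifact_segments(
            dirty, ptp_limit=10 * np.abs(rec.data).max())
        assert bad[40]
        assert "ptp" in reasons[40]

    def test_manual_interval_flags_overlapping_trials(self, subject):
        _, rec, _ = subject
        on = rec.events[10, 0]
        bad, reasons = ap.detect_artifact_segments(
            rec, manual=np.array([[on - 10, on + 10]]))
        assert bad[10] and "manual" in reasons[10]

    def test_nonpositive_threshold_raises(self, subject):
        _, rec, _ = subject
        with pytest.raises(ValueError):
            ap.detect_artifact_segments(rec, z_thresh=0.0)


class TestPreprocess:
    def test_pure_line_noise_removed(self):
        t = np.arange(10_000) / 1000.0
        x = np.sin(2 * np.pi * 50 * t)
        rec = SensorRecording(data=np.vstack([x, -x, x, -x]), fs=1000.0)
        out = ap.preprocess(rec, average_reference=False)
        assert np.sqrt(np.mean(out.data ** 2)) < 1e-6 * np.sqrt(np.mean(x ** 2))

    def test_average_reference_zero_sum(self, subject):
        _, rec, _ = subject
        out = ap.preprocess(rec)
        assert np.abs(out.data.sum(axis=0)).max() < 1e-9 * np.abs(out.data).max()

    def test_lowpass_passes_10hz_blocks_150hz(self):
        t = np.arange(20_000) / 1000.0
        x10 = np.sin(2 * np.pi * 10 * t)
        x150 = np.sin(2 * np.pi * 150 * t)
        rec = SensorRecording(data=np.vstack([x10, x150]), fs=1000.0)
        out = ap.preprocess(rec, notch=0, average_reference=False)
        mid = slice(5000, 15_000)
        assert out.data[0, mid].std() > 0.9 * x10[mid].std()
        assert out.data[1, mid].std() < 0.01 * x150[mid].std()

    def test_low_sampling_rate_raises(self):
        rec = SensorRecording(data=np.zeros((2, 100)), fs=150.0)
        with pytest.raises(ValueError):
            ap.preprocess(rec)


class TestEpoching:
    def test_window_sample_arithmetic(self):
        rec = SensorRecording(data=np.zeros((2, 10_000)), fs=1000.0,
                              events=np.array([[5000, 1]]))
        ep = ap.segment_epochs(rec)
        w = ep.window_slice("entrainment")
        assert (w.start, w.stop) == (400, 950)
        assert ep.stim_window("entrainment").shape[-1] == 550
        # absolute samples: onset 5000 -> [5400, 5950)
        assert ep.stim.shape[-1] == 1000

    def test_no_events_warns_and_returns_empty(self):
        rec = SensorRecording(data=np.zeros((2, 1000)), fs=1000.0)
        with pytest.warns(UserWarning, match="no events"):
            ep = ap.segment_epochs(rec)
        assert ep.n_trials == 0

    def test_all_trials_kept_when_clean(self, subject):
        _, rec, _ = subject
        ep = ap.segment_epochs(rec)
        assert ep.n_trials == 120
        assert len(ep.rejected) == 0

    def test_edge_trials_dropped_with_log(self):
        rec = SensorRecording(data=np.zeros((2, 5000)), fs=1000.0,
                              events=np.array([[100, 1], [2500, 1],
                                               [4800, 1]]))
        ep = ap.segment_epochs(rec)
        assert ep.n_trials == 1
        assert set(ep.rejected["reason"]) == {"edge"}

    def test_bad_mask_drops_pairs(self, subject):
        _, rec, _ = subject
        bad = np.zeros(120, dtype=bool)
        bad[[3, 4]] = True
        ep = ap.segment_epochs(rec, bad_mask=bad)
        assert ep.n_trials == 118
        assert ep.prestim.shape[0] == ep.stim.shape[0]

    def test_thalamic_baseline_mirrors_window_length(self, subject):
        _, rec, _ = subject
        ep = ap.segment_epochs(rec)
        assert (ep.prestim_window("thalamic").shape[-1]
                == ep.stim_window("thalamic").shape[-1])


class TestSourceContrasts:
    def test_identical_conditions_give_zero_contrast(self, default_lf, rng):
        T = 1000
        x = rng.standard_normal((5, 12, T))
        ep = ap.EpochSet(prestim=x, stim=x.copy(), fs=1000.0,
                         kept=np.arange(5),
                         rejected=__import__("pandas").DataFrame())
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            _, _, c_freq = ap.source_contrast_freq(ep, default_lf)
            _, _, c_time = ap.source_contrast_time(ep, default_lf)
        assert np.allclose(c_freq, 0.0)
        assert np.allclose(c_time, 0.0)

    def test_too_few_trials_raise(self, default_lf):
        import pandas as pd
        ep = ap.EpochSet(prestim=np.zeros((1, 12, 1000)),
                         stim=np.zeros((1, 12, 1000)), fs=1000.0,
                         kept=np.array([0]), rejected=pd.DataFrame())
        with pytest.raises(ValueError, match="trials"):
            ap.source_contrast_freq(ep, default_lf)

    @staticmethod
    def _single_component_subject(lf, keep: str, seed: int = 13,
                                  positions=None, noise_scale: float = 1.0):
        """One subject whose recording carries only one component
        (controlled recovery conditions)."""
        proto = asyn.AssrProtocol(n_subjects=1, seed=seed, amplitude_cv=0.0,
                                  noise_white=10e-6 * noise_scale,
                                  noise_pink=20e-6 * noise_scale)
        for c in proto.components:
            if c.name != keep:
                c.amplitude = 0.0
            elif positions is not None:
                c.seed_positions = positions
        rec, gt = asyn.generate_assr_subject(lf, proto, 0)
        return rec, gt

    def test_planted_entrainment_recovered_per_subject(self, default_lf,
                                                       default_head):
        rec, gt = self._single_component_subject(
            default_lf, "entrainment", positions=[(-5.0, -3.0, -2.0)])
        ep = ap.segment_epochs(ap.preprocess(rec))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            _, _, c = ap.source_contrast_freq(ep, default_lf)
        am = int(np.argmax(c))
        g = default_head.grid
        d = min(np.linalg.norm(g.positions[am] - g.positions[p])
                for p in gt.component_dipoles["entrainment"])
        assert d <= 2.0

    def test_planted_late_source_recovered(self, default_lf, default_head):
        # high-SNR controlled recovery (at default noise the superficial
        # depth bias grows to ~3 mm)
        rec, gt = self._single_component_subject(
            default_lf, "late", positions=[(-1.5, 4.0, -2.0)],
            noise_scale=0.1)
        ep = ap.segment_epochs(ap.preprocess(rec))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            _, _, c = ap.source_contrast_time(ep, default_lf, solver="lcmv",
                                              window="late")
        am = int(np.argmax(c))
        g = default_head.grid
        d = min(np.linalg.norm(g.positions[am] - g.positions[p])
                for p in gt.component_dipoles["late"])
        assert d <= 2.0

    def test_thalamic_burst_recovered_nearby(self, default_lf, default_head):
        # deep-source localization on a dorsal-only 12-channel montage is
        # blurry: the argmax lands in the deep neighbourhood of the
        # planted dipole but overshoots in depth by a few mm
        rec, gt = self._single_component_subject(default_lf, "thalamic",
                                                 noise_scale=0.1)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            _, _, c = ap.thalamic_pathway(rec, default_lf)
        am = int(np.argmax(c))
        g = default_head.grid
        d = min(np.linalg.norm(g.positions[am] - g.positions[p])
                for p in gt.component_dipoles["thalamic"])
        assert d <= 4.5

    def test_thalamic_low_fs_raises(self, default_lf):
        rec = SensorRecording(data=np.zeros((12, 1000)), fs=500.0)
        with pytest.raises(ValueError):
            ap.thalamic_pathway(rec, default_lf)


class TestSubjectCurve:
    def test_full_set_correlation_is_one(self, rng):
        maps = rng.random((8, 50))
        curve = ap.subject_correlation_curve(maps, n_draws=20, rng=rng)
        assert curve.iloc[-1]["mean"] == 1.0

    def test_monotone_in_expectation(self, rng):
        # common signal + subject noise: more subjects -> higher
        # correlation with the grand average (checked over 3 seeds)
        for seed in range(3):
            r = np.random.default_rng(seed)
            signal = r.random(60)
            maps = signal + 0.8 * r.standard_normal((12, 60))
            curve = ap.subject_correlation_curve(maps, n_draws=60, rng=r)
            m = curve["mean"].to_numpy()
            assert np.all(np.diff(m) > -0.02)  # monotone up to draw noise

    def test_too_few_subjects_raise(self, rng):
        with pytest.raises(ValueError):
            ap.subject_correlation_curve(rng.random((2, 10)))
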