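"""Preprocessing contracts: CAR, epoching, EOG screening, filtering, splits,
leak-free standardization."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import signal

from mieeg.data import EEGTrialSet
from mieeg.errors import ConfigurationError, GeometryError
from mieeg.preprocessing import (
    FilterSpec,
    SplitScheme,
    apply_standardizer,
    bandpass,
    car_reference,
    epoch,
    fit_standardizer,
    reject_eog_trials,
    stratified_split,
)
from mieeg.synth import SynthSpec, generate_dataset


def _trialset(data, labels=None, subjects=None, fs=250.0, window=None, eog=None):
    n, c, t = data.shape
    if window is None:
        window = (0.0, t / fs)
    return EEGTrialSet(
        data=data,
        labels=np.zeros(n, dtype=int) if labels is None else labels,
        subjects=np.zeros(n, dtype=int) if subjects is None else subjects,
        channel_names=[f"ch{i}" for i in range(c)],
        fs=fs,
        window=window,
        eog=eog,
    )


# ---------------------------------------------------------------------------
# common average reference
# ---------------------------------------------------------------------------
class TestCarReference:
    def test_zero_mean_input_unchanged(self, rng):
        x = rng.normal(size=(2, 4, 100))
        x -= x.mean(axis=1, keepdims=True)
        out = car_reference(_trialset(x))
        np.testing.assert_allclose(out.data, x, atol=1e-12)

    def test_offset_invariance(self, rng):
        x = rng.normal(size=(2, 4, 100))
        shifted = x + 7.5  # constant offset on all channels
        a = car_reference(_trialset(x)).data
        b = car_reference(_trialset(shifted)).data
        np.testing.assert_allclose(a, b, atol=1e-12)

    def test_output_channel_mean_is_zero(self, rng):
        out = car_reference(_trialset(rng.normal(size=(3, 4, 200)) * 50))
        assert np.abs(out.data.mean(axis=1)).max() < 1e-9

    def test_single_channel_errors(self, rng):
        with pytest.raises(GeometryError):
            car_reference(_trialset(rng.normal(size=(2, 1, 100))))


# ---------------------------------------------------------------------------
# epoching
# ---------------------------------------------------------------------------
class TestEpoch:
    def test_epoch_length_1125_samples(self, rng):
        cont = rng.normal(size=(3, 5000))
        ds, skipped = epoch(cont, [200, 2000], (-0.5, 4.0), 250.0)
        assert ds.n_samples == 1125  # 4.5 s at 250 Hz
        assert not skipped

    def test_cue_at_edge_skipped_with_report(self, rng, caplog):
        cont = rng.normal(size=(2, 2000))
        with caplog.at_level("WARNING"):
            ds, skipped = epoch(cont, [0, 500], (-0.5, 4.0), 250.0)
        assert skipped == [0]
        assert ds.n_trials == 1
        assert "skipped" in caplog.text

    def test_epochs_equal_continuous_slices(self, rng):
        cont = rng.normal(size=(2, 3000))
        cues = [400, 1200]
        ds, _ = epoch(cont, cues, (-0.5, 4.0), 250.0)
        for i, cue in enumerate(cues):
            np.testing.assert_array_equal(
                ds.data[i], cont[:, cue - 125 : cue + 1000]
            )


# ---------------------------------------------------------------------------
# EOG rejection
# ---------------------------------------------------------------------------
class TestRejectEog:
    def _ds(self, peaks):
        n = len(peaks)
        eog = np.zeros((n, 1, 100))
        for i, p in enumerate(peaks):
            eog[i, 0, 50] = p
        return _trialset(np.zeros((n, 2, 100)), eog=eog)

    def test_all_within_threshold_nothing_rejected(self):
        kept, rejected = reject_eog_trials(self._ds([50, -40, 30]), 100.0)
        assert kept.n_trials == 3 and len(rejected) == 0

    def test_150uv_trial_rejected(self):
        kept, rejected = reject_eog_trials(self._ds([50, 150, -30]), 100.0)
        assert list(rejected) == [1]
        assert kept.n_trials == 2

    def test_exactly_threshold_retained(self):
        kept, rejected = reject_eog_trials(self._ds([100.0, -100.0]), 100.0)
        assert kept.n_trials == 2 and len(rejected) == 0

    def test_no_eog_block_warns_and_passes_through(self, caplog):
        ds = _trialset(np.zeros((2, 2, 100)))
        with caplog.at_level("WARNING"):
            kept, rejected = reject_eog_trials(ds, 100.0)
        assert kept.n_trials == 2 and len(rejected) == 0


# ---------------------------------------------------------------------------
# band-pass filter
# ---------------------------------------------------------------------------
def _analytic_butter_bandpass_gain(f, low, high, order, fs):
    """Analytic squared magnitude of the digital Butterworth band-pass at f,
    computed from the analog prototype with bilinear prewarping."""
    warp = lambda x: 2 * fs * np.tan(np.pi * x / fs)  # noqa: E731
    w = warp(f)
    w1, w2 = warp(low), warp(high)
    w0 = np.sqrt(w1 * w2)
    bw = w2 - w1
    ratio = (w**2 - w0**2) / (bw * w)
    mag2 = 1.0 / (1.0 + ratio ** (2 * order))
    return mag2**2  # forward-backward doubles the attenuation


class TestBandpass:
    def _sine(self, freq, fs=250.0, seconds=4.0):
        t = np.arange(int(fs * seconds)) / fs
        x = np.sin(2 * np.pi * freq * t)[None, None, :]
        return _trialset(x, fs=fs)

    def test_zero_signal_stays_zero(self):
        out = bandpass(_trialset(np.zeros((1, 2, 1000))))
        np.testing.assert_array_equal(out.data, 0.0)

    @pytest.mark.parametrize("freq,bound", [(20.0, "pass"), (2.0, "stop")])
    def test_steady_state_gain_matches_analytic_response(self, freq, bound):
        ds = self._sine(freq)
        out = bandpass(ds, FilterSpec())
        mid = slice(250, 750)  # steady-state portion
        gain = np.sqrt(
            (out.data[0, 0, mid] ** 2).mean() / (ds.data[0, 0, mid] ** 2).mean()
        )
        expected = np.sqrt(_analytic_butter_bandpass_gain(freq, 8, 30, 4, 250.0))
        if bound == "pass":
            assert gain >= 0.95
        else:
            assert gain <= 0.01
        np.testing.assert_allclose(gain, expected, atol=0.02)

    def test_zero_phase_reversal_identity(self, rng):
        x = rng.normal(size=(2, 3, 1000))
        fwd = bandpass(_trialset(x)).data
        rev = bandpass(_trialset(x[:, :, ::-1].copy())).data[:, :, ::-1]
        assert np.linalg.norm(fwd - rev) / np.linalg.norm(fwd) < 1e-9

    def test_band_outside_nyquist_errors(self, rng):
        ds = _trialset(rng.normal(size=(1, 2, 500)), fs=50.0)
        with pytest.raises(ConfigurationError):
            bandpass(ds, FilterSpec(low_hz=8, high_hz=30))


# ---------------------------------------------------------------------------
# standardization
# ---------------------------------------------------------------------------
class TestStandardizer:
    def test_train_moments_become_standard(self, rng):
        train = _trialset(rng.normal(5.0, 2.0, size=(30, 3, 200)))
        s = fit_standardizer(train)
        out = apply_standardizer(s, train)
        np.testing.assert_allclose(out.data.mean(axis=(0, 2)), 0.0, atol=1e-6)
        np.testing.assert_allclose(out.data.std(axis=(0, 2)), 1.0, atol=1e-3)

    def test_constant_channel_maps_to_zero(self, rng, caplog):
        data = rng.normal(size=(5, 2, 100))
        data[:, 1, :] = 4.2
        with caplog.at_level("WARNING"):
            s = fit_standardizer(_trialset(data))
        out = apply_standardizer(s, _trialset(data))
        np.testing.assert_allclose(out.data[:, 1, :], 0.0, atol=1e-6)

    def test_shifted_test_set_proves_no_refit(self, rng):
        train = _trialset(rng.normal(0.0, 2.0, size=(50, 1, 500)))
        s = fit_standardizer(train)
        test = _trialset(train.data[:10] + 10.0)
        out = apply_standardizer(s, test)
        expected_shift = 10.0 / s.sd[0]
        base = apply_standardizer(s, _trialset(train.data[:10]))
        np.testing.assert_allclose(
            out.data.mean() - base.data.mean(), expected_shift, rtol=1e-6
        )

    def test_mutating_test_data_never_changes_fit(self, rng):
        train = _trialset(rng.normal(size=(10, 2, 100)))
        test = _trialset(rng.normal(size=(4, 2, 100)))
        s = fit_standardizer(train)
        mean_before = s.mean.copy()
        test.data *= 1000.0
        apply_standardizer(s, test)
        np.testing.assert_array_equal(s.mean, mean_before)


# ---------------------------------------------------------------------------
# stratified splitting
# ---------------------------------------------------------------------------
def _balanced_ds(n_per_class, n_classes=2, n_subjects=1, rng=None):
    rng = rng or np.random.default_rng(0)
    n = n_per_class * n_classes * n_subjects
    labels = np.tile(np.repeat(np.arange(n_classes), n_per_class), n_subjects)
    subjects = np.repeat(np.arange(n_subjects), n_per_class * n_classes)
    return _trialset(
        rng.normal(size=(n, 2, 50)), labels=labels, subjects=subjects, fs=100.0
    )


class TestStratifiedSplit:
    def test_iv2a_proportions_40_trials(self):
        ds = _balanced_ds(20)
        plan = stratified_split(ds, SplitScheme.from_name("IV-2a"))
        s = plan.per_subject[0]
        assert len(s.test_idx) == 8 and len(s.val_idx) == 8 and len(s.train_idx) == 24
        for part in (s.test_idx, s.val_idx):
            counts = np.bincount(ds.labels[part], minlength=2)
            assert (counts == len(part) // 2).all()

    def test_iv2b_proportions_200_trials(self):
        ds = _balanced_ds(100)
        plan = stratified_split(ds, SplitScheme.from_name("IV-2b"))
        s = plan.per_subject[0]
        assert len(s.test_idx) == 30    # round(0.15 * 200)
        assert len(s.val_idx) == 31     # round(0.18 * 170) = round(30.6)
        assert len(s.train_idx) == 139

    def test_same_seed_identical_plans(self):
        ds = _balanced_ds(10, n_subjects=3)
        a = stratified_split(ds, SplitScheme.from_name("IV-2a", seed=5))
        b = stratified_split(ds, SplitScheme.from_name("IV-2a", seed=5))
        for s in a.per_subject:
            np.testing.assert_array_equal(
                a.per_subject[s].train_idx, b.per_subject[s].train_idx
            )
            np.testing.assert_array_equal(
                a.per_subject[s].test_idx, b.per_subject[s].test_idx
            )

    def test_too_few_trials_per_class_errors(self):
        ds = _balanced_ds(1)
        with pytest.raises(ConfigurationError):
            stratified_split(ds, SplitScheme.from_name("IV-2a"))

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(
        n_per_class=st.integers(min_value=8, max_value=40),
        n_classes=st.sampled_from([2, 4]),
        n_subjects=st.integers(min_value=1, max_value=3),
        seed=st.integers(min_value=0, max_value=1000),
    )
    def test_partition_is_exact_and_proportional(
        self, n_per_class, n_classes, n_subjects, seed
    ):
        """Train/val/test are pairwise disjoint, exhaustive per subject, and
        per-class counts stay within one of exact proportionality."""
        ds = _balanced_ds(n_per_class, n_classes, n_subjects)
        plan = stratified_split(ds, SplitScheme.from_name("IV-2a", seed=seed))
        for subject, s in plan.per_subject.items():
            all_idx = np.concatenate([s.train_idx, s.val_idx, s.test_idx])
            expected = np.flatnonzero(ds.subjects == subject)
            np.testing.assert_array_equal(np.sort(all_idx), expected)
            assert len(np.unique(all_idx)) == len(all_idx)
            for part in (s.train_idx, s.val_idx, s.test_idx):
                counts = np.bincount(ds.labels[part], minlength=n_classes)
                exact = len(part) / n_classes
                assert np.all(np.abs(counts - exact) <= 1)


def test_full_pipeline_order_runs_end_to_end():
    """CAR -> EOG-reject -> band-pass -> split -> standardize on synthetic data."""
    ds = generate_dataset(
        SynthSpec(n_subjects=2, n_trials_per_class=10, artifact_fraction=0.2,
                  epoch_window=(-0.5, 1.5), seed=31)
    )
    ds = car_reference(ds)
    ds, rejected = reject_eog_trials(ds, 100.0)
    assert len(rejected) > 0  # 150 uV artifacts must be caught
    ds = bandpass(ds, FilterSpec())
    plan = stratified_split(ds, SplitScheme.from_name("IV-2b"))
    train = ds.select(plan.train_idx)
    s = fit_standardizer(train)
    out = apply_standardizer(s, train)
    assert np.abs(out.data.mean(axis=(0, 2))).max() < 1e-6
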