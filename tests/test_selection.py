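"""Focality classification and component pruning."""

import numpy as np
import pytest

from ar2eeg import (
    classify_components,
    infomax_ica,
    normalize_topography,
    prune_backproject,
)


class TestNormalizeTopography:
    def test_uniform_column_maps_to_zeros(self):
        mixing = np.ones((19, 1))
        assert np.all(normalize_topography(mixing) == 0.0)

    def test_one_hot_closed_form(self):
        """One active electrode of 19: z at the hot electrode is
        (1 - 1/19) / sqrt(p(1-p)) = sqrt(18) = 4.2426 (population SD)."""
        col = np.zeros((19, 1))
        col[7, 0] = 1.0
        z = normalize_topography(col)
        assert z[7, 0] == pytest.approx(np.sqrt(18.0), abs=1e-12)
        assert z[7, 0] == pytest.approx(4.243, abs=5e-4)

    def test_scale_and_sign_invariance(self, rng):
        mixing = rng.normal(size=(19, 4))
        z = normalize_topography(mixing)
        assert np.allclose(normalize_topography(mixing * 7.3), z, atol=1e-12)
        assert np.allclose(normalize_topography(-mixing), z, atol=1e-12)


class TestClassify:
    def test_all_uniform_nothing_pruned(self):
        z = np.zeros((19, 5))
        labels = classify_components(z)
        assert all(lab.klass == "neurogenic" for lab in labels)

    def test_one_hot_component_is_myogenic(self):
        col = np.zeros((19, 1))
        col[3, 0] = 1.0
        labels = classify_components(normalize_topography(col))
        assert labels[0].klass == "myogenic"
        assert labels[0].focality == pytest.approx(np.sqrt(18.0), abs=1e-9)

    def test_both_rules_on_worked_example(self):
        """z-maxima [5, 3, 1.5, 4, 0.5] by variance order: per-component flags
        {0, 1, 3}; variance-prefix extends to everything up to the last focal
        component, {0, 1, 2, 3}."""
        maxima = [5.0, 3.0, 1.5, 4.0, 0.5]
        z = np.zeros((19, 5))
        for i, m in enumerate(maxima):
            z[0, i] = m
        per = classify_components(z, 2.0, "per_component")
        assert [l.klass == "myogenic" for l in per] == [True, True, False, True, False]
        pre = classify_components(z, 2.0, "variance_prefix")
        assert [l.klass == "myogenic" for l in pre] == [True, True, True, True, False]

    def test_threshold_inclusive(self):
        z = np.zeros((19, 1))
        z[0, 0] = 2.0
        assert classify_components(z, 2.0)[0].klass == "myogenic"


@pytest.fixture(scope="module")
def toy_decomposition():
    rng = np.random.default_rng(11)
    s = rng.laplace(size=(3, 24000))
    a = rng.normal(size=(3, 3))
    x = a @ s
    x -= x.mean(axis=1, keepdims=True)  # zero-mean fixture
    return x, infomax_ica(x, seed=4)


class TestPruneBackproject:
    def test_nothing_pruned_is_identity(self, toy_decomposition):
        x, d = toy_decomposition
        labels = classify_components(np.zeros((3, 3)))  # all neurogenic
        cleaned = prune_backproject(d, labels)
        assert np.max(np.abs(cleaned - x)) / np.max(np.abs(x)) <= 1e-6

    def test_everything_pruned_is_zero(self, toy_decomposition):
        x, d = toy_decomposition
        z = np.full((3, 3), 0.0)
        z[0, :] = 99.0  # all components focal
        labels = classify_components(z)
        cleaned = prune_backproject(d, labels)
        assert np.allclose(cleaned, 0.0, atol=1e-9)

    def test_idempotent(self, toy_decomposition):
        x, d = toy_decomposition
        z = np.zeros((3, 3))
        z[0, 0] = 5.0  # prune the highest-variance component
        labels = classify_components(z)
        once = prune_backproject(d, labels)
        d2 = infomax_ica(once, seed=4)
        # pruning with no myogenic labels on the cleaned data changes nothing
        keep_all = classify_components(np.zeros((3, d2.n_components)))
        twice = prune_backproject(d2, keep_all)
        assert np.max(np.abs(twice - once)) <= 1e-6 * np.max(np.abs(once))

    def test_label_count_mismatch_rejected(self, toy_decomposition):
        _, d = toy_decomposition
        with pytest.raises(ValueError):
            prune_backproject(d, [])


class TestEndToEndTrialCleaning:
    def test_removes_focal_emg_keeps_smooth_rhythm(self):
        """A trial of smooth-topography 25 Hz rhythm plus one-hot EMG noise:
        pruning the focal component removes >= 90% of the EMG channel's
        high-band excess power while the rhythm stays correlated >= 0.9."""
        from ar2eeg.synthetic import _DEFAULT_LABELS, _coords, _gauss_topo

        rng = np.random.default_rng(21)
        n_ch, n = 19, 24000
        # genuinely distributed topography (max z < 2 by construction)
        smooth = _gauss_topo(_coords(_DEFAULT_LABELS), _coords(["F3"])[0], 0.9)
        # waxing narrowband (20-30 Hz) rhythm: the amplitude ramp makes the
        # source super-Gaussian, as ictal rhythms are, hence separable
        w = np.fft.rfft(rng.normal(size=n))
        f = np.fft.rfftfreq(n, 1 / 200.0)
        w[(f < 20) | (f > 30)] = 0
        rhythm_src = np.fft.irfft(w, n=n)
        rhythm_src = rhythm_src / rhythm_src.std() * np.linspace(0.2, 1.8, n)
        rhythm = 10.0 * smooth[:, None] * rhythm_src
        emg_topo = np.zeros(n_ch)
        emg_topo[5] = 1.0
        emg = 40.0 * emg_topo[:, None] * rng.normal(size=n)
        noise = 1.0 * rng.normal(size=(n_ch, n))
        x = rhythm + emg + noise

        d = infomax_ica(x, seed=0)
        z = normalize_topography(d.mixing)
        labels = classify_components(z, 2.0)
        assert any(l.klass == "myogenic" for l in labels)
        cleaned = prune_backproject(d, labels)

        excess_before = np.var(x[5] - rhythm[5])
        excess_after = np.var(cleaned[5] - rhythm[5])
        assert excess_after <= 0.1 * excess_before
        onset = _DEFAULT_LABELS.index("F3")
        assert np.corrcoef(cleaned[onset], rhythm[onset])[0, 1] >= 0.9

    def test_focal_emg_component_exceeds_two_sd(self):
        """Across seeded repeats, the EMG component's focality beats 2 SD for
        both 1- and 2-electrode muscle topographies."""
        hits = 0
        reps = 20
        for k in range(reps):
            rng = np.random.default_rng(300 + k)
            n_ch, n = 19, 8000
            two = k % 2 == 0
            topo = np.zeros(n_ch)
            topo[3] = 1.0
            if two:
                topo[4] = 0.7
            emg = 40.0 * topo[:, None] * rng.normal(size=n)
            base = 5.0 * rng.normal(size=(n_ch, n))
            d = infomax_ica(emg + base, seed=k)
            z = normalize_topography(d.mixing)
            focal = z.max(axis=0) >= 2.0
            # the component carrying the EMG channel's variance must be focal
            emg_comp = int(np.argmax(np.abs(d.mixing[3, :])))
            hits += bool(focal[emg_comp])
        assert hits >= 0.95 * reps
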