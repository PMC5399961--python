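"""Artifact-epoch detection and NMI channel screening."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ar2eeg import (
    ArtifactEpoch,
    EEGRecording,
    composite_envelope,
    longest_suprathreshold_epoch,
    mi_adjacency,
    normalized_mi,
    screen_channels,
)


def brute_force_longest_run(env: np.ndarray, thr: float):
    """Exhaustive scan over all maximal suprathreshold runs (oracle)."""
    best = None
    i = 0
    n = env.size
    while i < n:
        if env[i] > thr:
            j = i
            while j < n and env[j] > thr:
                j += 1
            if best is None or (j - i) > (best[1] - best[0]):
                best = (i, j)
            i = j
        else:
            i += 1
    return best


def brute_force_nmi(x, y, n_bins):
    """Independent plug-in NMI via explicit bin-by-bin enumeration."""
    def bin_of(v, lo, hi):
        if hi == lo:
            return 0
        b = int((v - lo) / (hi - lo) * n_bins)
        return min(b, n_bins - 1)

    counts = {}
    for xi, yi in zip(x, y):
        key = (bin_of(xi, min(x), max(x)), bin_of(yi, min(y), max(y)))
        counts[key] = counts.get(key, 0) + 1
    n = len(x)
    px, py = {}, {}
    for (bx, by), c in counts.items():
        px[bx] = px.get(bx, 0) + c
        py[by] = py.get(by, 0) + c
    hx = -sum(c / n * np.log(c / n) for c in px.values())
    hy = -sum(c / n * np.log(c / n) for c in py.values())
    mi = sum(
        c / n * np.log((c / n) / (px[bx] / n * py[by] / n))
        for (bx, by), c in counts.items()
    )
    return mi / np.sqrt(hx * hy)


class TestCompositeEnvelope:
    def test_burst_drives_composite_above_one_sd(self, rng):
        """A 10-s 3x-amplitude burst on all channels must push the composite
        above +1 SD inside the burst and below 0 outside."""
        n, fs = 12000, 200.0
        carrier = rng.normal(size=(4, n))
        gain = np.ones(n)
        gain[5000:7000] = 3.0
        rec = EEGRecording([f"c{i}" for i in range(4)], fs, carrier * gain)
        env = composite_envelope(rec, 0.5)
        assert env[5200:6800].max() > 1.0
        assert np.median(env[5200:6800]) > np.median(np.r_[env[:4800], env[7200:]])
        assert np.median(np.r_[env[:4800], env[7200:]]) < 0.0

    def test_single_channel_matches_direct_formula(self, rng):
        from ar2eeg import hilbert_envelope, moving_average

        x = rng.normal(size=(1, 4000))
        rec = EEGRecording(["only"], 200.0, x)
        env = composite_envelope(rec, 0.5)
        e = hilbert_envelope(x[0])
        ref = moving_average((e - e.mean()) / e.std(), 101)
        ref = (ref - ref.mean()) / ref.std()
        assert np.allclose(env, ref, atol=1e-12)

    def test_flat_channel_omitted_with_warning(self, rng):
        data = rng.normal(size=(3, 2000))
        data[2] = 0.0
        rec = EEGRecording(["a", "b", "dead"], 200.0, data)
        with pytest.warns(RuntimeWarning, match="dead"):
            env = composite_envelope(rec, 0.5)
        assert env.size == 2000

    def test_all_flat_is_error(self):
        rec = EEGRecording(["a", "b"], 200.0, np.zeros((2, 2000)))
        with pytest.raises(ValueError):
            composite_envelope(rec, 0.5)


class TestLongestEpoch:
    def test_none_when_below_threshold(self):
        assert longest_suprathreshold_epoch(np.zeros(100), 1.0) is None

    def test_picks_longest_run(self):
        env = np.zeros(1000)
        env[100:110] = 2.0
        env[400:425] = 1.5
        ep = longest_suprathreshold_epoch(env, 1.0)
        assert (ep.start_sample, ep.end_sample) == (400, 425)
        assert ep.peak_sd == 1.5

    def test_tie_broken_to_earliest(self):
        env = np.zeros(1000)
        env[100:120] = 2.0
        env[400:420] = 2.0
        ep = longest_suprathreshold_epoch(env, 1.0)
        assert (ep.start_sample, ep.end_sample) == (100, 120)

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(seed=st.integers(0, 100_000))
    def test_matches_brute_force_scan(self, seed):
        env = np.random.default_rng(seed).normal(size=200)
        ep = longest_suprathreshold_epoch(env, 1.0)
        oracle = brute_force_longest_run(env, 1.0)
        if oracle is None:
            assert ep is None
        else:
            assert (ep.start_sample, ep.end_sample) == oracle

    def test_boundary_is_strict(self):
        env = np.full(50, 1.0)  # exactly at threshold: not greater
        assert longest_suprathreshold_epoch(env, 1.0) is None


class TestNormalizedMI:
    def test_self_information_is_one(self, rng):
        x = rng.normal(size=500)
        assert normalized_mi(x, x) == 1.0

    def test_discrete_toy_matches_enumeration(self):
        x = np.array([0.0, 0, 1, 1, 2, 2, 3, 3])
        y = np.array([0.0, 1, 0, 1, 0, 1, 0, 1])
        got = normalized_mi(x, y, n_bins=4)
        expected = brute_force_nmi(x, y, 4)
        assert got == pytest.approx(expected, abs=1e-12)
        assert got == pytest.approx(0.0, abs=1e-12)  # hand computation: independent

    def test_dependent_toy_matches_enumeration(self):
        x = np.array([0.0, 0, 1, 1, 2, 2, 3, 3] * 4)
        y = (x % 2).astype(float)
        got = normalized_mi(x, y, n_bins=4)
        assert got == pytest.approx(brute_force_nmi(x, y, 4), abs=1e-12)

    @settings(derandomize=True, max_examples=20, deadline=None)
    @given(seed=st.integers(0, 10_000),
           a=st.floats(0.1, 50.0), b=st.floats(-10.0, 10.0))
    def test_affine_invariance(self, seed, a, b):
        g = np.random.default_rng(seed)
        x = g.normal(size=300)
        y = x + 0.3 * g.normal(size=300)
        assert normalized_mi(x, a * y + b) == pytest.approx(
            normalized_mi(x, y), abs=1e-12
        )

    def test_symmetry(self, rng):
        x, y = rng.normal(size=(2, 400))
        assert normalized_mi(x, y) == pytest.approx(normalized_mi(y, x), abs=1e-12)

    def test_constant_input_is_error(self, rng):
        with pytest.raises(ValueError, match="zero entropy"):
            normalized_mi(np.ones(100), rng.normal(size=100))


class TestAdjacency:
    def test_duplicate_channels_have_unit_nmi(self, rng):
        x = rng.normal(size=500)
        rec = EEGRecording(["a", "b"], 200.0, np.vstack([x, x]))
        adj = mi_adjacency(rec, ArtifactEpoch(0, 500, 2.0))
        assert adj[0, 1] == 1.0
        assert adj[0, 0] == 0.0

    def test_symmetric(self, rng):
        rec = EEGRecording([f"c{i}" for i in range(5)], 200.0,
                           rng.normal(size=(5, 600)))
        adj = mi_adjacency(rec, ArtifactEpoch(0, 600, 2.0))
        assert np.array_equal(adj, adj.T)

    def test_independent_channel_has_lowest_row_max(self):
        g = np.random.default_rng(7)
        shared = g.normal(size=2000)
        data = np.vstack([
            shared + 0.2 * g.normal(size=2000),
            shared + 0.2 * g.normal(size=2000),
            shared + 0.2 * g.normal(size=2000),
            g.uniform(-1, 1, size=2000),  # independent
        ])
        rec = EEGRecording(["a", "b", "c", "noise"], 200.0, data)
        adj = mi_adjacency(rec, ArtifactEpoch(0, 2000, 2.0))
        row_max = adj.max(axis=1)
        assert row_max[3] < row_max[:3].min()

    def test_short_epoch_rejected(self, rng):
        rec = EEGRecording(["a", "b"], 200.0, rng.normal(size=(2, 100)))
        with pytest.raises(ValueError, match="longer epoch or fewer bins"):
            mi_adjacency(rec, ArtifactEpoch(0, 60, 2.0), n_bins=16)


class TestScreening:
    def test_perfect_coherence_keeps_all(self):
        adj = np.ones((4, 4)) - np.eye(4)
        rep = screen_channels(adj, 0.2)
        assert rep.included.all() and not rep.fallback

    def test_low_mi_channel_excluded(self):
        adj = np.zeros((3, 3))
        adj[0, 1] = adj[1, 0] = 0.9
        adj[0, 2] = adj[2, 0] = 0.05
        adj[1, 2] = adj[2, 1] = 0.05
        rep = screen_channels(adj, 0.2, labels=["a", "b", "c"])
        assert rep.excluded_labels == ["c"]
        assert rep.max_nmi[0] == pytest.approx(0.9)

    def test_all_excluded_triggers_fallback(self):
        adj = np.full((3, 3), 0.05) - 0.05 * np.eye(3)
        rep = screen_channels(adj, 0.2)
        assert rep.fallback and rep.included.all()

    def test_report_serializes(self):
        rep = screen_channels(np.ones((2, 2)) - np.eye(2), 0.2,
                              epoch=ArtifactEpoch(10, 50, 1.4))
        d = rep.to_dict()
        assert d["epoch"]["start_sample"] == 10
        import json

        json.dumps(d)
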