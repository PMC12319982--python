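"""backfit_stats: labeling, smoothing, statistics, matching, trimming."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from mstates import (
    EpochedEEG,
    FeatureTable,
    LabelSequence,
    PrototypeSet,
    ValidationError,
    backfit_labels,
    canonical_templates,
    compute_microstate_stats,
    make_montage,
    match_prototypes,
    simulate_microstate_eeg,
    simulate_state_sequence,
    smooth_short_segments,
    trim_feature_outliers,
)


def _orthonormal_protos(K=3, C=8, seed=0):
    rng = np.random.default_rng(seed)
    M = rng.normal(size=(K, C))
    M -= M.mean(axis=1, keepdims=True)
    q, _ = np.linalg.qr(M.T)
    maps = q[:, :K].T
    maps -= maps.mean(axis=1, keepdims=True)
    maps /= np.linalg.norm(maps, axis=1, keepdims=True)
    return PrototypeSet(maps=maps)


class TestBackfit:
    def test_negative_scaled_prototype_gets_its_label(self):
        protos = _orthonormal_protos()
        arr = np.zeros((1, 8, 10))
        arr[0, :, 3] = -3.0 * protos.maps[2]
        ep = EpochedEEG(arr, 5.0, 2.0, make_montage(8, seed=0))
        seq = backfit_labels(ep, protos)
        assert seq.labels[0, 3] == 2
        assert seq.corr[0, 3, 2] == pytest.approx(1.0, abs=1e-9)

    def test_zero_sample_ties_to_class_zero(self):
        protos = _orthonormal_protos()
        ep = EpochedEEG(np.zeros((1, 8, 10)), 5.0, 2.0, make_montage(8, seed=0))
        seq = backfit_labels(ep, protos)
        assert (seq.labels == 0).all()
        assert np.abs(seq.corr).max() == pytest.approx(0.0, abs=1e-12)

    def test_matches_brute_force_argmax(self, protos5):
        labels = simulate_state_sequence(5, 80, 500, 3000, seed=1)
        ep, _ = simulate_microstate_eeg(protos5, labels, 500, snr=2.0, seed=2)
        seq = backfit_labels(ep, protos5)
        flat = ep.epochs.transpose(0, 2, 1).reshape(-1, 64)
        for t in range(0, flat.shape[0], 97):
            v = flat[t] - flat[t].mean()
            n = np.linalg.norm(v)
            if n < 1e-12:
                continue
            corrs = np.abs(protos5.maps @ (v / n))
            assert seq.labels.reshape(-1)[t] == np.argmax(corrs)

    def test_invariant_to_sign_and_scale_of_data(self, protos5):
        labels = simulate_state_sequence(5, 80, 500, 2000, seed=3)
        ep, _ = simulate_microstate_eeg(protos5, labels, 500, snr=4.0, seed=4)
        seq0 = backfit_labels(ep, protos5)
        ep2 = EpochedEEG(-2.5 * ep.epochs, ep.fs, ep.epoch_length_s,
                         ep.channel_positions)
        seq1 = backfit_labels(ep2, protos5)
        np.testing.assert_array_equal(seq0.labels, seq1.labels)

    def test_channel_mismatch_raises(self, protos5):
        ep = EpochedEEG(np.zeros((1, 8, 10)), 5.0, 2.0, make_montage(8, seed=0))
        with pytest.raises(ValidationError):
            backfit_labels(ep, protos5)


def _seq(labels_2d, K, fs=500.0, corr=None, seed=0):
    labels_2d = np.asarray(labels_2d)
    if corr is None:
        rng = np.random.default_rng(seed)
        corr = rng.uniform(0, 0.5, size=labels_2d.shape + (K,))
        for e in range(labels_2d.shape[0]):
            corr[e, np.arange(labels_2d.shape[1]), labels_2d[e]] = \
                rng.uniform(0.6, 1.0, size=labels_2d.shape[1])
    return LabelSequence(labels=labels_2d, corr=corr, fs=fs)


class TestSmoothing:
    def test_no_short_runs_is_identity(self):
        labels = np.repeat([0, 1, 0, 2], 20)[None, :]
        seq = _seq(labels, K=3)
        out = smooth_short_segments(seq, min_duration_ms=30)
        np.testing.assert_array_equal(out.labels, labels)

    def test_two_sample_intrusion_reassigned_to_neighbor(self):
        # at fs=500, 30 ms = 15 samples; A(100) B(2) A(100) with B's
        # second-best correlation pointing at A collapses to one A run
        fs = 500.0
        labels = np.array([[0] * 100 + [1] * 2 + [0] * 100])
        corr = np.zeros((1, 202, 2))
        corr[0, :, 0] = 0.8
        corr[0, :, 1] = 0.1
        corr[0, 100:102, 1] = 0.9  # B wins initially on its two samples
        seq = LabelSequence(labels=labels, corr=corr, fs=fs)
        out = smooth_short_segments(seq, min_duration_ms=30)
        assert (out.labels == 0).all()
        runs = np.flatnonzero(np.diff(out.labels[0]))
        assert runs.size == 0

    def test_zero_threshold_is_noop(self):
        rng = np.random.default_rng(1)
        labels = rng.integers(0, 3, size=(2, 50))
        seq = _seq(labels, K=3)
        out = smooth_short_segments(seq, min_duration_ms=0)
        np.testing.assert_array_equal(out.labels, labels)

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(st.integers(0, 10**6))
    def test_no_subthreshold_runs_remain(self, seed):
        rng = np.random.default_rng(seed)
        fs = 500.0
        K = rng.integers(2, 5)
        n = int(rng.integers(20, 200))
        labels = rng.integers(0, K, size=(1, n))
        seq = _seq(labels, K=int(K), fs=fs, seed=seed)
        min_ms = 30.0
        out = smooth_short_segments(seq, min_duration_ms=min_ms)
        thr = int(np.ceil(min_ms * fs / 1000.0 - 1e-9))
        runs = np.diff(np.concatenate(
            [[0], np.flatnonzero(np.diff(out.labels[0])) + 1, [n]]))
        assert np.all((runs >= thr) | (runs == n))

    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(st.integers(0, 10**6))
    def test_never_picks_a_rejected_worse_label(self, seed):
        # smoothing only moves samples to the best not-yet-rejected class,
        # so the final label's correlation is >= any unrejected alternative
        # unless the run was merged into a neighbor
        rng = np.random.default_rng(seed)
        labels = rng.integers(0, 3, size=(1, 60))
        seq = _seq(labels, K=3, seed=seed)
        out = smooth_short_segments(seq, min_duration_ms=10)
        assert out.labels.min() >= 0 and out.labels.max() < 3


class TestStats:
    def test_single_run_epoch(self):
        seq = _seq(np.zeros((1, 1000), dtype=int), K=2)
        st_ = compute_microstate_stats(seq)
        assert st_.duration_ms[0] == pytest.approx(2000.0)
        assert st_.occurrence_per_s[0] == pytest.approx(0.5)
        assert st_.coverage_fraction[0] == pytest.approx(1.0)
        assert st_.occurrence_per_s[1] == 0.0
        assert np.isnan(st_.duration_ms[1])

    def test_alternating_quarters(self):
        labels = np.tile(np.repeat([0, 1], 125), 4)[None, :]
        seq = _seq(labels, K=2)
        st_ = compute_microstate_stats(seq)
        np.testing.assert_allclose(st_.duration_ms, [250.0, 250.0])
        np.testing.assert_allclose(st_.occurrence_per_s, [2.0, 2.0])
        np.testing.assert_allclose(st_.coverage_fraction, [0.5, 0.5])

    @settings(derandomize=True, max_examples=100, deadline=None)
    @given(st.integers(0, 10**6))
    def test_occurrence_duration_coverage_identity(self, seed):
        rng = np.random.default_rng(seed)
        K = int(rng.integers(2, 6))
        labels = rng.integers(0, K, size=(int(rng.integers(1, 4)),
                                          int(rng.integers(10, 300))))
        seq = _seq(labels, K=K, seed=seed)
        st_ = compute_microstate_stats(seq)
        present = ~np.isnan(st_.duration_ms)
        np.testing.assert_allclose(
            st_.occurrence_per_s[present] * st_.duration_ms[present] / 1000.0,
            st_.coverage_fraction[present], atol=1e-12)
        assert st_.coverage_fraction.sum() == pytest.approx(1.0, abs=1e-9)

    def test_runs_do_not_span_epochs(self):
        labels = np.array([[0, 0, 0, 0], [0, 0, 0, 0]])
        seq = _seq(labels, K=2, fs=2.0)
        st_ = compute_microstate_stats(seq)
        # two runs of 4 samples at 2 Hz = 2000 ms each, not one of 8
        assert st_.duration_ms[0] == pytest.approx(2000.0)
        assert st_.occurrence_per_s[0] == pytest.approx(2 / 4.0)


class TestMatching:
    def test_permutation_recovered(self, protos5):
        perm = [3, 0, 4, 1, 2]
        ref = PrototypeSet(maps=protos5.maps[perm])
        mapping = match_prototypes(protos5, ref,
                                   reference_labels=["A", "B", "C", "D", "E"])
        labels = ["A", "B", "C", "D", "E"]
        for i in range(5):
            assert mapping.assignment[perm[i]] == labels[i]
            assert mapping.scores[perm[i]] == pytest.approx(1.0, abs=1e-9)

    def test_sign_flips_do_not_matter(self, protos5):
        flipped = PrototypeSet(maps=protos5.maps * np.array([1, -1, 1, -1, 1])[:, None])
        a = match_prototypes(protos5, protos5)
        b = match_prototypes(protos5, flipped)
        assert a.assignment == b.assignment
        for k in a.scores:
            assert a.scores[k] == pytest.approx(b.scores[k], abs=1e-9)

    def test_hungarian_equals_exhaustive_search(self, protos5, montage64):
        rng = np.random.default_rng(4)
        noisy = protos5.maps + rng.normal(scale=0.3, size=protos5.maps.shape)
        noisy -= noisy.mean(axis=1, keepdims=True)
        noisy /= np.linalg.norm(noisy, axis=1, keepdims=True)
        found = PrototypeSet(maps=noisy)
        mapping = match_prototypes(found, protos5,
                                   reference_labels=list("ABCDE"))
        corr = np.abs(found.maps @ protos5.maps.T)
        best_score, best_perm = -1, None
        for perm in itertools.permutations(range(5)):
            s = sum(corr[i, perm[i]] for i in range(5))
            if s > best_score:
                best_score, best_perm = s, perm
        got = sum(mapping.scores.values())
        assert got == pytest.approx(best_score, abs=1e-12)
        assert [mapping.assignment[i] for i in range(5)] == \
               ["ABCDE"[best_perm[i]] for i in range(5)]

    def test_canonical_templates_are_valid_maps(self, montage64):
        tpl = canonical_templates(montage64)
        assert tpl.K == 7
        np.testing.assert_allclose(tpl.maps.mean(axis=1), 0, atol=1e-12)
        np.testing.assert_allclose(np.linalg.norm(tpl.maps, axis=1), 1, atol=1e-12)


class TestOutlierTrimming:
    def _table(self, values, cls="A"):
        rows = [dict(subject=f"s{i}", cohort="x", visit=1, age_months=4.0,
                     sex=0, retained_segments=20, **{"class": cls},
                     feature="duration", value=v)
                for i, v in enumerate(values)]
        return FeatureTable(pd.DataFrame(rows))

    def test_constant_group_removes_nothing(self):
        table = self._table([5.0] * 10)
        trimmed, report = trim_feature_outliers(table)
        assert len(trimmed) == 10
        assert report["n_removed"].sum() == 0

    def test_single_gross_outlier_removed(self):
        rng = np.random.default_rng(11)
        values = rng.standard_normal(100).tolist() + [10.0]
        table = self._table(values)
        trimmed, report = trim_feature_outliers(table, z=3)
        assert len(trimmed) == 100
        assert 10.0 not in trimmed.df["value"].values
        assert report["n_removed"].sum() == 1

    def test_small_group_skipped_with_warning(self, caplog):
        import logging
        table = self._table([1.0, 100.0])
        with caplog.at_level(logging.WARNING, logger="mstates"):
            trimmed, report = trim_feature_outliers(table)
        assert len(trimmed) == 2
        assert "skipped" in caplog.text

    def test_default_z_is_three(self):
        import inspect
        assert inspect.signature(trim_feature_outliers).parameters["z"].default == 3.0
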