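"""V tuning, stable-set extraction and K selection."""

import numpy as np
import pytest

from ckm import (
    KmOptions,
    SimSpec,
    elbow_refine,
    generate,
    run_model_selection,
    select_k,
    select_v_for_k,
    stable_set,
    standardize,
)
import ckm.model_selection as ms


@pytest.fixture(scope="module")
def small12():
    """J=12 clustered data where full-grid search is the oracle for zoom-in."""
    ds = generate(SimSpec(K=3, n_per_cluster=15, n_signal=7, V=5,
                          delta_mu=1.5, seed=88))
    return ds, standardize(ds.x_raw)


class TestSelectV:
    def test_zoom_equals_full_grid(self, small12):
        _, X = small12
        v_full, s_full, _ = select_v_for_k(X, 3, strategy="full", B=5,
                                           opts=KmOptions(seed=4), seed=4)
        v_zoom, s_zoom, _ = select_v_for_k(X, 3, strategy="zoom", B=5,
                                           opts=KmOptions(seed=4), seed=4)
        assert v_zoom == v_full
        np.testing.assert_array_equal(s_zoom, s_full)

    def test_zoom_finds_argmax_of_unimodal_stub(self, monkeypatch, rng):
        X = standardize(rng.normal(size=(20, 60)))
        peak = 37

        def fake_gap(dm, K, v, B=20, opts=None, seed=None, refit=True):
            from ckm.gap_statistic import CandidateGap
            g = -abs(v - peak) / 10.0
            return CandidateGap(v, g, 0.0, g, np.zeros(B), 1.0,
                                np.arange(v, dm.n_vars), None, None)

        monkeypatch.setattr(ms, "gap_for_candidate", fake_gap)
        v, _, _ = select_v_for_k(X, 3, strategy="zoom", seed=0)
        assert v == peak

    def test_full_forbidden_for_large_j(self, rng):
        X = standardize(rng.normal(size=(20, 120)))
        with pytest.raises(ValueError, match="prohibitive"):
            select_v_for_k(X, 2, strategy="full")

    def test_recovers_true_v_on_easy_data(self, easy_data):
        ds, X = easy_data
        v, s, _ = select_v_for_k(X, 3, strategy="zoom", B=20,
                                 opts=KmOptions(seed=6), seed=6)
        assert v == 50
        np.testing.assert_array_equal(s, ds.true_signal)


class TestElbowRefine:
    def test_kinked_curve_finds_kink(self, rng):
        X = standardize(rng.normal(size=(20, 60)))
        curve = lambda v: (50 - v) * 2.0 if v <= 50 else (50 - v) * 10.0
        assert elbow_refine(X, 3, v_hat=47, between_fn=curve) == 50

    def test_linear_curve_warns_and_keeps_v(self, rng):
        X = standardize(rng.normal(size=(20, 60)))
        with pytest.warns(RuntimeWarning, match="linear"):
            assert elbow_refine(X, 3, v_hat=47, between_fn=lambda v: -2.0 * v) == 47

    def test_flat_curve_warns_and_keeps_v(self, rng):
        X = standardize(rng.normal(size=(20, 60)))
        with pytest.warns(RuntimeWarning, match="flat"):
            assert elbow_refine(X, 3, v_hat=30, between_fn=lambda v: 1.0) == 30


class TestStableSet:
    def test_intersection(self):
        per_k = {2: (1, np.array([1, 2, 3]), None), 3: (1, np.array([2, 3, 4]), None)}
        np.testing.assert_array_equal(stable_set(per_k), [2, 3])

    def test_identical_sets(self):
        per_k = {2: (0, np.array([0, 5]), None), 3: (0, np.array([0, 5]), None)}
        np.testing.assert_array_equal(stable_set(per_k), [0, 5])

    def test_empty_intersection_raises(self):
        per_k = {2: (0, np.array([1]), None), 3: (0, np.array([2]), None)}
        with pytest.raises(ValueError, match="K_max"):
            stable_set(per_k)


class TestSelectK:
    def test_gap_criteria_on_stub(self, monkeypatch, rng):
        X = standardize(rng.normal(size=(30, 6)))
        stub = {2: 1.0, 3: 3.0, 4: 2.0, 5: 4.0}

        monkeypatch.setattr(ms, "_gap_over_k",
                            lambda Xs, ks, fits, B, opts, seed: stub)
        k_global, _ = select_k(X, [0, 1, 2], [2, 3, 4, 5], criterion="globalGap")
        k_first, _ = select_k(X, [0, 1, 2], [2, 3, 4, 5], criterion="firstGap")
        assert k_global == 5
        assert k_first == 3

    def test_single_candidate_trivial(self, rng):
        X = standardize(rng.normal(size=(30, 6)))
        k, _ = select_k(X, [0, 1], [4], criterion="globalGap")
        assert k == 4

    @pytest.mark.parametrize("criterion", ["globalGap", "firstGap", "KL"])
    def test_well_separated_three_clusters(self, criterion):
        ds = generate(SimSpec(K=3, n_per_cluster=20, n_signal=20, V=5,
                              delta_mu=2.0, seed=13))
        X = standardize(ds.x_raw)
        k, values = select_k(X, ds.true_signal, range(2, 7), criterion=criterion,
                             B=10, opts=KmOptions(seed=1), seed=1)
        assert k == 3
        assert set(values) == set(range(2, 7))

    def test_dindex_returns_valid_k(self):
        # second-difference criteria are conservative on evenly spaced mean
        # ladders (merging adjacent clusters is cheap); only sanity-check it
        ds = generate(SimSpec(K=3, n_per_cluster=20, n_signal=20, V=5,
                              delta_mu=2.0, seed=13))
        X = standardize(ds.x_raw)
        k, values = select_k(X, ds.true_signal, range(2, 7), criterion="Dindex",
                             B=10, opts=KmOptions(seed=1), seed=1)
        assert k in range(2, 7)
        assert np.isfinite([values[i] for i in range(2, 7)]).all()


class TestRunModelSelection:
    def test_easy_regime_end_to_end(self):
        ds = generate(SimSpec(K=3, n_per_cluster=50, n_signal=50, V=50,
                              delta_mu=1.0, seed=303))
        X = standardize(ds.x_raw)
        res = run_model_selection(X, K_max=5, seed=7, opts=KmOptions(seed=7))
        assert res.K_opt == 3
        # tuned V sits within a whisker of the truth: the Gap curve is flat to
        # within Monte-Carlo noise when a single noise column is kept
        assert abs(res.V_opt - 50) <= 2
        assert np.isin(ds.true_signal, res.s_opt).all()
        # set containment: the stable set is inside every per-K signaling set
        for _, s_k, _ in res.per_k.values():
            assert np.isin(res.stable, s_k).all()

    def test_kmax2_trivial(self, small12):
        _, X = small12
        res = run_model_selection(X, K_max=2, seed=3, opts=KmOptions(seed=3), B=5)
        assert res.K_opt == 2
        np.testing.assert_array_equal(res.stable, res.per_k[2][1])
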