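"""ReliefF screening, stratified bootstrap and the 0.632+ AUC estimator."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from rtlipred.containers import feature_name, format_params
from rtlipred.select import (
    Bootstrap632Ranker,
    ReliefFSelector,
    auc_0632plus,
    bootstrap_resample,
    relief_weights,
    screen_candidates,
    select_top_per_paramset,
)
from oracles import brute_relieff


def _texture_name(i, params_tag, seq="T2w"):
    return feature_name(seq, "mtl", "glcm", f"f{i}", params_tag)


def _random_table(rng, n=20, paramsets=4, per_set=5):
    cols, data = [], []
    for p in range(paramsets):
        tag = format_params(1.0, float(p + 1), "uniform", 8)
        for i in range(per_set):
            cols.append(_texture_name(i, tag))
    X = pd.DataFrame(rng.normal(size=(n, len(cols))), columns=cols)
    y = np.array([0, 1] * (n // 2))
    return X, y


class TestRelief:
    def test_matches_bruteforce_oracle(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(20, 8))
        y = np.array([0, 1] * 10)
        X[:, 3] = y  # label-identical feature
        w = relief_weights(X, y, n_neighbors=5)
        w_oracle = brute_relieff(X, y, k=5)
        np.testing.assert_allclose(w, w_oracle, rtol=1e-10, atol=1e-12)
        assert np.argmax(w) == 3

    def test_constant_feature_zero_weight(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(12, 4))
        X[:, 2] = 5.0
        w = relief_weights(X, np.array([0, 1] * 6), n_neighbors=3)
        assert w[2] == 0.0

    def test_duplicated_column_equal_weight(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(14, 5))
        X[:, 4] = X[:, 0]
        w = relief_weights(X, np.array([0, 1] * 7), n_neighbors=3)
        assert w[0] == pytest.approx(w[4], rel=1e-12)

    def test_small_class_reduces_k_with_warning(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(7, 3))
        y = np.array([0, 0, 0, 0, 0, 1, 1])
        with pytest.warns(UserWarning, match="neighbours"):
            relief_weights(X, y, n_neighbors=10)

    def test_needs_two_per_class(self):
        with pytest.raises(ValueError, match="per class"):
            relief_weights(np.zeros((3, 2)), np.array([0, 0, 1]), n_neighbors=1)


class TestTopPerParamset:
    def test_counts(self):
        rng = np.random.default_rng(4)
        X, y = _random_table(rng, paramsets=6)
        w = relief_weights(X, y, n_neighbors=3)
        sel = select_top_per_paramset(w, n_per_set=2)
        assert len(sel) == 12
        tags = {c.split("|")[-1] for c in sel}
        assert len(tags) == 6

    def test_single_paramset_gives_two(self):
        rng = np.random.default_rng(5)
        X, y = _random_table(rng, paramsets=1)
        w = relief_weights(X, y, n_neighbors=3)
        assert len(select_top_per_paramset(w)) == 2

    def test_planted_best_always_kept(self):
        rng = np.random.default_rng(6)
        X, y = _random_table(rng, paramsets=3)
        planted = X.columns[0]
        X[planted] = y.astype(float)
        sel = ReliefFSelector(n_neighbors=5).fit(X, y).selected_
        assert planted in sel

    def test_nontexture_not_candidates_but_rejoin_ranking(self):
        rng = np.random.default_rng(7)
        X, y = _random_table(rng, paramsets=2)
        X[feature_name("T2w", "mtl", "nontexture", "volume", "-")] = rng.normal(size=len(X))
        w = relief_weights(X, y, n_neighbors=3)
        sel = select_top_per_paramset(w)
        assert all("nontexture" not in c for c in sel)
        cands = screen_candidates(X, sel)
        assert any("nontexture" in c for c in cands)

    def test_too_few_finite_features_error(self):
        w = pd.Series({_texture_name(0, "R1_S1_uniform_Ng8"): 0.1})
        with pytest.raises(ValueError, match="finite-weight"):
            select_top_per_paramset(w, n_per_set=2)


class TestBootstrapResample:
    def test_oob_fraction_matches_binomial_expectation(self):
        """Mean out-of-bag fraction matches sum_c n_c (1-1/n_c)^{n_c} / n,
        the per-class binomial expectation (~ e^-1 ~ 0.368 as classes grow)."""
        subjects = [f"s{i}" for i in range(50)]
        labels = np.array([1] * 40 + [0] * 10)
        splits = bootstrap_resample(subjects, labels, B=1000, seed=0)
        frac = np.mean([len(s.out_of_bag) / 50 for s in splits])
        expected = (40 * (1 - 1 / 40) ** 40 + 10 * (1 - 1 / 10) ** 10) / 50
        assert abs(frac - expected) < 0.02
        assert abs(expected - np.exp(-1)) < 0.02  # close to the asymptotic 0.368

    def test_stratified_in_bag(self):
        labels = np.array([1] * 12 + [0] * 4)
        splits = bootstrap_resample(np.arange(16), labels, B=50, seed=1)
        for s in splits:
            assert labels[s.in_bag].sum() == 12
            assert len(s.in_bag) == 16
            assert set(np.unique(labels[s.out_of_bag])) == {0, 1}
            assert len(np.intersect1d(s.in_bag, s.out_of_bag)) == 0

    def test_deterministic(self):
        labels = np.array([1] * 8 + [0] * 4)
        a = bootstrap_resample(np.arange(12), labels, B=20, seed=9)
        b = bootstrap_resample(np.arange(12), labels, B=20, seed=9)
        for x, y in zip(a, b):
            np.testing.assert_array_equal(x.in_bag, y.in_bag)


class TestAuc0632Plus:
    def test_no_overfit_identity(self):
        r = auc_0632plus(0.8, [0.8, 0.8, 0.8])
        assert r.auc_0632plus == pytest.approx(0.8, abs=1e-12)
        assert np.all(r.overfit_rate == 0) and np.all(r.weight == pytest.approx(0.632))

    def test_clamp_case(self):
        r = auc_0632plus(0.9, [0.4])
        assert r.auc_prime[0] == 0.5
        assert r.overfit_rate[0] == 1.0
        assert r.weight[0] == pytest.approx(1.0)
        assert r.auc_0632plus == pytest.approx(0.5, abs=1e-12)

    def test_mixed_case_hand_value(self):
        r = auc_0632plus(0.9, [0.7])
        assert r.overfit_rate[0] == pytest.approx(0.5)
        assert r.weight[0] == pytest.approx(0.632 / (1 - 0.368 * 0.5))
        assert r.auc_0632plus == pytest.approx(0.7450980392156862, abs=1e-12)

    def test_apparent_below_half_guard(self):
        r = auc_0632plus(0.45, [0.6, 0.4])
        assert list(r.overfit_rate) == [0.0, 1.0]

    @given(
        apparent=st.floats(0.5, 1.0),
        oob=st.lists(st.floats(0.0, 1.0), min_size=1, max_size=20),
    )
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_aggregate_bounds(self, apparent, oob):
        """R in [0,1], a in [0.632,1]; when apparent >= every AUC', the
        aggregate lies between mean(AUC') and apparent."""
        r = auc_0632plus(apparent, oob)
        assert np.all((0 <= r.overfit_rate) & (r.overfit_rate <= 1))
        assert np.all((0.632 - 1e-12 <= r.weight) & (r.weight <= 1 + 1e-12))
        if apparent >= r.auc_prime.max():
            assert r.auc_prime.mean() - 1e-9 <= r.auc_0632plus <= apparent + 1e-9


class TestRanker:
    def _table(self, rng, n_subj=30, p=10):
        subj = [f"s{i:02d}" for i in range(n_subj)]
        idx = pd.MultiIndex.from_tuples([(s, 1) for s in subj], names=["subject_id", "time_index"])
        cols = [_texture_name(i, format_params(1.0, 1.0, "uniform", 8)) for i in range(p)]
        X = pd.DataFrame(rng.normal(size=(n_subj, p)), index=idx, columns=cols)
        y = np.array([1] * (2 * n_subj // 3) + [0] * (n_subj - 2 * n_subj // 3))
        return X, y

    def test_label_identical_feature_ranks_first(self):
        rng = np.random.default_rng(0)
        X, y = self._table(rng)
        X[X.columns[4]] = y.astype(float)
        ranker = Bootstrap632Ranker(B=50, top_n=3, random_state=0).fit(X, y)
        assert ranker.ranking_[0] == X.columns[4]
        assert ranker.scores_[X.columns[4]] == pytest.approx(1.0)

    def test_noise_features_score_near_half(self):
        """Null simulation: pure-noise feature scores concentrate near 0.5.

        The orientation flip biases each null score up by ~E|AUC - 0.5|,
        which vanishes with cohort size, so the check uses 200 subjects."""
        rng = np.random.default_rng(1)
        X, y = self._table(rng, n_subj=200, p=100)
        ranker = Bootstrap632Ranker(B=200, top_n=10, random_state=0).fit(X, y)
        assert abs(ranker.scores_.mean() - 0.5) < 0.05

    def test_deterministic_and_tie_break(self):
        rng = np.random.default_rng(2)
        X, y = self._table(rng)
        a = Bootstrap632Ranker(B=30, top_n=5, random_state=3).fit(X, y)
        b = Bootstrap632Ranker(B=30, top_n=5, random_state=3).fit(X, y)
        assert a.ranking_ == b.ranking_

    def test_monotone_in_effect_size(self):
        """Boosting a planted feature's effect never lowers its rank."""
        rng = np.random.default_rng(3)
        ranks = []
        for effect in (0.5, 1.5, 3.0):
            X, y = self._table(np.random.default_rng(3), n_subj=30, p=10)
            X[X.columns[0]] = y + rng.normal(0, 1.0 / effect, size=len(y))
            ranker = Bootstrap632Ranker(B=50, top_n=5, random_state=0).fit(X, y)
            ranks.append(ranker.ranking_.index(X.columns[0]))
        assert ranks[0] >= ranks[1] >= ranks[2]

    def test_rejects_nonfinite(self):
        rng = np.random.default_rng(4)
        X, y = self._table(rng)
        X.iloc[0, 0] = np.nan
        with pytest.raises(ValueError, match="non-finite"):
            Bootstrap632Ranker(B=10).fit(X, y)
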