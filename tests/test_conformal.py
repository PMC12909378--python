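"""Mondrian conformal classifier: p-values, sets, validity, efficiency."""

import numpy as np
import pytest
from sklearn.linear_model import LogisticRegression

from edscreen import conformal, synthdata
from edscreen.similarity import SimilarityMatrix


class FixedProbaModel:
    """Base-model stub returning a fixed P(active) per row (last feature)."""

    classes_ = np.array([0, 1])

    def get_params(self, deep=True):
        return {}

    def fit(self, X, y):
        return self

    def predict_proba(self, X):
        p1 = np.asarray(X)[:, -1]
        return np.column_stack([1 - p1, p1])


def model_with_scores(cal_active, cal_inactive):
    return conformal.ConformalModel(
        base_model=FixedProbaModel(),
        calibration_scores={
            1: np.sort(np.asarray(cal_active, dtype=float))[::-1],
            0: np.sort(np.asarray(cal_inactive, dtype=float))[::-1],
        },
        feature_ids=None,
        seed=0,
    )


class TestPValue:
    # with FixedProbaModel, alpha(active) = 1 - x[-1]
    def test_rank_arithmetic(self):
        m = model_with_scores([0.9, 0.7, 0.5, 0.3], [0.5])
        # alpha_x = 0.6 -> two calibration scores >= 0.6 -> (2+1)/5
        assert conformal.p_value(m, np.array([0.4]), 1) == pytest.approx(0.6)

    def test_smaller_than_all_gives_one(self):
        m = model_with_scores([0.9, 0.7, 0.5, 0.3], [0.5])
        assert conformal.p_value(m, np.array([0.99]), 1) == 1.0

    def test_larger_than_all_gives_floor(self):
        m = model_with_scores([0.9, 0.7, 0.5, 0.3], [0.5])
        assert conformal.p_value(m, np.array([0.0]), 1) == pytest.approx(1 / 5)

    def test_unknown_class_raises(self):
        m = model_with_scores([0.5], [0.5])
        with pytest.raises(ValueError):
            conformal.p_value(m, np.array([0.5]), 2)

    def test_non_increasing_in_alpha(self):
        m = model_with_scores([0.9, 0.6, 0.4, 0.2, 0.1], [0.5])
        xs = np.linspace(0, 1, 11)
        ps = [conformal.p_value(m, np.array([x]), 1) for x in xs]
        assert ps == sorted(ps)  # larger x[-1] -> smaller alpha -> larger p

    def test_vectorized_matches_scalar(self, rng):
        m = model_with_scores(rng.uniform(0, 1, 7), rng.uniform(0, 1, 9))
        X = rng.uniform(0, 1, (20, 3))
        batch = conformal.predict_p_values(m, X)
        for k, x in enumerate(X):
            assert batch[k, 1] == pytest.approx(conformal.p_value(m, x, 1))
            assert batch[k, 0] == pytest.approx(conformal.p_value(m, x, 0))


class TestPredictionSet:
    def test_single_label(self):
        s = conformal.PredictionSet(p_active=0.6, p_inactive=0.05)
        assert s.labels_at(0.20) == {"active"}

    def test_both_and_empty(self):
        s = conformal.PredictionSet(p_active=0.6, p_inactive=0.5)
        assert s.labels_at(0.2) == {"active", "inactive"}
        s2 = conformal.PredictionSet(p_active=0.1, p_inactive=0.1)
        assert s2.labels_at(0.2) == frozenset()

    def test_nested_in_epsilon(self, rng):
        for _ in range(20):
            s = conformal.PredictionSet(p_active=float(rng.random()),
                                        p_inactive=float(rng.random()))
            assert s.labels_at(0.3) <= s.labels_at(0.1)

    def test_bad_epsilon(self):
        s = conformal.PredictionSet(p_active=0.5, p_inactive=0.5)
        with pytest.raises(ValueError):
            s.labels_at(1.5)


class TestSimilarityFeatures:
    def _matrix(self, rng, n=5):
        v = rng.uniform(0, 1, (n, n))
        v = (v + v.T) / 2
        np.fill_diagonal(v, 1.0)
        return SimilarityMatrix([f"c{i}" for i in range(n)], v)

    def test_row_extraction(self, rng):
        m = self._matrix(rng)
        train = ["c1", "c3", "c4"]
        x = conformal.similarity_features("c0", m, train)
        assert x.shape == (3,)
        assert x == pytest.approx([m.loc("c0", t) for t in train])

    def test_self_similarity_component(self, rng):
        m = self._matrix(rng)
        x = conformal.similarity_features("c2", m, ["c0", "c2"])
        assert x[1] == 1.0

    def test_unresolvable_raises(self, rng):
        m = self._matrix(rng)
        with pytest.raises(KeyError):
            conformal.similarity_features("zz", m, ["c0"])
        with pytest.raises(KeyError):
            conformal.similarity_features("c0", m, ["zz"])


class TestFitICP:
    def _data(self, seed=0, n=100):
        X, y = synthdata.generate_exchangeable_features(n, seed=seed)
        return X, y

    def test_deterministic_under_seed(self):
        X, y = self._data()
        m1 = conformal.fit_icp(X, y, 0.2, seed=3)
        m2 = conformal.fit_icp(X, y, 0.2, seed=3)
        for c in (0, 1):
            np.testing.assert_array_equal(m1.calibration_scores[c],
                                          m2.calibration_scores[c])

    def test_calibration_size_stratified(self):
        X, y = self._data(n=100)
        m = conformal.fit_icp(X, y, 0.2, seed=0)
        n_cal = sum(len(m.calibration_scores[c]) for c in (0, 1))
        assert n_cal == 20
        # per class within +-1 of proportional
        for c in (0, 1):
            expect = 0.2 * (y == c).sum()
            assert abs(len(m.calibration_scores[c]) - expect) <= 1

    def test_scores_sorted_descending(self):
        X, y = self._data()
        m = conformal.fit_icp(X, y, 0.25, seed=1)
        for c in (0, 1):
            s = m.calibration_scores[c]
            assert (np.diff(s) <= 0).all()

    def test_separable_data_low_nonconformity(self):
        rng = np.random.default_rng(7)
        n = 200
        y = (rng.random(n) < 0.5).astype(int)
        X = y[:, None] + rng.normal(0, 0.05, (n, 3))  # cleanly separable
        m = conformal.fit_icp(X, y, 0.25, seed=0,
                              base_model=LogisticRegression())
        for c in (0, 1):
            assert m.calibration_scores[c].mean() < 0.5

    def test_single_class_raises(self):
        X = np.zeros((10, 2))
        with pytest.raises(ValueError):
            conformal.fit_icp(X, np.ones(10, dtype=int), 0.2, seed=0)

    def test_save_load_round_trip(self, tmp_path):
        X, y = self._data()
        m = conformal.fit_icp(X, y, 0.2, seed=0,
                              base_model=LogisticRegression())
        p = tmp_path / "model.bin"
        m.save(p)
        back = conformal.ConformalModel.load(p)
        for c in (0, 1):
            np.testing.assert_array_equal(back.calibration_scores[c],
                                          m.calibration_scores[c])
        x = X[0]
        assert conformal.p_value(back, x, 1) == conformal.p_value(m, x, 1)


class TestValidityEfficiency:
    def test_trivial_both_label_sets(self):
        m = model_with_scores([1.0] * 10, [1.0] * 10)
        # every alpha_x <= 1 ties with all calibration scores -> p large
        X = np.random.default_rng(0).uniform(0.3, 0.7, (50, 2))
        rows = conformal.validity_efficiency(m, X, np.zeros(50, dtype=int),
                                             epsilons=[0.2])
        for r in rows:
            if r["class"] == 0:
                assert r["error_rate"] == 0.0
            assert r["efficiency"] == 0.0

    def test_empty_test_raises(self):
        m = model_with_scores([0.5], [0.5])
        with pytest.raises(ValueError):
            conformal.validity_efficiency(m, np.zeros((0, 2)), [])

    def test_uninformative_model_inefficient(self):
        # label-independent features: both p-values tend large, few
        # single-label sets at strict significance
        rng = np.random.default_rng(11)
        X = rng.uniform(0, 1, (400, 5))
        y = (rng.random(400) < 0.5).astype(int)
        m = conformal.fit_icp(X[:200], y[:200], 0.3, seed=0,
                              base_model=LogisticRegression())
        rows = conformal.validity_efficiency(m, X[200:], y[200:],
                                             epsilons=[0.15])
        assert rows[0]["efficiency"] < 0.5

    def test_marginal_validity_on_exchangeable_data(self):
        # 30 seeds of the exchangeable world; mean per-class error within
        # epsilon plus 3 binomial standard errors
        errs = {(c, e): [] for c in (0, 1) for e in (0.15, 0.30)}
        for seed in range(30):
            d = synthdata.preset("cp-validity", seed=seed)
            m = conformal.fit_icp(d["X_fit"][:400], d["y_fit"][:400],
                                  0.25, seed=seed,
                                  base_model=LogisticRegression())
            rows = conformal.validity_efficiency(
                m, d["X_test"][:500], d["y_test"][:500], epsilons=[0.15, 0.30])
            for r in rows:
                errs[(r["class"], r["epsilon"])].append(r["error_rate"])
        for (c, e), vals in errs.items():
            n_eff = 30 * 250  # ~ per-class test examples across seeds
            se = np.sqrt(e * (1 - e) / n_eff)
            assert np.mean(vals) <= e + 3 * se
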