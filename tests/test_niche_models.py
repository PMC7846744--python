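"""Learners, rank-based AUC, confusion metrics and the TSS exclusion rule."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from amocrange import (
    confusion_metrics,
    exclude_poor_models,
    fit_suitability,
    roc_auc,
    screen_algorithms,
)
from amocrange.errors import FitError, MetricError, ParameterError
from amocrange.niche_models import DEFAULT_ALGORITHMS


def brute_force_auc(sp, sb):
    """Exhaustive pair-count oracle: wins + half-ties over all pairs."""
    wins = sum((p > b) + 0.5 * (p == b) for p in sp for b in sb)
    return wins / (len(sp) * len(sb))


class TestRocAuc:
    def test_perfect_separation(self):
        assert roc_auc([0.9, 0.8], [0.1, 0.2]) == 1.0

    def test_all_ties_give_half(self):
        assert roc_auc([0.5, 0.5], [0.5, 0.5, 0.5]) == 0.5

    def test_three_of_four_pairs(self):
        assert roc_auc([0.8, 0.4], [0.6, 0.2]) == 0.75

    def test_empty_side_raises(self):
        with pytest.raises(MetricError):
            roc_auc([], [0.5])

    @settings(max_examples=200, deadline=None)
    @given(
        st.lists(st.integers(0, 20), min_size=1, max_size=50),
        st.lists(st.integers(0, 20), min_size=1, max_size=50),
    )
    def test_matches_pair_count_oracle(self, sp, sb):
        # integer scores force plenty of ties
        sp = np.asarray(sp) / 20
        sb = np.asarray(sb) / 20
        assert roc_auc(sp, sb) == pytest.approx(brute_force_auc(sp, sb))

    @settings(max_examples=50, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_invariant_under_monotone_transform(self, seed):
        rng = np.random.default_rng(seed)
        sp, sb = rng.normal(1, 1, 15), rng.normal(0, 1, 25)
        base = roc_auc(sp, sb)
        for f in (np.exp, np.tanh, lambda x: 3 * x - 7):
            assert roc_auc(f(sp), f(sb)) == pytest.approx(base)

    def test_agrees_with_sklearn(self, rng):
        from sklearn.metrics import roc_auc_score

        sp, sb = rng.normal(1, 1, 40), rng.normal(0, 1, 60)
        y = np.r_[np.ones(40), np.zeros(60)]
        assert roc_auc(sp, sb) == pytest.approx(roc_auc_score(y, np.r_[sp, sb]))


class TestConfusionMetrics:
    def test_direct_ratios(self):
        m = confusion_metrics(40, 10, 70, 30)
        assert m.sensitivity == pytest.approx(0.8)
        assert m.specificity == pytest.approx(0.7)
        assert m.tss == pytest.approx(0.5)
        assert m.omission == pytest.approx(0.2)

    def test_kappa_hand_computed(self):
        # po = 110/150; pe = (50*70 + 100*80)/150^2; kappa = (po-pe)/(1-pe)
        po = 110 / 150
        pe = (50 * 70 + 100 * 80) / 150**2
        m = confusion_metrics(40, 10, 70, 30)
        assert m.kappa == pytest.approx((po - pe) / (1 - pe))

    def test_kappa_agrees_with_sklearn(self):
        from sklearn.metrics import cohen_kappa_score

        tp, fn, tn, fp = 33, 17, 51, 24
        y_true = [1] * (tp + fn) + [0] * (tn + fp)
        y_pred = [1] * tp + [0] * fn + [0] * tn + [1] * fp
        m = confusion_metrics(tp, fn, tn, fp)
        assert m.kappa == pytest.approx(cohen_kappa_score(y_true, y_pred))

    def test_perfect_classifier(self):
        m = confusion_metrics(25, 0, 75, 0)
        assert (m.tss, m.kappa, m.omission) == (1.0, 1.0, 0.0)

    def test_zero_marginal_raises(self):
        with pytest.raises(MetricError):
            confusion_metrics(0, 0, 50, 50)


@pytest.fixture(scope="module")
def separable_data():
    rng = np.random.default_rng(99)
    n = 150
    x_pos = rng.normal([12.0, 25.0, 2.0, 900.0, 40.0], [1.0, 1.0, 1.0, 60.0, 4.0], (n, 5))
    x_neg = rng.normal([20.0, 33.0, 9.0, 500.0, 70.0], [1.0, 1.0, 1.0, 60.0, 4.0], (n, 5))
    x = np.vstack([x_pos, x_neg])
    y = np.r_[np.ones(n, int), np.zeros(n, int)]
    train = np.r_[np.arange(100), np.arange(n, n + 100)]
    test = np.r_[np.arange(100, n), np.arange(n + 100, 2 * n)]
    return x, y, train, test


class TestFitSuitability:
    @pytest.mark.parametrize("algorithm", DEFAULT_ALGORITHMS)
    def test_separable_cloud_high_auc(self, separable_data, algorithm):
        x, y, train, test = separable_data
        model = fit_suitability(algorithm, x[train], y[train], seed=1)
        p = model.predict(x[test])
        assert np.all((p >= 0) & (p <= 1))
        assert roc_auc(p[y[test] == 1], p[y[test] == 0]) > 0.95

    @pytest.mark.parametrize("algorithm", DEFAULT_ALGORITHMS)
    def test_fit_and_predict_deterministic(self, separable_data, algorithm):
        x, y, train, _ = separable_data
        p1 = fit_suitability(algorithm, x[train], y[train], seed=5).predict(x[:20])
        p2 = fit_suitability(algorithm, x[train], y[train], seed=5).predict(x[:20])
        np.testing.assert_array_equal(p1, p2)

    def test_unknown_algorithm_rejected(self, separable_data):
        x, y, train, _ = separable_data
        with pytest.raises(ParameterError):
            fit_suitability("MARS", x[train], y[train])

    def test_single_class_rejected(self, separable_data):
        x, y, train, _ = separable_data
        with pytest.raises(FitError):
            fit_suitability("CART", x[:10], np.ones(10, int))


class TestScreening:
    def test_screening_sample_takes_up_to_15_per_realm(self):
        from types import SimpleNamespace

        from amocrange import sample_screening_species

        records = [SimpleNamespace(realm="A", species_id=f"a{i}") for i in range(40)]
        records += [SimpleNamespace(realm="B", species_id=f"b{i}") for i in range(8)]
        sample = sample_screening_species(records, seed=1)
        realms = [r.realm for r in sample]
        assert realms.count("A") == 15  # default sample size per realm
        assert realms.count("B") == 8  # capped at what the realm offers
        ids = [r.species_id for r in sample]
        assert len(set(ids)) == len(ids)

    def _rows(self):
        return [
            {"species_id": "s1", "algorithm": a, "run": r, "auc": auc, "tss": tss,
             "kappa": 0.5, "omission": 0.1}
            for a, auc, tss in (("CART", 0.8, 0.5), ("BRT", 0.9, 0.7))
            for r in range(2)
        ]

    def test_table_ordered_by_tss_descending(self):
        table = screen_algorithms(self._rows())
        assert list(table["algorithm"]) == ["BRT", "CART"]
        assert table["tss"].is_monotonic_decreasing

    def test_single_algorithm_single_row(self):
        rows = [r for r in self._rows() if r["algorithm"] == "CART"]
        table = screen_algorithms(rows)
        assert len(table) == 1
        assert table.loc[0, "n_fits"] == 2


class TestExclusion:
    def _frame(self, tss_by_species):
        rows = []
        for (sid, alg), values in tss_by_species.items():
            for run, tss in enumerate(values):
                rows.append({"species_id": sid, "algorithm": alg, "run": run, "tss": tss})
        return pd.DataFrame(rows)

    def test_boundary_is_inclusive(self):
        df = self._frame({("a", "CART"): [0.40, 0.40], ("b", "CART"): [0.41, 0.41]})
        retained, log = exclude_poor_models(df)
        assert set(retained["species_id"]) == {"b"}
        assert log.loc[0, "species_id"] == "a"

    def test_mean_across_runs_decides(self):
        # per-run dips below 0.4 are fine if the mean clears the bar
        df = self._frame({("a", "BRT"): [0.2, 0.7]})
        retained, log = exclude_poor_models(df)
        assert len(retained) == 2 and log.empty

    def test_empty_retained_set_allowed(self):
        df = self._frame({("a", "BRT"): [0.1, 0.2]})
        retained, log = exclude_poor_models(df)
        assert retained.empty
        assert len(log) == 1
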