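import numpy as np
import pandas as pd
import pytest

from cellpeer.dfs import (
    DFSThresholds,
    dynamic_select,
    fisher_scores,
    mahalanobis_criterion,
    max_posterior_criterion,
    stepwise_preselect,
)


def two_class_table(rng, n=200, informative_shift=3.0, n_noise=1):
    y = np.repeat(["a", "b"], n // 2)
    cols = {"class_label": y,
            "informative": np.where(y == "a", 0.0, informative_shift)
            + rng.normal(0, 1, n)}
    for i in range(n_noise):
        cols[f"noise{i}"] = rng.normal(0, 1, n)
    return pd.DataFrame(cols)


class TestStepwise:
    def test_informative_descriptor_found_reliably(self):
        """One informative + 10 noise descriptors: the informative one
        enters the pool in >= 95/100 replicates."""
        hits = 0
        for rep in range(100):
            rng = np.random.default_rng(rep)
            t = two_class_table(rng, n=200, n_noise=10)
            pool = stepwise_preselect(t, [c for c in t.columns if c != "class_label"],
                                      p_enter=0.05)
            hits += "informative" in pool
        assert hits >= 95

    def test_p_enter_one_admits_everything(self, rng):
        t = two_class_table(rng, n=60, n_noise=3)
        desc = [c for c in t.columns if c != "class_label"]
        assert set(stepwise_preselect(t, desc, p_enter=1.0)) == set(desc)

    def test_all_noise_triggers_fallback(self, rng):
        t = two_class_table(rng, n=100, informative_shift=0.0, n_noise=4)
        t = t.drop(columns=["informative"])
        desc = [c for c in t.columns if c != "class_label"]
        pool = stepwise_preselect(t, desc, p_enter=0.001)
        assert pool == desc  # full-set fallback


class TestFisher:
    def test_two_class_unit_ratio(self):
        # equal n, means 0 and 2, population variance 1 -> raw ratio 1.0
        rng = np.random.default_rng(0)
        a = rng.normal(size=5000)
        a = (a - a.mean()) / a.std()
        t = pd.DataFrame({"class_label": np.repeat(["a", "b"], 5000),
                          "d": np.concatenate([a, a + 2.0])})
        raw = fisher_scores(t, ["d"], normalize=False)
        assert raw["d"] == pytest.approx(1.0, abs=1e-12)

    def test_equal_means_scores_zero(self, rng):
        x = rng.normal(size=100)
        t = pd.DataFrame({"class_label": np.repeat(["a", "b"], 50),
                          "d": np.concatenate([x[:50], x[:50]]),
                          "e": np.concatenate([x[:50], x[:50] + 5])})
        s = fisher_scores(t, ["d", "e"])
        assert s["d"] == pytest.approx(0.0, abs=1e-12)

    def test_best_descriptor_normalized_to_one(self, rng):
        t = two_class_table(rng, n_noise=3)
        s = fisher_scores(t, [c for c in t.columns if c != "class_label"])
        assert s.max() == 1.0


class TestMahalanobis:
    def _train(self, rng):
        return pd.DataFrame({"class_label": np.repeat(["a", "b"], 50),
                             "d": rng.normal(0, 1, 100),
                             "e": rng.normal(0, 1, 100)})

    def test_value_at_mean_passes(self, rng):
        t = self._train(rng)
        row = pd.Series({"d": t["d"].mean(), "e": t["e"].mean() + 10 * t["e"].std()})
        dist = mahalanobis_criterion(t, row, ["d", "e"])
        assert dist["d"] == 0.0

    def test_normalized_ratio_arithmetic(self):
        t = pd.DataFrame({"class_label": ["a", "b"] * 50,
                          "d": np.tile([-1.0, 1.0], 50),
                          "e": np.tile([-1.0, 1.0], 50)})
        # sigma = 1 for both; test at mu+sigma and mu+10sigma
        row = pd.Series({"d": 1.0, "e": 10.0})
        dist = mahalanobis_criterion(t, row, ["d", "e"])
        assert dist["d"] == pytest.approx(0.1)
        assert dist["e"] == pytest.approx(1.0)

    def test_threshold_one_passes_all(self, rng):
        t = self._train(rng)
        row = pd.Series({"d": 5.0, "e": -3.0})
        dist = mahalanobis_criterion(t, row, ["d", "e"])
        assert (dist <= 1.0).all()

    def test_zero_std_excluded(self, rng, caplog):
        import logging

        t = self._train(rng)
        t["const"] = 1.0
        with caplog.at_level(logging.WARNING):
            dist = mahalanobis_criterion(t, pd.Series({"d": 0, "e": 0, "const": 1}),
                                         ["d", "e", "const"])
        assert np.isnan(dist["const"])


class TestMaxPosterior:
    def _train(self):
        rng = np.random.default_rng(2)
        return pd.DataFrame({"class_label": np.repeat(["a", "b"], 200),
                             "d": np.concatenate([rng.normal(0, 1, 200),
                                                  rng.normal(20, 1, 200)])})

    def test_deep_inside_one_class(self):
        t = self._train()
        p = max_posterior_criterion(t, pd.Series({"d": 0.0}), ["d"])
        assert p["d"] > 0.999

    def test_midpoint_of_equal_variance_classes(self):
        rng = np.random.default_rng(3)
        a = rng.normal(size=300)
        a = (a - a.mean()) / a.std()
        t = pd.DataFrame({"class_label": np.repeat(["a", "b"], 300),
                          "d": np.concatenate([a, a + 4.0])})
        p = max_posterior_criterion(t, pd.Series({"d": 2.0}), ["d"])
        assert p["d"] == pytest.approx(0.5, abs=1e-6)

    def test_three_identical_classes(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=100)
        t = pd.DataFrame({"class_label": np.repeat(["a", "b", "c"], 100),
                          "d": np.tile(x, 3)})
        p = max_posterior_criterion(t, pd.Series({"d": 0.3}), ["d"])
        assert p["d"] == pytest.approx(1 / 3, abs=1e-12)

    def test_extreme_outlier_resolves_to_limit(self):
        t = self._train()
        p = max_posterior_criterion(t, pd.Series({"d": 1e6}), ["d"])
        assert np.isfinite(p["d"]) and 0.0 < p["d"] <= 1.0


class TestDynamicSelect:
    def test_all_criteria_pass_returns_pool(self, rng):
        t = two_class_table(rng, n=100, n_noise=0)
        row = pd.Series({"informative": t["informative"].mean()})
        loose = DFSThresholds(0.0, 1.0, 0.0, 0.3)
        assert dynamic_select(t, row, ["informative"], loose) == ["informative"]

    def test_never_empty(self, rng):
        t = two_class_table(rng, n=100, n_noise=2)
        pool = ["informative", "noise0", "noise1"]
        strict = DFSThresholds(1.0, 0.0, 1.0, 0.3)
        row = pd.Series({c: 99.0 for c in pool})
        assert len(dynamic_select(t, row, pool, strict)) > 0

    def test_threshold_monotonicity(self, rng):
        """Loosening any single threshold never shrinks the per-criterion
        pass sets (checked on the raw criteria, before the fallback chain)."""
        t = two_class_table(rng, n=200, n_noise=3)
        pool = [c for c in t.columns if c != "class_label"]
        row = t.iloc[10].drop("class_label")
        fisher = fisher_scores(t, pool)
        maha = mahalanobis_criterion(t, row, pool)
        post = max_posterior_criterion(t, row, pool)
        for tight, loose in [(0.9, 0.5), (0.5, 0.1)]:
            assert {c for c in pool if fisher[c] >= tight} <= \
                   {c for c in pool if fisher[c] >= loose}
            assert {c for c in pool if maha[c] <= 1 - tight} <= \
                   {c for c in pool if maha[c] <= 1 - loose + 0.9}
            assert {c for c in pool if post[c] >= tight} <= \
                   {c for c in pool if post[c] >= loose}

    def test_noise_rejected_with_informative_present(self):
        """At the conventional motility thresholds (0.9 / 0.1 / 0.2), a
        pure-noise descriptor is excluded for >= 95% of test rows."""
        rng = np.random.default_rng(11)
        t = two_class_table(rng, n=400, n_noise=1)
        pool = ["informative", "noise0"]
        th = DFSThresholds(0.9, 0.1, 0.2, 0.3)
        test_rows = two_class_table(np.random.default_rng(99), n=100, n_noise=1)
        rejected = 0
        from cellpeer.dfs import fisher_scores as fs

        fisher = fs(t, pool)
        for _, row in test_rows.iterrows():
            sel = dynamic_select(t, row, pool, th, fisher=fisher)
            rejected += "noise0" not in sel
        assert rejected >= 95

    def test_invalid_thresholds(self):
        with pytest.raises(ValueError):
            DFSThresholds(1.5, 0.1, 0.2, 0.3)

    def test_family_defaults(self):
        assert DFSThresholds.for_family("shape") == DFSThresholds(1.0, 0.1, 1.0, 0.3)
        assert DFSThresholds.for_family("motility") == DFSThresholds(0.9, 0.1, 0.2, 0.3)
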