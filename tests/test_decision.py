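import numpy as np
import pandas as pd
import pytest

from cellpeer.decision import (
    ABSTAIN,
    ClassifierOutput,
    decide_clusters,
    majority_vote,
    max_trust,
    predict_tracks,
    train_classifier,
)


def separable_table(rng, n=60, n_classes=2):
    labels = np.repeat([f"c{i}" for i in range(n_classes)], n // n_classes)
    shift = np.array([10.0 * i for i in range(n_classes)])
    idx = np.repeat(np.arange(n_classes), n // n_classes)
    return pd.DataFrame({
        "video_id": "v0", "track_id": np.arange(n), "cluster_id": 1,
        "class_label": labels,
        "f1": shift[idx] + rng.normal(0, 0.5, n),
        "f2": -shift[idx] + rng.normal(0, 0.5, n),
    })


def out(label, scores, key=("v0", 0)):
    return ClassifierOutput(track_key=key, label=label, scores=scores)


class TestClassifiers:
    @pytest.mark.parametrize("kind", ["lda", "svm", "knn"])
    def test_separable_data_perfect_training_accuracy(self, rng, kind):
        t = separable_table(rng)
        model = train_classifier(t, ["f1", "f2"], kind)
        scores = model.predict_scores(t[["f1", "f2"]].to_numpy())
        pred = [model.classes[i] for i in scores.argmax(axis=1)]
        assert (np.array(pred) == t["class_label"].to_numpy()).all()

    @pytest.mark.parametrize("kind", ["lda", "svm", "knn"])
    def test_scores_normalized(self, rng, kind):
        t = separable_table(rng, n_classes=3)
        model = train_classifier(t, ["f1", "f2"], kind)
        grid = rng.normal(0, 10, size=(50, 2))
        s = model.predict_scores(grid)
        assert (s >= 0).all()
        np.testing.assert_allclose(s.sum(axis=1), 1.0, atol=1e-9)

    def test_knn_unanimous_neighborhood(self, rng):
        t = separable_table(rng)
        model = train_classifier(t, ["f1", "f2"], "knn")
        s = model.predict_scores(np.array([[0.0, 0.0]]))[0]
        assert s[model.classes.index("c0")] == 1.0

    def test_single_class_raises(self, rng):
        t = separable_table(rng)
        with pytest.raises(ValueError):
            train_classifier(t[t.class_label == "c0"], ["f1"], "lda")

    def test_lda_singular_covariance_shrinks(self, rng, caplog):
        import logging

        t = separable_table(rng, n=40)
        t["f2"] = t["f1"]  # perfectly collinear -> singular pooled covariance
        with caplog.at_level(logging.INFO):
            model = train_classifier(t, ["f1", "f2"], "lda")
        s = model.predict_scores(t[["f1", "f2"]].to_numpy())
        np.testing.assert_allclose(s.sum(axis=1), 1.0, atol=1e-9)


class TestPredictTracks:
    def test_training_duplicate_gets_training_label(self, rng):
        train = separable_table(rng)
        test = train.iloc[[0, 35]].copy()
        subsets = {(r["video_id"], int(r["track_id"])): ["f1", "f2"]
                   for _, r in test.iterrows()}
        outs = predict_tracks(train, test, subsets, "lda")
        assert [o.label for o in outs] == list(test["class_label"])

    def test_rows_without_subset_are_skipped(self, rng):
        train = separable_table(rng)
        test = train.iloc[:4].copy()
        subsets = {("v0", 0): ["f1"], ("v0", 2): ["f1"]}
        outs = predict_tracks(train, test, subsets)
        assert {o.track_key for o in outs} == {("v0", 0), ("v0", 2)}

    def test_model_cache_reused(self, rng, monkeypatch):
        import cellpeer.decision as dec

        calls = []
        original = dec.train_classifier

        def counting(*args, **kw):
            calls.append(1)
            return original(*args, **kw)

        monkeypatch.setattr(dec, "train_classifier", counting)
        train = separable_table(rng)
        test = train.iloc[:6].copy()
        subsets = {("v0", i): ["f1", "f2"] for i in range(6)}
        dec.predict_tracks(train, test, subsets, "lda")
        assert len(calls) == 1  # six rows, one fitted model

    def test_empty_test_warns(self, rng, caplog):
        import logging

        with caplog.at_level(logging.WARNING):
            assert predict_tracks(separable_table(rng), pd.DataFrame(), {}) == []


class TestClusterDecisions:
    def test_majority_simple(self):
        outs = [out("A", {"A": 0.9, "B": 0.1}), out("A", {"A": 0.8, "B": 0.2}),
                out("B", {"A": 0.2, "B": 0.8})]
        assert majority_vote(outs) == "A"

    def test_majority_tie_resolved_by_scores(self):
        outs = [out("A", {"A": 0.9, "B": 0.1}), out("B", {"A": 0.0, "B": 1.1})]
        # vote tie 1-1; score sums A=0.9, B=1.2 -> B
        assert majority_vote(outs) == "B"

    def test_empty_cluster_abstains(self):
        assert majority_vote([]) == ABSTAIN
        assert max_trust([]) == ABSTAIN

    def test_max_trust_sum(self):
        outs = [out("A", {"A": 0.9, "B": 0.1}), out("A", {"A": 0.8, "B": 0.2})]
        assert max_trust(outs) == "A"

    def test_criteria_may_disagree(self):
        # two weak A votes vs one strong B: majority says A, trust says B
        outs = [out("A", {"A": 0.51, "B": 0.49}), out("A", {"A": 0.51, "B": 0.49}),
                out("B", {"A": 0.02, "B": 0.98})]
        assert majority_vote(outs) == "A"
        assert max_trust(outs) == "B"

    def test_single_member(self):
        outs = [out("B", {"A": 0.3, "B": 0.7})]
        assert majority_vote(outs) == "B" and max_trust(outs) == "B"

    def test_unanimous_criteria_agree(self, rng):
        for _ in range(10):
            p = rng.uniform(0.5, 1.0, size=4)
            outs = [out("A", {"A": float(pi), "B": float(1 - pi)}) for pi in p]
            assert majority_vote(outs) == max_trust(outs) == "A"

    def test_member_order_invariance(self, rng):
        outs = [out("A", {"A": 0.6, "B": 0.4}), out("B", {"A": 0.1, "B": 0.9}),
                out("A", {"A": 0.7, "B": 0.3}), out("B", {"A": 0.45, "B": 0.55})]
        for _ in range(5):
            perm = [outs[i] for i in rng.permutation(4)]
            assert majority_vote(perm) == majority_vote(outs)
            assert max_trust(perm) == max_trust(outs)

    def test_decide_clusters_grouping_and_abstention(self):
        outs = [out("A", {"A": 1.0, "B": 0.0}, key=("v0", 0)),
                out("B", {"A": 0.0, "B": 1.0}, key=("v0", 1))]
        cluster_of = {("v0", 0): 1, ("v0", 1): 1, ("v0", 2): 2, ("v0", 3): 0}
        decisions = decide_clusters(outs, cluster_of)
        by_id = {d.cluster_id: d for d in decisions}
        assert set(by_id) == {1, 2}
        assert by_id[2].maj_vot == ABSTAIN  # no surviving member
        assert sum(by_id[1].vote_counts.values()) == 2
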