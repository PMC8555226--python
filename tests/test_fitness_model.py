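"""Naive Bayes fitness models: closed-form posteriors, selection, consensus."""

import numpy as np
import pandas as pd
import pytest

from targetfit import fitness_model as fm
from targetfit.centrality import compute_centrality_table
from targetfit.synthetic_data import SynthConfig, synth_study

FEATURES = [
    "degree",
    "neighborhood_connectivity",
    "clustering_coefficient",
    "topological_coefficient",
    "log_deg_topo",
    "average_shortest_path",
    "closeness",
    "radiality",
]


def study_features(cfg):
    g, ann = synth_study(cfg)
    table = compute_centrality_table(g)
    feats = table[FEATURES].fillna(-1.0)
    return feats, ann.reindex(feats.index)


class TestNaiveBayes:
    def test_gaussian_posterior_closed_form(self):
        """Two unit-variance Gaussians at 0 and 4, equal priors: the posterior
        at x=1 is a logistic of the log-likelihood ratio, e^4/(1+e^4)."""
        rng = np.random.default_rng(0)
        n = 20000
        x = np.r_[rng.normal(0, 1, n), rng.normal(4, 1, n)]
        X = pd.DataFrame({"f": x})
        y = np.r_[np.zeros(n, bool), np.ones(n, bool)]
        model = fm.NaiveBayes().fit(X, y)
        post = model.predict_proba(pd.DataFrame({"f": [1.0]}))[0, 0]
        assert post == pytest.approx(np.e**4 / (1 + np.e**4), abs=0.02)

    def test_perfectly_separating_binary_feature(self):
        X = pd.DataFrame({"flag": [1.0] * 20 + [0.0] * 80})
        y = np.array([True] * 20 + [False] * 80)
        spec = fm.ModelSpec(selection="fixed", seed=0)
        model, report = fm.train_nb(X, y, spec)
        assert report.phase4_recall == 1.0
        assert report.accuracy == 1.0

    def test_posteriors_sum_to_one(self):
        feats, ann = study_features(SynthConfig(n_nodes=400, seed=0))
        y = ann["target_status"] == "phase4"
        model = fm.NaiveBayes().fit(feats, y)
        post = model.predict_proba(feats)
        assert np.allclose(post.sum(axis=1), 1.0)

    def test_uninformative_features_give_majority_rate(self, rng):
        X = pd.DataFrame({"noise": rng.normal(size=300), "noise2": rng.normal(size=300)})
        y = np.zeros(300, bool)
        y[:30] = True
        accs = []
        for seed in range(10):
            spec = fm.ModelSpec(selection="fixed", seed=seed)
            _, rep = fm.train_nb(X, y, spec)
            accs.append(rep.accuracy)
        assert np.mean(accs) == pytest.approx(0.9, abs=0.06)

    def test_zero_variance_feature_floored_not_fatal(self):
        X = pd.DataFrame({"const": np.zeros(100) + 2.5, "ok": np.r_[np.zeros(50), np.ones(50)]})
        y = np.array([False] * 50 + [True] * 50)
        model = fm.NaiveBayes().fit(X, y)
        assert np.isfinite(model.predict_proba(X)).all()


class TestFeatureSelection:
    def test_informative_feature_selected_first(self, rng):
        picks = []
        for seed in range(10):
            local = np.random.default_rng(seed)
            y = np.zeros(400, bool)
            y[:80] = True
            X = pd.DataFrame(
                {
                    "noise": local.normal(size=400),
                    "signal": np.where(y, 2.0, 0.0) + local.normal(size=400),
                }
            )
            spec = fm.ModelSpec(selection="forward", seed=seed)
            cols = fm.select_features(X, y, spec)
            picks.append(cols[0])
        assert picks.count("signal") >= 8

    def test_duplicate_features_keep_one(self):
        y = np.array([True] * 30 + [False] * 70)
        base = np.where(y, 3.0, 0.0) + np.random.default_rng(1).normal(size=100)
        X = pd.DataFrame({"a": base, "b": base, "c": base})
        spec = fm.ModelSpec(selection="forward", seed=0)
        assert len(fm.select_features(X, y, spec)) == 1

    def test_backward_keeps_informative(self):
        rng = np.random.default_rng(3)
        y = np.zeros(300, bool)
        y[:60] = True
        X = pd.DataFrame(
            {"signal": np.where(y, 2.5, 0.0) + rng.normal(size=300),
             "noise": rng.normal(size=300)}
        )
        spec = fm.ModelSpec(selection="backward", seed=0)
        assert "signal" in fm.select_features(X, y, spec)


class TestPerClassSuite:
    def test_class_specific_signal_favors_per_class_models(self):
        """With class backgrounds at different hub scales, a single
        network-wide boundary underfits; class-wise training wins
        (majority of seeds on median recall)."""
        pc, nw = [], []
        for seed in range(4):
            feats, ann = study_features(SynthConfig(n_nodes=1500, seed=seed))
            spec = fm.ModelSpec(features=FEATURES, selection="fixed", seed=seed)
            suite = fm.per_class_suite(feats, ann, spec)
            pc.append(np.nanmean([r.phase4_recall for r in suite["per_class"].values()]))
            nw.append(suite["network_wide"].phase4_recall)
        assert np.median(pc) > np.median(nw)

    def test_small_class_skipped(self):
        feats, ann = study_features(
            SynthConfig(n_nodes=800, seed=1, phase4_per_class={"kinase": 7, "gpcr": 2})
        )
        spec = fm.ModelSpec(features=FEATURES, selection="fixed", seed=1)
        suite = fm.per_class_suite(feats, ann, spec)
        assert "gpcr" not in suite["per_class"]
        assert "kinase" in suite["per_class"]

    def test_rescue_threshold_above_one_rescues_nothing(self):
        feats, ann = study_features(SynthConfig(n_nodes=600, seed=2))
        spec = fm.ModelSpec(features=FEATURES, selection="fixed", seed=2)
        suite = fm.per_class_suite(feats, ann, spec, rescue_threshold=1.01)
        assert suite["rescued"] == []

    def test_label_permutation_control(self):
        """After shuffling labels the recall collapses toward chance."""
        feats, ann = study_features(SynthConfig(n_nodes=1000, seed=3))
        is_target = ann["target_status"].isin(["phase4", "all_target"])
        X = feats[is_target]
        y = (ann.loc[is_target, "target_status"] == "phase4").to_numpy()
        recalls_true, recalls_perm = [], []
        for seed in range(5):
            rng = np.random.default_rng(seed)
            spec = fm.ModelSpec(selection="fixed", seed=seed)
            _, rep = fm.train_nb(X, y, spec)
            recalls_true.append(rep.phase4_recall)
            _, rep_p = fm.train_nb(X, rng.permutation(y), spec)
            recalls_perm.append(rep_p.phase4_recall)
        assert np.mean(recalls_true) > np.mean(recalls_perm) + 0.2


class TestConsensus:
    def test_counts_and_reference_recall(self):
        preds = [{"a", "b"}, {"a", "c"}, {"a", "b"}, {"b"}]
        out = fm.consensus(preds, reference=["a", "b", "z"])
        assert out["counts"]["a"] == 3
        assert out["recall"] == pytest.approx(2 / 3)
        assert out["median_consensus"] == 3.0

    def test_full_recovery(self):
        preds = [{"a", "b"}, {"a", "b"}]
        out = fm.consensus(preds, reference=["a", "b"])
        assert out["recall"] == 1.0 and out["median_consensus"] == 2.0

    def test_confusion_identities(self):
        rep = fm.ModelReport(features=[], tp=8, fp=4, fn=2, tn=86)
        assert rep.phase4_recall == pytest.approx(0.8)
        assert rep.phase4_precision == pytest.approx(0.667, abs=1e-3)
        f1 = 2 * 0.8 * (8 / 12) / (0.8 + 8 / 12)
        assert f1 == pytest.approx(0.727, abs=1e-3)
        assert rep.accuracy == pytest.approx(0.94)

    def test_needs_two_models(self):
        with pytest.raises(ValueError):
            fm.consensus([{"a"}])
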