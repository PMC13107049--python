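"""Class-conditional mixture fitting, posteriors and metrics."""

import numpy as np
import pandas as pd
import pytest

from fpbarcode import classify, features, simulate, tags
from fpbarcode.classify import (
    ClassConditionalMixture,
    confusion_and_accuracy,
    fit_class_conditional,
    kmeans_classify,
    majority_vote_mapping,
    posterior_membership,
    sensitivity,
    stratified_split,
)


def labeled_frame(arrays: dict[str, np.ndarray]) -> pd.DataFrame:
    frames = []
    for lab, X in arrays.items():
        df = pd.DataFrame(np.atleast_2d(X), columns=["f1", "f2"][: np.atleast_2d(X).shape[1]])
        df["population"] = lab
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


def naive_posteriors(model: ClassConditionalMixture, X: np.ndarray) -> np.ndarray:
    """Independent oracle: direct density-ratio computation, no log tricks."""
    dens = np.empty((len(X), model.n_classes))
    d = X.shape[1]
    for k in range(model.n_classes):
        mu, cov, w = model.means[k], model.covariances[k], model.weights[k]
        diff = X - mu
        inv = np.linalg.inv(cov)
        quad = np.einsum("ni,ij,nj->n", diff, inv, diff)
        norm = 1.0 / np.sqrt((2 * np.pi) ** d * np.linalg.det(cov))
        dens[:, k] = w * norm * np.exp(-0.5 * quad)
    return dens / dens.sum(axis=1, keepdims=True)


class TestStratifiedSplit:
    def test_80_20_per_population(self):
        rng = np.random.default_rng(0)
        t = labeled_frame({lab: rng.normal(size=(100, 2)) for lab in "abc"})
        tr, te = stratified_split(t, 0.8, seed=1)
        assert tr.groupby("population").size().tolist() == [80, 80, 80]
        assert te.groupby("population").size().tolist() == [20, 20, 20]
        assert set(tr.index).isdisjoint(te.index)

    def test_two_cells_split_one_one(self):
        t = labeled_frame({"a": np.zeros((2, 2))})
        tr, te = stratified_split(t, 0.5, seed=0)
        assert len(tr) == 1 and len(te) == 1

    def test_rounds_toward_train(self):
        t = labeled_frame({"a": np.zeros((10, 2))})
        tr, te = stratified_split(t, 0.85, seed=0)
        assert len(tr) == 9

    def test_deterministic(self):
        rng = np.random.default_rng(3)
        t = labeled_frame({"a": rng.normal(size=(50, 2)), "b": rng.normal(size=(50, 2))})
        s1 = stratified_split(t, 0.8, seed=7)
        s2 = stratified_split(t, 0.8, seed=7)
        assert s1[0].index.tolist() == s2[0].index.tolist()

    def test_singleton_population_named_in_error(self):
        t = labeled_frame({"a": np.zeros((5, 2)), "lonely": np.zeros((1, 2))})
        with pytest.raises(ValueError, match="lonely"):
            stratified_split(t, 0.8, seed=0)


class TestFit:
    def test_degenerate_class_gets_regularized_identity(self):
        t = labeled_frame({"a": np.full((5, 2), 45.0)})
        m = fit_class_conditional(t, feature_names=("f1", "f2"),
                                  covariance_regularization=1e-6)
        assert np.allclose(m.means[0], [45.0, 45.0])
        assert np.allclose(m.covariances[0], 1e-6 * np.eye(2))

    def test_recovers_generator_parameters(self):
        rng = np.random.default_rng(4)
        mu_a, mu_b = np.array([10.0, 20.0]), np.array([60.0, 70.0])
        t = labeled_frame({
            "a": rng.normal(mu_a, 2.0, size=(10_000, 2)),
            "b": rng.normal(mu_b, 2.0, size=(10_000, 2)),
        })
        m = fit_class_conditional(t, feature_names=("f1", "f2"))
        se = 2.0 / np.sqrt(10_000)
        assert np.allclose(m.means[0], mu_a, atol=5 * se)
        assert np.allclose(m.means[1], mu_b, atol=5 * se)

    def test_uniform_weights(self):
        t = labeled_frame({lab: np.random.default_rng(5).normal(size=(8, 2)) for lab in "abcd"})
        m = fit_class_conditional(t, feature_names=("f1", "f2"))
        assert np.allclose(m.weights, 0.25)

    def test_json_round_trip(self, tmp_path):
        rng = np.random.default_rng(6)
        t = labeled_frame({"a": rng.normal(size=(30, 2)), "b": rng.normal(3, 1, size=(30, 2))})
        m = fit_class_conditional(t, feature_names=("f1", "f2"))
        p = tmp_path / "model.json"
        m.to_json(p)
        back = ClassConditionalMixture.from_json(p)
        assert back.labels == m.labels
        assert np.allclose(back.means, m.means)
        assert np.allclose(back.covariances, m.covariances)


class TestPosterior:
    def symmetric_model(self):
        return ClassConditionalMixture(
            labels=["lo", "hi"],
            means=np.array([[0.0], [10.0]]),
            covariances=np.array([[[1.0]], [[1.0]]]),
            weights=np.array([0.5, 0.5]),
            feature_names=["f1"],
        )

    def test_midpoint_is_half_half(self):
        res = posterior_membership(self.symmetric_model(), np.array([[5.0]]))
        assert np.allclose(res.posteriors[0], [0.5, 0.5])

    def test_at_isolated_mean_posterior_near_one(self):
        res = posterior_membership(self.symmetric_model(), np.array([[0.0]]))
        assert res.posteriors[0, 0] > 0.99
        assert res.predicted[0] == "lo"

    def test_matches_naive_oracle(self):
        rng = np.random.default_rng(8)
        t = labeled_frame({lab: rng.normal(i * 3, 1.0, size=(40, 2))
                           for i, lab in enumerate("abc")})
        m = fit_class_conditional(t, feature_names=("f1", "f2"))
        X = rng.normal(3, 3, size=(200, 2))
        res = posterior_membership(m, X)
        assert np.allclose(res.posteriors, naive_posteriors(m, X), atol=1e-9)

    def test_posteriors_sum_to_one_far_from_all_means(self):
        # contract: no overflow even 10^3 standard deviations out
        m = self.symmetric_model()
        X = np.array([[1000.0], [-1000.0], [5.0]])
        res = posterior_membership(m, X)
        assert np.allclose(res.posteriors.sum(axis=1), 1.0, atol=1e-9)

    def test_random_inputs_normalize(self):
        rng = np.random.default_rng(9)
        t = labeled_frame({lab: rng.normal(i, 1, size=(30, 2)) for i, lab in enumerate("abcde")})
        m = fit_class_conditional(t, feature_names=("f1", "f2"))
        X = rng.normal(0, 50, size=(10_000, 2))
        res = posterior_membership(m, X)
        assert np.allclose(res.posteriors.sum(axis=1), 1.0, atol=1e-9)
        # predicted label attains the max posterior
        idx = np.argmax(res.posteriors, axis=1)
        assert all(res.predicted[i] == m.labels[idx[i]] for i in range(0, 10_000, 997))

    def test_nonfinite_features_flagged_not_dropped(self):
        m = self.symmetric_model()
        X = np.array([[np.nan], [0.0]])
        res = posterior_membership(m, X)
        assert res.valid.tolist() == [False, True]
        assert len(res.predicted) == 2
        assert res.predicted[0] == ""

    def test_reliability_direction(self):
        # cells above 0.95 max posterior are more often correct than those below
        cfg = simulate.GeneratorConfig(n_cells_per_population=1500, seed=10,
                                       sigma_chan=0.22)
        panel4 = [tags.TagSpec(c, 0, 0) for c in (1, 2, 4, 8)]
        t = simulate.simulate_intensity_table(panel4, cfg)
        t = features.add_spherical_features(t)
        t["angle_ref_deg"] = features.to_polar_angle(t["ch_C"], t["ch_ref"])
        tr, te = stratified_split(t, 0.8, seed=1)
        m = fit_class_conditional(tr, feature_names=("angle_ref_deg",))
        res = posterior_membership(m, te)
        correct = te["population"].to_numpy() == res.predicted
        hi = res.max_posterior >= 0.95
        assert hi.any() and (~hi).any()
        assert correct[hi].mean() > correct[~hi].mean()


class TestMetrics:
    def test_perfect_predictions(self):
        cm, acc, per = confusion_and_accuracy(list("aabb"), list("aabb"))
        assert acc == 1.0
        assert np.allclose(cm.to_numpy(), np.eye(2))

    def test_single_error_row(self):
        true = ["A"] * 10 + ["B"] * 10
        pred = ["A"] * 9 + ["B"] * 11
        cm, acc, per = confusion_and_accuracy(true, pred)
        assert cm.loc["A"].tolist() == [0.9, 0.1]
        assert acc == pytest.approx(0.95)

    def test_hand_tallied_four_class(self):
        true = ["a", "a", "b", "b", "c", "c", "d", "d", "d"]
        pred = ["a", "b", "b", "b", "c", "d", "d", "d", "a"]
        cm, acc, per = confusion_and_accuracy(true, pred)
        assert acc == pytest.approx(6 / 9)
        assert cm.loc["a", "b"] == pytest.approx(0.5)
        assert cm.loc["d", "a"] == pytest.approx(1 / 3)
        assert per["b"] == pytest.approx(1.0)

    def test_unknown_label_rejected(self):
        with pytest.raises(ValueError):
            confusion_and_accuracy(["a"], ["zzz"], labels=["a", "b"])

    @pytest.mark.parametrize("tp, gt, expected", [(19, 20, 95.0), (20, 20, 100.0), (17, 19, 89.47)])
    def test_sensitivity(self, tp, gt, expected):
        assert sensitivity(tp, gt) == pytest.approx(expected, abs=0.005)

    def test_sensitivity_domain(self):
        with pytest.raises(ValueError):
            sensitivity(1, 0)
        with pytest.raises(ValueError):
            sensitivity(5, 4)

    def test_adjacent_level_error_structure(self):
        # with moderate noise on the 4-level single-channel panel, errors land
        # on neighboring copy numbers far more often than 2+ levels away
        cfg = simulate.GeneratorConfig(n_cells_per_population=3000, seed=12,
                                       sigma_chan=0.18)
        panel4 = [tags.TagSpec(c, 0, 0) for c in (1, 2, 4, 8)]
        t = simulate.simulate_intensity_table(panel4, cfg)
        t["angle_ref_deg"] = features.to_polar_angle(t["ch_C"], t["ch_ref"])
        tr, te = stratified_split(t, 0.8, seed=2)
        m = fit_class_conditional(tr, feature_names=("angle_ref_deg",))
        res = posterior_membership(m, te)
        level = {f"C{c}G0R0": i for i, c in enumerate((1, 2, 4, 8))}
        ti = np.array([level[x] for x in te["population"]])
        pi = np.array([level[x] for x in res.predicted])
        off = np.abs(ti - pi)
        assert (off == 1).mean() > (off > 1).mean()
        assert (off > 1).sum() < (off == 1).sum()


class TestKMeans:
    def test_two_separated_blobs(self):
        rng = np.random.default_rng(13)
        t = labeled_frame({"a": rng.normal(0, 0.5, size=(200, 2)),
                           "b": rng.normal(20, 0.5, size=(200, 2))})
        _, acc, _ = kmeans_classify(t, 2, t["population"], feature_names=("f1", "f2"), seed=0)
        assert acc == 1.0

    def test_bimodal_population_merged_from_two_clusters(self):
        rng = np.random.default_rng(14)
        bimodal = np.vstack([rng.normal(0, 0.3, size=(150, 2)),
                             rng.normal(8, 0.3, size=(150, 2))])
        t = labeled_frame({"uni": rng.normal(20, 0.3, size=(300, 2)), "bi": bimodal})
        pred, acc, mapping = kmeans_classify(t, 3, t["population"], feature_names=("f1", "f2"), seed=0)
        assert sum(1 for v in mapping.values() if v == "bi") == 2
        assert acc > 0.99

    def test_majority_vote_equals_exhaustive_mapping(self):
        # oracle: enumerate all cluster->label mappings, take the best accuracy
        rng = np.random.default_rng(15)
        clusters = rng.integers(0, 3, size=300)
        labels = np.array([["x", "y"][rng.random() < [0.2, 0.8, 0.5][c]] for c in clusters],
                          dtype=object)
        mapping = majority_vote_mapping(clusters, labels)
        voted_acc = np.mean([mapping[c] == l for c, l in zip(clusters, labels)])
        from itertools import product
        best = max(
            np.mean([m[c] == l for c, l in zip(clusters, labels)])
            for m in ({0: a, 1: b, 2: c} for a, b, c in product("xy", repeat=3))
        )
        assert voted_acc == pytest.approx(best)

    def test_fewer_clusters_than_populations_rejected(self):
        t = labeled_frame({lab: np.zeros((5, 2)) for lab in "abc"})
        with pytest.raises(ValueError):
            kmeans_classify(t, 2, t["population"], feature_names=("f1", "f2"))
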