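import numpy as np
import pytest

from xomivae.attribution import (AttributionResult, RankedGeneList,
                                 ReferenceSet, TargetSpec, aggregate_abs_mean,
                                 attribute, baseline_attribution,
                                 build_reference_set, deeplift_rescale,
                                 explain_class_by_genes,
                                 explain_class_by_latent,
                                 explain_latent_by_genes)
from xomivae.evalbench import overlap_count
from xomivae.nncore import FeedForward, Linear, random_feedforward
from xomivae.synthetic import saturated_relu_fixture


def _linear_net(w, b=0.0):
    W = np.asarray(w, dtype=float).reshape(-1, 1)
    return FeedForward([Linear.from_weights(W, np.array([b]))])


class TestRescaleRule:
    def test_single_linear_layer_closed_form(self, rng):
        """f(x) = w.x + b against one reference: scores_i = w_i (x_i - r_i)."""
        w = rng.normal(size=5)
        net = _linear_net(w, b=0.7)
        x = rng.random((3, 5))
        r = rng.random((1, 5))
        scores, delta = deeplift_rescale(net, x, r, 0)
        np.testing.assert_allclose(scores, w * (x - r), atol=1e-12)
        np.testing.assert_allclose(delta, (x - r) @ w, atol=1e-12)

    def test_reference_identity_null(self, rng):
        net = random_feedforward(rng, 6)
        x = rng.random((4, 6))
        scores, delta = deeplift_rescale(net, x, x[:1], 0)
        # sample 0 explained against itself: exact zeros
        np.testing.assert_allclose(scores[0], 0.0, atol=1e-12)
        assert delta[0] == pytest.approx(0.0, abs=1e-12)

    def test_summation_to_delta_random_networks(self):
        """Rescale-rule contributions sum to f(x) - f(r) per (sample,
        reference) pair on random ReLU/sigmoid nets."""
        rng = np.random.default_rng(123)
        for _ in range(20):
            n_in = int(rng.integers(3, 10))
            net = random_feedforward(rng, n_in)
            for _ in range(5):
                x = rng.normal(size=(1, n_in))
                r = rng.normal(size=(1, n_in))
                scores, delta = deeplift_rescale(net, x, r, 0)
                gap = abs(scores.sum() - delta[0]) / (abs(delta[0]) + 1e-6)
                assert gap < 1e-4

    def test_deep_linear_effective_weight(self, rng):
        """On purely linear stacks of any depth the attribution equals
        w_eff * (x - r) where w_eff is the product of the weight matrices."""
        for depth in (2, 4, 6):
            net = random_feedforward(rng, 7, n_hidden_layers=depth,
                                     linear_only=True)
            w_eff = np.eye(7)
            for lyr in net.layers:
                w_eff = w_eff @ lyr.W
            x, r = rng.normal(size=(2, 7)), rng.normal(size=(1, 7))
            scores, _ = deeplift_rescale(net, x, r, 0)
            np.testing.assert_allclose(scores, w_eff[:, 0] * (x - r), atol=1e-8)

    def test_multi_reference_average(self, rng):
        """Averaged scores sum to f(x) - mean_r f(r)."""
        net = random_feedforward(rng, 5)
        x = rng.normal(size=(3, 5))
        refs = rng.normal(size=(7, 5))
        scores, delta = deeplift_rescale(net, x, refs, 0)
        f = net.forward(x)[:, 0]
        fr = net.forward(refs)[:, 0].mean()
        np.testing.assert_allclose(scores.sum(axis=1), delta, atol=1e-8)
        np.testing.assert_allclose(delta, f - fr, atol=1e-10)

    def test_feature_mismatch_rejected(self, rng):
        net = random_feedforward(rng, 5)
        with pytest.raises(ValueError, match="mismatch"):
            deeplift_rescale(net, rng.random((2, 5)), rng.random((1, 4)), 0)

    def test_unsupported_layer_named(self):
        class Odd:
            has_params = False
        net = FeedForward([Linear.from_weights(np.ones((2, 1)))])
        net.layers.append(Odd())
        with pytest.raises(TypeError, match="Odd"):
            deeplift_rescale(net, np.ones((1, 2)), np.zeros((1, 2)), 0)


class TestAggregate:
    def _result(self, scores):
        scores = np.asarray(scores, dtype=float)
        return AttributionResult(scores, scores.sum(axis=1),
                                 [f"g{i+1}" for i in range(scores.shape[1])],
                                 TargetSpec("class_logit", 0), {})

    def test_absolute_value_single_sample(self):
        ranked = aggregate_abs_mean(self._result([[-3.0, 2.0]]))
        assert ranked.gene_ids == ["g1", "g2"]
        np.testing.assert_allclose(ranked.scores, [3.0, 2.0])

    def test_opposite_signs_do_not_cancel(self):
        ranked = aggregate_abs_mean(self._result([[1.0], [-1.0]]))
        assert ranked.scores[0] == 1.0

    def test_sample_permutation_invariance(self, rng):
        scores = rng.normal(size=(6, 4))
        r1 = aggregate_abs_mean(self._result(scores))
        r2 = aggregate_abs_mean(self._result(scores[::-1]))
        assert r1.gene_ids == r2.gene_ids
        np.testing.assert_allclose(r1.scores, r2.scores)

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            aggregate_abs_mean(self._result([[1.0]]),
                               np.zeros(1, dtype=bool))

    def test_tie_break_by_gene_id(self):
        ranked = aggregate_abs_mean(self._result([[2.0, -2.0, 2.0]]))
        assert ranked.gene_ids == ["g1", "g2", "g3"]


@pytest.fixture(scope="module")
def refs(tiny_matrix):
    return build_reference_set(tiny_matrix, "random_train", k_refs=20, seed=0)


class TestModelExplanations:
    def test_planted_genes_dominate_class_ranking(self, tiny_model,
                                                  tiny_matrix, tiny_truth,
                                                  refs):
        y = np.asarray(tiny_matrix.class_labels)
        hits = []
        for cls in tiny_model.classes:
            ranked = explain_class_by_genes(
                tiny_model, cls, tiny_matrix.values[y == cls][:25], refs)
            planted = set(tiny_truth.planted_gene_ids(tiny_matrix, cls))
            hits.append(len(set(ranked.top(10)) & planted))
        assert np.median(hits) >= 7

    def test_self_reference_gives_zero_scores(self, tiny_model, tiny_matrix):
        x = tiny_matrix.values[:1]
        res = attribute(tiny_model, x, ReferenceSet(x), TargetSpec("class_logit", 0))
        np.testing.assert_allclose(res.scores, 0.0, atol=1e-12)

    def test_latent_explanation_sums_to_logit_delta(self, tiny_model,
                                                    tiny_matrix, refs):
        mu, _ = tiny_model.encode(tiny_matrix.values[:6])
        mu_r, _ = tiny_model.encode(refs.profiles)
        res = attribute(tiny_model, mu,
                        ReferenceSet(mu_r, feature_space="latent_mu"),
                        TargetSpec("class_logit", 1, "latent_mu"))
        assert res.summation_gap().max() < 1e-5

    def test_dead_latent_path_scores_zero(self, tiny_model, tiny_matrix, refs):
        first = tiny_model.classifier.param_layers()[0]
        saved = first.W.copy()
        try:
            first.W[3, :] = 0.0
            ranked = explain_class_by_latent(tiny_model, tiny_model.classes[0],
                                             tiny_matrix.values[:10], refs)
            assert ranked.scores[ranked.gene_ids.index("dim3")] == 0.0
        finally:
            first.W = saved

    def test_gene_to_latent_sums_to_mu_delta(self, tiny_model, tiny_matrix,
                                             refs):
        res = attribute(tiny_model, tiny_matrix.values[:6], refs,
                        TargetSpec("latent_dim", 2))
        assert res.summation_gap().max() < 1e-5

    def test_different_dims_rank_differently(self, tiny_model, tiny_matrix,
                                             refs):
        r0 = explain_latent_by_genes(tiny_model, 0, tiny_matrix.values[:15], refs)
        r1 = explain_latent_by_genes(tiny_model, 1, tiny_matrix.values[:15], refs)
        assert r0.gene_ids != r1.gene_ids

    def test_out_of_range_targets(self, tiny_model, tiny_matrix, refs):
        with pytest.raises(IndexError):
            attribute(tiny_model, tiny_matrix.values[:2], refs,
                      TargetSpec("class_logit", 99))
        with pytest.raises(IndexError):
            attribute(tiny_model, tiny_matrix.values[:2], refs,
                      TargetSpec("latent_dim", 99))

    def test_feature_space_mismatch(self, tiny_model, tiny_matrix, refs):
        with pytest.raises(ValueError, match="latent_mu"):
            attribute(tiny_model, tiny_matrix.values[:2], refs,
                      TargetSpec("class_logit", 0, "latent_mu"))


class TestBaselines:
    def test_linear_saliency_is_weight_magnitude(self, rng):
        w = rng.normal(size=4)
        net = _linear_net(w)
        x = rng.random((3, 4))
        res = baseline_attribution("saliency", net, x,
                                   ReferenceSet(np.zeros((1, 4))),
                                   TargetSpec("class_logit", 0))
        np.testing.assert_allclose(res.scores, np.abs(w) * np.ones((3, 1)),
                                   atol=1e-12)

    def test_linear_gradient_shap_recovers_closed_form(self, rng):
        """For linear f, gradient-SHAP converges to w * (x - mean_r r)."""
        w = rng.normal(size=4)
        net = _linear_net(w)
        x = rng.random((2, 4))
        refs = ReferenceSet(rng.random((6, 4)))
        res = baseline_attribution("gradient_shap", net, x, refs,
                                   TargetSpec("class_logit", 0),
                                   n_draws=4000, seed=5)
        expected = w * (x - refs.profiles.mean(axis=0))
        np.testing.assert_allclose(res.scores, expected, atol=0.05)

    def test_input_x_gradient_linear(self, rng):
        w = rng.normal(size=3)
        net = _linear_net(w)
        x = rng.random((2, 3))
        res = baseline_attribution("input_x_gradient", net, x,
                                   ReferenceSet(np.zeros((1, 3))),
                                   TargetSpec("class_logit", 0))
        np.testing.assert_allclose(res.scores, x * w, atol=1e-12)

    def test_unknown_method(self, rng):
        with pytest.raises(ValueError, match="unknown"):
            baseline_attribution("lime", _linear_net([1.0]),
                                 np.ones((1, 1)), ReferenceSet(np.zeros((1, 1))),
                                 TargetSpec("class_logit", 0))

    def test_saturation_blinds_saliency_but_not_rescale(self):
        """A unit saturated for the sample but active for the reference:
        gradient saliency sees (almost) nothing, the rescale rule credits
        the full difference-from-reference."""
        fx = saturated_relu_fixture(seed=2)
        planted_idx = [fx.gene_ids.index(g) for g in sorted(fx.planted)]
        sal = baseline_attribution("saliency", fx.network, fx.samples[:5],
                                   ReferenceSet(fx.refs[:5]),
                                   TargetSpec("class_logit", 0))
        scores, _ = deeplift_rescale(fx.network, fx.samples[:5], fx.refs[:1], 0)
        assert np.abs(sal.scores[:, planted_idx]).max() < 0.01
        assert np.abs(scores[:, planted_idx]).min() > 0.3


class TestReferenceSets:
    def test_seed_determinism(self, tiny_matrix):
        r1 = build_reference_set(tiny_matrix, "random_train", 10, seed=3)
        r2 = build_reference_set(tiny_matrix, "random_train", 10, seed=3)
        np.testing.assert_array_equal(r1.profiles, r2.profiles)

    def test_phenotype_filter_contract(self, tiny_matrix):
        refs = build_reference_set(tiny_matrix, "phenotype_matched", 15,
                                   phenotype_filter="class==C0", seed=0)
        # every reference row must be a C0 sample
        y = np.asarray(tiny_matrix.class_labels)
        c0_rows = {tuple(row) for row in tiny_matrix.values[y == "C0"]}
        for row in refs.profiles:
            assert tuple(row) in c0_rows

    def test_empty_filter_is_error(self, tiny_matrix):
        with pytest.raises(ValueError, match="matches no sample"):
            build_reference_set(tiny_matrix, "phenotype_matched", 5,
                                phenotype_filter="class==NOPE")

    def test_reference_choice_changes_ranking_partially(self, tiny_model,
                                                        tiny_matrix):
        """Random-training vs phenotype-matched references give related but
        not identical top-gene lists (0 < Jaccard < 1)."""
        y = np.asarray(tiny_matrix.class_labels)
        x = tiny_matrix.values[y == "C0"][:25]
        jaccards = []
        for seed in range(5):
            rnd = build_reference_set(tiny_matrix, "random_train", 20, seed=seed)
            matched = build_reference_set(tiny_matrix, "phenotype_matched", 20,
                                          phenotype_filter="class==C1",
                                          seed=seed)
            a = explain_class_by_genes(tiny_model, "C0", x, rnd).top(30)
            b = explain_class_by_genes(tiny_model, "C0", x, matched).top(30)
            jaccards.append(overlap_count(a, b)[1])
        med = np.median(jaccards)
        assert 0.0 < med < 1.0


class TestRankedGeneList:
    def test_tsv_roundtrip(self, tmp_path):
        ranked = RankedGeneList.from_scores(["b", "a", "c"], [1.0, 3.0, 2.0])
        assert ranked.gene_ids == ["a", "c", "b"]
        ranked.write_tsv(tmp_path / "r.tsv")
        back = RankedGeneList.read_tsv(tmp_path / "r.tsv")
        assert back.gene_ids == ranked.gene_ids
        np.testing.assert_allclose(back.scores, ranked.scores)

    def test_rank_lookup(self):
        ranked = RankedGeneList.from_scores(["a", "b"], [1.0, 2.0])
        assert ranked.rank_of("b") == 1
        with pytest.raises(KeyError):
            ranked.rank_of("zzz")


class TestPropertyBased:
    """Hypothesis-driven invariants of the rescale rule and rankings."""

    from hypothesis import given, settings, strategies as st

    @given(st.lists(st.floats(-5, 5), min_size=6, max_size=6),
           st.lists(st.floats(-5, 5), min_size=6, max_size=6))
    @settings(derandomize=True, max_examples=50, deadline=None)
    def test_summation_to_delta_for_arbitrary_inputs(self, xs, rs):
        net = random_feedforward(np.random.default_rng(55), 6)
        x = np.array([xs])
        r = np.array([rs])
        scores, delta = deeplift_rescale(net, x, r, 0)
        assert abs(scores.sum() - delta[0]) <= 1e-4 * (abs(delta[0]) + 1e-6)

    @given(st.lists(st.floats(0, 100), min_size=1, max_size=30))
    @settings(derandomize=True, max_examples=50, deadline=None)
    def test_ranked_list_sorted_and_complete(self, values):
        ids = [f"g{i:03d}" for i in range(len(values))]
        ranked = RankedGeneList.from_scores(ids, values)
        assert sorted(ranked.gene_ids) == sorted(ids)
        assert all(a >= b for a, b in zip(ranked.scores, ranked.scores[1:]))
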