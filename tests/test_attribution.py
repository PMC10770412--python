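import numpy as np
import pytest

import pathsurv as ps
from pathsurv.attribution import (ActStep, AffineStep, Chain, LinearStep,
                                  deeplift_attributions, deepshap_scores,
                                  fold_inference_transforms)
from pathsurv.nn import BatchNorm, Linear, ReLU, Tanh


def linear_chain(W, b=None):
    W = np.asarray(W, dtype=float)
    b = np.zeros(W.shape[1]) if b is None else np.asarray(b, dtype=float)
    return Chain([LinearStep(W=W, b=b)])


class TestFolding:
    def test_identity_batchnorm_leaves_network_unchanged(self):
        rng = np.random.default_rng(0)
        lin = Linear(3, 2, rng)
        bn = BatchNorm(3)  # mean 0, var 1, gamma 1, beta 0
        chain = fold_inference_transforms([bn, lin])
        atol = 1e-10
        assert np.allclose(chain.steps[0].W, lin.W, atol=atol)
        x = rng.normal(size=(5, 3))
        assert np.allclose(chain(x), lin.forward(x), atol=1e-8)

    def test_folded_network_matches_original_outputs(self):
        rng = np.random.default_rng(1)
        lin1 = Linear(4, 6, rng)
        bn = BatchNorm(6)
        bn.running_mean = rng.normal(size=6)
        bn.running_var = rng.random(6) + 0.5
        bn.gamma = rng.random(6) + 0.5
        bn.beta = rng.normal(size=6)
        lin2 = Linear(6, 2, rng)
        chain = fold_inference_transforms([lin1, ReLU(), bn, lin2])
        for _ in range(100):
            x = rng.normal(size=(1, 4))
            direct = lin2.forward(bn.forward(
                np.maximum(lin1.forward(x), 0), training=False))
            assert np.allclose(chain(x), direct, atol=1e-6)

    def test_folding_is_idempotent(self):
        rng = np.random.default_rng(2)
        lin = Linear(3, 3, rng)
        bn = BatchNorm(3)
        bn.running_mean = rng.normal(size=3)
        chain = fold_inference_transforms([lin, Tanh(), bn])
        refolded = fold_inference_transforms(chain.steps)
        x = rng.normal(size=(4, 3))
        assert np.allclose(chain(x), refolded(x))

    def test_trailing_batchnorm_becomes_affine_step(self):
        rng = np.random.default_rng(3)
        chain = fold_inference_transforms([Linear(2, 2, rng), ReLU(), BatchNorm(2)])
        assert isinstance(chain.steps[-1], AffineStep)


class TestDeepLift:
    def test_reference_equal_to_input_gives_zero(self):
        rng = np.random.default_rng(4)
        chain = fold_inference_transforms([Linear(3, 4, rng), Tanh(),
                                           Linear(4, 1, rng)])
        x = rng.random((1, 3))
        contrib = deeplift_attributions(chain, x, x, 0)
        assert np.allclose(contrib, 0)

    def test_linear_network_closed_form(self):
        W = np.array([[2.0], [-3.0], [0.5]])
        chain = linear_chain(W, b=[0.7])
        x = np.array([[1.0, 2.0, 3.0]])
        ref = np.array([[0.5, 0.0, -1.0]])
        contrib = deeplift_attributions(chain, x, ref, 0)
        assert np.allclose(contrib, W[:, 0] * (x - ref))

    def test_tanh_toy_network_matches_hand_rescale(self):
        # pre = 1*x1 + 2*x2; out = 3*tanh(pre)
        chain = Chain([
            LinearStep(W=np.array([[1.0], [2.0]]), b=np.zeros(1)),
            ActStep(kinds=np.array(["tanh"])),
            LinearStep(W=np.array([[3.0]]), b=np.zeros(1)),
        ])
        x = np.array([[0.5, 0.25]])
        ref = np.array([[0.0, 0.0]])
        pre_x, pre_r = 1.0, 0.0
        slope = (np.tanh(pre_x) - np.tanh(pre_r)) / (pre_x - pre_r)
        expected = 3.0 * slope * np.array([1.0 * 0.5, 2.0 * 0.25])
        contrib = deeplift_attributions(chain, x, ref, 0)
        assert np.allclose(contrib[0], expected)
        # summation-to-delta
        assert contrib.sum() == pytest.approx(3 * np.tanh(1.0))

    def test_summation_to_delta_on_trained_networks(self, planted_pipeline):
        vae = planted_pipeline["vae"]
        sm = planted_pipeline["surv_model"]
        feats = planted_pipeline["feats"]
        X = np.hstack([planted_pipeline["xg"], planted_pipeline["xm"]])
        rows_e = planted_pipeline["hi_rows"][:5]
        rows_r = planted_pipeline["lo_rows"][:20]
        cases = [
            (ps.lfsurv_chain(sm), feats, 0),
            (ps.encoder_chain(vae), X, 3),
            (ps.gene_pathway_chain(vae), planted_pipeline["xg"], 1),
        ]
        for chain, data, target in cases:
            for i in rows_e:
                contrib = deeplift_attributions(chain, data[i:i + 1],
                                                data[rows_r], target)
                out_x = chain(data[i:i + 1])[0, target]
                out_r = chain(data[rows_r])[:, target]
                assert np.allclose(contrib.sum(axis=1), out_x - out_r,
                                   rtol=1e-4, atol=1e-8)

    def test_relu_near_zero_delta_uses_derivative(self):
        chain = Chain([
            LinearStep(W=np.eye(1), b=np.zeros(1)),
            ActStep(kinds=np.array(["relu"])),
            LinearStep(W=np.array([[2.0]]), b=np.zeros(1)),
        ])
        x = np.array([[1.0]])
        ref = np.array([[1.0 + 1e-12]])  # delta below threshold
        contrib = deeplift_attributions(chain, x, ref, 0)
        assert np.isfinite(contrib).all()


class TestDeepShap:
    def test_single_reference_equal_to_explained_gives_zeros(self):
        rng = np.random.default_rng(5)
        chain = fold_inference_transforms([Linear(2, 3, rng), ReLU(),
                                           Linear(3, 1, rng)])
        x = rng.random((3, 2))
        tab = deepshap_scores(chain, x, x.mean(axis=0, keepdims=True) * 0 + x[0],
                              0)
        assert np.allclose(tab.shap[0], 0)

    def test_linear_network_overall_matches_direct_average(self):
        W = np.array([[1.5], [-2.0]])
        chain = linear_chain(W)
        rng = np.random.default_rng(6)
        E = rng.random((10, 2))
        R = rng.random((7, 2))
        tab = deepshap_scores(chain, E, R, 0)
        expected_shap = np.stack([
            (W[:, 0] * (E[i] - R)).mean(axis=0) for i in range(10)])
        assert np.allclose(tab.shap, expected_shap)
        assert np.allclose(tab.overall, np.abs(expected_shap).mean(axis=0))

    def test_empty_sets_raise(self):
        chain = linear_chain(np.eye(2))
        with pytest.raises(ValueError):
            deepshap_scores(chain, np.empty((0, 2)), np.ones((1, 2)), 0)


class TestRankingAndKIF:
    def _table(self, overall, target="z0"):
        n = len(overall)
        return ps.AttributionTable(
            explained_sample_ids=["e"], reference_sample_ids=["r"],
            target=target, feature_ids=[f"f{i}" for i in range(n)],
            shap=np.asarray(overall, dtype=float).reshape(1, -1))

    def test_dominant_feature_ranked_first(self):
        tab = self._table([0.1, 5.0, 0.2])
        assert ps.rank_latent_features(tab)[0] == "f1"

    def test_ties_broken_by_feature_id(self):
        tab = self._table([0.5, 0.5, 0.1])
        assert ps.rank_latent_features(tab)[:2] == ["f0", "f1"]

    def test_ranking_content_invariant_under_permutation(self):
        rng = np.random.default_rng(7)
        overall = rng.random(8)
        tab = self._table(overall)
        perm = rng.permutation(8)
        tab2 = ps.AttributionTable(
            explained_sample_ids=["e"], reference_sample_ids=["r"],
            target="z0", feature_ids=[f"f{i}" for i in perm],
            shap=overall[perm].reshape(1, -1))
        assert ps.rank_latent_features(tab) == ps.rank_latent_features(tab2)

    def test_kif_requires_membership_in_two_lists(self):
        t1 = self._table([9, 8, 0, 0], target="z0")   # top: f0, f1
        t2 = self._table([0, 7, 9, 0], target="z1")   # top: f2, f1
        report = ps.identify_kif([t1, t2], top_k=2)
        assert report.key_factors == {"f1": 2}
        assert report.per_latent_top["z0"] == ["f0", "f1"]

    def test_single_latent_warns_and_returns_empty(self):
        t1 = self._table([1, 2, 3])
        with pytest.warns(UserWarning, match="2 latent"):
            report = ps.identify_kif([t1])
        assert report.key_factors == {}

    def test_sampling_warns_when_group_too_small(self):
        groups = ps.RiskGroups(0.0, ["a", "b", "c", "d"],
                               ["high", "high", "low", "low"])
        with pytest.warns(UserWarning, match="using all"):
            hi, lo = ps.sample_risk_groups(groups, 100, 100, seed=0)
        assert sorted(hi) == ["a", "b"] and sorted(lo) == ["c", "d"]


class TestPlantedRecovery:
    def test_planted_module_scores_exceed_null_background(self, planted_pipeline):
        """Composed encoder+survival attribution concentrates on the genes
        that carry the survival factors: every planted-module gene scores
        above the 90th percentile of the null genes."""
        pp = planted_pipeline
        k = len(pp["planted"])
        cchain = ps.composed_chain(pp["vae"], pp["surv_model"], n_clinical=2)
        X = np.hstack([pp["xg"], pp["xm"], pp["data"].clinical.values])
        tab = deepshap_scores(cchain, X[pp["hi_rows"]], X[pp["lo_rows"]], 0)
        n_genes = pp["data"].gene.n_features
        gene_scores = tab.overall[:n_genes]
        null, planted = gene_scores[:-k], gene_scores[-k:]
        assert planted.min() > np.quantile(null, 0.9)

    def test_pathway_factor_reports_top_contributing_genes(self, planted_pipeline):
        """For a pathway node, the attribution table over the gene layer
        names its top contributing genes (the KPF-to-gene linkage)."""
        pp = planted_pipeline
        mask = pp["mask"]
        chain = ps.gene_pathway_chain(pp["vae"])
        target = mask.pathway_ids.index("Pplanted_a")
        tab = deepshap_scores(chain, pp["xg"][pp["hi_rows"][:30]],
                              pp["xg"][pp["lo_rows"][:30]], target,
                              feature_ids=mask.gene_ids)
        top = ps.rank_latent_features(tab)[:10]
        members = {g for g, m in zip(mask.gene_ids, mask.mask[:, target]) if m}
        assert len(set(top) & members) >= 5
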