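"""Joint factorization checks: reduction to PCA for one block, recovery of
shared simulated factors, the exact full-rank back-mapping equivalence, and
factor-correlation behavior."""

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import linear_sum_assignment
from scipy.stats import spearmanr

import grnjdr as g
from grnjdr.pca import FilteredBlock, PcaModel


def raw_feature_block(block: g.OmicsBlock, center=True, scale=True) -> FilteredBlock:
    """A FilteredBlock whose 'scores' are the standardized features
    themselves (identity loadings): the direct-fit route for the
    back-mapping equivalence oracle."""
    x = block.values.to_numpy(dtype=float).T
    mu = x.mean(axis=0) if center else np.zeros(x.shape[1])
    x = x - mu
    sd = x.std(axis=0, ddof=1) if scale else np.ones(x.shape[1])
    x = x / sd
    scores = pd.DataFrame(x, index=block.sample_ids, columns=block.feature_ids)
    loadings = pd.DataFrame(
        np.eye(x.shape[1]), index=block.feature_ids, columns=block.feature_ids
    )
    pca = PcaModel(
        scores=scores,
        loadings=loadings,
        variance_ratios=np.ones(x.shape[1]) / x.shape[1],
        center=pd.Series(mu, index=block.feature_ids),
        scale=pd.Series(sd, index=block.feature_ids),
    )
    return FilteredBlock(block.name, pca, x.shape[1], 1.0)


def match_factors(est: pd.DataFrame, truth: pd.DataFrame) -> np.ndarray:
    """Max-matched absolute correlations between estimated and true factors."""
    c = np.abs(np.corrcoef(est.to_numpy().T, truth.to_numpy().T))
    c = c[: est.shape[1], est.shape[1]:]
    rows, cols = linear_sum_assignment(-c)
    return c[rows, cols]


@pytest.fixture(scope="module")
def shared_factor_blocks():
    # factor strengths are deliberately staggered across blocks; equal
    # strengths would leave the joint decomposition rotationally degenerate
    lf = g.simulate_latent_factors(120, 4, seed=21)
    blocks = [
        g.simulate_omics_block(
            lf, "b1", 80, [1, 3], loading_scale=(1.0, 0.28), noise_sd=0.05, seed=22
        ),
        g.simulate_omics_block(
            lf, "b2", 50, [1, 2, 3], loading_scale=(1.0, 0.5, 0.28), noise_sd=0.05,
            seed=23,
        ),
        g.simulate_omics_block(
            lf, "b3", 90, [1, 2, 4], loading_scale=(1.0, 0.5, 0.22), noise_sd=0.05,
            seed=24,
        ),
    ]
    filtered = [g.filter_block(b, threshold=0.85, floor=4) for b in blocks]
    return lf, filtered


class TestFitJdr:
    def test_single_block_reduces_to_pca(self, random_block):
        fb = g.filter_block(random_block, threshold=0.9, floor=1, scale=False)
        model = g.fit_jdr([fb], k=3)
        for j in range(3):
            r = np.corrcoef(
                model.factor_scores.iloc[:, j], fb.pca.scores.iloc[:, j]
            )[0, 1]
            assert abs(r) == pytest.approx(1.0, abs=1e-8)

    def test_recovers_shared_factors_at_study_scale(self):
        cfg = g.SimulationConfig(noise_sd=0.05, seed=13)
        cohort = g.simulate_cohort(cfg)
        filtered = [g.filter_block(b, threshold=0.85, floor=4) for b in cohort.omics]
        model = g.fit_jdr(filtered, k=4)
        matched = match_factors(
            model.factor_scores, cohort.truth["factors"].scores
        )
        assert matched.min() >= 0.95

    def test_deterministic(self, shared_factor_blocks):
        _, filtered = shared_factor_blocks
        a = g.fit_jdr(filtered, k=4)
        b = g.fit_jdr(filtered, k=4)
        pd.testing.assert_frame_equal(a.factor_scores, b.factor_scores)
        for name in a.block_weights:
            pd.testing.assert_frame_equal(a.block_weights[name], b.block_weights[name])

    def test_sample_order_invariance(self, random_block):
        fb = g.filter_block(random_block, threshold=0.9, floor=2, scale=False)
        model = g.fit_jdr([fb], k=2)
        rng = np.random.default_rng(3)
        perm = rng.permutation(random_block.n_samples)
        shuffled = g.OmicsBlock(
            random_block.name, random_block.values.iloc[:, perm]
        )
        fb_p = g.filter_block(shuffled, threshold=0.9, floor=2, scale=False)
        model_p = g.fit_jdr([fb_p], k=2)
        reordered = model_p.factor_scores.loc[model.factor_scores.index]
        pd.testing.assert_frame_equal(reordered, model.factor_scores, atol=1e-8)

    def test_sample_mismatch_names_offenders(self, shared_factor_blocks):
        _, filtered = shared_factor_blocks
        broken = FilteredBlock(
            "bad",
            PcaModel(
                scores=filtered[0].pca.scores.iloc[:-2],
                loadings=filtered[0].pca.loadings,
                variance_ratios=filtered[0].pca.variance_ratios,
                center=filtered[0].pca.center,
                scale=filtered[0].pca.scale,
            ),
            filtered[0].k_selected,
            filtered[0].retained_variance,
        )
        with pytest.raises(ValueError, match="sample"):
            g.fit_jdr([filtered[1], broken], k=2)

    def test_k_beyond_rank_rejected(self, random_block):
        fb = g.filter_block(random_block, threshold=0.9, floor=2, scale=False)
        with pytest.raises(ValueError, match="rank"):
            g.fit_jdr([fb], k=10)


class TestVarianceExplained:
    def test_rank_one_block_fully_explained(self, small_factors):
        blk = g.simulate_omics_block(small_factors, "b", 30, [1], noise_sd=0.0, seed=2)
        fb = g.filter_block(blk, threshold=0.99, floor=1, scale=False)
        model = g.fit_jdr([fb], k=1)
        assert model.variance_explained.iloc[0, 0] == pytest.approx(1.0, abs=1e-8)

    def test_matches_direct_frobenius_oracle(self, shared_factor_blocks):
        _, filtered = shared_factor_blocks
        model = g.fit_jdr(filtered, k=3)
        ve = g.variance_explained(model, filtered)
        z = model.factor_scores.to_numpy()
        for blk in filtered:
            s = blk.scores.to_numpy()
            s = s - s.mean(axis=0)
            s = s / np.linalg.svd(s, compute_uv=False)[0]
            a = model.block_weights[blk.name].to_numpy()
            for j in range(3):
                resid = s - np.outer(z[:, j], a[:, j])
                expected = 1 - (resid**2).sum() / (s**2).sum()
                assert ve.loc[blk.name].iloc[j] == pytest.approx(expected, abs=1e-10)

    def test_zeroing_weights_never_increases_r2(self, shared_factor_blocks):
        _, filtered = shared_factor_blocks
        model = g.fit_jdr(filtered, k=3)
        ablated = g.FactorModel(
            factor_scores=model.factor_scores,
            block_weights={
                n: w * 0.0 if n == filtered[0].name else w
                for n, w in model.block_weights.items()
            },
            variance_explained=pd.DataFrame(),
            block_scale=model.block_scale,
        )
        ve = g.variance_explained(model, filtered)
        ve0 = g.variance_explained(ablated, filtered)
        name = filtered[0].name
        assert (ve0.loc[name] <= ve.loc[name] + 1e-12).all()
        assert np.abs(ve0.loc[name]).max() < 1e-12


class TestBackmap:
    def test_identity_loadings_pass_weights_through(self):
        loadings = pd.DataFrame(np.eye(3), index=list("abc"), columns=["PC1", "PC2", "PC3"])
        weights = pd.DataFrame(
            np.arange(6.0).reshape(3, 2), index=["PC1", "PC2", "PC3"], columns=["F1", "F2"]
        )
        fw = g.backmap_weights(loadings, weights)
        assert np.allclose(fw.weights.to_numpy(), weights.to_numpy())

    def test_full_rank_equivalence_with_direct_fit(self):
        lf = g.simulate_latent_factors(25, 3, seed=31)
        blocks = [
            g.simulate_omics_block(lf, "b1", 15, [1, 2], noise_sd=0.2, seed=32),
            g.simulate_omics_block(lf, "b2", 10, [2, 3], noise_sd=0.2, seed=33),
        ]
        pc_route = [
            g.filter_block(b, threshold=1.0, floor=100) for b in blocks
        ]  # floor above rank: all PCs retained
        raw_route = [raw_feature_block(b) for b in blocks]
        model_pc = g.fit_jdr(pc_route, k=3)
        model_raw = g.fit_jdr(raw_route, k=3)
        mapped = g.backmap_model(model_pc, pc_route)
        for blk in blocks:
            w_pc = mapped[blk.name].weights.to_numpy()
            w_raw = model_raw.block_weights[blk.name].to_numpy()
            for j in range(3):
                diff = min(
                    np.abs(w_pc[:, j] - w_raw[:, j]).max(),
                    np.abs(w_pc[:, j] + w_raw[:, j]).max(),
                )
                assert diff < 1e-8

    def test_truncation_preserves_feature_rankings(self):
        lf = g.simulate_latent_factors(80, 3, seed=41)
        blk = g.simulate_omics_block(lf, "b", 120, [1, 2, 3], noise_sd=0.3, seed=42)
        full = [raw_feature_block(blk)]
        trunc = [g.filter_block(blk, threshold=0.85, floor=3)]
        model_full = g.fit_jdr(full, k=3)
        model_trunc = g.fit_jdr(trunc, k=3)
        w_full = model_full.block_weights["b"].to_numpy()
        w_trunc = g.backmap_model(model_trunc, trunc)["b"].weights.to_numpy()
        # factors may come out in a different order/sign: match on |corr|
        c = np.abs(np.corrcoef(w_full.T, w_trunc.T))[:3, 3:]
        rows, cols = linear_sum_assignment(-c)
        for i, j in zip(rows, cols):
            rho = spearmanr(np.abs(w_full[:, i]), np.abs(w_trunc[:, j])).statistic
            assert rho >= 0.9

    def test_dimension_mismatch_rejected(self):
        loadings = pd.DataFrame(np.eye(3), index=list("abc"))
        weights = pd.DataFrame(np.ones((2, 2)))
        with pytest.raises(ValueError):
            g.backmap_weights(loadings, weights)


class TestFactorCorrelation:
    def test_self_correlation_diagonal_one(self, shared_factor_blocks):
        _, filtered = shared_factor_blocks
        model = g.fit_jdr(filtered, k=3)
        c = g.factor_correlation(model, model)
        assert np.allclose(np.diag(c.to_numpy()), 1.0)

    def test_sign_flip_invisible(self, shared_factor_blocks):
        _, filtered = shared_factor_blocks
        model = g.fit_jdr(filtered, k=3)
        flipped = g.FactorModel(
            factor_scores=-model.factor_scores,
            block_weights=model.block_weights,
            variance_explained=model.variance_explained,
        )
        c = g.factor_correlation(model, flipped)
        assert np.allclose(np.diag(c.to_numpy()), 1.0)

    def test_independent_models_weakly_correlated(self):
        rng = np.random.default_rng(7)
        ids = [f"s{i}" for i in range(200)]
        mk = lambda seed: g.FactorModel(
            factor_scores=pd.DataFrame(
                np.random.default_rng(seed).standard_normal((200, 3)),
                index=ids,
                columns=["F1", "F2", "F3"],
            ),
            block_weights={},
            variance_explained=pd.DataFrame(),
        )
        c = g.factor_correlation(mk(1), mk(2))
        assert c.to_numpy().max() < 0.3

    def test_too_few_shared_samples_rejected(self):
        mk = lambda ids: g.FactorModel(
            factor_scores=pd.DataFrame(
                np.eye(len(ids), 2), index=ids, columns=["F1", "F2"]
            ),
            block_weights={},
            variance_explained=pd.DataFrame(),
        )
        with pytest.raises(ValueError):
            g.factor_correlation(mk(["a", "b", "c"]), mk(["c", "d", "e"]))
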