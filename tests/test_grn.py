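"""Network inference checks: co-expression against the textbook Pearson
formula, the message-passing update against a loop-written one-step oracle,
the single-sample interpolation identity, and degree conservation."""

import numpy as np
import pandas as pd
import pytest

import grnjdr as g


def brute_force_pearson(x: np.ndarray) -> np.ndarray:
    """Per-pair textbook Pearson correlation of the rows of x."""
    n = x.shape[0]
    out = np.empty((n, n))
    for i in range(n):
        for j in range(n):
            xi, xj = x[i] - x[i].mean(), x[j] - x[j].mean()
            out[i, j] = (xi * xj).sum() / np.sqrt((xi**2).sum() * (xj**2).sum())
    return out


class TestCoexpression:
    def test_duplicated_gene_correlates_exactly(self):
        rng = np.random.default_rng(1)
        base = rng.standard_normal(10)
        vals = pd.DataFrame(
            [base, base, -base, rng.standard_normal(10)],
            index=["a", "a2", "neg", "other"],
            columns=[f"s{i}" for i in range(10)],
        )
        co = g.compute_coexpression(g.OmicsBlock("e", vals))
        assert co.values.loc["a", "a2"] == pytest.approx(1.0)
        assert co.values.loc["a", "neg"] == pytest.approx(-1.0)

    def test_matches_textbook_formula(self):
        rng = np.random.default_rng(2)
        x = rng.standard_normal((5, 10))
        blk = g.OmicsBlock(
            "e",
            pd.DataFrame(x, index=list("abcde"), columns=[f"s{i}" for i in range(10)]),
        )
        co = g.compute_coexpression(blk)
        expected = brute_force_pearson(x)
        np.fill_diagonal(expected, 1.0)
        assert np.abs(co.values.to_numpy() - expected).max() < 1e-12

    def test_zero_variance_gene_named_in_error(self):
        vals = pd.DataFrame(
            [[1.0, 1.0, 1.0], [1.0, 2.0, 3.0]],
            index=["flatgene", "ok"],
            columns=["s1", "s2", "s3"],
        )
        with pytest.raises(ValueError, match="flatgene"):
            g.compute_coexpression(g.OmicsBlock("e", vals))


def one_step_oracle(motif, ppi, coexpr, alpha):
    """Straight-line scalar transcription of one message-passing update."""

    def zscore(w):
        n_r, n_c = w.shape
        mu_all, sd_all = w.mean(), w.std()
        if sd_all == 0:
            sd_all = 1.0
        out = np.empty_like(w, dtype=float)
        for i in range(n_r):
            for j in range(n_c):
                sd_r = w[i, :].std()
                sd_c = w[:, j].std()
                zr = (w[i, j] - w[i, :].mean()) / sd_r if sd_r > 0 else (
                    (w[i, j] - mu_all) / sd_all
                )
                zc = (w[i, j] - w[:, j].mean()) / sd_c if sd_c > 0 else (
                    (w[i, j] - mu_all) / sd_all
                )
                out[i, j] = (zr + zc) / np.sqrt(2.0)
        return out

    def tanimoto(x, y):
        s = float(np.dot(x, y))
        return s / np.sqrt((x**2).sum() + (y**2).sum() - abs(s))

    w = zscore(motif)
    p = zscore(ppi)
    c = zscore(coexpr)
    n_tfs, n_genes = w.shape
    r = np.empty_like(w)
    a = np.empty_like(w)
    for i in range(n_tfs):
        for j in range(n_genes):
            r[i, j] = tanimoto(p[i, :], w[:, j])
            a[i, j] = tanimoto(w[i, :], c[:, j])
    return (1 - alpha) * w + alpha * 0.5 * (r + a)


class TestMessagePassing:
    @pytest.fixture
    def toy_inputs(self):
        motif = g.MotifPrior(
            pd.DataFrame(
                [[1.0, 0.0, 1.0], [0.0, 1.0, 1.0]],
                index=["t1", "t2"],
                columns=["g1", "g2", "g3"],
            )
        )
        ppi = g.PpiPrior(
            pd.DataFrame(
                [[1.0, 0.5], [0.5, 1.0]], index=["t1", "t2"], columns=["t1", "t2"]
            )
        )
        co = g.CoexpressionMatrix(
            pd.DataFrame(
                [[1.0, 0.2, -0.4], [0.2, 1.0, 0.7], [-0.4, 0.7, 1.0]],
                index=["g1", "g2", "g3"],
                columns=["g1", "g2", "g3"],
            )
        )
        return motif, ppi, co

    def test_alpha_zero_returns_normalized_prior(self, toy_inputs):
        motif, ppi, co = toy_inputs
        grn = g.panda_aggregate(motif, ppi, co, alpha=0.0)
        assert grn.converged
        assert grn.n_iterations == 1
        from grnjdr.grn import _zscore_network

        expected = _zscore_network(motif.weights.to_numpy())
        assert np.abs(grn.weights.to_numpy() - expected).max() < 1e-12

    def test_max_iter_zero_returns_unconverged_prior(self, toy_inputs):
        motif, ppi, co = toy_inputs
        grn = g.panda_aggregate(motif, ppi, co, max_iter=0)
        assert not grn.converged
        from grnjdr.grn import _zscore_network

        expected = _zscore_network(motif.weights.to_numpy())
        assert np.abs(grn.weights.to_numpy() - expected).max() < 1e-12

    def test_single_step_matches_loop_oracle(self, toy_inputs):
        motif, ppi, co = toy_inputs
        grn = g.panda_aggregate(motif, ppi, co, alpha=0.1, tol=1e-12, max_iter=1)
        expected = one_step_oracle(
            motif.weights.to_numpy(),
            ppi.weights.to_numpy(),
            co.values.to_numpy(),
            alpha=0.1,
        )
        assert np.abs(grn.weights.to_numpy() - expected).max() < 1e-10

    def test_converges_and_is_complete(self, tiny_priors, small_factors):
        motif, ppi = tiny_priors
        _, expr = g.simulate_factor_dependent_networks(
            small_factors, motif, seed=4
        )
        grn = g.panda_aggregate(motif, ppi, g.compute_coexpression(expr))
        assert grn.converged
        w = grn.weights.to_numpy()
        assert np.all(np.isfinite(w))
        # complete bipartite: prior zeros still receive weights
        assert (w[motif.weights.to_numpy() == 0] != 0).any()

    def test_permutation_equivariance(self, tiny_priors, small_factors):
        motif, ppi = tiny_priors
        _, expr = g.simulate_factor_dependent_networks(small_factors, motif, seed=4)
        co = g.compute_coexpression(expr)
        grn = g.panda_aggregate(motif, ppi, co)
        rng = np.random.default_rng(0)
        pt, pg = rng.permutation(len(motif.tf_ids)), rng.permutation(len(motif.gene_ids))
        grn_p = g.panda_aggregate(
            g.MotifPrior(motif.weights.iloc[pt, pg]),
            g.PpiPrior(ppi.weights.iloc[pt, pt]),
            g.CoexpressionMatrix(co.values.iloc[pg, pg]),
        )
        assert np.allclose(
            grn_p.weights.to_numpy(), grn.weights.iloc[pt, pg].to_numpy()
        )

    def test_dimension_mismatch_rejected(self, toy_inputs):
        motif, ppi, co = toy_inputs
        bad_co = g.CoexpressionMatrix(co.values.iloc[:2, :2])
        with pytest.raises(ValueError, match="gene"):
            g.panda_aggregate(motif, ppi, bad_co)


def outer_contribution(col: pd.Series) -> pd.DataFrame:
    v = col.to_numpy(dtype=float)
    return pd.DataFrame(
        np.outer(v[:2], v[2:5]), index=["t1", "t2"], columns=["g1", "g2", "g3"]
    )


class TestLioness:
    def test_identical_samples_share_the_aggregate(self):
        vals = pd.DataFrame(
            np.tile(np.arange(5.0)[:, None], (1, 4)),
            index=[f"f{i}" for i in range(5)],
            columns=[f"s{i}" for i in range(4)],
        )
        nets = g.lioness_networks(
            g.OmicsBlock("e", vals), g.make_mean_contribution_fn(outer_contribution)
        )
        assert np.abs(nets.weights - nets.weights[0]).max() < 1e-12

    def test_mean_contribution_recovered_exactly(self):
        rng = np.random.default_rng(3)
        vals = pd.DataFrame(
            rng.standard_normal((6, 12)),
            index=[f"f{i}" for i in range(6)],
            columns=[f"s{i}" for i in range(12)],
        )
        blk = g.OmicsBlock("e", vals)
        nets = g.lioness_networks(blk, g.make_mean_contribution_fn(outer_contribution))
        truth = np.stack(
            [outer_contribution(vals[s]).to_numpy() for s in blk.sample_ids]
        )
        assert np.abs(nets.weights - truth).max() < 1e-10
        agg = np.stack(
            [outer_contribution(vals[s]).to_numpy() for s in blk.sample_ids]
        ).mean(axis=0)
        assert np.abs(nets.weights.mean(axis=0) - agg).max() < 1e-10

    def test_two_sample_interpolation_arithmetic(self):
        # e(all) = [[1]], e(-sample_a) = [[0]]  =>  e(a) = 2*(1-0)+0 = [[2]]
        def fn(block):
            val = 1.0 if block.n_samples == 2 else (0.0 if "a" not in block.sample_ids else 5.0)
            return pd.DataFrame([[val]], index=["t"], columns=["g"])

        blk = g.OmicsBlock(
            "e", pd.DataFrame([[1.0, 2.0]], index=["f"], columns=["a", "b"])
        )
        nets = g.lioness_networks(blk, fn)
        assert nets.weights[nets.sample_ids.index("a"), 0, 0] == pytest.approx(2.0)

    def test_single_sample_rejected(self):
        blk = g.OmicsBlock("e", pd.DataFrame([[1.0]], index=["f"], columns=["a"]))
        with pytest.raises(ValueError):
            g.lioness_networks(blk, g.make_mean_contribution_fn(outer_contribution))

    def test_masked_coexpression_network_fn(self, tiny_priors, small_factors):
        motif, _ = tiny_priors
        rng = np.random.default_rng(9)
        rows = motif.tf_ids + motif.gene_ids
        vals = pd.DataFrame(
            rng.standard_normal((len(rows), 30)),
            index=rows,
            columns=[f"s{i}" for i in range(30)],
        )
        fn = g.make_masked_coexpression_fn(motif)
        net = fn(g.OmicsBlock("e", vals))
        m = motif.weights.to_numpy()
        assert (net.to_numpy()[m == 0] == 0).all()
        # a supported edge equals the TF-gene Pearson correlation
        tfs, genes = np.nonzero(m)
        i, j = tfs[0], genes[0]
        r = np.corrcoef(vals.loc[motif.tf_ids[i]], vals.loc[motif.gene_ids[j]])[0, 1]
        assert net.iloc[i, j] == pytest.approx(r)


class TestDegrees:
    @pytest.fixture
    def toy_network(self):
        return g.SampleNetworkSet(
            weights=np.array([[[1.0, 2.0], [3.0, 4.0]]]),
            sample_ids=["s1"],
            tf_ids=["t1", "t2"],
            gene_ids=["g1", "g2"],
        )

    def test_toy_degrees(self, toy_network):
        ind = g.indegree(toy_network)
        outd = g.outdegree(toy_network)
        assert list(ind.values.loc["s1"]) == [4.0, 6.0]
        assert list(outd.values.loc["s1"]) == [3.0, 7.0]
        assert ind.values.to_numpy().sum() == outd.values.to_numpy().sum() == 10.0

    def test_all_zero_network(self, toy_network):
        zero = g.SampleNetworkSet(
            weights=np.zeros_like(toy_network.weights),
            sample_ids=toy_network.sample_ids,
            tf_ids=toy_network.tf_ids,
            gene_ids=toy_network.gene_ids,
        )
        assert (g.indegree(zero).values.to_numpy() == 0).all()

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_sums_and_conserves(self, seed):
        rng = np.random.default_rng(seed)
        w = rng.standard_normal((4, 5, 8))
        nets = g.SampleNetworkSet(
            weights=w,
            sample_ids=[f"s{i}" for i in range(4)],
            tf_ids=[f"t{i}" for i in range(5)],
            gene_ids=[f"g{i}" for i in range(8)],
        )
        ind = g.indegree(nets).values.to_numpy()
        outd = g.outdegree(nets).values.to_numpy()
        for q in range(4):
            for gi in range(8):
                assert ind[q, gi] == pytest.approx(sum(w[q, t, gi] for t in range(5)))
            assert ind[q].sum() == pytest.approx(outd[q].sum())
            assert ind[q].sum() == pytest.approx(w[q].sum())
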