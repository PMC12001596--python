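import numpy as np
import pytest

from pathlmm import (
    PathwaySkip, pathway_scores_mfa, pathway_scores_pca, pca_scores,
    standardize_columns,
)
from pathlmm.lmm import design_matrix
from .conftest import make_quant_table


def svd_pca_oracle(Z):
    """Independent PCA reference: eigendecomposition of the covariance."""
    n = Z.shape[0]
    C = Z.T @ Z / (n - 1)
    eig, vec = np.linalg.eigh(C)
    order = np.argsort(eig)[::-1]
    return eig[order], vec[:, order]


class TestStandardize:
    def test_center_and_scale(self):
        Z = np.array([[1.0], [2.0], [3.0]])
        centered, flags = standardize_columns(Z, scale=False)
        np.testing.assert_allclose(centered[:, 0], [-1, 0, 1])
        scaled, _ = standardize_columns(Z)
        np.testing.assert_allclose(scaled[:, 0], np.array([-1, 0, 1]) / 1.0)
        assert not flags.any()

    def test_constant_column_flagged(self):
        Z = np.column_stack([np.arange(3.0), np.full(3, 5.0)])
        _, flags = standardize_columns(Z)
        assert list(flags) == [False, True]

    def test_output_moments(self):
        rng = np.random.default_rng(0)
        Z, _ = standardize_columns(rng.random((10, 3)))
        np.testing.assert_allclose(Z.mean(axis=0), 0, atol=1e-12)
        np.testing.assert_allclose(Z.std(axis=0, ddof=1), 1, atol=1e-12)


class TestPcaScores:
    def test_duplicated_column(self):
        """Two identical columns: all variance on PC1 (eigenvalue 2) and
        PC1 scores are sqrt(2) * z; the rank-1 matrix truncates to one
        component when two are requested."""
        rng = np.random.default_rng(1)
        z, _ = standardize_columns(rng.random((8, 1)))
        Z = np.column_stack([z, z])
        scores, eig, load = pca_scores(Z, 2)
        assert scores.shape[1] == 1  # truncated to rank
        np.testing.assert_allclose(eig[0], 2.0, atol=1e-10)
        np.testing.assert_allclose(scores[:, 0], np.sqrt(2) * z[:, 0])

    def test_single_column_identity(self):
        rng = np.random.default_rng(2)
        z, _ = standardize_columns(rng.random((8, 1)))
        scores, eig, _ = pca_scores(z, 1)
        np.testing.assert_allclose(scores[:, 0], z[:, 0])
        np.testing.assert_allclose(eig, [1.0])

    def test_matches_eigh_oracle(self):
        rng = np.random.default_rng(3)
        Z, _ = standardize_columns(rng.random((8, 4)))
        scores, eig, load = pca_scores(Z, 4)
        assert abs(eig.sum() - 4) < 1e-10
        eig_o, vec_o = svd_pca_oracle(Z)
        np.testing.assert_allclose(eig, eig_o, atol=1e-10)
        for j in range(4):
            # equal up to sign
            dot = abs(load[:, j] @ vec_o[:, j])
            np.testing.assert_allclose(dot, 1.0, atol=1e-8)

    def test_score_variance_equals_eigenvalue(self):
        rng = np.random.default_rng(4)
        Z, _ = standardize_columns(rng.random((20, 5)))
        scores, eig, _ = pca_scores(Z, 5)
        np.testing.assert_allclose(scores.var(axis=0, ddof=1), eig, atol=1e-10)

    def test_sign_convention(self):
        rng = np.random.default_rng(5)
        Z, _ = standardize_columns(rng.random((10, 3)))
        _, _, load = pca_scores(Z, 3)
        for j in range(3):
            k = np.argmax(np.abs(load[:, j]))
            assert load[k, j] > 0

    def test_column_order_invariance(self):
        rng = np.random.default_rng(6)
        Z, _ = standardize_columns(rng.random((12, 4)))
        s1, e1, _ = pca_scores(Z, 2)
        s2, e2, _ = pca_scores(Z[:, [2, 0, 3, 1]], 2)
        np.testing.assert_allclose(e1, e2, atol=1e-10)
        for j in range(2):
            assert (np.allclose(s1[:, j], s2[:, j], atol=1e-8)
                    or np.allclose(s1[:, j], -s2[:, j], atol=1e-8))


class TestPathwayScoresPca:
    def test_m_star_capped_by_f(self, toy_qt):
        b2 = pathway_scores_pca(toy_qt, {"m1", "m2"}, F=2, pathway_id="p")
        assert b2.n_components == 2
        b7 = pathway_scores_pca(
            toy_qt, {"m1", "m2", "m3", "m4", "m5", "m6"}, F=2, pathway_id="p"
        )
        assert b7.n_components == 2

    def test_constant_member_triggers_skip(self, toy_qt):
        qt = toy_qt.copy()
        qt.values["m1"] = 3.0
        with pytest.raises(PathwaySkip):
            pathway_scores_pca(qt, {"m1", "m2"}, F=2, pathway_id="p")

    def test_unquantified_members_ignored(self, toy_qt):
        b = pathway_scores_pca(toy_qt, {"m1", "m2", "zzz"}, F=2, pathway_id="p")
        assert b.members == ["m1", "m2"]


class TestPathwayScoresMfa:
    def test_single_block_equals_weighted_pca(self):
        qt = make_quant_table(n_ind=6, T=1)
        pca = pathway_scores_pca(qt, {"m1", "m2", "m3"}, F=2, pathway_id="p")
        mfa = pathway_scores_mfa(
            qt, {"m1", "m2", "m3"}, F=2, block_var="time", pathway_id="p"
        )
        np.testing.assert_allclose(
            mfa.scores, pca.scores / np.sqrt(pca.eigenvalues[0]), atol=1e-10
        )

    def test_identical_blocks_are_aligned_copies(self):
        qt = make_quant_table(n_ind=5, T=3, seed=8)
        first_rows = qt.design["time"] == "t0"
        v = qt.values.copy()
        for t in ("t1", "t2"):
            v.loc[(qt.design["time"] == t).to_numpy()] = v.loc[first_rows].to_numpy()
        qt = qt.with_values(v)
        mfa = pathway_scores_mfa(qt, {"m1", "m2", "m3"}, F=2, pathway_id="p")
        blocks = [
            mfa.scores[(qt.design["time"] == t).to_numpy()]
            for t in ("t0", "t1", "t2")
        ]
        np.testing.assert_allclose(blocks[0], blocks[1], atol=1e-10)
        np.testing.assert_allclose(blocks[0], blocks[2], atol=1e-10)

    def test_permuted_block_matches_per_block_svd_oracle(self):
        qt = make_quant_table(n_ind=6, T=2, seed=9)
        # block 2 = block 1 with rows permuted
        perm = [3, 0, 5, 1, 4, 2]
        v = qt.values.copy()
        b1 = v.loc[(qt.design["time"] == "t0").to_numpy()].to_numpy()
        v.loc[(qt.design["time"] == "t1").to_numpy()] = b1[perm]
        qt = qt.with_values(v)
        members = {"m1", "m2", "m3", "m4"}
        mfa = pathway_scores_mfa(qt, members, F=2, pathway_id="p")
        assert np.allclose(mfa.block_weights[0], mfa.block_weights[1])
        # from-scratch per-block oracle
        for t, mask in (("t0", qt.design["time"] == "t0"),
                        ("t1", qt.design["time"] == "t1")):
            Zb = qt.values.loc[mask, sorted(members)].to_numpy()
            Zb = (Zb - Zb.mean(0)) / Zb.std(0, ddof=1)
            eig, vec = svd_pca_oracle(Zb)
            oracle = (Zb @ vec[:, :2]) / np.sqrt(eig[0])
            got = mfa.scores[mask.to_numpy()]
            for j in range(2):
                assert (np.allclose(got[:, j], oracle[:, j], atol=1e-8)
                        or np.allclose(got[:, j], -oracle[:, j], atol=1e-8))

    def test_small_block_errors(self):
        qt = make_quant_table(n_ind=2, T=2)
        with pytest.raises(PathwaySkip, match="block too small"):
            pathway_scores_mfa(qt, {"m1", "m2"}, F=2, pathway_id="p")

    def test_time_blocks_erase_time_signal(self):
        """Stacked partial scores carry no between-time mean structure even
        when the data has a pure mean-shift time effect."""
        qt = make_quant_table(n_ind=8, T=3, seed=10)
        v = qt.values.copy()
        shift = qt.design["time"].cat.codes.to_numpy()[:, None] * 5.0
        v.loc[:, :] = v.to_numpy() + shift
        qt = qt.with_values(v)
        mfa = pathway_scores_mfa(qt, {"m1", "m2", "m3"}, F=2, pathway_id="p")
        X, _, _ = design_matrix(qt.design, ("time",))
        y = mfa.scores[:, 0]
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ beta
        r2 = 1 - resid.var() / y.var()
        assert r2 < 0.05
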