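"""Contact-inference scores: frequencies, covariance, MI, mfDCA, plmDCA,
APC, Frobenius scoring, and score-file output."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import phylodca as pdca
from phylodca.inference import (DEFAULT_LAMBDA_MFDCA, _one_hot,
                                frobenius_scores)


def _random_binary_msa(m, ell, seed):
    gen = np.random.default_rng(seed)
    return pdca.SpinMSA(matrix=gen.choice([-1, 1], size=(m, ell)))


def _sample_single_edge_pairs(m, temperature, seed):
    """Exact sampler for a 2-site Ising model P(s1, s2) ~ exp(s1 s2 / T)."""
    states = np.array([[-1, -1], [-1, 1], [1, -1], [1, 1]])
    w = np.exp(states[:, 0] * states[:, 1] / temperature)
    p = w / w.sum()
    gen = np.random.default_rng(seed)
    return states[gen.choice(4, size=m, p=p)]


class TestFrequencies:
    def test_lambda_one_is_uniform(self):
        msa = _random_binary_msa(50, 5, 0)
        fm = pdca.compute_frequencies(msa, 1.0)
        assert np.allclose(fm.f1, 0.5)
        off = ~np.eye(5, dtype=bool)
        assert np.allclose(fm.f2[off], 0.25)

    def test_lambda_zero_is_empirical(self):
        msa = pdca.SpinMSA(matrix=np.array([[1, 1], [1, -1], [-1, -1],
                                            [1, 1]]))
        fm = pdca.compute_frequencies(msa, 0.0)
        # States ordered (-1, +1).
        assert fm.f1[0, 1] == pytest.approx(0.75)
        assert fm.f2[0, 1, 1, 1] == pytest.approx(0.5)

    def test_normalization_and_marginalization(self):
        msa = _random_binary_msa(40, 6, 1)
        fm = pdca.compute_frequencies(msa, 0.37)
        assert np.allclose(fm.f1.sum(axis=1), 1.0)
        off = ~np.eye(6, dtype=bool)
        assert np.allclose(fm.f2.sum(axis=(2, 3))[off], 1.0)
        # sum_b f_ij(a, b) = f_i(a) for i != j.
        marg = fm.f2.sum(axis=3)
        for i in range(6):
            for j in range(6):
                if i != j:
                    assert np.allclose(marg[i, j], fm.f1[i])

    def test_diagonal_convention(self):
        msa = _random_binary_msa(40, 4, 2)
        fm = pdca.compute_frequencies(msa, 0.1)
        for i in range(4):
            assert np.allclose(np.diag(fm.f2[i, i]), fm.f1[i])
            assert fm.f2[i, i, 0, 1] == 0.0

    def test_invalid_lambda_rejected(self):
        msa = _random_binary_msa(10, 3, 3)
        with pytest.raises(ValueError):
            pdca.compute_frequencies(msa, 1.5)

    @given(st.integers(min_value=0, max_value=10**6),
           st.floats(min_value=0.0, max_value=1.0))
    def test_marginalization_property(self, seed, lam):
        msa = _random_binary_msa(15, 4, seed)
        fm = pdca.compute_frequencies(msa, lam)
        marg = fm.f2.sum(axis=3)
        for i in range(4):
            for j in range(4):
                if i != j:
                    assert np.allclose(marg[i, j], fm.f1[i], atol=1e-12)


class TestCovariance:
    def test_identical_balanced_columns_score_one(self):
        col = np.array([1, -1] * 10)
        msa = pdca.SpinMSA(matrix=np.column_stack([col, col]))
        s = pdca.covariance_scores(msa)
        assert s.scores[0, 1] == pytest.approx(1.0)

    def test_anticorrelated_balanced_columns_score_one(self):
        col = np.array([1, -1] * 10)
        msa = pdca.SpinMSA(matrix=np.column_stack([col, -col]))
        assert pdca.covariance_scores(msa).scores[0, 1] == pytest.approx(1.0)

    def test_matches_frequency_form(self):
        # |C_ij| == |4 (f_ij(1,1) - f_i(1) f_j(1))| at lambda = 0.
        for seed in range(20):
            msa = _random_binary_msa(30, 5, seed)
            fm = pdca.compute_frequencies(msa, 0.0)
            expected = np.abs(4.0 * (fm.f2[:, :, 1, 1]
                                     - np.outer(fm.f1[:, 1], fm.f1[:, 1])))
            np.fill_diagonal(expected, 0.0)
            assert np.allclose(pdca.covariance_scores(msa).scores, expected)

    def test_qstate_rejected(self):
        msa = pdca.SpinMSA(matrix=np.zeros((4, 3), dtype=int), n_states=4)
        with pytest.raises(ValueError):
            pdca.covariance_scores(msa)


class TestMI:
    def test_identical_balanced_columns_log2(self):
        col = np.array([1, -1] * 20)
        msa = pdca.SpinMSA(matrix=np.column_stack([col, col]))
        assert pdca.mi_scores(msa, lam=0.0).scores[0, 1] == pytest.approx(
            np.log(2.0))

    def test_independent_columns_near_zero(self):
        msa = _random_binary_msa(5000, 4, 7)
        s = pdca.mi_scores(msa, lam=0.0).scores
        off = s[~np.eye(4, dtype=bool)]
        # MI bias for independent binary columns is ~ 1/(2M).
        assert np.all(off < 20 / msa.n_sequences)

    def test_bounds(self):
        for seed in range(10):
            msa = _random_binary_msa(25, 5, seed)
            lam = seed / 10.0
            s = pdca.mi_scores(msa, lam=lam).scores
            off = s[~np.eye(5, dtype=bool)]
            assert np.all(off >= -1e-12)
            assert np.all(off <= np.log(2.0) + 1e-12)


class TestMfdca:
    def test_lambda_zero_reduces_to_covariance_inverse(self):
        msa = _random_binary_msa(500, 6, 11)
        x = msa.matrix.astype(float)
        cov = x.T @ x / len(x) - np.outer(x.mean(0), x.mean(0))
        np.fill_diagonal(cov, 1 - x.mean(0) ** 2)
        expected = -np.linalg.inv(cov)
        np.fill_diagonal(expected, 0.0)
        s, model = pdca.mfdca_scores(msa, lam=0.0)
        assert np.allclose(model.couplings, 0.5 * (expected + expected.T))

    def test_matches_naive_inversion_oracle(self):
        # Independent construction of C~ from pseudocount frequencies.
        lam = DEFAULT_LAMBDA_MFDCA
        for seed in range(5):
            msa = _random_binary_msa(200, 10, seed)
            x = msa.matrix.astype(float)
            m1 = (1 - lam) * x.mean(axis=0)                 # <s_i> with pc
            m2 = (1 - lam) * (x.T @ x) / len(x)             # <s_i s_j> with pc
            ctil = m2 - np.outer(m1, m1)
            np.fill_diagonal(ctil, (1 - lam) ** 2 * (1 - x.mean(0) ** 2)
                             + lam * (2 - lam))
            expected = -np.linalg.inv(ctil)
            np.fill_diagonal(expected, 0.0)
            s, _ = pdca.mfdca_scores(msa, lam=lam)
            assert np.allclose(s.scores, np.abs(0.5 * (expected + expected.T)))

    def test_singular_matrix_reports_advice(self):
        # Duplicated column at lambda = 0 makes C~ exactly singular.
        col = np.array([1, -1, 1, 1, -1, -1, 1, -1])
        msa = pdca.SpinMSA(matrix=np.column_stack([col, col, -col]))
        with pytest.raises(np.linalg.LinAlgError, match="pseudocount"):
            pdca.mfdca_scores(msa, lam=0.0)

    def test_isolated_pair_top_ranked(self):
        g = pdca.ContactGraph(n_sites=6, edges=frozenset({(2, 4)}))
        spec = pdca.HamiltonianSpec(graph=g)
        msa = pdca.sample_equilibrium(
            spec, pdca.SamplerParams(temperature=2.0, rng_seed=5), 3000)
        s, _ = pdca.mfdca_scores(msa)
        iu = np.triu_indices(6, k=1)
        best = np.argmax(s.scores[iu])
        assert (iu[0][best], iu[1][best]) == (2, 4)


class TestPlmdca:
    def test_single_edge_recovers_inverse_temperature(self):
        # P(s1, s2) ~ exp(s1 s2 / T): pseudolikelihood estimate of J
        # approaches 1/T = 0.2 for large M and small regularization.
        msa = pdca.SpinMSA(matrix=_sample_single_edge_pairs(20000, 5.0, 3))
        s, model = pdca.plmdca_scores(msa, lambda_j=1e-4, lambda_h=1e-4)
        assert model.couplings[0, 1] == pytest.approx(0.2, abs=0.02)

    def test_independent_columns_below_noise_threshold(self):
        msa = _random_binary_msa(2000, 8, 13)
        s, _ = pdca.plmdca_scores(msa)
        # |J| ~ O(1/sqrt(M)) for independent columns.
        assert s.scores.max() < 5.0 / np.sqrt(msa.n_sequences)

    def test_symmetry_exact(self):
        msa = _random_binary_msa(100, 6, 17)
        s, model = pdca.plmdca_scores(msa)
        assert np.array_equal(model.couplings, model.couplings.T)
        assert np.array_equal(s.scores, s.scores.T)

    def test_qstate_zero_sum_gauge_and_frobenius(self):
        gen = np.random.default_rng(19)
        msa = pdca.SpinMSA(matrix=gen.integers(3, size=(300, 4)), n_states=3)
        s, model = pdca.plmdca_scores(msa)
        assert model.gauge == "zero_sum"
        # Row and column sums of every coupling block vanish.
        assert np.allclose(model.couplings.sum(axis=2), 0.0, atol=1e-10)
        assert np.allclose(model.couplings.sum(axis=3), 0.0, atol=1e-10)
        # Frobenius score matches a direct norm on one block.
        assert s.scores[0, 1] == pytest.approx(
            np.sqrt(np.sum(model.couplings[0, 1] ** 2)))

    def test_binary_and_qstate_agree_on_planted_pair(self):
        # Columns (0, 1) carry a strong 2-site Ising coupling; 2-4 are
        # independent noise.  Both the binary path and the q-state path
        # (same data re-encoded with a 3-letter alphabet) must rank the
        # planted pair first.
        gen = np.random.default_rng(23)
        pair = _sample_single_edge_pairs(500, 2.0, 23)
        noise = gen.choice([-1, 1], size=(500, 3))
        msa = pdca.SpinMSA(matrix=np.column_stack([pair, noise]))
        msa_q = pdca.SpinMSA(matrix=(msa.matrix + 1) // 2, n_states=3)
        for m in (msa, msa_q):
            s, _ = pdca.plmdca_scores(m)
            iu = np.triu_indices(5, k=1)
            best = int(np.argmax(s.scores[iu]))
            assert (iu[0][best], iu[1][best]) == (0, 1)


class TestApc:
    def test_constant_matrix_zeroed(self):
        s = np.full((5, 5), 0.7)
        np.fill_diagonal(s, 0.0)
        out = pdca.apply_apc(pdca.ScoreMatrix(scores=s, method="mi"))
        off = out.scores[~np.eye(5, dtype=bool)]
        assert np.allclose(off, 0.0, atol=1e-12)

    def test_hand_computed_3x3(self):
        s = np.array([[0.0, 2.0, 4.0],
                      [2.0, 0.0, 6.0],
                      [4.0, 6.0, 0.0]])
        out = pdca.apply_apc(pdca.ScoreMatrix(scores=s, method="mi"))
        # Independent elementwise computation of S_ij - S_i. S_.j / S_bar.
        row = np.array([(2 + 4) / 2, (2 + 6) / 2, (4 + 6) / 2])
        sbar = (2 + 4 + 6 + 2 + 4 + 6) / 6
        for i in range(3):
            for j in range(3):
                if i != j:
                    assert out.scores[i, j] == pytest.approx(
                        s[i, j] - row[i] * row[j] / sbar)

    def test_symmetry_preserved(self):
        msa = _random_binary_msa(60, 7, 29)
        out = pdca.apply_apc(pdca.mi_scores(msa))
        assert np.allclose(out.scores, out.scores.T)
        assert out.apc_applied

    def test_zero_mean_returns_unchanged_with_warning(self):
        s = np.zeros((4, 4))
        with pytest.warns(UserWarning, match="APC skipped"):
            out = pdca.apply_apc(pdca.ScoreMatrix(scores=s, method="mi"))
        assert not out.apc_applied


class TestFrobenius:
    def test_zero_couplings_zero_scores(self):
        model = pdca.PottsModel(fields=None,
                                couplings=np.zeros((4, 4, 3, 3)),
                                n_states=3, gauge="zero_sum")
        assert np.all(frobenius_scores(model).scores == 0.0)

    def test_requires_gauge(self):
        model = pdca.PottsModel(fields=None,
                                couplings=np.zeros((4, 4, 3, 3)), n_states=3)
        with pytest.raises(ValueError, match="gauge"):
            frobenius_scores(model)

    def test_binary_rejected(self):
        model = pdca.PottsModel(fields=None, couplings=np.zeros((4, 4)),
                                n_states=2, gauge="zero_sum")
        with pytest.raises(ValueError):
            frobenius_scores(model)

    def test_random_block_hand_norm(self):
        gen = np.random.default_rng(31)
        j = gen.normal(size=(2, 2, 21, 21))
        j[1, 0] = np.transpose(j[0, 1])
        j[0, 0] = j[1, 1] = 0.0
        model = pdca.PottsModel(fields=None, couplings=j, n_states=21)
        zs = model.to_zero_sum_gauge()
        s = frobenius_scores(zs)
        hand = np.sqrt(sum(zs.couplings[0, 1, a, b] ** 2
                           for a in range(21) for b in range(21)))
        assert s.scores[0, 1] == pytest.approx(hand)


class TestInvariances:
    def test_row_permutation_invariance(self):
        msa = _random_binary_msa(80, 6, 37)
        gen = np.random.default_rng(0)
        perm = gen.permutation(80)
        msa_p = pdca.SpinMSA(matrix=msa.matrix[perm])
        for fn in (pdca.covariance_scores, pdca.mi_scores):
            assert np.allclose(fn(msa).scores, fn(msa_p).scores)
        assert np.allclose(pdca.mfdca_scores(msa)[0].scores,
                           pdca.mfdca_scores(msa_p)[0].scores)
        assert np.allclose(pdca.plmdca_scores(msa)[0].scores,
                           pdca.plmdca_scores(msa_p)[0].scores, atol=1e-4)

    def test_column_relabeling_equivariance(self):
        msa = _random_binary_msa(80, 6, 41)
        gen = np.random.default_rng(1)
        perm = gen.permutation(6)
        msa_p = pdca.SpinMSA(matrix=msa.matrix[:, perm])
        for fn in (pdca.covariance_scores, pdca.mi_scores):
            assert np.allclose(fn(msa).scores[np.ix_(perm, perm)],
                               fn(msa_p).scores)
        assert np.allclose(
            pdca.plmdca_scores(msa)[0].scores[np.ix_(perm, perm)],
            pdca.plmdca_scores(msa_p)[0].scores, atol=1e-4)


class TestScoreMatrixAndIO:
    def test_validation(self):
        with pytest.raises(ValueError):
            pdca.ScoreMatrix(scores=np.zeros((2, 3)), method="mi")
        bad = np.array([[0.0, 1.0], [2.0, 0.0]])
        with pytest.raises(ValueError):
            pdca.ScoreMatrix(scores=bad, method="mi")
        inf = np.array([[0.0, np.inf], [np.inf, 0.0]])
        with pytest.raises(ValueError):
            pdca.ScoreMatrix(scores=inf, method="mi")

    def test_write_scores_sorted_desc(self, tmp_path):
        import pandas as pd
        msa = _random_binary_msa(50, 5, 43)
        raw = pdca.mi_scores(msa)
        apc = pdca.apply_apc(raw)
        path = tmp_path / "scores.tsv"
        pdca.write_scores(raw, path, apc=apc, reg=0.01)
        df = pd.read_csv(path, sep="\t")
        assert len(df) == 10
        assert (df["raw_score"].diff().dropna() <= 1e-12).all()
        assert set(df.columns) == {"i", "j", "raw_score", "apc_score",
                                   "method", "lambda"}

    def test_one_hot_binary_order(self):
        msa = pdca.SpinMSA(matrix=np.array([[1, -1]]))
        oh = _one_hot(msa)
        # state order (-1, +1)
        assert oh[0, 0].tolist() == [0.0, 1.0]
        assert oh[0, 1].tolist() == [1.0, 0.0]
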