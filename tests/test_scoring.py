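"""Signature scoring: analytic ssGSEA cases, direct-summation oracle
equivalence, z-score oracle, meta-gene behaviour and invariances."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import rankdata

from stromascope import (BULK_LOG2, ExpressionMatrix, GeneSignature,
                         ModuleMetagene, SignatureScorer, metagene,
                         scaled_average_score, ssgsea_score)


def ssgsea_oracle(x, in_set, alpha):
    """Independent direct-summation ssGSEA oracle: explicit walk in pure
    Python over genes sorted by descending expression."""
    n = len(x)
    idx = sorted(range(n), key=lambda i: (-x[i], i))
    r = rankdata(x)
    wsum = sum(abs(r[i]) ** alpha for i in range(n) if in_set[i])
    nout = n - sum(bool(b) for b in in_set)
    es, cin, cout = 0.0, 0.0, 0
    for i in idx:
        if in_set[i]:
            cin += abs(r[i]) ** alpha
        else:
            cout += 1
        es += cin / wsum - cout / nout
    return es


def _mat(values, genes=None, samples=None, tag=BULK_LOG2):
    values = np.asarray(values, dtype=float)
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    samples = samples or [f"s{j}" for j in range(values.shape[1])]
    return ExpressionMatrix(pd.DataFrame(values, index=genes,
                                         columns=samples), tag)


class TestSsgsea:
    def test_top_gene_set_scores_one(self):
        """Two genes, the set holding the higher-expressed one: the walk
        contributes (1-0) then (1-1), so ES = 1 regardless of values."""
        m = _mat([[5.0], [2.0]])
        s = ssgsea_score(m, GeneSignature("top", ("g0",)), alpha=0.0)
        assert s.iloc[0] == pytest.approx(1.0, abs=1e-12)

    def test_bottom_gene_set_scores_minus_one(self):
        m = _mat([[5.0], [2.0]])
        s = ssgsea_score(m, GeneSignature("bottom", ("g1",)), alpha=0.0)
        assert s.iloc[0] == pytest.approx(-1.0, abs=1e-12)

    @pytest.mark.parametrize("alpha", [0.0, 0.25, 1.0])
    def test_matches_direct_summation_oracle(self, alpha):
        rng = np.random.default_rng(42)
        for _ in range(100):
            vals = rng.normal(size=(20, 3))
            k = int(rng.integers(1, 19))
            members = rng.choice(20, size=k, replace=False)
            in_set = np.zeros(20, dtype=bool)
            in_set[members] = True
            sig = GeneSignature("s", tuple(f"g{i}" for i in members))
            got = ssgsea_score(_mat(vals), sig, alpha=alpha)
            for j in range(3):
                want = ssgsea_oracle(list(vals[:, j]), list(in_set), alpha)
                assert got.iloc[j] == pytest.approx(want, abs=1e-12)

    def test_rank_monotone_transform_invariance(self):
        rng = np.random.default_rng(0)
        vals = rng.normal(size=(15, 4))
        sig = GeneSignature("s", ("g1", "g4", "g7"))
        base = ssgsea_score(_mat(vals), sig, alpha=0.25)
        warped = ssgsea_score(_mat(np.exp(vals)), sig, alpha=0.25)
        np.testing.assert_allclose(base, warped, atol=1e-12)

    def test_gene_order_permutation_invariance(self):
        rng = np.random.default_rng(1)
        vals = rng.normal(size=(12, 3))
        genes = [f"g{i}" for i in range(12)]
        sig = GeneSignature("s", ("g2", "g5"))
        base = ssgsea_score(_mat(vals, genes), sig, alpha=0.25)
        perm = rng.permutation(12)
        shuffled = _mat(vals[perm], [genes[i] for i in perm])
        np.testing.assert_allclose(
            base, ssgsea_score(shuffled, sig, alpha=0.25), atol=1e-12)

    def test_disjoint_or_covering_signature_rejected(self):
        m = _mat(np.ones((3, 2)))
        with pytest.raises(ValueError, match="no genes"):
            ssgsea_score(m, GeneSignature("x", ("nope",)))
        with pytest.raises(ValueError, match="every gene"):
            ssgsea_score(m, GeneSignature("x", ("g0", "g1", "g2")))


class TestScaledAverage:
    def test_identical_columns_score_zero(self):
        m = _mat(np.tile([[3.0], [1.0], [2.0]], (1, 4)))
        s = scaled_average_score(m, GeneSignature("s", ("g0",)))
        np.testing.assert_allclose(s, 0.0, atol=1e-12)

    def test_monotone_signature_gene_gives_increasing_scores(self):
        vals = np.vstack([[1.0, 2.0, 3.0, 4.0], np.full((3, 4), 5.0)])
        s = scaled_average_score(_mat(vals), GeneSignature("s", ("g0",)))
        assert (np.diff(s) > 0).all()

    def test_hand_computed_example(self):
        """4 genes x 3 samples; signature {g0}. g1 is constant (z = 0);
        frozen expectations computed by hand with population-SD z-scores:
        score_j = z_{g0,j} - mean(z_{g1..g3,j}) = -+sqrt(3/2), 0."""
        vals = [[1.0, 2.0, 3.0],
                [5.0, 5.0, 5.0],
                [2.0, 0.0, 1.0],
                [4.0, 8.0, 6.0]]
        s = scaled_average_score(_mat(vals), GeneSignature("s", ("g0",)))
        np.testing.assert_allclose(
            s, [-1.224744871391589, 0.0, 1.224744871391589], atol=1e-12)

    def test_signature_and_complement_are_negatives(self):
        rng = np.random.default_rng(3)
        vals = rng.normal(size=(10, 5))
        m = _mat(vals)
        half = tuple(f"g{i}" for i in range(5))
        rest = tuple(f"g{i}" for i in range(5, 10))
        a = scaled_average_score(m, GeneSignature("a", half))
        b = scaled_average_score(m, GeneSignature("b", rest))
        np.testing.assert_allclose(a, -b, atol=1e-12)

    def test_covering_signature_rejected(self):
        m = _mat(np.ones((2, 3)))
        with pytest.raises(ValueError, match="non-signature"):
            scaled_average_score(m, GeneSignature("s", ("g0", "g1")))


class TestMetagene:
    def test_single_gene_module_is_centred_profile(self):
        rng = np.random.default_rng(5)
        vals = rng.normal(size=(6, 8))
        mg = metagene(_mat(vals), ["g2"])
        centred = vals[2] - vals[2].mean()
        np.testing.assert_allclose(np.corrcoef(mg, centred)[0, 1], 1.0,
                                   atol=1e-12)

    def test_two_identical_genes_perfectly_correlated(self):
        rng = np.random.default_rng(6)
        x = rng.normal(size=10)
        vals = np.vstack([x, x, rng.normal(size=10)])
        mg = metagene(_mat(vals), ["g0", "g1"])
        assert abs(np.corrcoef(mg, x)[0, 1]) == pytest.approx(1.0, abs=1e-10)

    def test_sign_oriented_to_mean_module_expression(self):
        rng = np.random.default_rng(7)
        vals = rng.normal(size=(10, 15))
        mg = metagene(_mat(vals), [f"g{i}" for i in range(4)])
        mean_expr = vals[:4].mean(axis=0)
        assert np.corrcoef(mg, mean_expr)[0, 1] >= 0

    def test_pc1_matches_eigendecomposition_oracle(self):
        """PC1 variance share agrees with an independent eigendecomposition
        of the gene-gene covariance, and scores match up to sign."""
        rng = np.random.default_rng(8)
        vals = rng.normal(size=(10, 25))
        module = [f"g{i}" for i in range(10)]
        est = ModuleMetagene(module).fit(_mat(vals).values.T)
        scores = est.transform(_mat(vals).values.T)
        centred = vals - vals.mean(axis=1, keepdims=True)
        cov = centred @ centred.T / (25 - 1)
        w, v = np.linalg.eigh(cov)
        lead = v[:, -1]
        oracle_scores = centred.T @ lead
        c = np.corrcoef(scores, oracle_scores)[0, 1]
        assert abs(c) == pytest.approx(1.0, abs=1e-10)
        assert scores.var(ddof=1) == pytest.approx(w[-1], rel=1e-10)

    def test_constant_module_rejected(self):
        m = _mat(np.ones((4, 5)))
        with pytest.raises(ValueError, match="constant"):
            metagene(m, ["g0", "g1"])


def test_scorer_is_sklearn_compatible(random_matrix, stromal_sig):
    """The scorer round-trips get_params/set_params and clones."""
    from sklearn.base import clone
    sig = GeneSignature("s", ("g1", "g4"))
    sc = SignatureScorer([sig], alpha=0.25)
    assert clone(sc).get_params()["alpha"] == 0.25
    out = sc.fit_transform(random_matrix.values.T)
    assert list(out.columns) == ["s"] and len(out) == 12
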