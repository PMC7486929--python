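"""Gene-set signature scoring: mean expression, CD8/Treg ratio, ssGSEA."""

import numpy as np
import pytest

from depthscore import GeneSet, mean_signature_score, ssgsea_score, stim_inhib_ratio
from .conftest import make_expression, ssgsea_oracle


class TestMeanSignatureScore:
    def test_mean_of_present_genes(self):
        expr = make_expression([[2.0], [4.0], [9.0]], gene_ids=["A", "B", "C"])
        table = mean_signature_score(expr, GeneSet("sig", "", ("A", "B")))
        assert table["score"].iloc[0] == pytest.approx(3.0)
        assert table["n_genes_used"].iloc[0] == 2
        assert (table["method"] == "mean_expression").all()

    def test_absent_genes_dropped_with_warning(self):
        expr = make_expression([[2.0], [4.0]], gene_ids=["A", "B"])
        with pytest.warns(UserWarning, match="MISSING"):
            table = mean_signature_score(expr, GeneSet("sig", "", ("A", "B", "MISSING")))
        assert table["score"].iloc[0] == pytest.approx(3.0)
        assert table["n_genes_used"].iloc[0] == 2

    def test_singleton_set_returns_that_gene(self):
        expr = make_expression([[2.5, 7.0], [0.0, 1.0]], gene_ids=["A", "B"])
        table = mean_signature_score(expr, GeneSet("sig", "", ("A",)))
        np.testing.assert_allclose(table["score"], [2.5, 7.0])

    def test_empty_intersection_names_the_set(self):
        expr = make_expression([[1.0], [2.0]], gene_ids=["A", "B"])
        with pytest.raises(ValueError, match="mysig"):
            mean_signature_score(expr, GeneSet("mysig", "", ("X", "Y")))

    def test_linear_in_constant_shift(self):
        rng = np.random.default_rng(0)
        values = rng.random((10, 4))
        genes = [f"g{i}" for i in range(10)]
        gs = GeneSet("sig", "", tuple(genes[:4]))
        base = mean_signature_score(make_expression(values, gene_ids=genes), gs)
        shifted_values = values.copy()
        shifted_values[:4] += 1.7
        shifted = mean_signature_score(
            make_expression(shifted_values, gene_ids=genes), gs
        )
        np.testing.assert_allclose(shifted["score"], base["score"] + 1.7)


class TestStimInhibRatio:
    def test_equal_means_score_zero(self):
        expr = make_expression([[2.0], [2.0]], gene_ids=["CD8A", "FOXP3"])
        table = stim_inhib_ratio(
            expr, GeneSet("cd8", "", ("CD8A",)), GeneSet("treg", "", ("FOXP3",))
        )
        assert table["score"].iloc[0] == pytest.approx(0.0, abs=1e-12)

    def test_hand_worked_linear_means(self):
        # linear means 3 and 1 (log2 values log2(4) and log2(2)) -> log2(4/2) = 1
        expr = make_expression(
            [[np.log2(4.0)], [np.log2(2.0)]], gene_ids=["CD8A", "FOXP3"]
        )
        table = stim_inhib_ratio(
            expr, GeneSet("cd8", "", ("CD8A",)), GeneSet("treg", "", ("FOXP3",))
        )
        assert table["score"].iloc[0] == pytest.approx(1.0, rel=1e-12)

    def test_antisymmetric_under_set_swap(self):
        rng = np.random.default_rng(1)
        genes = [f"g{i}" for i in range(8)]
        expr = make_expression(rng.random((8, 5)) * 6, gene_ids=genes)
        a = GeneSet("a", "", tuple(genes[:3]))
        b = GeneSet("b", "", tuple(genes[3:6]))
        fwd = stim_inhib_ratio(expr, a, b)["score"].to_numpy()
        rev = stim_inhib_ratio(expr, b, a)["score"].to_numpy()
        np.testing.assert_allclose(fwd, -rev, atol=1e-12)

    def test_log_scale_variant(self):
        expr = make_expression([[3.0], [1.0]], gene_ids=["A", "B"])
        table = stim_inhib_ratio(
            expr, GeneSet("a", "", ("A",)), GeneSet("b", "", ("B",)), linear=False
        )
        assert table["score"].iloc[0] == pytest.approx(np.log2(4.0 / 2.0))


class TestSsgsea:
    def _toy(self, seed=2, m=10, s=1):
        rng = np.random.default_rng(seed)
        genes = [f"g{i}" for i in range(m)]
        values = rng.permutation(np.arange(1.0, m * s + 1.0)).reshape(m, s)
        return make_expression(values, gene_ids=genes), genes

    def test_matches_bruteforce_oracle_top2(self):
        expr, genes = self._toy()
        v = expr.values[:, 0]
        top2 = [genes[i] for i in np.argsort(-v)[:2]]
        table = ssgsea_score(expr, GeneSet("top2", "", tuple(top2)), normalize=False)
        expected = ssgsea_oracle(list(v), genes, set(top2), alpha=0.25)
        assert table["score"].iloc[0] == pytest.approx(expected, abs=1e-12)

    def test_oracle_agreement_with_ties_and_alphas(self):
        rng = np.random.default_rng(5)
        genes = [f"g{i}" for i in range(12)]
        values = rng.integers(0, 5, size=(12, 1)).astype(float)  # many ties
        expr = make_expression(values, gene_ids=genes)
        gs = GeneSet("s", "", tuple(genes[2:6]))
        for alpha in (0.0, 0.25, 1.0):
            got = ssgsea_score(expr, gs, alpha=alpha, normalize=False)["score"].iloc[0]
            want = ssgsea_oracle(list(values[:, 0]), genes, set(gs.genes), alpha)
            assert got == pytest.approx(want, abs=1e-12)

    def test_top_set_beats_bottom_set(self):
        expr, genes = self._toy(seed=3)
        v = expr.values[:, 0]
        order = np.argsort(-v)
        top = GeneSet("top", "", tuple(genes[i] for i in order[:3]))
        bottom = GeneSet("bottom", "", tuple(genes[i] for i in order[-3:]))
        s_top = ssgsea_score(expr, top, normalize=False)["score"].iloc[0]
        s_bottom = ssgsea_score(expr, bottom, normalize=False)["score"].iloc[0]
        assert s_top > s_bottom

    def test_identical_samples_identical_scores(self):
        rng = np.random.default_rng(4)
        col = rng.random(15)
        genes = [f"g{i}" for i in range(15)]
        expr = make_expression(np.column_stack([col, col]), gene_ids=genes)
        table = ssgsea_score(expr, GeneSet("s", "", tuple(genes[:4])), normalize=False)
        assert table["score"].iloc[0] == table["score"].iloc[1]

    def test_rank_only_at_alpha_zero_invariant_to_monotone_transform(self):
        rng = np.random.default_rng(6)
        genes = [f"g{i}" for i in range(20)]
        values = rng.random((20, 1)) * 4
        gs = GeneSet("s", "", tuple(genes[:5]))
        a = ssgsea_score(make_expression(values, gene_ids=genes), gs,
                         alpha=0.0, normalize=False)["score"].iloc[0]
        b = ssgsea_score(make_expression(np.exp(values), gene_ids=genes), gs,
                         alpha=0.0, normalize=False)["score"].iloc[0]
        assert a == pytest.approx(b, abs=1e-12)

    def test_gene_permutation_invariance(self):
        rng = np.random.default_rng(7)
        genes = [f"g{i}" for i in range(15)]
        values = rng.integers(0, 6, size=(15, 2)).astype(float)
        gs = GeneSet("s", "", tuple(genes[:4]))
        base = ssgsea_score(make_expression(values, gene_ids=genes), gs,
                            normalize=False)["score"].to_numpy()
        perm = rng.permutation(15)
        shuffled = make_expression(values[perm], gene_ids=[genes[i] for i in perm])
        out = ssgsea_score(shuffled, gs, normalize=False)["score"].to_numpy()
        np.testing.assert_allclose(out, base, atol=1e-12)

    def test_normalization_divides_by_range(self):
        rng = np.random.default_rng(8)
        genes = [f"g{i}" for i in range(10)]
        values = rng.random((10, 4))
        gs = GeneSet("s", "", tuple(genes[:3]))
        raw = ssgsea_score(make_expression(values, gene_ids=genes), gs,
                           normalize=False)["score"].to_numpy()
        norm = ssgsea_score(make_expression(values, gene_ids=genes), gs,
                            normalize=True)["score"].to_numpy()
        np.testing.assert_allclose(norm, raw / (raw.max() - raw.min()), atol=1e-12)

    def test_full_coverage_set_rejected(self):
        expr, genes = self._toy()
        with pytest.raises(ValueError, match="every gene"):
            ssgsea_score(expr, GeneSet("all", "", tuple(genes)))

    def test_constant_sample_scores_zero_with_warning(self):
        genes = [f"g{i}" for i in range(5)]
        expr = make_expression(np.ones((5, 1)), gene_ids=genes)
        with pytest.warns(UserWarning, match="constant"):
            table = ssgsea_score(expr, GeneSet("s", "", tuple(genes[:2])),
                                 normalize=False)
        assert table["score"].iloc[0] == 0.0
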