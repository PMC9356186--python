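import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cdk9sig.genesets import (
    GeneSet,
    GseaParams,
    Signature,
    derive_signature,
    expression_filter,
    gene_set_fc_comparison,
    gsva_scores,
    preranked_gsea,
    preranked_gsea_multi,
    rank_genes,
    read_gmt,
    write_gmt,
)

from . import _oracles
from .conftest import make_de_frame


def random_expr(rng, p=10, n=4):
    genes = [f"g{i:03d}" for i in range(p)]
    return pd.DataFrame(rng.normal(size=(p, n)), index=genes,
                        columns=[f"s{j}" for j in range(n)])


class TestGmtIO:
    def test_roundtrip(self, tmp_path):
        sets = [GeneSet("a", ("g1", "g2")), GeneSet("b", ("g3",))]
        write_gmt(sets, tmp_path / "x.gmt")
        back = read_gmt(tmp_path / "x.gmt")
        assert [(s.name, s.members) for s in back] == [(s.name, s.members) for s in sets]

    def test_short_line_rejected(self, tmp_path):
        (tmp_path / "bad.gmt").write_text("onlyname\tdesc\n")
        with pytest.raises(ValueError):
            read_gmt(tmp_path / "bad.gmt")

    def test_duplicate_members_rejected(self):
        with pytest.raises(ValueError):
            GeneSet("a", ("g1", "g1"))


class TestDeriveSignature:
    def test_capacity_reached_with_ample_candidates(self, rng):
        lfc = np.concatenate([-rng.uniform(0.5, 5, 400), rng.normal(0, 0.01, 600)])
        fdr = np.concatenate([np.full(400, 0.001), np.full(600, 0.5)])
        de = make_de_frame(lfc, fdr=fdr)
        sig = derive_signature(de)
        assert len(sig.repressed) == 250
        assert len(sig.insensitive) == 110

    def test_capacity_limited_by_qualifiers(self, rng):
        lfc = np.concatenate([-rng.uniform(0.5, 5, 100), rng.normal(0, 0.01, 200)])
        fdr = np.concatenate([np.full(100, 0.001), np.full(200, 0.5)])
        sig = derive_signature(make_de_frame(lfc, fdr=fdr))
        assert len(sig.repressed) == 100

    def test_most_repressed_selected(self):
        lfc = [-5.0, -1.0, -3.0, 0.0]
        de = make_de_frame(lfc, fdr=[0.001] * 4, genes=list("abcd"))
        sig = derive_signature(de, n_sig=2, n_ctrl=1)
        assert set(sig.repressed.members) == {"a", "c"}

    def test_insensitive_prefers_exact_zero_then_nearest(self):
        de = make_de_frame([0.0, 1e-9, 0.05, -0.02, 2.0],
                           fdr=[0.9] * 5, genes=list("abcde"))
        sig = derive_signature(de, n_ctrl=3)
        assert set(sig.insensitive.members) == {"a", "b", "d"}

    def test_rederivation_is_stable(self, treatment_de):
        de = treatment_de["treatment_rs"]
        s1 = derive_signature(de, n_sig=50, n_ctrl=20)
        s2 = derive_signature(de.sample(frac=1, random_state=0), n_sig=50, n_ctrl=20)
        assert s1.repressed.members == s2.repressed.members
        assert s1.insensitive.members == s2.insensitive.members

    def test_sets_disjoint(self, treatment_de):
        sig = derive_signature(treatment_de["treatment_rs"], n_sig=100, n_ctrl=50)
        assert not set(sig.repressed.members) & set(sig.insensitive.members)

    def test_no_qualifier_warns_and_empties(self, caplog):
        de = make_de_frame([1.0, -1.0], fdr=[0.9, 0.9])
        sig = derive_signature(de)
        assert len(sig.repressed) == 0


class TestGsvaScores:
    def test_matches_brute_force_transcription(self, rng):
        expr = random_expr(rng, p=10, n=4)
        gs = GeneSet("s", ("g001", "g004", "g007"))
        ours = gsva_scores(expr, [gs])
        oracle = _oracles.gsva_scores(
            expr.to_numpy().tolist(), list(expr.index), list(expr.columns),
            list(gs.members),
        )
        for sample in expr.columns:
            assert ours.loc["s", sample] == pytest.approx(oracle[sample], abs=1e-9)

    def test_scores_bounded(self, rng):
        for _ in range(50):
            p = int(rng.integers(5, 30))
            n = int(rng.integers(3, 8))
            expr = random_expr(rng, p, n)
            k = int(rng.integers(1, p - 1))
            gs = GeneSet("s", tuple(rng.choice(expr.index, k, replace=False)))
            sc = gsva_scores(expr, [gs])
            assert (sc.abs() <= 1 + 1e-12).all().all()

    def test_top_and_complement_sign_symmetry(self):
        rng = np.random.default_rng(3)
        expr = random_expr(rng, p=12, n=4)
        # one sample where g000..g003 clearly top-ranked
        expr.iloc[:4, 0] += 10
        top = GeneSet("top", tuple(expr.index[:4]))
        rest = GeneSet("rest", tuple(expr.index[4:]))
        sc = gsva_scores(expr, [top, rest])
        assert sc.loc["top", "s0"] > 0
        assert sc.loc["rest", "s0"] < 0

    def test_invariant_to_gene_and_sample_permutation(self, rng):
        expr = random_expr(rng, p=15, n=5)
        gs = GeneSet("s", ("g002", "g009", "g013"))
        base = gsva_scores(expr, [gs])
        perm = expr.sample(frac=1, random_state=1)[
            list(rng.permutation(expr.columns))
        ]
        shuffled = gsva_scores(perm, [gs])
        for c in expr.columns:
            assert shuffled.loc["s", c] == pytest.approx(base.loc["s", c], abs=1e-12)

    def test_location_invariance_per_gene(self, rng):
        expr = random_expr(rng, p=10, n=4)
        gs = GeneSet("s", ("g001", "g005"))
        base = gsva_scores(expr, [gs])
        expr2 = expr.copy()
        expr2.loc["g005"] += 100.0  # constant offset, same gene everywhere
        shifted = gsva_scores(expr2, [gs])
        pd.testing.assert_frame_equal(base, shifted)

    def test_zero_variance_gene_warns(self, rng, caplog):
        expr = random_expr(rng, p=6, n=4)
        expr.loc["g000"] = 2.5
        with caplog.at_level("WARNING"):
            gsva_scores(expr, [GeneSet("s", ("g001", "g002"))])
        assert any("zero-variance" in r.message for r in caplog.records)

    def test_no_overlap_gives_na_row(self, rng):
        expr = random_expr(rng)
        sc = gsva_scores(expr, [GeneSet("s", ("absent",))])
        assert sc.loc["s"].isna().all()

    def test_too_few_samples_rejected(self, rng):
        expr = random_expr(rng, p=5, n=2)
        with pytest.raises(ValueError):
            gsva_scores(expr, [GeneSet("s", ("g001",))])


class TestRankGenes:
    def test_metric_arithmetic(self):
        de = make_de_frame([-1.5, 2.0], wald_p=[0.01, 0.001], genes=["down", "up"])
        ranked = rank_genes(de)
        assert ranked["down"] == pytest.approx(-2.0)
        assert ranked["up"] == pytest.approx(3.0)
        assert list(ranked.index) == ["up", "down"]

    def test_ties_break_by_gene_id(self):
        de = make_de_frame([1.0, 1.0, 1.0], wald_p=[0.1] * 3, genes=["c", "a", "b"])
        assert list(rank_genes(de).index) == ["a", "b", "c"]


class TestPrerankedGsea:
    def test_top_set_maximally_enriched(self, rng):
        ranked = pd.Series(np.linspace(5, -5, 100),
                           index=[f"g{i:03d}" for i in range(100)])
        gs = GeneSet("top", tuple(ranked.index[:10]))
        res = preranked_gsea(ranked, gs, GseaParams(n_permutations=500, seed=2))
        assert res.es > 0
        assert res.p_value <= 1 / 501 + 1e-12

    def test_es_matches_oracle(self, rng):
        scores = np.sort(rng.normal(size=40))[::-1]
        ranked = pd.Series(scores, index=[f"g{i:03d}" for i in range(40)])
        members = tuple(rng.choice(ranked.index, 8, replace=False))
        res = preranked_gsea(ranked, GeneSet("s", members),
                             GseaParams(n_permutations=100, seed=0))
        mask = [g in set(members) for g in ranked.index]
        assert res.es == pytest.approx(_oracles.gsea_es(list(scores), mask, 1.0),
                                       abs=1e-12)

    def test_unweighted_complement_antisymmetry(self, rng):
        scores = np.sort(rng.normal(size=12))[::-1]
        ranked = pd.Series(scores, index=[f"g{i:02d}" for i in range(12)])
        members = tuple(ranked.index[[0, 3, 7]])
        comp = tuple(g for g in ranked.index if g not in members)
        params = GseaParams(weight_exponent=0.0, n_permutations=100, seed=0)
        es_set = preranked_gsea(ranked, GeneSet("s", members), params).es
        es_comp = preranked_gsea(ranked, GeneSet("c", comp), params).es
        assert es_set == pytest.approx(-es_comp, abs=1e-12)

    def test_sampled_p_matches_exhaustive_enumeration(self, rng):
        scores = np.sort(rng.normal(size=8))[::-1]
        ranked = pd.Series(scores, index=[f"g{i}" for i in range(8)])
        members = tuple(ranked.index[[0, 2, 5]])
        res = preranked_gsea(ranked, GeneSet("s", members),
                             GseaParams(n_permutations=2000, seed=5))
        p_exact = _oracles.gsea_exhaustive_p(list(scores), 3, abs(res.es), 1.0)
        half = 2.576 * np.sqrt(p_exact * (1 - p_exact) / 2000)
        assert abs(res.p_value - p_exact) <= half + 1 / 2001

    def test_leading_edge_subset_of_members(self, rng):
        ranked = pd.Series(np.linspace(3, -3, 50),
                           index=[f"g{i:03d}" for i in range(50)])
        members = tuple(ranked.index[[1, 4, 9, 40]])
        res = preranked_gsea(ranked, GeneSet("s", members),
                             GseaParams(n_permutations=100, seed=0))
        assert set(res.leading_edge) <= set(members)
        assert res.leading_edge  # never empty: the peak includes >= 1 member

    def test_multi_set_bh_adjusted(self, rng):
        ranked = pd.Series(np.linspace(3, -3, 60),
                           index=[f"g{i:03d}" for i in range(60)])
        sets = [GeneSet("top", tuple(ranked.index[:6])),
                GeneSet("rand", tuple(ranked.index[[5, 17, 33, 50]]))]
        table = preranked_gsea_multi(ranked, sets, GseaParams(n_permutations=200, seed=3))
        assert (table["fdr"] >= table["p_value"] - 1e-15).all()

    def test_oversized_set_rejected(self, rng):
        ranked = pd.Series([1.0, 0.5], index=["a", "b"])
        with pytest.raises(ValueError):
            preranked_gsea(ranked, GeneSet("s", ("a", "b", "c")),
                           GseaParams(n_permutations=100))


class TestExpressionFilter:
    def test_requires_both_arms(self):
        counts = pd.DataFrame(
            {"u1": [5, 100], "u2": [5, 100], "t1": [20, 100], "t2": [20, 100]},
            index=["low_untreated", "ok"],
        )
        lengths = pd.Series([1000, 1000], index=counts.index)
        # low_untreated: FPKM ~4.8e4 untreated / ~1.7e5 treated; passing the
        # treated arm alone must not rescue it
        kept = expression_filter(counts, ["u1", "u2"], ["t1", "t2"],
                                 gene_lengths=lengths, threshold=1e5)
        assert list(kept) == ["ok"]

    def test_boundary_inclusive(self):
        counts = pd.DataFrame({"u": [10, 990], "t": [10, 990]}, index=["edge", "big"])
        lengths = pd.Series([10_000, 1000], index=counts.index)
        # edge gene: 10 / (0.01 kb-denominator...) chosen to land exactly on
        # threshold = fpkm of the edge gene
        fpkm_edge = 10 / (10 / 1e3) / (1000 / 1e6) / 1e3  # reads/(kb * M reads)
        kept = expression_filter(counts, ["u"], ["t"], gene_lengths=lengths,
                                 threshold=fpkm_edge)
        assert "edge" in list(kept)

    def test_matches_brute_force(self, rng):
        counts = pd.DataFrame(
            rng.integers(0, 300, size=(1000, 4)),
            index=[f"g{i:04d}" for i in range(1000)],
            columns=["u1", "u2", "t1", "t2"],
        )
        lengths = pd.Series(rng.integers(200, 5000, size=1000), index=counts.index)
        kept = expression_filter(counts, ["u1", "u2"], ["t1", "t2"],
                                 gene_lengths=lengths, threshold=1.0)
        totals = counts.sum(axis=0)
        expected = []
        for g in counts.index:
            fpkm = {
                s: counts.loc[g, s] / (totals[s] / 1e6) / (lengths[g] / 1e3)
                for s in counts.columns
            }
            if (fpkm["u1"] + fpkm["u2"]) / 2 >= 1.0 and (fpkm["t1"] + fpkm["t2"]) / 2 >= 1.0:
                expected.append(g)
        assert list(kept) == expected


class TestGeneSetFcComparison:
    def test_identical_sets_p_one(self):
        de = make_de_frame([1.0, 2.0, 3.0], genes=list("abc"))
        gs = GeneSet("s", ("a", "b", "c"))
        res = gene_set_fc_comparison(de, gs, GeneSet("t", ("a", "b", "c")))
        assert res.p_value == pytest.approx(1.0)

    def test_u_matches_pair_count(self, rng):
        lfc = np.round(rng.normal(size=46), 1)
        genes = [f"g{i:02d}" for i in range(46)]
        de = make_de_frame(lfc, genes=genes)
        a = GeneSet("naive", tuple(genes[:19]))
        b = GeneSet("memory", tuple(genes[19:]))
        res = gene_set_fc_comparison(de, a, b)
        assert res.u_statistic == pytest.approx(
            _oracles.mann_whitney_u(list(lfc[:19]), list(lfc[19:]))
        )

    def test_shifted_set_detected_at_fig_sizes(self, rng):
        lfc = np.concatenate([rng.normal(0, 0.5, 19), rng.normal(1.0, 0.5, 27)])
        genes = [f"g{i:02d}" for i in range(46)]
        de = make_de_frame(lfc, genes=genes)
        res = gene_set_fc_comparison(
            de, GeneSet("naive", tuple(genes[:19])), GeneSet("memory", tuple(genes[19:]))
        )
        assert res.p_value < 0.01

    def test_empty_intersection_rejected(self):
        de = make_de_frame([1.0], genes=["a"])
        with pytest.raises(ValueError):
            gene_set_fc_comparison(de, GeneSet("s", ("zz",)), GeneSet("t", ("a",)))


@settings(max_examples=25, deadline=None)
@given(st.integers(min_value=0, max_value=2**31 - 1))
def test_gsva_bounds_property(seed):
    """|ES| <= 1 for arbitrary random instances (seeded hypothesis sweep)."""
    rng = np.random.default_rng(seed)
    p = int(rng.integers(4, 25))
    n = int(rng.integers(3, 7))
    expr = random_expr(rng, p, n)
    k = int(rng.integers(1, p))
    gs = GeneSet("s", tuple(rng.choice(expr.index, k, replace=False)))
    if k == p:
        return
    sc = gsva_scores(expr, [gs])
    assert (sc.abs() <= 1 + 1e-12).all().all()
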