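import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from cardiosnv import functional, synthetic


@pytest.fixture(scope="module")
def annotated_genome():
    ref = synthetic.generate_reference(1, 1_000_000, 0.45, seed=200)
    genes, cds = synthetic.generate_annotation(ref, n_genes=50, seed=201)
    return ref, genes, cds


def _variant(chrom, pos, ref_base, alt):
    return pd.DataFrame({"chrom": [chrom], "pos": [pos], "ref": [ref_base], "alt": [alt]})


class TestGenicAnnotation:
    def test_constructed_codon_effects(self):
        # gene on +: CDS 10..19 (9 bp) codes ATG GAA TGG -> M E W
        seq = "x" * 10 + "ATGGAATGG" + "x" * 10
        seq = seq.replace("x", "A")
        ref = synthetic.ReferenceGenome(["c1"], [seq])
        genes = pd.DataFrame(
            [{"gene_id": "g", "chrom": "c1", "strand": "+", "start": 5, "end": 25}]
        )
        cds = pd.DataFrame([{"gene_id": "g", "start": 10, "end": 19}])
        # TGG -> TGA : stopgain at third position of codon 3 (pos 18)
        out = functional.annotate_genic(_variant("c1", 18, "G", "A"), genes, cds, ref)
        assert out.iloc[0] == "exonic-stopgain"
        # GAA -> GAG (Glu): synonymous third-position change (pos 15)
        out = functional.annotate_genic(_variant("c1", 15, "A", "G"), genes, cds, ref)
        assert out.iloc[0] == "exonic-synonymous"
        # ATG -> GTG (Met->Val): nonsynonymous (pos 10)
        out = functional.annotate_genic(_variant("c1", 10, "A", "G"), genes, cds, ref)
        assert out.iloc[0] == "exonic-nonsynonymous"
        # inside transcript, before CDS -> UTR; outside transcript -> intergenic
        assert functional.annotate_genic(_variant("c1", 7, "A", "C"), genes, cds, ref).iloc[0] == "UTR"
        assert functional.annotate_genic(_variant("c1", 3, "A", "C"), genes, cds, ref).iloc[0] == "intergenic"

    def test_minus_strand_gene(self):
        # gene on -: genomic CAT at 10..13 reads ATG on the coding strand
        seq = "A" * 10 + "CAT" + "A" * 10
        ref = synthetic.ReferenceGenome(["c1"], [seq])
        genes = pd.DataFrame(
            [{"gene_id": "g", "chrom": "c1", "strand": "-", "start": 8, "end": 16}]
        )
        cds = pd.DataFrame([{"gene_id": "g", "start": 10, "end": 13}])
        # genomic C>T at pos 10 -> coding ATG -> ATA (Met->Ile): nonsynonymous
        out = functional.annotate_genic(_variant("c1", 10, "C", "T"), genes, cds, ref)
        assert out.iloc[0] == "exonic-nonsynonymous"

    def test_intronic(self, annotated_genome):
        ref, genes, cds = annotated_genome
        g = genes.iloc[0]
        sub = cds[cds["gene_id"] == g["gene_id"]].sort_values("start")
        gap_pos = int(sub.iloc[0]["end"]) + 1  # between first and second CDS
        base = ref.sequences[g["chrom"]][gap_pos]
        alt = "A" if base != "A" else "C"
        out = functional.annotate_genic(
            _variant(g["chrom"], gap_pos, base, alt), genes, cds, ref
        )
        assert out.iloc[0] == "intronic"

    def test_frame_violation_rejected(self):
        ref = synthetic.ReferenceGenome(["c1"], ["A" * 30])
        genes = pd.DataFrame(
            [{"gene_id": "g", "chrom": "c1", "strand": "+", "start": 0, "end": 20}]
        )
        cds = pd.DataFrame([{"gene_id": "g", "start": 5, "end": 9}])  # 4 bp
        with pytest.raises(ValueError):
            functional.annotate_genic(_variant("c1", 6, "A", "C"), genes, cds, ref)


def _fisher_enumeration(table):
    """Two-sided Fisher p by full enumeration of tables with fixed margins."""
    (a, b), (c, d) = table
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2

    def prob(x):
        return (
            math.comb(r1, x) * math.comb(r2, c1 - x) / math.comb(n, c1)
        )
    p_obs = prob(a)
    total = 0.0
    for x in range(max(0, c1 - r2), min(r1, c1) + 1):
        p = prob(x)
        if p <= p_obs * (1 + 1e-9):
            total += p
    return total


class TestExcessTest:
    def test_identity_table(self):
        orr, p = functional.excess_test((1, 0), (0, 1))
        assert p == pytest.approx(1.0)

    def test_transposition_symmetry(self):
        o1, p1 = functional.excess_test((7, 3), (3, 7))
        o2, p2 = functional.excess_test((3, 7), (7, 3))
        assert p1 == pytest.approx(p2)
        assert o1 == pytest.approx(1 / o2, rel=1e-6)

    def test_matches_enumeration_oracle(self):
        """Exact agreement with brute-force enumeration, totals <= 20."""
        for a, b, c, d in itertools.product(range(1, 5), repeat=4):
            if a + b + c + d > 20:
                continue
            _, p = functional.excess_test((a, b), (c, d))
            assert p == pytest.approx(_fisher_enumeration(((a, b), (c, d))), abs=1e-10)

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError):
            functional.excess_test((0, 0), (3, 4))


class TestQuartiles:
    def test_ties_take_lower_quartile(self):
        expr = pd.Series([1.0, 1.0, 1.0, 1.0, 2.0, 3.0, 4.0, 5.0],
                         index=[f"g{i}" for i in range(8)])
        q = functional.expression_quartiles(expr)
        assert list(q[:4]) == [1, 1, 2, 2]  # ties fill lower quartiles first

    def test_degenerate_expression_rejected(self):
        expr = pd.Series(np.ones(8), index=[f"g{i}" for i in range(8)])
        with pytest.raises(ValueError):
            functional.expression_quartiles(expr)


class TestQuartileAssociation:
    def _setup(self, n=40, length=1000):
        genes = pd.DataFrame({
            "gene_id": [f"g{i}" for i in range(n)],
            "chrom": "c1", "strand": "+",
            "start": np.arange(n) * 2 * length,
            "end": np.arange(n) * 2 * length + length,
        })
        expr = pd.Series(np.arange(n, dtype=float), index=genes["gene_id"])
        return genes, expr

    def test_variants_only_in_top_quartile(self):
        genes, expr = self._setup()
        top = expr.nlargest(5).index
        vg = pd.Series(list(top) * 3)
        out = functional.quartile_association(vg, genes, expr, n_perm=50, seed=0)
        assert out.loc[out["quartile"] == 4, "density"].iloc[0] > 0
        assert (out.loc[out["quartile"] != 4, "density"] == 0).all()

    def test_length_homogeneity(self):
        genes, expr = self._setup()
        vg = pd.Series(["g1", "g5", "g30"])
        out1 = functional.quartile_association(vg, genes, expr, n_perm=10, seed=0)
        genes2 = genes.assign(end=genes["start"] + 2 * (genes["end"] - genes["start"]))
        out2 = functional.quartile_association(vg, genes2, expr, n_perm=10, seed=0)
        assert np.allclose(out2["density"], out1["density"] / 2)

    def test_permutation_sd_stabilizes(self):
        genes, expr = self._setup()
        rng = np.random.default_rng(3)
        vg = pd.Series(rng.choice(genes["gene_id"], 60))
        a = functional.quartile_association(vg, genes, expr, n_perm=500, seed=1)
        b = functional.quartile_association(vg, genes, expr, n_perm=1000, seed=2)
        rel = np.abs(b["perm_sd"] - a["perm_sd"]) / a["perm_sd"]
        assert (rel < 0.10).all()

    def test_uniform_placement_null(self):
        genes, expr = self._setup()
        rng = np.random.default_rng(4)
        vg = pd.Series(rng.choice(genes["gene_id"], 200))
        out = functional.quartile_association(vg, genes, expr, n_perm=300, seed=5)
        z = (out["density"] - out["density"].mean()) / out["perm_sd"]
        assert (np.abs(z) < 3).all()


class TestGenesetEnrichment:
    def test_equal_lengths_reduce_to_hypergeometric(self):
        """With equal gene lengths the Wallenius odds are 1 and the p-value
        equals the exact hypergeometric tail (checked by enumeration)."""
        genes = [f"g{i}" for i in range(15)]
        lengths = pd.Series(1000.0, index=genes)
        sets = {"s1": genes[:6], "rest": genes}
        mutated = pd.Series([1, 1, 1, 1, 0, 0] + [0] * 7 + [1, 0], index=genes)
        out = functional.geneset_enrichment(mutated, sets, lengths, min_mutated=1)
        row = out[out["set_id"] == "s1"].iloc[0]
        M, n, N, x = 15, 6, int(mutated.sum()), 4
        p_enum = sum(
            math.comb(n, k) * math.comb(M - n, N - k) / math.comb(M, N)
            for k in range(x, min(n, N) + 1)
        )
        assert row["p"] == pytest.approx(p_enum, rel=1e-6)

    def test_sparse_sets_excluded(self):
        genes = [f"g{i}" for i in range(30)]
        lengths = pd.Series(1000.0, index=genes)
        sets = {"tiny": genes[:6], "ok": genes[5:25]}
        mutated = pd.Series([1, 0, 0, 0, 0, 1] + [1] * 10 + [0] * 14, index=genes)
        out = functional.geneset_enrichment(mutated, sets, lengths, min_mutated=5)
        assert "tiny" not in set(out["set_id"])

    def test_oversize_sets_excluded(self):
        genes = [f"g{i}" for i in range(40)]
        lengths = pd.Series(1000.0, index=genes)
        sets = {"big": genes}
        mutated = pd.Series(1, index=genes)
        out = functional.geneset_enrichment(mutated, sets, lengths, max_size=30)
        assert len(out) == 0

    def test_synthetic_enrichment_detected(self):
        """A 5x in-set mutation rate on 5000 genes is detected at p < 0.01."""
        rng = np.random.default_rng(6)
        genes = [f"g{i}" for i in range(5000)]
        lengths = pd.Series(rng.uniform(500, 50_000, 5000), index=genes)
        in_set = genes[:50]
        base = 500 / 5000
        p_mut = np.full(5000, base * lengths.to_numpy() / lengths.mean())
        p_mut[:50] *= 5
        mutated = pd.Series(rng.random(5000) < np.clip(p_mut, 0, 1), index=genes).astype(int)
        sets = {"target": in_set, "all": genes}
        out = functional.geneset_enrichment(mutated, sets, lengths)
        assert out[out["set_id"] == "target"]["p"].iloc[0] < 0.01


class TestBHFDR:
    def test_matches_step_up_definition(self):
        p = np.array([0.001, 0.01, 0.02, 0.04, 0.9])
        # hand step-up: q_i = min_{j>=i} (m p_(j) / j)
        m = len(p)
        expected = [min(m * p[j] / (j + 1) for j in range(i, m)) for i in range(m)]
        assert np.allclose(functional.bh_fdr(p), expected)

    def test_monotone_in_inputs(self):
        rng = np.random.default_rng(7)
        p = np.sort(rng.random(10))
        q = functional.bh_fdr(p)
        assert (np.diff(q) >= -1e-12).all()


class TestRankDifference:
    def _universe(self, rng, n=400, n_sets=8, set_size=40):
        genes = [f"g{i}" for i in range(n)]
        lengths = pd.Series(2000.0, index=genes)
        sets = {
            f"s{k}": list(rng.choice(genes, set_size, replace=False))
            for k in range(n_sets)
        }
        return genes, lengths, sets

    def test_identical_tables_give_no_signal(self):
        rng = np.random.default_rng(8)
        genes, lengths, sets = self._universe(rng)
        tab = pd.Series(rng.random(len(genes)) < 0.3, index=genes).astype(int)
        out = functional.rank_difference_permutation(
            tab, tab.copy(), sets, lengths, n_perm=100, candidate_alpha=1.1
        )
        assert (out["rank_diff"] == 0).all()
        assert (out["p_perm"] >= 1 / 101).all()
        assert (out["fdr"] >= 0.4).all()

    def test_set_enriched_only_in_a_detected(self):
        """One set enriched 5x in table A only stands out against shared-
        signal candidate sets; the statistic needs several candidates to
        rank, so the background sets carry moderate enrichment in both."""
        rng = np.random.default_rng(9)
        genes, lengths, sets = self._universe(rng, n=2000, n_sets=60, set_size=25)
        # a broad annotation term defines the universe (itself too large to
        # be tested, mirroring the exclusion of huge ontology terms)
        sets["catchall"] = list(genes)
        base_a = pd.Series(rng.random(len(genes)) < 0.08, index=genes).astype(int)
        base_b = pd.Series(rng.random(len(genes)) < 0.08, index=genes).astype(int)
        for k in range(1, 60):  # candidates enriched in both cell types
            members = sets[f"s{k}"]
            shared = (rng.random(len(members)) < 0.5).astype(int)
            base_a.loc[members] = np.maximum(base_a.loc[members].to_numpy(), shared)
            base_b.loc[members] = np.maximum(base_b.loc[members].to_numpy(), shared)
        target = sets["s0"]  # A-specific signal, strong enough to rank first
        base_a.loc[target] = np.maximum(
            base_a.loc[target].to_numpy(), (rng.random(len(target)) < 0.95).astype(int)
        )
        out = functional.rank_difference_permutation(
            base_a, base_b, sets, lengths, n_perm=6000, seed=10
        )
        row = out[out["set_id"] == "s0"]
        assert len(row) == 1
        assert row["fdr"].iloc[0] < 0.05
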