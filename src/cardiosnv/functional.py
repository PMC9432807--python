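"""Functional impact of somatic SNVs.

Codon-aware genic annotation against simple gene models (one transcript per
gene), excess-burden tests versus germline variants, expression-quartile
association with permutation uncertainty, and gene-set enrichment using the
Wallenius noncentral hypergeometric with a monotone gene-length weighting
function, plus the two-cell-type rank-difference permutation test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio.Seq import Seq
from scipy import stats
from sklearn.isotonic import IsotonicRegression
from statsmodels.stats.multitest import multipletests

from .contexts import revcomp

SEVERITY = [
    "exonic-stopgain",
    "exonic-nonsynonymous",
    "exonic-synonymous",
    "UTR",
    "intronic",
    "intergenic",
]


def _coding_effect(cds_seq: str, cds_index: int, alt_coding_base: str) -> str:
    codon_start = 3 * (cds_index // 3)
    codon = cds_seq[codon_start:codon_start + 3]
    if len(codon) < 3:
        return "exonic-synonymous"  # trailing partial codon: treat as silent
    off = cds_index - codon_start
    mutated = codon[:off] + alt_coding_base + codon[off + 1:]
    aa0 = str(Seq(codon).translate())
    aa1 = str(Seq(mutated).translate())
    if aa1 == "*" and aa0 != "*":
        return "exonic-stopgain"
    if aa1 != aa0:
        return "exonic-nonsynonymous"
    return "exonic-synonymous"


def annotate_genic(
    variants: pd.DataFrame,
    genes: pd.DataFrame,
    cds: pd.DataFrame,
    reference,
) -> pd.Series:
    """Genic category per variant (most severe across overlapping genes).

    ``genes``: gene_id, chrom, strand, start, end (transcript span, 0-based
    half-open). ``cds``: gene_id, start, end intervals; their total length
    must be a multiple of 3 per gene. ``reference`` provides sequences.
    """
    cds_by_gene = {g: sub.sort_values("start") for g, sub in cds.groupby("gene_id")}
    for g, sub in cds_by_gene.items():
        if int((sub["end"] - sub["start"]).sum()) % 3 != 0:
            raise ValueError(f"CDS length of {g} not a multiple of 3")
    out = []
    for _, v in variants.iterrows():
        chrom, pos, alt = v["chrom"], int(v["pos"]), v["alt"]
        seq = reference.sequences[chrom]
        overlapping = genes[
            (genes["chrom"] == chrom) & (genes["start"] <= pos) & (pos < genes["end"])
        ]
        best = "intergenic"
        for _, g in overlapping.iterrows():
            sub = cds_by_gene.get(g["gene_id"])
            cat = "UTR"
            if sub is not None and len(sub):
                starts = sub["start"].to_numpy()
                ends = sub["end"].to_numpy()
                inside = (starts <= pos) & (pos < ends)
                if inside.any():
                    i = int(np.where(inside)[0][0])
                    offset = int((ends[:i] - starts[:i]).sum() + pos - starts[i])
                    coding = "".join(seq[s:e] for s, e in zip(starts, ends))
                    if g["strand"] == "+":
                        cat = _coding_effect(coding, offset, alt)
                    else:
                        coding_rc = revcomp(coding)
                        idx = len(coding) - 1 - offset
                        from .contexts import COMPLEMENT

                        cat = _coding_effect(coding_rc, idx, COMPLEMENT[alt])
                elif starts[0] <= pos < ends[-1]:
                    cat = "intronic"
                else:
                    cat = "UTR"
            if SEVERITY.index(cat) < SEVERITY.index(best):
                best = cat
        out.append(best)
    return pd.Series(out, index=variants.index, name="genic_category")


def excess_test(somatic_counts: tuple[int, int], germline_counts: tuple[int, int]):
    """Two-tailed Fisher's exact test of category excess.

    Each tuple is (in-category, not-in-category). Returns (conditional-MLE
    odds ratio, two-sided p).
    """
    table = np.array([somatic_counts, germline_counts])
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError("zero margin in 2x2 table")
    res = stats.fisher_exact(table, alternative="two-sided")
    orr = stats.contingency.odds_ratio(table, kind="conditional")
    return float(orr.statistic), float(res.pvalue)


def expression_quartiles(expression: pd.Series) -> pd.Series:
    """Quartile label (1..4) per gene by expression; ties take the lower quartile."""
    if expression.nunique() == 1:
        raise ValueError("all expression values equal: quartiles degenerate")
    order = np.argsort(expression.to_numpy(), kind="stable")
    n = len(expression)
    q = np.empty(n, dtype=np.int64)
    q[order] = 1 + (np.arange(n) * 4) // n
    return pd.Series(q, index=expression.index, name="quartile")


def quartile_association(
    variant_genes: pd.Series,
    genes: pd.DataFrame,
    expression: pd.Series,
    mean_power: float = 1.0,
    n_perm: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-expression-quartile sSNV density with permutation s.d.

    ``variant_genes``: gene_id per genic variant (one row per variant).
    Density_q = (# variants in quartile-q genes) / (total gene length in q
    x mean per-cell detection power); the s.d. comes from ``n_perm`` random
    shuffles of the quartile labels.
    """
    if len(genes) < 40:
        raise ValueError("need >= 40 genes")
    expr = expression.reindex(genes["gene_id"]).astype(float)
    if expr.isna().any() or not np.isfinite(expr).all():
        raise ValueError("expression must be finite for every gene")
    quart = expression_quartiles(expr)
    lengths = pd.Series(
        (genes["end"] - genes["start"]).to_numpy(), index=genes["gene_id"], dtype=float
    )
    counts = variant_genes.value_counts()
    gene_counts = counts.reindex(lengths.index, fill_value=0).to_numpy(dtype=float)
    L = lengths.to_numpy()
    qlab = quart.to_numpy()

    def densities(q):
        return np.array([
            gene_counts[q == k].sum() / (L[q == k].sum() * mean_power)
            for k in (1, 2, 3, 4)
        ])

    obs = densities(qlab)
    rng = np.random.default_rng(seed)
    perm = np.empty((n_perm, 4))
    for i in range(n_perm):
        perm[i] = densities(rng.permutation(qlab))
    return pd.DataFrame({
        "quartile": [1, 2, 3, 4],
        "n_genes": [(qlab == k).sum() for k in (1, 2, 3, 4)],
        "total_length": [L[qlab == k].sum() for k in (1, 2, 3, 4)],
        "n_variants": [gene_counts[qlab == k].sum() for k in (1, 2, 3, 4)],
        "density": obs,
        "perm_sd": perm.std(axis=0, ddof=1),
    })


def _length_weights(mutated: np.ndarray, lengths: np.ndarray) -> np.ndarray:
    """Monotone probability-weighting function of gene length.

    Isotonic (monotone non-decreasing) fit of the mutation indicator on log
    length, floored away from zero so every gene keeps positive weight.
    """
    iso = IsotonicRegression(increasing=True, out_of_bounds="clip")
    w = iso.fit_transform(np.log(lengths + 1.0), mutated.astype(float))
    return np.maximum(w, 1e-6)


def geneset_enrichment(
    table: pd.Series,
    sets: dict[str, list[str]],
    gene_lengths: pd.Series,
    min_mutated: int = 5,
    max_size: int = 1000,
) -> pd.DataFrame:
    """Length-aware gene-set enrichment (Wallenius approximation).

    ``table`` is the binary mutated-gene indicator over the gene universe
    (genes with at least one set membership). Per-set odds = mean weight of
    member genes / mean weight of non-members; p is the upper tail of the
    Wallenius noncentral hypergeometric. Sets with more than ``max_size``
    members or fewer than ``min_mutated`` mutated members are excluded.
    """
    universe = sorted({g for gs in sets.values() for g in gs} & set(table.index))
    if not universe:
        raise ValueError("empty gene universe")
    tab = table.reindex(universe).fillna(0).astype(int)
    lengths = gene_lengths.reindex(universe).astype(float)
    mutated = tab.to_numpy()
    w = pd.Series(_length_weights(mutated, lengths.to_numpy()), index=universe)
    M = len(universe)
    N = int(mutated.sum())
    rows = []
    for set_id, members in sets.items():
        mem = [g for g in members if g in tab.index]
        n = len(mem)
        if n == 0 or n > max_size:
            continue
        x = int(tab.loc[mem].sum())
        if x < min_mutated:
            continue
        w_in = w.loc[mem].mean()
        out_mask = ~w.index.isin(mem)
        w_out = w.loc[out_mask].mean() if out_mask.any() else w_in
        odds = float(w_in / w_out) if w_out > 0 else 1.0
        if np.isclose(odds, 1.0):
            p = float(stats.hypergeom.sf(x - 1, M, n, N))
        else:
            p = float(stats.nchypergeom_wallenius.sf(x - 1, M, n, N, odds))
        rows.append({"set_id": set_id, "n_set": n, "n_mutated": x, "odds": odds, "p": p})
    return pd.DataFrame(rows)


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values."""
    p = np.asarray(pvalues, dtype=float)
    return multipletests(p, method="fdr_bh")[1]


def rank_difference_permutation(
    table_a: pd.Series,
    table_b: pd.Series,
    sets: dict[str, list[str]],
    gene_lengths: pd.Series,
    n_perm: int = 1000,
    candidate_alpha: float = 0.01,
    seed: int = 0,
) -> pd.DataFrame:
    """Cell-type-specific enrichment via rank-difference permutation.

    Candidate sets are those with enrichment p < ``candidate_alpha`` in
    either table. The statistic is rank(set in B) - rank(set in A) over the
    candidate sets (ranks ascending in p), so sets specifically enriched in
    A score high. The null redistributes each table's mutated-gene labels
    uniformly (preserving the mutated count) ``n_perm`` times; the add-one
    empirical p is (1 + #{null >= observed})/(n_perm + 1), BH-adjusted.
    """
    if n_perm < 100:
        warnings.warn("fewer than 100 permutations: empirical p is coarse")
    pa = geneset_enrichment(table_a, sets, gene_lengths).set_index("set_id")
    pb = geneset_enrichment(table_b, sets, gene_lengths).set_index("set_id")
    common = pa.index.intersection(pb.index)
    cand = [
        s for s in common
        if pa.loc[s, "p"] < candidate_alpha or pb.loc[s, "p"] < candidate_alpha
    ]
    if not cand:
        return pd.DataFrame(
            columns=["set_id", "p_a", "p_b", "rank_diff", "p_perm", "fdr"]
        )
    cand_sets = {s: sets[s] for s in cand}
    universe = sorted({g for gs in sets.values() for g in gs} & set(table_a.index))
    equal_lengths = gene_lengths.reindex(universe).nunique() == 1

    def rank_stats(ta, tb):
        ea = geneset_enrichment(ta, cand_sets, gene_lengths, min_mutated=0).set_index("set_id")
        eb = geneset_enrichment(tb, cand_sets, gene_lengths, min_mutated=0).set_index("set_id")
        ra = ea["p"].reindex(cand).rank(method="average")
        rb = eb["p"].reindex(cand).rank(method="average")
        return (rb - ra).to_numpy()

    obs = rank_stats(table_a, table_b)
    rng = np.random.default_rng(seed)
    va = table_a.reindex(universe).fillna(0).to_numpy().copy()
    vb = table_b.reindex(universe).fillna(0).to_numpy().copy()
    if equal_lengths:
        # fast permutation path: with equal weights the enrichment p is the
        # hypergeometric upper tail, vectorized across sets and rounds
        from scipy.stats import rankdata

        M = len(universe)
        gidx = {g: i for i, g in enumerate(universe)}
        member = np.zeros((M, len(cand)), dtype=np.int64)
        for j, s in enumerate(cand):
            member[[gidx[g] for g in set(sets[s]) & set(universe)], j] = 1
        n_set = member.sum(axis=0)
        Na, Nb = int(va.sum()), int(vb.sum())
        null = np.empty((n_perm, len(cand)))
        for i in range(n_perm):
            xa = rng.permutation(va) @ member
            xb = rng.permutation(vb) @ member
            pa_i = stats.hypergeom.sf(xa - 1, M, n_set, Na)
            pb_i = stats.hypergeom.sf(xb - 1, M, n_set, Nb)
            null[i] = rankdata(pb_i) - rankdata(pa_i)
    else:
        null = np.empty((n_perm, len(cand)))
        for i in range(n_perm):
            ta = pd.Series(rng.permutation(va), index=universe)
            tb = pd.Series(rng.permutation(vb), index=universe)
            null[i] = rank_stats(ta, tb)
    p_perm = (1 + (null >= obs[None, :]).sum(axis=0)) / (n_perm + 1)
    return pd.DataFrame({
        "set_id": cand,
        "p_a": pa.loc[cand, "p"].to_numpy(),
        "p_b": pb.loc[cand, "p"].to_numpy(),
        "rank_diff": obs,
        "p_perm": p_perm,
        "fdr": bh_fdr(p_perm),
    })
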