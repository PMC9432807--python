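"""Age-group mutation spectra and transcriptional strand bias.

Donors are grouped as infant (<=4 y), middle-aged (30-66 y) and aged
(>=75 y). The net-increase spectrum converts group spectra to absolute
counts (proportion x mean per-cell burden) and subtracts infant from aged.
Strand assignment follows the pyrimidine representation: a variant whose
pyrimidine base lies on the gene's sense strand is 'untranscribed', on the
template strand 'transcribed'; sites under genes on both strands are
ambiguous and excluded from the exact binomial (conditional Poisson)
strand-bias test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .contexts import CONTEXT_96, SUBSTITUTION_TYPES, substitution_type

AGE_GROUPS = ("infant", "middle", "aged")


def age_group(age: float) -> str | None:
    """Study age category; None outside the three bands."""
    if age <= 4.0:
        return "infant"
    if 30.0 <= age <= 66.0:
        return "middle"
    if age >= 75.0:
        return "aged"
    return None


@dataclass
class AgeGroupSpectrum:
    group: str
    proportions: pd.Series  # over 6 types or 96 classes, sums to 1
    mean_burden: float      # mean corrected sSNVs per cell
    n_cells: int


def spectrum_from_contexts(contexts_list, granularity: int = 6) -> pd.Series:
    """Proportion vector over the 6 substitution types or 96 classes."""
    s = pd.Series(contexts_list, dtype="object")
    if granularity == 6:
        keys = s.map(substitution_type)
        counts = keys.value_counts().reindex(list(SUBSTITUTION_TYPES), fill_value=0)
    elif granularity == 96:
        counts = s.value_counts().reindex(list(CONTEXT_96), fill_value=0)
    else:
        raise ValueError("granularity must be 6 or 96")
    total = counts.sum()
    if total == 0:
        raise ValueError("no variants to build a spectrum from")
    return counts / total


def net_increase_spectrum(aged: AgeGroupSpectrum, infant: AgeGroupSpectrum) -> pd.Series:
    """Absolute per-type net increase: p_aged x B_aged - p_infant x B_infant.

    Negative entries are reported as-is. The total equals the burden
    difference between groups.
    """
    if aged.mean_burden == 0 and infant.mean_burden == 0:
        raise ValueError("both groups have zero burden")
    a = aged.proportions * aged.mean_burden
    b = infant.proportions.reindex(aged.proportions.index, fill_value=0.0) * infant.mean_burden
    return a - b


def _merged_intervals(genes: pd.DataFrame, chrom: str, strand: str):
    sub = genes[(genes["chrom"] == chrom) & (genes["strand"] == strand)]
    iv = sorted(zip(sub["start"], sub["end"]))
    merged = []
    for s, e in iv:
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    if not merged:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    a = np.array(merged, dtype=np.int64)
    return a[:, 0], a[:, 1]


def assign_strand(variants: pd.DataFrame, genes: pd.DataFrame) -> pd.Series:
    """Transcriptional strand per variant.

    ``genes`` needs chrom, start, end (0-based half-open), strand in {+,-}.
    Returns 'untranscribed', 'transcribed', 'intergenic' or 'ambiguous'.
    """
    if not set(genes["strand"].unique()) <= {"+", "-"}:
        raise ValueError("gene strands must be '+' or '-'")
    res = np.full(len(variants), "intergenic", dtype=object)
    for chrom in variants["chrom"].unique():
        mask = (variants["chrom"] == chrom).to_numpy()
        pos = variants.loc[mask, "pos"].to_numpy()
        hits = {}
        for strand in "+-":
            starts, ends = _merged_intervals(genes, chrom, strand)
            if len(starts) == 0:
                hits[strand] = np.zeros(len(pos), dtype=bool)
                continue
            j = np.searchsorted(starts, pos, side="right") - 1
            ok = j >= 0
            hits[strand] = ok & (pos < ends[np.clip(j, 0, None)])
        ref_is_pyr = variants.loc[mask, "ref"].isin(["C", "T"]).to_numpy()
        pyr_strand = np.where(ref_is_pyr, "+", "-")
        both = hits["+"] & hits["-"]
        plus_only = hits["+"] & ~hits["-"]
        minus_only = hits["-"] & ~hits["+"]
        out = np.full(len(pos), "intergenic", dtype=object)
        out[both] = "ambiguous"
        # pyrimidine on the gene's sense strand -> untranscribed
        out[plus_only] = np.where(pyr_strand[plus_only] == "+", "untranscribed", "transcribed")
        out[minus_only] = np.where(pyr_strand[minus_only] == "-", "untranscribed", "transcribed")
        res[mask] = out
    return pd.Series(res, index=variants.index, name="strand")


def strand_bias_test(n_transcribed: int, n_untranscribed: int) -> float:
    """Two-sided exact binomial test of strand symmetry.

    The conditional form of comparing two Poisson rates: given n_T + n_U
    events, n_T ~ Binomial(n, 1/2) under no bias.
    """
    n = n_transcribed + n_untranscribed
    if n < 1:
        raise ValueError("need at least one stranded variant")
    return float(stats.binomtest(n_transcribed, n, 0.5).pvalue)


def strand_bias_table(variants: pd.DataFrame, genes: pd.DataFrame) -> pd.DataFrame:
    """Per-substitution-type transcribed/untranscribed counts and exact p."""
    strands = assign_strand(variants, genes)
    sub = variants.assign(strand=strands)
    sub = sub[sub["strand"].isin(["transcribed", "untranscribed"])]
    sub = sub.assign(subtype=sub["context"].map(substitution_type))
    rows = []
    for t in SUBSTITUTION_TYPES:
        s = sub[sub["subtype"] == t]
        nt = int((s["strand"] == "transcribed").sum())
        nu = int((s["strand"] == "untranscribed").sum())
        rows.append({
            "type": t, "transcribed": nt, "untranscribed": nu,
            "p": strand_bias_test(nt, nu) if nt + nu > 0 else float("nan"),
        })
    return pd.DataFrame(rows)
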