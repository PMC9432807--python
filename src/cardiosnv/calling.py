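"""Phasing/linkage-based somatic SNV calling.

A candidate somatic variant is accepted only under *complete linkage*: every
read jointly covering the candidate and its nearest phased germline het
supports the alternate allele on exactly one haplotype, and no reference-
supporting read phases to that same haplotype. A per-cell threshold on the
number of phasable alt reads is calibrated from a two-component mixture
(true somatic vs. MDA artifact read support) to control the true-positive
rate among calls at 90%; detection sensitivity is estimated by treating
each phased germline het as a pseudo-somatic variant and applying the full
calling rule.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

PASS, FAIL, UNPHASABLE = "pass", "fail", "unphasable"
MIN_ALT_READS = 2  # candidate discovery threshold


@dataclass
class CallerModel:
    threshold_k: int
    estimated_precision: float
    sensitivity: float | None = None

    def __post_init__(self):
        if self.threshold_k < 1:
            raise ValueError("threshold_k must be >= 1")


def test_linkage(c_ref_h1, c_ref_h2, c_alt_h1, c_alt_h2):
    """Vectorized linkage status for candidate calls.

    pass: all alt-linked reads on one haplotype h and no ref-linked reads on
    h; fail: alt reads on both haplotypes, or ref reads on the alt
    haplotype; unphasable: no alt-linked reads at all.
    """
    cr = np.stack([np.atleast_1d(np.asarray(c_ref_h1)), np.atleast_1d(np.asarray(c_ref_h2))], axis=1)
    ca = np.stack([np.atleast_1d(np.asarray(c_alt_h1)), np.atleast_1d(np.asarray(c_alt_h2))], axis=1)
    total_alt = ca.sum(axis=1)
    unphasable = total_alt == 0
    on_h1 = (ca[:, 0] > 0) & (ca[:, 1] == 0)
    on_h2 = (ca[:, 1] > 0) & (ca[:, 0] == 0)
    clean_h1 = on_h1 & (cr[:, 0] == 0)
    clean_h2 = on_h2 & (cr[:, 1] == 0)
    status = np.where(unphasable, UNPHASABLE, np.where(clean_h1 | clean_h2, PASS, FAIL))
    return status if status.size > 1 else str(status[0])


def calibrate_threshold(
    depth: float = 30.0,
    allele_fraction: float = 0.5,
    artifact_geom_p: float = 0.5,
    prior_artifact_fraction: float = 0.5,
    target_precision: float = 0.9,
    k_max: int = 10,
    fallback_k: int = 2,
) -> CallerModel:
    """Smallest phasable-read threshold controlling the true-positive rate.

    Under the mixture (true somatic: Binomial(depth, AF) alt support;
    artifact: Geometric(p) support), find the smallest k <= k_max with
    P(true | support >= k) >= target. Falls back to ``fallback_k`` when no
    k qualifies.
    """
    if not 0 <= prior_artifact_fraction < 1:
        raise ValueError("prior_artifact_fraction must be in [0, 1)")
    if not 0 < artifact_geom_p <= 1:
        raise ValueError("degenerate artifact support distribution")
    pt = 1.0 - prior_artifact_fraction
    for k in range(1, k_max + 1):
        p_true_tail = stats.binom.sf(k - 1, int(round(depth)), allele_fraction)
        p_art_tail = (1.0 - artifact_geom_p) ** (k - 1)  # P(Geom >= k), support 1,2,...
        num = pt * p_true_tail
        den = num + (1.0 - pt) * p_art_tail
        if den == 0:
            continue
        post = num / den
        if post >= target_precision:
            return CallerModel(threshold_k=k, estimated_precision=post)
    return CallerModel(threshold_k=fallback_k, estimated_precision=float("nan"))


def _phasable_alt(evidence: pd.DataFrame) -> np.ndarray:
    return evidence["c_alt_h1"].to_numpy() + evidence["c_alt_h2"].to_numpy()


def call_cell(
    evidence: pd.DataFrame,
    germline: pd.DataFrame,
    model: CallerModel,
) -> pd.DataFrame:
    """Apply the full calling rule to a cell's evidence table.

    Calls are evidence rows that (1) are not germline records, (2) show at
    least two alt reads, (3) pass complete linkage, and (4) have at least
    ``model.threshold_k`` phasable alt reads.
    """
    germ_idx = pd.MultiIndex.from_frame(germline[["chrom", "pos"]])
    is_germ = pd.MultiIndex.from_frame(evidence[["chrom", "pos"]]).isin(germ_idx)
    status = test_linkage(
        evidence["c_ref_h1"], evidence["c_ref_h2"],
        evidence["c_alt_h1"], evidence["c_alt_h2"],
    )
    status = np.atleast_1d(status)
    keep = (
        (~is_germ)
        & (evidence["alt_reads"].to_numpy() >= MIN_ALT_READS)
        & (status == PASS)
        & (_phasable_alt(evidence) >= model.threshold_k)
    )
    return evidence.loc[keep].reset_index(drop=True)


def estimate_sensitivity(
    evidence: pd.DataFrame,
    germline: pd.DataFrame,
    model: CallerModel,
) -> float:
    """Detection sensitivity from germline hets treated as pseudo-somatic.

    Each phased het (linked against its next-nearest het in the evidence
    table) is pushed through the full rule — coverage, alt-read discovery,
    complete linkage on its known haplotype, and the phasable-read
    threshold. Returns the passing fraction.
    """
    key = pd.MultiIndex.from_frame(germline[["chrom", "pos"]])
    ev_key = pd.MultiIndex.from_frame(evidence[["chrom", "pos"]])
    sub = evidence.loc[ev_key.isin(key)]
    if len(sub) < 100:
        raise ValueError("need >= 100 phased germline hets")
    status = np.atleast_1d(
        test_linkage(sub["c_ref_h1"], sub["c_ref_h2"], sub["c_alt_h1"], sub["c_alt_h2"])
    )
    ok = (
        (sub["alt_reads"].to_numpy() >= MIN_ALT_READS)
        & (status == PASS)
        & (_phasable_alt(sub) >= model.threshold_k)
    )
    return float(ok.mean())


def thin_evidence(evidence: pd.DataFrame, rate: float, seed: int | np.random.SeedSequence = 0) -> pd.DataFrame:
    """Binomially downsample all read counts (depth, alleles, linkage)."""
    rng = np.random.default_rng(seed)
    out = evidence.copy()
    for col in ["ref_reads", "alt_reads", "c_ref_h1", "c_ref_h2", "c_alt_h1", "c_alt_h2"]:
        out[col] = rng.binomial(evidence[col].to_numpy(), rate)
    out["depth"] = out["ref_reads"] + out["alt_reads"]
    return out


def precision_against_truth(calls: pd.DataFrame, truth_somatic: pd.DataFrame) -> float:
    """Fraction of calls present in the generator's somatic truth."""
    if len(calls) == 0:
        return float("nan")
    truth = set(zip(truth_somatic["chrom"], truth_somatic["pos"].astype(int)))
    hit = sum((c, int(p)) in truth for c, p in zip(calls["chrom"], calls["pos"]))
    return hit / len(calls)
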