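"""Ploidy-aware gene-knockout probability model.

A gene is knocked out when every functional allele is hit. Dosage-sensitive
genes (high pLI, fraction pi of all genes, default 0.17) are treated as
haploinsufficient: a single deleterious hit suffices. With n expected
deleterious mutations and per-gene deleterious-hit probability D,

    Pr(KO | pi, D, n) = pi * (1 - (1-D)^n) + (1-pi) * (1 - exp(-n*D))

where n = (estimated sSNVs) x (deleterious fraction) x p, and the ploidy
factor p is the probability of hitting the remaining alleles: 0.5 for
diploid, 0.125 for tetraploid genomes. Polyploidy therefore buffers
knockout accumulation for the non-haploinsufficient majority.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

PLOIDY_FACTOR = {2: 0.5, 4: 0.125}
DEFAULT_PI_HIGH_PLI = 0.17
#: damaging fraction among coding sSNVs over the total catalogue
DEFAULT_DEL_FRACTION = 36 / 10407


@dataclass
class KOParams:
    pi_highpli: float = DEFAULT_PI_HIGH_PLI
    del_fraction: float = DEFAULT_DEL_FRACTION
    n_genes: int = 20000
    D: float | None = None  # per-gene deleterious-hit probability

    def __post_init__(self):
        if not 0 <= self.pi_highpli <= 1 or not 0 <= self.del_fraction <= 1:
            raise ValueError("pi and del_fraction must be probabilities")
        if self.D is None:
            self.D = 1.0 / self.n_genes


def expected_deleterious(n_snvs: float, del_fraction: float, p_ploidy: float) -> float:
    """n = estimated sSNVs x deleterious fraction x ploidy factor."""
    if n_snvs < 0 or not 0 <= del_fraction <= 1:
        raise ValueError("invalid inputs")
    return float(n_snvs * del_fraction * p_ploidy)


def pr_ko(pi: float, D: float, n) -> float | np.ndarray:
    """Knockout probability; increasing in each argument, bounded in [0,1]."""
    if not 0 <= pi <= 1 or not 0 <= D <= 1:
        raise ValueError("pi and D must be in [0,1]")
    n = np.asarray(n, dtype=float)
    if (n < 0).any():
        raise ValueError("n must be >= 0")
    val = pi * (1.0 - (1.0 - D) ** n) + (1.0 - pi) * (1.0 - np.exp(-n * D))
    return float(val) if val.ndim == 0 else val


def cell_ko_probability(params: KOParams, n: float, g_eff: int = 1) -> float:
    """Probability a cell carries at least one knocked-out gene.

    With per-gene probability q = pr_ko(pi, D, n), the cell-level value is
    1 - (1-q)^g_eff. The default g_eff = 1 reads the formula as already
    cell-level; g_eff = n_genes treats genes independently.
    """
    if g_eff < 1:
        raise ValueError("g_eff must be >= 1")
    q = pr_ko(params.pi_highpli, params.D, n)
    return float(1.0 - (1.0 - q) ** g_eff)


def cohort_ko_curve(
    burdens: pd.DataFrame,
    params: KOParams | None = None,
    g_eff: int = 1,
) -> tuple[pd.DataFrame, dict]:
    """Per-donor KO probability curves for tetraploid vs. diploid models.

    ``burdens`` needs cell_id, donor_id, age, est_count (tetraploid
    genome-wide corrected counts). The diploid model uses 50% of the
    matched tetraploid burden with p = 0.5; the tetraploid model the full
    burden with p = 0.125. Returns the per-donor curve (mean +/- s.e.m. per
    ploidy) and a dict with the exponential fits ln Pr = ln a + b x age and
    the paired two-sided Wilcoxon comparison across donors.
    """
    if params is None:
        params = KOParams()
    if burdens["donor_id"].nunique() < 3:
        raise ValueError("need >= 3 donors")
    rows = []
    for (donor, age), sub in burdens.groupby(["donor_id", "age"]):
        counts = sub["est_count"].to_numpy(dtype=float)
        counts = counts[np.isfinite(counts)]
        if len(counts) == 0:
            import warnings

            warnings.warn(f"donor {donor} has no usable cells; skipped")
            continue
        for ploidy, frac in ((4, 1.0), (2, 0.5)):
            n = expected_deleterious(1.0, params.del_fraction, PLOIDY_FACTOR[ploidy]) * counts * frac
            pr = np.array([cell_ko_probability(params, x, g_eff) for x in n])
            rows.append({
                "donor_id": donor, "age": age, "ploidy": ploidy,
                "mean": pr.mean(),
                "sem": pr.std(ddof=1) / np.sqrt(len(pr)) if len(pr) > 1 else 0.0,
                "n_cells": len(pr),
            })
    curve = pd.DataFrame(rows)
    fits = {}
    for ploidy in (2, 4):
        sub = curve[(curve["ploidy"] == ploidy) & (curve["mean"] > 0)]
        if len(sub) >= 2 and sub["age"].nunique() >= 2:
            b, lna = np.polyfit(sub["age"], np.log(sub["mean"]), 1)
            fits[ploidy] = {"a": float(np.exp(lna)), "b": float(b)}
        else:
            fits[ploidy] = None
    wide = curve.pivot_table(index="donor_id", columns="ploidy", values="mean")
    if wide.shape[0] >= 3 and not (wide[2] == wide[4]).all():
        diff = wide[2] - wide[4]
        stat = stats.wilcoxon(diff, alternative="two-sided")
        p_wilcoxon = float(stat.pvalue)
    else:
        p_wilcoxon = float("nan")
    return curve, {"exp_fit": fits, "p_wilcoxon_diploid_vs_tetraploid": p_wilcoxon}
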