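"""Per-cell amplification quality control.

Dropout rates are estimated from germline heterozygous SNVs: a site is a
locus dropout when its total single-cell depth is below 5 reads, and an
allelic dropout when it is covered but one allele has fewer than 2
supporting reads. Amplification evenness is summarized by MAPD (median
absolute difference of neighbouring bins' normalized copy ratios) and CoV
(s.d./mean of the ratios).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

LOCUS_DEPTH_THRESHOLD = 5
ALLELE_READ_THRESHOLD = 2


@dataclass
class DropoutEstimate:
    locus_rate: float
    allelic_rate: float
    n_sites: int


@dataclass
class EvennessMetrics:
    mapd: float
    cov: float
    n_bins: int


def estimate_dropout(
    evidence: pd.DataFrame,
    include_locus_in_allelic_denominator: bool = False,
) -> DropoutEstimate:
    """Locus/allelic dropout rates from germline-het evidence rows.

    ``evidence`` must contain depth, ref_reads, alt_reads for germline
    heterozygous sites only. By default the allelic rate is computed among
    sites that are not locus-dropped (the flag restores the all-sites
    denominator).
    """
    n = len(evidence)
    if n == 0:
        raise ValueError("no germline het sites provided")
    depth = evidence["depth"].to_numpy()
    ref = evidence["ref_reads"].to_numpy()
    alt = evidence["alt_reads"].to_numpy()
    locus = depth < LOCUS_DEPTH_THRESHOLD
    allelic = (~locus) & (np.minimum(ref, alt) < ALLELE_READ_THRESHOLD)
    denom = n if include_locus_in_allelic_denominator else int((~locus).sum())
    allelic_rate = float(allelic.sum() / denom) if denom > 0 else 0.0
    return DropoutEstimate(
        locus_rate=float(locus.mean()), allelic_rate=allelic_rate, n_sites=n
    )


def bin_and_normalize(
    bins: pd.DataFrame,
    reads_per_bin: int = 5000,
    n_gc_bins: int = 10,
) -> pd.DataFrame:
    """Merge fixed windows into equal-expected-read bins and normalize.

    ``bins`` holds per-window read counts (columns chrom, start, end, gc,
    reads). Windows are aggregated, in genomic order within each
    chromosome, into variable-length bins expected to hold ``reads_per_bin``
    reads under a uniform baseline; the observed/expected ratio is corrected
    by the median ratio of the bin's GC decile and rescaled to mean 1.
    """
    total = bins["reads"].sum()
    if total < 10 * reads_per_bin:
        raise ValueError("fewer than 10 bins' worth of reads")
    genome_len = (bins["end"] - bins["start"]).sum()
    rate = total / genome_len  # expected reads per bp under uniformity
    rows = []
    for chrom, sub in bins.groupby("chrom", sort=False):
        sub = sub.sort_values("start")
        exp_per_window = rate * (sub["end"] - sub["start"]).to_numpy()
        cum = np.cumsum(exp_per_window)
        # split points every reads_per_bin expected reads
        group = np.minimum((cum - 1e-9) // reads_per_bin, np.inf).astype(np.int64)
        g = pd.DataFrame(
            {
                "group": group,
                "start": sub["start"].to_numpy(),
                "end": sub["end"].to_numpy(),
                "gc": sub["gc"].to_numpy(),
                "reads": sub["reads"].to_numpy(),
                "expected": exp_per_window,
            }
        )
        agg = g.groupby("group").agg(
            start=("start", "min"),
            end=("end", "max"),
            gc=("gc", "mean"),
            reads=("reads", "sum"),
            expected=("expected", "sum"),
        )
        agg["chrom"] = chrom
        rows.append(agg.reset_index(drop=True))
    out = pd.concat(rows, ignore_index=True)
    if len(out) < 10:
        raise ValueError("fewer than 10 bins after aggregation")
    out["ratio"] = out["reads"] / out["expected"]
    # GC correction: divide by the median ratio of the bin's GC decile;
    # keep >= 5 bins per GC stratum so the correction cannot absorb all
    # bin-to-bin variation on small genomes
    n_gc = max(1, min(n_gc_bins, len(out) // 5))
    deciles = pd.qcut(out["gc"], q=n_gc, duplicates="drop")
    med = out.groupby(deciles, observed=True)["ratio"].transform("median")
    med = med.replace(0, np.nan).fillna(1.0)
    out["ratio"] = out["ratio"] / med
    out["ratio"] /= out["ratio"].mean()
    return out[["chrom", "start", "end", "gc", "ratio"]]


def mapd(ratios: pd.DataFrame | np.ndarray) -> float:
    """Median absolute difference of neighbouring bins' copy ratios.

    Accepts the output of :func:`bin_and_normalize` (differences are taken
    within chromosomes only) or a plain ordered array.
    """
    if isinstance(ratios, pd.DataFrame):
        diffs = []
        for _, sub in ratios.groupby("chrom", sort=False):
            r = sub.sort_values("start")["ratio"].to_numpy()
            if len(r) >= 2:
                diffs.append(np.abs(np.diff(r)))
        if not diffs:
            raise ValueError("need >= 2 bins on some chromosome")
        return float(np.median(np.concatenate(diffs)))
    r = np.asarray(ratios, dtype=float)
    if len(r) < 2:
        raise ValueError("need >= 2 bins")
    return float(np.median(np.abs(np.diff(r))))


def cov(ratios: pd.DataFrame | np.ndarray) -> float:
    """Coefficient of variation (sample s.d. / mean) of bin copy ratios."""
    r = ratios["ratio"].to_numpy() if isinstance(ratios, pd.DataFrame) else np.asarray(ratios, dtype=float)
    if len(r) < 2:
        raise ValueError("need >= 2 bins")
    m = r.mean()
    if m == 0:
        raise ValueError("zero mean ratio")
    return float(r.std(ddof=1) / m)


def evenness_metrics(bins: pd.DataFrame, reads_per_bin: int = 5000) -> EvennessMetrics:
    """Convenience: normalize binned counts and compute MAPD and CoV."""
    norm = bin_and_normalize(bins, reads_per_bin=reads_per_bin)
    return EvennessMetrics(mapd=mapd(norm), cov=cov(norm), n_bins=len(norm))
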