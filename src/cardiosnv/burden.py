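"""Genome-wide sSNV burden estimation with ploidy-aware dropout correction.

For tetraploid nuclei, a somatic variant sits on one of four haplotype
copies and can only display complete linkage when the duplicate
same-haplotype reference copy dropped out during amplification. The
observed tetraploid dropout rates are therefore decomposed into the rates
of the two (assumed equal) diploid origins: the tetraploid locus-dropout
rate is the product of the origins' rates, and a specific allele is
unobserved only when both of its two copies were lost independently. The
germline-derived sensitivity is then discounted by the per-copy allele-loss
probability u and by the sensitivity loss from halved per-haplotype depth.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class TetraploidDropoutModel:
    """Dropout decomposition of a tetraploid cell into its diploid origins.

    L4/A4: observed tetraploid locus/allelic dropout rates; L2/a2: inferred
    per-origin rates; u: per-copy allele-loss probability (the chance that
    one specific haplotype copy contributes no reads at a site).
    """

    L4: float
    A4: float
    L2: float
    a2: float
    u: float


def site_to_allele_rate(a_site: float) -> float:
    """Convert a site-level allelic-dropout rate to a per-allele loss rate.

    The QC estimator flags a site when *either* allele has <2 reads; with
    the two alleles lost independently (given no locus dropout) at rate q,
    the site-level rate is 1-(1-q)^2, inverted here.
    """
    if not 0 <= a_site <= 1:
        raise ValueError("rate must be in [0,1]")
    return 1.0 - float(np.sqrt(1.0 - a_site))


def decompose_dropout(L4: float, A4: float, basis: str = "allele") -> TetraploidDropoutModel:
    """Infer diploid-origin dropout rates from tetraploid observations.

    L2 = sqrt(L4) (a tetraploid locus drops only when both origins
    dropped); u = sqrt(L4 + (1-L4) * A4) with A4 on the per-allele basis (an
    allele is unobserved iff both of its copies are lost, independently at
    rate u); a2 = (u - L2)/(1 - L2). ``basis="site"`` first converts a
    site-level (either-allele) A4 to the per-allele scale.
    """
    if not 0 <= L4 < 1:
        raise ValueError("L4 must be in [0, 1)")
    if not 0 <= A4 <= 1:
        raise ValueError("A4 must be in [0, 1]")
    if basis == "site":
        A4_allele = site_to_allele_rate(A4)
    elif basis == "allele":
        A4_allele = A4
    else:
        raise ValueError("basis must be 'allele' or 'site'")
    L2 = float(np.sqrt(L4))
    u = float(np.sqrt(L4 + (1.0 - L4) * A4_allele))
    if u < L2:
        warnings.warn("per-copy loss u below L2; clipping a2 to 0")
        u = L2
    a2 = (u - L2) / (1.0 - L2) if L2 < 1 else 0.0
    a2 = float(np.clip(a2, 0.0, 1.0))
    return TetraploidDropoutModel(L4=L4, A4=A4, L2=L2, a2=a2, u=u)


def tetraploid_sensitivity(
    s_germline: float, model: TetraploidDropoutModel, depth_factor: float
) -> float:
    """Somatic detection sensitivity in a tetraploid cell.

    s_tetra = s_germline x u x depth_factor: the germline-derived
    sensitivity, times the probability u that the interfering same-haplotype
    reference copy dropped out (a prerequisite for complete linkage of a
    1/4-fraction variant), times the sensitivity ratio at halved
    per-haplotype depth.
    """
    return float(s_germline * model.u * depth_factor)


def estimate_interferer_silence(evidence: pd.DataFrame, germline: pd.DataFrame) -> float:
    """Probability that one specific haplotype copy contributes no linked
    reference read at a site, estimated from germline hets in a 4n cell.

    A quarter-fraction somatic variant can show complete linkage only when
    the duplicate same-haplotype reference copy is silent — dropped out or
    simply never sampled into a linked read pair. At a germline het the
    reference allele sits on two such copies (one per diploid origin,
    independent), so with z the fraction of linked hets whose
    reference-haplotype linked count is zero, the per-copy silence
    probability is sqrt(z).
    """
    key = pd.MultiIndex.from_frame(germline[["chrom", "pos"]])
    ev_key = pd.MultiIndex.from_frame(evidence[["chrom", "pos"]])
    sub = evidence.loc[ev_key.isin(key)].copy()
    sub = sub.merge(germline[["chrom", "pos", "hap"]], on=["chrom", "pos"])
    sub = sub[sub["het_pos"] >= 0]
    if len(sub) < 100:
        raise ValueError("need >= 100 linked germline hets")
    c_ref_refhap = np.where(sub["hap"] == 0, sub["c_ref_h2"], sub["c_ref_h1"])
    z = float((c_ref_refhap == 0).mean())
    return float(np.sqrt(z))


def plant_sensitivity(
    reference,
    germline: pd.DataFrame,
    params,
    ploidy: int,
    model,
    n_plant: int = 2000,
    seed: int | np.random.SeedSequence = 0,
) -> float:
    """Somatic detection sensitivity by planting pseudo-variants.

    The calling rule couples the variant copy's phasable alt depth with the
    silence of the duplicate same-haplotype reference copy through the
    shared linkage geometry, so factorized corrections are biased. Instead,
    ``n_plant`` single-copy variants are planted at random positions into a
    model amplification of the cell's germline and the full caller is
    applied; the pass fraction is the sensitivity. Monte-Carlo s.e. is
    about sqrt(s/n_plant).

    ``params`` must describe the amplification *model* (per-copy dropout
    probabilities, target depth), not the operationalized depth<5 /
    reads<2 rates measured from evidence — the simulation reproduces those
    read-level tails itself, so feeding measured rates back in would count
    them twice.
    """
    import numpy as _np

    from . import synthetic as _synth
    from .calling import call_cell

    ss = seed if isinstance(seed, _np.random.SeedSequence) else _np.random.SeedSequence(seed)
    s_pos, s_a, s_b = ss.spawn(3)
    rng = _np.random.default_rng(s_pos)
    taken = set(zip(germline["chrom"], germline["pos"].astype(int)))
    chroms, lens = reference.chrom_names, [reference.chrom_length(c) for c in reference.chrom_names]
    w = _np.array(lens, dtype=float) / sum(lens)
    rows = []
    n_real = ploidy // 2
    while len(rows) < n_plant:
        ci = rng.choice(len(chroms), p=w)
        p = int(rng.integers(1, lens[ci] - 1))
        if (chroms[ci], p) in taken:
            continue
        taken.add((chroms[ci], p))
        base = reference.sequences[chroms[ci]][p]
        alt = "A" if base != "A" else "T"
        rows.append({
            "chrom": chroms[ci], "pos": p, "ref": base, "alt": alt,
            "hap": int(rng.integers(0, 2)), "origin": int(rng.integers(0, n_real)),
        })
    planted = pd.DataFrame(rows)
    empty = pd.DataFrame(columns=["chrom", "pos", "ref", "alt", "hap", "origin"])
    sites = _synth._assemble_sites(germline, planted, empty)
    per_copy = params.mean_depth / 2.0 / n_real
    ev_a, _ = _synth.simulate_realization(
        sites, germline, reference, params, 0, per_copy, s_a
    )
    drop = ["_r_h1", "_r_h2"]
    if n_real == 1:
        ev = ev_a.drop(columns=drop)
    else:
        ev_b, _ = _synth.simulate_realization(
            sites, germline, reference, params, 1, per_copy, s_b
        )
        ev = _synth.make_tetraploid(ev_a.drop(columns=drop), ev_b.drop(columns=drop))
    calls = call_cell(ev, germline, model)
    hit = set(zip(calls["chrom"], calls["pos"].astype(int)))
    found = sum((c, p) in hit for c, p in zip(planted["chrom"], planted["pos"]))
    return found / n_plant


def estimate_depth_factor(evidence, germline, model, seed=0) -> float:
    """Sensitivity loss from halved allele depth, by binomial thinning.

    Re-runs germline sensitivity estimation after thinning every read count
    at rate 0.5 and returns s_half / s_full.
    """
    from .calling import estimate_sensitivity, thin_evidence

    s_full = estimate_sensitivity(evidence, germline, model)
    if s_full == 0:
        return 1.0
    thinned = thin_evidence(evidence, 0.5, seed=seed)
    s_half = estimate_sensitivity(thinned, germline, model)
    return float(s_half / s_full)


MIN_SENSITIVITY = 0.01  # cells below are QC-fail: correction factor unbounded


@dataclass
class BurdenEstimate:
    cell_id: str
    raw_count: int
    sensitivity: float
    est_count: float
    genome_mb: float
    density_per_mb: float
    artifact_corrected_density: float | None = None
    qc_fail: bool = False


def estimate_burden(
    cell_id: str,
    raw_count: int,
    sensitivity: float,
    ploidy: int,
    diploid_genome_mb: float,
) -> BurdenEstimate:
    """Sensitivity-corrected genome-wide count and per-Mb density.

    genome_mb = (ploidy/2) x diploid genome size, so tetraploid densities
    are per Mb of the doubled DNA content. Cells with sensitivity at or
    below 1% are returned flagged rather than corrected.
    """
    genome_mb = (ploidy / 2.0) * diploid_genome_mb
    if sensitivity <= MIN_SENSITIVITY:
        return BurdenEstimate(
            cell_id=cell_id, raw_count=raw_count, sensitivity=sensitivity,
            est_count=float("nan"), genome_mb=genome_mb,
            density_per_mb=float("nan"), qc_fail=True,
        )
    est = raw_count / sensitivity
    return BurdenEstimate(
        cell_id=cell_id, raw_count=raw_count, sensitivity=sensitivity,
        est_count=est, genome_mb=genome_mb, density_per_mb=est / genome_mb,
    )


def subtract_artifact_density(density: float, artifact_weights) -> float:
    """Remove the amplification-artifact share of an sSNV density.

    ``artifact_weights`` are the refit weights of the artifact signatures
    (scE/scF-like); corrected = density x (1 - sum of weights).
    """
    w = np.asarray(list(artifact_weights.values()) if isinstance(artifact_weights, dict)
                   else artifact_weights, dtype=float)
    if ((w < 0) | (w > 1)).any():
        raise ValueError("weights must be in [0,1]")
    if w.sum() > 1 + 1e-9:
        raise ValueError("artifact weights sum above 1")
    return float(density * max(0.0, 1.0 - w.sum()))


def burden_table(estimates: list[BurdenEstimate]) -> pd.DataFrame:
    return pd.DataFrame([vars(e) for e in estimates])
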