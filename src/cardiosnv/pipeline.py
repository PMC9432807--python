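"""End-to-end orchestration: simulate -> QC -> call -> burden -> models.

`analyze_cell`/`analyze_cohort` are the programmatic entry points used by
the examples and the test-suite; `run_pipeline` executes every stage from a
TOML configuration and writes plain-file outputs plus a hashed manifest so
reruns are verifiable.
"""

from __future__ import annotations

import hashlib
import json
import sys
import time
import zlib
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import burden as burden_mod
from . import calling, io, ko, qc, regression, signatures, spectra, synthetic
from .synthetic import CellData, Cohort, CohortSpec, ReferenceGenome


@dataclass
class CellAnalysis:
    cell_id: str
    dropout: qc.DropoutEstimate
    evenness: qc.EvennessMetrics
    model: calling.CallerModel
    calls: pd.DataFrame
    burden: burden_mod.BurdenEstimate
    signature_weights: pd.Series | None
    precision: float | None = None


def analyze_cell(
    cell: CellData,
    germline: pd.DataFrame,
    reference: ReferenceGenome,
    prior_artifact_fraction: float = 0.5,
    refit_panel: pd.DataFrame | None = None,
    artifact_signatures: tuple[str, ...] = ("scE_like", "scF_like"),
    seed: int = 0,
    min_refit_calls: int = 50,
    fallback_weights: pd.Series | None = None,
    amp_params=None,
    sensitivity_override: float | None = None,
) -> CellAnalysis:
    """Full single-cell analysis chain.

    QC (dropout + evenness), per-cell threshold calibration, linkage
    calling, germline-based sensitivity with the tetraploid dropout/depth
    correction where applicable, burden estimation, and artifact-signature
    refitting/subtraction of the per-Mb density.
    """
    ev = cell.evidence
    key = pd.MultiIndex.from_frame(germline[["chrom", "pos"]])
    ev_key = pd.MultiIndex.from_frame(ev[["chrom", "pos"]])
    germ_rows = ev.loc[ev_key.isin(key)]
    dropout = qc.estimate_dropout(germ_rows)
    evenness = qc.evenness_metrics(cell.bins)

    depth = float(germ_rows["depth"].mean())
    model = calling.calibrate_threshold(
        depth=depth,
        allele_fraction=1.0 / cell.ploidy,
        artifact_geom_p=0.5,
        prior_artifact_fraction=prior_artifact_fraction,
    )
    calls = calling.call_cell(ev, germline, model)
    s_germ = calling.estimate_sensitivity(ev, germline, model)

    if sensitivity_override is not None:
        sens = sensitivity_override
    elif cell.ploidy == 4:
        # callability of a 1/4-fraction variant requires a silent duplicate
        # reference copy; the coupling with linkage geometry makes factorized
        # corrections biased, so sensitivity comes from planting
        # pseudo-variants into a model amplification of the cell's germline
        if amp_params is None:
            from .synthetic import AmplificationParams

            amp_params = AmplificationParams()
        sens = burden_mod.plant_sensitivity(
            reference, germline, amp_params, cell.ploidy, model, seed=seed
        )
    else:
        sens = s_germ
    model.sensitivity = sens

    est = burden_mod.estimate_burden(
        cell_id=cell.cell_id,
        raw_count=len(calls),
        sensitivity=sens,
        ploidy=cell.ploidy,
        diploid_genome_mb=2.0 * reference.haploid_mb,
    )

    # signature-based artifact subtraction; per-cell refits are unreliable
    # below ~50 mutations, so small cells fall back to pooled weights
    weights = None
    if len(calls) >= min_refit_calls and not est.qc_fail:
        if refit_panel is None:
            refit_panel = signatures.load_reference_signatures()
        calls_ctx = calls.assign(cell_id=cell.cell_id)
        mat = signatures.context_matrix(calls_ctx, reference)
        weights, _ = signatures.refit_fixed(mat.iloc[0].to_numpy(), refit_panel)
    elif fallback_weights is not None:
        weights = fallback_weights
    if not est.qc_fail:
        if weights is not None:
            w_art = {s: weights.get(s, 0.0) for s in artifact_signatures}
            est.artifact_corrected_density = burden_mod.subtract_artifact_density(
                est.density_per_mb, w_art
            )
        else:
            est.artifact_corrected_density = est.density_per_mb

    precision = calling.precision_against_truth(calls, cell.truth_somatic)
    return CellAnalysis(
        cell_id=cell.cell_id, dropout=dropout, evenness=evenness, model=model,
        calls=calls, burden=est, signature_weights=weights, precision=precision,
    )


def pooled_signature_weights(
    cohort: Cohort, prior_artifact_fraction: float = 0.5
) -> pd.Series | None:
    """Refit weights of the cohort-pooled called-variant profile."""
    panel = signatures.load_reference_signatures()
    frames = []
    for cell in cohort.cells:
        model = calling.calibrate_threshold(
            allele_fraction=1.0 / cell.ploidy,
            prior_artifact_fraction=prior_artifact_fraction,
        )
        c = calling.call_cell(cell.evidence, cohort.germline[cell.donor_id], model)
        if len(c):
            frames.append(c.assign(cell_id="pooled"))
    if not frames:
        return None
    pooled = pd.concat(frames, ignore_index=True)
    mat = signatures.context_matrix(pooled, cohort.reference)
    weights, _ = signatures.refit_fixed(mat.iloc[0].to_numpy(), panel)
    return weights


def analyze_cohort(cohort: Cohort, prior_artifact_fraction: float = 0.5) -> pd.DataFrame:
    """Per-cell analysis for a whole cohort; returns the tidy burden table.

    Artifact-signature weights for cells with fewer than 50 calls come from
    the cohort-pooled call profile; the plant-based tetraploid sensitivity
    is computed once per donor (cells of a donor share germline and
    amplification parameters) to amortize the simulation.
    """
    panel = signatures.load_reference_signatures()
    plant_cache: dict[tuple[str, int], float] = {}
    results: list[CellAnalysis] = []
    for i, cell in enumerate(cohort.cells):
        germline = cohort.germline[cell.donor_id]
        override = None
        if cell.ploidy == 4:
            cache_key = (cell.donor_id, cell.ploidy)
            if cache_key not in plant_cache:
                model = calling.calibrate_threshold(
                    allele_fraction=1.0 / cell.ploidy,
                    prior_artifact_fraction=prior_artifact_fraction,
                )
                plant_seed = zlib.crc32(cell.donor_id.encode()) % (2**31)
                # the draw is shared by all of the donor's cells, so keep
                # its Monte-Carlo error small relative to Poisson noise
                plant_cache[cache_key] = burden_mod.plant_sensitivity(
                    cohort.reference, germline, cohort.spec.amp_params,
                    cell.ploidy, model, n_plant=8000, seed=plant_seed,
                )
            override = plant_cache[cache_key]
        results.append(
            analyze_cell(
                cell, germline, cohort.reference,
                prior_artifact_fraction=prior_artifact_fraction,
                refit_panel=panel, seed=i,
                sensitivity_override=override,
            )
        )

    # pooled artifact weights from all calls, applied to small cells
    frames = [
        r.calls.assign(cell_id=r.cell_id) for r in results if len(r.calls)
    ]
    pooled_w = None
    if frames:
        pooled = pd.concat(frames, ignore_index=True)
        mat = signatures.context_matrix(pooled.assign(cell_id="pooled"), cohort.reference)
        pooled_w, _ = signatures.refit_fixed(mat.iloc[0].to_numpy(), panel)
    for r in results:
        if r.signature_weights is None and pooled_w is not None and not r.burden.qc_fail:
            w_art = {s: pooled_w.get(s, 0.0) for s in ("scE_like", "scF_like")}
            r.burden.artifact_corrected_density = burden_mod.subtract_artifact_density(
                r.burden.density_per_mb, w_art
            )
            r.signature_weights = pooled_w

    rows = []
    for cell, res in zip(cohort.cells, results):
        row = {
            "cell_id": cell.cell_id,
            "donor_id": cell.donor_id,
            "age": cell.age,
            "cell_type": cell.cell_type,
            "ploidy": cell.ploidy,
            "raw_count": res.burden.raw_count,
            "sensitivity": res.burden.sensitivity,
            "est_count": res.burden.est_count,
            "genome_mb": res.burden.genome_mb,
            "density_per_mb": res.burden.density_per_mb,
            "corrected_density": res.burden.artifact_corrected_density,
            "qc_fail": res.burden.qc_fail,
            "locus_rate": res.dropout.locus_rate,
            "allelic_rate": res.dropout.allelic_rate,
            "mapd": res.evenness.mapd,
            "cov": res.evenness.cov,
            "threshold_k": res.model.threshold_k,
            "precision": res.precision,
            "truth_count": len(cell.truth_somatic),
        }
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# config-driven pipeline


_CONFIG_SCHEMA = {
    "seed": int,
    "output_dir": str,
    "reference": {"n_chrom": int, "chrom_length": int, "gc_fraction": float},
    "cohort": {
        "ages": list, "cells_per_donor": int, "cell_type": str, "ploidy": int,
        "rate_per_mb_per_year": float, "intercept_per_mb": float,
        "het_density_per_kb": float,
    },
    "amplification": {
        "locus_dropout_rate": float, "allelic_dropout_rate": float,
        "mean_depth": float, "depth_dispersion": float, "unevenness_sigma": float,
        "artifact_rate_per_mb": float, "linkage_window": int,
    },
    "caller": {"prior_artifact_fraction": float},
    "ko": {"pi_highpli": float, "del_fraction": float, "n_genes": int},
}


def _validate(config: dict, schema=_CONFIG_SCHEMA, prefix=""):
    for key, val in config.items():
        if key not in schema:
            raise ValueError(f"unknown config key: {prefix}{key}")
        if isinstance(schema[key], dict):
            if not isinstance(val, dict):
                raise ValueError(f"config key {prefix}{key} must be a table")
            _validate(val, schema[key], prefix=f"{prefix}{key}.")


def load_config(path) -> dict:
    import tomllib

    with open(path, "rb") as fh:
        config = tomllib.load(fh)
    _validate(config)
    if "seed" not in config:
        raise ValueError("config must set an explicit seed")
    return config


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: dict | str | Path, output_dir: str | Path | None = None) -> dict:
    """Execute every stage from a validated configuration.

    Writes FASTA/VCF/TSV/JSON outputs under ``output_dir`` and returns the
    manifest (also written as manifest.json) with per-file SHA-256 hashes.
    Reruns with the same seed reproduce identical hashes.
    """
    if not isinstance(config, dict):
        config = load_config(config)
    else:
        _validate(config)
    outdir = Path(output_dir or config.get("output_dir", "pipeline_out"))
    outdir.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    log = lambda msg: print(f"[cardiosnv +{time.time() - t0:6.1f}s] {msg}", file=sys.stderr)

    seed = int(config["seed"])
    ref_cfg = config.get("reference", {})
    cohort_cfg = dict(config.get("cohort", {}))
    amp_cfg = config.get("amplification", {})

    ages = cohort_cfg.pop("ages", list(synthetic.DEFAULT_DONOR_AGES))
    spec = CohortSpec(
        donors=[(f"donor{i + 1:02d}", float(a)) for i, a in enumerate(ages)],
        amp_params=synthetic.AmplificationParams(**amp_cfg),
        seed=seed,
        **cohort_cfg,
    )
    log("simulating cohort")
    ref = synthetic.generate_reference(
        seed=np.random.SeedSequence(seed).spawn(1)[0], **ref_cfg
    )
    cohort = synthetic.simulate_cohort(spec, ref=ref)

    files: dict[str, Path] = {}
    ref_path = outdir / "reference.fa"
    ref.write_fasta(ref_path)
    files["reference"] = ref_path
    for donor, hets in cohort.germline.items():
        p = outdir / f"germline_{donor}.vcf"
        io.write_germline_vcf(hets, p, sample=donor)
        files[f"germline_{donor}"] = p

    log("per-cell QC, calling and burden")
    prior = config.get("caller", {}).get("prior_artifact_fraction", 0.5)
    burden_df = analyze_cohort(cohort, prior_artifact_fraction=prior)
    p = outdir / "burden.tsv"
    burden_df.to_csv(p, sep="\t", index=False)
    files["burden"] = p

    log("mixed-effects age regression")
    usable = burden_df[~burden_df["qc_fail"]]
    fit = regression.fit_burden_age_model(
        usable["corrected_density"], usable["age"], usable["donor_id"],
        usable["sensitivity"], usable["genome_mb"],
    )
    reg = {
        "slope": fit.slope, "slope_ci": list(fit.slope_ci), "p_age": fit.p_age,
        "intercept": float(fit.params["intercept"]),
        "n_cells": fit.n_cells, "n_donors": fit.n_donors,
    }
    p = outdir / "age_model.json"
    p.write_text(json.dumps(reg, indent=2))
    files["age_model"] = p

    log("signature discovery")
    calls_frames = []
    panel = signatures.load_reference_signatures()
    for cell in cohort.cells:
        res_calls = calling.call_cell(
            cell.evidence, cohort.germline[cell.donor_id],
            calling.calibrate_threshold(prior_artifact_fraction=prior),
        )
        if len(res_calls):
            calls_frames.append(res_calls.assign(cell_id=cell.cell_id))
    if calls_frames:
        calls_all = pd.concat(calls_frames, ignore_index=True)
        mat = signatures.context_matrix(calls_all, ref)
        sig = signatures.nmf_decompose(mat, rank_range=range(2, 5), restarts=20, seed=seed)
        sig.signatures.to_csv(outdir / "signatures.tsv", sep="\t")
        sig.exposures.to_csv(outdir / "exposures.tsv", sep="\t")
        files["signatures"] = outdir / "signatures.tsv"
        files["exposures"] = outdir / "exposures.tsv"

    log("spectra and strand bias")
    ann_seed = np.random.SeedSequence(seed + 1).spawn(3)
    genes, cds_df = synthetic.generate_annotation(ref, n_genes=120, seed=ann_seed[0])
    io.write_gtf(genes, cds_df, outdir / "genes.gtf")
    files["annotation"] = outdir / "genes.gtf"
    if calls_frames:
        calls_all = pd.concat(calls_frames, ignore_index=True)
        ctx = [
            signatures.trinucleotide_context(ref.sequences[c], int(p), r, a)
            for c, p, r, a in zip(
                calls_all["chrom"], calls_all["pos"], calls_all["ref"], calls_all["alt"]
            )
        ]
        calls_ctx = calls_all.assign(context=ctx)
        meta = cohort.metadata().set_index("cell_id")
        calls_ctx["age"] = meta.loc[calls_ctx["cell_id"], "age"].to_numpy()
        group_rows = []
        by_group = {}
        for g in spectra.AGE_GROUPS:
            sub = calls_ctx[calls_ctx["age"].map(spectra.age_group) == g]
            if len(sub) == 0:
                continue
            props = spectra.spectrum_from_contexts(sub["context"], granularity=6)
            n_cells_g = meta.index[meta["age"].map(spectra.age_group) == g].size
            by_group[g] = spectra.AgeGroupSpectrum(
                g, props, mean_burden=len(sub) / max(n_cells_g, 1), n_cells=n_cells_g
            )
            for t, p_ in props.items():
                group_rows.append({"group": g, "type": t, "proportion": p_})
        pd.DataFrame(group_rows).to_csv(outdir / "spectra.tsv", sep="\t", index=False)
        files["spectra"] = outdir / "spectra.tsv"
        if "aged" in by_group and "infant" in by_group:
            net = spectra.net_increase_spectrum(by_group["aged"], by_group["infant"])
            net.rename("net_increase").to_csv(outdir / "net_increase.tsv", sep="\t")
            files["net_increase"] = outdir / "net_increase.tsv"
        strand_tab = spectra.strand_bias_table(calls_ctx, genes)
        strand_tab.to_csv(outdir / "strand_bias.tsv", sep="\t", index=False)
        files["strand_bias"] = outdir / "strand_bias.tsv"

        log("functional annotation and enrichment")
        from . import functional

        cats = functional.annotate_genic(calls_all, genes, cds_df, ref)
        cats.value_counts().rename("count").to_csv(
            outdir / "genic_categories.tsv", sep="\t"
        )
        files["genic_categories"] = outdir / "genic_categories.tsv"
        gene_sets = synthetic.generate_gene_sets(genes, seed=ann_seed[1])
        lengths = pd.Series(
            (genes["end"] - genes["start"]).to_numpy(),
            index=genes["gene_id"], dtype=float,
        )
        mutated = pd.Series(0, index=genes["gene_id"])
        for _, v in calls_all.iterrows():
            hit = genes[
                (genes["chrom"] == v["chrom"])
                & (genes["start"] <= v["pos"]) & (v["pos"] < genes["end"])
            ]
            if len(hit):
                mutated.loc[hit["gene_id"].iloc[0]] = 1
        enr = functional.geneset_enrichment(mutated, gene_sets, lengths, min_mutated=1)
        enr.to_csv(outdir / "geneset_enrichment.tsv", sep="\t", index=False)
        files["geneset_enrichment"] = outdir / "geneset_enrichment.tsv"

    log("KO model")
    ko_cfg = config.get("ko", {})
    params = ko.KOParams(**ko_cfg) if ko_cfg else ko.KOParams()
    curve, ko_stats = ko.cohort_ko_curve(usable, params)
    curve.to_csv(outdir / "ko_curve.tsv", sep="\t", index=False)
    (outdir / "ko_fit.json").write_text(json.dumps(ko_stats, indent=2))
    files["ko_curve"] = outdir / "ko_curve.tsv"
    files["ko_fit"] = outdir / "ko_fit.json"

    manifest = {
        "seed": seed,
        "n_cells": len(cohort.cells),
        "files": {k: {"path": str(v), "sha256": _sha256(v)} for k, v in files.items()},
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    log("done")
    return manifest
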