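import numpy as np
import pandas as pd
import pytest
from scipy import stats

from cardiosnv import contexts, qc, signatures, synthetic
from cardiosnv.contexts import substitution_type


class TestReference:
    def test_gc_within_binomial_ci(self):
        ref = synthetic.generate_reference(1, 10_000, 0.4, seed=1)
        seq = ref.sequences["chr1"]
        gc = sum(seq.count(b) for b in "GC")
        lo, hi = stats.binom.interval(0.99, 10_000, 0.4)
        assert lo <= gc <= hi

    def test_deterministic_given_seed(self):
        a = synthetic.generate_reference(2, 10_000, 0.5, seed=7)
        b = synthetic.generate_reference(2, 10_000, 0.5, seed=7)
        assert a.sequences == b.sequences

    def test_gc_zero_is_all_at(self):
        ref = synthetic.generate_reference(1, 10_000, 0.0, seed=3)
        assert set(ref.sequences["chr1"]) <= {"A", "T"}

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            synthetic.generate_reference(0, 10_000, 0.4)
        with pytest.raises(ValueError):
            synthetic.generate_reference(1, 100, 0.4)

    def test_fasta_round_trip(self, tmp_path, reference_small):
        p = tmp_path / "ref.fa"
        reference_small.write_fasta(p)
        back = synthetic.ReferenceGenome.from_fasta(p)
        assert back.sequences == reference_small.sequences


class TestGermline:
    def test_count_within_poisson_ci(self):
        ref = synthetic.generate_reference(1, 10_000_000, 0.41, seed=5)
        hets = synthetic.generate_germline(ref, 0.67, seed=6)
        lo, hi = stats.poisson.interval(0.99, 0.67 * 10_000)
        assert lo <= len(hets) <= hi

    def test_alt_differs_from_reference(self, reference_small, germline_small):
        seq = reference_small.sequences["chr1"]
        for r in germline_small.itertuples():
            assert seq[r.pos] == r.ref
            assert r.alt != r.ref

    def test_tiny_density_may_be_empty(self):
        ref = synthetic.generate_reference(1, 10_000, 0.4, seed=8)
        hets = synthetic.generate_germline(ref, 1e-4, seed=9)
        assert len(hets) >= 0  # empty is valid

    def test_excessive_density_rejected(self, reference_small):
        with pytest.raises(ValueError):
            synthetic.generate_germline(reference_small, 2000.0)


class TestSomatic:
    def test_zero_rate_zero_intercept(self, reference_small):
        df = synthetic.generate_somatic(
            reference_small, 50.0, 0.0, 0.0, 2, {"scF_like": 1.0}, seed=1
        )
        assert len(df) == 0

    def test_poisson_mean_closed_form(self, reference_default):
        # tetraploid, 20 Mb haploid, rate 0.010/Mb/yr, age 50 -> mean 40
        counts = [
            len(
                synthetic.generate_somatic(
                    reference_default, 50.0, 0.010, 0.0, 4,
                    {"SBS5_like": 1.0}, seed=s,
                )
            )
            for s in range(10)
        ]
        mean = 0.010 * 50 * 4 * reference_default.haploid_mb / 2 * 2  # 40
        lo, hi = stats.poisson.interval(0.99, mean * 10)
        assert lo <= sum(counts) <= hi

    def test_pure_artifact_profile_gives_ct_only(self, reference_small):
        df = synthetic.generate_somatic(
            reference_small, 80.0, 0.02, 0.1, 4, {"scF_like": 1.0}, seed=2
        )
        assert len(df) > 0
        subs = {substitution_type(c) for c in df["context"]}
        assert subs <= {"C>T", "C>A"}  # scF-like support

    def test_context_matches_reference(self, reference_small):
        df = synthetic.generate_somatic(
            reference_small, 80.0, 0.02, 0.1, 2, {"SBS5_like": 1.0}, seed=3
        )
        for r in df.itertuples():
            seq = reference_small.sequences[r.chrom]
            assert contexts.class_of_variant(seq, r.pos, r.ref, r.alt) == r.context

    def test_signature_recovery_of_truth(self, reference_default):
        """96-class frequencies of >=2000 truth variants match the mixture."""
        mix = {"SBS5_like": 0.7, "SBS18_like": 0.3}
        frames = [
            synthetic.generate_somatic(reference_default, 80.0, 0.02, 0.2, 4, mix, seed=s)
            for s in range(15)
        ]
        df = pd.concat(frames)
        assert len(df) >= 2000
        counts = df["context"].value_counts().reindex(contexts.CONTEXT_96, fill_value=0)
        panel = signatures.load_reference_signatures()
        target = 0.7 * panel["SBS5_like"] + 0.3 * panel["SBS18_like"]
        assert signatures.cosine(counts.to_numpy(), target.to_numpy()) >= 0.98


class TestAmplification:
    def test_no_dropout_limit(self, reference_small, germline_small):
        params = synthetic.AmplificationParams(
            locus_dropout_rate=0.0, allelic_dropout_rate=0.0,
            unevenness_sigma=0.0, artifact_rate_per_mb=0.0,
        )
        cell = synthetic.simulate_cell(
            reference_small, germline_small, params, 2, 0.0, 0.0, 0.0,
            {"SBS5_like": 1.0}, seed=4,
        )
        ev = cell.evidence
        # every het covered on both alleles around mean depth
        assert (ev["depth"] >= 5).mean() > 0.999
        assert ev["depth"].mean() == pytest.approx(30.0, rel=0.05)
        assert (np.minimum(ev["ref_reads"], ev["alt_reads"]) >= 2).mean() > 0.99

    def test_no_artifacts_means_no_extra_sites(self, reference_small, germline_small):
        params = synthetic.AmplificationParams(artifact_rate_per_mb=0.0)
        cell = synthetic.simulate_cell(
            reference_small, germline_small, params, 2, 50.0, 0.01, 0.05,
            {"SBS5_like": 1.0}, seed=5,
        )
        n_truth = len(cell.truth_somatic) + len(germline_small)
        assert len(cell.evidence) == n_truth
        assert len(cell.truth_artifacts) == 0

    def test_evidence_is_union_of_truth_and_artifacts(self, diploid_cell, germline_small):
        ev_keys = set(zip(diploid_cell.evidence["chrom"], diploid_cell.evidence["pos"]))
        truth = set(zip(diploid_cell.truth_somatic["chrom"], diploid_cell.truth_somatic["pos"]))
        arts = set(zip(diploid_cell.truth_artifacts["chrom"], diploid_cell.truth_artifacts["pos"]))
        germ = set(zip(germline_small["chrom"], germline_small["pos"]))
        assert truth.isdisjoint(arts)
        assert ev_keys == truth | arts | germ

    def test_linkage_count_invariants(self, diploid_cell):
        ev = diploid_cell.evidence
        linked = ev["c_ref_h1"] + ev["c_ref_h2"] + ev["c_alt_h1"] + ev["c_alt_h2"]
        assert (linked <= ev["depth"]).all()
        assert (ev["c_alt_h1"] + ev["c_alt_h2"] <= ev["alt_reads"]).all()

    def test_determinism(self, reference_small, germline_small, default_mix):
        params = synthetic.AmplificationParams()
        a = synthetic.simulate_cell(
            reference_small, germline_small, params, 2, 50.0, 0.01, 0.05,
            default_mix, seed=6,
        )
        b = synthetic.simulate_cell(
            reference_small, germline_small, params, 2, 50.0, 0.01, 0.05,
            default_mix, seed=6,
        )
        pd.testing.assert_frame_equal(a.evidence, b.evidence)
        pd.testing.assert_frame_equal(a.bins, b.bins)


class TestTetraploid:
    def test_merging_with_self_doubles_counts(self, diploid_cell):
        merged = synthetic.make_tetraploid(diploid_cell.evidence, diploid_cell.evidence)
        for col in ["depth", "ref_reads", "alt_reads", "c_alt_h1"]:
            assert (merged[col] == 2 * diploid_cell.evidence[col]).all()

    def test_mismatched_sites_rejected(self, diploid_cell):
        with pytest.raises(ValueError):
            synthetic.make_tetraploid(
                diploid_cell.evidence, diploid_cell.evidence.iloc[:-1]
            )

    def test_empty_realization_is_identity(self, diploid_cell):
        zero = diploid_cell.evidence.copy()
        for col in ["depth", "ref_reads", "alt_reads",
                    "c_ref_h1", "c_ref_h2", "c_alt_h1", "c_alt_h2"]:
            zero[col] = 0
        merged = synthetic.make_tetraploid(diploid_cell.evidence, zero)
        pd.testing.assert_frame_equal(merged, diploid_cell.evidence)

    def test_locus_dropout_product_law(self, reference_default):
        """Tetraploid locus-dropout rate equals the product of its origins'
        rates, within 3 binomial standard errors over >= 5000 hets."""
        germ = synthetic.generate_germline(reference_default, 0.67, seed=20)
        assert len(germ) >= 5000
        params = synthetic.AmplificationParams(
            locus_dropout_rate=0.15, allelic_dropout_rate=0.1, artifact_rate_per_mb=0.0
        )
        somatic = synthetic.generate_somatic(
            reference_default, 0.0, 0.0, 0.0, 4, {"SBS5_like": 1.0}, seed=21
        )
        sites = synthetic._assemble_sites(
            germ, somatic, synthetic.generate_artifacts(
                reference_default, params, 2, np.random.default_rng(22), set()
            ),
        )
        ev_a, _ = synthetic.simulate_realization(
            sites, germ, reference_default, params, 0, 7.5, seed=23
        )
        ev_b, _ = synthetic.simulate_realization(
            sites, germ, reference_default, params, 1, 7.5, seed=24
        )
        merged = synthetic.make_tetraploid(ev_a, ev_b)
        la = (ev_a["depth"] < 5).mean()
        lb = (ev_b["depth"] < 5).mean()
        l4 = (merged["depth"] < 5).mean()
        n = len(merged)
        se = np.sqrt(la * lb * (1 - la * lb) / n)
        assert abs(l4 - la * lb) <= 3 * se
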