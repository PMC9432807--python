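import numpy as np
import pandas as pd
import pytest
from scipy import stats

from cardiosnv import calling, synthetic


class TestLinkage:
    @pytest.mark.parametrize(
        "c_ref,c_alt,expected",
        [
            ((0, 4), (3, 0), "pass"),        # alt on hap1, no ref on hap1
            ((4, 0), (0, 3), "pass"),        # mirrored
            ((0, 0), (2, 1), "fail"),        # alt on both haplotypes
            ((2, 4), (3, 0), "fail"),        # ref reads on the alt haplotype
            ((5, 5), (0, 0), "unphasable"),  # no phasable alt reads
            ((0, 0), (0, 0), "unphasable"),
        ],
    )
    def test_rule(self, c_ref, c_alt, expected):
        assert calling.test_linkage(c_ref[0], c_ref[1], c_alt[0], c_alt[1]) == expected

    def test_vectorized(self):
        status = calling.test_linkage([0, 0], [4, 0], [3, 2], [0, 1])
        assert list(status) == ["pass", "fail"]


def _posterior_oracle(depth, af, geom_p, prior_artifact, target=0.9, kmax=10):
    """Exhaustive evaluation of P(true | linkage pass, phasable >= k)."""
    for k in range(1, kmax + 1):
        pt = (1 - prior_artifact) * sum(
            stats.binom.pmf(x, depth, af) for x in range(k, depth + 1)
        )
        pa = prior_artifact * sum(
            stats.geom.pmf(x, geom_p) for x in range(k, 200)
        )
        if pt + pa > 0 and pt / (pt + pa) >= target:
            return k
    return 2


class TestCalibration:
    def test_no_artifacts_gives_k1(self):
        model = calling.calibrate_threshold(prior_artifact_fraction=0.0)
        assert model.threshold_k == 1

    @pytest.mark.parametrize("prior", [0.1, 0.3, 0.5, 0.8])
    def test_matches_brute_force_posterior(self, prior):
        model = calling.calibrate_threshold(
            depth=30, allele_fraction=0.5, artifact_geom_p=0.5,
            prior_artifact_fraction=prior,
        )
        assert model.threshold_k == _posterior_oracle(30, 0.5, 0.5, prior)

    def test_degenerate_error_model_rejected(self):
        with pytest.raises(ValueError):
            calling.calibrate_threshold(artifact_geom_p=0.0)


def _candidate(c_ref, c_alt, alt_reads=10):
    return pd.DataFrame({
        "chrom": ["chr1"], "pos": [500], "ref": ["A"], "alt": ["T"],
        "depth": [30], "ref_reads": [30 - alt_reads], "alt_reads": [alt_reads],
        "het_pos": [600], "c_ref_h1": [c_ref[0]], "c_ref_h2": [c_ref[1]],
        "c_alt_h1": [c_alt[0]], "c_alt_h2": [c_alt[1]],
    })


class TestCallCell:
    def test_single_clean_candidate_called(self):
        ev = _candidate((0, 5), (3, 0))
        germ = pd.DataFrame({"chrom": ["chr1"], "pos": [600]})
        model = calling.CallerModel(threshold_k=3, estimated_precision=0.95)
        assert len(calling.call_cell(ev, germ, model)) == 1

    def test_germline_sites_never_called(self):
        ev = _candidate((0, 5), (3, 0))
        germ = pd.DataFrame({"chrom": ["chr1"], "pos": [500]})
        model = calling.CallerModel(threshold_k=1, estimated_precision=0.95)
        assert len(calling.call_cell(ev, germ, model)) == 0

    def test_no_somatic_no_artifacts_yields_no_calls(
        self, reference_small, germline_small
    ):
        params = synthetic.AmplificationParams(artifact_rate_per_mb=0.0)
        cell = synthetic.simulate_cell(
            reference_small, germline_small, params, 2, 0.0, 0.0, 0.0,
            {"SBS5_like": 1.0}, seed=30,
        )
        model = calling.calibrate_threshold()
        assert len(calling.call_cell(cell.evidence, germline_small, model)) == 0

    def test_calls_subset_of_truth_union_artifacts(self, diploid_cell, germline_small):
        model = calling.calibrate_threshold()
        calls = calling.call_cell(diploid_cell.evidence, germline_small, model)
        truth = set(zip(diploid_cell.truth_somatic["chrom"], diploid_cell.truth_somatic["pos"]))
        arts = set(zip(diploid_cell.truth_artifacts["chrom"], diploid_cell.truth_artifacts["pos"]))
        for r in calls.itertuples():
            assert (r.chrom, r.pos) in truth | arts


class TestSensitivity:
    def test_monotone_decreasing_in_threshold(self, diploid_cell, germline_small):
        sens = [
            calling.estimate_sensitivity(
                diploid_cell.evidence, germline_small,
                calling.CallerModel(threshold_k=k, estimated_precision=1.0),
            )
            for k in (1, 2, 4, 8)
        ]
        assert sens == sorted(sens, reverse=True)

    def test_all_locus_dropped_gives_zero(self, germline_small):
        ev = pd.DataFrame({
            "chrom": germline_small["chrom"], "pos": germline_small["pos"],
            "ref": germline_small["ref"], "alt": germline_small["alt"],
            "depth": 0, "ref_reads": 0, "alt_reads": 0, "het_pos": -1,
            "c_ref_h1": 0, "c_ref_h2": 0, "c_alt_h1": 0, "c_alt_h2": 0,
        })
        model = calling.CallerModel(threshold_k=1, estimated_precision=1.0)
        assert calling.estimate_sensitivity(ev, germline_small, model) == 0.0

    def test_matches_analytic_linkage_geometry_oracle(
        self, reference_small, germline_small
    ):
        """With no dropout, sensitivity at k=1 equals the analytic
        expectation from linkage geometry and the binomial sampling law."""
        params = synthetic.AmplificationParams(
            locus_dropout_rate=0.0, allelic_dropout_rate=0.0,
            unevenness_sigma=0.0, artifact_rate_per_mb=0.0, mean_depth=60,
        )
        cell = synthetic.simulate_cell(
            reference_small, germline_small, params, 2, 0.0, 0.0, 0.0,
            {"SBS5_like": 1.0}, seed=31,
        )
        ev = cell.evidence
        model = calling.CallerModel(threshold_k=1, estimated_precision=1.0)
        observed = calling.estimate_sensitivity(ev, germline_small, model)
        # oracle: detection requires alt discovery (>=2 reads, essentially
        # sure at 30x per allele) and >= 1 linked alt read, Binomial(alt, p)
        window = params.linkage_window
        d = np.abs(ev["het_pos"] - ev["pos"])
        p_link = np.clip(1.0 - d / window, 0.0, 1.0) * (ev["het_pos"] >= 0)
        alt = ev["alt_reads"].to_numpy()
        p_detect = np.where(alt >= 2, 1.0 - (1.0 - p_link) ** alt, 0.0)
        expected = p_detect.mean()
        se = np.sqrt((p_detect * (1 - p_detect)).sum()) / len(ev)
        assert abs(observed - expected) <= max(3 * se, 0.01)

    def test_requires_enough_hets(self):
        ev = _candidate((0, 5), (3, 0))
        germ = pd.DataFrame({"chrom": ["chr1"], "pos": [500]})
        model = calling.CallerModel(threshold_k=1, estimated_precision=1.0)
        with pytest.raises(ValueError):
            calling.estimate_sensitivity(ev, germ, model)


def test_tetraploid_variant_callable_only_without_interferer(
    reference_small, germline_small, default_mix
):
    """A 1/4-haplotype variant can show complete linkage only when the
    duplicate same-haplotype reference copy contributed no reads (dropout)
    or no phasable reads; interferer reads that ARE linked always fail."""
    cells = [
        synthetic.simulate_cell(
            reference_small, germline_small, synthetic.AmplificationParams(),
            4, 80.0, 0.02, 0.1, default_mix, seed=700 + s,
        )
        for s in range(4)
    ]
    n_pass_dropped, n_pass_present, n_present = 0, 0, 0
    for cell in cells:
        truth = cell.truth_somatic
        ev = cell.evidence
        idx = pd.MultiIndex.from_frame(ev[["chrom", "pos"]])
        loc = idx.get_indexer(pd.MultiIndex.from_frame(truth[["chrom", "pos"]]))
        for (_, t), j in zip(truth.iterrows(), loc):
            row = ev.iloc[j]
            status = calling.test_linkage(
                row["c_ref_h1"], row["c_ref_h2"], row["c_alt_h1"], row["c_alt_h2"]
            )
            # pass requires zero linked ref reads on the variant haplotype,
            # which are exactly the interferer's linked reads
            c_ref_h = row["c_ref_h1"] if t["hap"] == 0 else row["c_ref_h2"]
            if status == "pass":
                assert c_ref_h == 0
            if t["interferer_reads"] == 0:
                n_pass_dropped += status == "pass"
            else:
                n_present += 1
                n_pass_present += status == "pass"
    # linkage pass should be driven by interferer dropout
    assert n_pass_dropped > 0
    assert n_pass_present <= 0.25 * max(n_present, 1)


def test_precision_at_calibrated_threshold(reference_default, default_mix):
    """Calibrated calling keeps >= 90% of calls true on default diploid
    cells (three independent seeds)."""
    germ = synthetic.generate_germline(reference_default, 0.67, seed=40)
    for seed in (41, 42, 43):
        cells = [
            synthetic.simulate_cell(
                reference_default, germ, synthetic.AmplificationParams(),
                2, 80.0, 0.01, 0.05, default_mix, seed=seed * 100 + i,
            )
            for i in range(4)
        ]
        model = calling.calibrate_threshold()
        n_true, n_calls = 0, 0
        for cell in cells:
            calls = calling.call_cell(cell.evidence, germ, model)
            truth = set(zip(cell.truth_somatic["chrom"], cell.truth_somatic["pos"]))
            n_calls += len(calls)
            n_true += sum((c, p) in truth for c, p in zip(calls["chrom"], calls["pos"]))
        assert n_calls > 0
        assert n_true / n_calls >= 0.9
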