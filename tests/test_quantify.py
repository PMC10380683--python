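"""Estimators: Poisson concentration, VCN, HR%, concatemer%, expression."""

import math

import numpy as np
import pytest

import dualaav as da
from dualaav.quantify import (
    ConcentrationEstimate,
    EmptyRunError,
    GenomicContaminationError,
    ProtocolMismatchError,
    SaturatedCountsError,
    UndefinedEfficiencyError,
    ZeroReferenceError,
    concatemer_fraction,
    expression_profile,
    hr_efficiency,
    poisson_concentration,
    quant_report,
    vcn,
)


def ce(lam, se=1e-6, dv=8.5e-4):
    """Hand-built estimate at an exact occupancy (for formula tests)."""
    return ConcentrationEstimate(
        k=0, N=1, lambda_hat=lam, lambda_se=se,
        lambda_ci95=(lam - 1.96 * se, lam + 1.96 * se),
        droplet_volume=dv, dilution=1.0,
    )


class TestPoissonConcentration:
    def test_zero_positives_zero_lambda(self):
        est = poisson_concentration(0, 20000)
        assert est.lambda_hat == 0.0 and est.copies_per_ul == 0.0

    def test_half_positive_gives_ln2(self):
        est = poisson_concentration(10000, 20000)
        assert est.lambda_hat == pytest.approx(math.log(2), abs=1e-12)

    def test_worked_example_copies_per_ul(self):
        # 1813/20000 positives in 0.85 nL droplets
        est = poisson_concentration(1813, 20000, droplet_volume=8.5e-4)
        assert est.lambda_hat == pytest.approx(0.0950, abs=2e-4)
        assert est.copies_per_ul == pytest.approx(111.8, abs=0.2)

    def test_delta_se_formula(self):
        k, N = 1813, 20000
        est = poisson_concentration(k, N)
        p = k / N
        assert est.lambda_se == pytest.approx(math.sqrt(p / (N * (1 - p))))
        lo, hi = est.lambda_ci95
        assert lo <= est.lambda_hat <= hi

    def test_exact_ci_contains_delta_point(self):
        est = poisson_concentration(50, 20000, ci="exact")
        lo, hi = est.lambda_ci95
        assert lo < est.lambda_hat < hi
        assert poisson_concentration(0, 100, ci="exact").lambda_ci95[0] == 0.0

    def test_saturated_and_empty_runs_rejected(self):
        with pytest.raises(SaturatedCountsError):
            poisson_concentration(100, 100)
        with pytest.raises(EmptyRunError):
            poisson_concentration(0, 0)
        with pytest.raises(ValueError):
            poisson_concentration(-1, 100)


class TestVcn:
    def test_ratio_with_titin(self):
        # 300 vs 200 copies/µL at ploidy 2 -> 3.0 vg per diploid genome
        target, titin = ce(300 * 8.5e-4), ce(200 * 8.5e-4)
        assert vcn(target, titin).value == pytest.approx(3.0)

    def test_zero_target_zero_vcn(self):
        assert vcn(ce(0.0), ce(0.2)).value == 0.0

    def test_zero_reference_rejected(self):
        with pytest.raises(ZeroReferenceError):
            vcn(ce(0.3), ce(0.0))

    def test_recovery_against_ground_truth(self):
        # end-to-end: per-run VCN estimate against that run's own truth
        sc = da.paper_like_scenario("TA")
        hits, errs = 0, []
        for seed in range(20):
            rep, gt = da.run_in_memory(sc, seed=seed)
            true5 = gt.T5 / sc.sim.host_genomes
            errs.append(abs(rep.vcn5.value - true5))
            hits += rep.vcn5.covers(true5)
        assert hits >= 16  # ~95% nominal coverage
        assert np.mean(errs) < 0.2


class TestHrEfficiency:
    def test_limiting_vector_denominator(self):
        est = hr_efficiency(ce(2.0), ce(4.0), ce(5.0))
        assert est.value == pytest.approx(50.0)

    def test_zero_rec_zero_percent(self):
        assert hr_efficiency(ce(0.0), ce(4.0), ce(5.0)).value == 0.0

    def test_zero_limiting_vector_rejected(self):
        with pytest.raises(UndefinedEfficiencyError):
            hr_efficiency(ce(1.0), ce(0.0), ce(5.0))

    def test_scale_invariance(self):
        a = hr_efficiency(ce(2.0), ce(4.0), ce(5.0))
        b = hr_efficiency(ce(6.0), ce(12.0), ce(15.0))
        assert a.value == pytest.approx(b.value)


class TestConcatemerFraction:
    def test_sum_over_vector_concentrations(self):
        juncs = [ce(0.10), ce(0.10), ce(0.05), ce(0.05)]
        est = concatemer_fraction(juncs, ce(3.0), ce(3.0))
        assert est.value == pytest.approx(5.0)

    def test_no_junctions_zero_percent(self):
        assert concatemer_fraction([], ce(3.0), ce(3.0)).value == 0.0

    def test_single_multiplexed_estimate_accepted(self):
        est = concatemer_fraction(ce(0.30), ce(3.0), ce(3.0))
        assert est.value == pytest.approx(5.0)

    def test_zero_vectors_rejected(self):
        with pytest.raises(ZeroReferenceError):
            concatemer_fraction([ce(0.1)], ce(0.0), ce(0.0))

    def test_raw_droplet_variant(self):
        j = poisson_concentration(100, 20000)
        v5 = poisson_concentration(1000, 20000)
        v3 = poisson_concentration(1000, 20000)
        est = concatemer_fraction([j], v5, v3, raw_droplets=True)
        assert est.value == pytest.approx(100 / 2000 * 100)


class TestExpression:
    def test_specific_verdict(self):
        prof = expression_profile(
            {"recombined": ce(1000 * 8.5e-4), "five_leak": ce(20 * 8.5e-4),
             "three_aberrant": ce(0.0)}
        )
        assert prof.specific
        assert prof.five_over_rec == pytest.approx(0.02)

    def test_three_prime_signal_breaks_specificity(self):
        prof = expression_profile(
            {"recombined": ce(1.0), "five_leak": ce(0.0),
             "three_aberrant": ce(0.05)}
        )
        assert not prof.specific

    def test_minus_rt_contamination_rejected(self):
        rt = {"recombined": poisson_concentration(5000, 20000)}
        with pytest.raises(GenomicContaminationError):
            expression_profile(rt, minus_rt={"recombined": (500, 20000)})

    def test_leak_ratio_recovery_from_simulator(self):
        # FIVE/REC concentration ratio ~ ε·free5 / (r·R)
        p = da.SimParams(hr_fraction=0.5, concat_fraction=0.0,
                         host_genomes=2000, seed=21)
        pop, gt = da.simulate_sample(p)
        eps, r = 0.02, 2.0
        ratios = []
        for seed in range(30):
            tp = da.simulate_transcripts(pop, eps, r, seed=seed)
            ratios.append(tp.five_leak / tp.recombined)
        expected = eps * (gt.T5 - gt.R) / (r * gt.R)
        assert np.mean(ratios) == pytest.approx(expected, rel=0.1)


class TestQuantReport:
    def _runs(self, rec_lam=0.4, junc_lam=0.04):
        N = 20000
        mk = lambda lam: poisson_concentration(
            int(round(N * (1 - math.exp(-lam)))), N)
        vcn_run = {"FIVE": mk(0.8), "THREE": mk(1.2), "REC": mk(rec_lam),
                   "TTN": mk(0.2)}
        junc_run = {"FIVE": mk(0.8), "THREE": mk(1.2),
                    "JUNC_A": mk(junc_lam), "JUNC_B": mk(junc_lam / 2),
                    "JUNC_C": mk(junc_lam / 2), "JUNC_D": mk(junc_lam / 4)}
        return vcn_run, junc_run

    def test_fold_ratio(self):
        vcn_run, junc_run = self._runs()
        rep = quant_report(vcn_run, "SmaI", junc_run, "AleI")
        assert rep.fold_hr_over_concat == pytest.approx(
            rep.hr_pct.value / rep.concat_pct.value)
        assert 10 < rep.fold_hr_over_concat < 20

    def test_zero_concatemers_flagged_infinite(self):
        vcn_run, junc_run = self._runs(junc_lam=0.0)
        for k in list(junc_run):
            if k.startswith("JUNC"):
                junc_run[k] = poisson_concentration(0, 20000)
        rep = quant_report(vcn_run, "SmaI", junc_run, "AleI")
        assert rep.fold_hr_over_concat == math.inf
        assert "no_concatemers_detected" in rep.flags

    def test_protocol_mismatch_raises_or_flags(self):
        vcn_run, junc_run = self._runs()
        with pytest.raises(ProtocolMismatchError):
            quant_report(vcn_run, None, junc_run, "AleI")
        rep = quant_report(vcn_run, None, junc_run, "AleI",
                           allow_protocol_mismatch=True)
        assert any("protocol_mismatch" in f for f in rep.flags)

    def test_report_serialization(self, tmp_path):
        vcn_run, junc_run = self._runs()
        rep = quant_report(vcn_run, "SmaI", junc_run, "AleI")
        rep.to_json(tmp_path / "report.json")
        import json

        d = json.loads((tmp_path / "report.json").read_text())
        assert d["hr_pct"]["value"] == pytest.approx(rep.hr_pct.value)
        row = rep.to_tsv_row()
        assert row["hr_pct"] == rep.hr_pct.value
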