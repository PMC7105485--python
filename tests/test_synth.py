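import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.special import logit

from gwaspipe import synth
from gwaspipe.errors import ConfigError, DataError, LdInfeasibleError


class TestSpecs:
    def test_variant_freq_bounds(self):
        with pytest.raises(ConfigError):
            synth.VariantSpec("v", "A", 0.0, 0.1)
        with pytest.raises(ConfigError):
            synth.VariantSpec("v", "A", 1.0, 0.1)

    def test_interaction_distinct_variants(self):
        with pytest.raises(ConfigError):
            synth.InteractionSpec("v", "v", 0.1)

    def test_cohort_spec_unresolved_reference(self):
        v = synth.VariantSpec("a", "A", 0.5, 0.0)
        with pytest.raises(ConfigError):
            synth.CohortSpec(
                ethnicity="east_asian",
                variants=(v,),
                interactions=(synth.InteractionSpec("a", "b", 0.1),),
            )

    def test_serology_rate_ordering(self):
        with pytest.raises(ConfigError):
            synth.SerologySpec(0.0, 0.4, control_exceed_rate_20=0.2, control_exceed_rate_2=0.1)


class TestLdHaplotypes:
    def test_independence_joint_frequency(self):
        # r2 = 0 implies freq(1,1) = p*q
        haps = synth.make_ld_haplotypes(0.3, 0.15, 0.0, 200_000, seed=1)
        joint = np.mean((haps[:, 0] == 1) & (haps[:, 1] == 1))
        assert joint == pytest.approx(0.045, abs=0.003)

    def test_target_r2_realized(self):
        haps = synth.make_ld_haplotypes(0.30, 0.15, 0.40, 100_000, seed=2)
        r = np.corrcoef(haps[:, 0], haps[:, 1])[0, 1]
        assert r**2 == pytest.approx(0.40, abs=0.02)
        assert haps[:, 0].mean() == pytest.approx(0.30, abs=0.01)
        assert haps[:, 1].mean() == pytest.approx(0.15, abs=0.01)

    def test_infeasible_r2_reports_maximum(self):
        # D_max = min(0.5*0.99, 0.01*0.5) = 0.005; r2_max = 0.005^2/(0.25*0.0099)
        with pytest.raises(LdInfeasibleError) as err:
            synth.make_ld_haplotypes(0.5, 0.01, 0.9, 100)
        assert err.value.r2_max == pytest.approx(0.005**2 / (0.25 * 0.0099), rel=1e-9)


class TestSimulateGenotypes:
    def test_allele_frequency_converges(self):
        spec = synth.CohortSpec(
            ethnicity="east_asian",
            variants=(synth.VariantSpec("v", "A", 0.7, 0.0),),
        )
        geno, _ = synth.simulate_genotypes(spec, 50_000, seed=3)
        assert geno["v"].mean() / 2 == pytest.approx(0.7, abs=0.005)

    def test_hwe_chi_square(self):
        spec = synth.CohortSpec(
            ethnicity="east_asian",
            variants=(synth.VariantSpec("v", "A", 0.7, 0.0),),
        )
        geno, _ = synth.simulate_genotypes(spec, 50_000, seed=4)
        counts = geno["v"].value_counts().reindex([0.0, 1.0, 2.0], fill_value=0)
        p_hat = geno["v"].mean() / 2
        n = len(geno)
        expected = n * np.array(
            [(1 - p_hat) ** 2, 2 * p_hat * (1 - p_hat), p_hat**2]
        )
        chi2 = float(((counts.to_numpy() - expected) ** 2 / expected).sum())
        assert stats.chi2.sf(chi2, 1) > 0.001

    def test_determinism(self):
        spec = synth.east_asian_spec(seed=5)
        g1, _ = synth.simulate_genotypes(spec, 1000, seed=9)
        g2, _ = synth.simulate_genotypes(spec, 1000, seed=9)
        pd.testing.assert_frame_equal(g1, g2)


class TestCalibrateIntercept:
    def test_null_effects_closed_form(self):
        v = synth.VariantSpec("v", "A", 0.5, 0.0)
        c = synth.calibrate_intercept(0.001, (v,))
        assert c == pytest.approx(float(logit(0.001)), abs=1e-9)
        assert c == pytest.approx(-6.9068, abs=1e-4)

    def test_half_prevalence_zero_intercept(self):
        v = synth.VariantSpec("v", "A", 0.5, 0.0)
        assert synth.calibrate_intercept(0.5, (v,)) == pytest.approx(0.0, abs=1e-9)

    def test_attained_prevalence_monte_carlo(self):
        spec = synth.east_asian_spec(prevalence=0.001, seed=0)
        intercept = synth.calibrate_intercept(
            0.001, spec.variants, spec.interactions, seed=77
        )
        geno, _ = synth.simulate_genotypes(spec, 1_000_000, seed=78)
        lp = synth.linear_predictor(geno, spec.variants, spec.interactions)
        rng = np.random.default_rng(79)
        prevalence = np.mean(rng.random(len(lp)) < 1 / (1 + np.exp(-(intercept + lp))))
        assert prevalence == pytest.approx(0.001, rel=0.10)


class TestSimulateCaseControl:
    def test_quotas_exact(self, ea_cohort):
        assert ea_cohort.n_cases == 1500
        assert ea_cohort.n_controls == 3000

    def test_control_frequencies_match_spec(self, ea_cohort):
        spec = synth.east_asian_spec(n_cases=1500, n_controls=3000, prevalence=0.01, seed=11)
        controls = ea_cohort.genotypes[ea_cohort.status == 0]
        for v in spec.variants:
            p = v.control_allele_freq
            se = math.sqrt(p * (1 - p) / (2 * len(controls)))
            assert controls[v.variant_id].mean() / 2 == pytest.approx(p, abs=4 * se)

    def test_null_model_equal_frequencies(self):
        spec = synth.CohortSpec(
            ethnicity="east_asian",
            variants=(synth.VariantSpec("v", "A", 0.4, 0.0),),
            prevalence=0.05,
            n_cases=2000,
            n_controls=2000,
            seed=6,
        )
        cohort = synth.simulate_case_control(spec, batch_size=100_000)
        cases = cohort.genotypes[cohort.status == 1]["v"].mean() / 2
        ctrls = cohort.genotypes[cohort.status == 0]["v"].mean() / 2
        se = math.sqrt(2 * 0.4 * 0.6 / (2 * 2000))
        assert cases - ctrls == pytest.approx(0.0, abs=4 * se)

    def test_risk_allele_enriched_in_cases(self):
        spec = synth.CohortSpec(
            ethnicity="east_asian",
            variants=(synth.VariantSpec("v", "C", 0.70, math.log(2.81)),),
            prevalence=0.01,
            n_cases=1000,
            n_controls=1000,
            seed=7,
        )
        cohort = synth.simulate_case_control(spec, batch_size=200_000)
        cases = cohort.genotypes[cohort.status == 1]["v"].mean()
        ctrls = cohort.genotypes[cohort.status == 0]["v"].mean()
        assert cases > ctrls

    def test_reproducibility_bit_identical(self):
        spec = synth.east_asian_spec(n_cases=200, n_controls=300, prevalence=0.02, seed=42)
        c1 = synth.simulate_case_control(spec, batch_size=50_000)
        c2 = synth.simulate_case_control(spec, batch_size=50_000)
        pd.testing.assert_frame_equal(c1.genotypes, c2.genotypes)
        pd.testing.assert_frame_equal(c1.phenotypes, c2.phenotypes)

    def test_quota_unreachable(self):
        spec = synth.CohortSpec(
            ethnicity="east_asian",
            variants=(synth.VariantSpec("v", "A", 0.5, 0.0),),
            prevalence=0.001,
            n_cases=1000,
            n_controls=10,
            seed=8,
        )
        with pytest.raises(Exception, match="quota"):
            synth.simulate_case_control(spec, batch_size=1000, max_batches=2)


class TestSerology:
    def test_requires_grs_column(self, ea_cohort):
        cohort = synth.Cohort(
            genotypes=ea_cohort.genotypes,
            phenotypes=ea_cohort.phenotypes[["status"]].copy(),
        )
        with pytest.raises(DataError, match="grs"):
            synth.simulate_antibody(cohort, synth.default_serology("east_asian"))

    def test_case_sensitivity_near_60pct(self, ea_scored):
        titers = synth.simulate_antibody(
            ea_scored, synth.default_serology("east_asian"), seed=13
        )
        sens = np.mean(titers[ea_scored.status == 1] >= 20)
        assert sens == pytest.approx(0.60, abs=0.03)

    def test_zero_exceed_rate_all_controls_below_20(self, ea_scored):
        serology = synth.default_serology("east_asian")
        assert serology.control_exceed_rate_20 == 0.0
        titers = synth.simulate_antibody(ea_scored, serology, seed=14)
        assert (titers[ea_scored.status == 0] < 20).all()

    def test_positive_slope_orders_grs(self, ea_scored):
        titers = synth.simulate_antibody(
            ea_scored, synth.default_serology("east_asian"), seed=15
        )
        grs = ea_scored.phenotypes["grs"].to_numpy()
        cases = ea_scored.status == 1
        seropos = cases & (titers >= 20)
        seroneg = cases & (titers < 20)
        assert grs[seropos].mean() > grs[seroneg].mean()

    def test_titers_nonnegative(self, ea_scored):
        titers = synth.simulate_antibody(
            ea_scored, synth.default_serology("east_asian"), seed=16
        )
        assert (titers >= 0).all()


class TestResidues:
    def test_published_risk_residues(self):
        table = synth.default_drb1_residues()
        assert table.residue("DRB1*1501", 71) == "Ala"
        assert table.residue("DRB1*0301", 74) == "Arg"
        assert table.residue("DRB1*0301", 71) == "Lys"

    def test_homozygote_dosage_two_everywhere(self):
        table = synth.default_drb1_residues()
        haps = np.array([["DRB1*1501", "DRB1*1501"]], dtype=object)
        residues = synth.assign_residues(haps, table)
        for pos in table.positions:
            dosage = synth.residue_dosages(residues[pos])
            assert dosage.iloc[0].max() == 2.0
            assert dosage.iloc[0].sum() == 2.0

    def test_phase_preserved(self):
        table = synth.default_drb1_residues()
        haps = np.array([["DRB1*1501", "DRB1*0301"]], dtype=object)
        residues = synth.assign_residues(haps, table)
        assert residues[71][0, 0] == "Ala"
        assert residues[71][0, 1] == "Lys"

    def test_unmapped_allele_named(self):
        table = synth.default_drb1_residues()
        haps = np.array([["DRB1*9999", "DRB1*0301"]], dtype=object)
        with pytest.raises(DataError, match="DRB1\\*9999"):
            synth.assign_residues(haps, table)


class TestDefaultSpecCalibration:
    def test_control_sd_tie_in(self, ea_cohort):
        # simulated control raw-GRS SD within 5% of the published 1.0033
        from gwaspipe import scores

        definition = scores.load_score_definition("east_asian")
        raw = scores.compute_grs(ea_cohort.genotypes, definition)["grs_raw"]
        sd = raw[ea_cohort.status == 0].std(ddof=1)
        assert sd == pytest.approx(1.0033, rel=0.05)

    def test_analytic_variance_matches_simulation(self):
        spec = synth.east_asian_spec(seed=0)
        freqs = {v.variant_id: v.control_allele_freq for v in spec.variants}
        weights = {v.variant_id: (v.effect_allele, v.log_odds) for v in spec.variants}
        it = spec.interactions[0]
        var = synth.grs_model_variance(weights, (it.variant_a, it.variant_b, it.log_odds), freqs)
        geno, _ = synth.simulate_genotypes(spec, 200_000, seed=21)
        lp = synth.linear_predictor(geno, spec.variants, spec.interactions)
        assert lp.var() == pytest.approx(var, rel=0.03)
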