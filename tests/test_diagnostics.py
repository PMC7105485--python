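import numpy as np
import pandas as pd
import pytest

from gwaspipe import diagnostics, synth
from gwaspipe.diagnostics import auroc, cutoff_table, decile_or, idi_nri, phenotype_association
from gwaspipe.errors import DataError


def _brute_force_auc(cases, controls):
    wins = sum(
        1.0 if c > k else 0.5 if c == k else 0.0 for c in cases for k in controls
    )
    return wins / (len(cases) * len(controls))


class TestAuroc:
    def test_four_pair_example(self):
        scores = np.array([3.0, 1.0, 2.0, 0.0])
        status = np.array([1, 1, 0, 0])
        assert auroc(scores, status).auroc == pytest.approx(0.75, rel=1e-12)

    def test_perfect_separation(self):
        scores = np.r_[np.arange(10, 20), np.arange(10)].astype(float)
        status = np.r_[np.ones(10, int), np.zeros(10, int)]
        assert auroc(scores, status).auroc == 1.0

    def test_constant_scores_degenerate(self):
        r = auroc(np.ones(20), np.r_[np.ones(10, int), np.zeros(10, int)])
        assert r.auroc == 0.5
        assert r.degenerate

    def test_exhaustive_concordance_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(25):
            n = int(rng.integers(10, 200))
            scores = rng.normal(0, 1, n)
            if rng.random() < 0.5:
                scores = np.round(scores, 1)  # force ties
            status = rng.integers(0, 2, n)
            if status.sum() in (0, n):
                continue
            expected = _brute_force_auc(scores[status == 1], scores[status == 0])
            assert auroc(scores, status).auroc == pytest.approx(expected, abs=1e-12)

    def test_delong_ci_covers(self):
        rng = np.random.default_rng(1)
        cases = rng.normal(1, 1, 300)
        controls = rng.normal(0, 1, 300)
        r = auroc(np.r_[cases, controls], np.r_[np.ones(300, int), np.zeros(300, int)])
        lo, hi = r.ci95
        assert lo < r.auroc < hi
        assert hi - lo < 0.15

    def test_bootstrap_ci_close_to_delong(self):
        rng = np.random.default_rng(2)
        scores = np.r_[rng.normal(1, 1, 200), rng.normal(0, 1, 200)]
        status = np.r_[np.ones(200, int), np.zeros(200, int)]
        d = auroc(scores, status, ci_method="delong")
        b = auroc(scores, status, ci_method="bootstrap", n_boot=500, seed=3)
        assert b.ci95[0] == pytest.approx(d.ci95[0], abs=0.03)
        assert b.ci95[1] == pytest.approx(d.ci95[1], abs=0.03)


class TestCutoffTable:
    def test_perfect_scores(self):
        scores = np.r_[np.arange(10, 20), np.arange(10)].astype(float)
        status = np.r_[np.ones(10, int), np.zeros(10, int)]
        table = cutoff_table(scores, status)
        top = table[table["target_specificity"] == 1.0].iloc[0]
        assert top["specificity"] == 1.0
        assert top["sensitivity"] == 1.0

    def test_lr_formulas(self):
        rng = np.random.default_rng(4)
        scores = np.r_[rng.normal(1, 1, 500), rng.normal(0, 1, 500)]
        status = np.r_[np.ones(500, int), np.zeros(500, int)]
        table = cutoff_table(scores, status)
        for _, row in table.iterrows():
            sens, spec = row["sensitivity"], row["specificity"]
            if spec < 1.0:
                assert row["lr_pos"] == pytest.approx(sens / (1 - spec), rel=1e-12)
            assert row["lr_neg"] == pytest.approx((1 - sens) / spec, rel=1e-12)

    def test_monotone_sensitivity(self):
        rng = np.random.default_rng(5)
        scores = np.r_[rng.normal(0.5, 1, 400), rng.normal(0, 1, 600)]
        status = np.r_[np.ones(400, int), np.zeros(600, int)]
        table = cutoff_table(scores, status)
        assert (np.diff(table["sensitivity"]) <= 1e-12).all()

    def test_serology_cutoff_20(self, ea_scored):
        titers = synth.simulate_antibody(
            ea_scored, synth.default_serology("east_asian"), seed=31
        )
        table = cutoff_table(titers, ea_scored.status, specificity_grid=[1.0])
        row = table.iloc[0]
        assert row["specificity"] == 1.0
        assert row["sensitivity"] == pytest.approx(0.60, abs=0.04)
        assert row["lr_neg"] == pytest.approx(0.40, abs=0.04)


class TestIdiNri:
    def test_no_change_zero(self):
        p = np.array([0.2, 0.4, 0.6, 0.8])
        status = np.array([0, 1, 0, 1])
        r = idi_nri(p, p, status)
        assert r.idi == 0.0
        assert r.nri == 0.0

    def test_nri_upper_bound(self):
        p_old = np.array([0.5, 0.5, 0.5, 0.5])
        p_new = np.array([0.9, 0.8, 0.1, 0.2])
        status = np.array([1, 1, 0, 0])
        assert idi_nri(p_old, p_new, status).nri == pytest.approx(2.0, rel=1e-12)

    def test_worked_example(self):
        # events: 0.2->0.4, 0.6->0.5; non-events: 0.3->0.1, 0.2->0.3
        p_old = np.array([0.2, 0.6, 0.3, 0.2])
        p_new = np.array([0.4, 0.5, 0.1, 0.3])
        status = np.array([1, 1, 0, 0])
        r = idi_nri(p_old, p_new, status)
        # IDI = mean(0.2, -0.1) - mean(-0.2, 0.1) = 0.05 - (-0.05)
        assert r.idi == pytest.approx(0.10, rel=1e-12)
        # NRI = (0.5 - 0.5) + (0.5 - 0.5)
        assert r.nri == pytest.approx(0.0, abs=1e-12)

    def test_idi_equals_discrimination_slope_difference(self):
        rng = np.random.default_rng(6)
        n = 500
        p_old = rng.random(n)
        p_new = np.clip(p_old + rng.normal(0, 0.1, n), 0, 1)
        status = rng.integers(0, 2, n)
        r = idi_nri(p_old, p_new, status)
        slope_new = p_new[status == 1].mean() - p_new[status == 0].mean()
        slope_old = p_old[status == 1].mean() - p_old[status == 0].mean()
        assert r.idi == pytest.approx(slope_new - slope_old, abs=1e-12)

    def test_requires_both_classes(self):
        with pytest.raises(DataError):
            idi_nri(np.array([0.5]), np.array([0.6]), np.array([1]))


class TestDecileOr:
    def test_null_score_flat_ors(self):
        rng = np.random.default_rng(7)
        n = 20_000
        scores_arr = rng.normal(0, 1, n)
        status = rng.integers(0, 2, n)
        table = decile_or(scores_arr, status)
        ors = table["or_"].to_numpy()[1:]
        assert np.all((ors > 0.8) & (ors < 1.25))

    def test_monotone_expectation(self, ea_scored):
        table = decile_or(ea_scored.phenotypes["grs"], ea_scored.status)
        ors = table["or_"].to_numpy()
        # non-decreasing in expectation: check rank correlation, not strictness
        assert np.corrcoef(np.arange(10), np.log(ors + 1e-9))[0, 1] > 0.9

    def test_log_linearity_control_basis(self):
        spec = synth.east_asian_spec(n_cases=10_000, n_controls=20_000,
                                     prevalence=0.01, seed=61)
        cohort = synth.simulate_case_control(spec)
        from gwaspipe import scores as sc

        grs = sc.compute_grs(cohort.genotypes,
                             sc.load_score_definition("east_asian"))["grs"]
        table = decile_or(grs, cohort.status, basis="controls")
        ok = table["or_"].notna() & (table["or_"] > 0)
        log_or = np.log(table.loc[ok, "or_"].to_numpy())
        mean_grs = np.array([
            grs[np.asarray(_bin_index(grs, cohort.status) == k)].mean()
            for k in table.loc[ok, "decile"] - 1
        ])
        r2 = np.corrcoef(mean_grs, log_or)[0, 1] ** 2
        assert r2 > 0.9


def _bin_index(grs, status, n_bins=10):
    ref = np.asarray(grs)[np.asarray(status) == 0]
    edges = np.quantile(ref, np.linspace(0, 1, n_bins + 1))
    edges[0], edges[-1] = -np.inf, np.inf
    return np.clip(np.searchsorted(edges, np.asarray(grs), side="right") - 1, 0, n_bins - 1)


class TestPhenotypeAssociation:
    def test_recovers_linear_slope(self):
        rng = np.random.default_rng(8)
        n = 3000
        grs = rng.normal(0, 1, n)
        trait = 0.4 * grs + rng.normal(0, 1, n)
        r = phenotype_association(grs, trait, family="linear")
        assert abs(r["slope"] - 0.4) < 2 * r["se"]

    def test_null_trait_uniform_p(self):
        rng = np.random.default_rng(9)
        pvals = []
        for _ in range(300):
            grs = rng.normal(0, 1, 300)
            trait = rng.normal(0, 1, 300)
            pvals.append(phenotype_association(grs, trait)["p"])
        from scipy import stats

        assert stats.kstest(pvals, "uniform").pvalue > 0.001

    def test_log_transform_rejects_nonpositive(self):
        with pytest.raises(DataError, match="rows"):
            phenotype_association(
                np.array([0.1, 0.2]), np.array([1.0, 0.0]), transform="log"
            )

    def test_seropositivity_logistic_direction(self, ea_scored):
        hits = 0
        for seed in range(20):
            titers = synth.simulate_antibody(
                ea_scored, synth.default_serology("east_asian"), seed=100 + seed
            )
            cases = ea_scored.status == 1
            seropos = (titers[cases] >= 20).astype(float)
            r = phenotype_association(
                ea_scored.phenotypes["grs"].to_numpy()[cases], seropos,
                family="logistic",
            )
            if r["beta"] > 0:
                hits += 1
        assert hits >= 19

    def test_covariate_adjustment_runs(self):
        rng = np.random.default_rng(10)
        n = 1000
        grs = rng.normal(0, 1, n)
        cov = rng.normal(0, 1, (n, 2))
        trait = 0.3 * grs + 0.5 * cov[:, 0] + rng.normal(0, 1, n)
        r = phenotype_association(grs, trait, covariates=cov)
        assert abs(r["slope"] - 0.3) < 3 * r["se"]
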