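import warnings

import numpy as np
import pytest
from scipy import stats

from saltscan import (
    ScanRecord, code_genotype, fit_interaction_lrt, genome_scan,
    genomic_control, qq_data, two_stage_evaluate,
)
from saltscan.scan import CHI2_MEDIAN_1DF, scan_table


class TestGenotypeCoding:
    def test_best_guess_and_dosage(self):
        gp = [[0.1, 0.7, 0.2]]
        dosage, _ = code_genotype(posteriors=gp, model="dosage")
        additive, _ = code_genotype(posteriors=gp, model="additive")
        assert dosage[0] == pytest.approx(1.1)
        assert additive[0] == 1.0

    def test_recessive_coding_of_reference_homozygote_class(self):
        # contrast GG (hom-ref) vs AG/AA: code the ref allele recessively
        gp = np.eye(3)  # one subject per genotype class: GG, AG, AA
        coded, _ = code_genotype(posteriors=gp, model="recessive",
                                 effect_allele="ref")
        assert coded.tolist() == [1.0, 0.0, 0.0]

    def test_dominant_equals_recessive_without_heterozygotes(self):
        gp = np.array([[1.0, 0, 0], [0, 0, 1.0], [1.0, 0, 0]])
        dom, _ = code_genotype(posteriors=gp, model="dominant")
        rec, _ = code_genotype(posteriors=gp, model="recessive")
        assert np.array_equal(dom, rec)

    def test_posterior_tie_broken_low_and_flagged(self):
        coded, ties = code_genotype(posteriors=[[0.5, 0.5, 0.0]],
                                    model="additive")
        assert coded[0] == 0.0 and ties[0]

    def test_hard_call_path_and_missing(self):
        coded, _ = code_genotype(hard_calls=[0, 1, 2, -1], model="dominant")
        assert coded[0] == 0 and coded[1] == 1 and coded[2] == 1
        assert np.isnan(coded[3])


def _closed_form_lrt(G, E, bp):
    """Independent oracle: explicit normal equations for both nested models."""
    n = len(bp)
    X1 = np.column_stack([np.ones(n), G, E])
    X2 = np.column_stack([np.ones(n), G, E, G * E])
    out = []
    for X in (X1, X2):
        beta = np.linalg.solve(X.T @ X, X.T @ bp)
        r = bp - X @ beta
        out.append((beta, float(r @ r)))
    (b1, rss1), (b2, rss2) = out
    lrt = n * np.log(rss1 / rss2)
    sigma2 = rss2 / (n - X2.shape[1])
    se = np.sqrt(sigma2 * np.linalg.inv(X2.T @ X2)[3, 3])
    return lrt, b2, se


class TestInteractionLRT:
    def test_matches_closed_form_oracle(self, worked_dataset):
        G, E, bp = worked_dataset
        rec = fit_interaction_lrt(G, E, bp)
        lrt, beta2, se = _closed_form_lrt(G, E, bp)
        assert rec.lrt_stat == pytest.approx(lrt, rel=1e-10)
        assert rec.beta_GE == pytest.approx(beta2[3], rel=1e-10)
        assert rec.beta_G == pytest.approx(beta2[1], rel=1e-10)
        assert rec.beta_E == pytest.approx(beta2[2], rel=1e-10)
        assert rec.se_GE == pytest.approx(se, rel=1e-10)
        assert rec.p_raw == pytest.approx(stats.chi2.sf(lrt, 1), rel=1e-10)

    def test_permutation_null_rejection_rate(self):
        rng = np.random.default_rng(30)
        n, reps, alpha = 300, 1000, 0.05
        E = rng.normal(165, 38, n)
        G = rng.binomial(2, 0.3, n).astype(float)
        hits = 0
        for _ in range(reps):
            bp = rng.normal(128, 19, n)
            rec = fit_interaction_lrt(rng.permutation(G), E, bp)
            hits += rec.p_raw < alpha
        envelope = 1.96 * np.sqrt(alpha * (1 - alpha) / reps)
        assert abs(hits / reps - alpha) < envelope + 0.005  # small-n LRT slack

    def test_constant_exposure_untestable(self):
        rng = np.random.default_rng(31)
        G = rng.binomial(2, 0.4, 50).astype(float)
        rec = fit_interaction_lrt(G, np.full(50, 160.0), rng.normal(128, 19, 50))
        assert rec.untestable and "rank" in rec.reason

    def test_constant_genotype_untestable(self):
        rng = np.random.default_rng(32)
        rec = fit_interaction_lrt(np.zeros(50), rng.normal(165, 38, 50),
                                  rng.normal(128, 19, 50))
        assert rec.untestable and "constant" in rec.reason

    def test_affine_invariance_of_exposure(self):
        rng = np.random.default_rng(33)
        n = 400
        G = rng.binomial(2, 0.3, n).astype(float)
        E = rng.normal(165, 38, n)
        C = rng.normal(size=(n, 3))
        bp = 120 + 0.05 * E + 0.1 * G * E + rng.normal(0, 15, n)
        a = fit_interaction_lrt(G, E, bp, covariates=C)
        b = fit_interaction_lrt(G, 3.5 * E - 40, bp, covariates=2 * C + 1)
        assert a.lrt_stat == pytest.approx(b.lrt_stat, abs=1e-8)
        assert a.p_raw == pytest.approx(b.p_raw, abs=1e-10)
        assert b.beta_GE == pytest.approx(a.beta_GE / 3.5, rel=1e-8)

    def test_wald_agrees_with_lrt_asymptotically(self):
        rng = np.random.default_rng(34)
        n = 2000
        G = rng.binomial(2, 0.3, n).astype(float)
        E = rng.normal(165, 38, n)
        bp = 120 + 0.04 * E + 0.05 * G * E + rng.normal(0, 17, n)
        rec = fit_interaction_lrt(G, E, bp)
        wald = (rec.beta_GE / rec.se_GE) ** 2
        assert abs(wald - rec.lrt_stat) / rec.lrt_stat < 0.10

    def test_complete_case_drops_missing(self):
        rng = np.random.default_rng(35)
        n = 100
        G = rng.binomial(2, 0.4, n).astype(float)
        E = rng.normal(165, 38, n)
        bp = rng.normal(128, 19, n)
        E[:10] = np.nan
        rec = fit_interaction_lrt(G, E, bp)
        assert rec.n_used == 90


class TestGenomicControl:
    def _records(self, lrt_values):
        recs = []
        for i, s in enumerate(lrt_values):
            recs.append(ScanRecord(variant_id=f"v{i}", coding_model="dosage",
                                   lrt_stat=float(s),
                                   p_raw=float(stats.chi2.sf(s, 1))))
        return recs

    def test_calibrated_null_lambda_one(self):
        recs = self._records([CHI2_MEDIAN_1DF] * 120)
        lam, recs = genomic_control(recs)
        assert lam == pytest.approx(1.0)
        assert all(r.p_gc == pytest.approx(r.p_raw) for r in recs)

    def test_direct_quantile_arithmetic(self):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            lam, recs = genomic_control(self._records([1.0, 2.0, 3.0]))
        assert lam == pytest.approx(2.0 / CHI2_MEDIAN_1DF, rel=1e-6)
        corrected = [r.lrt_stat / lam for r in recs]
        assert corrected == pytest.approx([0.22746821, 0.45493642, 0.68240463],
                                          rel=1e-6)
        for r, c in zip(recs, corrected):
            assert r.p_gc == pytest.approx(stats.chi2.sf(c, 1), rel=1e-10)

    def test_lambda_floored_no_deflation(self):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            lam, recs = genomic_control(self._records([0.1, 0.2, 0.3]))
        assert lam < 1.0
        assert all(r.p_gc == pytest.approx(r.p_raw) for r in recs)

    def test_ranking_preserved(self):
        rng = np.random.default_rng(36)
        stats_ = rng.chisquare(1, 500) * 1.3
        lam, recs = genomic_control(self._records(stats_))
        raw_order = np.argsort([r.p_raw for r in recs])
        gc_order = np.argsort([r.p_gc for r in recs])
        assert np.array_equal(raw_order, gc_order)

    def test_no_testable_records_error(self):
        rec = ScanRecord(variant_id="v", coding_model="dosage", untestable=True)
        with pytest.raises(ValueError, match="no testable"):
            genomic_control([rec])


class TestGenomeScan:
    def test_null_scan_uniform_p(self, null_cohort):
        cohort, genotypes = null_cohort
        records = genome_scan(cohort, genotypes, "additive", trait="sbp")
        assert len(records) == genotypes.n_variants
        assert not any(r.untestable for r in records)
        p = [r.p_raw for r in records]
        assert stats.kstest(p, "uniform").pvalue > 0.01

    def test_model_frequency_filter_contract(self, null_cohort):
        cohort, genotypes = null_cohort
        # make the first variant's minor-hom class rare (<1%) while keeping
        # MAF above threshold and genotype counts Hardy-Weinberg consistent
        geno = genotypes
        calls = geno.hard_calls.copy()
        rng = np.random.default_rng(1)
        n = calls.shape[1]  # 800: counts (675, 120, 5) sit on HWE at p=0.081
        row = np.array([0] * 675 + [1] * 120 + [2] * 5, dtype=np.int8)
        rng.shuffle(row)
        calls[0] = row
        geno.hard_calls = calls
        geno.gp[0] = np.eye(3)[row]
        geno.dosages[0] = row.astype(float)
        dosage_ids = {r.variant_id for r in
                      genome_scan(cohort, geno, "dosage")}
        recessive_ids = {r.variant_id for r in
                         genome_scan(cohort, geno, "recessive")}
        vid = geno.variant_ids[0]
        assert vid in dosage_ids and vid not in recessive_ids

    def test_missing_trait_column_named(self, null_cohort):
        cohort, genotypes = null_cohort
        with pytest.raises(KeyError, match="map"):
            genome_scan(cohort, genotypes, "dosage", trait="map")

    def test_planted_interaction_ranks_first(self):
        from saltscan import SimulationConfig, gen_cohort, prepare_cohort
        top_hits = 0
        for seed in range(20):
            config = SimulationConfig(
                n_subjects=600, n_variants=40, maf=0.45, causal_index=7,
                coding_model="additive", beta_GE=0.18, seed=100 + seed)
            cohort, geno = gen_cohort(config)
            cohort = prepare_cohort(cohort)
            records = genome_scan(cohort, geno, "additive")
            best = max(records, key=lambda r: r.lrt_stat)
            top_hits += best.variant_id == geno.variant_ids[7]
        assert top_hits >= 19


class TestTwoStage:
    @staticmethod
    def _rec(vid="rs1", p_gc=np.nan, p_raw=0.5, beta=-0.05, site=False):
        return ScanRecord(variant_id=vid, coding_model="recessive",
                          beta_GE=beta, p_raw=p_raw, p_gc=p_gc,
                          site_adjusted=site)

    def test_replicated_genome_wide_locus(self):
        # discovery/replication/combined triplet of a genome-wide significant
        # interaction with consistent negative effects
        dec = two_stage_evaluate(
            self._rec(p_gc=4.7e-6, beta=-0.064),
            self._rec(p_raw=4.1e-4, beta=-0.049),
            self._rec(p_raw=4.3e-9, beta=-0.056, site=True))
        assert dec.status == "genome_wide"
        assert dec.direction_consistent

    @pytest.mark.parametrize("disc_p, repl_p, comb_p, repl_beta, expected", [
        (2e-5, 4.1e-4, 4.3e-9, -0.049, "none"),        # discovery gate fails
        (4.7e-6, 0.06, 4.3e-9, -0.049, "suggestive"),  # replication p fails
        (4.7e-6, 4.1e-4, 4.3e-9, +0.049, "suggestive"),  # direction flips
        (4.7e-6, 4.1e-4, 6e-8, -0.049, "replicated"),  # combined gate fails
    ])
    def test_gate_ordering(self, disc_p, repl_p, comb_p, repl_beta, expected):
        dec = two_stage_evaluate(
            self._rec(p_gc=disc_p, beta=-0.064),
            self._rec(p_raw=repl_p, beta=repl_beta),
            self._rec(p_raw=comb_p, beta=-0.056, site=True))
        assert dec.status == expected

    def test_combined_must_be_site_adjusted(self):
        dec = two_stage_evaluate(
            self._rec(p_gc=4.7e-6, beta=-0.064),
            self._rec(p_raw=4.1e-4, beta=-0.049),
            self._rec(p_raw=4.3e-9, beta=-0.056, site=False))
        assert dec.status == "replicated"

    def test_mismatched_ids_error(self):
        with pytest.raises(ValueError, match="mismatched variant ids"):
            two_stage_evaluate(self._rec("rs1"), self._rec("rs2"),
                               self._rec("rs1"))


def test_qq_data_monotone_and_sized():
    rng = np.random.default_rng(37)
    df = qq_data(rng.uniform(size=500))
    assert len(df) == 500
    assert (np.diff(df["expected_neglog10p"]) <= 0).all()


def test_scan_table_round_trip_columns(null_cohort):
    cohort, genotypes = null_cohort
    records = genome_scan(cohort, genotypes, "dosage")
    table = scan_table(records)
    assert {"variant_id", "beta_GE", "se_GE", "lrt_stat", "p_raw"} <= set(table)
    assert len(table) == len(records)
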