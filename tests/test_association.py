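import math

import numpy as np
import pytest

import neanderscan as ns


def table_2x2_data(a, b, c, d):
    """Cases exposed/unexposed (a, b); controls exposed/unexposed (c, d)."""
    dos = np.concatenate([np.ones(a), np.zeros(b), np.ones(c), np.zeros(d)])
    status = np.concatenate([np.ones(a + b), np.zeros(c + d)])
    return dos, status


class TestFitLogistic:
    def test_matches_closed_form_2x2_odds_ratio(self):
        dos, status = table_2x2_data(30, 70, 10, 90)
        res = ns.fit_logistic(dos, status)
        expected_or = (30 * 90) / (70 * 10)
        assert res.odds_ratio == pytest.approx(expected_or, rel=1e-6)
        assert res.beta == pytest.approx(math.log(expected_or), rel=1e-6)
        expected_se = math.sqrt(1 / 30 + 1 / 70 + 1 / 10 + 1 / 90)
        assert res.se == pytest.approx(expected_se, rel=1e-6)

    def test_fifty_random_tables_match_closed_form(self, rng):
        for _ in range(50):
            a, b, c, d = rng.integers(5, 200, 4)
            dos, status = table_2x2_data(a, b, c, d)
            res = ns.fit_logistic(dos, status)
            assert res.beta == pytest.approx(
                math.log(a * d / (b * c)), rel=1e-6
            )
            assert res.se == pytest.approx(
                math.sqrt(1 / a + 1 / b + 1 / c + 1 / d), rel=1e-6
            )

    def test_matches_statsmodels_with_covariates(self, rng):
        import statsmodels.api as sm

        n = 400
        dos = rng.binomial(2, 0.3, n).astype(float)
        cov = np.column_stack([rng.normal(50, 8, n), rng.binomial(1, 0.5, n)])
        eta = -0.5 + 0.4 * dos + 0.02 * (cov[:, 0] - 50)
        status = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(float)
        res = ns.fit_logistic(dos, status, cov)
        X = sm.add_constant(np.column_stack([dos, cov]))
        ref = sm.Logit(status, X).fit(disp=0)
        assert res.beta == pytest.approx(ref.params[1], abs=1e-7)
        assert res.se == pytest.approx(ref.bse[1], rel=1e-5)

    def test_null_coverage(self, rng):
        """|beta| < 2 SE in >= 93% of null replicates."""
        n, hits = 5000, 0
        reps = 100
        for _ in range(reps):
            dos = rng.binomial(2, 0.3, n).astype(float)
            status = rng.binomial(1, 0.5, n).astype(float)
            res = ns.fit_logistic(dos, status)
            hits += abs(res.beta) < 2 * res.se
        assert hits >= 0.93 * reps

    def test_separation_flagged_with_warning(self):
        dos = np.array([2.0] * 10 + [0.0] * 10)
        status = np.array([1.0] * 10 + [0.0] * 10)
        with pytest.warns(ns.SeparationWarning):
            res = ns.fit_logistic(dos, status)
        assert res.separation

    def test_rank_deficiency_names_columns(self, rng):
        n = 50
        dos = rng.binomial(2, 0.4, n).astype(float)
        status = rng.binomial(1, 0.5, n).astype(float)
        cov = np.column_stack([dos, rng.normal(size=n)])  # duplicates dosage
        with pytest.raises(ns.ValidationError, match="covar0"):
            ns.fit_logistic(dos, status, cov)

    def test_needs_both_outcomes(self):
        with pytest.raises(ns.ValidationError):
            ns.fit_logistic(np.array([0.0, 1.0]), np.array([1.0, 1.0]))

    def test_ci_brackets_or(self, rng):
        dos = rng.binomial(2, 0.25, 300).astype(float)
        status = rng.binomial(1, 0.4, 300).astype(float)
        res = ns.fit_logistic(dos, status)
        assert res.ci_low < res.odds_ratio < res.ci_high


class TestLogisticScan:
    def test_agrees_with_single_fits(self, rng):
        n = 300
        D = rng.binomial(2, rng.uniform(0.05, 0.5, (40, 1)), (40, n)).astype(float)
        cov = np.column_stack([rng.normal(60, 10, n), rng.binomial(1, 0.5, n)])
        y = rng.binomial(1, 0.5, n).astype(float)
        beta, se, chi2 = ns.logistic_scan(D, y, cov)
        for i in range(0, 40, 7):
            ref = ns.fit_logistic(D[i], y, cov)
            assert beta[i] == pytest.approx(ref.beta, abs=1e-7)
            assert se[i] == pytest.approx(ref.se, rel=1e-6)


class TestLD:
    def test_identical_vectors_full_r2(self, rng):
        g = rng.binomial(2, 0.3, 100).astype(float)
        assert ns.ld_r2(g, g) == pytest.approx(1.0)

    def test_complementary_haplotypes(self):
        h = np.tile([0, 1], 50)
        assert ns.ld_r2(h, 1 - h) == pytest.approx(1.0)
        assert ns.ld_dprime(h, 1 - h) == pytest.approx(1.0)

    def test_hand_counts(self):
        # 100 haplotypes: AB=40, Ab=10, aB=10, ab=40
        h1 = np.array([1] * 50 + [0] * 50)
        h2 = np.array([1] * 40 + [0] * 10 + [1] * 10 + [0] * 40)
        d = 0.40 - 0.5 * 0.5
        assert d == pytest.approx(0.15)
        assert ns.ld_dprime(h1, h2) == pytest.approx(0.6)
        assert ns.ld_r2(h1, h2) == pytest.approx(0.36)

    def test_monomorphic_treated_as_zero(self, rng):
        g = rng.binomial(2, 0.3, 50).astype(float)
        assert ns.ld_r2(g, np.zeros(50)) == 0.0


class TestPruning:
    def _results(self, specs):
        return [
            ns.AssociationResult(
                snp=s, n_cases=10, n_controls=10, beta=0.1, se=0.1,
                odds_ratio=1.1, ci_low=1.0, ci_high=1.2, wald_p=p, pos=pos,
            )
            for s, p, pos in specs
        ]

    def test_single_snp_kept(self):
        res = self._results([("A", 1e-4, 100)])
        ld = ns.LDMatrix(ids=["A"], r2=np.ones((1, 1)))
        assert [r.snp for r in ns.greedy_prune(res, ld)] == ["A"]

    def test_pair_keeps_lower_p(self):
        res = self._results([("A", 1e-5, 100), ("B", 1e-3, 200)])
        ld = ns.LDMatrix(ids=["A", "B"], r2=np.array([[1.0, 0.6], [0.6, 1.0]]))
        assert [r.snp for r in ns.greedy_prune(res, ld, 0.5)] == ["A"]

    def test_chain_hand_trace(self):
        # A-B 0.6, B-C 0.6, A-C 0.1; P(A) < P(C) < P(B) -> keep {A, C}
        res = self._results([("A", 1e-6, 100), ("B", 1e-3, 200), ("C", 1e-4, 300)])
        r2 = np.array([[1.0, 0.6, 0.1], [0.6, 1.0, 0.6], [0.1, 0.6, 1.0]])
        ld = ns.LDMatrix(ids=["A", "B", "C"], r2=r2)
        assert [r.snp for r in ns.greedy_prune(res, ld, 0.5)] == ["A", "C"]

    def test_no_kept_pair_above_threshold(self, rng):
        m = 30
        base = rng.binomial(2, 0.3, (6, 200)).astype(float)
        D = base[rng.integers(0, 6, m)] + rng.normal(0, 0.6, (m, 200))
        ld = ns.ld_matrix(D, [f"s{i}" for i in range(m)])
        res = self._results(
            [(f"s{i}", float(rng.uniform()), i * 10) for i in range(m)]
        )
        kept = ns.greedy_prune(res, ld, 0.5)
        for i, a in enumerate(kept):
            for b in kept[i + 1:]:
                assert ld.lookup(a.snp, b.snp) <= 0.5

    def test_missing_ld_entry_is_error(self):
        res = self._results([("A", 1e-5, 100), ("Z", 1e-3, 200)])
        ld = ns.LDMatrix(ids=["A"], r2=np.ones((1, 1)))
        with pytest.raises(ns.ValidationError):
            ns.greedy_prune(res, ld)


class TestCountIndependent:
    def test_all_unlinked(self):
        r2 = np.full((10, 10), 0.05)
        np.fill_diagonal(r2, 1.0)
        ld = ns.LDMatrix(ids=[f"s{i}" for i in range(10)], r2=r2)
        assert ns.count_independent(ld, 0.8) == 10

    def test_all_linked(self):
        r2 = np.full((10, 10), 0.9)
        np.fill_diagonal(r2, 1.0)
        ld = ns.LDMatrix(ids=[f"s{i}" for i in range(10)], r2=r2)
        assert ns.count_independent(ld, 0.8) == 1

    def test_hand_built_six_snp_matrix(self):
        # greedy in position order: keep 0; 1 linked to 0 -> drop;
        # keep 2; keep 3; 4 linked to 3 -> drop; keep 5  => m = 4
        r2 = np.eye(6)
        pairs = {(0, 1): 0.9, (3, 4): 0.85, (0, 2): 0.3, (2, 5): 0.7}
        for (i, j), v in pairs.items():
            r2[i, j] = r2[j, i] = v
        ld = ns.LDMatrix(ids=[f"s{i}" for i in range(6)], r2=r2,
                         positions=np.arange(6) * 100)
        assert ns.count_independent(ld, 0.8) == 4

    def test_dosage_variant_agrees_with_matrix(self, rng):
        D = rng.binomial(2, 0.3, (25, 300)).astype(float)
        D[5] = D[4]
        D[11] = D[10]
        pos = np.arange(25) * 1000
        ld = ns.ld_matrix(D, [f"s{i}" for i in range(25)], positions=pos)
        assert ns.count_independent(ld, 0.8) == ns.count_independent_from_dosages(
            D, pos, 0.8
        )


class TestBonferroni:
    @pytest.mark.parametrize(
        "m,expected",
        [(19_623, 2.55e-6), (21_780, 2.30e-6), (21_965, 2.28e-6), (1, 0.05)],
    )
    def test_reported_thresholds(self, m, expected):
        thr = ns.bonferroni_threshold(m, 0.05)
        assert float(f"{thr:.3g}") == pytest.approx(expected)

    def test_exact_inverse(self):
        for m in (1, 7, 19_623):
            assert ns.bonferroni_threshold(m, 0.05) * m == pytest.approx(0.05)

    def test_invalid_m(self):
        with pytest.raises(ValueError):
            ns.bonferroni_threshold(0)


class TestGenomicLambda:
    def test_median_half_gives_unity(self):
        p = np.linspace(0.01, 0.99, 999)  # median exactly 0.5
        assert ns.genomic_lambda(p=p) == pytest.approx(1.0, abs=1e-9)

    def test_scaling_in_chi2(self, rng):
        stats_vec = rng.chisquare(1, 5000)
        lam = ns.genomic_lambda(chi2_stats=stats_vec)
        assert ns.genomic_lambda(chi2_stats=3 * stats_vec) == pytest.approx(
            3 * lam, rel=1e-9
        )

    def test_null_simulation_near_one(self, rng):
        stats_vec = rng.chisquare(1, 10_000)
        assert 0.95 <= ns.genomic_lambda(chi2_stats=stats_vec) <= 1.05

    def test_requires_input(self):
        with pytest.raises(ValueError):
            ns.genomic_lambda()
        with pytest.raises(ValueError):
            ns.genomic_lambda(p=np.array([]))


class TestConcordance:
    def _rec(self, beta, p, study, allele="T"):
        return ns.SummaryStatRecord(
            snp="rs1", effect_allele=allele, beta=beta, se=0.05, p=p, study=study
        )

    def test_same_direction_all_significant_passes(self):
        recs = [self._rec(0.3, 0.01, "a"), self._rec(0.2, 0.02, "b"),
                self._rec(0.25, 0.04, "c")]
        assert ns.concordance_filter(recs)

    def test_sign_flip_fails(self):
        recs = [self._rec(0.3, 0.01, "a"), self._rec(0.2, 0.02, "b"),
                self._rec(-0.1, 0.01, "c")]
        assert not ns.concordance_filter(recs)

    def test_one_nonsignificant_fails(self):
        recs = [self._rec(0.3, 0.01, "a"), self._rec(0.2, 0.06, "b")]
        assert not ns.concordance_filter(recs)

    def test_mismatched_alleles_error(self):
        recs = [self._rec(0.3, 0.01, "a"), self._rec(0.2, 0.02, "b", allele="C")]
        with pytest.raises(ns.ValidationError):
            ns.concordance_filter(recs)

    def test_single_study_error(self):
        with pytest.raises(ns.ValidationError):
            ns.concordance_filter([self._rec(0.3, 0.01, "a")])
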