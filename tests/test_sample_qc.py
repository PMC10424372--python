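import numpy as np
import pytest
from scipy import stats

import neanderscan as ns
from tests.conftest import make_panel


def panel_from_dosages(dos, populations=None, positions=None):
    """Diploid panel from a (n_variants, n_samples) dosage matrix."""
    dos = np.asarray(dos)
    n_var, n_samp = dos.shape
    h = np.zeros((n_var, 2 * n_samp), dtype=np.int8)
    for s in range(n_samp):
        for i in range(n_var):
            d = dos[i, s]
            if d < 0:
                h[i, 2 * s] = h[i, 2 * s + 1] = -1
            else:
                h[i, 2 * s] = 1 if d >= 1 else 0
                h[i, 2 * s + 1] = 1 if d == 2 else 0
    pops = populations or ["EUR"] * n_samp
    return make_panel(h, populations=pops, positions=positions)


class TestCallRateFilters:
    def test_variant_below_threshold_removed(self):
        dos = np.zeros((2, 10))
        dos[0, :2] = -1  # call rate 0.8
        dos[1, 5] = 1
        panel, rep = ns.filter_variant_call_rate(panel_from_dosages(dos), 0.9)
        assert panel.n_variants == 1
        assert rep.removed[0][0] == "v0"

    def test_exactly_at_threshold_retained(self):
        dos = np.zeros((1, 10))
        dos[0, 0] = -1  # call rate exactly 0.9
        panel, rep = ns.filter_variant_call_rate(panel_from_dosages(dos), 0.9)
        assert panel.n_variants == 1 and rep.removed == []

    def test_clean_panel_unchanged_and_idempotent(self, rng):
        dos = rng.integers(0, 3, (20, 8))
        panel = panel_from_dosages(dos)
        once, rep1 = ns.filter_variant_call_rate(panel, 0.9)
        twice, rep2 = ns.filter_variant_call_rate(once, 0.9)
        assert once.n_variants == panel.n_variants == twice.n_variants

    def test_sample_call_rate_boundary(self):
        dos = np.zeros((4, 3))
        dos[0, 0] = -1  # sample 0: rate 0.75, retained (strict <)
        dos[:2, 1] = -1  # sample 1: rate 0.5, removed
        panel, rep = ns.filter_sample_call_rate(panel_from_dosages(dos), 0.75)
        assert panel.n_samples == 2
        assert len(rep.removed) == 1


class TestHeterozygosity:
    def test_planted_outlier_removed(self, rng):
        n_var, n_samp = 400, 21
        h = (rng.random((n_var, 2 * n_samp)) < 0.18).astype(np.int8)
        # sample 0 heterozygous at ~90% of sites
        het_sites = rng.random(n_var) < 0.9
        h[:, 0] = het_sites.astype(np.int8)
        h[:, 1] = 0
        panel = make_panel(h, populations=["EUR"] * n_samp)
        filtered, rep = ns.filter_sample_het(panel, sd=3.0)
        assert [r[0] for r in rep.removed] == [panel.samples[0]]

    def test_identical_heterozygosity_removes_none(self):
        h = np.tile(np.array([[0, 1], [1, 0]], dtype=np.int8), (5, 3))
        panel = make_panel(h, populations=["EUR"] * 3)
        filtered, rep = ns.filter_sample_het(panel)
        assert filtered.n_samples == 3 and rep.removed == []

    def test_two_samples_degenerate_rule(self, rng):
        h = rng.integers(0, 2, (30, 4)).astype(np.int8)
        panel = make_panel(h, populations=["EUR"] * 2)
        filtered, rep = ns.filter_sample_het(panel)
        assert filtered.n_samples == 2
        assert any("fewer than 3" in n for n in rep.notes)


class TestPiHat:
    @staticmethod
    def _unrelated(rng, n_snps=1000, n_samples=12):
        maf = rng.uniform(0.05, 0.5, n_snps)
        dos = rng.binomial(2, maf[:, None], (n_snps, n_samples))
        return dos

    def test_duplicate_sample_near_one(self, rng):
        dos = self._unrelated(rng)
        dos[:, 1] = dos[:, 0]
        panel = panel_from_dosages(dos)
        assert ns.estimate_pi_hat(panel, 0, 1) >= 0.95

    def test_unrelated_near_zero(self, rng):
        vals = []
        for _ in range(8):
            panel = panel_from_dosages(self._unrelated(rng))
            vals.append(ns.estimate_pi_hat(panel, 0, 1))
        assert abs(np.mean(vals)) < 0.05

    def test_parent_offspring_near_half(self, rng):
        n_snps = 1000
        maf = rng.uniform(0.2, 0.5, n_snps)
        pop = (rng.random((n_snps, 40, 2)) < maf[:, None, None]).astype(np.int8)
        child = pop[:, 0].copy()
        child[:, 0] = pop[:, 1, 0]  # inherits one full parental haplotype
        geno = np.concatenate([pop, child[:, None, :]], axis=1)
        h = geno.reshape(n_snps, -1)
        panel = make_panel(h, populations=["EUR"] * 41)
        pi = ns.estimate_pi_hat(panel, 1, 40)
        assert abs(pi - 0.5) < 0.1

    def test_monomorphic_panel_is_estimation_error(self):
        panel = panel_from_dosages(np.zeros((50, 6)))
        with pytest.raises(ns.EstimationError):
            ns.estimate_pi_hat(panel, 0, 1)

    def test_filter_removes_lower_call_rate_member(self, rng):
        dos = self._unrelated(rng, n_samples=6)
        dos[:, 3] = dos[:, 2]
        dos[:50, 3] = -1  # sample 3 has the lower call rate
        panel = panel_from_dosages(dos)
        filtered, rep = ns.filter_relatedness(panel, 0.2)
        removed = [r[0] for r in rep.removed]
        assert removed == [panel.samples[3]]


class TestHWE:
    def test_exact_proportions(self):
        chi2, p = ns.hwe_test(25, 50, 25)
        assert chi2 == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_total_heterozygote_deficit(self):
        # expected (25, 50, 25) under p=q=0.5 -> chi2 = 25+50+25 = 100
        chi2, p = ns.hwe_test(50, 0, 50)
        assert chi2 == pytest.approx(100.0)
        assert p < 1e-20

    def test_monomorphic_convention(self):
        assert ns.hwe_test(0, 0, 80) == (0.0, 1.0)

    def test_matches_independent_chi2_oracle(self, rng):
        """Pearson chi-square equals scipy's chisquare with ddof=1 on the
        expected Hardy-Weinberg counts, over random genotype tables."""
        for _ in range(100):
            n = rng.integers(20, 500)
            p = rng.uniform(0.05, 0.95)
            counts = rng.multinomial(n, [p * p, 2 * p * (1 - p), (1 - p) ** 2])
            naa, nab, nbb = map(int, counts)
            chi2, pval = ns.hwe_test(naa, nab, nbb)
            ph = (2 * naa + nab) / (2 * n)
            if ph in (0.0, 1.0):
                assert (chi2, pval) == (0.0, 1.0)
                continue
            expected = n * np.array([ph**2, 2 * ph * (1 - ph), (1 - ph) ** 2])
            ref_chi2, _ = stats.chisquare([naa, nab, nbb], expected, ddof=1)
            assert chi2 == pytest.approx(float(ref_chi2), rel=1e-8)
            assert pval == pytest.approx(float(stats.chi2.sf(ref_chi2, 1)), rel=1e-8)


class TestInfoFilter:
    def test_boundary_and_hand_count(self):
        h = np.zeros((5, 4), dtype=np.int8)
        h[:, 0] = 1
        panel = make_panel(
            h, populations=["EUR"] * 2,
            info_scores=[0.69, 0.70, None, 0.95, 0.1],
        )
        filtered, rep = ns.filter_info(panel, 0.7)
        assert filtered.n_variants == 3  # 0.70, None, 0.95 survive
        assert {r[0] for r in rep.removed} == {"v0", "v4"}

    def test_all_missing_info_warns_and_keeps(self):
        h = np.zeros((3, 4), dtype=np.int8)
        h[:, 1] = 1
        panel = make_panel(h, populations=["EUR"] * 2)
        with pytest.warns(UserWarning, match="INFO"):
            filtered, rep = ns.filter_info(panel)
        assert filtered.n_variants == 3


class TestPCA:
    @staticmethod
    def _two_pop_panel(rng, n_per=25, n_snps=300, fst_shift=0.35):
        f1 = rng.uniform(0.1, 0.9, n_snps)
        f2 = np.clip(f1 + rng.choice([-1, 1], n_snps) * fst_shift, 0.02, 0.98)
        h1 = (rng.random((n_snps, 2 * n_per)) < f1[:, None]).astype(np.int8)
        h2 = (rng.random((n_snps, 2 * n_per)) < f2[:, None]).astype(np.int8)
        return make_panel(
            np.hstack([h1, h2]), populations=["AFR"] * n_per + ["EUR"] * n_per
        )

    def test_pc1_separates_populations(self, rng):
        panel = self._two_pop_panel(rng)
        scores, eigvals = ns.pca_genotypes(panel, k=4)
        labels = (np.asarray(panel.populations) == "EUR").astype(float)
        r = np.corrcoef(scores[:, 0], labels)[0, 1]
        assert abs(r) > 0.9
        assert np.all(np.diff(eigvals) <= 1e-9)  # sorted descending

    def test_homogeneous_panel_no_outliers(self, rng):
        f = rng.uniform(0.2, 0.8, 200)
        h = (rng.random((200, 60)) < f[:, None]).astype(np.int8)
        panel = make_panel(h, populations=["EUR"] * 30)
        scores, _ = ns.pca_genotypes(panel, k=5)
        assert not ns.flag_pca_outliers(scores, sd=6.0).any()

    def test_planted_divergent_sample_flagged(self, rng):
        panel = self._two_pop_panel(rng, n_per=30, fst_shift=0.1)
        h = panel.genotypes.reshape(panel.n_variants, -1).copy()
        # sample 0 from a strongly diverged third population
        f3 = rng.uniform(0.0, 1.0, panel.n_variants) ** 3
        h[:, 0] = (rng.random(panel.n_variants) < f3).astype(np.int8)
        h[:, 1] = (rng.random(panel.n_variants) < f3).astype(np.int8)
        divergent = make_panel(h, populations=list(panel.populations))
        scores, _ = ns.pca_genotypes(divergent, k=4)
        flagged = ns.flag_pca_outliers(scores, sd=6.0)
        assert flagged[0]

    def test_k_truncated_to_rank_with_warning(self, rng):
        # 8 samples but only 2 distinct genotype profiles -> rank < k
        base = rng.integers(0, 2, (60, 4)).astype(np.int8)
        h = np.hstack([base] * 4)
        panel = make_panel(h, populations=["EUR"] * 8)
        with pytest.warns(UserWarning, match="rank"):
            scores, _ = ns.pca_genotypes(panel, k=5)
        assert scores.shape[1] < 5


class TestFunnel:
    def test_full_funnel_order_and_counts(self, rng):
        dos = rng.integers(0, 3, (120, 12))
        dos[0, :5] = -1  # variant 0 call rate 7/12
        panel = panel_from_dosages(dos, populations=["EUR"] * 12)
        out, reports = ns.run_sample_qc(panel, skip_pca=True)
        names = [r.filter_name for r in reports]
        assert names == [
            "variant_call_rate", "sample_call_rate", "heterozygosity",
            "relatedness", "hwe", "info",
        ]
        for rep in reports:
            assert rep.n_before - len(rep.removed) == rep.n_after
        assert out.n_variants <= panel.n_variants

    def test_filters_idempotent(self, rng):
        dos = rng.integers(0, 3, (80, 10))
        dos[dos == 2] = 1
        panel = panel_from_dosages(dos, populations=["EUR"] * 10)
        once, _ = ns.run_sample_qc(panel, skip_pca=True)
        twice, _ = ns.run_sample_qc(once, skip_pca=True)
        assert twice.n_variants == once.n_variants
        assert twice.n_samples == once.n_samples
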