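"""Poisson likelihoods, breakend-pair maximization, mapability scaling, cap."""

import math

import numpy as np
import pytest
from scipy import stats as sps

from probsv.fragments import Signature
from probsv.geometry import BreakendPolygon, CandidateVariant, trapezoid_region
from probsv.likelihood import (ModelParams, candidate_breakend_pairs,
                               column_model, copy_conditional_logprob,
                               coverage_cap, poisson_log_pmf,
                               scale_concordant_count, score_breakend_variant,
                               score_deletion_variant)
from tests.conftest import make_coverage


def make_candidate(x, y, stats, sig=Signature.DELETION, k=1,
                   signs=None):
    signs = signs or {Signature.DELETION: (1, -1),
                      Signature.INV_PP: (1, 1),
                      Signature.INV_MM: (-1, -1)}[sig]
    region = trapezoid_region(x, y, signs[0], signs[1], stats)
    poly = BreakendPolygon.from_region(region, sig, "chr1", "chr1")
    return CandidateVariant(id=0, chrom_a="chr1", chrom_b="chr1",
                            signature=sig, fragment_ids=tuple(range(k)),
                            alignment_rows=tuple(range(k)), polygon=poly)


def uniform_coverage(n, lo=1, hi=1_000_000, length=300, spacing=None):
    """Roughly uniform coverage of depth ~n via evenly spaced extents."""
    spacing = spacing or max(1, length // n)
    starts = np.arange(lo - length, hi + length, spacing)
    return make_coverage([(int(s), int(s + length - 1)) for s in starts],
                         length=hi + 10 * length)


class TestPoissonLogPmf:
    def test_closed_forms(self):
        assert poisson_log_pmf(3.0, 0) == pytest.approx(-3.0)
        assert poisson_log_pmf(2.0, 2) == pytest.approx(math.log(2 * math.exp(-2)))

    def test_zero_mean_point_mass(self):
        assert poisson_log_pmf(0.0, 0) == 0.0
        assert poisson_log_pmf(0.0, 3) == -math.inf

    @pytest.mark.parametrize("lam", [0.5, 5.0, 50.0])
    def test_normalization(self, lam):
        ks = np.arange(0, 400)
        total = np.exp(poisson_log_pmf(lam, ks)).sum()
        assert abs(total - 1.0) < 1e-12

    def test_matches_scipy_and_extends_to_real_k(self):
        assert poisson_log_pmf(7.3, 11) == pytest.approx(
            sps.poisson.logpmf(11, 7.3))
        # gamma extension is continuous and interpolates the integer pmf
        lo, hi = poisson_log_pmf(7.3, 11), poisson_log_pmf(7.3, 12)
        mid = poisson_log_pmf(7.3, 11.5)
        assert min(lo, hi) <= mid <= max(lo, hi)

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValueError):
            poisson_log_pmf(-1.0, 0)
        with pytest.raises(ValueError):
            poisson_log_pmf(1.0, -1)


class TestCopyConditional:
    def test_homozygous_with_clean_breakends(self, params):
        # no stray coverage: only the Pois(lam_d; k) term remains
        p = ModelParams(lam=0.01, lavg=400, readlength=50, p_err=0.01)
        val = copy_conditional_logprob(2, 2, 0, 0,
                                       ModelParams(lam=2 / 300, lavg=350,
                                                   readlength=50))
        # lam_d = (350-100)*2/300 = 5/3; general formula check:
        assert val == pytest.approx(poisson_log_pmf(5 / 3, 2))

    def test_null_at_mean_coverage(self):
        p = ModelParams(lam=0.3, lavg=200, readlength=50)
        val = copy_conditional_logprob(0, 0, 60, 60, p)
        assert val == pytest.approx(2 * poisson_log_pmf(60.0, 60))

    def test_heterozygous_factorizes(self, params):
        n_a = n_b = params.lam_c / 2
        k = params.lam_d / 2
        val = copy_conditional_logprob(1, k, n_a, n_b, params)
        oracle = (sps.poisson.logpmf(int(n_a), params.lam_c / 2) * 2
                  + sps.poisson.logpmf(int(k), params.lam_d / 2))
        assert val == pytest.approx(oracle)

    def test_invalid_copy_number(self, params):
        with pytest.raises(ValueError):
            copy_conditional_logprob(3, 1, 0, 0, params)


class TestScaling:
    def test_full_mapability_is_identity(self):
        assert scale_concordant_count(17, 1.0) == 17.0

    def test_zero_mapability(self):
        assert scale_concordant_count(3, 0.0) == pytest.approx(10.0)

    def test_partial(self):
        assert scale_concordant_count(30, 0.5) == pytest.approx(30 / 0.65)

    def test_r_out_of_range(self):
        with pytest.raises(ValueError):
            scale_concordant_count(3, 1.5)


class TestCoverageCap:
    def test_central_mass_not_capped(self):
        assert not coverage_cap(60, 60.0)
        assert not coverage_cap(0, 60.0)

    def test_threshold_matches_pmf_summation(self):
        mean = 60.0
        # smallest n with upper-tail probability < 1e-4, by direct summation
        pmf = np.exp(poisson_log_pmf(mean, np.arange(0, 400)))
        upper = 1.0 - np.cumsum(pmf)  # P(X > n)
        n_star = int(np.argmax(upper < 1e-4))
        assert coverage_cap(n_star + 1, mean)
        assert not coverage_cap(n_star, mean)


class TestBreakendPairs:
    def _exhaustive_best(self, poly, coverage, params, c, k):
        region = poly.region()
        best = -math.inf
        for a in range(region.a_lo, region.a_hi + 1):
            for b in range(region.b_lo, region.b_hi + 1):
                if not region.contains(a, b):
                    continue
                val = copy_conditional_logprob(
                    c, k, coverage.n_point("chr1", a),
                    coverage.n_point("chr1", b), params)
                best = max(best, val)
        return best

    def test_uniform_coverage_vertices_suffice(self, params):
        stats_small = _small_stats()
        cand = make_candidate(1000, 1100, stats_small)
        cov = make_coverage([], length=10_000)
        pairs = candidate_breakend_pairs(cand.polygon, cov)
        region = cand.polygon.region()
        for c in (0, 1, 2):
            cand_best = max(copy_conditional_logprob(
                c, 1, cov.n_point("chr1", a), cov.n_point("chr1", b), params)
                for a, b in pairs)
            assert cand_best == pytest.approx(
                self._exhaustive_best(cand.polygon, cov, params, c, 1))

    def test_coverage_step_adds_cells(self):
        stats_small = _small_stats()
        cand = make_candidate(1000, 1100, stats_small)
        # one step inside the polygon on the a-axis
        cov = make_coverage([(900, 1005)] * 5, length=10_000)
        pairs = candidate_breakend_pairs(cand.polygon, cov)
        n_vals = {cov.n_point("chr1", a) for a, _ in pairs}
        assert {0, 5} <= n_vals

    def test_max_matches_exhaustive_enumeration(self, params, rng):
        stats_small = _small_stats()
        for trial in range(5):
            x = int(rng.integers(1000, 1200))
            y = x + int(rng.integers(50, 200))
            cand = make_candidate(x, y, stats_small)
            extents = []
            for _ in range(40):
                s = int(rng.integers(x - 100, y + 100))
                extents.append((s, s + int(rng.integers(20, 120))))
            cov = make_coverage(extents, length=10_000)
            pairs = candidate_breakend_pairs(cand.polygon, cov)
            for c in (0, 1, 2):
                got = max(copy_conditional_logprob(
                    c, 2, cov.n_point("chr1", a), cov.n_point("chr1", b),
                    params) for a, b in pairs)
                want = self._exhaustive_best(cand.polygon, cov, params, c, 2)
                assert got == pytest.approx(want), (trial, c)

    def test_empty_polygon_rejected(self, params):
        stats_small = _small_stats()
        r1 = trapezoid_region(1000, 1100, 1, -1, stats_small)
        poly = BreakendPolygon.from_region(
            r1.intersect(trapezoid_region(5000, 5100, 1, -1, stats_small)),
            Signature.DELETION, "chr1", "chr1")
        with pytest.raises(ValueError):
            candidate_breakend_pairs(poly, make_coverage([]))


def _small_stats():
    from probsv.fragments import LibraryStats

    # small geometry keeps exhaustive lattice oracles cheap: gap band [10, 40]
    return LibraryStats(lmin=30, lmax=60, lavg=45, readlength=10)


class TestBreakendScore:
    def test_clean_homozygous_breakend(self, params, stats, empty_coverage):
        k = round(params.lam_d)
        cand = make_candidate(10_000, 12_000, stats, k=k)
        score = score_breakend_variant(cand, empty_coverage, params)
        assert score.copy_call == 2
        assert score.log_lambda > 0

    def test_full_coverage_single_fragment_rejected(self, params, stats):
        cov = uniform_coverage(60, hi=100_000, length=200,
                               spacing=max(1, 200 // 60))
        cand = make_candidate(10_000, 12_000, stats, k=1)
        score = score_breakend_variant(cand, cov, params)
        assert score.log_lambda < 0
        assert score.copy_call == 0

    def test_half_coverage_calls_heterozygote(self, params, stats):
        spacing = 200 // 30
        cov = uniform_coverage(30, hi=100_000, length=200, spacing=spacing)
        k = round(params.lam_d / 2)
        cand = make_candidate(10_000, 12_000, stats, k=k)
        score = score_breakend_variant(cand, cov, params)
        assert score.copy_call == 1
        assert score.best_pair is not None

    def test_monotone_in_support(self, params, stats, empty_coverage):
        prev = -math.inf
        col = column_model(make_candidate(10_000, 12_000, stats,
                                          sig=Signature.INV_PP),
                           empty_coverage, None, params)
        for k in range(0, int(params.lam_d) + 1):
            cur = col.log_lambda(k)
            assert cur >= prev
            prev = cur

    def test_nonincreasing_in_breakend_coverage(self, params, stats):
        vals = []
        for depth in (0, 10, 20, 40, 60):
            cov = (make_coverage([], length=200_000) if depth == 0 else
                   uniform_coverage(depth, hi=150_000, length=200,
                                    spacing=max(1, 200 // depth)))
            cand = make_candidate(50_000, 52_000, stats,
                                  sig=Signature.INV_PP, k=10)
            vals.append(score_breakend_variant(cand, cov, params).log_lambda)
        assert all(a >= b - 1e-9 for a, b in zip(vals, vals[1:]))


class TestDeletionScore:
    def test_lam_interval_formula(self, params):
        # interval of length 1000 at lam=0.3, Lavg=200 -> lam_I = 360
        assert params.lam_interval(1001) == pytest.approx(360.0)

    def test_clean_homozygous_deletion(self, params, stats, empty_coverage):
        cand = make_candidate(10_000, 13_000, stats,
                              k=round(params.lam_d))
        assert cand.amax <= cand.bmin
        score = score_deletion_variant(cand, empty_coverage, None, params)
        assert score.model == "deletion"
        assert score.copy_call == 2
        assert score.log_lambda > 0
        assert score.n_interval == 0

    def test_full_interval_coverage_no_variant(self, params, stats):
        cand = make_candidate(10_000, 13_000, stats, k=1)
        lam_i = params.lam_interval(cand.bmin - cand.amax + 1)
        # lay down approximately lam_I fragments overlapping the interval
        n = int(lam_i)
        width = cand.bmin - cand.amax + 200
        starts = np.linspace(cand.amax - 150, cand.bmin - 50, n).astype(int)
        cov = make_coverage([(int(s), int(s + 199)) for s in starts],
                            length=200_000)
        # score at k=0 by constructing the column model directly
        col = column_model(cand, cov, None, params)
        assert col.variant_score(0).copy_call == 0
        assert col.variant_score(0).log_lambda < 0

    def test_inverted_interval_falls_back_to_breakend_model(self, params,
                                                            stats,
                                                            empty_coverage):
        # a single short-deletion fragment: amax > bmin
        cand = make_candidate(10_000, 10_300, stats, k=1)
        assert cand.amax > cand.bmin
        score = score_deletion_variant(cand, empty_coverage, None, params)
        assert score.model == "breakend"

    def test_mapability_scaling_enters_the_interval_count(self, params,
                                                          stats):
        from probsv.fragments import MapabilityTrack

        cand = make_candidate(10_000, 13_000, stats, k=20)
        starts = np.arange(10_100, 12_800, 60)
        cov = make_coverage([(int(s), int(s + 199)) for s in starts],
                            length=200_000)
        full = score_deletion_variant(cand, cov, MapabilityTrack.uniform(),
                                      params)
        half = MapabilityTrack(
            {"chr1": np.array([[float(cand.amax), float(cand.bmin), 0.0]])})
        scaled = score_deletion_variant(cand, cov, half, params)
        assert scaled.n_hat == pytest.approx(full.n_interval / 0.3)
        assert scaled.r_map == 0.0


class TestGenotypeRecovery:
    def test_noise_free_copy_number_recovery(self, params, stats):
        """Counts drawn at the model's own means recover the generating copy
        number in at least 99% of draws (lam_c = 60, lam_d = 30)."""
        rng = np.random.default_rng(7)
        cand = make_candidate(50_000, 52_000, stats, sig=Signature.INV_PP)
        correct = 0
        n_draws = 1000
        cases = rng.integers(0, 3, size=n_draws)
        for c in cases:
            mean_n = {0: params.lam_c, 1: params.lam_c / 2, 2: 0.0}[int(c)]
            mean_k = {0: 0.0, 1: params.lam_d / 2, 2: params.lam_d}[int(c)]
            n_a = rng.poisson(mean_n)
            n_b = rng.poisson(mean_n)
            k = rng.poisson(mean_k) if c else 0
            logs = [copy_conditional_logprob(cc, k, n_a, n_b, params)
                    for cc in (0, 1, 2)]
            call = int(np.argmax(logs))
            correct += int(call == c)
        assert correct / n_draws >= 0.99
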