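"""Burrows composite r^2 and the LD effective-size estimator."""

import math

import numpy as np
import pytest

from ne_workbench.genepop import apply_pcrit
from ne_workbench.ld import (
    LdEstimationError,
    burrows_r2,
    ld_jackknife_ci,
    ld_ne,
    ld_ne_point,
)
from ne_workbench.simulate import simulate_wright_fisher

from conftest import explicit_loop_r2, genotypes_from_pairs, random_genotypes




class TestBurrowsR2:
    def test_perfect_association_is_one(self):
        # identical dosage patterns at two biallelic loci
        pairs = [
            [[1, 1], [1, 1]],
            [[1, 2], [1, 2]],
            [[1, 2], [1, 2]],
            [[2, 2], [2, 2]],
        ]
        g = genotypes_from_pairs(pairs)
        table = burrows_r2(g)
        assert table.r2[0] == pytest.approx(1.0, abs=1e-12)

    def test_monomorphic_pair_skipped(self):
        pairs = [[[1, 1], [2, 2], [1, 2]], [[1, 1], [2, 2], [1, 1]]]
        g = genotypes_from_pairs(pairs)  # loci 0, 1 monomorphic
        filt = apply_pcrit(g, 0.0)
        assert g.loci[0] in filt.excluded_loci
        assert g.loci[1] in filt.excluded_loci
        with pytest.raises(LdEstimationError):
            burrows_r2(g, filt)

    @pytest.mark.parametrize("seed,missing", [(0, 0.0), (1, 0.1), (2, 0.25)])
    def test_matches_explicit_loop_oracle(self, seed, missing):
        rng = np.random.default_rng(seed)
        g = random_genotypes(rng, 20, 5, 4, missing_rate=missing)
        filt = apply_pcrit(g, 0.0)
        table = burrows_r2(g, filt)
        oracle = explicit_loop_r2(g, filt)
        assert len(table) == len(oracle)
        for i in range(len(table)):
            key = (table.locus_a[i], table.locus_b[i])
            r2, ncomp, n = oracle[key]
            assert table.r2[i] == pytest.approx(r2, abs=1e-12)
            assert table.n_comparisons[i] == ncomp
            assert table.n_individuals[i] == n

    def test_r2_bounded_unit_interval(self):
        rng = np.random.default_rng(11)
        for _ in range(10):
            g = random_genotypes(rng, 15, 4, 5, missing_rate=0.1)
            try:
                table = burrows_r2(g, apply_pcrit(g, 0.02))
            except LdEstimationError:
                continue
            assert np.all(table.r2 >= 0.0)
            assert np.all(table.r2 <= 1.0 + 1e-12)


class TestNePoint:
    def test_naive_inversion(self):
        r2 = 1 / 100 + 1 / (3 * 50)
        assert ld_ne_point(r2, 100, method="naive") == pytest.approx(50.0)

    def test_no_signal_is_infinite(self):
        assert math.isinf(ld_ne_point(0.005, 100, method="waples"))
        assert math.isinf(ld_ne_point(0.009, 100, method="naive"))

    def test_waples_inverts_quadratic_drift_relation(self):
        for ne in (10, 50, 200):
            drift = 1 / (3 * ne) - 0.69 / ne**2
            S = 1e12  # no sampling component
            assert ld_ne_point(drift + 1 / S + 3.19 / S**2, S) == pytest.approx(
                ne, rel=1e-6
            )

    def test_invalid_sample_size(self):
        with pytest.raises(ValueError):
            ld_ne_point(0.02, 0)


class TestJackknife:
    def test_identical_loci_zero_width(self):
        # four loci with pairwise-identical dosage patterns give the
        # same r^2 for every locus pair, so deleting any locus changes
        # nothing: the jackknife variance is zero
        base = [[1, 1], [1, 2], [1, 2], [2, 2], [1, 1], [2, 2]]
        pairs = [[row] * 4 for row in base]
        g = genotypes_from_pairs(pairs)
        table = burrows_r2(g)
        assert np.allclose(table.r2, table.r2[0])
        lo, hi = ld_jackknife_ci(table)
        assert lo == pytest.approx(hi)

    def test_ci_brackets_point(self):
        rng = np.random.default_rng(12)
        hits = 0
        for seed in range(10):
            wf = simulate_wright_fisher(40, 10, 6, 8, seed=seed)
            est = ld_ne(wf.matrix(8), pcrit=0.05)
            if est.infinite or est.ci_low is None:
                continue
            hits += 1
            assert est.ci_low <= est.point <= est.ci_high
        assert hits > 5

    def test_too_few_loci_undefined(self):
        g = random_genotypes(np.random.default_rng(1), 20, 2, 4)
        table = burrows_r2(g)
        assert ld_jackknife_ci(table) is None


class TestPipelineProperties:
    def test_pcrit_screening_estimates_consistent(self):
        """Estimates at the three conventional Pcrit values should rank
        populations consistently (the screening changes little when
        sample sizes are healthy)."""
        points = {0.05: [], 0.02: [], 0.01: []}
        for seed in range(8):
            wf = simulate_wright_fisher(50, 17, 8, 8, seed=100 + seed)
            g = wf.matrix(8)
            for p in points:
                points[p].append(ld_ne(g, pcrit=p, ci=False).point)
        from scipy.stats import spearmanr

        assert spearmanr(points[0.05], points[0.01]).statistic > 0.5
        assert spearmanr(points[0.05], points[0.02]).statistic > 0.5

    def test_mean_r2_matches_drift_sampling_closed_form(self):
        """Under drift-sampling equilibrium, E[r^2] ~ 1/S + 1/(3 Ne)."""
        vals = []
        for seed in range(60):
            wf = simulate_wright_fisher(50, 17, 8, 10, seed=200 + seed)
            vals.append(ld_ne(wf.matrix(10), pcrit=0.02, ci=False).mean_r2)
        expected = 1 / 50 + 1 / (3 * 50)
        assert np.mean(vals) == pytest.approx(expected, rel=0.10)


    def test_jackknife_coverage_near_nominal(self):
        """Empirical coverage of the 95% jackknife CI for the true size
        of an ideal population stays at or above 80%."""
        import math

        from ne_workbench.simulate import simulate_wright_fisher

        cover = n_ok = 0
        for seed in range(200):
            wf = simulate_wright_fisher(50, 17, 8, 10, seed=3000 + seed)
            est = ld_ne(wf.matrix(10), pcrit=0.05)
            if est.ci_low is None or not math.isfinite(est.point):
                continue
            n_ok += 1
            hi = est.ci_high if math.isfinite(est.ci_high) else float("inf")
            if est.ci_low <= 50 <= hi:
                cover += 1
        assert n_ok >= 180
        assert cover / n_ok >= 0.80
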