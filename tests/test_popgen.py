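"""Windowed FST / diversity scan: estimator correctness against
first-principles oracles, window bookkeeping, and the coalescent nulls."""

import numpy as np
import pytest

from seedvigor.popgen import (
    DemographicModel,
    HaplotypeMatrix,
    permutation_threshold,
    pi,
    simulate_coalescent_window,
    simulate_coalescent_windows,
    site_fst,
    window_scan,
)


def wc_anova_oracle(counts1, counts2):
    """Literal one-way ANOVA-of-allele-indicators transcription of the
    haploid Weir-Cockerham components, summing over individual alleles."""
    x1 = np.array([0] * counts1[0] + [1] * counts1[1], float)
    x2 = np.array([0] * counts2[0] + [1] * counts2[1], float)
    groups = [x1, x2]
    ns = np.array([g.size for g in groups])
    N = ns.sum()
    grand = np.concatenate(groups).mean()
    ssb = sum(g.size * (g.mean() - grand) ** 2 for g in groups)
    ssw = sum(((g - g.mean()) ** 2).sum() for g in groups)
    msp = ssb / (len(groups) - 1)
    msg = ssw / (N - len(groups))
    nc = (N - (ns**2).sum() / N) / (len(groups) - 1)
    a = (msp - msg) / nc
    return a, a + msg


class TestSiteFst:
    def test_no_differentiation_is_nonpositive(self):
        a, d = site_fst((10, 10), (10, 10))
        assert d > 0 and a / d <= 0

    def test_fixed_difference_is_one(self):
        a, d = site_fst((20, 0), (0, 20))
        assert a / d == pytest.approx(1.0)

    @pytest.mark.parametrize(
        "c1,c2",
        [((6, 4), (9, 1)), ((3, 7), (8, 2)), ((15, 5), (2, 18)), ((2, 2), (3, 1))],
    )
    def test_matches_anova_transcription(self, c1, c2):
        assert site_fst(c1, c2) == pytest.approx(wc_anova_oracle(c1, c2))

    def test_random_counts_match_oracle(self, rng):
        for _ in range(50):
            n1, n2 = rng.integers(2, 30, 2)
            a1 = int(rng.integers(0, n1 + 1))
            a2 = int(rng.integers(0, n2 + 1))
            c1, c2 = (n1 - a1, a1), (n2 - a2, a2)
            if a1 + a2 == 0 or (a1 == n1 and a2 == n2):
                continue  # monomorphic overall: components are defined 0
            assert site_fst(c1, c2) == pytest.approx(wc_anova_oracle(c1, c2))

    def test_monomorphic_site_gives_zero_components(self):
        assert site_fst((10, 0), (10, 0)) == (0.0, 0.0)

    def test_too_few_alleles_rejected(self):
        with pytest.raises(ValueError):
            site_fst((1, 0), (5, 5))

    def test_hudson_fixed_difference(self):
        a, d = site_fst((20, 0), (0, 20), estimator="hudson")
        assert a / d == pytest.approx(1.0)


class TestPi:
    def test_identical_haplotypes_zero(self):
        assert pi(np.zeros((5, 10), dtype=np.int8), 100) == 0.0

    def test_two_haplotypes_one_difference(self):
        alleles = np.array([[0], [1]], dtype=np.int8)
        assert pi(alleles, 100) == pytest.approx(0.01)

    def test_matches_pairwise_hamming_oracle(self, rng):
        alleles = (rng.random((10, 20)) < 0.4).astype(np.int8)
        span = 500
        n = alleles.shape[0]
        total = sum(
            (alleles[i] != alleles[j]).sum()
            for i in range(n)
            for j in range(i + 1, n)
        )
        expected = total / (n * (n - 1) / 2) / span
        assert pi(alleles, span) == pytest.approx(expected)

    def test_all_missing_warns_and_returns_zero(self):
        alleles = np.full((4, 3), -1, dtype=np.int8)
        with pytest.warns(UserWarning):
            assert pi(alleles, 100) == 0.0


class TestWindowScan:
    def test_window_count_formula(self, rng):
        positions = np.array([1, 10_000])
        alleles = np.array([[0, 0], [1, 1], [0, 1], [1, 0]], dtype=np.int8)
        hm = HaplotypeMatrix(alleles, positions, np.array(["a", "a", "b", "b"]))
        stats = window_scan(hm, window_bp=3000, step_bp=100, min_sites=0)
        assert len(stats) == 71
        assert stats[0].start == 1 and stats[-1].start == 7001

    def test_monomorphic_windows_undefined_fst_zero_pi(self):
        alleles = np.zeros((6, 4), dtype=np.int8)
        hm = HaplotypeMatrix(
            alleles, np.array([100, 200, 300, 3200]), np.array(["a"] * 3 + ["b"] * 3)
        )
        stats = window_scan(hm, 3000, 100, min_sites=1)
        assert all(np.isnan(w.fst) for w in stats)
        assert all(w.pi_pop1 == 0 and w.pi_pop2 == 0 for w in stats)

    def test_single_site_window_membership(self):
        positions = np.array([1, 5000, 10_000])
        alleles = np.array(
            [[0, 0, 0], [0, 1, 0], [0, 0, 0], [0, 1, 0]], dtype=np.int8
        )
        hm = HaplotypeMatrix(alleles, positions, np.array(["a", "a", "b", "b"]))
        stats = window_scan(hm, 3000, 100, min_sites=0)
        for w in stats:
            covered = w.start <= 5000 < w.end
            assert (w.n_sites == 1) == covered

    def test_short_region_truncated_window(self):
        hm = HaplotypeMatrix(
            np.array([[0], [1], [0], [1]], dtype=np.int8),
            np.array([50]),
            np.array(["a", "a", "b", "b"]),
        )
        with pytest.warns(UserWarning):
            stats = window_scan(hm, 3000, 100, min_sites=0)
        assert len(stats) == 1

    def test_pooled_pi_invariant_to_label_permutation(self, two_pop_matrix, rng):
        span = two_pop_matrix.positions[-1] - two_pop_matrix.positions[0] + 1
        pooled = pi(two_pop_matrix.alleles, span)
        labels = two_pop_matrix.pop_labels.copy()
        rng.shuffle(labels)
        hm2 = HaplotypeMatrix(
            two_pop_matrix.alleles, two_pop_matrix.positions, labels
        )
        assert pi(hm2.alleles, span) == pytest.approx(pooled)

    def test_invariant_to_site_order_after_sorting(self, two_pop_matrix, rng):
        order = rng.permutation(two_pop_matrix.alleles.shape[1])
        shuffled = HaplotypeMatrix(
            two_pop_matrix.alleles[:, order][:, np.argsort(two_pop_matrix.positions[order], kind="stable")],
            np.sort(two_pop_matrix.positions[order]),
            two_pop_matrix.pop_labels,
        )
        a = window_scan(two_pop_matrix, 3000, 500, min_sites=0)
        b = window_scan(shuffled, 3000, 500, min_sites=0)
        for wa, wb in zip(a, b):
            assert wa.n_sites == wb.n_sites
            assert np.isnan(wa.fst) and np.isnan(wb.fst) or wa.fst == pytest.approx(wb.fst)

    def test_window_fst_bounded(self, two_pop_matrix):
        for w in window_scan(two_pop_matrix, 3000, 100, min_sites=1):
            if not np.isnan(w.fst):
                assert -0.5 < w.fst <= 1.0


class TestCoalescent:
    def test_zero_mutation_rate_no_sites(self):
        m = DemographicModel(mu=1e-30)
        hm = simulate_coalescent_window(m, 1000, 2, 2, seed=3)
        assert hm.alleles.shape[1] == 0 or hm.alleles.shape == (4, 0)

    def test_determinism(self):
        m = DemographicModel(N_anc=5000, N_teosinte=5000, N_maize_now=5000,
                             N_maize_bottleneck=500, mu=1e-7)
        a = simulate_coalescent_window(m, 5000, 6, 6, seed=11)
        b = simulate_coalescent_window(m, 5000, 6, 6, seed=11)
        assert np.array_equal(a.alleles, b.alleles)
        assert np.array_equal(a.positions, b.positions)

    def test_invalid_model_rejected(self):
        with pytest.raises(ValueError):
            DemographicModel(t_split=100, t_bottleneck_end=200)
        with pytest.raises(ValueError):
            DemographicModel(N_anc=-1)


class TestThresholds:
    def test_permutation_alpha_one_is_minimum(self, two_pop_matrix):
        thr = permutation_threshold(
            two_pop_matrix, 3000, 1000, n_perm=100, alpha=1.0, seed=1
        )
        thr05 = permutation_threshold(
            two_pop_matrix, 3000, 1000, n_perm=100, alpha=0.05, seed=1
        )
        assert thr <= thr05

    def test_permutation_needs_enough_haplotypes(self):
        hm = HaplotypeMatrix(
            np.array([[0, 1], [1, 0]], dtype=np.int8),
            np.array([1, 2]),
            np.array(["a", "b"]),
        )
        with pytest.raises(ValueError):
            permutation_threshold(hm, 3000, 100, n_perm=100, seed=0)

    def test_planted_differentiation_exceeds_threshold(self, rng):
        # strong true differentiation in one region: power should be high
        n, s = 40, 30
        freqs = rng.uniform(0.2, 0.8, s)
        alleles = (rng.random((n, s)) < freqs).astype(np.int8)
        positions = np.arange(1, s + 1) * 100
        # plant near-fixed differences at 5 adjacent sites
        alleles[:20, 10:15] = 1
        alleles[20:, 10:15] = 0
        hm = HaplotypeMatrix(alleles, positions, np.array(["a"] * 20 + ["b"] * 20))
        stats = window_scan(hm, 1000, 100, min_sites=1)
        obs_max = np.nanmax([w.fst for w in stats])
        thr = permutation_threshold(hm, 1000, 100, n_perm=200, alpha=0.05, seed=7)
        assert obs_max > thr
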