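import math

import numpy as np
import pytest

from invflux.io import MISSING
from invflux.popgen import (hwe_exact_test, hwe_test, ld_r2, migration_rate,
                            net_divergence, polarized_sfs, window_stats)

from conftest import make_matrix


# ---------------------------------------------------------------------------
# Independent oracles

def brute_force_window(gt_a, gt_b):
    """Per-site allele-pair enumeration for pi_A, pi_B, dxy, Hudson FST."""
    def alleles(col):
        out = []
        for g in col:
            if g == MISSING:
                continue
            out += [1] * int(g) + [0] * (2 - int(g))
        return out

    def within(gt):
        diffs = comps = 0
        for j in range(gt.shape[1]):
            a = alleles(gt[:, j])
            for x in range(len(a)):
                for y in range(x + 1, len(a)):
                    comps += 1
                    diffs += a[x] != a[y]
        return diffs, comps

    da, ca = within(gt_a)
    db, cb = within(gt_b)
    dab = cab = 0
    for j in range(gt_a.shape[1]):
        for x in alleles(gt_a[:, j]):
            for y in alleles(gt_b[:, j]):
                cab += 1
                dab += x != y
    pi_a = da / ca if ca else None
    pi_b = db / cb if cb else None
    dxy = dab / cab if cab else None
    fst = None
    if dxy and pi_a is not None and pi_b is not None:
        fst = 1 - 0.5 * (pi_a + pi_b) / dxy
    return pi_a, pi_b, dxy, fst


def hwe_distribution_oracle(n_minor, n):
    """Exact P(n_het = h | minor allele count, n diploids) via the
    closed-form genotype-count probability with integer factorials."""
    f = math.factorial
    probs = {}
    for h in range(n_minor % 2, n_minor + 1, 2):
        hom_min = (n_minor - h) // 2
        hom_maj = n - h - hom_min
        if hom_maj < 0:
            continue
        num = f(n) * (2 ** h) * f(n_minor) * f(2 * n - n_minor)
        den = f(hom_min) * f(h) * f(hom_maj) * f(2 * n)
        probs[h] = num / den
    total = sum(probs.values())
    return {h: p / total for h, p in probs.items()}


def hwe_p_oracle(n_hom_ref, n_het, n_hom_alt):
    n = n_hom_ref + n_het + n_hom_alt
    n_a = 2 * n_hom_alt + n_het
    n_minor = min(n_a, 2 * n - n_a)
    if n_minor == 0:
        return 1.0
    probs = hwe_distribution_oracle(n_minor, n)
    p_obs = probs[n_het]
    return min(1.0, sum(p for p in probs.values() if p <= p_obs * (1 + 1e-9)))


# ---------------------------------------------------------------------------

class TestWindowStats:
    def test_identical_groups_have_zero_diversity_and_undefined_fst(self):
        gt = np.zeros((6, 5), dtype=np.int8)
        m = make_matrix(gt)
        (w,) = window_stats(m, ["s0", "s1", "s2"], ["s3", "s4", "s5"],
                            window_bp=100)
        assert w.pi_a == 0 and w.pi_b == 0 and w.dxy == 0
        assert w.fst is None  # dxy = 0 -> FST undefined, not zero

    def test_fixed_differences_give_fst_one(self):
        # group A fixed ref, group B fixed alt at 2 of 10 sites
        gt = np.zeros((6, 10), dtype=np.int8)
        gt[3:, [2, 7]] = 2
        m = make_matrix(gt)
        (w,) = window_stats(m, ["s0", "s1", "s2"], ["s3", "s4", "s5"],
                            window_bp=100)
        assert w.pi_a == 0 and w.pi_b == 0
        assert w.dxy == pytest.approx(2 / 10)
        assert w.fst == pytest.approx(1.0)

    def test_zero_comparison_window_reports_missing(self):
        gt = np.full((4, 2), MISSING, dtype=np.int8)
        gt[0, 0] = 0  # group A called at site 0 only
        m = make_matrix(gt, positions=[5, 150])
        stats = window_stats(m, ["s0", "s1"], ["s2", "s3"], window_bp=100,
                             span=(0, 200))
        assert stats[0].dxy is None and stats[0].fst is None
        assert stats[1].n_sites == 0

    def test_matches_brute_force_oracle_on_random_matrices(self):
        """Vectorized pair counting equals allele-pair enumeration on 200
        random matrices with missing data, to 1e-12 relative tolerance."""
        rng = np.random.default_rng(42)
        for trial in range(200):
            n = int(rng.integers(4, 11))
            s = int(rng.integers(2, 101))
            gt = rng.choice([MISSING, 0, 1, 2], size=(n, s),
                            p=[0.1, 0.5, 0.2, 0.2]).astype(np.int8)
            m = make_matrix(gt, positions=np.arange(1, s + 1))
            half = n // 2
            ga = [f"s{i}" for i in range(half)]
            gb = [f"s{i}" for i in range(half, n)]
            (w,) = window_stats(m, ga, gb, window_bp=s + 1)
            exp = brute_force_window(gt[:half], gt[half:])
            for got, want in zip((w.pi_a, w.pi_b, w.dxy, w.fst), exp):
                if want is None:
                    assert got is None
                else:
                    assert got == pytest.approx(want, rel=1e-12)

    def test_adding_invariant_sites_dilutes_pi_and_dxy_not_fst_order(self):
        rng = np.random.default_rng(3)
        gt = rng.choice([0, 1, 2], size=(8, 30)).astype(np.int8)
        m_var = make_matrix(gt, positions=np.arange(1, 31))
        padded = np.concatenate([gt, np.zeros((8, 70), dtype=np.int8)], axis=1)
        alt = ["C"] * 30 + [None] * 70
        m_all = make_matrix(padded, positions=np.arange(1, 101), alt=alt)
        ga, gb = [f"s{i}" for i in range(4)], [f"s{i}" for i in range(4, 8)]
        (w_var,) = window_stats(m_var, ga, gb, window_bp=200)
        (w_all,) = window_stats(m_all, ga, gb, window_bp=200)
        assert w_all.pi_a < w_var.pi_a
        assert w_all.dxy < w_var.dxy
        assert w_all.fst == pytest.approx(w_var.fst, rel=1e-9)


class TestNetDivergence:
    def test_equal_within_and_between_gives_zero_age(self):
        # identical monomorphic groups: d_xy == (d_x + d_y)/2 -> d_a = 0
        gt = np.zeros((4, 5), dtype=np.int8)
        m = make_matrix(gt, samples=list("abcd"))
        est = net_divergence(m, ["a", "b"], ["c", "d"], lam_per_year=3.3e-10)
        assert est.d_a == pytest.approx(0.0)
        assert est.t_years == pytest.approx(0.0)
        assert not est.negative

    def test_dating_arithmetic(self):
        # d_a = 6.6e-4 at lambda = 3.3e-10 per year -> T = 1.0e6 years
        assert 6.6e-4 / (2 * 3.3e-10) == pytest.approx(1.0e6)

    def test_doubling_lambda_halves_t(self, cohort_no_flux, truth_groups):
        m = cohort_no_flux.matrix
        kw = dict(n_invariant_sites=cohort_no_flux.params.L - m.n_sites)
        e1 = net_divergence(m, truth_groups["NN"], truth_groups["SS"],
                            lam_per_year=3.3e-10, **kw)
        e2 = net_divergence(m, truth_groups["NN"], truth_groups["SS"],
                            lam_per_year=6.6e-10, **kw)
        assert e2.t_years == pytest.approx(e1.t_years / 2, rel=1e-12)

    def test_invalid_lambda_rejected(self, cohort_no_flux, truth_groups):
        with pytest.raises(ValueError, match="lambda"):
            net_divergence(cohort_no_flux.matrix, truth_groups["NN"],
                           truth_groups["SS"], lam_per_year=0.0)


class TestMigrationRate:
    @pytest.mark.parametrize("fst,nm", [(0.2, 1.0), (1.0, 0.0), (0.5, 0.25)])
    def test_formula(self, fst, nm):
        assert migration_rate(fst) == pytest.approx(nm)

    def test_nonpositive_fst_is_infinite_migration(self):
        assert migration_rate(0.0) == math.inf
        assert migration_rate(-0.1) == math.inf


class TestLd:
    def test_duplicated_site_has_r2_one_and_thinning_removes_close_pair(self):
        rng = np.random.default_rng(9)
        col = rng.choice([0, 1, 2], size=10).astype(np.int8)
        gt = np.stack([col, col, col], axis=1)
        m = make_matrix(gt, positions=[1_000, 4_000, 7_000])
        recs = ld_r2(m, [f"s{i}" for i in range(10)], thin_bp=5_000)
        # site at 4 kb thinned (3 kb from the first); one pair remains
        assert recs[["pos_i", "pos_j"]].values.tolist() == [[1_000, 7_000]]
        assert recs["r2"].iloc[0] == pytest.approx(1.0)

    def test_effectively_unlinked_panmictic_sites_have_low_mean_r2(self):
        """With recombination fast enough that thinned flank SNPs are
        effectively independent, background R^2 at n=30 stays below 0.1."""
        from invflux.simulate import CohortParams, simulate_cohort
        params = CohortParams(n_N=15, n_S=15, n_het=0, L=100_000,
                              inversion_interval=(0, 1_000),
                              recombination_rate=2e-7, flux_rate=0, seed=21,
                              T_split_gen=300_000, T_outgroup_gen=2_000_000)
        cohort = simulate_cohort(params)
        m = cohort.matrix
        flank = m.take_sites(m.region_mask("chr1", 1_000, 100_000))
        recs = ld_r2(flank, m.samples, thin_bp=5_000)
        assert len(recs) >= 10
        assert recs["r2"].mean() < 0.1

    def test_fewer_than_two_sites_is_empty(self):
        m = make_matrix(np.zeros((4, 1), dtype=np.int8))
        assert ld_r2(m, [f"s{i}" for i in range(4)]).empty


class TestPolarizedSfs:
    def test_counts_and_exclusions_by_hand(self):
        gt = np.array([[1, 1, 2], [1, 0, 2], [1, 0, 2], [0, 0, 2],
                       [0, 0, 2]], dtype=np.int8)
        m = make_matrix(gt, aa=["A", "C", "G"],
                        fclass=["synonymous", "non-synonymous", "synonymous"])
        # site 0: AA=ref -> derived count 3; site 1: AA=alt -> derived
        # count 10-1=9; site 2: AA matches neither -> excluded
        sfs, excluded = polarized_sfs(m, m.samples)
        assert excluded == 1
        rows = {(r.fclass, r.derived_count): r.n_sites
                for r in sfs.itertuples()}
        assert rows == {("synonymous", 3): 1, ("non-synonymous", 9): 1}

    def test_matches_truth_polarization_on_synthetic_cohort(
            self, cohort_no_flux, truth_groups):
        """Implementation equals a per-site loop over the emitted matrix
        using the recorded outgroup allele."""
        m = cohort_no_flux.matrix
        samples = truth_groups["NN"]
        sfs, _ = polarized_sfs(m, samples)
        idx = m.sample_indices(samples)
        expected = {}
        for j, site in enumerate(m.sites.itertuples(index=False)):
            col = m.genotypes[idx, j]
            col = col[col != MISSING]
            alt = int(col.sum())
            c = 2 * len(col)
            derived = alt if site.aa == site.ref else c - alt
            if 0 < derived < c:
                key = (site.fclass, derived)
                expected[key] = expected.get(key, 0) + 1
        got = {(r.fclass, r.derived_count): r.n_sites
               for r in sfs.itertuples()}
        assert got == expected


class TestHwe:
    def test_matches_enumeration_oracle(self):
        cases = [(25, 50, 25), (10, 0, 10), (0, 20, 0), (30, 10, 2),
                 (5, 5, 5), (12, 1, 0)]
        for hom_ref, het, hom_alt in cases:
            got = hwe_exact_test(hom_ref, het, hom_alt)
            want = hwe_p_oracle(hom_ref, het, hom_alt)
            assert got == pytest.approx(want, rel=1e-9), (hom_ref, het, hom_alt)

    def test_perfect_hwe_is_not_rejected(self):
        assert hwe_exact_test(25, 50, 25) > 0.5

    def test_all_heterozygotes_rejected(self):
        assert hwe_exact_test(0, 20, 0) < 0.01

    def test_monomorphic_returns_one(self):
        assert hwe_exact_test(30, 0, 0) == 1.0

    def test_matrix_interface_requires_five_diploids(self):
        m = make_matrix(np.array([[1], [1], [1], [1]], dtype=np.int8))
        with pytest.raises(ValueError, match=">=5"):
            hwe_test(m, m.samples, 0)
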