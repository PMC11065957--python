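"""Window engine, H_P, Weir-Cockerham F_ST and Z-transformation.

The F_ST oracle here is a literal scalar transliteration of the published
two-population variance-component estimator (per-allele a, b, c summed
over both alleles), independent of the package's vectorised code path.
"""

import numpy as np
import pytest

from conftest import make_gm
from sweeptx import qc, windows
from sweeptx.datamodel import ConfigError
from sweeptx.qc import AlleleCounts


class TestMakeWindows:
    def test_enumeration_250kb(self):
        w = windows.make_windows({"c": 250_000})
        # starts every 50 kb while <= length; the trailing 50-kb window
        # [200001, 250000] has length == step and is emitted
        assert w["start"].tolist() == [1, 50001, 100001, 150001, 200001]
        assert w["end"].tolist() == [100000, 150000, 200000, 250000, 250000]

    def test_boundary_rule_100kb(self):
        w = windows.make_windows({"c": 100_000})
        assert len(w) == 2
        assert w.iloc[1][["start", "end"]].tolist() == [50001, 100000]

    def test_single_window_degenerate(self):
        w = windows.make_windows({"c": 40_000})
        assert len(w) == 1
        assert w.iloc[0][["start", "end"]].tolist() == [1, 40000]

    def test_step_larger_than_size_rejected(self):
        with pytest.raises(ConfigError):
            windows.make_windows({"c": 100_000}, size=1000, step=2000)


def counts_from_maj_min(pairs):
    maj = np.array([p[0] for p in pairs])
    mn = np.array([p[1] for p in pairs])
    # encode with ref as the major allele so n_major/n_minor reproduce inputs
    return AlleleCounts(n_ref=maj, n_alt=mn,
                        n_called_samples=(maj + mn) // 2,
                        call_rate=np.ones(len(pairs)))


class TestPooledHeterozygosity:
    def test_hand_example(self):
        ac = counts_from_maj_min([(18, 2), (14, 6)])
        assert windows.pooled_heterozygosity(ac) == pytest.approx(0.32)

    def test_all_fixed_is_zero(self):
        ac = counts_from_maj_min([(20, 0), (20, 0)])
        assert windows.pooled_heterozygosity(ac) == 0.0

    def test_balanced_is_max(self):
        ac = counts_from_maj_min([(10, 10), (10, 10)])
        assert windows.pooled_heterozygosity(ac) == pytest.approx(0.5)

    def test_zero_alleles_is_nan(self):
        ac = counts_from_maj_min([(0, 0)])
        assert np.isnan(windows.pooled_heterozygosity(ac))

    def test_invariant_under_allele_swap_and_order(self):
        # swapping which allele is "major" at a 50/50 site and reordering
        # SNPs cannot change H_P
        a = counts_from_maj_min([(10, 10), (14, 6)])
        b = counts_from_maj_min([(14, 6), (10, 10)])
        assert windows.pooled_heterozygosity(a) == windows.pooled_heterozygosity(b)


def wc_fst_oracle(genotypes_a, genotypes_b):
    """Scalar Weir-Cockerham (1984) theta-hat, summing components per allele.

    ``genotypes_*``: list of (allele0, allele1) tuples for one site.
    """
    pops = [genotypes_a, genotypes_b]
    r = 2
    n = [len(g) for g in pops]
    n_bar = sum(n) / r
    n_c = (sum(n) - sum(ni**2 for ni in n) / sum(n)) / (r - 1)
    a_sum = b_sum = c_sum = 0.0
    for allele in (0, 1):
        p = [sum(int(g[0] == allele) + int(g[1] == allele) for g in pop) / (2 * ni)
             for pop, ni in zip(pops, n)]
        h = [sum(int((g[0] == allele) != (g[1] == allele)) for g in pop) / ni
             for pop, ni in zip(pops, n)]
        p_bar = sum(ni * pi for ni, pi in zip(n, p)) / (r * n_bar)
        s2 = sum(ni * (pi - p_bar) ** 2 for ni, pi in zip(n, p)) / ((r - 1) * n_bar)
        h_bar = sum(ni * hi for ni, hi in zip(n, h)) / (r * n_bar)
        a = (n_bar / n_c) * (s2 - (p_bar * (1 - p_bar) - (r - 1) / r * s2
                                   - h_bar / 4) / (n_bar - 1))
        b = (n_bar / (n_bar - 1)) * (p_bar * (1 - p_bar) - (r - 1) / r * s2
                                     - (2 * n_bar - 1) / (4 * n_bar) * h_bar)
        c = h_bar / 2
        a_sum, b_sum, c_sum = a_sum + a, b_sum + b, c_sum + c
    denom = a_sum + b_sum + c_sum
    return np.nan if denom == 0 else a_sum / denom


def gm_from_genotype_lists(site_genos_a, site_genos_b):
    n_var = len(site_genos_a)
    na, nb = len(site_genos_a[0]), len(site_genos_b[0])
    alleles = np.zeros((n_var, na + nb, 2), dtype=np.int8)
    for v in range(n_var):
        for i, g in enumerate(site_genos_a[v]):
            alleles[v, i] = g
        for i, g in enumerate(site_genos_b[v]):
            alleles[v, na + i] = g
    return make_gm(alleles, pops=["A"] * na + ["B"] * nb)


class TestFstPerSnp:
    def test_no_differentiation_nonpositive(self):
        site_a = [(0, 1)] * 10 + [(0, 0)] * 5 + [(1, 1)] * 5
        gm = gm_from_genotype_lists([site_a], [site_a])
        assert windows.fst_per_snp(gm)[0] <= 0

    def test_fixed_difference_is_one(self):
        gm = gm_from_genotype_lists([[(1, 1)] * 10], [[(0, 0)] * 10])
        assert windows.fst_per_snp(gm)[0] == pytest.approx(1.0)

    def test_monomorphic_site_is_nan(self):
        gm = gm_from_genotype_lists([[(0, 0)] * 6], [[(0, 0)] * 6])
        assert np.isnan(windows.fst_per_snp(gm)[0])

    def test_matches_scalar_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(30):
            ga = [tuple(rng.integers(0, 2, 2)) for _ in range(10)]
            gb = [tuple(rng.integers(0, 2, 2)) for _ in range(10)]
            gm = gm_from_genotype_lists([ga], [gb])
            got = windows.fst_per_snp(gm)[0]
            want = wc_fst_oracle(ga, gb)
            if np.isnan(want):
                assert np.isnan(got)
            else:
                assert got == pytest.approx(want, abs=1e-12)

    def test_negative_estimates_retained(self, neutral_gm):
        fst = windows.fst_per_snp(neutral_gm)
        assert np.nanmin(fst) < 0  # not clamped


class TestWindowMean:
    def test_two_point_mean(self):
        win = windows.make_windows({"c": 100})
        out = windows.window_mean(np.array([10, 20]), [0.1, 0.3], win,
                                  chrom=np.array(["c", "c"]), min_snps=1)
        assert out[0] == pytest.approx(0.2)

    def test_empty_window_is_nan(self):
        win = windows.make_windows({"c": 100})
        out = windows.window_mean(np.array([], dtype=np.int64), [], win,
                                  chrom=np.array([]), min_snps=1)
        assert np.isnan(out[0])

    def test_closed_interval_includes_end(self):
        win = windows.make_windows({"c": 100_000})
        out = windows.window_mean(np.array([100_000]), [0.7], win,
                                  chrom=np.array(["c"]), min_snps=1)
        assert out[0] == pytest.approx(0.7) and out[1] == pytest.approx(0.7)

    def test_min_snps_gate(self):
        win = windows.make_windows({"c": 100})
        out = windows.window_mean(np.array([10, 20]), [0.1, 0.3], win,
                                  chrom=np.array(["c", "c"]), min_snps=3)
        assert np.isnan(out[0])

    def test_mean_within_range(self, neutral_gm):
        fst = windows.fst_per_snp(neutral_gm)
        win = windows.make_windows({"chr1": 2_000_000})
        means = windows.window_mean(neutral_gm.pos, fst, win,
                                    chrom=neutral_gm.chrom)
        ok = ~np.isnan(means)
        assert np.all(means[ok] >= np.nanmin(fst)) and np.all(means[ok] <= np.nanmax(fst))


class TestZTransform:
    def test_hand_example(self):
        z = windows.z_transform([1, 2, 3])
        np.testing.assert_allclose(z, [-1.224745, 0, 1.224745], atol=1e-6)

    def test_constant_vector_warns_nan(self):
        with pytest.warns(UserWarning):
            z = windows.z_transform([2.0, 2.0, 2.0])
        assert np.all(np.isnan(z))

    def test_normalisation_identity(self):
        rng = np.random.default_rng(0)
        x = rng.normal(5, 3, 500)
        x[::7] = np.nan
        z = windows.z_transform(x)
        assert np.nanmean(z) == pytest.approx(0, abs=1e-12)
        assert np.nanstd(z) == pytest.approx(1, abs=1e-12)
        assert np.array_equal(np.isnan(x), np.isnan(z))  # NA propagates
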