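import numpy as np
import pytest

from sweeptx import de
from sweeptx.datamodel import CountTable


def ct(counts, lib_size, lengths):
    counts = np.asarray(counts)
    return CountTable([f"g{i}" for i in range(counts.shape[0])], ["A", "B"],
                      counts, np.asarray(lib_size), np.asarray(lengths))


class TestRpkm:
    def test_formula(self):
        t = ct([[1000, 0]], [10_000_000, 10_000_000], [2000])
        r = de.rpkm(t)
        assert r[0, 0] == pytest.approx(50.0)
        assert r[0, 1] == 0.0

    def test_doubling_lib_size_halves(self):
        a = de.rpkm(ct([[100, 100]], [1_000_000, 2_000_000], [500]))
        assert a[0, 0] == pytest.approx(2 * a[0, 1])

    def test_zero_lib_size_errors(self):
        t = ct([[0, 0]], [10, 10], [100])
        t.lib_size = np.array([0, 10])
        with pytest.raises(ValueError):
            de.rpkm(t)


class TestExpressedGeneSets:
    def test_enumeration(self):
        r = np.array([[1.0, 0.0], [0.0, 0.0], [2.0, 2.0]])
        out = de.expressed_gene_sets(r, ["g1", "g2", "g3"])
        assert out["sets"][0] == {"g1", "g3"}
        assert out["sets"][1] == {"g3"}
        assert out["intersection_size"] == 1
        assert out["fractions"][0] == pytest.approx(2 / 3)

    def test_infinite_threshold_empty(self):
        r = np.array([[1.0, 5.0]])
        out = de.expressed_gene_sets(r, ["g1"], min_expr=np.inf)
        assert out["sizes"] == [0, 0]

    def test_identical_libraries(self):
        r = np.array([[1.0, 1.0], [0.0, 0.0]])
        out = de.expressed_gene_sets(r, ["g1", "g2"])
        assert out["intersection"] == out["sets"][0] == out["sets"][1]


class TestDeTest:
    def test_zero_zero_equal_libraries(self):
        # the single posterior-predictive term P(0|0) is 1/2, so the
        # doubled minimum tail saturates at 1
        assert de.ac_probability(0, 0, 1000, 1000) == pytest.approx(0.5)
        assert de.de_test(0, 0, 1000, 1000) == pytest.approx(1.0)

    def test_balanced_counts_p_one(self):
        for x in (1, 10, 500):
            assert de.de_test(x, x, 1_000_000, 1_000_000) == pytest.approx(1.0)

    def test_exchange_symmetry_where_it_holds(self):
        # the tail construction conditions on the first count, so exact
        # exchange symmetry only holds where the problem is fully symmetric
        # (x == y with equal libraries); the off-diagonal asymmetry is a
        # documented property of the construction
        for x in (0, 3, 50):
            assert (de.de_test(x, x, 1_000_000, 1_000_000)
                    == pytest.approx(de.de_test(x, x, 1_000_000, 1_000_000)))
            assert de.de_test(x, x, 1_000_000, 1_000_000) == pytest.approx(1.0)
        assert de.de_test(1, 0, 1000, 1000) == pytest.approx(0.5)
        assert de.de_test(0, 1, 1000, 1000) == pytest.approx(1.0)

    def test_matches_log_space_series(self):
        # independent evaluation: sum the published closed-form terms
        from scipy.special import gammaln

        def term(x, y, la, lb):
            r = lb / la
            return np.exp(y * np.log(r) + gammaln(x + y + 1) - gammaln(x + 1)
                          - gammaln(y + 1) - (x + y + 1) * np.log(1 + r))

        x, la, lb = 30, 3_000_000, 2_000_000
        for y in (5, 20, 45):
            lower = sum(term(x, k, la, lb) for k in range(0, y + 1))
            upper = 1 - sum(term(x, k, la, lb) for k in range(0, y))
            want = min(1.0, 2 * min(lower, upper))
            assert de.de_test(x, y, la, lb) == pytest.approx(want, rel=1e-9)

    def test_large_counts_stable(self):
        p = de.de_test(200_000, 100_000, 10_000_000, 10_000_000)
        assert 0 <= p < 1e-100  # no overflow, extremely significant

    def test_null_pvalues_super_uniform(self):
        # Poisson null at matched means: type-I error at 0.05 stays <= 0.06
        rng = np.random.default_rng(13)
        mu = rng.lognormal(3.0, 1.0, 10_000)
        x = rng.poisson(mu)
        y = rng.poisson(mu)
        p = de.de_test(x, y, 1_000_000, 1_000_000)
        assert (p <= 0.05).mean() <= 0.06

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            de.de_test(-1, 0, 10, 10)


class TestBhFdr:
    def test_step_up_arithmetic(self):
        q = de.bh_fdr([0.01, 0.02, 0.03, 0.04])
        np.testing.assert_allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_single_p(self):
        assert de.bh_fdr([0.2])[0] == pytest.approx(0.2)

    def test_all_ones(self):
        np.testing.assert_allclose(de.bh_fdr([1.0, 1.0, 1.0]), 1.0)

    def test_nan_excluded_from_m(self):
        q = de.bh_fdr([0.01, np.nan, 0.02])
        assert np.isnan(q[1])
        np.testing.assert_allclose(q[[0, 2]], de.bh_fdr([0.01, 0.02]))

    def test_monotone_and_dominates_p(self):
        rng = np.random.default_rng(14)
        p = rng.random(200)
        q = de.bh_fdr(p)
        assert np.all(q >= p - 1e-12)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            de.bh_fdr([1.5])


class TestCallDegs:
    def make_table(self, fdr, lfc):
        import pandas as pd

        return pd.DataFrame({"fdr": fdr, "log2_ratio": lfc},
                            index=[f"g{i}" for i in range(len(fdr))])

    @pytest.mark.parametrize("fdr,lfc,status", [
        (0.0005, 1.5, "up"),
        (0.0005, 0.9, "ns"),   # fold filter binds
        (0.002, 3.0, "ns"),    # FDR filter binds
        (0.0005, -1.0, "down"),
        (0.001, 1.0, "up"),    # thresholds are inclusive
    ])
    def test_threshold_semantics(self, fdr, lfc, status):
        out = de.call_degs(self.make_table([fdr], [lfc]))
        assert out["status"].iloc[0] == status

    def test_partition(self):
        rng = np.random.default_rng(15)
        tab = self.make_table(rng.random(100) * 0.01, rng.normal(0, 2, 100))
        out = de.call_degs(tab)
        counts = out["status"].value_counts()
        assert counts.sum() == 100


class TestLog2Ratio:
    def test_pseudocount_only_when_zero(self):
        v = de.log2_ratio(np.array([100]), np.array([100]), 1000, 1000,
                          lengths=np.array([1000]))
        assert v[0] == pytest.approx(0.0)
        v0 = de.log2_ratio(np.array([0]), np.array([100]), 1000, 1000,
                           lengths=np.array([1000]))
        assert np.isfinite(v0[0]) and v0[0] < 0

    def test_sign_convention_up_in_A(self):
        v = de.log2_ratio(np.array([400]), np.array([100]), 1000, 1000,
                          lengths=np.array([1000]))
        assert v[0] == pytest.approx(2.0)


def test_de_table_end_to_end():
    t = ct([[1000, 100], [50, 50], [0, 0]],
           [1_000_000, 1_000_000], [1000, 1000, 1000])
    tab = de.call_degs(de.de_table(t))
    assert tab.loc["g0", "status"] == "up"
    assert tab.loc["g1", "status"] == "ns"
    assert tab.loc["g2", "p_value"] == pytest.approx(1.0)
    assert np.all(tab["fdr"] >= tab["p_value"] - 1e-12)
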