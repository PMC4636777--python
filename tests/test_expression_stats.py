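import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import binom

from mirvar.expression_stats import (
    DEParams,
    FilterParams,
    bh_adjust,
    estimate_common_dispersion,
    exact_test_pvalue,
    expression_filter,
    nb_exact_test,
    tmm_factors,
    tmm_normalize,
    venn_sets,
)
from mirvar.reference_io import CountTable
from mirvar.synthetic_data import SimConfig, simulate_counts


def _table(counts: dict, groups: dict) -> CountTable:
    return CountTable(counts=pd.DataFrame(counts).T, groups=groups)


class TestExpressionFilter:
    GROUPS = {f"a{i}": "A" for i in range(4)} | {f"b{i}": "B" for i in range(4)}

    def test_boundary_of_the_rule_is_kept(self):
        t = _table({"t1": dict({f"a{i}": 10 for i in range(4)}, **{f"b{i}": 0 for i in range(4)})}, self.GROUPS)
        out = expression_filter(t, FilterParams())
        assert list(out.counts.index) == ["t1"]

    def test_three_of_four_high_samples_dropped(self):
        row = {"a0": 9, "a1": 100, "a2": 100, "a3": 100} | {f"b{i}": 0 for i in range(4)}
        t = _table({"t1": row}, self.GROUPS)
        assert expression_filter(t, FilterParams()).counts.empty

    def test_group_exception_lowers_requirement(self):
        row = {"a0": 9, "a1": 100, "a2": 100, "a3": 100} | {f"b{i}": 0 for i in range(4)}
        t = _table({"t1": row}, self.GROUPS)
        out = expression_filter(t, FilterParams(group_exceptions={"A": 3}))
        assert list(out.counts.index) == ["t1"]

    def test_empty_table_passes_through(self):
        t = CountTable(counts=pd.DataFrame(columns=list(self.GROUPS)), groups=self.GROUPS)
        assert expression_filter(t, FilterParams()).counts.empty

    def test_group_smaller_than_requirement_is_an_error(self):
        t = _table({"t1": {"a0": 10, "b0": 10}}, {"a0": "A", "b0": "B"})
        with pytest.raises(ValueError, match="requires"):
            expression_filter(t, FilterParams())

    def test_monotone_in_min_reads(self, rng):
        counts = pd.DataFrame(
            rng.integers(0, 30, (200, 8)),
            index=[f"t{i}" for i in range(200)],
            columns=list(self.GROUPS),
        )
        t = CountTable(counts=counts, groups=self.GROUPS)
        kept_10 = set(expression_filter(t, FilterParams(min_reads=10)).counts.index)
        kept_15 = set(expression_filter(t, FilterParams(min_reads=15)).counts.index)
        assert kept_15 <= kept_10


class TestTMM:
    def test_identical_libraries_give_unit_factors(self, rng):
        col = rng.integers(1, 200, 300)
        counts = pd.DataFrame({"s1": col, "s2": col})
        assert np.allclose(tmm_factors(counts), 1.0)

    def test_pure_depth_difference_handled_by_cpm_not_factor(self, rng):
        col = rng.integers(1, 200, 300)
        counts = pd.DataFrame({"s1": col, "s2": 2 * col})
        f = tmm_factors(counts)
        assert np.allclose(f, 1.0)  # all M-values are zero
        _, cpm = tmm_normalize(counts)
        assert np.allclose(cpm["s1"], cpm["s2"])

    def test_composition_skew_recovered_within_5_percent(self, rng):
        # sample B carries one dominant contaminant taking ~1/3 of its library;
        # TMM should scale the shared tags' ratio (1 - f) back out
        base = rng.integers(50, 500, 500)
        a = pd.Series(base)
        spike = int(base.sum() * 0.5)
        b = pd.concat([pd.Series(base), pd.Series([spike])], ignore_index=True)
        a = pd.concat([a, pd.Series([0])], ignore_index=True)
        counts = pd.DataFrame({"A": a, "B": b})
        f = tmm_factors(counts)
        planted = 1.0 - spike / b.sum()  # shared-tag ratio after the spike
        assert f["B"] / f["A"] == pytest.approx(planted, rel=0.05)

    def test_cpm_invariant_to_scaling_one_library(self, rng):
        counts = pd.DataFrame(rng.integers(1, 100, (200, 3)), columns=list("abc"))
        _, cpm1 = tmm_normalize(counts)
        scaled = counts.copy()
        scaled["b"] = scaled["b"] * 7
        _, cpm2 = tmm_normalize(scaled)
        assert np.allclose(cpm1.values, cpm2.values, rtol=1e-6)

    def test_all_zero_sample_rejected(self):
        counts = pd.DataFrame({"a": [1, 2], "b": [0, 0]})
        with pytest.raises(ValueError, match="all-zero"):
            tmm_factors(counts)


class TestDispersion:
    def test_poisson_counts_give_near_zero(self, rng):
        mu = np.exp(rng.uniform(np.log(50), np.log(500), 2000))
        counts = pd.DataFrame(
            {f"s{i}": rng.poisson(mu) for i in range(8)},
        )
        groups = {f"s{i}": "A" if i < 4 else "B" for i in range(8)}
        phi = estimate_common_dispersion(counts.astype(float), groups)
        assert 0 <= phi < 0.02

    def test_nb_dispersion_recovered_within_25_percent(self):
        rng = np.random.default_rng(1234)
        phi_true = 0.1
        r = 1 / phi_true
        mu = np.exp(rng.uniform(np.log(100), np.log(1000), 4000))
        cols = {f"s{i}": rng.negative_binomial(r, r / (r + mu)) for i in range(10)}
        counts = pd.DataFrame(cols).astype(float)
        groups = {f"s{i}": "A" if i < 5 else "B" for i in range(10)}
        phi = estimate_common_dispersion(counts, groups)
        assert phi == pytest.approx(phi_true, rel=0.25)

    def test_constant_counts_give_zero(self):
        counts = pd.DataFrame({"s1": [5.0, 7.0], "s2": [5.0, 7.0], "s3": [5.0, 7.0]})
        assert estimate_common_dispersion(counts, {"s1": "A", "s2": "A", "s3": "A"}) == 0.0

    def test_no_replicates_warns_and_returns_zero(self):
        counts = pd.DataFrame({"s1": [5.0], "s2": [9.0]})
        with pytest.warns(UserWarning):
            phi = estimate_common_dispersion(counts, {"s1": "A", "s2": "B"})
        assert phi == 0.0


def binomial_oracle(a: int, b: int, n_a: int, n_b: int) -> float:
    """Exhaustive enumeration of all splits of the total under phi = 0."""
    s = a + b
    pmf = binom.pmf(np.arange(s + 1), s, n_a / (n_a + n_b))
    return float(min(1.0, pmf[pmf <= pmf[a] * (1 + 1e-12)].sum()))


class TestExactTest:
    def test_symmetric_split_has_p_one(self):
        assert exact_test_pvalue(5, 5, 3, 3, 0.0) == pytest.approx(1.0)

    def test_zero_total(self):
        assert exact_test_pvalue(0, 0, 3, 3, 0.1) == 1.0

    @pytest.mark.parametrize("seed", range(5))
    def test_phi_zero_equals_binomial_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        for _ in range(50):
            s = int(rng.integers(1, 51))
            a = int(rng.integers(0, s + 1))
            n_a = int(rng.integers(1, 7))
            n_b = int(rng.integers(1, 7))
            assert exact_test_pvalue(a, s - a, n_a, n_b, 0.0) == pytest.approx(
                binomial_oracle(a, s - a, n_a, n_b), abs=1e-12
            )

    def test_null_type_one_error_calibrated(self):
        cfg = SimConfig(rng_seed=2024, dispersion=0.05, de_fraction=0.0)
        table, _ = simulate_counts(cfg, {"A": 5, "B": 5}, 200, rng=np.random.default_rng(2024))
        res = nb_exact_test(table, "A", "B", phi=0.05)
        frac = float((res.p < 0.05).mean())
        assert 0.01 <= frac <= 0.10

    def test_significance_combines_lfc_and_fdr(self):
        cfg = SimConfig(rng_seed=9, dispersion=0.02)
        table, truth = simulate_counts(cfg, {"A": 4, "B": 4}, 300, rng=np.random.default_rng(9))
        res = nb_exact_test(table, "A", "B", phi=0.02, params=DEParams())
        assert (
            res.significant == ((res.log2fc.abs() >= 1.0) & (res.fdr < 0.05))
        ).all()
        assert (res.fdr >= res.p - 1e-12).all()


class TestBH:
    def test_hand_computed_step_up(self):
        assert np.allclose(bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04])

    def test_single_p_unchanged(self):
        assert bh_adjust([0.37])[0] == pytest.approx(0.37)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=50))
    @settings(max_examples=200, deadline=None)
    def test_matches_definition_oracle(self, pvals):
        p = np.array(pvals)
        m = len(p)
        order = np.argsort(p, kind="stable")
        q_sorted = np.minimum.accumulate((p[order] * m / np.arange(1, m + 1))[::-1])[::-1]
        oracle = np.empty(m)
        oracle[order] = np.minimum(q_sorted, 1.0)
        assert np.allclose(bh_adjust(p), oracle, atol=1e-12)
        assert (bh_adjust(p) >= p - 1e-12).all()


class TestVenn:
    def test_two_set_regions(self):
        r = venn_sets({"A": {1, 2}, "B": {2, 3}})
        assert r[("A",)] == 1 and r[("A", "B")] == 1 and r[("B",)] == 1

    def test_disjoint_sets(self):
        r = venn_sets({"A": {1}, "B": {2}})
        assert r[("A", "B")] == 0

    def test_regions_partition_the_union(self, rng):
        sets = {k: set(rng.integers(0, 40, 20).tolist()) for k in "ABC"}
        r = venn_sets(sets)
        assert sum(r.values()) == len(sets["A"] | sets["B"] | sets["C"])
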