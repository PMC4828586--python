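"""Exact association statistics: hypergeometric kernel, Fisher,
stratified convolution test, onset stratification, Mann-Whitney,
population-frequency comparisons."""

from __future__ import annotations

import random
import shutil
import subprocess

import pytest
from hypothesis import given, strategies as st
from scipy import stats as sps

from cnvburden import (
    CarrierTable,
    OnsetPolicy,
    PopulationPrior,
    exact_cmh,
    fisher_exact_2x2,
    fold_vs_population,
    hypergeom_pmf_2x2,
    loo_sensitivity,
    mann_whitney_onset,
    onset_stratify,
    population_binomial_test,
    population_expected_count,
    prevalence_estimate,
)
from cnvburden.model import SampleRecord
from oracles import (
    binom_upper_tail,
    convolve_enumerate,
    hypergeom_pmf_exact,
    mann_whitney_enumerate,
)


def T(a, b, c, d, stratum="s"):
    return CarrierTable(stratum, a, b, c, d)


small_tables = st.tuples(
    st.integers(0, 3), st.integers(1, 40), st.integers(0, 3), st.integers(1, 40)
).map(lambda t: T(*t))


class TestHypergeomKernel:
    def test_two_carriers_all_in_cases(self):
        # m=2 carriers among 1592 cases + 4939 controls:
        # P(S=2) = (1592/6531)(1591/6530)
        pmf = hypergeom_pmf_2x2(T(2, 1590, 0, 4939))
        assert pmf[2] == pytest.approx((1592 / 6531) * (1591 / 6530), rel=1e-12)
        assert pmf[2] == pytest.approx(0.0594, abs=5e-5)

    def test_degenerate_zero_margin(self):
        assert hypergeom_pmf_2x2(T(0, 10, 0, 12)) == {0: 1.0}

    @given(small_tables)
    def test_matches_exact_rational_oracle(self, t):
        pmf = hypergeom_pmf_2x2(t)
        oracle = hypergeom_pmf_exact(t.a, t.b, t.c, t.d)
        assert set(pmf) == set(oracle)
        for s, p in pmf.items():
            assert p == pytest.approx(float(oracle[s]), abs=1e-12)
        assert sum(pmf.values()) == pytest.approx(1.0, abs=1e-12)


class TestFisher:
    @given(small_tables)
    def test_matches_scipy_both_alternatives(self, t):
        table = [[t.a, t.b], [t.c, t.d]]
        assert fisher_exact_2x2(t, "two_sided_minlike") == pytest.approx(
            sps.fisher_exact(table, alternative="two-sided")[1], rel=1e-9, abs=1e-12
        )
        assert fisher_exact_2x2(t, "one_greater") == pytest.approx(
            sps.fisher_exact(table, alternative="greater")[1], rel=1e-9, abs=1e-12
        )

    def test_minlike_adds_opposite_extreme(self):
        # 2/804 cases vs 0/684 controls: upper tail ~0.29 but the minlike
        # rule also counts the likel-or-less opposite extreme, giving ~0.50
        t = T(2, 802, 0, 684)
        assert fisher_exact_2x2(t, "one_greater") == pytest.approx(0.29, abs=0.005)
        assert fisher_exact_2x2(t, "two_sided_minlike") == pytest.approx(0.50, abs=0.005)

    def test_degenerate_margin_gives_one(self):
        assert fisher_exact_2x2(T(0, 10, 0, 10)) == 1.0


class TestStratifiedExact:
    @given(small_tables)
    def test_single_stratum_reduces_to_fisher(self, t):
        res = exact_cmh([t])
        assert res.p_two_sided == pytest.approx(fisher_exact_2x2(t), abs=1e-12)
        assert res.p_one_sided == pytest.approx(fisher_exact_2x2(t, "one_greater"), abs=1e-12)

    @given(st.lists(small_tables, min_size=1, max_size=5))
    def test_convolution_matches_brute_force_enumeration(self, tables):
        tables = [T(t.a, t.b, t.c, t.d, stratum=f"s{i}") for i, t in enumerate(tables)]
        res = exact_cmh(tables)
        oracle = convolve_enumerate([(t.a, t.b, t.c, t.d) for t in tables])
        assert set(res.null_pmf) == set(oracle)
        for s, p in res.null_pmf.items():
            assert p == pytest.approx(oracle[s], abs=1e-12)
        assert sum(res.null_pmf.values()) == pytest.approx(1.0, abs=1e-12)
        assert res.p_two_sided >= res.null_pmf[res.s_observed] - 1e-15
        assert 0 < res.p_two_sided <= 1 and 0 < res.p_one_sided <= 1

    def test_stratum_order_invariance_and_degenerate_identity(self):
        tables = [T(2, 30, 1, 40, "a"), T(1, 25, 0, 35, "b"), T(0, 10, 0, 12, "zero")]
        r1 = exact_cmh(tables)
        r2 = exact_cmh(tables[::-1])
        assert r1.p_two_sided == pytest.approx(r2.p_two_sided, abs=1e-14)
        r3 = exact_cmh(tables[:2])  # dropping the zero-carrier stratum changes nothing
        assert r1.p_two_sided == pytest.approx(r3.p_two_sided, abs=1e-14)

    def test_empty_strata_rejected(self):
        with pytest.raises(ValueError):
            exact_cmh([])

    @pytest.mark.skipif(shutil.which("Rscript") is None, reason="Rscript not on PATH")
    def test_matches_r_exact_mantel_haenszel(self, tmp_path):
        tables = [T(2, 1590, 0, 4939, "w"), T(1, 739, 0, 1996, "d"), T(2, 802, 0, 684, "u")]
        res = exact_cmh(tables)
        cells = sum(([t.a, t.b, t.c, t.d] for t in tables), [])
        script = tmp_path / "mh.R"
        script.write_text(
            "x <- array(0, dim=c(2,2,%d))\n" % len(tables)
            + "v <- c(%s)\n" % ",".join(map(str, cells))
            + "for (k in 1:%d) x[,,k] <- matrix(v[(4*k-3):(4*k)], nrow=2, byrow=TRUE)\n"
            % len(tables)
            + 'cat(sprintf("%.12g %.12g\\n",'
            ' mantelhaen.test(x, exact=TRUE)$p.value,'
            ' mantelhaen.test(x, exact=TRUE, alternative="greater")$p.value))\n'
        )
        out = subprocess.run(
            ["Rscript", "--vanilla", str(script)], capture_output=True, text=True, check=True
        )
        p_two_r, p_one_r = map(float, out.stdout.split())
        assert res.p_two_sided == pytest.approx(p_two_r, rel=1e-9)
        assert res.p_one_sided == pytest.approx(p_one_r, rel=1e-9)


class TestSensitivity:
    def test_grouped_exclusion_and_max(self):
        tables = [T(2, 30, 0, 40, "a1"), T(1, 25, 0, 35, "a2"), T(2, 28, 0, 30, "b")]
        res = loo_sensitivity(tables, {"a1": "A", "a2": "A", "b": "B"})
        assert set(res.results) == {"A", "B"}
        assert res.results["A"].p_two_sided == pytest.approx(
            exact_cmh([tables[2]]).p_two_sided, abs=1e-14
        )
        assert res.max_p_two_sided == max(r.p_two_sided for r in res.results.values())

    def test_excluding_zero_carrier_study_leaves_p_unchanged(self):
        tables = [T(2, 30, 1, 40, "a"), T(1, 25, 0, 35, "b"), T(0, 10, 0, 12, "z")]
        res = loo_sensitivity(tables)
        assert res.results["z"].p_two_sided == pytest.approx(
            exact_cmh(tables).p_two_sided, abs=1e-14
        )

    def test_identical_studies_are_symmetric(self):
        tables = [T(1, 20, 0, 30, "a"), T(1, 20, 0, 30, "b")]
        res = loo_sensitivity(tables)
        assert res.results["a"].p_two_sided == pytest.approx(
            res.results["b"].p_two_sided, abs=1e-14
        )

    def test_single_study_rejected(self):
        with pytest.raises(ValueError):
            loo_sensitivity([T(1, 10, 0, 10, "only")])


def mk_case(i, study, onset, carrier=False):
    return SampleRecord(f"{study}_c{i}", study, "case", onset, 0.1, 0.05, 2)


def mk_ctrl(i, study):
    return SampleRecord(f"{study}_k{i}", study, "control", None, 0.1, 0.05, 2)


class TestOnsetStratify:
    def test_boundary_and_missing_onset_handling(self):
        samples = [
            mk_case(0, "A", 44.9),   # early
            mk_case(1, "A", 45.0),   # exactly at cutoff: late
            mk_case(2, "A", 60.0),   # late
            mk_case(3, "A", None),   # dropped from onset analyses
            mk_ctrl(0, "A"),
            mk_ctrl(1, "A"),
        ]
        tabs = onset_stratify(samples, {"A_c0"}, OnsetPolicy(45.0))
        (evc,) = tabs.early_vs_control
        (lvc,) = tabs.late_vs_control
        (evl,) = tabs.early_vs_late
        assert (evc.n1, evc.a) == (1, 1)
        assert (lvc.n1, lvc.a) == (2, 0)
        assert (evl.n1 + evl.n2) == 3  # the known-onset cases only
        assert (evl.a, evl.c) == (1, 0)

    def test_zero_cutoff_puts_everyone_late(self):
        samples = [mk_case(0, "A", 30.0), mk_case(1, "A", 70.0), mk_ctrl(0, "A")]
        tabs = onset_stratify(samples, set(), OnsetPolicy(1e-9))
        assert tabs.early_vs_control == [] and tabs.early_vs_late == []
        (lvc,) = tabs.late_vs_control
        assert lvc.n1 == 2

    def test_totals_preserved_across_strata(self):
        r = random.Random(5)
        samples = []
        for study in ("A", "B"):
            samples += [
                mk_case(i, study, r.choice([None, 30.0, 44.0, 50.0, 66.0])) for i in range(20)
            ]
            samples += [mk_ctrl(i, study) for i in range(15)]
        tabs = onset_stratify(samples, set())
        n_known = sum(
            1 for s in samples if s.group == "case" and s.onset_age is not None
        )
        assert sum(t.n1 + t.n2 for t in tabs.early_vs_late) == n_known


class TestMannWhitney:
    def test_identical_samples_give_one(self):
        assert mann_whitney_onset([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]) == 1.0

    def test_tiny_exact_case(self):
        assert mann_whitney_onset([1, 2], [3, 4], mode="exact") == pytest.approx(1 / 3)

    @given(st.integers(0, 5_000))
    def test_exact_mode_matches_permutation_enumeration(self, seed):
        r = random.Random(seed)
        n, m = r.randint(2, 5), r.randint(2, 5)
        vals = r.sample(range(1000), n + m)  # tie-free
        x, y = [float(v) for v in vals[:n]], [float(v) for v in vals[n:]]
        assert mann_whitney_onset(x, y, mode="exact") == pytest.approx(
            mann_whitney_enumerate(x, y), abs=1e-12
        )

    def test_auto_switches_to_normal_approximation_with_ties(self):
        x = [30.0, 40.0, 40.0, 50.0]
        y = [55.0, 60.0, 60.0, 62.0, 70.0] * 30
        p = mann_whitney_onset(x, y, mode="auto")
        assert 0 < p <= 1

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney_onset([], [1.0])


class TestPopulationComparisons:
    def test_expected_count(self):
        prior = PopulationPrior()
        assert population_expected_count(13_863, prior) == pytest.approx(3.327, abs=1e-3)
        assert population_expected_count(0, prior) == 0.0
        assert population_expected_count(1_014, prior) == pytest.approx(0.243, abs=5e-4)

    def test_binomial_tail_matches_direct_summation(self):
        p = population_binomial_test(2, 1000, PopulationPrior(carrier_frequency=0.001))
        assert p == pytest.approx(binom_upper_tail(2, 1000, 0.001), rel=1e-10)
        assert p == pytest.approx(0.264, abs=5e-3)
        assert population_binomial_test(0, 50) == 1.0

    def test_fold_estimators(self):
        prior = PopulationPrior()
        assert fold_vs_population(5, 1014, prior) == pytest.approx((5 / 1014) / 0.00024)
        f = PopulationPrior(carrier_frequency=0.001)
        assert fold_vs_population(1, 1000, f) == pytest.approx(1.0)
        pr = fold_vs_population(3, 1000, f, "proportion_ratio")
        orr = fold_vs_population(3, 1000, f, "odds_ratio")
        assert abs(orr - pr) / pr < 0.01  # rare-event agreement
        # scaling x and n together leaves the proportion ratio unchanged
        assert fold_vs_population(6, 2000, f) == pytest.approx(pr)
        with pytest.raises(ValueError):
            fold_vs_population(10, 10, f, "odds_ratio")

    def test_prevalence_product(self):
        assert prevalence_estimate(140, 0.04, 0.005) == pytest.approx(0.028)
        assert prevalence_estimate(100, 0.10, 0.01) == pytest.approx(0.10)
        assert prevalence_estimate(140, 0.0, 0.005) == 0.0
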