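import numpy as np
import pytest
from scipy import stats

from adcvar.bsens import (
    BValueCombination,
    HighestBGroup,
    delta_pairwise_tests,
    enumerate_combinations,
    group_by_highest_b,
    longitudinal_four_combinations,
    slope_per_100,
    welch_t_from_summaries,
)
from adcvar.exceptions import InsufficientDataError
from adcvar.fitting import fit_adc_loglinear
from adcvar.synthetic import TissueState, ivim_signal


def combos_for_tissue(scheme, tissue):
    out = []
    for c in enumerate_combinations(scheme):
        b = np.asarray(c.bvalues)
        out.append((c, fit_adc_loglinear(b, ivim_signal(b, tissue, 1.0))))
    return out


def groups(hb_mean_pairs):
    return [
        HighestBGroup(highest_b=hb, mean_adc=m, se_adc=se, n_combinations=n)
        for hb, m, se, n in hb_mean_pairs
    ]


class TestEnumerateCombinations:
    def test_two_point_scheme(self):
        combos = enumerate_combinations((0.0, 1000.0))
        assert [c.bvalues for c in combos] == [(0.0, 1000.0)]

    def test_four_value_scheme_has_seven(self):
        combos = enumerate_combinations((0.0, 100.0, 500.0, 1000.0))
        assert len(combos) == 7
        assert all(c.bvalues[0] == 0.0 for c in combos)
        assert len({c.bvalues for c in combos}) == 7

    @pytest.mark.parametrize("m", range(1, 9))
    def test_count_law(self, m):
        scheme = (0.0,) + tuple(100.0 * (i + 1) for i in range(m))
        assert len(enumerate_combinations(scheme)) == 2**m - 1

    def test_deterministic_order(self):
        scheme = (0.0, 100.0, 500.0, 1000.0)
        assert [c.bvalues for c in enumerate_combinations(scheme)] == [
            c.bvalues for c in enumerate_combinations(scheme)
        ]

    def test_no_nonzero_rejected(self):
        with pytest.raises(Exception):
            enumerate_combinations((0.0,))


class TestGrouping:
    def test_single_member_group(self):
        g = group_by_highest_b([(BValueCombination((0.0, 500.0)), 1.3)])
        assert g[0].mean_adc == pytest.approx(1.3)
        assert g[0].se_adc is None

    def test_two_member_group_closed_form(self):
        g = group_by_highest_b(
            [
                (BValueCombination((0.0, 500.0)), 1.0),
                (BValueCombination((0.0, 100.0, 500.0)), 1.2),
            ]
        )
        assert len(g) == 1
        assert g[0].mean_adc == pytest.approx(1.1)
        assert g[0].se_adc == pytest.approx(0.1, rel=1e-9)

    def test_groups_partition_combinations(self):
        scheme = (0.0, 100.0, 200.0, 500.0, 800.0, 1000.0)
        t = TissueState(f=0.07, d_tissue=1.0, d_pseudo=20.0, target_adc=1.0)
        combos = combos_for_tissue(scheme, t)
        g = group_by_highest_b(combos)
        assert sum(x.n_combinations for x in g) == len(combos)
        assert [x.highest_b for x in g] == sorted(x.highest_b for x in g)

    def test_monotone_decreasing_for_perfused_tissue(self):
        scheme = (0.0, 50.0, 100.0, 200.0, 500.0, 800.0, 1000.0)
        t = TissueState(f=0.0675, d_tissue=1.0, d_pseudo=20.0, target_adc=1.0)
        g = group_by_highest_b(combos_for_tissue(scheme, t))
        means = [x.mean_adc for x in g]
        assert all(b < a for a, b in zip(means, means[1:]))


class TestSlopePer100:
    def test_monoexponential_null(self):
        scheme = (0.0, 100.0, 200.0, 500.0, 800.0, 1000.0)
        t = TissueState(f=0.0, d_tissue=1.2, d_pseudo=20.0, target_adc=1.2)
        g = group_by_highest_b(combos_for_tissue(scheme, t))
        assert slope_per_100(g) == pytest.approx(0.0, abs=1e-8)

    def test_two_group_closed_form(self):
        g = groups([(200.0, 1.614, None, 1), (1000.0, 1.2054, None, 1)])
        # ln-ratio over 8 steps of 100
        expected = 100.0 * (1 - np.exp(np.log(1.2054 / 1.614) / 8.0))
        assert slope_per_100(g) == pytest.approx(expected, rel=1e-12)
        assert expected == pytest.approx(3.6, abs=0.05)

    def test_range_filter(self):
        g = groups([(50.0, 5.0, None, 1), (200.0, 1.6, None, 1), (1000.0, 1.2, None, 1)])
        full = slope_per_100(g, fit_range=(200.0, 1000.0))
        assert full == pytest.approx(
            slope_per_100(g[1:], fit_range=(0.0, 2000.0)), rel=1e-12
        )
        with pytest.raises(InsufficientDataError):
            slope_per_100(g, fit_range=(900.0, 1000.0))


class TestLongitudinal:
    def test_identical_groups_zero_deltas(self):
        g = groups([(800.0, 1.2, 0.01, 4), (1000.0, 1.1, 0.01, 8)])
        deltas = longitudinal_four_combinations(g, g)
        assert len(deltas) == 4
        for d in deltas:
            if d.diag_choice == d.resp_choice:
                assert d.percent_change == pytest.approx(0.0)

    def test_hand_computed_example(self):
        diag = groups([(800.0, 1.1, 0.02, 4), (1000.0, 1.0, 0.02, 8)])
        resp = groups([(800.0, 1.7, 0.02, 4), (1000.0, 1.5, 0.02, 8)])
        deltas = longitudinal_four_combinations(diag, resp)
        got = {
            (d.diag_choice, d.resp_choice): d.percent_change for d in deltas
        }
        assert got[("highest", "highest")] == pytest.approx(50.0)
        assert got[("highest", "second_highest")] == pytest.approx(70.0)
        assert got[("second_highest", "highest")] == pytest.approx(36.36, abs=0.01)
        assert got[("second_highest", "second_highest")] == pytest.approx(54.55, abs=0.01)

    def test_swap_identity(self):
        diag = groups([(800.0, 1.3, 0.02, 4), (1000.0, 1.15, 0.02, 8)])
        resp = groups([(800.0, 1.8, 0.02, 4), (1000.0, 1.6, 0.02, 8)])
        fwd = longitudinal_four_combinations(diag, resp)
        # swapping timepoints maps delta -> -100*delta/(100+delta) with
        # the two b-max choices transposed
        rev = {
            (d.diag_choice, d.resp_choice): d.percent_change
            for d in longitudinal_four_combinations(resp, diag)
        }
        for d in fwd:
            expected = -100.0 * d.percent_change / (100.0 + d.percent_change)
            assert rev[(d.resp_choice, d.diag_choice)] == pytest.approx(expected)

    def test_insufficient_groups(self):
        one = groups([(1000.0, 1.0, 0.02, 4)])
        two = groups([(800.0, 1.2, 0.02, 4), (1000.0, 1.1, 0.02, 4)])
        with pytest.raises(InsufficientDataError):
            longitudinal_four_combinations(one, two)


class TestWelch:
    def test_equal_means(self):
        t, df, p = welch_t_from_summaries(1.0, 0.1, 5, 1.0, 0.1, 5)
        assert t == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_closed_form_value(self):
        t, df, p = welch_t_from_summaries(1.0, 0.1, 5, 1.5, 0.1, 5)
        assert t == pytest.approx(-3.5355, abs=1e-3)
        assert df == pytest.approx(8.0)

    def test_sign_flip_symmetry(self):
        t1, _, p1 = welch_t_from_summaries(1.0, 0.1, 5, 1.5, 0.12, 7)
        t2, _, p2 = welch_t_from_summaries(1.5, 0.12, 7, 1.0, 0.1, 5)
        assert t1 == pytest.approx(-t2)
        assert p1 == pytest.approx(p2)

    def test_matches_raw_data_welch(self, rng):
        for _ in range(20):
            x = rng.normal(1.0, 0.3, size=int(rng.integers(5, 30)))
            y = rng.normal(1.2, 0.5, size=int(rng.integers(5, 30)))
            t, df, p = welch_t_from_summaries(
                x.mean(), x.std(ddof=1) / np.sqrt(x.size), x.size,
                y.mean(), y.std(ddof=1) / np.sqrt(y.size), y.size,
            )
            ref = stats.ttest_ind(x, y, equal_var=False)
            assert t == pytest.approx(ref.statistic, rel=1e-10)
            assert p == pytest.approx(ref.pvalue, rel=1e-10)

    def test_pairwise_tests_count(self):
        diag = groups([(800.0, 1.1, 0.02, 4), (1000.0, 1.0, 0.02, 8)])
        resp = groups([(800.0, 1.7, 0.02, 4), (1000.0, 1.5, 0.02, 8)])
        deltas = longitudinal_four_combinations(diag, resp)
        tests = delta_pairwise_tests(deltas)
        assert len(tests) == 6
        assert all(0.0 <= t["p_value"] <= 1.0 for t in tests)
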