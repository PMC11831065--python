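"""Rank-test and FDR oracles, summary-statistic t, Cronbach's alpha."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from neurocoh.exceptions import ConfigurationError, DataError, NumericalError
from neurocoh.group_stats import (
    SummaryStats,
    bh_fdr,
    cronbach_alpha,
    edgewise_comparison,
    mann_whitney_edge,
    t_from_summary,
)
from neurocoh.spectral import CoherenceProfile


def brute_force_mw(x, y):
    """Exact U and two-sided p by exhaustive enumeration (tie-free data)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n1, n2 = len(x), len(y)
    u_obs = sum(1.0 for a in x for b in y if a > b) + 0.5 * sum(
        1 for a in x for b in y if a == b
    )
    pooled = np.sort(np.concatenate([x, y]))
    ranks = np.arange(1, n1 + n2 + 1, dtype=float)
    combos = np.array(list(itertools.combinations(range(n1 + n2), n1)))
    u_all = ranks[combos].sum(axis=1) - n1 * (n1 + 1) / 2.0
    p_le = np.mean(u_all <= u_obs)
    p_ge = np.mean(u_all >= u_obs)
    return u_obs, min(1.0, 2.0 * min(p_le, p_ge)), pooled


class TestMannWhitney:
    def test_textbook_example(self):
        # case {1,2} vs control {3,4}: U = 0, exact two-sided p = 2/6
        U, p = mann_whitney_edge([1.0, 2.0], [3.0, 4.0])
        assert U == 0.0
        assert p == pytest.approx(1.0 / 3.0)

    def test_identical_multisets_symmetric_u(self):
        vals = [0.1, 0.4, 0.7, 0.9]
        U, _ = mann_whitney_edge(vals, list(vals))
        assert U == len(vals) ** 2 / 2.0

    def test_complementarity(self, rng):
        x = rng.normal(size=9)
        y = np.concatenate([rng.normal(size=6), x[:2]])  # include ties
        u_xy, _ = mann_whitney_edge(x, y)
        u_yx, _ = mann_whitney_edge(y, x)
        assert u_xy + u_yx == pytest.approx(len(x) * len(y))

    @pytest.mark.parametrize("n1,n2", [(2, 3), (3, 4), (4, 5), (5, 6)])
    def test_exact_path_matches_enumeration(self, n1, n2, rng):
        x = rng.normal(size=n1)
        y = rng.normal(size=n2)
        u_ref, p_ref, _ = brute_force_mw(x, y)
        U, p = mann_whitney_edge(x, y)
        assert U == pytest.approx(u_ref)
        assert p == pytest.approx(p_ref, abs=1e-12)

    def test_exact_and_asymptotic_agree_at_n8(self, rng):
        for _ in range(20):
            x = rng.normal(size=8)
            y = rng.normal(loc=rng.normal() * 0.5, size=8)
            _, p_exact = mann_whitney_edge(x, y)  # 64 <= 100 -> exact
            from scipy.stats import mannwhitneyu

            p_asym = mannwhitneyu(x, y, alternative="two-sided",
                                  method="asymptotic", use_continuity=True).pvalue
            assert p_exact == pytest.approx(p_asym, abs=0.02)

    def test_empty_group_rejected(self):
        with pytest.raises(DataError):
            mann_whitney_edge([1.0], [2.0, 3.0])


class TestBhFdr:
    def test_hand_worked_example(self):
        # step-up: q_(i) = min_{j>=i} m p_(j) / j
        q = bh_fdr([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_mixed_example(self):
        q = bh_fdr([0.005, 0.04, 0.03, 0.8])
        # sorted: .005 .03 .04 .8 -> m*p/j = .02 .06 .053.. .8 -> step-up: .02 .0533 .0533 .8
        assert np.allclose(q, [0.02, 4 * 0.04 / 3, 4 * 0.04 / 3, 0.8])

    def test_all_ones(self):
        assert np.allclose(bh_fdr([1.0, 1.0, 1.0]), 1.0)

    def test_single_p_unchanged(self):
        assert bh_fdr([0.037])[0] == pytest.approx(0.037)

    def test_domain_errors(self):
        with pytest.raises(ConfigurationError):
            bh_fdr([0.0, 0.5])
        with pytest.raises(ConfigurationError):
            bh_fdr([0.5, 1.2])

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.lists(st.floats(min_value=1e-12, max_value=1.0), min_size=1, max_size=40))
    def test_qs_dominate_ps_and_are_sorted_monotone(self, ps):
        q = bh_fdr(ps)
        p = np.asarray(ps)
        assert np.all(q >= p - 1e-15)
        assert np.all((q > 0) & (q <= 1))
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-15)


def profile_from_matrix(subject, group, mats, channels=("a", "b", "c")):
    return CoherenceProfile(
        subject_id=subject, group=group, condition="EO",
        channels=tuple(channels),
        band_matrices={k: np.asarray(v, float) for k, v in mats.items()},
    )


def toy_profiles(n_per_group=5, delta=0.3, seed=0):
    """3-channel profiles with a planted (a,b) group difference in alpha3."""
    rng = np.random.default_rng(seed)
    profs = []
    for group, off in (("control", delta), ("case", 0.0)):
        for s in range(n_per_group):
            base = np.clip(rng.uniform(0.1, 0.3, size=3), 0, 1)
            m = np.ones((3, 3))
            m[0, 1] = m[1, 0] = np.clip(base[0] + off, 0, 1)
            m[0, 2] = m[2, 0] = base[1]
            m[1, 2] = m[2, 1] = base[2]
            profs.append(profile_from_matrix(f"{group}-{s}", group, {"alpha3": m}))
    return profs


class TestEdgewise:
    def test_result_count_is_pair_count(self):
        res = edgewise_comparison(toy_profiles(), "alpha3", "EO")
        assert len(res) == 3

    def test_planted_pair_has_smallest_q(self):
        res = edgewise_comparison(toy_profiles(n_per_group=8, delta=0.4), "alpha3", "EO")
        by_pair = {r.pair: r for r in res}
        target = by_pair[("a", "b")]
        assert target.q == min(r.q for r in res)
        assert target.median_case < target.median_control

    def test_medians_attached_correctly(self):
        profs = toy_profiles(n_per_group=3, delta=0.0, seed=4)
        res = edgewise_comparison(profs, "alpha3", "EO")
        for r in res:
            i = profs[0].channels.index(r.pair[0])
            j = profs[0].channels.index(r.pair[1])
            vals = [p.band_matrices["alpha3"][i, j] for p in profs if p.group == "case"]
            assert r.median_case == pytest.approx(np.median(vals))

    def test_channel_mismatch_raises(self):
        profs = toy_profiles()
        profs[0] = profile_from_matrix("x", "control", {"alpha3": np.ones((3, 3))},
                                       channels=("a", "b", "z"))
        with pytest.raises(DataError):
            edgewise_comparison(profs, "alpha3", "EO")

    def test_too_few_subjects_raise(self):
        profs = toy_profiles(n_per_group=5)
        only_one_case = [p for p in profs if p.group == "control"] + \
            [p for p in profs if p.group == "case"][:1]
        with pytest.raises(DataError):
            edgewise_comparison(only_one_case, "alpha3", "EO")


class TestTFromSummary:
    # printed-table reproduction: M (SD) per group, n = 49 + 49, df = 96
    @pytest.mark.parametrize(
        "scale,mc,sc,mn,sn,t_expected",
        [
            ("exhaustion", 4.13, 1.00, 1.93, 0.75, -12.33),
            ("depression", 14.04, 7.61, 4.76, 4.72, -7.26),
            ("age", 34.94, 8.45, 37.37, 7.63, 1.49),
        ],
    )
    def test_reproduces_printed_magnitudes(self, scale, mc, sc, mn, sn, t_expected):
        s = SummaryStats(scale, mc, sc, 49, mn, sn, 49)
        t, df = t_from_summary(s)
        assert df == 96
        assert abs(t) == pytest.approx(abs(t_expected), abs=0.05)

    def test_equal_means_give_zero(self):
        t, _ = t_from_summary(SummaryStats("x", 2.0, 1.0, 10, 2.0, 1.5, 12))
        assert t == 0.0

    def test_antisymmetric_under_group_swap(self):
        a = SummaryStats("x", 4.0, 1.0, 20, 2.5, 0.8, 25)
        b = SummaryStats("x", 2.5, 0.8, 25, 4.0, 1.0, 20)
        assert t_from_summary(a)[0] == pytest.approx(-t_from_summary(b)[0])

    def test_degenerate_sds_raise(self):
        with pytest.raises(NumericalError):
            t_from_summary(SummaryStats("x", 1.0, 0.0, 5, 2.0, 0.0, 5))


class TestCronbachAlpha:
    def test_identical_items_alpha_one(self, rng):
        col = rng.normal(size=50)
        x = np.tile(col[:, None], (1, 4))
        assert cronbach_alpha(x) == pytest.approx(1.0)

    def test_independent_items_alpha_near_zero(self, rng):
        x = rng.normal(size=(4000, 2))
        assert cronbach_alpha(x) == pytest.approx(0.0, abs=0.1)

    def test_spearman_brown_identity_for_two_items(self, rng):
        x = rng.multivariate_normal([0, 0], [[1, 0.6], [0.6, 1]], size=200)
        x = (x - x.mean(axis=0)) / x.std(axis=0, ddof=1)  # identity needs equal variances
        r = np.corrcoef(x[:, 0], x[:, 1])[0, 1]
        assert cronbach_alpha(x) == pytest.approx(2 * r / (1 + r), abs=1e-10)

    def test_matches_pingouin(self, rng):
        import pandas as pd
        import pingouin as pg

        x = rng.normal(size=(40, 5))
        x += rng.normal(size=(40, 1))  # shared factor
        ours = cronbach_alpha(x)
        theirs = pg.cronbach_alpha(pd.DataFrame(x))[0]
        assert ours == pytest.approx(theirs, abs=1e-10)

    def test_degenerate_total_raises(self):
        with pytest.raises(NumericalError):
            cronbach_alpha(np.ones((5, 3)))
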