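import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from aneukit.stats import (
    agreement_report,
    aligned_responses,
    art_anova,
    benjamini_hochberg,
    bland_altman,
    paired_t,
    rpd,
    slope_and_pcc,
    wilcoxon_rank_sum,
)


class TestRpd:
    @pytest.mark.parametrize("a, b, expected", [
        (5.0, 5.0, 0.0),
        (3.0, 1.0, 100.0),
        (0.02, 0.03, 40.0),
        (0.0, 0.0, 0.0),
    ])
    def test_values(self, a, b, expected):
        assert rpd(a, b) == pytest.approx(expected)

    def test_symmetry_and_scale_invariance(self, rng):
        a, b = rng.normal(size=50), rng.normal(size=50)
        assert np.allclose(rpd(a, b), rpd(b, a))
        assert np.allclose(rpd(3.7 * a, 3.7 * b), rpd(a, b))

    @settings(derandomize=True, max_examples=100, deadline=None)
    @given(a=st.floats(-1e6, 1e6), b=st.floats(-1e6, 1e6),
           c=st.floats(1e-3, 1e3))
    def test_properties_hold_for_arbitrary_pairs(self, a, b, c):
        r = rpd(a, b)
        # opposite-sign pairs saturate at 200 (up to roundoff)
        assert 0.0 <= r <= 200.0 * (1 + 1e-12)
        assert r == pytest.approx(rpd(b, a))
        assert rpd(c * a, c * b) == pytest.approx(r, rel=1e-9, abs=1e-9)


class TestBlandAltman:
    def test_identical_vectors(self, rng):
        x = rng.normal(size=10)
        assert bland_altman(x, x) == (0.0, 0.0, 0.0)

    def test_constant_offset(self):
        x = np.arange(5.0)
        assert bland_altman(x, x + 1) == (1.0, 1.0, 1.0)

    def test_unit_sd_limits(self):
        x = np.zeros(3)
        y = np.array([-1.0, 0.0, 1.0])
        bias, up, low = bland_altman(x, y)
        assert bias == 0.0
        assert up == pytest.approx(1.96)
        assert low == pytest.approx(-1.96)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            bland_altman(np.zeros(4), np.zeros(5))


class TestSlopePcc:
    def test_exact_lines(self):
        x = np.linspace(0, 5, 10)
        assert slope_and_pcc(x, 2 * x + 3) == pytest.approx((2.0, 1.0))
        assert slope_and_pcc(x, -x) == pytest.approx((-1.0, -1.0))

    def test_matches_normal_equations(self, rng):
        x = rng.normal(size=5)
        y = 1.3 * x + rng.normal(size=5)
        xm, ym = x - x.mean(), y - y.mean()
        want_slope = float((xm @ ym) / (xm @ xm))
        want_r = float(xm @ ym / np.sqrt((xm @ xm) * (ym @ ym)))
        assert slope_and_pcc(x, y) == pytest.approx((want_slope, want_r))

    def test_through_origin_option(self):
        x = np.array([1.0, 2.0, 3.0])
        y = 2 * x + 1
        slope, _ = slope_and_pcc(x, y, through_origin=True)
        assert slope == pytest.approx(float(x @ y / (x @ x)))

    def test_constant_x_rejected(self):
        with pytest.raises(ValueError):
            slope_and_pcc(np.ones(5), np.arange(5.0))


class TestWilcoxon:
    def test_identical_groups(self):
        g = np.arange(6.0)
        _, p = wilcoxon_rank_sum(g, g + 0.0)
        assert p > 0.9

    def test_fully_separated_3v3_exact(self):
        u, p = wilcoxon_rank_sum([1, 2, 3], [10, 11, 12])
        assert u == 0.0
        assert p == pytest.approx(0.1)   # 2/20 arrangements as extreme

    def test_matches_permutation_enumeration(self, rng):
        g1 = rng.normal(size=4)
        g2 = rng.normal(size=4) + 0.5
        u, p = wilcoxon_rank_sum(g1, g2)
        # enumerate every 4-subset assignment of the pooled sample
        pooled = np.concatenate([g1, g2])
        ranks = pd.Series(pooled).rank().to_numpy()
        def u_stat(idx):
            r1 = ranks[list(idx)].sum()
            return r1 - 4 * 5 / 2
        observed = u_stat(range(4))
        n1u = min(observed, 16 - observed)
        count = sum(min(u_stat(c), 16 - u_stat(c)) <= n1u
                    for c in itertools.combinations(range(8), 4))
        assert p == pytest.approx(count / 70)

    def test_monotone_transform_invariance(self, rng):
        g1, g2 = rng.normal(size=8), rng.normal(size=9) + 1
        _, p = wilcoxon_rank_sum(g1, g2)
        _, p_exp = wilcoxon_rank_sum(np.exp(g1), np.exp(g2))
        assert p == pytest.approx(p_exp)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_rank_sum([1.0], [1.0, 2.0])


class TestPairedT:
    def test_equal_vectors(self):
        x = np.arange(5.0)
        assert paired_t(x, x) == (0.0, 1.0)

    def test_constant_nonzero_difference_rejected(self):
        x = np.zeros(4)
        with pytest.raises(ValueError):
            paired_t(x, x + 1.0)

    def test_matches_textbook_formula(self, rng):
        x = rng.normal(size=10)
        y = x + rng.normal(0.3, 1.0, size=10)
        t, p = paired_t(x, y)
        d = y - x
        want_t = d.mean() / (d.std(ddof=1) / np.sqrt(10))
        from scipy.stats import t as tdist
        assert t == pytest.approx(want_t)
        assert p == pytest.approx(2 * tdist.sf(abs(want_t), 9))


def paired_layout(n_per_loc=(12, 16, 8)):
    locs = np.repeat(["ICA", "MCA", "ACA"], n_per_loc)
    n = locs.size
    cases = np.array([f"c{i}" for i in range(n)])
    return (np.concatenate([locs, locs]),
            np.array(["newtonian"] * n + ["carreau_yasuda"] * n),
            np.concatenate([cases, cases]))


class TestArtAnova:
    def test_alignment_zeroes_other_marginals(self, rng):
        loc, mod, case = paired_layout()
        y = rng.normal(size=loc.size) + (loc == "ICA") * 2 + (mod == "newtonian") * 1.5
        aligned = aligned_responses(y, loc, mod, case, effect="model")
        df = pd.DataFrame({"a": aligned, "loc": loc})
        assert np.allclose(df.groupby("loc")["a"].mean(), 0.0, atol=1e-9)
        aligned_loc = aligned_responses(y, loc, mod, case, effect="location")
        df2 = pd.DataFrame({"a": aligned_loc, "mod": mod})
        assert np.allclose(df2.groupby("mod")["a"].mean(), 0.0, atol=1e-9)

    def test_detects_large_location_effect(self, rng):
        loc, mod, case = paired_layout((30, 40, 20))
        y = rng.normal(size=loc.size) + (loc == "ACA") * 2.0
        res = art_anova(y, loc, mod, case)
        assert res.loc["location", "p"] < 1e-3
        assert res.loc["model", "p"] > 0.01

    def test_detects_model_effect(self, rng):
        loc, mod, case = paired_layout((30, 40, 20))
        y = rng.normal(size=loc.size) + (mod == "carreau_yasuda") * 1.0
        res = art_anova(y, loc, mod, case)
        assert res.loc["model", "p"] < 1e-3

    def test_unpaired_input_rejected(self):
        loc, mod, case = paired_layout()
        with pytest.raises(ValueError):
            art_anova(np.zeros(loc.size - 1), loc[:-1], mod[:-1], case[:-1])

    def test_single_factor_reduces_to_rank_anova(self, rng):
        # one location level: the model effect becomes a rank test
        n = 30
        loc = np.array(["MCA"] * (2 * n))
        mod = np.array(["newtonian"] * n + ["carreau_yasuda"] * n)
        case = np.concatenate([np.arange(n)] * 2).astype(str)
        y = rng.normal(size=2 * n) + (mod == "carreau_yasuda") * 2.0
        res = art_anova(y, loc, mod, case)
        assert res.loc["model", "p"] < 1e-4


class TestAgreementReport:
    def test_identity_input(self, rng):
        x = rng.normal(10, 2, 30)
        rep = agreement_report(x, x)
        assert rep.rpd_mean == 0.0 and rep.slope == pytest.approx(1.0)
        assert rep.pcc == pytest.approx(1.0)
        assert (rep.bias, rep.up_lim, rep.low_lim) == (0.0, 0.0, 0.0)

    def test_report_invariants(self, rng):
        x = rng.normal(5, 1, 40)
        y = 0.9 * x + rng.normal(0, 0.3, 40)
        rep = agreement_report(x, y)
        assert rep.low_lim <= rep.bias <= rep.up_lim
        assert abs(rep.pcc) <= 1.0


class TestBenjaminiHochberg:
    def test_matches_scipy(self, rng):
        from scipy.stats import false_discovery_control
        p = rng.uniform(size=25)
        assert np.allclose(benjamini_hochberg(p), false_discovery_control(p))
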