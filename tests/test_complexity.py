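"""Complexity indices against hand-computed oracles, plus rank correlation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from epidlog.complexity import (
    ComplexityError,
    aperture_area_variability,
    correlate_table,
    leaf_sequence_variability,
    leaf_travel,
    ltmcs,
    mcsv,
    plan_complexity_report,
    small_aperture_score,
    spearman,
    transition_metrics,
)
from epidlog.epid_io import PlanControlPoint, VmatPlan, read_table3
from epidlog.synthetic import make_arc_plan


def _cp(index, cum, bank_a, bank_b, gantry=0.0):
    return PlanControlPoint(index, gantry, 0.0, cum, list(bank_a), list(bank_b))


# Toy 3-CP plan used for the hand-computed oracles below (2 leaf pairs):
#   CP0: A=[0,0],  B=[10,10], cum=0
#   CP1: A=[0,10], B=[10,20], cum=40
#   CP2: A=[5,15], B=[15,25], cum=100
def _toy_plan():
    cps = [
        _cp(0, 0.0, [0.0, 0.0], [10.0, 10.0]),
        _cp(1, 40.0, [0.0, 10.0], [10.0, 20.0]),
        _cp(2, 100.0, [5.0, 15.0], [15.0, 25.0]),
    ]
    return VmatPlan("toy", "6", 100.0, cps, 2, [5.0, 5.0])


def _static_plan(n_cp=4):
    cps = [_cp(k, 25.0 * k, [-20.0] * 5, [20.0] * 5, gantry=10.0 * k) for k in range(n_cp)]
    return VmatPlan("static", "6", 25.0 * (n_cp - 1), cps, 5, [5.0] * 5)


class TestLsv:
    def test_aligned_leaves_give_one(self):
        cp = _cp(0, 0.0, [5.0, 5.0, 5.0], [15.0, 15.0, 15.0])
        assert leaf_sequence_variability(cp) == 1.0

    def test_two_pair_bank_hand_value(self):
        # bank A positions {0, 10}: pos_max=10, sum(pos_max-|diff|)=0 -> 0;
        # bank B aligned -> 1; product 0
        cp = _cp(0, 0.0, [0.0, 10.0], [20.0, 20.0])
        assert leaf_sequence_variability(cp) == 0.0

    def test_single_pair_warns_one(self):
        cp = _cp(0, 0.0, [0.0], [10.0])
        with pytest.warns(UserWarning, match="single"):
            assert leaf_sequence_variability(cp, pairs=[0]) == 1.0

    @given(
        st.lists(st.floats(-50, 50), min_size=2, max_size=10),
        st.lists(st.floats(0, 30), min_size=2, max_size=10),
    )
    @settings(max_examples=50, deadline=None)
    def test_unit_interval_bound(self, lefts, gaps):
        n = min(len(lefts), len(gaps))
        cp = _cp(0, 0.0, lefts[:n], [l + g for l, g in zip(lefts[:n], gaps[:n])])
        v = leaf_sequence_variability(cp)
        assert 0.0 <= v <= 1.0


class TestAav:
    def test_arc_maximum_gives_one(self):
        cp = _cp(0, 0.0, [-10.0, -10.0], [10.0, 10.0])
        assert aperture_area_variability(cp, [20.0, 20.0]) == 1.0

    def test_all_closed_gives_zero(self):
        cp = _cp(0, 0.0, [0.0, 0.0], [0.0, 0.0])
        assert aperture_area_variability(cp, [20.0, 20.0]) == 0.0

    def test_two_cp_toy_hand_value(self):
        # openings (10,10) against arc maxima (20,20) -> 0.5
        cp = _cp(0, 0.0, [0.0, 0.0], [10.0, 10.0])
        assert aperture_area_variability(cp, [20.0, 20.0]) == 0.5


class TestMcsv:
    def test_static_plan_is_one(self):
        assert mcsv(_static_plan()) == pytest.approx(1.0)

    def test_toy_plan_hand_value(self):
        # AAV: arc max opening 10 per pair -> every CP has AAV 1.
        # LSV: CP0 both banks aligned -> 1; CP1/CP2 both banks spread 10 with
        # |diff| = pos_max -> 0.
        # MCSv = 1*((1+0)/2)*(40/100) + 1*((0+0)/2)*(60/100) = 0.2
        assert mcsv(_toy_plan()) == pytest.approx(0.2)

    def test_unit_interval(self):
        plan = make_arc_plan(n_cp=15, n_leaf_pairs=8)
        assert 0.0 < mcsv(plan) <= 1.0

    def test_monotone_in_modulation_amplitude(self):
        # stronger per-CP aperture perturbation -> lower MCSv
        values = []
        for amp in (0.0, 2.0, 4.0, 8.0, 16.0):
            rng = np.random.default_rng(123)
            cps = []
            for k in range(10):
                jitter_a = amp * rng.uniform(-1, 1, 6)
                jitter_b = amp * rng.uniform(-1, 1, 6)
                cps.append(
                    _cp(k, 10.0 * k, -20.0 + jitter_a, 20.0 + jitter_b, gantry=5.0 * k)
                )
            values.append(mcsv(VmatPlan(f"m{amp}", "6", 90.0, cps, 6, [5.0] * 6)))
        assert all(b < a + 1e-12 for a, b in zip(values, values[1:]))

    def test_zero_total_mu_rejected(self):
        cps = [_cp(0, 0.0, [0.0], [10.0]), _cp(1, 0.0, [0.0], [10.0])]
        plan = VmatPlan("z", "6", 0.0, cps, 1, [5.0])
        with pytest.raises(ComplexityError, match="zero"):
            mcsv(plan)


class TestLtSasLtmcs:
    def test_static_limits(self):
        plan = _static_plan()
        assert leaf_travel(plan) == 0.0
        assert ltmcs(plan) == pytest.approx(mcsv(plan))

    def test_toy_lt_hand_value(self):
        # travels: bankA pair0 0+5, pair1 10+5; bankB pair0 0+5, pair1 10+5
        # -> total 40 over 4 leaves -> 10
        assert leaf_travel(_toy_plan()) == pytest.approx(10.0)

    def test_all_small_gaps_give_sas_one(self):
        cps = [_cp(k, 10.0 * k, [-1.0] * 4, [1.0] * 4) for k in range(3)]
        plan = VmatPlan("s", "6", 20.0, cps, 4, [5.0] * 4)
        assert small_aperture_score(plan, gap_threshold_mm=10.0) == pytest.approx(1.0)

    def test_toy_sas_at_default_threshold(self):
        # every gap in the toy plan equals 10 mm, not strictly below it
        assert small_aperture_score(_toy_plan(), gap_threshold_mm=10.0) == 0.0
        assert small_aperture_score(_toy_plan(), gap_threshold_mm=10.5) == pytest.approx(1.0)

    def test_ltmcs_hand_value(self):
        # mcsv 0.2, lt 10, norm 500 -> 0.2*(1 - 10/500) = 0.196
        assert ltmcs(_toy_plan()) == pytest.approx(0.196)


class TestTransitionMetrics:
    def test_uniform_single_style_transitions(self):
        cps = [
            _cp(0, 0.0, [0.0, 0.0], [10.0, 10.0]),
            _cp(1, 10.0, [5.0, 5.0], [15.0, 15.0]),
        ]
        plan = VmatPlan("u", "6", 10.0, cps, 2, [5.0, 5.0])
        assert transition_metrics(plan) == pytest.approx((5.0, 0.0, 5.0, 0.0, 10.0, 0.0))

    def test_two_transition_hand_values(self):
        # transition means 4 and 8 -> mean 6, sample SD 2*sqrt(2)
        cps = [
            _cp(0, 0.0, [0.0], [10.0]),
            _cp(1, 30.0, [4.0], [14.0]),
            _cp(2, 100.0, [12.0], [22.0]),
        ]
        plan = VmatPlan("t", "6", 100.0, cps, 1, [5.0])
        mn, sn, mx, sx, mu_mean, mu_std = transition_metrics(plan)
        assert mn == pytest.approx(6.0)
        assert sn == pytest.approx(2.8284271247461903)
        assert mx == pytest.approx(6.0)
        assert sx == pytest.approx(2.8284271247461903)
        assert mu_mean == pytest.approx(50.0)
        assert mu_std == pytest.approx(np.std([30.0, 70.0], ddof=1))

    def test_toy_plan_hand_values(self):
        mn, sn, mx, sx, mu_mean, mu_std = transition_metrics(_toy_plan())
        assert (mn, sn) == pytest.approx((5.0, 0.0))
        assert (mx, sx) == pytest.approx((7.5, 3.5355339059327378))
        assert (mu_mean, mu_std) == pytest.approx((50.0, 14.142135623730951))

    def test_uniform_mu_spacing_gives_zero_std(self):
        plan = _static_plan(n_cp=5)
        assert transition_metrics(plan)[5] == 0.0

    def test_reversal_invariance(self):
        plan = _toy_plan()
        rev_cps = []
        cum = [cp.cumulative_mu for cp in plan.control_points]
        for k, cp in enumerate(reversed(plan.control_points)):
            rev_cps.append(_cp(k, plan.total_mu - cum[len(cum) - 1 - k], cp.bank_A, cp.bank_B))
        rev = VmatPlan("r", "6", plan.total_mu, rev_cps, 2, [5.0, 5.0])
        mn, sn, mx, sx, _, _ = transition_metrics(plan)
        rmn, rsn, rmx, rsx, _, _ = transition_metrics(rev)
        assert (rmn, rsn, rmx, rsx) == pytest.approx((mn, sn, mx, sx))


def _brute_force_spearman(x, y):
    """Direct definition: average ranks, then the explicit product-moment sum."""

    def ranks(v):
        order = sorted(range(len(v)), key=lambda i: v[i])
        r = [0.0] * len(v)
        i = 0
        while i < len(order):
            j = i
            while j + 1 < len(order) and v[order[j + 1]] == v[order[i]]:
                j += 1
            avg = (i + j) / 2.0 + 1.0
            for k in range(i, j + 1):
                r[order[k]] = avg
            i = j + 1
        return r

    rx, ry = ranks(list(x)), ranks(list(y))
    mx, my = sum(rx) / len(rx), sum(ry) / len(ry)
    num = sum((a - mx) * (b - my) for a, b in zip(rx, ry))
    den = (
        sum((a - mx) ** 2 for a in rx) * sum((b - my) ** 2 for b in ry)
    ) ** 0.5
    return num / den


class TestSpearman:
    def test_table3_headline_coefficient(self):
        df = read_table3()
        res = spearman(df["gpr_prop"], df["gpr_mach"])
        assert res.rho == pytest.approx(0.737, abs=0.005)
        assert res.n == 18
        assert res.p_value < 0.05

    def test_perfect_anticorrelation(self):
        assert spearman([1, 2, 3, 4], [8, 6, 4, 2]).rho == -1.0

    def test_symmetry(self):
        rng = np.random.default_rng(2)
        x, y = rng.normal(size=10), rng.normal(size=10)
        assert spearman(x, y).rho == pytest.approx(spearman(y, x).rho)

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=25, deadline=None)
    def test_matches_brute_force_definition(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.integers(0, 5, 6).astype(float)  # small range forces ties
        y = rng.normal(size=6)
        if np.ptp(x) == 0:
            return
        assert spearman(x, y).rho == pytest.approx(_brute_force_spearman(x, y), abs=1e-12)

    def test_constant_vector_rejected(self):
        with pytest.raises(ComplexityError, match="constant"):
            spearman([1.0, 1.0, 1.0, 1.0], [1, 2, 3, 4])

    def test_short_input_rejected(self):
        with pytest.raises(ComplexityError, match=">= 4"):
            spearman([1, 2, 3], [3, 2, 1])


class TestCorrelateTable:
    def test_thirteen_rows_with_flags(self):
        out = correlate_table(read_table3())
        assert len(out) == 13
        assert set(out[out["excluded"]]["index"]) == {"sas", "lsv", "lt"}
        row = out[out["index"] == "gpr_mach"].iloc[0]
        assert row["rho"] == pytest.approx(0.737, abs=0.005)


class TestReport:
    def test_report_fields_consistent(self):
        plan = make_arc_plan(n_cp=12, n_leaf_pairs=8)
        rep = plan_complexity_report(plan)
        assert rep.mcsv == pytest.approx(mcsv(plan))
        assert rep.lt == pytest.approx(leaf_travel(plan))
        assert 0.0 < rep.aav <= 1.0
        assert 0.0 < rep.lsv <= 1.0
        assert rep.ltmcs <= rep.mcsv
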