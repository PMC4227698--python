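"""Dose-dependence aggregation, closed-time mixtures, voltage dependence,
two-mode identifiability, and agonist activity."""

import numpy as np
import pandas as pd
import pytest

from pegblock.blockade import (
    agonist_activity,
    apparent_open_time,
    blocking_kinetics,
    closed_time_components,
    propagate_kd_error,
    voltage_dependence,
)
from pegblock.mil import Dataset, fit_mil
from pegblock.schemes import CLOSED, OPEN, Conditions, Edge, KineticScheme, RateLaw, build_blockade_scheme
from pegblock.simulate import default_rate_table, simulate_dwells


class TestApparentOpenTime:
    def test_arithmetic_mean_single_cell(self):
        mean, sem = apparent_open_time([np.array([0.002, 0.004])])
        assert mean == pytest.approx(0.003)
        assert sem == 0.0

    def test_open_exit_rate_sets_tau_app(self):
        # alpha_total = 500 s^-1 without blocker -> tau_app ~ 2 ms;
        # adding a blocking rate of 500 s^-1 halves it
        table = default_rate_table(1)
        table.update(closing=450.0, d1_on=30.0, d2_on=15.0, d3_on=5.0, kb_on=25.0)
        s = build_blockade_scheme(table)
        for dose, expect in ((0.0, 1 / 500.0), (20.0, 1 / 1000.0)):
            d = simulate_dwells(s, Conditions(100.0, dose), n_events=6000, seed=77)
            opens = d.open_durations()
            se = opens.std(ddof=1) / np.sqrt(opens.size)
            assert abs(opens.mean() - expect) < 3 * se

    def test_no_openings_rejected(self):
        with pytest.raises(ValueError):
            apparent_open_time([np.array([])])


class TestClosedTimeComponents:
    def test_single_exponential_recovered(self):
        rng = np.random.default_rng(5)
        t = rng.exponential(0.010, 5000)
        mix = closed_time_components(t)
        assert mix.taus.size == 1
        se = 0.010 / np.sqrt(t.size)
        assert abs(mix.taus[0] - 0.010) < 3 * se

    def test_two_component_mixture_recovered(self):
        rng = np.random.default_rng(6)
        t = np.concatenate([rng.exponential(0.001, 2500), rng.exponential(0.100, 2500)])
        mix = closed_time_components(t)
        assert mix.taus.size == 2
        se_area = np.sqrt(0.25 / t.size)
        assert abs(mix.areas[0] - 0.5) < 4 * se_area
        assert mix.areas.sum() == pytest.approx(1.0)
        assert mix.hist_counts.sum() == t.size

    def test_blocked_component_area_grows_but_lifetime_fixed(self):
        """The sequential-block diagnostic: the blocked component's area is
        dose-dependent while its lifetime is not."""
        s = KineticScheme(
            ["C", "O", "B"],
            {"C": CLOSED, "O": OPEN, "B": CLOSED},
            [
                Edge("C", "O", RateLaw(500.0), "opening"),
                Edge("O", "C", RateLaw(200.0), "closing"),
                Edge("O", "B", RateLaw(15.0, ligand="blocker"), "kb_on"),
                Edge("B", "O", RateLaw(2.0), "kb_off"),
            ],
        )
        areas, taus = [], []
        for i, dose in enumerate((5.0, 10.0, 20.0)):
            d = simulate_dwells(s, Conditions(0.0, dose), n_events=6000, seed=90 + i)
            mix = closed_time_components(d.closed_durations(), n_components=2)
            areas.append(mix.areas[-1])
            taus.append(mix.taus[-1])
        assert areas[0] < areas[1] < areas[2]
        # tau_B = 1/k-B = 0.5 s at every dose, within ~2 SE of each other
        for tau, n_blocked in zip(taus, np.array(areas) * 3000):
            assert abs(tau - 0.5) < 3 * 0.5 / np.sqrt(n_blocked)

    def test_too_few_dwells_rejected(self):
        with pytest.raises(ValueError):
            closed_time_components(np.full(10, 0.01))


class TestBlockingKinetics:
    @staticmethod
    def _frame(blocking, unblocking, doses, cells=(0,)):
        rows = []
        for c in cells:
            for b, u, d in zip(blocking, unblocking, doses):
                rows.append({"cell": c, "dose_uM": d, "blocking_rate": b,
                             "unblocking_rate": u})
        return pd.DataFrame(rows)

    def test_exact_linear_rates_give_printed_slope(self):
        df = self._frame([75.0, 150.0, 300.0], [2.0, 2.0, 2.0], [5.0, 10.0, 20.0])
        summary = blocking_kinetics(df)
        m = summary.modes["single"]
        assert m.k_plus_B == pytest.approx(15.0)
        assert m.k_plus_B_intercept == pytest.approx(0.0, abs=1e-12)
        assert m.k_minus_B == pytest.approx(2.0)
        assert m.k_minus_B_sem == 0.0
        assert m.Kd_uM == pytest.approx(2.0 / 15.0)

    def test_kd_error_propagation_reduces_to_ratio(self):
        kd, se = propagate_kd_error(2.0, 0.0, 15.0, 0.0)
        assert kd == pytest.approx(0.13333333333333333)
        assert se == 0.0
        kd, se = propagate_kd_error(2.0, 0.2, 15.0, 1.5)
        assert se == pytest.approx(kd * np.sqrt(0.01 + 0.01))

    def test_single_dose_rejected(self):
        df = self._frame([75.0], [2.0], [5.0])
        with pytest.raises(ValueError):
            blocking_kinetics(df)

    def test_excluded_rows_are_dropped(self):
        df = self._frame([75.0, 150.0, 300.0, 9999.0], [2.0, 2.0, 2.0, 50.0],
                         [5.0, 10.0, 20.0, 20.0])
        df["excluded"] = [False, False, False, True]
        m = blocking_kinetics(df).modes["single"]
        assert m.k_plus_B == pytest.approx(15.0)
        assert m.k_minus_B == pytest.approx(2.0)


class TestTwoModeIdentifiability:
    def test_mode_order_recovered_in_most_replicates(self):
        """With k-B,fast = 60 s^-1 and k-B,slow = 3 s^-1 the two blockade
        modes separate, with the fitted fast rate in the tens and the slow
        rate in the low single digits, in >= 95% of replicates."""
        table = default_rate_table(2)
        scheme = build_blockade_scheme(table, n_block_modes=2)
        cond = Conditions(100.0, 10.0)
        free = ["kb_fast_on", "kb_fast_off", "kb_slow_on", "kb_slow_off"]
        start = {"kb_fast_on": 2.0, "kb_fast_off": 50.0,
                 "kb_slow_on": 2.0, "kb_slow_off": 5.0}
        n_ok = 0
        reps = 20
        for r in range(reps):
            d = simulate_dwells(scheme, cond, n_events=3000, seed=300 + r)
            codes, durs = d.class_dwells()
            res = fit_mil(scheme, [Dataset(codes, durs, cond)], free=free,
                          start=start, n_starts=3, jitter_sd=0.7)
            offs = sorted([res.estimates["kb_fast_off"], res.estimates["kb_slow_off"]])
            if offs[1] > offs[0] and 30.0 < offs[1] < 120.0 and 1.0 < offs[0] < 9.0:
                n_ok += 1
        assert n_ok >= int(np.ceil(0.95 * reps))


class TestVoltageDependence:
    def test_exact_linear_amplitude_gives_v_rest(self):
        V_hold = [50.0, 70.0, 100.0, 130.0]
        amps = [0.1 * v + 2.0 for v in V_hold]
        vs = voltage_dependence(V_hold, amps, k_plus_B=[10.0, 11.0, 12.0, 13.0])
        assert vs.V_rest == pytest.approx(-20.0)
        assert np.allclose(vs.V_m, -20.0 - np.asarray(V_hold))

    def test_voltage_slope_recovered_through_mil(self):
        """k+B(V) = k0 exp(-V_m / 50 mV): the fitted ln k+B line recovers a
        slope of -0.02 per mV from simulated recordings."""
        table = default_rate_table(1)
        scheme = build_blockade_scheme(table, voltage_sensitivity={"kb_on": -0.02})
        naive = build_blockade_scheme(table)  # the analyst's voltage-blind model
        V_hold = np.array([50.0, 70.0, 100.0, 130.0])
        V_rest = -20.0
        kb_hat, kb_se = [], []
        for i, vh in enumerate(V_hold):
            cond = Conditions(100.0, 10.0, V_m=V_rest - vh)
            d = simulate_dwells(scheme, cond, n_events=2500, seed=400 + i)
            codes, durs = d.class_dwells()
            res = fit_mil(naive, [Dataset(codes, durs, cond)],
                          free=["kb_on", "kb_off"],
                          start={"kb_on": 2.0, "kb_off": 10.0},
                          n_starts=3, jitter_sd=0.7)
            kb_hat.append(res.estimates["kb_on"])
            kb_se.append(res.standard_errors["kb_on"])
        amps = 0.07 * (V_hold - V_rest)
        vs = voltage_dependence(V_hold, amps, kb_hat)
        assert vs.V_rest == pytest.approx(V_rest, abs=1e-6)
        # slope uncertainty: residual-based SE combined with the MIL
        # estimation error propagated through the 4-point regression
        sxx = np.sum((vs.V_m - vs.V_m.mean()) ** 2)
        prop = np.mean(np.asarray(kb_se) / np.asarray(kb_hat)) / np.sqrt(sxx)
        se = np.sqrt(vs.ln_kplus_slope_se ** 2 + prop ** 2)
        assert abs(vs.ln_kplus_slope - (-0.02)) < 3 * se
        assert vs.increases_with_hyperpolarization

    def test_voltage_insensitive_slope_ci_contains_zero(self):
        table = default_rate_table(1)
        scheme = build_blockade_scheme(table)
        V_hold = np.array([50.0, 70.0, 100.0, 130.0])
        kb_hat, kb_se = [], []
        for i, vh in enumerate(V_hold):
            cond = Conditions(100.0, 10.0, V_m=-20.0 - vh)
            d = simulate_dwells(scheme, cond, n_events=2000, seed=500 + i)
            codes, durs = d.class_dwells()
            res = fit_mil(scheme, [Dataset(codes, durs, cond)],
                          free=["kb_on", "kb_off"],
                          start={"kb_on": 2.0, "kb_off": 10.0},
                          n_starts=2, jitter_sd=0.5)
            kb_hat.append(res.estimates["kb_on"])
            kb_se.append(res.standard_errors["kb_on"])
        vs = voltage_dependence(V_hold, 0.07 * (V_hold + 20.0), kb_hat)
        sxx = np.sum((vs.V_m - vs.V_m.mean()) ** 2)
        prop = np.mean(np.asarray(kb_se) / np.asarray(kb_hat)) / np.sqrt(sxx)
        se = np.sqrt(vs.ln_kplus_slope_se ** 2 + prop ** 2)
        assert abs(vs.ln_kplus_slope) < 3 * se

    def test_flat_amplitude_line_rejected(self):
        with pytest.raises(ValueError):
            voltage_dependence([50.0, 70.0, 100.0], [7.0, 7.0, 7.0], [1.0, 1.0, 1.0])


class TestAgonistActivity:
    def test_single_channel_open_fraction(self):
        act = agonist_activity([0, 1, 0], [0.7, 0.3, 0.0001])
        # fractions of total time, not exactly 0.3, so compute directly
        assert act.NPo == pytest.approx(0.3 / (0.7 + 0.3 + 0.0001))
        assert act.P_open_levels.sum() == pytest.approx(1.0)

    def test_two_independent_channels_sum_their_po(self):
        rng = np.random.default_rng(9)
        s = KineticScheme(
            ["C", "O"], {"C": CLOSED, "O": OPEN},
            [Edge("C", "O", RateLaw(50.0), "b"), Edge("O", "C", RateLaw(50.0), "a")],
        )
        dt = 1e-4
        grid = None
        for seed in (1, 2):
            d = simulate_dwells(s, Conditions(), total_time=60.0, seed=seed)
            codes, durs = d.class_dwells()
            edges = np.concatenate(([0.0], np.cumsum(durs)))
            mid = np.arange(int(60.0 / dt)) * dt + dt / 2
            lv = codes[np.clip(np.searchsorted(edges, mid, "right") - 1, 0, len(durs) - 1)]
            grid = lv if grid is None else grid + lv
        # RLE of the summed level signal
        change = np.flatnonzero(np.diff(grid)) + 1
        starts = np.concatenate(([0], change))
        lens = np.diff(np.concatenate((starts, [grid.size])))
        act = agonist_activity(grid[starts], lens * dt, N_max=2)
        assert abs(act.NPo - 1.0) < 0.05
        assert act.P_open_levels.size == 3

    def test_all_closed_record(self):
        with pytest.warns(UserWarning):
            act = agonist_activity([0], [1.0])
        assert act.NPo == 0.0
        assert act.N_max == 0
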