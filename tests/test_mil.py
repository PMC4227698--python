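"""Interval likelihood and MIL fitting: closed-form and quadrature oracles,
parameter recovery, identifiability, and invariances."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from pegblock.mil import Dataset, fit_mil, interval_log_likelihood
from pegblock.schemes import (
    CLOSED,
    OPEN,
    Conditions,
    Edge,
    KineticScheme,
    RateLaw,
    build_blockade_scheme,
    equilibrium_distribution,
    generator_matrix,
)
from pegblock.simulate import default_rate_table, simulate_dwells


def _ivp_loglik(scheme, cond, codes, durs):
    """Independent oracle: the same interval product, but every matrix
    exponential is obtained by high-accuracy ODE integration of
    dv/dt = v Q_aa instead of an eigendecomposition."""
    Q = generator_matrix(scheme, cond)
    idx = {0: scheme.class_indices(CLOSED), 1: scheme.class_indices(OPEN)}
    pi = equilibrium_distribution(Q)
    own, other = idx[int(codes[0])], idx[1 - int(codes[0])]
    v = pi[other] @ Q[np.ix_(other, own)]
    v = v / v.sum()
    ll = 0.0
    for i, (a, t) in enumerate(zip(codes, durs)):
        sub = Q[np.ix_(idx[a], idx[a])]
        sol = solve_ivp(lambda _, y: y @ sub, (0.0, t), v, rtol=1e-12, atol=1e-14)
        v = sol.y[:, -1]
        if i < len(durs) - 1:
            v = v @ Q[np.ix_(idx[a], idx[codes[i + 1]])]
        s = v.sum()
        ll += np.log(s)
        v = v / s
    return ll


class TestIntervalLogLikelihood:
    def test_single_open_dwell_density(self, two_state):
        # open dwell of 10 ms ending in closure: ln(100) - 100 * 0.01
        ll = interval_log_likelihood(two_state, Conditions(), [1, 0], [0.01, 1e-12])
        assert ll == pytest.approx(np.log(100.0) - 1.0, abs=1e-6)

    def test_two_state_likelihood_is_sum_of_exponential_densities(self, two_state):
        rng = np.random.default_rng(3)
        n = 101
        codes = (np.arange(n) % 2).astype(int)  # starts closed, ends closed
        durs = np.where(codes == 1, rng.exponential(0.01, n), rng.exponential(0.02, n))
        ll = interval_log_likelihood(two_state, Conditions(), codes, durs)
        rates = np.where(codes == 1, 100.0, 50.0)
        expected = float(np.sum(-rates * durs))  # survivor parts
        expected += float(np.sum(np.log(rates[:-1])))  # each non-final exit
        assert ll == pytest.approx(expected, abs=1e-8)

    @pytest.mark.parametrize("n_dwells", [21, 200])
    def test_matches_ivp_oracle_on_three_state_scheme(self, three_state, n_dwells):
        d = simulate_dwells(three_state, Conditions(), n_events=n_dwells, seed=40)
        codes, durs = d.class_dwells()
        ll = interval_log_likelihood(three_state, Conditions(), codes, durs)
        oracle = _ivp_loglik(three_state, Conditions(), codes, durs)
        assert ll == pytest.approx(oracle, abs=1e-6)

    def test_fast_path_equals_general_path(self, blockade_scheme, standard_conditions):
        d = simulate_dwells(blockade_scheme, standard_conditions, n_events=800, seed=41)
        codes, durs = d.class_dwells()
        fast = interval_log_likelihood(blockade_scheme, standard_conditions,
                                       codes, durs, method="fast")
        general = interval_log_likelihood(blockade_scheme, standard_conditions,
                                          codes, durs, method="general")
        assert fast == pytest.approx(general, abs=1e-8)

    def test_invariant_under_state_relabelling(self, blockade_scheme, standard_conditions):
        d = simulate_dwells(blockade_scheme, standard_conditions, n_events=400, seed=42)
        codes, durs = d.class_dwells()
        ll = interval_log_likelihood(blockade_scheme, standard_conditions, codes, durs)
        perm = blockade_scheme.relabeled(["B", "D2", "O", "C", "D3", "D1"])
        ll_perm = interval_log_likelihood(perm, standard_conditions, codes, durs)
        assert ll == pytest.approx(ll_perm, abs=1e-10)

    def test_rejects_non_alternating_classes(self, two_state):
        with pytest.raises(ValueError):
            interval_log_likelihood(two_state, Conditions(), [0, 0, 1], [0.1, 0.1, 0.1])


class TestFitMil:
    def test_two_state_matches_closed_form_mle(self, two_state):
        d = simulate_dwells(two_state, Conditions(), n_events=10_000, seed=50)
        codes, durs = d.class_dwells()
        res = fit_mil(two_state, [Dataset(codes, durs, Conditions())],
                      free=["opening", "closing"], n_starts=2)
        assert res.converged
        # closed-form MLE: exits / total time in class, counting only
        # dwells that end in an observed transition
        n_oc = int(np.sum((codes[:-1] == 1)))
        n_co = int(np.sum((codes[:-1] == 0)))
        t_open = durs[codes == 1].sum()
        t_closed = durs[codes == 0].sum()
        assert res.estimates["closing"] == pytest.approx(n_oc / t_open, rel=1e-6)
        assert res.estimates["opening"] == pytest.approx(n_co / t_closed, rel=1e-6)
        for name, truth in (("closing", 100.0), ("opening", 50.0)):
            assert abs(res.estimates[name] - truth) < 3 * res.standard_errors[name]

    def test_blockade_rate_recovery(self, blockade_scheme):
        cond = Conditions(100.0, 10.0)
        d = simulate_dwells(blockade_scheme, cond, n_events=3000, seed=51)
        codes, durs = d.class_dwells()
        res = fit_mil(blockade_scheme, [Dataset(codes, durs, cond)],
                      free=["kb_on", "kb_off"],
                      start={"kb_on": 2.0, "kb_off": 10.0}, n_starts=4, jitter_sd=0.7)
        assert res.converged
        assert abs(res.estimates["kb_on"] - 15.0) < 3 * res.standard_errors["kb_on"]
        assert abs(res.estimates["kb_off"] - 2.0) < 3 * res.standard_errors["kb_off"]

    def test_zero_blocker_makes_blocking_rate_non_identifiable(self, blockade_scheme):
        cond = Conditions(100.0, 0.0)
        d = simulate_dwells(blockade_scheme, cond, n_events=1500, seed=52)
        codes, durs = d.class_dwells()
        res = fit_mil(blockade_scheme, [Dataset(codes, durs, cond)],
                      free=["kb_on"], n_starts=1)
        assert "kb_on" in res.non_identifiable
        assert np.isnan(res.standard_errors["kb_on"])

    def test_estimator_bias_shrinks_with_sample_size(self, blockade_scheme):
        cond = Conditions(100.0, 10.0)
        errs = {1000: [], 10_000: []}
        for n, reps in ((1000, 20), (10_000, 20)):
            for r in range(reps):
                d = simulate_dwells(blockade_scheme, cond, n_events=n, seed=700 + r)
                codes, durs = d.class_dwells()
                res = fit_mil(blockade_scheme, [Dataset(codes, durs, cond)],
                              free=["kb_on", "kb_off"],
                              start={"kb_on": 2.0, "kb_off": 10.0},
                              n_starts=2, jitter_sd=0.7)
                errs[n].append(abs(res.estimates["kb_on"] - 15.0))
        assert np.mean(errs[10_000]) < np.mean(errs[1000])

    def test_joint_fit_agrees_with_separate_fits(self, blockade_scheme):
        doses = [5.0, 10.0, 20.0]
        datasets, separate = [], []
        for i, dose in enumerate(doses):
            cond = Conditions(100.0, dose)
            d = simulate_dwells(blockade_scheme, cond, n_events=2000, seed=60 + i)
            codes, durs = d.class_dwells()
            datasets.append(Dataset(codes, durs, cond))
            res = fit_mil(blockade_scheme, [datasets[-1]], free=["kb_on", "kb_off"],
                          start={"kb_on": 2.0, "kb_off": 10.0}, n_starts=3, jitter_sd=0.7)
            separate.append(res)
        joint = fit_mil(blockade_scheme, datasets, free=["kb_on", "kb_off"],
                        start={"kb_on": 2.0, "kb_off": 10.0}, n_starts=3, jitter_sd=0.7)
        # regression of separate per-dose blocking rates on dose
        from scipy.stats import linregress

        b = [r.estimates["kb_on"] * dose for r, dose in zip(separate, doses)]
        slope_fit = linregress(doses, b)
        se = np.sqrt(slope_fit.stderr ** 2 + joint.standard_errors["kb_on"] ** 2)
        assert abs(slope_fit.slope - joint.estimates["kb_on"]) < 3 * max(se, 0.3)

    def test_dead_time_correction_is_continuous_at_zero(self, blockade_scheme,
                                                        standard_conditions):
        d = simulate_dwells(blockade_scheme, standard_conditions, n_events=1000, seed=55)
        codes, durs = d.class_dwells()
        ll0 = interval_log_likelihood(blockade_scheme, standard_conditions, codes, durs)
        ll_eps = interval_log_likelihood(blockade_scheme, standard_conditions,
                                         codes, durs, dead_time=1e-10)
        assert ll_eps == pytest.approx(ll0, abs=1e-3)

    def test_dead_time_corrected_fit_recovers_rates(self, blockade_scheme):
        """On dead-time-imposed dwells the corrected likelihood recovers the
        blockade rates; the uncorrected one underestimates the unblocking
        rate (merged blocked dwells look longer)."""
        from pegblock.idealize import IdealizedEvents, impose_dead_time

        cond = Conditions(100.0, 20.0)
        td = 2e-4
        est, est_unc = [], []
        for r in range(3):
            d = simulate_dwells(blockade_scheme, cond, n_events=3000, seed=800 + r)
            codes, durs = d.class_dwells()
            ev = impose_dead_time(
                IdealizedEvents(codes, durs, np.full(len(durs), np.nan)), td)
            for dead, out in ((td, est), (0.0, est_unc)):
                res = fit_mil(blockade_scheme,
                              [Dataset(ev.class_codes, ev.durations, cond, dead_time=dead)],
                              free=["kb_on", "kb_off"],
                              start={"kb_on": 2.0, "kb_off": 10.0},
                              n_starts=2, jitter_sd=0.5)
                out.append(res.estimates["kb_off"])
        err = abs(np.mean(est) - 2.0)
        err_unc = abs(np.mean(est_unc) - 2.0)
        assert err < err_unc
        assert err < 0.15

    def test_requires_known_rate_names(self, two_state):
        with pytest.raises(KeyError):
            fit_mil(two_state, [Dataset([0, 1], [0.1, 0.1], Conditions())],
                    free=["nonexistent"])
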