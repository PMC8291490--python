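"""Dwell-sequence likelihood: exactness, invariances, and rate recovery."""

import numpy as np
import pytest

import gatingkit as gk
from gatingkit.dwells import OPEN, SHUT, DwellSequence
from gatingkit.likelihood import (
    dwell_loglik,
    fit_dwell_rates,
    predicted_mean_open,
    strip_long_shuttings,
    two_step_fit,
)
from gatingkit.schemes import Edge, KineticScheme
from conftest import WT_LIKE_SC, median_rate_error
from oracles import ode_dwell_loglik

SAT = 0.01


def _three_state_chain():
    """C1 <-> C2 <-> O with distinct rates: the smallest scheme whose shut
    dwell density is a genuine two-exponential with hidden structure."""
    return KineticScheme(
        name="C1C2O", states=["C1", "C2", "O"],
        state_class={"C1": SHUT, "C2": SHUT, "O": OPEN},
        edges=[Edge("C1", "C2", "k12"), Edge("C2", "C1", "k21"),
               Edge("C2", "O", "beta"), Edge("O", "C2", "alpha")],
        rates={"k12": 300.0, "k21": 900.0, "beta": 1500.0, "alpha": 800.0},
    )


class TestLoglikExactness:
    def test_two_state_factorizes_into_exponential_densities(self):
        ts = gk.two_state_scheme(0.4, 1.25)
        seq = gk.simulate_dwells(ts, 0.0, 800, seed=2)
        ll = dwell_loglik(seq, ts, 0.0).total
        beta = ts.rates["beta"] / 1000.0
        alpha = ts.rates["alpha"] / 1000.0
        lam = {OPEN: alpha, SHUT: beta}
        manual = 0.0
        for i, (c, d) in enumerate(zip(seq.classes, seq.durations_ms)):
            manual += -lam[c] * d
            if i < len(seq) - 1:
                manual += np.log(lam[c])
        assert ll == pytest.approx(manual, abs=1e-9)

    def test_three_state_matches_ode_integration_oracle(self):
        scheme = _three_state_chain()
        seq = gk.simulate_dwells(scheme, 0.0, 5, seed=3)
        ll = dwell_loglik(seq, scheme, 0.0).total
        assert ll == pytest.approx(ode_dwell_loglik(seq, scheme, 0.0),
                                   abs=1e-6)

    def test_doubling_data_doubles_magnitude(self, sc_oneD):
        small = gk.simulate_dwells(sc_oneD, SAT, 2000, seed=4)
        big = gk.simulate_dwells(sc_oneD, SAT, 4000, seed=4)
        r = dwell_loglik(big, sc_oneD, SAT).total \
            / dwell_loglik(small, sc_oneD, SAT).total
        assert r == pytest.approx(2.0, rel=0.1)

    def test_state_relabelling_within_class_invariant(self, sc_oneD):
        seq = gk.simulate_dwells(sc_oneD, SAT, 1000, seed=5)
        base = dwell_loglik(seq, sc_oneD, SAT).total
        # permute the state order (open states swapped, shut states rotated)
        reordered = KineticScheme(
            name=sc_oneD.name,
            states=["A2O'", "A2O", "A2D", "A2R", "A2F"],
            state_class=dict(sc_oneD.state_class),
            edges=list(sc_oneD.edges),
            rates=dict(sc_oneD.rates),
        )
        assert dwell_loglik(seq, reordered, SAT).total == pytest.approx(
            base, abs=1e-9)

    def test_cluster_contributions_sum_to_total(self, sc_oneD):
        seq = gk.simulate_dwells(sc_oneD, SAT, 3000, seed=6)
        clustered = strip_long_shuttings(seq, 10.0)
        ll = dwell_loglik(clustered, sc_oneD, SAT)
        assert ll.total == pytest.approx(sum(ll.per_cluster))
        assert len(ll.per_cluster) == len(clustered.cluster_ranges())

    def test_class_mismatch_raises(self):
        all_shut = KineticScheme(
            name="CC", states=["C1", "O1"],
            state_class={"C1": SHUT, "O1": OPEN},
            edges=[Edge("C1", "O1", "a"), Edge("O1", "C1", "b")],
            rates={"a": 1.0, "b": 1.0},
        )
        seq = DwellSequence(np.array([OPEN, SHUT], dtype=object),
                            np.array([1.0, 1.0]))
        # a scheme lacking one class entirely is structurally incompatible
        with pytest.raises(Exception):
            bad = KineticScheme(
                name="allshut", states=["C1", "C2"],
                state_class={"C1": SHUT, "C2": SHUT},
                edges=[Edge("C1", "C2", "a"), Edge("C2", "C1", "b")],
                rates={"a": 1.0, "b": 1.0},
            )
            dwell_loglik(seq, bad, 0.0)
        del all_shut


def _open_branch_aliases(rates):
    """The two open branches of sc-type schemes are exchangeable: compare
    up to that permutation."""
    swapped = dict(rates)
    swapped.update({
        "beta2": rates["beta2p"], "alpha2": rates["alpha2p"],
        "beta2p": rates["beta2"], "alpha2p": rates["alpha2"],
    })
    return [rates, swapped]


class TestRateRecovery:
    def test_self_fit_median_error_below_10_percent(self, sc_oneD):
        """ML on ideal-resolution synthetic data recovers the generating
        rates; weakly identified branch rates keep the median, not every
        rate, under 10%."""
        truth = WT_LIKE_SC
        seq = gk.simulate_dwells(sc_oneD, SAT, 10_000, seed=3)
        fit = fit_dwell_rates(seq, sc_oneD, SAT, starts=3, seed=0)
        ll_truth = dwell_loglik(seq, sc_oneD, SAT).total
        assert -fit.objective >= ll_truth - 1e-6
        err = min(median_rate_error(alias, truth)
                  for alias in _open_branch_aliases(fit.rates))
        assert err < 0.10

    def test_fixed_rates_unchanged_and_seed_reproducible(self, sc_oneD):
        seq = gk.simulate_dwells(sc_oneD, SAT, 1500, seed=9)
        fixed = {"delta2": 1500.0, "gamma2": 700.0}
        a = fit_dwell_rates(seq, sc_oneD, SAT, fixed=fixed, starts=2,
                            seed=1, maxiter=60)
        b = fit_dwell_rates(seq, sc_oneD, SAT, fixed=fixed, starts=2,
                            seed=1, maxiter=60)
        assert a.rates["delta2"] == 1500.0 and a.rates["gamma2"] == 700.0
        assert a.rates == b.rates
        assert a.objective == b.objective


class TestTwoStep:
    def test_degenerate_tcrit_reduces_to_one_step(self):
        scheme_noD = gk.make_builtin_scheme(
            "sc_noD", rates={k: v for k, v in WT_LIKE_SC.items()
                             if k not in ("d2", "r2")})
        raw = gk.simulate_dwells(scheme_noD, SAT, 800, seed=12)
        # start and end on openings so truncation has nothing to trim
        open_idx = np.nonzero(raw.classes == OPEN)[0]
        seq = DwellSequence(raw.classes[open_idx[0]:open_idx[-1] + 1],
                            raw.durations_ms[open_idx[0]:open_idx[-1] + 1])
        t_crit = seq.durations_of(SHUT).max() + 1.0
        full = gk.make_builtin_scheme("sc_oneD", rates=WT_LIKE_SC)
        res = two_step_fit(seq, full, SAT, t_crit, starts=1, seed=2,
                           validate=False)
        direct = fit_dwell_rates(seq, scheme_noD, SAT, starts=1, seed=2)
        for name in scheme_noD.rate_names():
            assert res.step1.rates[name] == pytest.approx(
                direct.rates[name], rel=1e-9)

    def test_pinned_rates_pass_unchanged_to_step2(self, sc_oneD):
        seq = gk.simulate_dwells(sc_oneD, SAT, 800, seed=13)
        res = two_step_fit(seq, sc_oneD, SAT, 15.0, starts=1, seed=3,
                           validate=False)
        assert res.step2.rates["delta2"] == res.step1.rates["delta2"]
        assert res.step2.rates["gamma2"] == res.step1.rates["gamma2"]
        assert res.pinned == {"delta2": res.step1.rates["delta2"],
                              "gamma2": res.step1.rates["gamma2"]}


class TestPredictedMeanOpen:
    def test_bifurcating_reciprocal_alpha2(self):
        s = gk.make_builtin_scheme("fJWM", rates={"alpha2": 1176.4706})
        assert predicted_mean_open(s) == pytest.approx(0.85, rel=1e-4)

    def test_linear_equals_bifurcating_when_d2_zero(self):
        f = gk.make_builtin_scheme("fJWM", rates={"alpha2": 1000.0})
        l = gk.make_builtin_scheme("fLM", rates={"alpha2": 1000.0,
                                                 "d2": 0.0})
        assert predicted_mean_open(l) == pytest.approx(
            predicted_mean_open(f))

    def test_linear_sums_exit_rates(self):
        s = gk.make_builtin_scheme("fLM", rates={"alpha2": 1000.0,
                                                 "d2": 1000.0})
        assert predicted_mean_open(s) == pytest.approx(0.5)

    def test_multi_open_state_flagged(self, sc_oneD):
        with pytest.warns(UserWarning, match="open states"):
            predicted_mean_open(sc_oneD)

    def test_discrimination_direction_for_wt_like_truth(self):
        """Fitted on data whose desensitization branches from the flipped
        state, the linear model must predict a shorter mean open time than
        the bifurcating one (its open state carries the extra d2 exit)."""
        alpha2, d2 = 1176.5, 1000.0
        bif = gk.make_builtin_scheme("fJWM", rates={"alpha2": alpha2,
                                                    "d2": d2})
        lin = gk.make_builtin_scheme("fLM", rates={"alpha2": alpha2,
                                                   "d2": d2})
        assert predicted_mean_open(lin) < predicted_mean_open(bif)
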