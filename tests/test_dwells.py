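"""Dwell simulation, dead-time imposition, mixtures, t_crit, bursts, modes."""

import numpy as np
import pytest
from hypothesis import assume, given, settings
from hypothesis import strategies as st

import gatingkit as gk
from gatingkit.dwells import (
    OPEN,
    SHUT,
    DwellSequence,
    ResolutionSpec,
    default_tcrit_components,
    effective_cutoff,
    tcrit_between,
)
from gatingkit.errors import (
    EmptyRecordError,
    InsufficientDataError,
    NoSeparationError,
    SingularFitError,
)
from gatingkit.schemes import build_q, equilibrium_occupancy
from oracles import bisect_tcrit

SAT = 0.01


def _seq(pairs, t_d=0.0):
    classes, durs = zip(*pairs)
    return DwellSequence(np.array(classes, dtype=object), np.array(durs),
                         t_d_ms=t_d)


class TestSimulateDwells:
    def test_mean_open_dwell_is_reciprocal_exit_rate(self, sc_oneD):
        seq = gk.simulate_dwells(sc_oneD, SAT, 10_000, seed=1)
        opens = seq.durations_of(OPEN)
        # exit from the open class: alpha2-weighted mix; check against the
        # simulated mean's own SE rather than a closed form
        q = build_q(sc_oneD, SAT)
        p = equilibrium_occupancy(q)
        open_idx = q.class_indices(OPEN)
        exit_r = -np.diag(q.matrix)[open_idx] / 1000.0
        entry = p[open_idx] * exit_r  # stationary entry flux weights
        entry = entry / entry.sum()
        expected = float((entry / exit_r).sum())
        se = opens.std(ddof=1) / np.sqrt(len(opens))
        assert abs(opens.mean() - expected) <= 3 * se

    def test_fraction_open_matches_equilibrium(self, sc_oneD):
        seq = gk.simulate_dwells(sc_oneD, SAT, 20_000, seed=2)
        q = build_q(sc_oneD, SAT)
        p = equilibrium_occupancy(q)
        popen_eq = p[q.class_indices(OPEN)].sum()
        popen_sim = seq.durations_of(OPEN).sum() / seq.total_duration_ms
        # conservative MC tolerance via batch means over 20 chunks
        n = len(seq)
        chunk = [
            seq.durations_ms[i:i + n // 20][
                seq.classes[i:i + n // 20] == OPEN].sum()
            / seq.durations_ms[i:i + n // 20].sum()
            for i in range(0, n - n // 20, n // 20)
        ]
        se = np.std(chunk, ddof=1) / np.sqrt(len(chunk))
        assert abs(popen_sim - popen_eq) <= 3 * se

    def test_identical_seed_identical_sequence(self, sc_oneD):
        a = gk.simulate_dwells(sc_oneD, SAT, 500, seed=7)
        b = gk.simulate_dwells(sc_oneD, SAT, 500, seed=7)
        np.testing.assert_array_equal(a.durations_ms, b.durations_ms)
        assert list(a.classes) == list(b.classes)

    def test_strict_alternation(self, sc_oneD):
        seq = gk.simulate_dwells(sc_oneD, SAT, 2_000, seed=3)
        assert all(a != b for a, b in zip(seq.classes, seq.classes[1:]))


class TestImposeResolution:
    def test_zero_dead_time_is_identity(self, sc_oneD):
        seq = gk.simulate_dwells(sc_oneD, SAT, 500, seed=4)
        assert gk.impose_resolution(seq, 0.0) is seq

    def test_forced_merge_conserves_duration(self):
        seq = _seq([(OPEN, 5.0), (SHUT, 0.02), (OPEN, 5.0)])
        out = gk.impose_resolution(seq, 0.04)
        assert list(out.classes) == [OPEN]
        assert out.durations_ms[0] == pytest.approx(10.02)

    def test_apparent_open_time_exceeds_true_mean(self, sc_oneD):
        """Missed brief shuttings lengthen apparent openings."""
        seq = gk.simulate_dwells(sc_oneD, SAT, 20_000, seed=5)
        app = gk.impose_resolution(seq, 0.06)
        assert app.durations_of(OPEN).mean() > seq.durations_of(OPEN).mean()

    def test_everything_unresolved_raises(self):
        seq = _seq([(OPEN, 0.01), (SHUT, 0.02), (OPEN, 0.01)])
        with pytest.raises(EmptyRecordError):
            gk.impose_resolution(seq, 1.0)

    @settings(max_examples=50, deadline=None)
    @given(st.lists(st.floats(min_value=1e-3, max_value=50.0),
                    min_size=2, max_size=60),
           st.booleans(),
           st.floats(min_value=0.0, max_value=0.5))
    def test_conservation_alternation_idempotence(self, durs, start_open,
                                                  t_d):
        classes = [(OPEN if (i % 2 == 0) == start_open else SHUT)
                   for i in range(len(durs))]
        seq = _seq(list(zip(classes, durs)))
        assume(max(durs) >= t_d)
        out = gk.impose_resolution(seq, t_d)
        assert out.total_duration_ms == pytest.approx(
            seq.total_duration_ms, rel=1e-12)
        assert np.all(out.durations_ms >= t_d)
        assert all(a != b for a, b in zip(out.classes, out.classes[1:]))
        again = gk.impose_resolution(out, t_d)
        np.testing.assert_allclose(again.durations_ms, out.durations_ms)
        assert list(again.classes) == list(out.classes)


def _mixture_ll(s, taus, weights):
    dens = (np.asarray(weights) / np.asarray(taus)) * np.exp(
        -s[:, None] / np.asarray(taus))
    return float(np.log(dens.sum(axis=1)).sum())


class TestMixtureFit:
    def test_two_component_recovery_wt_open_shape(self):
        rng = np.random.default_rng(42)
        n = 10_000
        fast = rng.random(n) < 0.55
        d = np.where(fast, rng.exponential(1.02, n), rng.exponential(2.86, n))
        fit = gk.fit_dwell_mixture(d, OPEN, k_max=4, seed=0)
        assert fit.k == 2
        assert fit.taus_ms[0] == pytest.approx(1.02, rel=0.10)
        assert fit.taus_ms[1] == pytest.approx(2.86, rel=0.10)
        assert fit.weights[0] == pytest.approx(0.55, rel=0.10)

    def test_single_exponential_parsimony(self):
        rng = np.random.default_rng(0)
        fit = gk.fit_dwell_mixture(rng.exponential(1.5, 5000), SHUT,
                                   k_max=4, seed=0)
        assert fit.k == 1
        assert fit.taus_ms[0] == pytest.approx(1.5, rel=0.05)

    def test_truncation_corrected_tau_unbiased(self):
        """Dead time at half the time constant still yields the true tau
        and the full-distribution area."""
        rng = np.random.default_rng(1)
        d = 0.5 + rng.exponential(1.0, 10_000)  # exact left truncation
        fit = gk.fit_dwell_mixture(d, OPEN, k_max=3, t_d_ms=0.5, seed=0)
        assert fit.k == 1
        assert fit.taus_ms[0] == pytest.approx(1.0, rel=0.05)
        assert fit.weights[0] == pytest.approx(1.0)

    def test_loglik_at_fit_beats_generating_parameters(self):
        rng = np.random.default_rng(3)
        n = 5000
        fast = rng.random(n) < 0.6
        d = np.where(fast, rng.exponential(0.3, n), rng.exponential(3.0, n))
        fit = gk.fit_dwell_mixture(d, SHUT, k=2, seed=0)
        ll_truth = _mixture_ll(d, [0.3, 3.0], [0.6, 0.4])
        assert fit.loglik >= ll_truth - 1e-6

    def test_insufficient_events(self):
        with pytest.raises(InsufficientDataError):
            gk.fit_dwell_mixture(np.ones(50) + np.arange(50), OPEN)

    def test_degenerate_equal_durations(self):
        with pytest.raises(SingularFitError):
            gk.fit_dwell_mixture(np.full(500, 2.0), OPEN)

    def test_mean_open_time_examples(self):
        wt = gk.MixtureFit(OPEN, np.array([1.02, 2.86]),
                           np.array([0.55, 0.45]), np.array([0.55, 0.45]),
                           0.0, 0.0, 0)
        assert gk.mean_open_time(wt) == pytest.approx(1.848, abs=1e-3)
        mut = gk.MixtureFit(OPEN, np.array([0.55, 1.39]),
                            np.array([0.82, 0.18]), np.array([0.82, 0.18]),
                            0.0, 0.0, 0)
        assert gk.mean_open_time(mut) == pytest.approx(0.701, abs=1e-3)
        single = gk.MixtureFit(OPEN, np.array([1.7]), np.array([1.0]),
                               np.array([1.0]), 0.0, 0.0, 0)
        assert gk.mean_open_time(single) == pytest.approx(1.7)


class TestTcrit:
    def test_matches_bisection_oracle(self):
        t = tcrit_between(1.0, 0.5, 100.0, 0.5)
        assert t == pytest.approx(bisect_tcrit(1.0, 0.5, 100.0, 0.5),
                                  abs=1e-8)
        assert t == pytest.approx(3.39872, abs=1e-4)

    def test_bracketed_between_time_constants(self):
        for (ti, pi, tj, pj) in [(0.2, 0.3, 5.0, 0.7), (1.0, 0.9, 50.0, 0.1),
                                 (0.05, 0.5, 2.0, 0.5)]:
            t = tcrit_between(ti, pi, tj, pj)
            assert ti < t < tj

    def test_monotone_in_area_ratio(self):
        ts = [tcrit_between(1.0, 0.5, 200.0, pj)
              for pj in (0.5, 0.1, 0.01, 0.001)]
        assert ts == sorted(ts)

    def test_misclassification_balance_holds_at_root(self):
        ti, pi, tj, pj = 0.8, 0.35, 30.0, 0.65
        t = tcrit_between(ti, pi, tj, pj)
        slow_below = pj * (1 - np.exp(-t / tj))
        fast_above = pi * np.exp(-t / ti)
        assert fast_above == pytest.approx(slow_below, rel=1e-9)

    def test_overlapping_components_raise(self):
        with pytest.raises(NoSeparationError):
            tcrit_between(1.0, 0.001, 1.5, 0.999)

    def test_component_pair_convention(self):
        assert default_tcrit_components(4) == (2, 3)
        assert default_tcrit_components(3) == (1, 2)

    def test_compute_tcrit_from_fit_requires_shut_class(self):
        fit = gk.MixtureFit(OPEN, np.array([1.0, 10.0]),
                            np.array([0.5, 0.5]), np.array([0.5, 0.5]),
                            0.0, 0.0, 0)
        with pytest.raises(ValueError):
            gk.compute_tcrit(fit, 0, 1)


class TestBursts:
    def test_all_short_shuttings_one_burst(self):
        seq = _seq([(OPEN, 2.0), (SHUT, 1.0), (OPEN, 3.0), (SHUT, 0.5),
                    (OPEN, 1.0)])
        stats = gk.segment_bursts(seq, 10.0)
        assert stats.n_bursts == 1
        assert stats.lengths_ms[0] == pytest.approx(7.5)

    def test_worked_example(self):
        seq = _seq([(OPEN, 2.0), (SHUT, 1.0), (OPEN, 2.0), (SHUT, 50.0),
                    (OPEN, 4.0)])
        stats = gk.segment_bursts(seq, 10.0)
        np.testing.assert_allclose(stats.lengths_ms, [5.0, 4.0])
        np.testing.assert_allclose(stats.popens, [0.8, 1.0])

    def test_partition_tiles_the_record(self, sc_oneD):
        seq = gk.simulate_dwells(sc_oneD, SAT, 5_000, seed=6)
        stats = gk.segment_bursts(seq, 8.0)
        assert (stats.lengths_ms.sum() + stats.interburst_shut_ms
                == pytest.approx(seq.total_duration_ms, rel=1e-12))

    def test_burst_popen_matches_conditional_occupancy(self):
        """With desensitized sojourns far longer than t_crit and all other
        shuttings far shorter, burst P_open approaches the stationary
        openness conditional on non-desensitized states."""
        rates = dict(delta2=1500.0, gamma2=700.0, beta2=1500.0,
                     alpha2=345.0, beta2p=1000.0, alpha2p=1000.0,
                     d2=50.0, r2=5.0)
        scheme = gk.make_builtin_scheme("sc_oneD", rates=rates)
        seq = gk.simulate_dwells(scheme, SAT, 30_000, seed=8)
        stats = gk.segment_bursts(seq, 30.0)
        q = build_q(scheme, SAT)
        p = equilibrium_occupancy(q)
        i_open = q.class_indices(OPEN)
        i_desens = [k for k, s in enumerate(q.states) if "D" in s]
        cond = p[i_open].sum() / (1.0 - p[i_desens].sum())
        open_t = stats.lengths_ms * stats.popens
        ratio = open_t.sum() / stats.lengths_ms.sum()
        # jackknife SE of the aggregated ratio over bursts
        n = stats.n_bursts
        jk = np.array([
            (open_t.sum() - open_t[i])
            / (stats.lengths_ms.sum() - stats.lengths_ms[i])
            for i in range(n)
        ])
        se = np.sqrt((n - 1) * np.mean((jk - jk.mean()) ** 2))
        assert abs(ratio - cond) <= 3 * max(se, 1e-4)

    def test_tcrit_not_above_dead_time(self):
        seq = _seq([(OPEN, 1.0), (SHUT, 1.0), (OPEN, 1.0)], t_d=0.5)
        with pytest.raises(ValueError):
            gk.segment_bursts(seq, 0.3)


class TestModes:
    def test_three_mode_recovery(self):
        rng = np.random.default_rng(10)
        vals = np.concatenate([
            rng.normal(0.65, 0.04, 36), rng.normal(0.90, 0.03, 15),
            rng.normal(0.15, 0.04, 9),
        ])
        modes = gk.select_predominant_mode(vals, k_max=4, seed=0)
        assert modes.k == 3
        assert modes.means[modes.predominant] == pytest.approx(0.65,
                                                               abs=0.05)
        assert modes.shares[modes.predominant] == pytest.approx(0.6,
                                                                abs=0.05)

    def test_tight_values_single_mode(self):
        vals = 0.7 + 0.005 * np.sin(np.arange(20))
        modes = gk.select_predominant_mode(vals)
        assert modes.k == 1

    def test_equal_share_tie_broken_to_higher_popen(self):
        rng = np.random.default_rng(11)
        vals = np.concatenate([rng.normal(0.2, 0.01, 10),
                               rng.normal(0.8, 0.01, 10)])
        modes = gk.select_predominant_mode(vals, k_max=2, seed=0)
        assert modes.k == 2
        assert modes.means[modes.predominant] == pytest.approx(0.8,
                                                               abs=0.05)
        assert "tie" in modes.log

    def test_too_few_clusters(self):
        with pytest.raises(InsufficientDataError):
            gk.select_predominant_mode(np.array([0.5, 0.6]))


class TestEffectiveCutoff:
    def test_equal_cascade(self):
        spec = ResolutionSpec(fa_khz=10.0, fd_khz=10.0)
        assert effective_cutoff(spec) == pytest.approx(10 / np.sqrt(2),
                                                       rel=1e-9)

    def test_single_filter_limit(self):
        spec = ResolutionSpec(fa_khz=10.0, fd_khz=np.inf)
        assert effective_cutoff(spec) == 10.0

    def test_sampling_rate_is_ten_times_cutoff(self):
        spec = ResolutionSpec(fa_khz=10.0, fd_khz=5.0)
        assert spec.fs_khz == pytest.approx(10 * spec.fc_khz)
        assert spec.fc_khz <= min(spec.fa_khz, spec.fd_khz)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            effective_cutoff(ResolutionSpec(fa_khz=-1.0, fd_khz=10.0))
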