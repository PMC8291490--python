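"""Synthetic data generation with the statistical structure of patch-clamp
recordings.

Macroscopic fixtures are composed directly from the descriptor equations —
an exponential onset matched to the target 10-90% rise time, the
biexponential-plus-constant desensitization decay, and an exponential
deactivation tail after washout — rather than from scheme simulation, so
descriptor-extraction tests do not depend on any choice of model rates.
Scheme-based traces come from :func:`gatingkit.macroscopic.simulate_response`
when rate-level ground truth is needed.

Noise follows the recording acceptance convention of a signal-to-noise
ratio (peak amplitude / noise SD) of at least 15. Single-channel records
are built as clusters of activity separated by long (default 1 s) shut
gaps, far above any critical time, with each cluster drawn from one
activity mode (its own rate set); ground-truth mode labels stay in the
metadata for round-trip testing. All generators are pure functions of
their parameters and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dwells import OPEN, DwellSequence, impose_resolution, simulate_dwells
from .errors import GatingKitError, ResolutionError
from .macroscopic import DoseResponse, MacroscopicTrace, build_dose_response, hill
from .profiles import PhenotypeProfile
from .schemes import SHUT, KineticScheme

_RISE_SPAN = np.log(9.0)  # 10-90% rise of 1 - exp(-t/tau) spans tau*ln9


def make_macro_trace(profile: PhenotypeProfile, snr: float = 15.0,
                     seed: int | None = 0, dt_ms: float = 0.05,
                     pulse_ms: float = 510.0, washout_ms: float = 1500.0
                     ) -> MacroscopicTrace:
    """Deterministic descriptor-equation response plus Gaussian noise.

    Onset: ``1 - exp(-t/tau_r)`` with ``tau_r`` set from the profile's
    10-90% rise time; the peak is taken where the onset reaches 99.99% of
    its asymptote, after which the normalized biexponential desensitization
    decay runs until washout, followed by a single-exponential deactivation
    tail with the profile's mean deactivation time constant. Noise SD is
    peak / ``snr`` (``snr=numpy.inf`` for noiseless traces).
    """
    if snr <= 0:
        raise ValueError("snr must be > 0")
    m = profile.macro
    tau_r = m.rise_time_ms / _RISE_SPAN
    eps = 1e-4
    t_peak = tau_r * np.log(1.0 / eps)
    if t_peak / dt_ms < 3:
        raise ResolutionError(
            f"dt={dt_ms} ms leaves fewer than 3 samples on the onset"
        )
    a_f, a_s, c = m.normalized_amplitudes()
    t = np.arange(0.0, pulse_ms + washout_ms + dt_ms / 2, dt_ms)
    y = np.empty_like(t)
    on = t <= t_peak
    y[on] = (1.0 - np.exp(-t[on] / tau_r)) / (1.0 - eps)
    mid = (t > t_peak) & (t <= pulse_ms)
    td = t[mid] - t_peak
    y[mid] = (a_f * np.exp(-td / m.tau_fast_ms)
              + a_s * np.exp(-td / m.tau_slow_ms) + c)
    off = t > pulse_ms
    y_end = (a_f * np.exp(-(pulse_ms - t_peak) / m.tau_fast_ms)
             + a_s * np.exp(-(pulse_ms - t_peak) / m.tau_slow_ms) + c)
    y[off] = y_end * np.exp(-(t[off] - pulse_ms) / m.tau_deact_ms)
    if np.isfinite(snr):
        rng = np.random.default_rng(seed)
        y = y + rng.normal(0.0, 1.0 / snr, size=len(y))
    return MacroscopicTrace(
        dt_ms=dt_ms, values=y, app_window_ms=(0.0, pulse_ms),
        metadata={
            "profile": profile.label, "snr": snr, "seed": seed,
            "truth": {
                "rise_time_ms": m.rise_time_ms,
                "tau_fast_ms": m.tau_fast_ms, "tau_slow_ms": m.tau_slow_ms,
                "pA_fast": a_f, "pA_slow": a_s, "pC": c,
                "tau_deact_ms": m.tau_deact_ms, "peak_time_ms": t_peak,
            },
        },
    )


def make_dose_response(ec50: float, n_h: float, concs: np.ndarray,
                       noise_sd: float = 0.0, seed: int | None = 0,
                       rundown: float = 1.0, sat_amp: float = 1.0
                       ) -> DoseResponse:
    """Hill-curve dose-response data with bracketing saturating sweeps.

    Each concentration is recorded from a fresh cell as the sweep triplet
    saturating / test / saturating, with a multiplicative ``rundown``
    factor per sweep; dividing the test response by the mean bracket
    corrects the rundown. ``noise_sd`` is the amplitude noise SD relative
    to the saturating amplitude.
    """
    rng = np.random.default_rng(seed)
    concs = np.asarray(concs, dtype=float)
    sat, test, used_concs = [], [], []
    for conc in concs:
        amps = np.array([
            sat_amp,                                  # saturating, sweep 0
            sat_amp * rundown * hill(conc, ec50, n_h),  # test, sweep 1
            sat_amp * rundown ** 2,                   # saturating, sweep 2
        ])
        if noise_sd > 0:
            amps = amps + rng.normal(0.0, noise_sd * sat_amp, size=3)
        sat.append((amps[0], amps[2]))
        test.append(amps[1])
        used_concs.append(conc)
    dr = build_dose_response(sat, test, used_concs)
    dr.metadata = {"truth": {"ec50": ec50, "n_h": n_h, "rundown": rundown},
                   "seed": seed, "noise_sd": noise_sd}
    return dr


@dataclass(frozen=True)
class ModeSpec:
    """One activity mode: a label, rate overrides defining it, and its
    share of clusters."""

    label: str
    rates: dict[str, float] = field(default_factory=dict)
    share: float = 1.0


def two_state_scheme(popen: float, mean_open_ms: float = 1.0,
                     name: str = "CO") -> KineticScheme:
    """Minimal shut<->open scheme with given equilibrium open probability
    and mean open time — convenient ground truth for mode fixtures."""
    if not 0 < popen < 1:
        raise ValueError("popen must lie strictly in (0, 1)")
    from .schemes import Edge
    alpha = 1000.0 / mean_open_ms
    beta = alpha * popen / (1.0 - popen)
    return KineticScheme(
        name=name, states=["C", "O"],
        state_class={"C": SHUT, "O": OPEN},
        edges=[Edge("C", "O", "beta"), Edge("O", "C", "alpha")],
        rates={"beta": beta, "alpha": alpha},
    )


def mode_spec_from_popen(levels_shares: list[tuple[float, float]],
                         mean_open_ms: float = 1.0) -> list[ModeSpec]:
    """Modes at given (P_open level, share) pairs over a two-state scheme
    with fixed mean open time: only the opening rate varies by mode."""
    alpha = 1000.0 / mean_open_ms
    return [
        ModeSpec(label=f"popen={p:g}", share=s,
                 rates={"beta": alpha * p / (1.0 - p)})
        for p, s in levels_shares
    ]


def make_sc_record(scheme: KineticScheme, conc: float, n_clusters: int,
                   mode_spec: list[ModeSpec], t_d_ms: float = 0.0,
                   seed: int | None = 0, events_per_cluster: int = 200,
                   gap_ms: float = 1000.0) -> DwellSequence:
    """Concatenated single-channel clusters with per-cluster activity modes.

    Each cluster draws its mode from ``mode_spec`` shares, simulates
    ``events_per_cluster`` dwells under that mode's rate set, and is trimmed
    to start and end on openings; clusters are separated by ``gap_ms`` shut
    gaps. Resolution is imposed per cluster at ``t_d_ms``. Ground-truth mode
    labels and cluster index ranges live in the metadata.
    """
    shares = np.array([m.share for m in mode_spec], dtype=float)
    if not np.isclose(shares.sum(), 1.0, atol=1e-6):
        raise GatingKitError("mode shares must sum to 1")
    for m in mode_spec:
        missing = set(m.rates) - set(scheme.rates)
        if missing:
            raise GatingKitError(
                f"mode {m.label!r} overrides unknown rates {missing}"
            )
    rng = np.random.default_rng(seed)
    classes: list[str] = []
    durs: list[float] = []
    ranges: list[tuple[int, int]] = []
    labels: list[str] = []
    for _ in range(n_clusters):
        mode = mode_spec[int(rng.choice(len(mode_spec), p=shares))]
        sim = simulate_dwells(scheme.with_rates(mode.rates), conc,
                              events_per_cluster, seed=rng)
        if t_d_ms > 0:
            sim = impose_resolution(sim, t_d_ms)
        open_idx = np.nonzero(sim.classes == OPEN)[0]
        if len(open_idx) == 0:
            continue
        a, b = open_idx[0], open_idx[-1] + 1
        if classes:
            classes.append(SHUT)
            durs.append(gap_ms)
        start = len(classes)
        classes.extend(sim.classes[a:b])
        durs.extend(sim.durations_ms[a:b])
        ranges.append((start, len(classes)))
        labels.append(mode.label)
    return DwellSequence(
        classes=np.array(classes, dtype=object),
        durations_ms=np.array(durs),
        t_d_ms=t_d_ms,
        metadata={
            "scheme": scheme.name, "conc_M": conc, "seed": seed,
            "gap_ms": gap_ms, "cluster_ranges": ranges,
            "mode_labels": labels,
            "mode_spec": [
                {"label": m.label, "share": m.share, "rates": dict(m.rates)}
                for m in mode_spec
            ],
        },
    )
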