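"""Macroscopic concentration-jump responses and their kinetic descriptors.

Forward model: the state-probability vector of a kinetic scheme is
propagated through each segment of an agonist application protocol by the
matrix exponential of that segment's generator; the simulated current is
proportional to total open-state occupancy.

Descriptors mirror standard whole-cell / excised-patch analysis of
GABA-evoked currents:

* onset measured as 10-90% rise time,
* macroscopic desensitization fitted post-peak with
  ``A_fast*exp(-t/tau_fast) + A_slow*exp(-t/tau_slow) + C`` and summarized
  by FR10/FR300/FR500, the fraction of peak current remaining 10/300/500 ms
  after the peak,
* deactivation after agonist washout fitted with one or two exponentials
  (chosen by an F-test) and summarized by the amplitude-weighted
  tau_mean = sum(A_n% * tau_n),
* dose-response relationships fitted with the Hill equation
  ``y = 1 / (1 + (EC50/c)^nH)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import expm
from scipy.optimize import curve_fit
from scipy.stats import f as f_dist

from .errors import (
    InsufficientDataError,
    NonIdentifiableError,
    ProtocolError,
    ResolutionError,
)
from .schemes import OPEN, KineticScheme, build_q, closed_class_occupancy


@dataclass
class AgonistProtocol:
    """Ordered (duration_ms, concentration_M) segments; optionally smoothed
    by an exponential solution-exchange time constant (ms)."""

    segments: list[tuple[float, float]]
    exchange_tau_ms: float | None = None

    def __post_init__(self):
        if any(d <= 0 for d, _ in self.segments):
            raise ValueError("all segment durations must be > 0")
        if any(c < 0 for _, c in self.segments):
            raise ValueError("concentrations must be >= 0")

    @property
    def total_ms(self) -> float:
        return float(sum(d for d, _ in self.segments))

    def application_window(self) -> tuple[float, float] | None:
        """(start, end) in ms of the span with nonzero agonist, or None."""
        t = 0.0
        start = end = None
        for d, c in self.segments:
            if c > 0:
                if start is None:
                    start = t
                end = t + d
            t += d
        return None if start is None else (start, end)

    @classmethod
    def jump(cls, conc: float, pulse_ms: float, washout_ms: float = 0.0,
             baseline_ms: float = 2.0, exchange_tau_ms: float | None = None
             ) -> "AgonistProtocol":
        """Concentration jump from rest: a zero-agonist baseline (so the
        initial condition is the resting equilibrium), the pulse, and an
        optional washout."""
        segs = []
        if baseline_ms > 0:
            segs.append((baseline_ms, 0.0))
        segs.append((pulse_ms, conc))
        if washout_ms > 0:
            segs.append((washout_ms, 0.0))
        return cls(segs, exchange_tau_ms=exchange_tau_ms)


@dataclass
class MacroscopicTrace:
    dt_ms: float
    values: np.ndarray
    t0_ms: float = 0.0
    app_window_ms: tuple[float, float] | None = None
    occupancy: np.ndarray | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(self.values)):
            raise ValueError("trace values must be finite")

    @property
    def times_ms(self) -> np.ndarray:
        return self.t0_ms + self.dt_ms * np.arange(len(self.values))

    @property
    def duration_ms(self) -> float:
        return self.dt_ms * (len(self.values) - 1)


@dataclass
class DesensDescriptors:
    rise_time_10_90_ms: float
    tau_fast_ms: float
    tau_slow_ms: float
    a_fast: float
    a_slow: float
    c: float
    fr10: float
    fr300: float
    fr500: float
    peak_time_ms: float = np.nan
    peak_value: float = np.nan
    residual_rms: float = np.nan
    note: str = ""

    def decay(self, t_ms: np.ndarray | float) -> np.ndarray | float:
        """Fitted normalized decay evaluated at t (ms after peak)."""
        return (self.a_fast * np.exp(-np.asarray(t_ms) / self.tau_fast_ms)
                + self.a_slow * np.exp(-np.asarray(t_ms) / self.tau_slow_ms)
                + self.c)

    def to_dict(self) -> dict:
        return {
            "rise_time_ms": self.rise_time_10_90_ms,
            "FR10": self.fr10, "FR300": self.fr300, "FR500": self.fr500,
            "tau_fast_ms": self.tau_fast_ms, "tau_slow_ms": self.tau_slow_ms,
            "pA_fast": self.a_fast, "pA_slow": self.a_slow, "pC": self.c,
            "peak_time_ms": self.peak_time_ms, "residual_rms": self.residual_rms,
            "note": self.note,
        }


@dataclass
class DeactFit:
    amplitudes: list[float]   # fractional amplitudes, sum to 1
    taus_ms: list[float]
    tau_mean_ms: float
    f_test_p: float = np.nan
    residual_rms: float = np.nan

    def to_dict(self) -> dict:
        return {
            "n_components": len(self.taus_ms),
            "pA": list(self.amplitudes), "tau_ms": list(self.taus_ms),
            "tau_mean_ms": self.tau_mean_ms, "f_test_p": self.f_test_p,
        }


@dataclass
class DoseResponse:
    concentrations: np.ndarray
    responses: np.ndarray
    records: list[dict] = field(default_factory=list)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        self.responses = np.asarray(self.responses, dtype=float)


@dataclass
class HillFit:
    ec50: float
    n_h: float
    residuals: np.ndarray = field(default_factory=lambda: np.array([]))

    def curve(self, conc: np.ndarray | float) -> np.ndarray | float:
        return hill(np.asarray(conc, dtype=float), self.ec50, self.n_h)


def hill(conc, ec50, n_h):
    """Hill equation, relative amplitude y = 1 / (1 + (EC50/c)^nH)."""
    conc = np.asarray(conc, dtype=float)
    with np.errstate(divide="ignore"):
        return 1.0 / (1.0 + (ec50 / conc) ** n_h)


# ---------------------------------------------------------------------------
# simulation

def simulate_response(scheme: KineticScheme, protocol: AgonistProtocol,
                      dt_ms: float, keep_occupancy: bool = False,
                      p0: np.ndarray | None = None) -> MacroscopicTrace:
    """Propagate the master equation through ``protocol`` and return the
    open-probability trace sampled every ``dt_ms``.

    Initial condition: stationary occupancy at the first segment's
    concentration (restricted to the closed communicating class when the
    chain is reducible there, e.g. the unbound state at zero agonist), or
    an explicit occupancy vector ``p0``.
    """
    if dt_ms <= 0:
        raise ValueError("dt must be > 0")
    if dt_ms > min(d for d, _ in protocol.segments):
        raise ResolutionError(
            f"dt={dt_ms} ms exceeds the shortest protocol segment"
        )
    open_mask = np.array(
        [scheme.state_class[s] == OPEN for s in scheme.states]
    )
    if p0 is not None:
        p = np.asarray(p0, dtype=float)
        if len(p) != scheme.n_states or not np.isclose(p.sum(), 1.0):
            raise ValueError("p0 must be a probability vector over states")
    else:
        p = closed_class_occupancy(build_q(scheme, protocol.segments[0][1]))
    occ = [p]

    if protocol.exchange_tau_ms:
        # exponential solution exchange: concentration relaxes toward each
        # segment's target; generator re-built per step
        tau = protocol.exchange_tau_ms
        conc = protocol.segments[0][1]
        for dur, target in protocol.segments:
            n_steps = int(round(dur / dt_ms))
            for _ in range(n_steps):
                conc = target + (conc - target) * np.exp(-dt_ms / tau)
                qm = build_q(scheme, conc).matrix / 1000.0
                p = p @ expm(qm * dt_ms)
                occ.append(p)
    else:
        for dur, conc in protocol.segments:
            n_steps = int(round(dur / dt_ms))
            qm = build_q(scheme, conc).matrix / 1000.0  # per ms
            prop = expm(qm * dt_ms)
            for _ in range(n_steps):
                p = p @ prop
                occ.append(p)

    occ = np.array(occ)
    return MacroscopicTrace(
        dt_ms=dt_ms,
        values=occ @ open_mask,
        app_window_ms=protocol.application_window(),
        occupancy=occ if keep_occupancy else None,
        metadata={"scheme": scheme.name},
    )


# ---------------------------------------------------------------------------
# descriptor fitting

def _crossing_time(t: np.ndarray, y: np.ndarray, level: float) -> float:
    """First time y crosses ``level`` upward, by linear interpolation."""
    above = np.nonzero(y >= level)[0]
    if len(above) == 0:
        return np.nan
    i = above[0]
    if i == 0:
        return t[0]
    t0, t1, y0, y1 = t[i - 1], t[i], y[i - 1], y[i]
    return t0 + (level - y0) / (y1 - y0) * (t1 - t0)


def _biexp_const(t, a_f, tau_f, a_s, tau_s, c):
    return a_f * np.exp(-t / tau_f) + a_s * np.exp(-t / tau_s) + c


def fit_desensitization(trace: MacroscopicTrace, window_ms: float
                        ) -> DesensDescriptors:
    """Fit the post-peak decay with a biexponential plus constant and read
    FR10/FR300/FR500 directly off the peak-normalized data.

    The peak is the global maximum within the application window (whole
    trace if no window is annotated); the fit starts at the first sample
    after the peak and extends ``window_ms``. FR values use the normalized
    raw trace (fraction of total amplitude remaining), not the fitted curve.
    """
    t = trace.times_ms
    y = trace.values
    if trace.app_window_ms is not None:
        lo, hi = trace.app_window_ms
        win = (t >= lo) & (t <= hi)
    else:
        win = np.ones(len(t), bool)
    i_peak = np.nonzero(win)[0][np.argmax(y[win])]
    peak_t, peak_v = t[i_peak], y[i_peak]
    if peak_v <= 0:
        raise InsufficientDataError("trace has no positive peak")
    yn = y / peak_v

    # 10-90% rise time on the onset (from window/trace start to peak)
    onset_start = trace.app_window_ms[0] if trace.app_window_ms else t[0]
    on = (t >= onset_start) & (t <= peak_t)
    t10 = _crossing_time(t[on], yn[on], 0.1)
    t90 = _crossing_time(t[on], yn[on], 0.9)
    rise = t90 - t10

    # post-peak decay segment
    half = trace.dt_ms / 2
    dec = (t > peak_t) & (t <= peak_t + window_ms + half)
    td = t[dec] - peak_t
    yd = yn[dec]
    if len(td) < 6:
        raise InsufficientDataError("fewer than 6 samples after the peak")

    fr = {}
    for ms in (10.0, 300.0, 500.0):
        fr[ms] = (float(np.interp(ms, td, yd))
                  if ms <= td[-1] + half else np.nan)

    note = ""
    if np.ptp(yd) < 1e-6:  # pure constant: no desensitization
        c = float(np.mean(yd))
        return DesensDescriptors(rise, np.nan, np.nan, 0.0, 0.0, c,
                                 fr[10.0], fr[300.0], fr[500.0],
                                 peak_t, peak_v, 0.0, "constant")

    c0 = max(float(np.mean(yd[-max(3, len(yd) // 20):])), 1e-4)
    amp0 = max(1.0 - c0, 1e-3)
    # initial fast tau: time to cover 1-1/e of the drop
    drop_target = 1.0 - (1.0 - c0) * (1 - 1 / np.e)
    below = np.nonzero(yd <= drop_target)[0]
    tf0 = td[below[0]] if len(below) else td[-1] / 5
    tf0 = max(tf0, 2 * trace.dt_ms)
    p0 = [0.75 * amp0, tf0, 0.25 * amp0, min(20 * tf0, td[-1]), c0]
    bounds = ([0, trace.dt_ms / 10, 0, trace.dt_ms / 10, 0],
              [2, 50 * td[-1], 2, 50 * td[-1], 2])
    try:
        popt, _ = curve_fit(_biexp_const, td, yd, p0=p0, bounds=bounds,
                            maxfev=20000)
        a_f, tau_f, a_s, tau_s, c = popt
    except RuntimeError:
        # non-decaying / ill-posed: single-exponential fallback
        note = "biexp fit degenerate; single-exponential fallback"
        def _single(tt, a, tau, cc):
            return a * np.exp(-tt / tau) + cc
        popt, _ = curve_fit(_single, td, yd, p0=[amp0, tf0, c0],
                            bounds=([0, trace.dt_ms / 10, 0],
                                    [2, 50 * td[-1], 2]), maxfev=20000)
        a_f, tau_f, c = popt
        a_s, tau_s = 0.0, np.nan
    if np.isfinite(tau_s) and tau_f > tau_s:
        a_f, a_s = a_s, a_f
        tau_f, tau_s = tau_s, tau_f
    total = a_f + a_s + c
    resid = yd - _biexp_const(td, a_f, tau_f, a_s if a_s else 0.0,
                              tau_s if np.isfinite(tau_s) else 1.0, c)
    return DesensDescriptors(
        rise_time_10_90_ms=rise,
        tau_fast_ms=float(tau_f), tau_slow_ms=float(tau_s),
        a_fast=float(a_f / total), a_slow=float(a_s / total),
        c=float(c / total),
        fr10=fr[10.0], fr300=fr[300.0], fr500=fr[500.0],
        peak_time_ms=float(peak_t), peak_value=float(peak_v),
        residual_rms=float(np.sqrt(np.mean(resid**2))), note=note,
    )


def _exp_sum(t, *params):
    """Sum of exponentials: params = (a1, tau1, a2, tau2, ...)."""
    y = np.zeros_like(t, dtype=float)
    for a, tau in zip(params[::2], params[1::2]):
        y = y + a * np.exp(-t / tau)
    return y


def fit_deactivation(trace: MacroscopicTrace, washout_start_ms: float
                     ) -> DeactFit:
    """Fit the current relaxation after agonist washout with one or two
    exponentials; the number of components is chosen by an F-test on
    residual sums of squares at alpha = 0.05."""
    t = trace.times_ms
    sel = t >= washout_start_ms
    if sel.sum() < 3:
        raise InsufficientDataError("washout segment shorter than 3 samples")
    td = t[sel] - washout_start_ms
    y0 = trace.values[sel][0]
    if y0 <= 0:
        raise InsufficientDataError("no current at washout start")
    yd = trace.values[sel] / y0

    tau0 = max(float(np.trapezoid(yd, td)), 2 * trace.dt_ms)
    p1, _ = curve_fit(_exp_sum, td, yd, p0=[1.0, tau0],
                      bounds=([0, trace.dt_ms / 10], [2, np.inf]),
                      maxfev=20000)
    ss1 = float(np.sum((yd - _exp_sum(td, *p1)) ** 2))
    try:
        p2, _ = curve_fit(
            _exp_sum, td, yd, p0=[0.6, tau0 / 5, 0.4, tau0 * 2],
            bounds=([0, trace.dt_ms / 10, 0, trace.dt_ms / 10],
                    [2, np.inf, 2, np.inf]), maxfev=20000)
        ss2 = float(np.sum((yd - _exp_sum(td, *p2)) ** 2))
    except RuntimeError:
        p2, ss2 = None, np.inf

    n = len(td)
    p_val = 1.0
    use_two = False
    if p2 is not None and ss2 < ss1 and n > 5:
        f_stat = ((ss1 - ss2) / 2) / (ss2 / (n - 4))
        p_val = float(f_dist.sf(f_stat, 2, n - 4))
        use_two = p_val < 0.05

    if use_two:
        amps = np.array([p2[0], p2[2]])
        taus = np.array([p2[1], p2[3]])
        order = np.argsort(taus)
        amps, taus = amps[order], taus[order]
        ss = ss2
    else:
        amps, taus = np.array([p1[0]]), np.array([p1[1]])
        ss = ss1
    frac = amps / amps.sum()
    return DeactFit(
        amplitudes=[float(a) for a in frac],
        taus_ms=[float(x) for x in taus],
        tau_mean_ms=float(np.sum(frac * taus)),
        f_test_p=p_val,
        residual_rms=float(np.sqrt(ss / n)),
    )


# ---------------------------------------------------------------------------
# dose-response

def build_dose_response(saturating_amps: list[tuple[float, float]],
                        test_amps: list[float],
                        concentrations: list[float]) -> DoseResponse:
    """Relative responses from bracketed amplitude measurements.

    Each test amplitude must be bracketed by saturating-concentration
    responses recorded before and after it; the relative response is
    test / mean(brackets), which corrects linear rundown. Responses at the
    same concentration (different cells) are averaged.
    """
    if not (len(saturating_amps) == len(test_amps) == len(concentrations)):
        raise ProtocolError("amplitude/concentration lists differ in length")
    records = []
    for (pre, post), amp, conc in zip(saturating_amps, test_amps,
                                      concentrations):
        if pre is None or post is None or not np.isfinite([pre, post]).all():
            raise ProtocolError(f"missing saturating bracket at conc={conc}")
        rel = amp / ((pre + post) / 2.0)
        records.append({"conc": float(conc), "test": float(amp),
                        "bracket": (float(pre), float(post)),
                        "relative": float(rel)})
    concs = sorted({r["conc"] for r in records})
    means = [float(np.mean([r["relative"] for r in records
                            if r["conc"] == c])) for c in concs]
    return DoseResponse(np.array(concs), np.array(means), records=records)


def fit_hill(dr: DoseResponse) -> HillFit:
    """Least-squares Hill fit of relative responses; the fitted curve passes
    through 0.5 at EC50 by construction."""
    if len(np.unique(dr.concentrations)) < 4:
        raise InsufficientDataError("need >= 4 distinct concentrations")
    if np.ptp(dr.responses) < 1e-12:
        raise NonIdentifiableError("all responses equal; EC50 unidentifiable")
    c, y = dr.concentrations, dr.responses
    # initialize EC50 at the concentration nearest half-response
    ec0 = c[np.argmin(np.abs(y - 0.5))]

    def model(conc, log_ec50, n_h):
        return hill(conc, np.exp(log_ec50), n_h)

    popt, _ = curve_fit(model, c, y, p0=[np.log(ec0), 1.0],
                        bounds=([np.log(c.min()) - 10, 0.05],
                                [np.log(c.max()) + 10, 10.0]),
                        maxfev=20000)
    fitted = HillFit(ec50=float(np.exp(popt[0])), n_h=float(popt[1]))
    fitted.residuals = y - fitted.curve(c)
    return fitted
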