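"""Waveform fitting: rate-constant optimization against macroscopic traces.

The forward model is the master-equation simulation of the agonist
application protocol; the objective is the sum of squared residuals over a
restricted fitting window, with the amplitude scale profiled analytically
at every evaluation (the simulated open probability is matched to the data
up to a free multiplicative factor). Binding rates are conventionally held
fixed, and short windows (~30 ms) isolate the fast gating transitions from
slow desensitization components a simplified scheme cannot represent.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._optimize import RateFitResult, multistart_minimize
from .macroscopic import AgonistProtocol, MacroscopicTrace, simulate_response
from .schemes import KineticScheme


def _window_data(trace: MacroscopicTrace, window_ms: float
                 ) -> tuple[np.ndarray, float]:
    """Data within ``window_ms`` from the start of agonist application."""
    t = trace.times_ms
    start = trace.app_window_ms[0] if trace.app_window_ms else t[0]
    sel = (t >= start) & (t <= start + window_ms)
    return trace.values[sel], start


def _truncated_protocol(protocol: AgonistProtocol, t_end_ms: float
                        ) -> AgonistProtocol:
    segs = []
    t = 0.0
    for dur, conc in protocol.segments:
        if t >= t_end_ms:
            break
        segs.append((min(dur, t_end_ms - t), conc))
        t += dur
    return AgonistProtocol(segs, exchange_tau_ms=protocol.exchange_tau_ms)


def fit_macroscopic_rates(
    trace: MacroscopicTrace,
    scheme: KineticScheme,
    protocol: AgonistProtocol,
    window_ms: float,
    fixed: dict[str, float] | None = None,
    starts: int = 8,
    seed: int | None = None,
    maxiter: int | None = None,
    perturb: tuple[float, float] = (0.5, 2.0),
) -> RateFitResult:
    """Optimize the free rate constants of ``scheme`` against ``trace``.

    ``fixed`` maps rate names to pinned values (e.g. the binding rates
    k_on/k_off); remaining rates are free, log-parameterized, and fitted by
    multistart Nelder-Mead. The best start is returned together with the
    complete multistart record; ``converged`` is False when no start
    converged (the result then documents the failure rather than hiding it).
    """
    if window_ms > trace.duration_ms:
        raise ValueError("fitting window exceeds trace duration")
    fixed = dict(fixed or {})
    init = dict(scheme.rates)
    init.update(fixed)
    free_names = [r for r in scheme.rate_names() if r not in fixed]
    if not free_names:
        raise ValueError("no free rates to optimize")

    data, app_start = _window_data(trace, window_ms)
    sim_protocol = _truncated_protocol(protocol, app_start + window_ms)

    def objective(rates: dict[str, float]) -> float:
        sim = simulate_response(scheme.with_rates(rates), sim_protocol,
                                trace.dt_ms)
        s, _ = _window_data(sim, window_ms)
        m = min(len(s), len(data))
        s, y = s[:m], data[:m]
        ss = float(s @ s)
        scale = max(float(s @ y) / ss, 0.0) if ss > 0 else 0.0
        r = y - scale * s
        return float(r @ r)

    rates, obj, nit, conv, record = multistart_minimize(
        objective, init, free_names, starts=starts, seed=seed,
        maxiter=maxiter, perturb=perturb,
    )
    rates.update(fixed)  # fixed rates bit-identical to inputs
    return RateFitResult(
        scheme=scheme.name, rates=rates, fixed=fixed, objective=obj,
        iterations=nit, converged=conv, window_ms=window_ms,
        starts=record, seed=seed,
    )


@dataclass
class WindowComparison:
    results: list[RateFitResult]
    window_sensitive: list[str]

    def to_dict(self) -> dict:
        return {
            "windows_ms": [r.window_ms for r in self.results],
            "window_sensitive": list(self.window_sensitive),
            "results": [r.to_dict() for r in self.results],
        }


def compare_windows(
    trace: MacroscopicTrace,
    scheme: KineticScheme,
    protocol: AgonistProtocol,
    windows_ms: list[float],
    fixed: dict[str, float] | None = None,
    starts: int = 8,
    seed: int | None = None,
    sensitivity: float = 0.5,
) -> WindowComparison:
    """Fit the same scheme over several windows and flag free rates whose
    estimates vary by more than ``sensitivity`` (relative spread) across
    windows — the signature of a model component (e.g. slow
    desensitization) that only some windows constrain."""
    if not windows_ms:
        raise ValueError("window list must not be empty")
    results = [
        fit_macroscopic_rates(trace, scheme, protocol, w, fixed=fixed,
                              starts=starts, seed=seed)
        for w in windows_ms
    ]
    sensitive = []
    free = [r for r in scheme.rate_names() if r not in (fixed or {})]
    for name in free:
        vals = np.array([r.rates[name] for r in results])
        mid = np.mean(vals)
        if mid > 0 and (vals.max() - vals.min()) / mid > sensitivity:
            sensitive.append(name)
    return WindowComparison(results=results, window_sensitive=sensitive)
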