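"""Shared multistart optimization machinery for rate fitting.

Rates are log-parameterized (strictly positive, spanning decades) and
minimized with the derivative-free Nelder-Mead simplex, which tolerates the
ill-conditioned, nearly overparametrized objectives typical of kinetic
scheme fitting. Multistart with log-uniform perturbation of the initial
guess replaces manual near-optimal guessing; the full per-start record is
kept so non-reproducible fits are visible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize


@dataclass
class RateFitResult:
    scheme: str
    rates: dict[str, float]
    fixed: dict[str, float]
    objective: float
    iterations: int
    converged: bool
    window_ms: float | None = None
    starts: list[dict] = field(default_factory=list)
    seed: int | None = None

    @property
    def free_rates(self) -> dict[str, float]:
        return {k: v for k, v in self.rates.items() if k not in self.fixed}

    def to_dict(self) -> dict:
        return {
            "scheme": self.scheme, "rates": dict(self.rates),
            "fixed": dict(self.fixed), "objective": self.objective,
            "iterations": self.iterations, "converged": self.converged,
            "window_ms": self.window_ms, "seed": self.seed,
            "starts": self.starts,
        }


def multistart_minimize(
    objective,
    init_rates: dict[str, float],
    free_names: list[str],
    starts: int = 8,
    seed: int | None = None,
    perturb: tuple[float, float] = (0.5, 2.0),
    maxiter: int | None = None,
    fatol: float = 1e-10,
    xatol: float = 1e-6,
) -> tuple[dict[str, float], float, int, bool, list[dict]]:
    """Minimize ``objective(rates_dict)`` over ``free_names`` (log scale).

    Start 0 uses ``init_rates`` unchanged; subsequent starts multiply each
    free rate by a log-uniform factor in ``perturb``. Returns the best
    rates, objective, iteration count, convergence flag, and per-start log.
    """
    rng = np.random.default_rng(seed)
    x0_base = np.log([max(init_rates[n], 1e-12) for n in free_names])
    lo, hi = np.log(perturb[0]), np.log(perturb[1])
    record = []
    best = None
    for s in range(starts):
        x0 = x0_base if s == 0 else x0_base + rng.uniform(lo, hi,
                                                          len(free_names))

        def fun(x):
            rates = dict(init_rates)
            # clip to a huge but finite range: keeps exploratory simplex
            # steps from underflowing a rate to exactly zero (which would
            # disconnect the chain)
            xc = np.clip(x, np.log(1e-6), np.log(1e12))
            rates.update({n: float(np.exp(v))
                          for n, v in zip(free_names, xc)})
            return objective(rates)

        res = minimize(fun, x0, method="Nelder-Mead",
                       options={"maxiter": maxiter or 400 * len(free_names),
                                "fatol": fatol, "xatol": xatol})
        # restart from the optimum once: a fresh simplex escapes the
        # collapsed one and polishes ill-conditioned directions
        res2 = minimize(fun, res.x, method="Nelder-Mead",
                        options={"maxiter": maxiter or 400 * len(free_names),
                                 "fatol": fatol, "xatol": xatol})
        if res2.fun <= res.fun:
            res2.nit += res.nit
            res = res2
        entry = {
            "start": s,
            "initial": {n: float(np.exp(v)) for n, v in zip(free_names, x0)},
            "fitted": {n: float(np.exp(v))
                       for n, v in zip(free_names, res.x)},
            "objective": float(res.fun),
            "converged": bool(res.success),
            "iterations": int(res.nit),
        }
        record.append(entry)
        if best is None or res.fun < best[1]:
            rates = dict(init_rates)
            rates.update({n: float(np.exp(v))
                          for n, v in zip(free_names, res.x)})
            best = (rates, float(res.fun), int(res.nit), bool(res.success))
    rates, obj, nit, conv = best
    any_conv = any(e["converged"] for e in record)
    return rates, obj, nit, conv or any_conv, record
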