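"""Independent oracles used by the test suite.

Deliberately avoid the code paths they check: stochastic (Gillespie)
trajectory simulation instead of matrix exponentials, explicit ODE
integration instead of spectral propagators, and manual bisection instead
of library root finding.
"""

from __future__ import annotations

import numpy as np
from scipy.integrate import solve_ivp

from gatingkit.schemes import OPEN, build_q, closed_class_occupancy


def gillespie_checkpoint_means(scheme, conc, checkpoints_ms, n_traj,
                               seed=0, p0=None):
    """Fraction of trajectories open at each checkpoint, with binomial SE.

    Vectorized stochastic simulation: every trajectory draws exponential
    holding times and categorical jumps from the generator at ``conc``;
    the state occupied when crossing each checkpoint is recorded.
    """
    rng = np.random.default_rng(seed)
    q = build_q(scheme, conc)
    qm = q.matrix / 1000.0
    n = q.n
    exit_r = -np.diag(qm)
    jump = qm.copy()
    np.fill_diagonal(jump, 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        jump = jump / np.where(exit_r > 0, exit_r, 1.0)[:, None]
    cum = np.cumsum(jump, axis=1)
    checkpoints = np.asarray(checkpoints_ms, dtype=float)
    t_end = checkpoints.max() + 1e-9
    if p0 is None:
        p0 = closed_class_occupancy(build_q(scheme, 0.0))
    state = rng.choice(n, size=n_traj, p=p0)
    t = np.zeros(n_traj)
    rec = np.full((len(checkpoints), n_traj), -1, dtype=int)
    active = np.ones(n_traj, dtype=bool)
    while np.any(active):
        lam = np.where(exit_r[state] > 0, exit_r[state], 1e-300)
        dt = rng.exponential(1.0 / lam)
        t_new = t + np.where(active, dt, 0.0)
        for ci, tc in enumerate(checkpoints):
            hit = active & (t <= tc) & (t_new > tc)
            rec[ci, hit] = state[hit]
        u = rng.random(n_traj)
        nxt = (cum[state] < u[:, None]).sum(axis=1)
        state = np.where(active, np.minimum(nxt, n - 1), state)
        t = t_new
        active = t < t_end
    assert np.all(rec >= 0)
    open_mask = np.array([scheme.state_class[s] == OPEN for s in q.states])
    is_open = open_mask[rec]
    mean = is_open.mean(axis=1)
    se = np.sqrt(np.maximum(mean * (1 - mean), 1e-12) / n_traj)
    return mean, se


def gillespie_time_occupancy(scheme, conc, n_steps, seed=0, n_batches=10):
    """Long-run time-weighted state occupancy of one trajectory, with a
    batch-means standard error per state."""
    rng = np.random.default_rng(seed)
    q = build_q(scheme, conc)
    qm = q.matrix / 1000.0
    exit_r = -np.diag(qm)
    jump = qm.copy()
    np.fill_diagonal(jump, 0.0)
    jump = jump / exit_r[:, None]
    cum = np.cumsum(jump, axis=1)
    state = int(rng.integers(q.n))
    batch = n_steps // n_batches
    occ_batches = np.zeros((n_batches, q.n))
    holds = rng.exponential(1.0, size=n_steps)
    us = rng.random(n_steps)
    for b in range(n_batches):
        for k in range(batch):
            i = b * batch + k
            occ_batches[b, state] += holds[i] / exit_r[state]
            state = int(np.searchsorted(cum[state], us[i]))
        occ_batches[b] /= occ_batches[b].sum()
    occ = occ_batches.mean(axis=0)
    se = occ_batches.std(axis=0, ddof=1) / np.sqrt(n_batches)
    return occ, se


def ode_dwell_loglik(seq, scheme, conc):
    """Dwell-sequence log-likelihood by direct numerical integration of the
    within-class master equation (no matrix exponentials)."""
    q = build_q(scheme, conc)
    qm = q.matrix / 1000.0
    idx = {c: q.class_indices(c) for c in ("open", "shut")}
    p_eq = closed_class_occupancy(q) if conc == 0 else None
    if p_eq is None:
        from gatingkit.schemes import equilibrium_occupancy
        p_eq = equilibrium_occupancy(q)

    def propagate(phi, cls, t):
        i = idx[cls]
        qaa = qm[np.ix_(i, i)]
        sol = solve_ivp(lambda _, y: y @ qaa, (0.0, t), phi,
                        rtol=1e-12, atol=1e-14, method="DOP853")
        return sol.y[:, -1]

    loglik = 0.0
    first = seq.classes[0]
    phi = p_eq[idx[first]]
    phi = phi / phi.sum()
    for k, (cls, dur) in enumerate(zip(seq.classes, seq.durations_ms)):
        other = "shut" if cls == "open" else "open"
        phi = propagate(phi, cls, float(dur))
        if k < len(seq) - 1:
            phi = phi @ qm[np.ix_(idx[cls], idx[other])]
        s = phi.sum()
        loglik += np.log(s)
        phi = phi / s
    return float(loglik)


def bisect_tcrit(tau_i, p_i, tau_j, p_j, tol=1e-10):
    """Critical time by plain bisection on the misclassified-count balance
    p_i*exp(-t/tau_i) - p_j*(1 - exp(-t/tau_j))."""

    def f(t):
        return p_i * np.exp(-t / tau_i) - p_j * (1 - np.exp(-t / tau_j))

    lo, hi = tau_i, tau_j
    assert f(lo) > 0 > f(hi)
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if f(mid) > 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)
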