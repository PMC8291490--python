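"""Single-channel dwell sequences: simulation, recording resolution, and
dwell-time / burst / mode analysis.

A dwell sequence is the idealized event list of one channel: strictly
alternating open and shut sojourns in the aggregated classes of a kinetic
scheme. Operations here cover

* exact continuous-time Markov chain sampling of dwell sequences,
* imposition of a recording dead time t_d (events shorter than t_d are
  unresolvable and are absorbed into the preceding resolved dwell, the
  standard retrospective convention), which produces "apparent" dwells,
* maximum-likelihood fitting of exponential mixtures to dwell-time
  distributions, with left truncation at the dead time,
* the critical shut time t_crit separating intra- from inter-burst
  closures, chosen so the expected numbers of misclassified events from the
  two flanking exponential components are equal,
* burst segmentation with per-burst open probability and length,
* clustering of per-cluster open probabilities into activity modes and
  selection of the predominant mode,
* composition of cascaded analogue/digital filter cutoffs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq
from sklearn.mixture import GaussianMixture

from .errors import (
    EmptyRecordError,
    InsufficientDataError,
    NoSeparationError,
    SingularFitError,
)
from .schemes import (
    OPEN,
    SHUT,
    KineticScheme,
    build_q,
    closed_class_occupancy,
)


@dataclass
class DwellSequence:
    """Alternating open/shut intervals with a recording resolution.

    ``clusters`` marks ``[start, stop)`` index ranges of independent
    stretches (e.g. bursts after removal of long shut periods); classes must
    alternate strictly within each cluster (globally when no clusters are
    set).
    """

    classes: np.ndarray
    durations_ms: np.ndarray
    t_d_ms: float = 0.0
    clusters: list[tuple[int, int]] | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.classes = np.asarray(self.classes, dtype=object)
        self.durations_ms = np.asarray(self.durations_ms, dtype=float)
        if len(self.classes) != len(self.durations_ms):
            raise ValueError("classes and durations differ in length")
        if np.any(self.durations_ms <= 0):
            raise ValueError("all durations must be > 0")
        bad = set(self.classes) - {OPEN, SHUT}
        if bad:
            raise ValueError(f"unknown dwell classes: {bad}")
        for lo, hi in self.cluster_ranges():
            cls = self.classes[lo:hi]
            if np.any(cls[1:] == cls[:-1]):
                raise ValueError("dwell classes must alternate strictly")

    def cluster_ranges(self) -> list[tuple[int, int]]:
        if self.clusters is None:
            return [(0, len(self.classes))] if len(self.classes) else []
        return list(self.clusters)

    def __len__(self) -> int:
        return len(self.classes)

    @property
    def total_duration_ms(self) -> float:
        return float(self.durations_ms.sum())

    def durations_of(self, cls: str) -> np.ndarray:
        return self.durations_ms[self.classes == cls]


# ---------------------------------------------------------------------------
# simulation

def simulate_dwells(scheme: KineticScheme, conc: float, n_events: int,
                    seed: int | np.random.Generator | None = None,
                    start_state: str | None = None) -> DwellSequence:
    """Sample ``n_events`` aggregated dwells by exact CTMC simulation.

    Holding times are exponential with the state's total exit rate;
    consecutive sojourns in states of the same class merge into one dwell.
    The initial state is drawn from the stationary distribution at ``conc``.
    """
    if n_events <= 0:
        raise ValueError("n_events must be > 0")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    q = build_q(scheme, conc)
    qm = q.matrix / 1000.0  # per ms
    exit_rates = -np.diag(qm)
    if np.any(exit_rates <= 0):
        dead = [s for s, r in zip(q.states, exit_rates) if r <= 0]
        raise RuntimeError(f"absorbing state(s) {dead}: simulation would stall")
    jump = qm.copy()
    np.fill_diagonal(jump, 0.0)
    jump /= exit_rates[:, None]
    cum = np.cumsum(jump, axis=1)
    cls_code = np.array(
        [scheme.state_class[s] == OPEN for s in q.states]
    )

    if start_state is not None:
        state = q.states.index(start_state)
    else:
        p0 = closed_class_occupancy(q)
        state = int(rng.choice(q.n, p=p0))

    classes: list[str] = []
    durations: list[float] = []
    cur_open = cls_code[state]
    cur_dur = 0.0
    while len(durations) < n_events:
        cur_dur += rng.exponential(1.0 / exit_rates[state])
        nxt = int(np.searchsorted(cum[state], rng.random()))
        if cls_code[nxt] != cur_open:
            classes.append(OPEN if cur_open else SHUT)
            durations.append(cur_dur)
            cur_dur = 0.0
            cur_open = cls_code[nxt]
        state = nxt
    return DwellSequence(
        classes=np.array(classes, dtype=object),
        durations_ms=np.array(durations),
        t_d_ms=0.0,
        metadata={"scheme": scheme.name, "conc_M": conc, "seed": repr(seed)},
    )


# ---------------------------------------------------------------------------
# resolution

def impose_resolution(seq: DwellSequence, t_d_ms: float) -> DwellSequence:
    """Impose a dead time: dwells shorter than ``t_d_ms`` are unresolved and
    absorbed into the preceding resolved dwell (same-class neighbours then
    re-merge). Total record duration is conserved exactly; the operation is
    idempotent at fixed dead time.
    """
    if t_d_ms < 0:
        raise ValueError("dead time must be >= 0")
    if t_d_ms == 0:
        return seq
    out_classes: list[str] = []
    out_durs: list[float] = []
    new_clusters: list[tuple[int, int]] = []
    for lo, hi in seq.cluster_ranges():
        cls = seq.classes[lo:hi]
        dur = seq.durations_ms[lo:hi]
        resolved = np.nonzero(dur >= t_d_ms)[0]
        if len(resolved) == 0:
            if seq.clusters is None:
                raise EmptyRecordError(
                    f"no dwell survives a {t_d_ms} ms dead time"
                )
            continue  # drop clusters with no resolvable event
        first = resolved[0]
        start_idx = len(out_classes)
        cur_cls = cls[first]
        cur_dur = float(dur[: first + 1].sum())  # leading unresolved absorbed
        for c, d in zip(cls[first + 1:], dur[first + 1:]):
            if d < t_d_ms or c == cur_cls:
                cur_dur += d
            else:
                out_classes.append(cur_cls)
                out_durs.append(cur_dur)
                cur_cls, cur_dur = c, float(d)
        out_classes.append(cur_cls)
        out_durs.append(cur_dur)
        new_clusters.append((start_idx, len(out_classes)))
    if not out_classes:
        raise EmptyRecordError(f"no dwell survives a {t_d_ms} ms dead time")
    return DwellSequence(
        classes=np.array(out_classes, dtype=object),
        durations_ms=np.array(out_durs),
        t_d_ms=t_d_ms,
        clusters=None if seq.clusters is None else new_clusters,
        metadata=dict(seq.metadata),
    )


# ---------------------------------------------------------------------------
# exponential mixtures

@dataclass
class MixtureFit:
    """Exponential mixture fitted to one dwell class.

    ``weights`` are truncation-corrected areas of the full (untruncated)
    components; ``observed_weights`` are the areas within the fitted
    (left-truncated) sample. Components are sorted by ascending tau.
    """

    dwell_class: str
    taus_ms: np.ndarray
    weights: np.ndarray
    observed_weights: np.ndarray
    loglik: float
    t_d_ms: float
    n: int
    selection: list[dict] = field(default_factory=list)

    @property
    def k(self) -> int:
        return len(self.taus_ms)

    def mean_ms(self) -> float:
        return float(np.sum(self.weights * self.taus_ms))

    def to_dict(self) -> dict:
        return {
            "class": self.dwell_class, "k": self.k,
            "tau_ms": [float(t) for t in self.taus_ms],
            "pP": [float(w) for w in self.weights],
            "observed_pP": [float(w) for w in self.observed_weights],
            "loglik": self.loglik, "t_d_ms": self.t_d_ms, "n": self.n,
        }


def _em_exponential(s: np.ndarray, k: int, rng: np.random.Generator,
                    n_restarts: int = 3, max_iter: int = 1000,
                    tol: float = 1e-9) -> tuple[np.ndarray, np.ndarray, float]:
    """EM for a k-component exponential mixture on nonnegative data."""
    n = len(s)
    best = None
    sorted_s = np.sort(s)
    for restart in range(n_restarts):
        if restart == 0:
            # deterministic quantile init
            blocks = np.array_split(sorted_s, k)
            taus = np.array([max(float(b.mean()), 1e-8) for b in blocks])
        else:
            taus = np.exp(rng.uniform(np.log(max(sorted_s[0] + 1e-8, 1e-8)),
                                      np.log(sorted_s[-1] + 1e-8), size=k))
        w = np.full(k, 1.0 / k)
        ll_old = -np.inf
        for _ in range(max_iter):
            with np.errstate(under="ignore"):
                dens = (w / taus)[None, :] * np.exp(-s[:, None] / taus[None, :])
            tot = dens.sum(axis=1)
            tot = np.maximum(tot, 1e-300)
            ll = float(np.log(tot).sum())
            resp = dens / tot[:, None]
            nk = resp.sum(axis=0)
            w = nk / n
            taus = np.maximum((resp * s[:, None]).sum(axis=0)
                              / np.maximum(nk, 1e-300), 1e-8)
            if abs(ll - ll_old) < tol * max(1.0, abs(ll)):
                break
            ll_old = ll
        if best is None or ll > best[2]:
            best = (taus, w, ll)
    return best


def fit_dwell_mixture(durations_ms: np.ndarray, dwell_class: str,
                      k_max: int = 5, t_d_ms: float = 0.0,
                      seed: int = 0, k: int | None = None,
                      min_events: int = 200) -> MixtureFit:
    """Maximum-likelihood exponential-mixture fit of dwell times.

    Left truncation at the dead time is handled exactly: by memorylessness,
    each truncated exponential component is again exponential in
    ``t - t_d``, so EM runs on the shifted data and the full-component
    areas are recovered as ``w_i ~ w_i' * exp(t_d / tau_i)``.

    The number of components is selected by BIC over ``1..k_max`` unless
    ``k`` pins it (the conventional choice of e.g. 4 shut + 2 open
    components can be forced that way).
    """
    d = np.asarray(durations_ms, dtype=float)
    if len(d) < min_events:
        raise InsufficientDataError(
            f"need >= {min_events} dwells, got {len(d)}"
        )
    if np.any(d < t_d_ms - 1e-12):
        raise ValueError("durations below the dead time are not resolvable")
    if np.ptp(d) < 1e-12:
        raise SingularFitError("all durations equal; mixture fit singular")
    s = np.maximum(d - t_d_ms, 0.0)
    rng = np.random.default_rng(seed)
    candidates = [k] if k is not None else list(range(1, k_max + 1))
    selection = []
    best = None
    for kk in candidates:
        taus, w, ll = _em_exponential(s, kk, rng)
        bic = -2.0 * ll + (2 * kk - 1) * np.log(len(s))
        selection.append({"k": kk, "loglik": ll, "bic": bic})
        if best is None or bic < best[3]:
            best = (kk, taus, w, bic, ll)
    kk, taus, w, _, ll = best
    order = np.argsort(taus)
    taus, w = taus[order], w[order]
    with np.errstate(over="ignore"):
        corr = w * np.exp(np.minimum(t_d_ms / taus, 700.0))
    corr = corr / corr.sum()
    return MixtureFit(
        dwell_class=dwell_class, taus_ms=taus, weights=corr,
        observed_weights=w / w.sum(), loglik=ll, t_d_ms=t_d_ms,
        n=len(d), selection=selection,
    )


def mean_open_time(fit: MixtureFit) -> float:
    """Amplitude-weighted mean open time, sum of %P_i * tau_i (ms)."""
    if fit.dwell_class != OPEN:
        raise ValueError("mean_open_time expects an open-class mixture fit")
    return fit.mean_ms()


# ---------------------------------------------------------------------------
# critical time and bursts

def tcrit_between(tau_i: float, p_i: float, tau_j: float, p_j: float
                  ) -> float:
    """Critical time between two exponential components: the t solving
    ``p_i * exp(-t/tau_i) = p_j * (1 - exp(-t/tau_j))`` — equal expected
    numbers of misclassified events on either side."""
    if not tau_i < tau_j:
        raise ValueError("components must satisfy tau_i < tau_j")

    def bal(t):
        return p_i * np.exp(-t / tau_i) - p_j * (1.0 - np.exp(-t / tau_j))

    lo, hi = tau_i, tau_j
    if bal(lo) <= 0 or bal(hi) >= 0:
        raise NoSeparationError(
            f"no misclassification-balance root in ({tau_i}, {tau_j}); "
            "components overlap too much"
        )
    return float(brentq(bal, lo, hi, xtol=1e-12, rtol=1e-12))


def compute_tcrit(shut_fit: MixtureFit, i: int, j: int) -> float:
    """Critical time between adjacent components ``i`` and ``j`` (0-based)
    of a shut-time mixture fit."""
    if shut_fit.dwell_class != SHUT:
        raise ValueError("t_crit is defined on a shut-time mixture")
    if not (0 <= i < j < shut_fit.k and j == i + 1):
        raise ValueError("i, j must be adjacent component indices")
    return tcrit_between(shut_fit.taus_ms[i], shut_fit.weights[i],
                         shut_fit.taus_ms[j], shut_fit.weights[j])


def default_tcrit_components(k: int) -> tuple[int, int]:
    """Conventional component pair: between the 3rd and 4th shut components
    for 4-component distributions, 2nd and 3rd for 3-component ones."""
    if k >= 4:
        return (2, 3)
    if k == 3:
        return (1, 2)
    return (0, 1)


@dataclass
class BurstStats:
    t_crit_ms: float
    lengths_ms: np.ndarray
    popens: np.ndarray
    event_counts: np.ndarray
    burst_ranges: list[tuple[int, int]]
    interburst_shut_ms: float

    @property
    def n_bursts(self) -> int:
        return len(self.lengths_ms)

    def _mean_sem(self, x):
        if len(x) == 0:
            return (np.nan, np.nan)
        sem = float(np.std(x, ddof=1) / np.sqrt(len(x))) if len(x) > 1 else np.nan
        return (float(np.mean(x)), sem)

    @property
    def mean_length_ms(self):
        return self._mean_sem(self.lengths_ms)

    @property
    def mean_popen(self):
        return self._mean_sem(self.popens)

    def to_dict(self) -> dict:
        ml, sl = self.mean_length_ms
        mp, sp = self.mean_popen
        return {
            "t_crit_ms": self.t_crit_ms, "n_bursts": self.n_bursts,
            "mean_length_ms": ml, "sem_length_ms": sl,
            "mean_popen": mp, "sem_popen": sp,
        }


def segment_bursts(seq: DwellSequence, t_crit_ms: float) -> BurstStats:
    """Partition the record into bursts delimited by shut dwells longer than
    ``t_crit_ms``. Bursts start and end with openings; burst length includes
    intra-burst shut dwells; single-opening bursts are retained. Shut time
    outside bursts (delimiters and trimmed edges) is accounted as
    inter-burst time, so bursts plus inter-burst shut time tile the record.
    """
    if t_crit_ms <= seq.t_d_ms:
        raise ValueError("t_crit must exceed the dead time")
    is_delim = (seq.classes == SHUT) & (seq.durations_ms > t_crit_ms)
    interburst = float(seq.durations_ms[is_delim].sum())
    lengths, popens, counts, ranges = [], [], [], []
    bounds = np.nonzero(is_delim)[0]
    starts = np.concatenate([[0], bounds + 1])
    stops = np.concatenate([bounds, [len(seq)]])
    for lo, hi in zip(starts, stops):
        if hi <= lo:
            continue
        cls = seq.classes[lo:hi]
        open_idx = np.nonzero(cls == OPEN)[0]
        if len(open_idx) == 0:
            interburst += float(seq.durations_ms[lo:hi].sum())
            continue
        a, b = lo + open_idx[0], lo + open_idx[-1] + 1
        # edge shut dwells <= t_crit trimmed off the burst are inter-burst
        interburst += float(seq.durations_ms[lo:a].sum())
        interburst += float(seq.durations_ms[b:hi].sum())
        dur = seq.durations_ms[a:b]
        cls = seq.classes[a:b]
        total = float(dur.sum())
        open_time = float(dur[cls == OPEN].sum())
        lengths.append(total)
        popens.append(open_time / total)
        counts.append(b - a)
        ranges.append((a, b))
    return BurstStats(
        t_crit_ms=t_crit_ms,
        lengths_ms=np.array(lengths),
        popens=np.array(popens),
        event_counts=np.array(counts),
        burst_ranges=ranges,
        interburst_shut_ms=interburst,
    )


# ---------------------------------------------------------------------------
# activity modes

@dataclass
class ModeAssignment:
    labels: np.ndarray
    means: np.ndarray
    sems: np.ndarray
    shares: np.ndarray
    predominant: int
    log: str = ""

    @property
    def k(self) -> int:
        return len(self.means)

    def to_dict(self) -> dict:
        return {
            "k": self.k,
            "modes": [
                {"popen_mean": float(m), "popen_sem": float(s),
                 "share": float(w), "predominant": i == self.predominant}
                for i, (m, s, w) in enumerate(
                    zip(self.means, self.sems, self.shares))
            ],
            "log": self.log,
        }


def select_predominant_mode(cluster_popen: np.ndarray, k_max: int = 3,
                            seed: int = 0) -> ModeAssignment:
    """Cluster per-cluster open probabilities into activity modes.

    One-dimensional Gaussian mixture, the number of modes chosen by BIC up
    to ``k_max``; the predominant mode is the one holding the largest share
    of clusters (ties broken toward the higher open probability).
    """
    x = np.asarray(cluster_popen, dtype=float).reshape(-1, 1)
    if len(x) < 3:
        raise InsufficientDataError("need >= 3 clusters for mode analysis")
    log = ""
    if k_max > len(x):
        warnings.warn(f"only {len(x)} clusters; reducing k_max from {k_max}")
        log += f"k_max reduced to {len(x)}; "
        k_max = len(x)
    if np.ptp(x) < 0.02:  # all clusters effectively at one level
        labels = np.zeros(len(x), dtype=int)
        return ModeAssignment(
            labels=labels, means=np.array([float(x.mean())]),
            sems=np.array([float(x.std(ddof=1) / np.sqrt(len(x)))
                           if len(x) > 1 else np.nan]),
            shares=np.array([1.0]), predominant=0,
            log=log + "spread < 0.02: single mode",
        )
    best = None
    for kk in range(1, k_max + 1):
        gm = GaussianMixture(n_components=kk, random_state=seed, n_init=5,
                             reg_covar=1e-6)
        gm.fit(x)
        bic = gm.bic(x)
        if best is None or bic < best[1]:
            best = (gm, bic, kk)
    gm = best[0]
    labels = gm.predict(x)
    means, sems, shares = [], [], []
    for m in range(gm.n_components):
        vals = x[labels == m, 0]
        means.append(float(vals.mean()) if len(vals) else float(gm.means_[m, 0]))
        sems.append(float(vals.std(ddof=1) / np.sqrt(len(vals)))
                    if len(vals) > 1 else np.nan)
        shares.append(len(vals) / len(x))
    means, sems, shares = map(np.array, (means, sems, shares))
    top = shares.max()
    tied = np.nonzero(np.isclose(shares, top))[0]
    predominant = int(tied[np.argmax(means[tied])])
    if len(tied) > 1:
        log += ("equal-share modes; tie broken toward higher P_open "
                f"(mode {predominant}); ")
    return ModeAssignment(labels=labels, means=means, sems=sems,
                          shares=shares, predominant=predominant, log=log)


# ---------------------------------------------------------------------------
# filter composition

@dataclass
class ResolutionSpec:
    """Recording bandwidth: analogue (fa) and digital (fd) low-pass cutoffs
    compose into the final cutoff fc = (fa^-2 + fd^-2)^(-1/2); sampling runs
    at fs = 10 * fc. All frequencies in kHz; dead time in microseconds."""

    fa_khz: float
    fd_khz: float = np.inf
    t_d_us: float = 0.0

    @property
    def fc_khz(self) -> float:
        return effective_cutoff(self)

    @property
    def fs_khz(self) -> float:
        return 10.0 * self.fc_khz


def effective_cutoff(spec: ResolutionSpec) -> float:
    """Final cutoff (kHz) of cascaded analogue and digital filters."""
    fa, fd = spec.fa_khz, spec.fd_khz
    if fa <= 0 or fd <= 0:
        raise ValueError("filter cutoffs must be > 0")
    if np.isinf(fd):
        return float(fa)
    if np.isinf(fa):
        return float(fd)
    return float((fa ** -2 + fd ** -2) ** -0.5)
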