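"""Aggregated Markov kinetic schemes and their generator (Q) matrices.

A kinetic scheme is a reversible, connected graph of receptor states, each
labelled ``open`` or ``shut``, with named rate constants on its edges.
Agonist-binding edges scale with the agonist concentration and may carry a
stoichiometric multiplier (two equivalent binding sites give ``2*k_on`` for
the first binding and ``2*k_off`` for unbinding from the doubly bound state).

The builtin schemes cover the standard two-site flipped Jones-Westbrook
topology used for GABA_A receptor gating — a preactivated ("flipped") shut
state A2F interposed between full binding and opening, with desensitized
state(s) branching off A2F — plus the stationary single-channel variants
(binding steps omitted at saturating agonist) and the flipped linear model
in which desensitization is entered from the open state.

Rate units: binding rates in M^-1 s^-1, all other rates in s^-1;
concentrations in molar.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import yaml
from scipy.sparse.csgraph import connected_components

from .errors import (
    ReducibleChainError,
    SchemeNotFoundError,
    SchemeValidationError,
    UnresolvedRateError,
)

OPEN = "open"
SHUT = "shut"

#: Placeholder rate values (s^-1; binding in M^-1 s^-1). These are NOT
#: experimentally fitted values — they are round numbers of realistic order
#: used to make builtin schemes runnable out of the box. Every fitting test
#: and example generates its own ground truth.
PLACEHOLDER_RATES = {
    "kon": 8.0e6,
    "koff": 2000.0,
    "delta2": 1500.0,
    "gamma2": 300.0,
    "beta2": 2500.0,
    "alpha2": 1100.0,
    "beta2p": 150.0,
    "alpha2p": 2500.0,
    "d2": 400.0,
    "r2": 20.0,
    "d2p": 15.0,
    "r2p": 2.0,
}

BUILTIN_SCHEMES = ("fJWM", "fJWM_2D", "sc_full", "sc_oneD", "sc_noD", "fLM")


@dataclass(frozen=True)
class Edge:
    """One directed transition: ``source -> target`` at ``mult * rate`` (times
    concentration if ``conc_dep``)."""

    source: str
    target: str
    rate: str
    conc_dep: bool = False
    mult: float = 1.0


@dataclass
class KineticScheme:
    name: str
    states: list[str]
    state_class: dict[str, str]
    edges: list[Edge]
    rates: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        self.validate()

    # -- structure ---------------------------------------------------------
    def validate(self) -> None:
        if len(set(self.states)) != len(self.states):
            raise SchemeValidationError(f"{self.name}: duplicate state labels")
        for s in self.states:
            if self.state_class.get(s) not in (OPEN, SHUT):
                raise SchemeValidationError(
                    f"{self.name}: state {s!r} must be classed open or shut"
                )
        classes = set(self.state_class[s] for s in self.states)
        if classes != {OPEN, SHUT}:
            raise SchemeValidationError(
                f"{self.name}: need at least one open and one shut state"
            )
        pairs = {(e.source, e.target) for e in self.edges}
        for e in self.edges:
            if e.source not in self.states or e.target not in self.states:
                raise SchemeValidationError(
                    f"{self.name}: edge {e.source}->{e.target} uses unknown state"
                )
            if e.source == e.target:
                raise SchemeValidationError(f"{self.name}: self-loop on {e.source}")
            if (e.target, e.source) not in pairs:
                raise SchemeValidationError(
                    f"{self.name}: edge {e.source}->{e.target} has no reverse edge"
                )
            if e.mult <= 0:
                raise SchemeValidationError(
                    f"{self.name}: nonpositive multiplier on {e.source}->{e.target}"
                )
        for name, value in self.rates.items():
            if value < 0:
                raise SchemeValidationError(f"{self.name}: rate {name} < 0")
        # undirected connectivity
        idx = {s: i for i, s in enumerate(self.states)}
        n = len(self.states)
        adj = np.zeros((n, n), bool)
        for e in self.edges:
            adj[idx[e.source], idx[e.target]] = True
            adj[idx[e.target], idx[e.source]] = True
        ncomp, _ = connected_components(adj, directed=False)
        if ncomp != 1:
            raise SchemeValidationError(f"{self.name}: state graph is not connected")

    @property
    def open_states(self) -> list[str]:
        return [s for s in self.states if self.state_class[s] == OPEN]

    @property
    def shut_states(self) -> list[str]:
        return [s for s in self.states if self.state_class[s] == SHUT]

    @property
    def n_states(self) -> int:
        return len(self.states)

    def undirected_edges(self) -> list[tuple[str, str]]:
        """The reversible connections, each counted once."""
        seen = set()
        out = []
        for e in self.edges:
            key = frozenset((e.source, e.target))
            if key not in seen:
                seen.add(key)
                out.append((e.source, e.target))
        return out

    def is_tree(self) -> bool:
        return len(self.undirected_edges()) == self.n_states - 1

    def with_rates(self, updates: dict[str, float]) -> "KineticScheme":
        """Return a copy with some rate values replaced."""
        rates = dict(self.rates)
        rates.update(updates)
        return replace(self, rates=rates)

    def rate_names(self) -> list[str]:
        seen = []
        for e in self.edges:
            if e.rate not in seen:
                seen.append(e.rate)
        return seen

    # -- config round trip -------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "states": list(self.states),
            "classes": {s: self.state_class[s] for s in self.states},
            "edges": [
                {
                    "from": e.source,
                    "to": e.target,
                    "rate": e.rate,
                    "conc_dep": e.conc_dep,
                    "mult": e.mult,
                }
                for e in self.edges
            ],
            "rates": dict(self.rates),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "KineticScheme":
        return cls(
            name=d["name"],
            states=list(d["states"]),
            state_class=dict(d["classes"]),
            edges=[
                Edge(
                    source=e["from"],
                    target=e["to"],
                    rate=e["rate"],
                    conc_dep=bool(e.get("conc_dep", False)),
                    mult=float(e.get("mult", 1.0)),
                )
                for e in d["edges"]
            ],
            rates={k: float(v) for k, v in d.get("rates", {}).items()},
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def load(cls, path: str | Path) -> "KineticScheme":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


@dataclass
class QMatrix:
    """Generator matrix of a scheme at a fixed agonist concentration.

    Off-diagonal entry (i, j) is the transition intensity i -> j in s^-1;
    diagonals are set so every row sums to zero.
    """

    matrix: np.ndarray
    states: list[str]
    state_class: dict[str, str]
    conc: float

    @property
    def n(self) -> int:
        return len(self.states)

    def class_indices(self, cls: str) -> np.ndarray:
        return np.array(
            [i for i, s in enumerate(self.states) if self.state_class[s] == cls],
            dtype=int,
        )

    def submatrix(self, cls_from: str, cls_to: str) -> np.ndarray:
        i = self.class_indices(cls_from)
        j = self.class_indices(cls_to)
        return self.matrix[np.ix_(i, j)]


def _pair_edges(spec: list[tuple[str, str, str, str]], conc_dep_rates=(),
                mults=None) -> list[Edge]:
    """Expand (a, b, fwd_rate, back_rate) tuples into directed Edge pairs."""
    mults = mults or {}
    edges = []
    for a, b, fwd, back in spec:
        edges.append(
            Edge(a, b, fwd, conc_dep=fwd in conc_dep_rates,
                 mult=mults.get((a, b), 1.0))
        )
        edges.append(
            Edge(b, a, back, conc_dep=back in conc_dep_rates,
                 mult=mults.get((b, a), 1.0))
        )
    return edges


def make_builtin_scheme(
    which: str,
    rates: dict[str, float] | None = None,
    d2p_attach: str = "A2F",
    o2p_attach: str = "A2F",
) -> KineticScheme:
    """Construct one of the builtin gating schemes.

    Parameters
    ----------
    which
        One of ``fJWM`` (two-site binding, flip, one open + one desensitized
        state branching from the flipped state), ``fJWM_2D`` (adds a second
        desensitized state), ``sc_full`` (stationary scheme: two open and two
        desensitized states around A2R<->A2F), ``sc_oneD`` (one desensitized
        state), ``sc_noD`` (no desensitization), ``fLM`` (linear scheme with
        desensitization entered from the open state).
    rates
        Rate values to use; defaults to :data:`PLACEHOLDER_RATES` (not
        experimental values).
    d2p_attach, o2p_attach
        Attachment state of the second desensitized (A2D') and second open
        (A2O') states; the published scheme drawings do not fix these, so the
        default is the star topology around A2F, configurable to ``"A2D"`` /
        ``"A2O"`` respectively.
    """
    if which not in BUILTIN_SCHEMES:
        raise SchemeNotFoundError(
            f"unknown scheme {which!r}; choose from {BUILTIN_SCHEMES}"
        )
    r = dict(PLACEHOLDER_RATES)
    if rates:
        r.update(rates)

    binding_states = ["R", "AR", "A2R"]
    binding_pairs = [("R", "AR", "kon", "koff"), ("AR", "A2R", "kon", "koff")]
    # two equivalent sites: 2*kon for the first binding, 2*koff for the
    # first unbinding from the doubly bound state
    binding_mults = {("R", "AR"): 2.0, ("A2R", "AR"): 2.0}

    if which in ("fJWM", "fJWM_2D"):
        states = binding_states + ["A2F", "A2O", "A2D"]
        pairs = binding_pairs + [
            ("A2R", "A2F", "delta2", "gamma2"),
            ("A2F", "A2O", "beta2", "alpha2"),
            ("A2F", "A2D", "d2", "r2"),
        ]
        open_states = {"A2O"}
        if which == "fJWM_2D":
            states = states + ["A2D'"]
            pairs = pairs + [(d2p_attach, "A2D'", "d2p", "r2p")]
    elif which in ("sc_full", "sc_oneD", "sc_noD"):
        states = ["A2R", "A2F", "A2O", "A2O'"]
        pairs = [
            ("A2R", "A2F", "delta2", "gamma2"),
            ("A2F", "A2O", "beta2", "alpha2"),
            (o2p_attach, "A2O'", "beta2p", "alpha2p"),
        ]
        open_states = {"A2O", "A2O'"}
        if which in ("sc_full", "sc_oneD"):
            states = states + ["A2D"]
            pairs = pairs + [("A2F", "A2D", "d2", "r2")]
        if which == "sc_full":
            states = states + ["A2D'"]
            pairs = pairs + [(d2p_attach, "A2D'", "d2p", "r2p")]
    else:  # fLM: desensitization from the open state
        states = binding_states + ["A2F", "A2O", "A2D"]
        pairs = binding_pairs + [
            ("A2R", "A2F", "delta2", "gamma2"),
            ("A2F", "A2O", "beta2", "alpha2"),
            ("A2O", "A2D", "d2", "r2"),
        ]
        open_states = {"A2O"}

    used = {rate for p in pairs for rate in p[2:]}
    edges = _pair_edges(pairs, conc_dep_rates={"kon"}, mults=binding_mults)
    return KineticScheme(
        name=which,
        states=states,
        state_class={s: (OPEN if s in open_states else SHUT) for s in states},
        edges=edges,
        rates={k: v for k, v in r.items() if k in used},
    )


def build_q(scheme: KineticScheme, conc: float) -> QMatrix:
    """Build the generator matrix of ``scheme`` at agonist concentration
    ``conc`` (molar)."""
    if conc < 0:
        raise ValueError(f"concentration must be >= 0, got {conc}")
    idx = {s: i for i, s in enumerate(scheme.states)}
    n = scheme.n_states
    q = np.zeros((n, n))
    for e in scheme.edges:
        if e.rate not in scheme.rates:
            raise UnresolvedRateError(
                f"{scheme.name}: no value for rate {e.rate!r}"
            )
        v = scheme.rates[e.rate] * e.mult
        if e.conc_dep:
            v *= conc
        q[idx[e.source], idx[e.target]] += v
    np.fill_diagonal(q, 0.0)
    np.fill_diagonal(q, -q.sum(axis=1))
    return QMatrix(matrix=q, states=list(scheme.states),
                   state_class=dict(scheme.state_class), conc=conc)


def _strong_components(q: QMatrix) -> list[list[str]]:
    adj = (q.matrix > 0).astype(np.int8)
    ncomp, labels = connected_components(adj, directed=True, connection="strong")
    return [
        [s for s, l in zip(q.states, labels) if l == c] for c in range(ncomp)
    ]


def equilibrium_occupancy(q: QMatrix) -> np.ndarray:
    """Stationary distribution p with pQ = 0 and sum(p) = 1.

    Raises :class:`ReducibleChainError` if the chain is not irreducible at
    this concentration (e.g. binding edges vanish at zero agonist), naming
    the disconnected blocks.
    """
    blocks = _strong_components(q)
    if len(blocks) > 1:
        raise ReducibleChainError(
            f"chain reducible at conc={q.conc:g} M; "
            f"strongly connected blocks: {blocks}",
            blocks=blocks,
        )
    a = np.vstack([q.matrix.T, np.ones(q.n)])
    b = np.zeros(q.n + 1)
    b[-1] = 1.0
    p, *_ = np.linalg.lstsq(a, b, rcond=None)
    p = np.clip(p, 0.0, None)
    return p / p.sum()


def closed_class_occupancy(q: QMatrix) -> np.ndarray:
    """Stationary distribution allowing reducible chains with one closed
    communicating class (mass confined to that class).

    Used for initial conditions, e.g. pre-application equilibrium at zero
    agonist where bound states are unreachable.
    """
    blocks = _strong_components(q)
    if len(blocks) == 1:
        return equilibrium_occupancy(q)
    idx = {s: i for i, s in enumerate(q.states)}
    closed = []
    for block in blocks:
        rows = [idx[s] for s in block]
        outside = np.setdiff1d(np.arange(q.n), rows)
        if q.matrix[np.ix_(rows, outside)].sum() <= 0:
            closed.append(block)
    if len(closed) != 1:
        raise ReducibleChainError(
            f"no unique closed class at conc={q.conc:g} M; closed: {closed}",
            blocks=blocks,
        )
    rows = np.array([idx[s] for s in closed[0]])
    sub = q.matrix[np.ix_(rows, rows)]
    # renormalize diagonal within the class (exit rates are zero anyway)
    sub = sub.copy()
    np.fill_diagonal(sub, 0.0)
    np.fill_diagonal(sub, -sub.sum(axis=1))
    a = np.vstack([sub.T, np.ones(len(rows))])
    b = np.zeros(len(rows) + 1)
    b[-1] = 1.0
    psub, *_ = np.linalg.lstsq(a, b, rcond=None)
    p = np.zeros(q.n)
    p[rows] = np.clip(psub, 0.0, None)
    return p / p.sum()


def detailed_balance_report(scheme: KineticScheme, conc: float = 1.0) -> dict:
    """Report cycle products for every independent cycle of the scheme.

    Tree-topology schemes (all builtins) have no cycles and are therefore
    automatically in detailed balance; the report then contains an empty
    cycle list.
    """
    import networkx as nx  # optional convenience; networkx ships with scipy stacks

    q = build_q(scheme, conc)
    g = nx.Graph()
    g.add_edges_from(scheme.undirected_edges())
    cycles = nx.cycle_basis(g)
    idx = {s: i for i, s in enumerate(scheme.states)}
    report = {"is_tree": scheme.is_tree(), "cycles": []}
    for cyc in cycles:
        fwd = back = 1.0
        for a, b in zip(cyc, cyc[1:] + cyc[:1]):
            fwd *= q.matrix[idx[a], idx[b]]
            back *= q.matrix[idx[b], idx[a]]
        report["cycles"].append(
            {"states": cyc, "forward_product": fwd, "backward_product": back,
             "balanced": np.isclose(fwd, back, rtol=1e-9)}
        )
    return report
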