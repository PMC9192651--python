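"""Minimal discrete Bayesian-network engine.

A network is a DAG over categorical nodes with one conditional probability
table (CPT) per node.  The module provides structure validation, CPT
estimation from a labelled cohort, exact inference by enumeration and by
variable elimination, ancestral sampling, and JSON (de)serialization.

Inference semantics: evidence maps nodes to observed states; a node mapped
to :data:`NEUTRAL` (or simply absent from the evidence) is marginalized.
Evidence with zero probability raises :class:`ImpossibleEvidenceError`
rather than propagating NaNs.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence, Union

import networkx as nx
import numpy as np


class _Neutral:
    """Sentinel marking a node as unobserved (marginalized) in evidence."""

    _instance = None

    def __new__(cls):
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __repr__(self) -> str:
        return "NEUTRAL"


NEUTRAL = _Neutral()

Evidence = Mapping[str, Union[str, _Neutral]]


class NetworkError(ValueError):
    pass


class ImpossibleEvidenceError(ValueError):
    """The supplied evidence has probability zero under the network."""


@dataclass(frozen=True)
class NetworkSpec:
    """Node state spaces plus directed edges; node order is declaration order."""

    nodes: tuple[tuple[str, tuple[str, ...]], ...]
    edges: tuple[tuple[str, str], ...]

    @classmethod
    def from_dicts(cls, nodes: Iterable[dict], edges: Iterable[Sequence[str]]) -> "NetworkSpec":
        return cls(tuple((n["name"], tuple(n["states"])) for n in nodes),
                   tuple((p, c) for p, c in edges))

    @property
    def node_names(self) -> tuple[str, ...]:
        return tuple(n for n, _ in self.nodes)

    def states(self, node: str) -> tuple[str, ...]:
        for n, s in self.nodes:
            if n == node:
                return s
        raise NetworkError(f"undeclared node {node!r}")

    def parents(self, node: str) -> tuple[str, ...]:
        # deterministic parent order: node declaration order
        order = {n: i for i, n in enumerate(self.node_names)}
        ps = [p for p, c in self.edges if c == node]
        return tuple(sorted(ps, key=order.__getitem__))

    def validate(self) -> list[str]:
        """Return a list of violations; empty means valid."""
        problems = []
        names = self.node_names
        if len(set(names)) != len(names):
            problems.append("duplicate node names")
        for n, s in self.nodes:
            if not s:
                problems.append(f"node {n!r}: empty state set")
            if len(set(s)) != len(s):
                problems.append(f"node {n!r}: duplicate states")
        declared = set(names)
        for p, c in self.edges:
            for end in (p, c):
                if end not in declared:
                    problems.append(f"edge ({p!r}, {c!r}): undeclared node {end!r}")
        g = nx.DiGraph()
        g.add_nodes_from(names)
        g.add_edges_from(e for e in self.edges if set(e) <= declared)
        if not nx.is_directed_acyclic_graph(g):
            cycle = nx.find_cycle(g)
            problems.append(f"cycle: {' -> '.join(str(e[0]) for e in cycle)}")
        return problems

    def topological_order(self) -> list[str]:
        g = nx.DiGraph()
        g.add_nodes_from(self.node_names)
        g.add_edges_from(self.edges)
        order = {n: i for i, n in enumerate(self.node_names)}
        return list(nx.lexicographical_topological_sort(g, key=order.__getitem__))


def validate_network(spec: NetworkSpec) -> list[str]:
    return spec.validate()


@dataclass
class Cpt:
    """P(node | parents): one probability row per parent-state combination."""

    node: str
    parents: tuple[str, ...]
    states: tuple[str, ...]
    parent_states: tuple[tuple[str, ...], ...]
    #: array of shape (*len(parent_states_i), len(states))
    values: np.ndarray

    def __post_init__(self) -> None:
        expected = tuple(len(ps) for ps in self.parent_states) + (len(self.states),)
        if self.values.shape != expected:
            raise NetworkError(
                f"CPT {self.node!r}: shape {self.values.shape} != {expected}")
        if np.any(self.values < -1e-12) or np.any(self.values > 1 + 1e-12):
            raise NetworkError(f"CPT {self.node!r}: probabilities outside [0, 1]")
        rows = self.values.reshape(-1, len(self.states))
        if not np.allclose(rows.sum(axis=1), 1.0, atol=1e-9):
            raise NetworkError(f"CPT {self.node!r}: rows do not sum to 1")

    def prob(self, state: str, parent_assignment: Mapping[str, str]) -> float:
        idx = tuple(self.parent_states[i].index(parent_assignment[p])
                    for i, p in enumerate(self.parents))
        return float(self.values[idx + (self.states.index(state),)])


@dataclass
class BayesNet:
    spec: NetworkSpec
    cpts: dict[str, Cpt]

    def __post_init__(self) -> None:
        problems = self.spec.validate()
        if problems:
            raise NetworkError("; ".join(problems))
        for name in self.spec.node_names:
            if name not in self.cpts:
                raise NetworkError(f"missing CPT for node {name!r}")
            cpt = self.cpts[name]
            if cpt.parents != self.spec.parents(name):
                raise NetworkError(
                    f"CPT {name!r}: parents {cpt.parents} != graph parents "
                    f"{self.spec.parents(name)}")

    def joint_probability(self, assignment: Mapping[str, str]) -> float:
        """Chain-rule joint probability of a full assignment."""
        missing = set(self.spec.node_names) - set(assignment)
        if missing:
            raise NetworkError(f"assignment missing nodes {sorted(missing)}")
        p = 1.0
        for name in self.spec.node_names:
            p *= self.cpts[name].prob(assignment[name], assignment)
        return p

    # --- serialization -------------------------------------------------
    def to_json(self) -> str:
        doc = {
            "schema_version": 1,
            "nodes": [{"name": n, "states": list(s)} for n, s in self.spec.nodes],
            "edges": [list(e) for e in self.spec.edges],
            "cpts": {
                name: {
                    "parents": list(c.parents),
                    "values": c.values.tolist(),
                }
                for name, c in self.cpts.items()
            },
        }
        return json.dumps(doc, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "BayesNet":
        doc = json.loads(text)
        spec = NetworkSpec.from_dicts(doc["nodes"], doc["edges"])
        cpts = {}
        for name, c in doc["cpts"].items():
            parents = tuple(c["parents"])
            cpts[name] = Cpt(
                node=name, parents=parents, states=spec.states(name),
                parent_states=tuple(spec.states(p) for p in parents),
                values=np.asarray(c["values"], dtype=float),
            )
        return cls(spec, cpts)


def _normalize_evidence(evidence: Evidence) -> dict[str, str]:
    return {k: v for k, v in evidence.items() if v is not NEUTRAL}


def posterior_enumeration(net: BayesNet, query: str, evidence: Evidence) -> dict[str, float]:
    """Exact posterior over ``query`` by brute-force summation of the joint.

    Reference implementation; exponential in the number of unobserved nodes.
    """
    ev = _normalize_evidence(evidence)
    if query in ev:
        raise NetworkError(f"query node {query!r} appears in evidence")
    for node, state in ev.items():
        if state not in net.spec.states(node):
            raise NetworkError(f"evidence {node!r}={state!r}: undeclared state")
    hidden = [n for n in net.spec.node_names if n != query and n not in ev]
    scores = {}
    for qstate in net.spec.states(query):
        total = 0.0
        for combo in itertools.product(*(net.spec.states(h) for h in hidden)):
            assignment = dict(ev)
            assignment[query] = qstate
            assignment.update(zip(hidden, combo))
            total += net.joint_probability(assignment)
        scores[qstate] = total
    z = sum(scores.values())
    if z <= 0.0:
        raise ImpossibleEvidenceError(f"evidence {ev} has probability 0")
    return {s: v / z for s, v in scores.items()}


# --- variable elimination ----------------------------------------------

@dataclass
class _Factor:
    vars: tuple[str, ...]
    cards: tuple[int, ...]
    values: np.ndarray  # shape == cards


def _cpt_factor(net: BayesNet, node: str) -> _Factor:
    cpt = net.cpts[node]
    vars_ = cpt.parents + (node,)
    cards = tuple(len(net.spec.states(v)) for v in vars_)
    return _Factor(vars_, cards, cpt.values.copy())


def _reduce(f: _Factor, node: str, state_idx: int) -> _Factor:
    ax = f.vars.index(node)
    vals = np.take(f.values, state_idx, axis=ax)
    vars_ = f.vars[:ax] + f.vars[ax + 1:]
    cards = f.cards[:ax] + f.cards[ax + 1:]
    return _Factor(vars_, cards, vals)


def _multiply(a: _Factor, b: _Factor) -> _Factor:
    vars_ = a.vars + tuple(v for v in b.vars if v not in a.vars)
    cards = a.cards + tuple(c for v, c in zip(b.vars, b.cards) if v not in a.vars)
    idx = {v: i for i, v in enumerate(vars_)}

    def expand(f: _Factor) -> np.ndarray:
        shape = [1] * len(vars_)
        perm = sorted(range(len(f.vars)), key=lambda i: idx[f.vars[i]])
        vals = np.transpose(f.values, perm)
        for i, v in enumerate(sorted(f.vars, key=idx.__getitem__)):
            shape[idx[v]] = f.cards[f.vars.index(v)]
        return vals.reshape(shape)

    return _Factor(vars_, cards, expand(a) * expand(b))


def _sum_out(f: _Factor, node: str) -> _Factor:
    ax = f.vars.index(node)
    return _Factor(f.vars[:ax] + f.vars[ax + 1:],
                   f.cards[:ax] + f.cards[ax + 1:],
                   f.values.sum(axis=ax))


def posterior_ve(net: BayesNet, query: str, evidence: Evidence) -> dict[str, float]:
    """Exact posterior over ``query`` by variable elimination.

    Agrees with :func:`posterior_enumeration` to numerical precision; scales
    to the shipped diagnostic networks with many neutral nodes.
    """
    ev = _normalize_evidence(evidence)
    if query in ev:
        raise NetworkError(f"query node {query!r} appears in evidence")
    factors = []
    for node in net.spec.node_names:
        f = _cpt_factor(net, node)
        for evnode, state in ev.items():
            if evnode in f.vars:
                states = net.spec.states(evnode)
                if state not in states:
                    raise NetworkError(f"evidence {evnode!r}={state!r}: undeclared state")
                f = _reduce(f, evnode, states.index(state))
        factors.append(f)

    hidden = [n for n in net.spec.node_names if n != query and n not in ev]
    # greedy min-size elimination order
    while hidden:
        def cost(h: str) -> int:
            vs: set[str] = set()
            for f in factors:
                if h in f.vars:
                    vs |= set(f.vars)
            vs.discard(h)
            size = 1
            for v in vs:
                size *= len(net.spec.states(v))
            return size

        h = min(hidden, key=lambda n: (cost(n), hidden.index(n)))
        hidden.remove(h)
        related = [f for f in factors if h in f.vars]
        factors = [f for f in factors if h not in f.vars]
        if not related:
            continue
        prod = related[0]
        for f in related[1:]:
            prod = _multiply(prod, f)
        factors.append(_sum_out(prod, h))

    result = _Factor((), (), np.array(1.0))
    for f in factors:
        result = _multiply(result, f)
    if result.vars != (query,):
        # disconnected scalar factors broadcast in; reorder if needed
        ax = result.vars.index(query)
        vals = np.moveaxis(result.values, ax, -1).reshape(-1, len(net.spec.states(query))).sum(axis=0)
    else:
        vals = result.values
    z = float(vals.sum())
    if z <= 0.0:
        raise ImpossibleEvidenceError(f"evidence {ev} has probability 0")
    probs = vals / z
    return dict(zip(net.spec.states(query), probs.tolist()))


# --- estimation ---------------------------------------------------------

def estimate_cpts(spec: NetworkSpec, cohort, *, alpha: float = 0.0,
                  unknown_policy: str = "as_state",
                  label_map: Optional[Mapping[str, str]] = None) -> BayesNet:
    """Estimate one CPT per node from a labelled cohort.

    Each CPT row is ``(count + alpha) / (row_total + alpha * n_states)``,
    counted over records where the node and all of its parents take a
    declared state.  Under ``unknown_policy="as_state"`` the literal
    ``unknown`` (and structural ``NA``) must be declared states to be
    counted; under ``"exclude"`` records carrying them are dropped for the
    CPTs they touch.  Rows with zero total become uniform.

    ``label_map`` optionally recodes the record's diagnosis label onto the
    outcome node's state space (e.g. the SIDS / non-SIDS collapse).
    """
    if unknown_policy not in ("as_state", "exclude"):
        raise ValueError(f"unknown_policy must be 'as_state' or 'exclude', got {unknown_policy!r}")
    if alpha < 0:
        raise ValueError("alpha must be >= 0")
    problems = spec.validate()
    if problems:
        raise NetworkError("; ".join(problems))

    known = set(cohort.factor_names) | {"diagnosis"}
    for name in spec.node_names:
        if name not in known:
            raise NetworkError(f"node {name!r} has no cohort variable")

    def value(rec, node: str) -> Optional[str]:
        v = rec.value(node)
        if node == "diagnosis" and label_map is not None:
            v = label_map.get(v, v)
        states = spec.states(node)
        if v in states:
            return v
        if v in ("unknown", "NA"):
            if unknown_policy == "exclude":
                return None
            raise NetworkError(
                f"node {node!r}: value {v!r} not a declared state under as_state policy")
        raise NetworkError(f"node {node!r}: undeclared cohort value {v!r}")

    cpts = {}
    for node in spec.node_names:
        parents = spec.parents(node)
        states = spec.states(node)
        parent_states = tuple(spec.states(p) for p in parents)
        shape = tuple(len(ps) for ps in parent_states) + (len(states),)
        counts = np.zeros(shape)
        for rec in cohort:
            vals = [value(rec, p) for p in parents] + [value(rec, node)]
            if any(v is None for v in vals):
                continue
            idx = tuple(ps.index(v) for ps, v in zip(parent_states + (states,), vals))
            counts[idx] += 1
        rows = counts.reshape(-1, len(states))
        out = np.empty_like(rows)
        for i, row in enumerate(rows):
            total = row.sum() + alpha * len(states)
            if total == 0:
                out[i] = 1.0 / len(states)
            else:
                out[i] = (row + alpha) / total
        cpts[node] = Cpt(node, parents, states, parent_states, out.reshape(shape))
    return BayesNet(spec, cpts)


# --- sampling -----------------------------------------------------------

def sample_assignments(net: BayesNet, n: int, rng: np.random.Generator) -> list[dict[str, str]]:
    """Ancestral sampling of ``n`` full assignments."""
    if n < 1:
        raise ValueError("n must be >= 1")
    order = net.spec.topological_order()
    columns: dict[str, np.ndarray] = {}
    for node in order:
        cpt = net.cpts[node]
        states = np.arange(len(cpt.states))
        if not cpt.parents:
            columns[node] = rng.choice(states, size=n, p=cpt.values)
        else:
            draw = np.empty(n, dtype=int)
            parent_cols = [columns[p] for p in cpt.parents]
            for combo in itertools.product(*(range(len(ps)) for ps in cpt.parent_states)):
                mask = np.ones(n, dtype=bool)
                for col, c in zip(parent_cols, combo):
                    mask &= col == c
                k = int(mask.sum())
                if k:
                    draw[mask] = rng.choice(states, size=k, p=cpt.values[combo])
            columns[node] = draw
    out = []
    for i in range(n):
        out.append({node: net.spec.states(node)[columns[node][i]]
                    for node in net.spec.node_names})
    return out
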