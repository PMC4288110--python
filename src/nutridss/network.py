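"""Discrete Bayesian networks: structure, CPTs, joint probability, sampling.

A network is a DAG of :class:`DiscreteNode` objects.  Each node carries an
ordered tuple of states and a conditional probability table (CPT) stored as
explicit rows keyed by the tuple of parent states, in parent order.  Explicit
rows (rather than flattened arrays) keep the on-disk JSON human-editable,
which matters here because the shipped clinical CPTs are expert-maintained.

Probabilities are kept in linear space: the clinical subnets have at most
~10 nodes, so underflow is not a concern and linear arithmetic is the
simplest thing that can be verified against brute-force enumeration.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np

from .errors import MissingNodeError, StructureError

__all__ = [
    "DiscreteNode",
    "BayesNetwork",
    "Diagnostic",
    "validate_network",
    "topological_order",
    "joint_probability",
    "forward_sample",
]

#: CPT rows must sum to one within this tolerance.
NORMALIZATION_TOL = 1e-9


@dataclass(frozen=True)
class DiscreteNode:
    """One discrete variable with its conditional probability table.

    Parameters
    ----------
    name
        Unique node identifier within its network.
    states
        Ordered state labels (>= 2).
    parents
        Ordered parent node names; the CPT row keys follow this order.
    cpt
        Mapping from a tuple of parent states to the distribution over
        ``states`` (a tuple of floats, same order as ``states``).  A root
        node has the single key ``()``.
    """

    name: str
    states: tuple[str, ...]
    parents: tuple[str, ...] = ()
    cpt: Mapping[tuple[str, ...], tuple[float, ...]] = field(default_factory=dict)

    def __post_init__(self):
        object.__setattr__(self, "states", tuple(self.states))
        object.__setattr__(self, "parents", tuple(self.parents))
        object.__setattr__(
            self,
            "cpt",
            {tuple(k): tuple(float(p) for p in v) for k, v in dict(self.cpt).items()},
        )

    @property
    def n_states(self) -> int:
        return len(self.states)

    def state_index(self, state: str) -> int:
        try:
            return self.states.index(state)
        except ValueError:
            raise KeyError(f"{state!r} is not a state of node {self.name!r}") from None

    def distribution(self, parent_states: tuple[str, ...]) -> tuple[float, ...]:
        """CPT row for one joint parent configuration."""
        return self.cpt[tuple(parent_states)]


class BayesNetwork:
    """A directed acyclic graph of :class:`DiscreteNode`, keyed by name.

    ``metadata`` is free-form provenance (where each CPT came from); it is
    round-tripped through serialization untouched.
    """

    def __init__(self, nodes: Iterable[DiscreteNode], name: str = "", metadata: dict | None = None):
        self.name = name
        self.metadata = dict(metadata or {})
        self.nodes: dict[str, DiscreteNode] = {}
        for node in nodes:
            if node.name in self.nodes:
                raise StructureError(f"duplicate node name {node.name!r}")
            self.nodes[node.name] = node

    def __contains__(self, name: str) -> bool:
        return name in self.nodes

    def __len__(self) -> int:
        return len(self.nodes)

    def node(self, name: str) -> DiscreteNode:
        try:
            return self.nodes[name]
        except KeyError:
            raise MissingNodeError(f"network {self.name!r} has no node {name!r}") from None

    def graph(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        for node in self.nodes.values():
            for parent in node.parents:
                g.add_edge(parent, node.name)
        return g

    def joint_size(self) -> int:
        """Number of full assignments (product of state-space sizes)."""
        size = 1
        for node in self.nodes.values():
            size *= node.n_states
        return size

    def full_assignments(self) -> Iterable[dict[str, str]]:
        """Iterate every full assignment (use only on small networks)."""
        names = list(self.nodes)
        spaces = [self.nodes[n].states for n in names]
        for combo in itertools.product(*spaces):
            yield dict(zip(names, combo))


@dataclass(frozen=True)
class Diagnostic:
    """One validation finding; ``kind`` is machine-checkable, ``message`` human-readable."""

    kind: str
    node: str
    message: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"[{self.kind}] {self.node}: {self.message}"


def validate_network(net: BayesNetwork) -> list[Diagnostic]:
    """Check every structural and numerical invariant; return one finding per violation.

    Findings rather than exceptions: a spec file author wants the full list
    of problems in one pass.  Kinds: ``too_few_states``, ``duplicate_state``,
    ``dangling_parent``, ``cycle``, ``missing_row``, ``extra_row``,
    ``bad_row``, ``non_normalized_row``, ``negative_probability``.
    """
    out: list[Diagnostic] = []
    for node in net.nodes.values():
        if len(node.states) < 2:
            out.append(Diagnostic("too_few_states", node.name, f"has {len(node.states)} state(s); need >= 2"))
        if len(set(node.states)) != len(node.states):
            out.append(Diagnostic("duplicate_state", node.name, f"duplicate state labels in {node.states}"))
        for parent in node.parents:
            if parent not in net.nodes:
                out.append(Diagnostic("dangling_parent", node.name, f"parent {parent!r} is not a node"))

    # Structure checks only make sense once parents resolve.
    graph = nx.DiGraph()
    graph.add_nodes_from(net.nodes)
    for node in net.nodes.values():
        for parent in node.parents:
            if parent in net.nodes:
                graph.add_edge(parent, node.name)
    for cycle in nx.simple_cycles(graph):
        out.append(Diagnostic("cycle", cycle[0], f"directed cycle {' -> '.join(cycle + [cycle[0]])}"))

    for node in net.nodes.values():
        parent_spaces = []
        resolvable = True
        for parent in node.parents:
            if parent in net.nodes:
                parent_spaces.append(net.nodes[parent].states)
            else:
                resolvable = False
        if resolvable:
            expected = set(itertools.product(*parent_spaces))
            got = set(node.cpt)
            for key in sorted(expected - got):
                out.append(Diagnostic("missing_row", node.name, f"no CPT row for parent states {key!r}"))
            for key in sorted(got - expected):
                out.append(Diagnostic("extra_row", node.name, f"CPT row {key!r} matches no parent configuration"))
        for key, dist in node.cpt.items():
            if len(dist) != node.n_states:
                out.append(
                    Diagnostic("bad_row", node.name, f"row {key!r} has {len(dist)} entries for {node.n_states} states")
                )
                continue
            if any(p < 0 for p in dist):
                out.append(Diagnostic("negative_probability", node.name, f"row {key!r} contains a negative entry"))
            total = float(sum(dist))
            if abs(total - 1.0) > NORMALIZATION_TOL:
                out.append(Diagnostic("non_normalized_row", node.name, f"row {key!r} sums to {total!r}"))
    return out


def topological_order(net: BayesNetwork) -> list[str]:
    """Parents-before-children order, lexicographic among ties (deterministic)."""
    try:
        return list(nx.lexicographical_topological_sort(net.graph()))
    except nx.NetworkXUnfeasible:
        raise StructureError(f"network {net.name!r} contains a directed cycle") from None


def joint_probability(net: BayesNetwork, full: Mapping[str, str]) -> float:
    """Chain-rule joint probability of one full assignment.

    The joint factorizes as the product over nodes of the CPT entry for the
    node's state given its parents' states.
    """
    missing = [n for n in net.nodes if n not in full]
    if missing:
        raise MissingNodeError(f"assignment is missing node(s) {missing!r}; joint probability needs a full assignment")
    prob = 1.0
    for node in net.nodes.values():
        row = node.distribution(tuple(full[p] for p in node.parents))
        prob *= row[node.state_index(full[node.name])]
    return prob


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    if isinstance(seed, bool) or not isinstance(seed, (int, np.integer)):
        raise TypeError(f"seed must be an integer or numpy Generator, got {type(seed).__name__}")
    return np.random.default_rng(int(seed))


def forward_sample(net: BayesNetwork, n: int, seed) -> list[dict[str, str]]:
    """Draw ``n`` full assignments by ancestral sampling.

    Nodes are sampled in (lexicographic) topological order, each from its CPT
    row selected by the already-sampled parent states.  Vectorized over
    samples per node, so 50k draws from a 10-node subnet are cheap.
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    rng = _as_rng(seed)
    order = topological_order(net)
    if n == 0:
        return []

    columns: dict[str, np.ndarray] = {}  # node -> int state indices, shape (n,)
    for name in order:
        node = net.nodes[name]
        if node.parents:
            parent_spaces = [net.nodes[p].states for p in node.parents]
            row_keys = list(itertools.product(*parent_spaces))
            row_of = {key: i for i, key in enumerate(row_keys)}
            cum = np.cumsum([node.cpt[key] for key in row_keys], axis=1)
            # map each sample's parent states to its CPT row
            strides = np.ones(len(node.parents), dtype=np.int64)
            for i in range(len(node.parents) - 2, -1, -1):
                strides[i] = strides[i + 1] * len(parent_spaces[i + 1])
            rows = np.zeros(n, dtype=np.int64)
            for pi, parent in enumerate(node.parents):
                rows += columns[parent] * strides[pi]
            # sanity: strides encode the same enumeration as itertools.product
            assert row_of[row_keys[0]] == 0
            cum_rows = cum[rows]
        else:
            cum_rows = np.broadcast_to(np.cumsum(node.cpt[()]), (n, node.n_states))
        u = rng.random(n)
        columns[name] = (u[:, None] >= cum_rows).sum(axis=1).astype(np.int64)

    samples = []
    state_labels = {name: net.nodes[name].states for name in order}
    for i in range(n):
        samples.append({name: state_labels[name][columns[name][i]] for name in order})
    return samples


def conditional_sample_step(
    net: BayesNetwork, assignment: dict[str, str], rng: np.random.Generator
) -> dict[str, str]:
    """Extend ``assignment`` over ``net`` ancestrally, keeping pre-set nodes.

    Nodes already present in ``assignment`` are treated as clamped and are
    not resampled; every other node is drawn from its CPT given the (clamped
    or sampled) parent states.  Used by the synthetic-cohort generator to
    keep evidence nodes shared between subnets consistent within one case.
    """
    for name in topological_order(net):
        if name in assignment:
            continue
        node = net.nodes[name]
        row = np.asarray(node.distribution(tuple(assignment[p] for p in node.parents)))
        idx = int((rng.random() >= np.cumsum(row)).sum())
        assignment[name] = node.states[idx]
    return assignment


def enumerate_marginal(net: BayesNetwork, query: str) -> dict[str, float]:
    """Marginal of one node by exhaustive enumeration (small networks only)."""
    node = net.node(query)
    totals = dict.fromkeys(node.states, 0.0)
    for full in net.full_assignments():
        totals[full[query]] += joint_probability(net, full)
    return totals


def assignments_equal(a: Sequence[Mapping[str, str]], b: Sequence[Mapping[str, str]]) -> bool:
    """Order-sensitive equality of two assignment lists (test helper)."""
    return len(a) == len(b) and all(dict(x) == dict(y) for x, y in zip(a, b))
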