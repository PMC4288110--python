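"""Shared fixtures: small hand-built networks and random-network factories."""

from __future__ import annotations

import itertools

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from nutridss import KnowledgeBase, default_ranges
from nutridss.network import BayesNetwork, DiscreteNode

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


def make_chain() -> BayesNetwork:
    """A -> B with mildly asymmetric CPTs."""
    return BayesNetwork(
        [
            DiscreteNode("A", ("t", "f"), (), {(): (0.4, 0.6)}),
            DiscreteNode("B", ("t", "f"), ("A",), {("t",): (0.9, 0.1), ("f",): (0.2, 0.8)}),
        ],
        name="chain",
    )


def make_disease_test() -> BayesNetwork:
    """Disease -> test: P(D)=0.1, P(+|D)=0.9, P(+|not D)=0.2."""
    return BayesNetwork(
        [
            DiscreteNode("disease", ("present", "absent"), (), {(): (0.1, 0.9)}),
            DiscreteNode(
                "test",
                ("pos", "neg"),
                ("disease",),
                {("present",): (0.9, 0.1), ("absent",): (0.2, 0.8)},
            ),
        ],
        name="disease_test",
    )


def make_copy_chain() -> BayesNetwork:
    """A -> B where B deterministically copies A; P(A=t)=0.4."""
    return BayesNetwork(
        [
            DiscreteNode("A", ("t", "f"), (), {(): (0.4, 0.6)}),
            DiscreteNode("B", ("t", "f"), ("A",), {("t",): (1.0, 0.0), ("f",): (0.0, 1.0)}),
        ],
        name="copy_chain",
    )


def random_network(rng: np.random.Generator, n_nodes: int, max_states: int = 3) -> BayesNetwork:
    """A random DAG over nodes n0..n{k-1} with random normalized CPTs.

    Edges only go from lower to higher index, so the graph is acyclic by
    construction; each node gets 0-3 parents among its predecessors.
    """
    names = [f"n{i}" for i in range(n_nodes)]
    nodes = []
    for i, name in enumerate(names):
        n_states = int(rng.integers(2, max_states + 1))
        states = tuple(f"s{j}" for j in range(n_states))
        n_parents = int(rng.integers(0, min(i, 3) + 1))
        parents = tuple(sorted(rng.choice(names[:i], size=n_parents, replace=False))) if n_parents else ()
        parent_spaces = [next(nd for nd in nodes if nd.name == p).states for p in parents]
        cpt = {}
        for key in itertools.product(*parent_spaces):
            raw = rng.dirichlet(np.ones(n_states))
            cpt[key] = tuple(raw / raw.sum())
        nodes.append(DiscreteNode(name, states, parents, cpt))
    return BayesNetwork(nodes, name=f"random_{n_nodes}")


@pytest.fixture
def chain_net():
    return make_chain()


@pytest.fixture
def disease_test_net():
    return make_disease_test()


@pytest.fixture
def copy_chain_net():
    return make_copy_chain()


@pytest.fixture(scope="session")
def kb():
    return KnowledgeBase.load()


@pytest.fixture(scope="session")
def ranges():
    return default_ranges()
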