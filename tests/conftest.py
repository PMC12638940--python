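"""Shared fixtures and independent oracles for the test suite.

The oracle functions here deliberately re-derive quantities from raw edge
lists with naive exhaustive algorithms, without touching the package's
census/enrichment code paths, so they can serve as independent references.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pytest

from biomarknet.motifs import SignedEdge, SignedNetwork


# ---------------------------------------------------------------------------
# independent oracles


def oracle_triangles(edges: list[tuple[str, str, int]]) -> dict:
    """Exhaustive triple scan over raw (source, target, sign) tuples.

    Returns {sorted member triple: (n_edges, n_negative, is_unbalanced,
    is_cycle)} computed from scratch.
    """
    nodes = sorted({n for s, t, _ in edges for n in (s, t)})
    arcs = {(s, t) for s, t, _ in edges}
    unique_edges = set(edges)
    out = {}
    for trip in combinations(nodes, 3):
        connected = all((u, v) in arcs or (v, u) in arcs
                        for u, v in combinations(trip, 2))
        if not connected:
            continue
        motif_edges = {(s, t, g) for s, t, g in unique_edges
                       if s in trip and t in trip}
        n_neg = sum(1 for _, _, g in motif_edges if g < 0)
        a, b, c = trip
        cycle = any(
            (x, y) in arcs and (y, z) in arcs and (z, x) in arcs
            for x, y, z in [(a, b, c), (a, c, b)])
        out[trip] = (len(motif_edges), n_neg, n_neg % 2 == 1, cycle)
    return out


def random_signed_edges(rng: np.random.Generator, n: int, p: float,
                        neg_frac: float) -> list[tuple[str, str, int]]:
    """Raw directed signed ER edge list, independent of the generator module."""
    nodes = [f"N{i}" for i in range(n)]
    edges = []
    for i in range(n):
        for j in range(n):
            if i != j and rng.random() < p:
                sign = -1 if rng.random() < neg_frac else 1
                edges.append((nodes[i], nodes[j], sign))
    return edges


def network_from_edges(edges, name="test") -> SignedNetwork:
    return SignedNetwork(name=name,
                         edges=[SignedEdge(s, t, g) for s, t, g in edges])


# ---------------------------------------------------------------------------
# fixtures


@pytest.fixture
def k3_positive_cycle() -> SignedNetwork:
    """A -> B -> C -> A, all activating: one balanced cycle triangle."""
    return network_from_edges([("A", "B", 1), ("B", "C", 1), ("C", "A", 1)])


@pytest.fixture
def feed_forward_negative() -> SignedNetwork:
    """A -> B, A -> C, B -> C with one inhibition: unbalanced, acyclic."""
    return network_from_edges([("A", "B", 1), ("A", "C", 1), ("B", "C", -1)])


@pytest.fixture
def small_random_network() -> SignedNetwork:
    rng = np.random.default_rng(11)
    return network_from_edges(random_signed_edges(rng, 25, 0.25, 0.3),
                              name="rand25")
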