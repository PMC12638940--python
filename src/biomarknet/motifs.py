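"""Signed directed networks and the three-node triangle motif census.

A signalling network is reduced to its *signed subnetwork*: the directed
edges annotated as activating (+1) or inhibiting (-1).  On that graph we
enumerate every fully connected three-node motif (triangle), classify each
as balanced/unbalanced by the parity of its negative edges and as
cycle/acyclic by the existence of a directed closed walk through all three
members, and report per-pair triangle participation statistics that feed
the downstream feature table.

Only triangles are consumed by the rest of the pipeline, so the census
enumerates them directly from the undirected skeleton instead of running a
general 3-node subgraph classifier; for that motif class the output is
identical and exactly testable against brute-force triple enumeration.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from itertools import permutations
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx

logger = logging.getLogger(__name__)

__all__ = [
    "SignedEdge",
    "SignedNetwork",
    "TriangleMotif",
    "LoadSummary",
    "load_signed_network",
    "network_density",
    "network_summary",
    "census_triangles",
    "classify_sign_pattern",
    "pair_triangle_participation",
    "write_census_tsv",
]

#: sign tokens accepted in edge-list files, mapped to +1 / -1
SIGN_TOKENS: Mapping[str, int] = {
    "+": 1,
    "-": -1,
    "1": 1,
    "-1": -1,
    "+1": 1,
    "activation": 1,
    "inhibition": -1,
}


class NetworkError(ValueError):
    """Base class for signed-network errors."""


class UndefinedDensityError(NetworkError):
    """Density is undefined for networks with fewer than two nodes."""


class MissingNodeError(KeyError, NetworkError):
    """A requested protein id is not a node of the network."""


class InvalidMotifError(NetworkError):
    """The given edges do not form a fully connected three-node motif."""


@dataclass(frozen=True, order=True)
class SignedEdge:
    """A directed signed interaction ``source -> target`` with sign +-1."""

    source: str
    target: str
    sign: int

    def __post_init__(self) -> None:
        if self.sign not in (1, -1):
            raise ValueError(f"edge sign must be +1 or -1, got {self.sign!r}")
        if self.source == self.target:
            raise ValueError(f"self-loop {self.source!r} is not a valid signed edge")


@dataclass
class LoadSummary:
    """Bookkeeping from reading an edge-list file."""

    n_rows: int = 0
    n_edges: int = 0
    n_self_loops: int = 0
    n_unsigned: int = 0
    n_duplicates: int = 0


class SignedNetwork:
    """A directed graph whose edges carry a sign.

    At most one edge is stored per (source, target, sign) triple; a pair
    annotated with both an activation and an inhibition is kept as two
    signed edges and both contribute to motif negative-edge counts.
    """

    def __init__(self, name: str = "", edges: Iterable[SignedEdge] = (),
                 nodes: Iterable[str] = ()) -> None:
        self.name = name
        self.edges: set[SignedEdge] = set(edges)
        self.nodes: set[str] = set(nodes)
        for e in self.edges:
            self.nodes.add(e.source)
            self.nodes.add(e.target)
        # directed adjacency (sign-blind) and per-ordered-pair sign sets
        self._succ: dict[str, set[str]] = {n: set() for n in self.nodes}
        self._signs: dict[tuple[str, str], set[int]] = {}
        for e in self.edges:
            self._succ[e.source].add(e.target)
            self._signs.setdefault((e.source, e.target), set()).add(e.sign)

    # -- basic accessors -------------------------------------------------
    def __contains__(self, node: str) -> bool:
        return node in self.nodes

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    @property
    def n_negative(self) -> int:
        return sum(1 for e in self.edges if e.sign < 0)

    def has_arc(self, u: str, v: str) -> bool:
        """True if a directed edge u->v of either sign exists."""
        return v in self._succ.get(u, ())

    def edge_sign(self, u: str, v: str) -> int:
        """Net sign of u->v: +1, -1, or 0 when absent or conflicting."""
        signs = self._signs.get((u, v))
        if not signs or len(signs) == 2:
            return 0
        return next(iter(signs))

    def edges_between(self, members: Iterable[str]) -> list[SignedEdge]:
        mem = set(members)
        return sorted(e for e in self.edges if e.source in mem and e.target in mem)

    def skeleton_pairs(self) -> set[frozenset[str]]:
        """Distinct unordered node pairs connected in at least one direction."""
        return {frozenset((e.source, e.target)) for e in self.edges}

    def undirected_adjacency(self) -> dict[str, set[str]]:
        adj: dict[str, set[str]] = {n: set() for n in self.nodes}
        for e in self.edges:
            adj[e.source].add(e.target)
            adj[e.target].add(e.source)
        return adj

    def to_networkx(self) -> nx.DiGraph:
        """Sign-blind directed simple graph (for centralities, paths)."""
        g = nx.DiGraph(name=self.name)
        g.add_nodes_from(sorted(self.nodes))
        for e in sorted(self.edges):
            g.add_edge(e.source, e.target)
        return g

    def __repr__(self) -> str:  # pragma: no cover - debug aid
        return (f"SignedNetwork(name={self.name!r}, nodes={self.n_nodes}, "
                f"edges={self.n_edges}, negative={self.n_negative})")


@dataclass
class TriangleMotif:
    """A fully connected three-node motif with its signed directed edges."""

    members: tuple[str, str, str]
    edges: tuple[SignedEdge, ...]
    negative_edge_count: int
    is_unbalanced: bool
    is_cycle: bool

    @property
    def key(self) -> tuple[str, str, str]:
        return self.members


def load_signed_network(path: str | Path, dialect: str = "edge-list-tsv",
                        name: str | None = None,
                        sif_sign_map: Mapping[str, int] | None = None,
                        ) -> tuple[SignedNetwork, LoadSummary]:
    """Read a signed edge list, keeping only rows with a recognised sign.

    Parameters
    ----------
    path
        Tab-separated file.  ``edge-list-tsv`` rows are
        ``source<TAB>target<TAB>sign``; ``sif`` rows are
        ``source<TAB>relation<TAB>target``.
    dialect
        ``"edge-list-tsv"`` or ``"sif"``.
    sif_sign_map
        Relation-to-sign map for the SIF dialect; defaults to
        :data:`SIGN_TOKENS`.

    Self-loops are dropped, duplicate rows collapse to a single edge, and
    rows with an unrecognised sign token are skipped with a warning.  An
    error is raised only when no valid signed edge remains.
    """
    path = Path(path)
    if dialect not in ("edge-list-tsv", "sif"):
        raise ValueError(f"unknown dialect {dialect!r}")
    sign_map = dict(SIGN_TOKENS)
    if sif_sign_map:
        sign_map.update({k.lower(): v for k, v in sif_sign_map.items()})

    summary = LoadSummary()
    edges: set[SignedEdge] = set()
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if lineno == 1 and _looks_like_header(parts):
                continue
            if len(parts) < 3:
                summary.n_unsigned += 1
                continue
            summary.n_rows += 1
            if dialect == "sif":
                src, token, dst = parts[0], parts[1], parts[2]
            else:
                src, dst, token = parts[0], parts[1], parts[2]
            sign = sign_map.get(token.strip().lower())
            if sign is None:
                summary.n_unsigned += 1
                warnings.warn(
                    f"{path.name}:{lineno}: unrecognised sign token {token!r}; row skipped",
                    stacklevel=2)
                continue
            if src == dst:
                summary.n_self_loops += 1
                continue
            edge = SignedEdge(src, dst, sign)
            if edge in edges:
                summary.n_duplicates += 1
            else:
                edges.add(edge)
    if not edges:
        raise NetworkError(f"{path}: no valid signed edges found")
    summary.n_edges = len(edges)
    net = SignedNetwork(name=name or path.stem, edges=edges)
    logger.info("loaded %s: %d nodes, %d edges (%d self-loops, %d unsigned, "
                "%d duplicate rows dropped)", net.name, net.n_nodes,
                net.n_edges, summary.n_self_loops, summary.n_unsigned,
                summary.n_duplicates)
    return net, summary


def _looks_like_header(parts: list[str]) -> bool:
    low = [p.strip().lower() for p in parts]
    return "source" in low or "target" in low or "sign" in low


def network_density(net: SignedNetwork) -> float:
    """Density eta = 2|E| / (|V|(|V|-1)) on the undirected simple skeleton.

    |E| counts distinct unordered connected node pairs, so reciprocal and
    parallel signed edges contribute once and the value is bounded by 1.
    """
    n = net.n_nodes
    if n < 2:
        raise UndefinedDensityError(
            f"density undefined for a network with {n} node(s)")
    return 2.0 * len(net.skeleton_pairs()) / (n * (n - 1))


def census_triangles(net: SignedNetwork) -> list[TriangleMotif]:
    """Enumerate every triangle (complete undirected skeleton on 3 nodes).

    Each motif carries all signed directed edges among its members, the
    negative-edge count over those edges, the unbalanced flag (odd number
    of negatives) and the cycle flag (a directed Hamiltonian walk over the
    three members exists in at least one orientation).  Output is sorted
    lexicographically on the sorted member triple.
    """
    adj = net.undirected_adjacency()
    order = sorted(net.nodes)
    rank = {n: i for i, n in enumerate(order)}
    motifs: list[TriangleMotif] = []
    for a in order:
        higher_a = {v for v in adj[a] if rank[v] > rank[a]}
        for b in sorted(higher_a):
            common = higher_a & {v for v in adj[b] if rank[v] > rank[b]}
            for c in sorted(common):
                motifs.append(_make_motif(net, (a, b, c)))
    return motifs


def _make_motif(net: SignedNetwork, members: tuple[str, str, str]) -> TriangleMotif:
    edges = tuple(net.edges_between(members))
    neg = sum(1 for e in edges if e.sign < 0)
    return TriangleMotif(
        members=members,
        edges=edges,
        negative_edge_count=neg,
        is_unbalanced=bool(neg % 2),
        is_cycle=_has_directed_cycle(net, members),
    )


def _has_directed_cycle(net: SignedNetwork, members: tuple[str, str, str]) -> bool:
    a = members[0]
    for b, c in permutations(members[1:]):
        if net.has_arc(a, b) and net.has_arc(b, c) and net.has_arc(c, a):
            return True
    return False


def classify_sign_pattern(motif: TriangleMotif) -> tuple[str, str]:
    """Return the (balance, cyclicity) class of a triangle motif.

    Unbalanced means an odd number of negative edges; cycle means a
    directed closed walk over all three members exists.
    """
    if len(motif.members) != 3 or len(set(motif.members)) != 3:
        raise InvalidMotifError(f"not a three-node motif: {motif.members!r}")
    pairs = {frozenset((e.source, e.target)) for e in motif.edges}
    if len(pairs) != 3:
        raise InvalidMotifError(
            f"motif on {motif.members!r} is not fully connected")
    balance = "unbalanced" if motif.is_unbalanced else "balanced"
    cyclicity = "cycle" if motif.is_cycle else "acyclic"
    return balance, cyclicity


@dataclass
class PairParticipation:
    """Triangle participation of one (neighbour, target) ordered pair."""

    neighbour: str
    target: str
    n_triangles: int
    n_unbalanced: int
    n_cycles: int
    sign_nt: int            # net sign of neighbour -> target (0 absent/conflicting)
    sign_tn: int            # net sign of target -> neighbour
    third_nodes: tuple[str, ...]   # multiset, one entry per shared triangle


def pair_triangle_participation(net: SignedNetwork, pair: tuple[str, str],
                                motifs: list[TriangleMotif] | None = None,
                                ) -> PairParticipation:
    """Count the triangles a node pair shares and summarise their classes.

    The pair is ordered (neighbour, target); the two directed edge signs
    are reported separately.  ``motifs`` may be passed to reuse a census.
    """
    n_id, t_id = pair
    for node in (n_id, t_id):
        if node not in net:
            raise MissingNodeError(node)
    if motifs is None:
        motifs = census_triangles(net)
    shared = [m for m in motifs if n_id in m.members and t_id in m.members]
    third = tuple(sorted(x for m in shared for x in m.members
                         if x not in (n_id, t_id)))
    return PairParticipation(
        neighbour=n_id,
        target=t_id,
        n_triangles=len(shared),
        n_unbalanced=sum(m.is_unbalanced for m in shared),
        n_cycles=sum(m.is_cycle for m in shared),
        sign_nt=net.edge_sign(n_id, t_id),
        sign_tn=net.edge_sign(t_id, n_id),
        third_nodes=third,
    )


def network_summary(net: SignedNetwork) -> dict:
    """Node/edge counts, negative fraction, density, and triangle count."""
    summary: dict = {
        "name": net.name,
        "n_nodes": net.n_nodes,
        "n_edges": net.n_edges,
        "negative_edge_fraction": (net.n_negative / net.n_edges
                                   if net.n_edges else 0.0),
    }
    try:
        summary["density"] = network_density(net)
    except UndefinedDensityError:
        summary["density"] = None
    motifs = census_triangles(net)
    summary["n_triangles"] = len(motifs)
    summary["n_unbalanced"] = sum(m.is_unbalanced for m in motifs)
    summary["n_cycles"] = sum(m.is_cycle for m in motifs)
    return summary


def write_census_tsv(motifs: list[TriangleMotif], path: str | Path) -> None:
    """Export a triangle census as a plain TSV table."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("member_a\tmember_b\tmember_c\tn_edges\tn_negative\t"
                 "is_unbalanced\tis_cycle\n")
        for m in motifs:
            a, b, c = m.members
            fh.write(f"{a}\t{b}\t{c}\t{len(m.edges)}\t{m.negative_edge_count}"
                     f"\t{int(m.is_unbalanced)}\t{int(m.is_cycle)}\n")
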