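"""Confidence-weighted undirected interaction networks.

A protein-protein interaction (PPI) network is modelled as an undirected
graph whose edges carry an interaction confidence ``c`` in (0, 1] (the
STRING convention, where scores may also be printed as integers 0-1000).
Confidence is converted to a distance ``d = 1 - c`` in [0, 1): perfectly
confident interactions sit at distance zero, barely supported ones near
one. Node pairs without an observed edge are treated as infinitely far
apart, so they never enter a common simplex downstream.

The :class:`WeightedNetwork` container is immutable; all operations
(thresholding, node deletion) return new networks.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import networkx as nx

from .errors import ParseError, ValidationError

logger = logging.getLogger(__name__)

Edge = tuple[str, str]


def _pair(u: str, v: str) -> Edge:
    """Canonical (sorted) unordered pair key."""
    return (u, v) if u <= v else (v, u)


def confidence_to_distance(c: float) -> float:
    """Map an interaction confidence in (0, 1] to a distance in [0, 1).

    Uses ``d = 1 - c``: the simplest strictly decreasing map with
    ``d(1) = 0``, so high-confidence interactions are close in the
    filtration metric.
    """
    if not (0.0 < c <= 1.0):
        raise ValidationError(f"confidence must be in (0, 1], got {c!r}")
    return 1.0 - c


def distance_to_confidence(d: float) -> float:
    """Inverse of :func:`confidence_to_distance`."""
    if not (0.0 <= d < 1.0):
        raise ValidationError(f"distance must be in [0, 1), got {d!r}")
    return 1.0 - d


@dataclass(frozen=True)
class WeightedNetwork:
    """Immutable undirected network with per-edge confidences.

    Parameters
    ----------
    confidences
        Mapping from canonical (sorted) node pairs to confidence values
        in (0, 1].
    nodes
        All node identifiers, including isolated ones.
    """

    confidences: Mapping[Edge, float]
    nodes: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self):
        node_set = set(self.nodes)
        for (u, v), c in self.confidences.items():
            if u == v:
                raise ValidationError(f"self-loop on {u!r}")
            if (u, v) != _pair(u, v):
                raise ValidationError(f"edge key {(u, v)!r} not in canonical order")
            if not (0.0 < c <= 1.0):
                raise ValidationError(f"confidence for {u}-{v} must be in (0, 1], got {c}")
            node_set.add(u)
            node_set.add(v)
        object.__setattr__(self, "nodes", frozenset(node_set))
        object.__setattr__(self, "confidences", dict(self.confidences))

    # -- constructors -------------------------------------------------

    @classmethod
    def from_edges(
        cls, edges: Iterable[tuple[str, str, float]], nodes: Iterable[str] = ()
    ) -> "WeightedNetwork":
        """Build from (u, v, confidence) triples; duplicates keep the max."""
        conf: dict[Edge, float] = {}
        extra = set(nodes)
        for u, v, c in edges:
            if u == v:
                raise ValidationError(f"self-loop on {u!r}")
            key = _pair(u, v)
            conf[key] = max(c, conf.get(key, 0.0))
        return cls(conf, frozenset(extra))

    # -- queries ------------------------------------------------------

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.confidences)

    def edges(self) -> Iterator[tuple[str, str, float]]:
        """Iterate (u, v, confidence) in deterministic sorted order."""
        for (u, v) in sorted(self.confidences):
            yield u, v, self.confidences[(u, v)]

    def confidence(self, u: str, v: str) -> float:
        return self.confidences[_pair(u, v)]

    def distance(self, u: str, v: str) -> float:
        """Edge distance, ``inf`` for non-adjacent pairs."""
        c = self.confidences.get(_pair(u, v))
        return math.inf if c is None else confidence_to_distance(c)

    def has_edge(self, u: str, v: str) -> bool:
        return _pair(u, v) in self.confidences

    def degree(self, v: str) -> int:
        if v not in self.nodes:
            raise KeyError(v)
        return sum(1 for e in self.confidences if v in e)

    def to_networkx(self) -> nx.Graph:
        """Export as a :class:`networkx.Graph` with ``confidence`` and
        ``distance`` edge attributes."""
        g = nx.Graph()
        g.add_nodes_from(sorted(self.nodes))
        for u, v, c in self.edges():
            g.add_edge(u, v, confidence=c, distance=confidence_to_distance(c))
        return g


# -- I/O (STRING-style TSV edge lists) --------------------------------

_HEADER_TOKENS = {"node1", "node2", "protein1", "protein2", "score", "combined_score"}


def load_string_edges(path: str | Path) -> WeightedNetwork:
    """Read a STRING-style tab-separated edge list.

    Expects at least three columns: node1, node2, score. Scores are
    auto-detected as either fractional ([0, 1]) or STRING integer
    (0-1000, any value > 1 triggers division by 1000). Duplicate rows
    for the same unordered pair keep the maximum confidence; self-loop
    rows are dropped with a warning.
    """
    rows: list[tuple[str, str, float, int]] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) == 1:  # tolerate space/comma separated exports
                parts = line.replace(",", " ").split()
            if len(parts) < 3:
                raise ParseError(f"expected >=3 columns, got {len(parts)}", lineno)
            u, v, score_txt = parts[0], parts[1], parts[2]
            if lineno == 1 and score_txt.lower() in _HEADER_TOKENS | {"score"}:
                continue
            try:
                score = float(score_txt)
            except ValueError:
                if lineno == 1:  # header row with arbitrary column names
                    continue
                raise ParseError(f"non-numeric score {score_txt!r}", lineno) from None
            if not (0.0 <= score <= 1000.0):
                raise ValidationError(f"line {lineno}: score {score} outside [0, 1000]")
            rows.append((u, v, score, lineno))

    scale = 1000.0 if any(s > 1.0 for _, _, s, _ in rows) else 1.0
    conf: dict[Edge, float] = {}
    for u, v, score, lineno in rows:
        if u == v:
            logger.warning("dropping self-loop row at line %d (%s)", lineno, u)
            continue
        c = score / scale
        if c == 0.0:
            logger.warning("dropping zero-confidence row at line %d (%s-%s)", lineno, u, v)
            continue
        key = _pair(u, v)
        conf[key] = max(c, conf.get(key, 0.0))
    return WeightedNetwork(conf)


def write_string_edges(net: WeightedNetwork, path: str | Path) -> None:
    """Write the same TSV dialect :func:`load_string_edges` reads."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("node1\tnode2\tscore\n")
        for u, v, c in net.edges():
            fh.write(f"{u}\t{v}\t{c:.3f}\n")


# -- transformations --------------------------------------------------


def apply_threshold(net: WeightedNetwork, tau: float) -> WeightedNetwork:
    """Keep edges with confidence >= ``tau``; drop isolated nodes.

    The node set of the result is the union of retained edge endpoints,
    matching the multi-resolution analysis in which each thresholded
    network is treated as a standalone graph. Idempotent, and composing
    two thresholds is equivalent to applying the larger one.
    """
    if not (0.0 <= tau <= 1.0):
        raise ValidationError(f"threshold must be in [0, 1], got {tau}")
    kept = {e: c for e, c in net.confidences.items() if c >= tau}
    return WeightedNetwork(kept, frozenset())


def remove_node(net: WeightedNetwork, v: str) -> WeightedNetwork:
    """Delete node ``v`` and all incident edges; input is unmodified."""
    if v not in net.nodes:
        raise KeyError(f"node {v!r} not in network")
    kept = {e: c for e, c in net.confidences.items() if v not in e}
    return WeightedNetwork(kept, frozenset(net.nodes - {v}))
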