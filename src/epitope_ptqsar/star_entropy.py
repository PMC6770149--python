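"""Star-graph sequence recurrence networks and Shannon-entropy descriptors.

A peptide sequence is embedded as a star-like recurrence network: one
branch per residue type radiates from a virtual center node, and repeated
occurrences of the same residue are chained along their branch in order of
appearance in the sequence.  Degree-normalizing the adjacency matrix of
this graph gives a row-stochastic Markov matrix ``Pi``.  Starting from a
uniform distribution over all nodes (center included), the natural powers
of ``Pi`` spread probability through the network, and the Shannon entropy

    theta_k = -sum_i p_i(k) * ln p_i(k),   p(k) = p0 @ Pi^k

of the node distribution after ``k`` steps is the k-th descriptor, in
nats.  ``theta_0`` depends only on the initial distribution (it equals
``ln(n)`` for the uniform start over ``n`` nodes); higher orders encode
increasingly non-local recurrence structure of the sequence.

Two graph variants are supported: the plain (non-embedded) star graph,
and an "embedded" variant that additionally joins consecutive sequence
positions, superimposing the linear backbone on the star topology.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import networkx as nx
import numpy as np

__all__ = [
    "InvalidSequenceError",
    "MarkovChain",
    "CENTER_NODE",
    "CENTER_LABEL",
    "validate_peptide",
    "build_star_graph",
    "markov_chain",
    "shannon_entropy_series",
    "entropy_descriptors",
    "descriptor_table",
]

#: Node id of the virtual center of every star graph.
CENTER_NODE = 0

#: Sentinel residue label attached to the center node.
CENTER_LABEL = "*"

#: Default number of Markov-matrix powers (descriptors theta_0..theta_5).
DEFAULT_K_MAX = 5


class InvalidSequenceError(ValueError):
    """Raised for sequences that are not valid uppercase residue strings."""


def validate_peptide(sequence: str) -> str:
    """Validate a peptide sequence and return it unchanged.

    A valid sequence is a non-empty string of uppercase letters A-Z.
    Nonstandard residue letters (B, J, O, U, X, Z) are accepted: they occur
    in curated epitope records and simply form branches of their own.
    """
    if not isinstance(sequence, str):
        raise InvalidSequenceError(
            f"peptide sequence must be a string, got {type(sequence).__name__}"
        )
    if not sequence:
        raise InvalidSequenceError("peptide sequence must be non-empty")
    for ch in sequence:
        if not ("A" <= ch <= "Z"):
            raise InvalidSequenceError(
                f"invalid character {ch!r} in peptide sequence {sequence!r}: "
                "only uppercase letters A-Z are allowed"
            )
    return sequence


def build_star_graph(sequence: str, embedded: bool = False) -> nx.Graph:
    """Build the star-graph recurrence network of a peptide sequence.

    Nodes are ``0`` (the center) and ``1..len(sequence)`` (one per residue
    position).  Each distinct residue letter owns one branch: its first
    occurrence is joined to the center and later occurrences are chained to
    the previous occurrence of the same letter, in sequence order.  With
    ``embedded=True``, edges between consecutive sequence positions are
    added on top of the star topology.

    Returns a :class:`networkx.Graph` whose nodes carry a ``residue``
    attribute (the center carries :data:`CENTER_LABEL`).
    """
    validate_peptide(sequence)
    g = nx.Graph(sequence=sequence, embedded=embedded)
    g.add_node(CENTER_NODE, residue=CENTER_LABEL)
    last_of: dict[str, int] = {}
    for pos, residue in enumerate(sequence, start=1):
        g.add_node(pos, residue=residue)
        prev = last_of.get(residue)
        g.add_edge(CENTER_NODE if prev is None else prev, pos)
        last_of[residue] = pos
    if embedded:
        for pos in range(1, len(sequence)):
            g.add_edge(pos, pos + 1)
    return g


@dataclass(frozen=True)
class MarkovChain:
    """Row-stochastic random walk on a star graph.

    Attributes
    ----------
    transition:
        Square row-stochastic matrix ``Pi`` (degree-normalized adjacency).
    initial:
        Initial node-probability vector ``p0`` (uniform over all nodes).
    nodes:
        Node ids, in the row/column order of ``transition``.
    """

    transition: np.ndarray
    initial: np.ndarray
    nodes: tuple[int, ...]


def markov_chain(graph: nx.Graph) -> MarkovChain:
    """Degree-normalize a star graph into its Markov transition matrix.

    ``Pi[i, j] = A[i, j] / deg(i)``, so each row sums to one; ``p0`` is
    uniform over all nodes including the center.  Star graphs are connected,
    so no node has degree zero.
    """
    nodes = tuple(sorted(graph.nodes))
    adjacency = nx.to_numpy_array(graph, nodelist=nodes, dtype=float)
    degrees = adjacency.sum(axis=1)
    if np.any(degrees == 0):
        raise ValueError("graph has an isolated node; star graphs are connected")
    transition = adjacency / degrees[:, None]
    initial = np.full(len(nodes), 1.0 / len(nodes))
    return MarkovChain(transition=transition, initial=initial, nodes=nodes)


def _entropy(p: np.ndarray) -> float:
    # Shannon entropy in nats with the 0*ln(0) = 0 convention.
    nz = p[p > 0.0]
    return float(-(nz * np.log(nz)).sum())


def shannon_entropy_series(mc: MarkovChain, k_max: int = DEFAULT_K_MAX) -> np.ndarray:
    """Entropies theta_0..theta_k_max of the walk's node distribution.

    theta_k is the Shannon entropy (nats) of ``p0 @ Pi^k``; the powers are
    accumulated by repeated vector-matrix products.
    """
    if k_max < 0:
        raise ValueError(f"k_max must be >= 0, got {k_max}")
    p = mc.initial.copy()
    thetas = [_entropy(p)]
    for _ in range(k_max):
        p = p @ mc.transition
        thetas.append(_entropy(p))
    return np.asarray(thetas)


def entropy_descriptors(
    sequence: str, k_max: int = DEFAULT_K_MAX, embedded: bool = False
) -> np.ndarray:
    """theta_0..theta_k_max for one peptide sequence (convenience wrapper)."""
    return shannon_entropy_series(
        markov_chain(build_star_graph(sequence, embedded=embedded)), k_max
    )


def descriptor_table(
    sequences: Iterable[str], k_max: int = DEFAULT_K_MAX, embedded: bool = False
) -> Mapping[str, np.ndarray]:
    """Compute entropy descriptors for a batch of sequences, memoized.

    Each distinct sequence is computed exactly once; the result does not
    depend on input order or multiplicity.  An invalid sequence raises
    :class:`InvalidSequenceError` naming the offender.
    """
    table: dict[str, np.ndarray] = {}
    for seq in sequences:
        if seq in table:
            continue
        try:
            table[seq] = entropy_descriptors(seq, k_max=k_max, embedded=embedded)
        except InvalidSequenceError as exc:
            raise InvalidSequenceError(f"sequence {seq!r}: {exc}") from exc
    return table
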