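"""Simplified sequence-similarity clustering of ligand candidates.

All-vs-all Smith-Waterman local alignment scores (BLOSUM62, gap open 11 /
extend 1) feed a threshold graph whose connected components are the clusters.
Instead of database-calibrated P-values, the edge criterion acts on
bits-per-shorter-sequence normalized scores (BLOSUM62 raw scores are in
half-bits, so bits = raw / 2): two sequences are connected when their best
local alignment carries at least ``threshold`` bits per residue of the
shorter sequence. The default of 0.5 bits/residue keeps sequences sharing a
conserved domain connected while leaving sequences that share only a short
motif apart.
"""

from __future__ import annotations

from dataclasses import dataclass

import biotite.sequence as bseq
import biotite.sequence.align as balign
import networkx as nx
import numpy as np

from .records import ContractViolationError

_BLOSUM62 = balign.SubstitutionMatrix.std_protein_matrix()


@dataclass
class ScoreMatrix:
    """Symmetric raw local-alignment score matrix with sequence lengths."""

    ids: list
    lengths: np.ndarray
    scores: np.ndarray


@dataclass
class SimilarityGraph:
    graph: nx.Graph
    threshold: float
    normalization: str
    components: list  # sorted tuples of node ids, lexicographic order


def _sw_score(a: bseq.ProteinSequence, b: bseq.ProteinSequence) -> int:
    aln = balign.align_optimal(
        a, b, _BLOSUM62, gap_penalty=(-11, -1), local=True, max_number=1
    )
    return int(aln[0].score)


def pairwise_scores(records, gap_open: int = 11, gap_extend: int = 1) -> ScoreMatrix:
    """Symmetric all-vs-all Smith-Waterman raw scores (diagonal = self-score)."""
    records = list(records)
    if len(records) < 2:
        raise ContractViolationError("pairwise_scores needs at least two records")
    seqs = [bseq.ProteinSequence(r.sequence) for r in records]
    n = len(records)
    scores = np.zeros((n, n), dtype=int)
    for i in range(n):
        for j in range(i, n):
            s = int(
                balign.align_optimal(
                    seqs[i],
                    seqs[j],
                    _BLOSUM62,
                    gap_penalty=(-gap_open, -gap_extend),
                    local=True,
                    max_number=1,
                )[0].score
            )
            scores[i, j] = scores[j, i] = s
    return ScoreMatrix(
        ids=[r.id for r in records],
        lengths=np.array([len(r.sequence) for r in records]),
        scores=scores,
    )


def build_graph(
    score_matrix: ScoreMatrix,
    threshold: float = 0.5,
    normalization: str = "BITS_PER_SHORTER",
) -> SimilarityGraph:
    """Threshold graph over the score matrix, with connected components.

    ``normalization`` is ``"RAW"`` (threshold on raw scores) or
    ``"BITS_PER_SHORTER"`` (threshold on ``(raw / 2) / min(len_i, len_j)``
    bits per residue; threshold must be non-negative). Components are
    reported deterministically: nodes sorted within each component,
    components sorted by their first node.
    """
    if normalization not in ("RAW", "BITS_PER_SHORTER"):
        raise ContractViolationError(f"unknown normalization {normalization!r}")
    if normalization == "BITS_PER_SHORTER" and threshold < 0:
        raise ContractViolationError("threshold must be non-negative in bit units")
    scores = score_matrix.scores
    if not np.array_equal(scores, scores.T):
        raise ContractViolationError("score matrix must be symmetric")
    ids = score_matrix.ids
    lengths = score_matrix.lengths
    g = nx.Graph()
    g.add_nodes_from(ids)
    n = len(ids)
    for i in range(n):
        for j in range(i + 1, n):
            raw = float(scores[i, j])
            if normalization == "RAW":
                value = raw
            else:
                value = (raw / 2.0) / float(min(lengths[i], lengths[j]))
            if value >= threshold:
                # attraction: edge weight saturating at ~2 bits/residue
                attraction = min(1.0, (raw / 2.0) / (2.0 * min(lengths[i], lengths[j])))
                g.add_edge(ids[i], ids[j], score=raw, norm=value, attraction=attraction)
    components = sorted(
        (tuple(sorted(c)) for c in nx.connected_components(g)), key=lambda c: c[0]
    )
    return SimilarityGraph(
        graph=g, threshold=threshold, normalization=normalization, components=components
    )


def layout(graph: SimilarityGraph, seed: int = 0, iterations: int = 500):
    """Optional force-directed 2D layout (visualization only)."""
    return nx.spring_layout(
        graph.graph, weight="attraction", seed=seed, iterations=iterations
    )
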