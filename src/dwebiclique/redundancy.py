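"""Sequence-redundancy removal between interaction chain pairs.

Two chain pairs (A_i, B_i) and (A_j, B_j) are redundant when both chains
match directly — sim(A_i, A_j) > s and sim(B_i, B_j) > s — or crosswise —
sim(A_i, B_j) > s and sim(B_i, A_j) > s — with s = 90 % by default.
Similarity is percent identity over the best local alignment (BLOSUM62,
affine gap open 11 / extend 1, no low-complexity masking). A greedy scan
in input order keeps the first member of each redundant group.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from functools import lru_cache
from typing import Dict, List, Sequence, Tuple

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

logger = logging.getLogger(__name__)

SIMILARITY_THRESHOLD = 90.0  # percent


@lru_cache(maxsize=1)
def _aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11.0
    aligner.extend_gap_score = -1.0
    return aligner


def pairwise_similarity(seq_a: str, seq_b: str) -> float:
    """Percent identity over the best local alignment (aligned columns,
    gaps included in the denominator). Symmetric by construction."""
    if not seq_a or not seq_b:
        raise ValueError("sequences must be non-empty")
    alignments = _aligner().align(seq_a, seq_b)
    try:
        alignment = alignments[0]
    except IndexError:
        return 0.0  # no positively scoring local alignment at all
    counts = alignment.counts()
    length = alignment.length
    if length == 0:
        return 0.0
    return 100.0 * counts.identities / length


@dataclass
class ChainPairSeqs:
    """Sequences of one interaction's two chains, for redundancy scanning."""

    pair_id: str
    seq_a: str
    seq_b: str


class SimilarityMatrix:
    """Cached symmetric percent-similarity lookup over chain sequences."""

    def __init__(self):
        self._cache: Dict[Tuple[str, str], float] = {}

    def similarity(self, seq_a: str, seq_b: str) -> float:
        if seq_a is seq_b or seq_a == seq_b:
            return 100.0
        key = (seq_a, seq_b) if seq_a <= seq_b else (seq_b, seq_a)
        if key not in self._cache:
            self._cache[key] = pairwise_similarity(*key)
        return self._cache[key]

    def matrix(self, sequences: Sequence[str]) -> np.ndarray:
        n = len(sequences)
        m = np.full((n, n), 100.0)
        for i in range(n):
            for j in range(i + 1, n):
                m[i, j] = m[j, i] = self.similarity(sequences[i], sequences[j])
        return m


def pairs_redundant(
    p: ChainPairSeqs,
    q: ChainPairSeqs,
    s: float = SIMILARITY_THRESHOLD,
    sims: SimilarityMatrix | None = None,
) -> bool:
    """Direct or crosswise both-chain similarity strictly above ``s``."""
    sims = sims or SimilarityMatrix()
    direct = (
        sims.similarity(p.seq_a, q.seq_a) > s
        and sims.similarity(p.seq_b, q.seq_b) > s
    )
    if direct:
        return True
    return (
        sims.similarity(p.seq_a, q.seq_b) > s
        and sims.similarity(p.seq_b, q.seq_a) > s
    )


def remove_redundant_pairs(
    pairs: Sequence[ChainPairSeqs],
    s: float = SIMILARITY_THRESHOLD,
) -> Tuple[List[ChainPairSeqs], List[Tuple[str, str]]]:
    """Greedy first-kept scan: each pair is kept unless redundant with an
    already-kept pair. Returns (retained, removed) where ``removed`` lists
    (removed_id, kept_id_that_triggered) tuples."""
    sims = SimilarityMatrix()
    retained: List[ChainPairSeqs] = []
    removed: List[Tuple[str, str]] = []
    for cand in pairs:
        trigger = next(
            (kept for kept in retained if pairs_redundant(cand, kept, s, sims)),
            None,
        )
        if trigger is None:
            retained.append(cand)
        else:
            logger.info("removing redundant pair %s (matches %s)",
                        cand.pair_id, trigger.pair_id)
            removed.append((cand.pair_id, trigger.pair_id))
    return retained, removed
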