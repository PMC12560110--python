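"""Pairwise proteome comparison: best full-length homologs and unique proteins.

Each query protein is locally aligned (Smith-Waterman, BLOSUM62, gap open
11 / extend 1 — a gap of length L costs 11 + L) against candidate targets
sharing at least one exact 3-mer.  The *best full-length hit* is the
highest-scoring hit covering at least ``full_length_min_cov`` percent of
the query and scoring at least ``min_score``; when no hit qualifies the
query has no homolog (reported as 0.00 identity).  E-values are not used:
an e-value depends on database size and search-tool calibration, so the
"no hit" boundary is a raw alignment-score threshold instead.

A protein is *unique* to its proteome when it is longer than
``unique_min_len`` residues and has no qualifying hit in any other
proteome.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from Bio.Align import PairwiseAligner, substitution_matrices

from .errors import DataError
from .io_formats import ProteinRecord

__all__ = ["CompareParams", "HomologHit", "best_full_length_hit", "unique_proteins"]


@dataclass(frozen=True)
class CompareParams:
    matrix: str = "BLOSUM62"
    gap_open: float = 11.0
    gap_extend: float = 1.0
    full_length_min_cov: float = 70.0  # percent of the query
    unique_min_len: int = 100  # residues; "larger than" (strict)
    min_score: float = 50.0  # raw-score floor below which a hit is "no hit"
    seed_k: int = 3

    def __post_init__(self) -> None:
        if self.gap_open <= 0 or self.gap_extend <= 0 or self.min_score <= 0:
            raise ValueError("thresholds must be positive")


@dataclass
class HomologHit:
    query_id: str
    subject_id: str
    identity_percent: float
    query_coverage_percent: float
    score: float

    def report_row(self) -> dict:
        return {
            "query_id": self.query_id,
            "subject_id": self.subject_id,
            "identity_percent": f"{self.identity_percent:.2f}",
            "query_coverage_percent": f"{self.query_coverage_percent:.2f}",
            "score": f"{self.score:.1f}",
        }


def _aa_aligner(params: CompareParams) -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load(params.matrix)
    aligner.open_gap_score = -(params.gap_open + params.gap_extend)
    aligner.extend_gap_score = -params.gap_extend
    return aligner


def _kmer_set(seq: str, k: int) -> set[str]:
    return {seq[i : i + k] for i in range(len(seq) - k + 1)}


def _align_pair(
    aligner: PairwiseAligner, query: ProteinRecord, target: ProteinRecord
) -> HomologHit | None:
    try:
        alignments = aligner.align(query.seq, target.seq)
        if len(alignments) == 0:
            return None
        aln = alignments[0]
    except (OverflowError, MemoryError):
        return None
    if aln.score <= 0:
        return None
    counts = aln.counts()
    columns = counts.identities + counts.mismatches + counts.gaps
    if columns == 0:
        return None
    aligned_query = sum(int(qe - qs) for qs, qe in aln.aligned[0])
    return HomologHit(
        query_id=query.id,
        subject_id=target.id,
        identity_percent=100.0 * counts.identities / columns,
        query_coverage_percent=100.0 * aligned_query / query.length,
        score=float(aln.score),
    )


def best_full_length_hit(
    query: ProteinRecord,
    target_proteome: Sequence[ProteinRecord],
    params: CompareParams | None = None,
    exhaustive: bool = False,
) -> HomologHit | None:
    """Highest-scoring qualifying hit of ``query`` in a target proteome.

    Qualifying means query coverage >= ``full_length_min_cov`` and score >=
    ``min_score``.  Ties are broken by higher identity, then lexicographic
    subject id, so the result is deterministic.  Returns None when nothing
    qualifies.  ``exhaustive=True`` skips the shared-3-mer prefilter and
    aligns against every target (the reference mode used to validate the
    prefilter).
    """
    params = params or CompareParams()
    if not target_proteome:
        raise DataError("target proteome is empty")
    aligner = _aa_aligner(params)
    if exhaustive:
        candidates = list(target_proteome)
    else:
        qkmers = _kmer_set(query.seq, params.seed_k)
        candidates = [t for t in target_proteome if qkmers & _kmer_set(t.seq, params.seed_k)]
    best: HomologHit | None = None
    for target in candidates:
        hit = _align_pair(aligner, query, target)
        if hit is None:
            continue
        if hit.query_coverage_percent < params.full_length_min_cov or hit.score < params.min_score:
            continue
        if best is None or (hit.score, hit.identity_percent, _RevLex(hit.subject_id)) > (
            best.score,
            best.identity_percent,
            _RevLex(best.subject_id),
        ):
            best = hit
    return best


class _RevLex:
    """Wrapper making the lexicographically smaller id compare as larger."""

    __slots__ = ("s",)

    def __init__(self, s: str):
        self.s = s

    def __gt__(self, other: "_RevLex") -> bool:
        return self.s < other.s

    def __lt__(self, other: "_RevLex") -> bool:
        return self.s > other.s

    def __eq__(self, other: object) -> bool:
        return isinstance(other, _RevLex) and self.s == other.s


def unique_proteins(
    focal_proteome: Sequence[ProteinRecord],
    other_proteomes: Sequence[Sequence[ProteinRecord]],
    params: CompareParams | None = None,
) -> list[ProteinRecord]:
    """Proteins longer than ``unique_min_len`` with no qualifying hit anywhere.

    A protein is dropped from the unique set as soon as any other proteome
    contains a hit with score >= ``min_score`` and query coverage >=
    ``full_length_min_cov``.
    """
    params = params or CompareParams()
    if not other_proteomes:
        raise DataError("unique_proteins requires at least one other proteome")
    unique = []
    for protein in focal_proteome:
        if protein.length <= params.unique_min_len:
            continue
        if all(
            best_full_length_hit(protein, other, params) is None for other in other_proteomes
        ):
            unique.append(protein)
    return unique
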