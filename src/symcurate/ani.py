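"""ANIb-style average nucleotide identity between two genomes.

The query genome is cut into consecutive non-overlapping fragments
(default 1020 bp, terminal remainder kept), each fragment is locally
aligned to the reference, and weak hits are discarded (identity < 30% or
fragment coverage < 70%).  The reported ANI is the mean identity of the
retained fragments; the aligned fraction is the share of fragments
retained.  The result is directional (query -> reference); a symmetric
value averages both directions.

Alignment is seed-and-extend: candidate reference regions are located by
exact shared k-mers (default k = 15) binned by alignment diagonal, and the
best-scoring Smith-Waterman local alignment over those regions is kept
(match +2, mismatch -3, gap open -5, gap extend -2 — a gap of length L
costs 5 + 2L).  Both reference strands are searched.  An exhaustive mode
that aligns every fragment against the full reference without seeding
exists to bound the seeding approximation.
"""

from __future__ import annotations

import math
from collections import defaultdict
from dataclasses import dataclass
from typing import Iterator, Sequence

from Bio.Align import PairwiseAligner
from Bio.Seq import reverse_complement

from .errors import DataError
from .io_formats import Contig

__all__ = [
    "AniParams",
    "AniResult",
    "FragmentHit",
    "fragment_genome",
    "align_fragment",
    "compute_ani",
]


@dataclass(frozen=True)
class AniParams:
    fragment_bp: int = 1020
    min_identity: float = 30.0  # percent
    min_frag_cov: float = 70.0  # percent of fragment length
    seed_k: int = 15
    diag_bin_bp: int = 250
    pad_bp: int = 200
    max_candidates: int = 4  # diagonal bins explored per strand

    def __post_init__(self) -> None:
        if self.fragment_bp <= 0 or self.seed_k <= 0:
            raise ValueError("fragment_bp and seed_k must be positive")
        for v in (self.min_identity, self.min_frag_cov):
            if not 0 < v <= 100:
                raise ValueError("identity/coverage thresholds must be in (0, 100]")


@dataclass
class AniResult:
    query_id: str
    ref_id: str
    ani_percent: float  # NaN when no fragment is retained
    aligned_fraction: float  # percent of fragments retained
    n_fragments: int
    n_retained: int


@dataclass
class FragmentHit:
    identity_percent: float
    coverage_percent: float
    score: float


def _nt_aligner() -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = 2
    aligner.mismatch_score = -3
    aligner.open_gap_score = -7  # open(5) + first extension(2)
    aligner.extend_gap_score = -2
    return aligner


def fragment_genome(contigs: Sequence[Contig], fragment_bp: int = 1020) -> list[str]:
    """Cut each contig into consecutive fragments of ``fragment_bp``.

    The terminal remainder of each contig is kept as its own (shorter)
    fragment.
    """
    if not contigs:
        raise DataError("cannot fragment an empty assembly")
    fragments = []
    for c in contigs:
        for start in range(0, c.length, fragment_bp):
            fragments.append(c.seq[start : start + fragment_bp])
    return fragments


class _SeedIndex:
    """Exact k-mer position index over the forward strands of a genome."""

    def __init__(self, contigs: Sequence[Contig], k: int):
        self.k = k
        self.seqs = {c.id: c.seq for c in contigs}
        self.index: dict[str, list[tuple[str, int]]] = defaultdict(list)
        for c in contigs:
            seq = c.seq
            for i in range(len(seq) - k + 1):
                kmer = seq[i : i + k]
                if "N" not in kmer:
                    self.index[kmer].append((c.id, i))

    def candidate_windows(
        self, fragment: str, params: AniParams
    ) -> Iterator[tuple[str, int, int]]:
        """Yield (contig_id, start, end) reference windows worth aligning.

        Seed hits are grouped by (contig, diagonal bin); the densest bins
        are expanded by the fragment length plus padding so that small
        indels shifting the diagonal stay inside the window.
        """
        k = self.k
        bins: dict[tuple[str, int], int] = defaultdict(int)
        for qpos in range(len(fragment) - k + 1):
            for cid, rpos in self.index.get(fragment[qpos : qpos + k], ()):
                bins[(cid, (rpos - qpos) // params.diag_bin_bp)] += 1
        top = sorted(bins.items(), key=lambda kv: (-kv[1], kv[0]))[: params.max_candidates]
        w = params.diag_bin_bp
        for (cid, b), _count in top:
            ref = self.seqs[cid]
            start = max(0, (b - 1) * w - params.pad_bp)
            end = min(len(ref), (b + 2) * w + len(fragment) + params.pad_bp)
            yield cid, start, end


def _best_local_hit(aligner: PairwiseAligner, fragment: str, window: str) -> FragmentHit | None:
    """Best local alignment of ``fragment`` against ``window`` as a hit."""
    try:
        alignments = aligner.align(fragment, window)
        if len(alignments) == 0:
            return None
        aln = alignments[0]
    except (OverflowError, MemoryError):  # pathological ambiguity; treat as no hit
        return None
    counts = aln.counts()
    columns = counts.identities + counts.mismatches + counts.gaps
    if columns == 0:
        return None
    aligned_query = sum(int(qe - qs) for qs, qe in aln.aligned[0])
    return FragmentHit(
        identity_percent=100.0 * counts.identities / columns,
        coverage_percent=100.0 * aligned_query / len(fragment),
        score=float(aln.score),
    )


def align_fragment(
    fragment: str,
    index: _SeedIndex,
    params: AniParams | None = None,
    aligner: PairwiseAligner | None = None,
) -> FragmentHit | None:
    """Best seeded local alignment of one fragment against both strands.

    Returns None when no seed is shared with the reference (the fragment
    is unaligned).
    """
    params = params or AniParams()
    aligner = aligner or _nt_aligner()
    best: FragmentHit | None = None
    for oriented in (fragment, reverse_complement(fragment)):
        for cid, start, end in index.candidate_windows(oriented, params):
            hit = _best_local_hit(aligner, oriented, index.seqs[cid][start:end])
            if hit is not None and (best is None or hit.score > best.score):
                best = hit
    return best


def _align_fragment_exhaustive(
    fragment: str, ref_contigs: Sequence[Contig], aligner: PairwiseAligner
) -> FragmentHit | None:
    """Seedless reference mode: align against every full reference contig."""
    best: FragmentHit | None = None
    for oriented in (fragment, reverse_complement(fragment)):
        for c in ref_contigs:
            hit = _best_local_hit(aligner, oriented, c.seq)
            if hit is not None and (best is None or hit.score > best.score):
                best = hit
    return best


def compute_ani(
    query_contigs: Sequence[Contig],
    ref_contigs: Sequence[Contig],
    params: AniParams | None = None,
    query_id: str = "query",
    ref_id: str = "reference",
    symmetric: bool = False,
    exhaustive: bool = False,
) -> AniResult:
    """ANIb of a query genome against a reference genome.

    With ``symmetric=True`` the reported ANI and aligned fraction are the
    means of the two directions.  ``exhaustive=True`` bypasses seeding and
    aligns every fragment against the whole reference (slow; used to bound
    the seed-and-extend approximation).
    """
    params = params or AniParams()
    if not query_contigs or not ref_contigs:
        raise DataError("both genomes must be non-empty")
    if symmetric:
        fwd = compute_ani(query_contigs, ref_contigs, params, query_id, ref_id, exhaustive=exhaustive)
        rev = compute_ani(ref_contigs, query_contigs, params, ref_id, query_id, exhaustive=exhaustive)
        ani = (fwd.ani_percent + rev.ani_percent) / 2.0
        return AniResult(
            query_id=query_id,
            ref_id=ref_id,
            ani_percent=ani,
            aligned_fraction=(fwd.aligned_fraction + rev.aligned_fraction) / 2.0,
            n_fragments=fwd.n_fragments + rev.n_fragments,
            n_retained=fwd.n_retained + rev.n_retained,
        )
    aligner = _nt_aligner()
    fragments = fragment_genome(query_contigs, params.fragment_bp)
    index = None if exhaustive else _SeedIndex(ref_contigs, params.seed_k)
    retained: list[float] = []
    for frag in fragments:
        if exhaustive:
            hit = _align_fragment_exhaustive(frag, ref_contigs, aligner)
        else:
            hit = align_fragment(frag, index, params, aligner)
        if (
            hit is not None
            and hit.identity_percent >= params.min_identity
            and hit.coverage_percent >= params.min_frag_cov
        ):
            retained.append(hit.identity_percent)
    n = len(fragments)
    return AniResult(
        query_id=query_id,
        ref_id=ref_id,
        ani_percent=sum(retained) / len(retained) if retained else math.nan,
        aligned_fraction=100.0 * len(retained) / n,
        n_fragments=n,
        n_retained=len(retained),
    )
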