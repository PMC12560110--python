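"""Trait-based plasmid prediction for draft symbiont assemblies.

Contigs over ``min_len`` (default 5 kb) are flagged as plasmid candidates
when they show all three traits shared by known *Cardinium* plasmids:

1. **GC** — GC content reduced relative to the pooled assembly GC by at
   least ``gc_delta_min`` percentage points (known plasmids sit ~31.5%
   against ~36% chromosomes, so the default 3.0 leaves margin without
   admitting chromosome contigs);
2. **PAR** — at least one plasmid-partitioning gene (ParA/ParB-like
   product) on the contig, with more than one partitioning-gene copy in
   the whole assembly;
3. **CONTENT** — no annotated housekeeping genes, together with an
   enrichment of hypothetical proteins (fraction >= ``hypothetical_frac_min``)
   or at least one mobile genetic element.

Keyword matching is case-insensitive substring matching on feature product
strings; an empty product counts as hypothetical.  Since fragmented
assemblies split plasmids over several contigs, all flagged contigs are
additionally pooled into a single candidate with summed length and pooled
GC.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

from .errors import DataError
from .io_formats import Contig, FeatureRecord
from .seqstats import assembly_stats, gc_content

__all__ = ["PlasmidParams", "PlasmidCall", "PlasmidCandidate", "score_contig", "predict_plasmids"]

_DEFAULT_PARTITION = ("parA", "parB", "partition")
_DEFAULT_HOUSEKEEPING = (
    "ribosomal protein",
    "tRNA ligase",
    "synthetase",
    "DNA polymerase",
    "RNA polymerase",
    "gyrase",
    "elongation factor",
    "chaperon",
)
_DEFAULT_MGE = ("transposase", "integrase", "recombinase", "phage")


@dataclass(frozen=True)
class PlasmidParams:
    min_len: int = 5000
    gc_delta_min: float = 3.0
    partition_keywords: tuple[str, ...] = _DEFAULT_PARTITION
    housekeeping_keywords: tuple[str, ...] = _DEFAULT_HOUSEKEEPING
    mge_keywords: tuple[str, ...] = _DEFAULT_MGE
    hypothetical_frac_min: float = 0.5

    def __post_init__(self) -> None:
        if self.min_len <= 0:
            raise ValueError("min_len must be positive")
        if not (self.partition_keywords and self.housekeeping_keywords and self.mge_keywords):
            raise ValueError("keyword lists must be non-empty")


@dataclass
class PlasmidCall:
    contig_id: str
    flagged: bool
    evaluated: bool
    gc_delta: float
    partition_hits: list[str] = field(default_factory=list)
    assembly_partition_copies: int = 0
    housekeeping_count: int = 0
    hypothetical_fraction: float = 0.0
    mge_count: int = 0
    traits_met: set[str] = field(default_factory=set)
    length: int = 0

    def report_row(self) -> dict:
        return {
            "contig_id": self.contig_id,
            "flagged": str(self.flagged).lower(),
            "evaluated": str(self.evaluated).lower(),
            "length": self.length,
            "gc_delta": f"{self.gc_delta:.2f}",
            "traits_met": ",".join(sorted(self.traits_met)),
            "partition_hits": len(self.partition_hits),
            "assembly_partition_copies": self.assembly_partition_copies,
            "housekeeping_count": self.housekeeping_count,
            "hypothetical_fraction": f"{self.hypothetical_fraction:.3f}",
            "mge_count": self.mge_count,
        }


@dataclass
class PlasmidCandidate:
    """Pooled multi-contig plasmid candidate (one per assembly)."""

    contig_ids: list[str]
    total_length: int
    gc_percent: float


def _matches(product: str, keywords: Sequence[str]) -> bool:
    p = product.lower()
    return any(k.lower() in p for k in keywords)


def _is_hypothetical(product: str) -> bool:
    return product.strip() == "" or "hypothetical" in product.lower()


def count_partition_features(
    features: Sequence[FeatureRecord], params: PlasmidParams | None = None
) -> int:
    """Number of partitioning-keyword features across a whole feature set."""
    params = params or PlasmidParams()
    return sum(1 for f in features if _matches(f.product, params.partition_keywords))


def score_contig(
    contig: Contig,
    features: Sequence[FeatureRecord],
    assembly_gc_percent: float,
    assembly_partition_copies: int,
    params: PlasmidParams | None = None,
) -> PlasmidCall:
    """Evaluate the three plasmid traits on one contig.

    ``features`` must be restricted to this contig.  Contigs shorter than
    ``min_len`` are never evaluated and return an unflagged call with no
    traits.
    """
    params = params or PlasmidParams()
    bad = [f.contig_id for f in features if f.contig_id != contig.id]
    if bad:
        raise DataError(f"features for {bad[0]!r} passed to score_contig({contig.id!r})")
    gc_delta = assembly_gc_percent - contig.gc * 100.0
    if contig.length < params.min_len:
        return PlasmidCall(
            contig_id=contig.id,
            flagged=False,
            evaluated=False,
            gc_delta=gc_delta,
            length=contig.length,
        )
    partition_hits = [
        f"{f.contig_id}:{f.start}-{f.end}"
        for f in features
        if _matches(f.product, params.partition_keywords)
    ]
    housekeeping = sum(1 for f in features if _matches(f.product, params.housekeeping_keywords))
    mge = sum(1 for f in features if _matches(f.product, params.mge_keywords))
    hyp_frac = (
        sum(1 for f in features if _is_hypothetical(f.product)) / len(features)
        if features
        else 0.0
    )
    traits = set()
    if gc_delta >= params.gc_delta_min:
        traits.add("GC")
    if partition_hits and assembly_partition_copies > 1:
        traits.add("PAR")
    if housekeeping == 0 and (hyp_frac >= params.hypothetical_frac_min or mge >= 1):
        traits.add("CONTENT")
    return PlasmidCall(
        contig_id=contig.id,
        flagged=traits == {"GC", "PAR", "CONTENT"},
        evaluated=True,
        gc_delta=gc_delta,
        partition_hits=partition_hits,
        assembly_partition_copies=assembly_partition_copies,
        housekeeping_count=housekeeping,
        hypothetical_fraction=hyp_frac,
        mge_count=mge,
        traits_met=traits,
        length=contig.length,
    )


def predict_plasmids(
    assembly: Sequence[Contig],
    features: Sequence[FeatureRecord],
    params: PlasmidParams | None = None,
) -> tuple[list[PlasmidCall], PlasmidCandidate | None]:
    """Score every contig and pool flagged contigs into one candidate.

    Returns ``(calls, candidate)`` where ``candidate`` is None when no
    contig is flagged.  Pooling reflects that a fragmented plasmid spans
    several contigs; when several distinct plasmids coexist they are
    reported together (a documented simplification).
    """
    params = params or PlasmidParams()
    stats = assembly_stats(assembly)
    copies = count_partition_features(features, params)
    by_contig: dict[str, list[FeatureRecord]] = {c.id: [] for c in assembly}
    for f in features:
        if f.contig_id in by_contig:
            by_contig[f.contig_id].append(f)
    calls = [
        score_contig(c, by_contig[c.id], stats.gc_percent, copies, params) for c in assembly
    ]
    flagged = [call.contig_id for call in calls if call.flagged]
    if not flagged:
        return calls, None
    flagged_contigs = [c for c in assembly if c.id in set(flagged)]
    pooled_seq = "".join(c.seq for c in flagged_contigs)
    candidate = PlasmidCandidate(
        contig_ids=flagged,
        total_length=sum(c.length for c in flagged_contigs),
        gc_percent=gc_content(pooled_seq) * 100.0,
    )
    return calls, candidate
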