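"""Per-contig and whole-assembly sequence statistics.

GC content is computed over unambiguous bases only: ambiguity codes and N
are excluded from both numerator and denominator.  N50 uses the cumulative
sum crossing definition: sort contig lengths descending and take the first
length at which the running total reaches half the assembly size.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

from .errors import DataError
from .io_formats import Contig

__all__ = ["AssemblyStats", "gc_content", "n50", "assembly_stats"]


@dataclass(frozen=True)
class AssemblyStats:
    total_size: int
    n_contigs: int
    n50: int
    gc_percent: float


def _base_counts(seq: str) -> tuple[int, int]:
    """(GC count, unambiguous base count) for an upper-case sequence."""
    g = seq.count("G")
    c = seq.count("C")
    a = seq.count("A")
    t = seq.count("T")
    return g + c, a + c + g + t


def gc_content(seq: str) -> float:
    """GC fraction (#G + #C) / (#A + #C + #G + #T) of one sequence.

    Returns NaN when the sequence holds no unambiguous bases; an empty
    sequence is a hard error.
    """
    if not seq:
        raise DataError("gc_content of an empty sequence is undefined")
    gc, unambig = _base_counts(seq.upper())
    if unambig == 0:
        return math.nan
    return gc / unambig


def n50(lengths: Sequence[int]) -> int:
    """Largest contig length L with cumulative length (descending) >= total/2."""
    if not lengths:
        raise DataError("n50 of an empty length list is undefined")
    if any(n <= 0 for n in lengths):
        raise DataError("n50 requires positive lengths")
    total = sum(lengths)
    acc = 0
    for n in sorted(lengths, reverse=True):
        acc += n
        if acc >= total / 2:
            return n
    raise AssertionError("unreachable")  # pragma: no cover


def assembly_stats(contigs: Sequence[Contig]) -> AssemblyStats:
    """Aggregate size, contig count, N50 and pooled %GC over an assembly.

    GC is pooled over all bases of all contigs (not a mean of per-contig
    GC), so long contigs weigh more.
    """
    if not contigs:
        raise DataError("assembly_stats requires at least one contig")
    gc_total = 0
    unambig_total = 0
    for c in contigs:
        gc, unambig = _base_counts(c.seq)
        gc_total += gc
        unambig_total += unambig
    gc_percent = math.nan if unambig_total == 0 else 100.0 * gc_total / unambig_total
    lengths = [c.length for c in contigs]
    return AssemblyStats(
        total_size=sum(lengths),
        n_contigs=len(contigs),
        n50=n50(lengths),
        gc_percent=gc_percent,
    )
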