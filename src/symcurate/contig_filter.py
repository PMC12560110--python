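"""Contig-removal rules for curating a draft symbiont assembly.

A contig is removed when ANY rule fires (the rules are disjunctive):

* ``LEN`` — length strictly below ``min_len`` (a contig of exactly
  ``min_len`` bp is kept),
* ``GC``  — GC strictly above ``max_gc`` percent (exactly ``max_gc`` kept),
* ``TAX`` — taxonomy label differs from ``required_label`` (including the
  unlabelled state),
* ``COV`` — mean depth strictly below ``min_cov``.

All fired rules are recorded, not just the first.  GC is compared on the
percent scale with full precision; no rounding happens before comparison.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .coverage_profile import CoverageSummary
from .errors import DataError
from .io_formats import Contig

__all__ = ["FilterParams", "FilterDecision", "apply_filters"]


@dataclass(frozen=True)
class FilterParams:
    min_len: int = 300
    max_gc: float = 42.0
    min_cov: float = 5.0
    required_label: str = "Cardinium"

    def __post_init__(self) -> None:
        if self.min_len <= 0 or self.max_gc <= 0 or self.min_cov <= 0:
            raise ValueError("filter thresholds must be positive")


@dataclass
class FilterDecision:
    contig_id: str
    kept: bool
    reasons: list[str] = field(default_factory=list)
    length: int = 0
    gc_percent: float = 0.0
    mean_depth: float = 0.0
    label: str | None = None

    def report_row(self) -> dict:
        return {
            "contig_id": self.contig_id,
            "kept": str(self.kept).lower(),
            "reasons": ",".join(self.reasons),
            "length": self.length,
            "gc_percent": f"{self.gc_percent:.2f}",
            "mean_depth": f"{self.mean_depth:.2f}",
            "label": self.label if self.label is not None else "NONE",
        }


def apply_filters(
    contigs: Sequence[Contig],
    summaries: Mapping[str, CoverageSummary],
    labels: Mapping[str, str | None] | None,
    params: FilterParams | None = None,
) -> list[FilterDecision]:
    """Apply the removal rules to every contig, in input order.

    ``labels`` may be None or partial; unlabelled contigs fail the TAX
    rule.  A contig without a coverage summary is a hard error naming it.
    """
    params = params or FilterParams()
    labels = labels or {}
    decisions = []
    for contig in contigs:
        if contig.id not in summaries:
            raise DataError(f"no coverage summary for contig {contig.id!r}")
        summary = summaries[contig.id]
        gc_percent = contig.gc * 100.0
        label = labels.get(contig.id)
        reasons = []
        if contig.length < params.min_len:
            reasons.append("LEN")
        if gc_percent > params.max_gc:
            reasons.append("GC")
        if label != params.required_label:
            reasons.append("TAX")
        if summary.mean_depth < params.min_cov:
            reasons.append("COV")
        decisions.append(
            FilterDecision(
                contig_id=contig.id,
                kept=not reasons,
                reasons=reasons,
                length=contig.length,
                gc_percent=gc_percent,
                mean_depth=summary.mean_depth,
                label=label,
            )
        )
    return decisions
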