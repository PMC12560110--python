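"""Readers and writers for every external format the pipeline touches.

FASTA (nucleotide and amino acid), plain-text SAM, per-position depth TSV,
taxonomy-label TSV, GFF3 / tabular feature files, and the TSV call reports.
All external coordinates are 1-based inclusive (GFF3/SAM convention);
anything half-open is internal.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

import gffutils

from .coverage_profile import DepthTrack
from .errors import DataError

__all__ = [
    "Contig",
    "ProteinRecord",
    "FeatureRecord",
    "read_fasta",
    "write_fasta",
    "read_depth_tsv",
    "depth_from_sam",
    "read_taxonomy_tsv",
    "read_features",
    "write_features_gff3",
    "write_report",
]

_AA_ALPHABET = set("ACDEFGHIKLMNPQRSTVWYX*")


@dataclass(frozen=True)
class Contig:
    """A nucleotide contig; length and GC fraction are derived from ``seq``."""

    id: str
    seq: str

    def __post_init__(self) -> None:
        if not self.seq:
            raise DataError(f"contig {self.id!r} has an empty sequence")

    @property
    def length(self) -> int:
        return len(self.seq)

    @property
    def gc(self) -> float:
        """GC fraction over unambiguous bases; NaN if there are none."""
        from .seqstats import gc_content

        return gc_content(self.seq)


@dataclass(frozen=True)
class ProteinRecord:
    """An amino-acid sequence over the 20 standard residues plus X."""

    id: str
    seq: str

    def __post_init__(self) -> None:
        if not self.seq:
            raise DataError(f"protein {self.id!r} has an empty sequence")
        bad = set(self.seq) - _AA_ALPHABET
        if bad:
            raise DataError(
                f"protein {self.id!r} contains non-standard residues: {sorted(bad)}"
            )

    @property
    def length(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class FeatureRecord:
    """One annotated feature (1-based inclusive coordinates).

    ``product`` may be empty but is never absent; keyword-based trait rules
    treat an empty product as an unannotated (hypothetical) gene.
    """

    contig_id: str
    start: int
    end: int
    strand: str
    ftype: str
    product: str = ""

    def __post_init__(self) -> None:
        if not 1 <= self.start <= self.end:
            raise DataError(
                f"feature on {self.contig_id!r} has invalid coordinates "
                f"{self.start}..{self.end}"
            )
        if self.strand not in {"+", "-", "."}:
            raise DataError(f"feature on {self.contig_id!r} has invalid strand {self.strand!r}")


def read_fasta(path: str | Path, alphabet: str = "nt") -> list[Contig] | list[ProteinRecord]:
    """Read a FASTA file into :class:`Contig` (``nt``) or :class:`ProteinRecord` (``aa``).

    Record ids are the header up to the first whitespace; sequence is
    upper-cased; input order is preserved.  Duplicate ids and empty
    sequences are hard errors.
    """
    if alphabet not in {"nt", "aa"}:
        raise ValueError("alphabet must be 'nt' or 'aa'")
    path = Path(path)
    if not path.exists():
        raise DataError(f"FASTA file not found: {path}")
    records: list = []
    seen: set[str] = set()
    cls = Contig if alphabet == "nt" else ProteinRecord
    for rec in SeqIO.parse(str(path), "fasta"):
        rid = rec.id
        if rid in seen:
            raise DataError(f"duplicate record id {rid!r} in {path}")
        seen.add(rid)
        seq = str(rec.seq).upper()
        if not seq:
            raise DataError(f"record {rid!r} in {path} has an empty sequence")
        records.append(cls(id=rid, seq=seq))
    if not records:
        raise DataError(f"no FASTA records in {path}")
    return records


def write_fasta(records: Iterable[Contig | ProteinRecord], path: str | Path, width: int = 70) -> None:
    seqrecords = [
        SeqRecord(Seq(r.seq), id=r.id, description="") for r in records
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(seqrecords)


def read_depth_tsv(path: str | Path, assembly: Sequence[Contig]) -> dict[str, DepthTrack]:
    """Read ``contig_id<TAB>pos<TAB>depth`` rows into per-contig depth tracks.

    Positions are 1-based; missing positions are depth 0; every assembly
    contig gets a track (all-zero when absent from the file).  A position
    beyond the contig length or a negative depth is a hard error.
    """
    lengths = {c.id: c.length for c in assembly}
    tracks = {cid: np.zeros(n, dtype=np.int64) for cid, n in lengths.items()}
    path = Path(path)
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise DataError(f"{path}:{lineno}: expected 3 tab-separated fields")
            cid, pos_s, depth_s = parts
            if cid not in lengths:
                raise DataError(f"{path}:{lineno}: unknown contig {cid!r}")
            pos, depth = int(pos_s), int(depth_s)
            if not 1 <= pos <= lengths[cid]:
                raise DataError(
                    f"{path}:{lineno}: position {pos} outside contig {cid!r} "
                    f"(length {lengths[cid]})"
                )
            if depth < 0:
                raise DataError(f"{path}:{lineno}: negative depth for {cid!r}")
            tracks[cid][pos - 1] = depth
    return {cid: DepthTrack(cid, arr) for cid, arr in tracks.items()}


# CIGAR operations that consume the reference.  Deletions (D) count as
# covered (samtools-style pileup breadth semantics); reference skips (N)
# advance the reference without contributing coverage.
_REF_COVERING_OPS = {0, 2, 7, 8}  # M, D, =, X
_REF_SKIP_OP = 3  # N


def depth_from_sam(
    path: str | Path, assembly: Sequence[Contig], min_mapq: int = 0
) -> dict[str, DepthTrack]:
    """Per-base depth from a plain-text SAM file.

    Depth at a position is the number of primary, non-duplicate alignments
    with MAPQ >= ``min_mapq`` whose reference span covers it.  Insertions
    and clips never contribute.  A reference name absent from the assembly
    is a hard error.
    """
    lengths = {c.id: c.length for c in assembly}
    tracks = {cid: np.zeros(n, dtype=np.int64) for cid, n in lengths.items()}
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for ref in sam.references:
            if ref not in lengths:
                raise DataError(f"SAM reference {ref!r} absent from the assembly")
        for aln in sam.fetch(until_eof=True):
            if aln.is_unmapped or aln.is_secondary or aln.is_supplementary or aln.is_duplicate:
                continue
            if aln.mapping_quality < min_mapq:
                continue
            track = tracks[aln.reference_name]
            pos = aln.reference_start  # 0-based
            for op, length in aln.cigartuples or ():
                if op in _REF_COVERING_OPS:
                    end = min(pos + length, len(track))
                    track[pos:end] += 1
                    pos += length
                elif op == _REF_SKIP_OP:
                    pos += length
    return {cid: DepthTrack(cid, arr) for cid, arr in tracks.items()}


def read_taxonomy_tsv(path: str | Path) -> dict[str, str | None]:
    """Read ``contig_id<TAB>label`` rows; the literal label ``NONE`` maps to None.

    Contigs absent from the file are simply absent from the mapping (callers
    treat them as unlabelled).  A contig listed twice is a hard error.
    """
    labels: dict[str, str | None] = {}
    path = Path(path)
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise DataError(f"{path}:{lineno}: expected 2 tab-separated fields")
            cid, label = parts
            if cid in labels:
                raise DataError(f"{path}:{lineno}: duplicate taxonomy label for {cid!r}")
            labels[cid] = None if label == "NONE" else label
    return labels


def read_features(path: str | Path) -> list[FeatureRecord]:
    """Read features from GFF3 or from the tabular fallback format.

    GFF3 is detected by extension (``.gff``, ``.gff3``) or a ``##gff``
    pragma; the product is taken from the column-9 ``product`` attribute.
    The tabular fallback has columns
    ``contig_id  start  end  strand  type  product``.
    """
    path = Path(path)
    is_gff = path.suffix.lower() in {".gff", ".gff3"}
    if not is_gff:
        with open(path) as fh:
            first = fh.readline()
        is_gff = first.startswith("##gff")
    if is_gff:
        feats = []
        for f in gffutils.DataIterator(str(path)):
            product = f.attributes.get("product", [""])
            feats.append(
                FeatureRecord(
                    contig_id=f.seqid,
                    start=f.start,
                    end=f.end,
                    strand=f.strand if f.strand in {"+", "-"} else ".",
                    ftype=f.featuretype,
                    product=product[0] if product else "",
                )
            )
        return feats
    feats = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 5:
                raise DataError(f"{path}:{lineno}: expected >= 5 tab-separated fields")
            cid, start, end, strand, ftype = parts[:5]
            product = parts[5] if len(parts) > 5 else ""
            feats.append(
                FeatureRecord(
                    contig_id=cid,
                    start=int(start),
                    end=int(end),
                    strand=strand,
                    ftype=ftype,
                    product=product,
                )
            )
    return feats


def write_features_gff3(features: Iterable[FeatureRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for i, f in enumerate(features, 1):
            attrs = f"ID=feat{i};product={f.product}"
            fh.write(
                f"{f.contig_id}\tsymcurate\t{f.ftype}\t{f.start}\t{f.end}\t.\t{f.strand}\t.\t{attrs}\n"
            )


def write_report(calls: Sequence, path: str | Path) -> None:
    """Write per-contig calls as a TSV with fixed, documented columns.

    Accepts the decision/call dataclasses from the filtering, demultiplexing
    and plasmid modules (anything exposing ``report_row()``).  Rows are
    written in input order; re-running on the same input is byte-identical.
    An empty call list yields a header-only file.
    """
    if calls:
        header = list(calls[0].report_row().keys())
    else:
        header = ["contig_id"]
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(header)
        for call in calls:
            row = call.report_row()
            if list(row.keys()) != header:
                raise DataError("mixed call types passed to write_report")
            writer.writerow(list(row.values()))
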