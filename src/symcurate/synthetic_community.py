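"""Seeded generator of a synthetic coinfection dataset with ground truth.

The generator emulates the statistical structure the curation pipeline
assumes, for a host coinfected by a high-density symbiont strain (A) and a
low-density strain (B):

* strain A: a random chromosome at symbiont GC (~36%) plus a low-GC
  (~31.5%) plasmid carrying partitioning genes (parA/parB);
* strain B: derived from strain A by iid substitutions at a chosen
  divergence, so the expected ANI between the strains is (1 - d) * 100;
* shared mobile repeats: transposase-like elements copied verbatim into
  several loci of both strains — in a single-infection read set these are
  the only places on strain-B contigs that attract (cross-mapped) strain-A
  reads;
* host contigs at elevated GC (~45%);
* depth tracks for a single-infection sample (strain A + host) and a
  coinfection sample (A + B + host), simulated by uniform random read
  placement (Lander-Waterman) at strain-specific mean depths.

Cross-mapping of shared repeats is modelled deterministically: the depth
over strain A's copy of a repeat element is pasted onto strain-B repeat
intervals in the single-infection track.  This idealises short-read
multi-mapping; it is not calibrated against any particular mapper.

Everything is driven by one seed; the same seed reproduces the dataset
byte for byte.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .coverage_profile import DepthTrack
from .errors import SymcurateError
from .io_formats import (
    Contig,
    FeatureRecord,
    write_fasta,
    write_features_gff3,
)

__all__ = ["SimParams", "SimTruth", "SimDataset", "generate", "make_worked_fixture", "WorkedFixture"]

STRAIN_A = "STRAIN_A"
STRAIN_B = "STRAIN_B"
HOST = "HOST"
PLASMID_A = "PLASMID_A"

_HOUSEKEEPING_PRODUCTS = (
    "30S ribosomal protein S3",
    "50S ribosomal protein L2",
    "DNA gyrase subunit A",
    "elongation factor Tu",
    "DNA polymerase III subunit alpha",
    "DNA-directed RNA polymerase subunit beta",
    "chaperonin GroEL",
    "leucine--tRNA ligase",
)
_TRANSPOSASE_PRODUCT = "IS5 family transposase"


@dataclass(frozen=True)
class SimParams:
    """Study conditions for the synthetic coinfection.

    The defaults describe a desk-scale (200 kb) version of a ~1 Mb
    high-density / low-density coinfection: strain A around 300x mean
    depth in the single-infection sample, strain B around 10x in the
    coinfection, 10% nucleotide divergence between the strains, a low-GC
    20 kb plasmid in strain A, host contigs at 45% GC, and a handful of
    kb-scale transposase-like repeats shared verbatim by both strains.
    """

    seed: int = 1
    strainA_size: int = 200_000
    strainB_size: int = 200_000
    divergence_AB: float = 0.10
    strainA_mean_depth: float = 300.0
    strainB_mean_depth: float = 10.0
    host_contigs: int = 8
    host_contig_size: int = 10_000
    host_gc: float = 0.45
    host_mean_depth: float = 30.0
    symbiont_gc: float = 0.36
    plasmid_size: int = 20_000
    plasmid_gc: float = 0.315
    split_plasmid: bool = False
    n_shared_repeats: int = 3
    repeat_len: int = 1000
    repeat_copies_per_strain: int = 2
    read_len: int = 150
    mean_contig_bp: int = 10_000
    min_contig_bp: int = 2_000

    def __post_init__(self) -> None:
        if min(self.strainA_size, self.strainB_size, self.plasmid_size, self.read_len) <= 0:
            raise ValueError("sizes must be positive")
        for frac in (self.divergence_AB, self.symbiont_gc, self.plasmid_gc, self.host_gc):
            if not 0.0 < frac < 1.0:
                raise ValueError("fractions must be in (0, 1)")
        needed = self.n_shared_repeats * self.repeat_copies_per_strain * self.repeat_len
        if needed > min(self.strainA_size, self.strainB_size) // 2:
            raise SymcurateError("repeat content exceeds half the genome; infeasible")


@dataclass
class SimTruth:
    labels: dict[str, str]  # contig_id -> STRAIN_A | STRAIN_B | HOST | PLASMID_A
    repeat_bearing: dict[str, bool]


@dataclass
class SimDataset:
    params: SimParams
    contigs: list[Contig]  # joint coinfection assembly (A + B + plasmid + host)
    single_depths: dict[str, DepthTrack]  # strain A + host reads only
    coinfection_depths: dict[str, DepthTrack]  # A + B + host reads
    features: list[FeatureRecord]
    taxonomy: dict[str, str | None]
    truth: SimTruth
    strainA_genome: str = ""
    strainB_genome: str = ""

    def strain_contigs(self, *labels: str) -> list[Contig]:
        want = set(labels)
        return [c for c in self.contigs if self.truth.labels[c.id] in want]

    def write(self, outdir: str | Path) -> None:
        """Write the full file set (FASTA, depth TSVs, GFF3, taxonomy, truth)."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_fasta(self.contigs, outdir / "joint_assembly.fasta")
        _write_depth_tsv(self.single_depths, outdir / "single_infection_depth.tsv")
        _write_depth_tsv(self.coinfection_depths, outdir / "coinfection_depth.tsv")
        write_features_gff3(self.features, outdir / "features.gff3")
        with open(outdir / "taxonomy.tsv", "w") as fh:
            for cid, label in self.taxonomy.items():
                fh.write(f"{cid}\t{label if label is not None else 'NONE'}\n")
        with open(outdir / "truth.tsv", "w") as fh:
            fh.write("contig_id\tlabel\trepeat_bearing\n")
            for cid, label in self.truth.labels.items():
                fh.write(f"{cid}\t{label}\t{int(self.truth.repeat_bearing[cid])}\n")


def _write_depth_tsv(tracks: dict[str, DepthTrack], path: Path) -> None:
    with open(path, "w") as fh:
        for cid in tracks:
            d = tracks[cid].depths
            for pos in np.nonzero(d)[0]:
                fh.write(f"{cid}\t{pos + 1}\t{d[pos]}\n")


_BASES = np.frombuffer(b"ACGT", dtype="S1")


def _random_seq(rng: np.random.Generator, length: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(_BASES, size=length, p=p).tobytes().decode()


def _mutate(rng: np.random.Generator, seq: str, rate: float, gc: float = 0.36) -> str:
    """iid substitutions at ``rate``; a hit position always changes base.

    The replacement scheme is flux-balanced for base composition at the
    given GC fraction (an AT base becomes G/C with probability ``gc``,
    else the other AT base, and symmetrically for GC bases), so the
    mutated sequence keeps the original composition in expectation instead
    of drifting toward 50% GC.
    """
    arr = np.frombuffer(seq.encode(), dtype="S1").copy()
    hits = np.nonzero(rng.random(len(arr)) < rate)[0]
    if len(hits) == 0:
        return seq
    old = arr[hits]
    is_gc = (old == b"G") | (old == b"C")
    cross = np.where(is_gc, rng.random(len(hits)) < (1 - gc), rng.random(len(hits)) < gc)
    coin = rng.random(len(hits)) < 0.5
    new = np.empty(len(hits), dtype="S1")
    # class switch: AT -> {G, C} or GC -> {A, T}, an even coin inside the class
    new[cross & is_gc] = np.where(coin[cross & is_gc], b"A", b"T")
    new[cross & ~is_gc] = np.where(coin[cross & ~is_gc], b"G", b"C")
    # within-class change: the other base of the same class
    stay = ~cross
    swap = {b"A": b"T", b"T": b"A", b"G": b"C", b"C": b"G"}
    for b, other in swap.items():
        sel = stay & (old == b)
        new[sel] = other
    arr[hits] = new
    return arr.tobytes().decode()


def _simulate_depth(
    rng: np.random.Generator, length: int, mean_depth: float, read_len: int
) -> np.ndarray:
    """Lander-Waterman per-base depth from uniform random read starts.

    Reads start uniformly over the sequence and are clipped at the end, so
    the expected mean depth stays close to ``mean_depth``.
    """
    n_reads = int(round(mean_depth * length / read_len))
    diff = np.zeros(length + 1, dtype=np.int64)
    if n_reads:
        starts = rng.integers(0, length, size=n_reads)
        ends = np.minimum(starts + read_len, length)
        np.add.at(diff, starts, 1)
        np.add.at(diff, ends, -1)
    return np.cumsum(diff[:-1])


def _breakpoints(
    rng: np.random.Generator,
    length: int,
    params: SimParams,
    keep_out: list[tuple[int, int]],
    forced: list[int],
) -> list[int]:
    """Contig boundaries: random cuts avoiding ``keep_out`` spans, plus forced cuts."""
    n_cuts = max(0, length // params.mean_contig_bp - 1)
    cuts = set(forced)
    candidates = rng.integers(params.min_contig_bp, length - params.min_contig_bp, size=4 * max(1, n_cuts))
    for pos in candidates:
        pos = (int(pos) // 500) * 500  # align to the uniformity-window grid
        if len(cuts) >= n_cuts + len(forced):
            break
        if any(a - params.min_contig_bp < pos < b + params.min_contig_bp for a, b in keep_out):
            continue
        if any(abs(pos - c) < params.min_contig_bp for c in cuts):
            continue
        cuts.add(pos)
    return sorted(cuts)


def _cut(length: int, cuts: list[int]) -> list[tuple[int, int]]:
    bounds = [0] + list(cuts) + [length]
    return [(bounds[i], bounds[i + 1]) for i in range(len(bounds) - 1)]


def _overlap(a0: int, a1: int, b0: int, b1: int) -> tuple[int, int] | None:
    lo, hi = max(a0, b0), min(a1, b1)
    return (lo, hi) if lo < hi else None


def _annotate_chromosome(
    contig_id: str,
    start: int,
    end: int,
    repeat_spans: list[tuple[int, int]],
    rng: np.random.Generator,
) -> list[FeatureRecord]:
    """CDS features every ~1.5 kb: mostly housekeeping, some hypothetical,
    transposases over repeat loci."""
    feats = []
    pos = start
    i = 0
    while pos + 900 <= end:
        f_start, f_end = pos, pos + 900
        in_repeat = any(_overlap(f_start, f_end, r0, r1) for r0, r1 in repeat_spans)
        if in_repeat:
            product = _TRANSPOSASE_PRODUCT
        elif rng.random() < 0.3:
            product = "hypothetical protein"
        else:
            product = _HOUSEKEEPING_PRODUCTS[i % len(_HOUSEKEEPING_PRODUCTS)]
        feats.append(
            FeatureRecord(
                contig_id=contig_id,
                start=f_start - start + 1,
                end=f_end - start,
                strand="+" if i % 2 == 0 else "-",
                ftype="CDS",
                product=product,
            )
        )
        i += 1
        pos += 1500
    return feats


def generate(params: SimParams | None = None) -> SimDataset:
    """Generate the joint assembly, depth tracks, annotation and ground truth."""
    params = params or SimParams()
    rng = np.random.default_rng(params.seed)

    # --- genomes -----------------------------------------------------------
    genome_a = _random_seq(rng, params.strainA_size, params.symbiont_gc)
    genome_b = _mutate(rng, genome_a[: params.strainB_size], params.divergence_AB, params.symbiont_gc)
    if params.strainB_size > params.strainA_size:
        genome_b += _random_seq(rng, params.strainB_size - params.strainA_size, params.symbiont_gc)
    plasmid = _random_seq(rng, params.plasmid_size, params.plasmid_gc)

    # shared repeat elements, pasted verbatim into both strains
    elements = [_random_seq(rng, params.repeat_len, params.symbiont_gc) for _ in range(params.n_shared_repeats)]

    def paste(genome: str, rng_: np.random.Generator) -> tuple[str, list[tuple[int, int, int]]]:
        """Paste each element ``repeat_copies_per_strain`` times; returns
        (genome, [(element_idx, start, end), ...]).

        Loci are aligned to the 500 bp uniformity-window grid and kept well
        apart, so a band-level contig never carries more than one repeat
        locus and the repeat mass always fills whole windows.
        """
        arr = bytearray(genome.encode())
        loci: list[tuple[int, int, int]] = []
        spacing = 6_000
        for ei, el in enumerate(elements):
            placed = 0
            while placed < params.repeat_copies_per_strain:
                start = int(rng_.integers(params.min_contig_bp, len(arr) - params.repeat_len - params.min_contig_bp))
                start = (start // 500) * 500
                end = start + params.repeat_len
                if any(_overlap(start - spacing, end + spacing, s, e) for _, s, e in loci):
                    continue
                arr[start:end] = el.encode()
                loci.append((ei, start, end))
                placed += 1
        return arr.decode(), loci

    genome_a, loci_a = paste(genome_a, rng)
    genome_b, loci_b = paste(genome_b, rng)

    # --- depth on whole genomes -------------------------------------------
    depth_a_single = _simulate_depth(rng, len(genome_a), params.strainA_mean_depth, params.read_len)
    depth_a_coinf = _simulate_depth(rng, len(genome_a), params.strainA_mean_depth, params.read_len)
    depth_b_coinf = _simulate_depth(rng, len(genome_b), params.strainB_mean_depth, params.read_len)
    depth_plasmid_single = _simulate_depth(rng, len(plasmid), params.strainA_mean_depth, params.read_len)
    depth_plasmid_coinf = _simulate_depth(rng, len(plasmid), params.strainA_mean_depth, params.read_len)

    # single-infection sample holds no strain-B reads; repeat intervals on B
    # receive the depth over strain A's first copy of the same element
    # (deterministic cross-mapping idealisation)
    depth_b_single = np.zeros(len(genome_b), dtype=np.int64)
    first_copy_a = {}
    for ei, s, e in loci_a:
        if ei not in first_copy_a:
            first_copy_a[ei] = (s, e)
    for ei, s, e in loci_b:
        a_s, a_e = first_copy_a[ei]
        depth_b_single[s:e] = depth_a_single[a_s:a_e]

    # --- cut genomes into contigs -----------------------------------------
    # Strain B: force one repeat locus onto a small contig so its inflated
    # band-level mean exercises the localization rescue rule.
    rescue_ei, rescue_s, rescue_e = loci_b[0]
    forced_b = [max(params.min_contig_bp, rescue_s - 1500), min(len(genome_b) - params.min_contig_bp, rescue_e + 1500)]
    keep_out_a = [(s, e) for _, s, e in loci_a]
    keep_out_b = [(s, e) for _, s, e in loci_b]
    cuts_a = _breakpoints(rng, len(genome_a), params, keep_out_a, [])
    cuts_b = _breakpoints(rng, len(genome_b), params, keep_out_b, forced_b)

    contigs: list[Contig] = []
    single: dict[str, np.ndarray] = {}
    coinf: dict[str, np.ndarray] = {}
    features: list[FeatureRecord] = []
    labels: dict[str, str] = {}
    repeat_bearing: dict[str, bool] = {}

    def emit_strain(
        prefix: str,
        genome: str,
        spans: list[tuple[int, int]],
        loci: list[tuple[int, int, int]],
        d_single: np.ndarray,
        d_coinf: np.ndarray,
        label: str,
    ) -> None:
        for i, (s, e) in enumerate(spans, 1):
            cid = f"{prefix}_{i:03d}"
            contigs.append(Contig(cid, genome[s:e]))
            single[cid] = d_single[s:e]
            coinf[cid] = d_coinf[s:e]
            local_repeats = []
            for _, rs, re_ in loci:
                ov = _overlap(s, e, rs, re_)
                if ov:
                    local_repeats.append(ov)
            repeat_bearing[cid] = bool(local_repeats)
            labels[cid] = label
            features.extend(_annotate_chromosome(cid, s, e, local_repeats, rng))

    emit_strain("A", genome_a, _cut(len(genome_a), cuts_a), loci_a, depth_a_single, depth_a_coinf, STRAIN_A)
    emit_strain("B", genome_b, _cut(len(genome_b), cuts_b), loci_b, depth_b_single, depth_b_coinf, STRAIN_B)

    # --- plasmid -----------------------------------------------------------
    if params.split_plasmid:
        mid = int(round(params.plasmid_size * 0.6))
        plasmid_spans = [(0, mid), (mid, params.plasmid_size)]
    else:
        plasmid_spans = [(0, params.plasmid_size)]
    par_products = ["plasmid partitioning protein ParA", "ParB family partition protein"]
    for i, (s, e) in enumerate(plasmid_spans, 1):
        cid = f"P_{i:03d}"
        contigs.append(Contig(cid, plasmid[s:e]))
        single[cid] = depth_plasmid_single[s:e]
        coinf[cid] = depth_plasmid_coinf[s:e]
        labels[cid] = PLASMID_A
        repeat_bearing[cid] = False
        # one partitioning gene per plasmid contig, the rest hypothetical + MGE
        features.append(
            FeatureRecord(cid, 101, 1000, "+", "CDS", par_products[(i - 1) % len(par_products)])
        )
        if not params.split_plasmid:
            features.append(FeatureRecord(cid, 1101, 2000, "+", "CDS", par_products[1]))
        pos = 2101
        k = 0
        while pos + 900 <= e - s:
            product = _TRANSPOSASE_PRODUCT if k % 5 == 4 else "hypothetical protein"
            features.append(FeatureRecord(cid, pos, pos + 899, "+", "CDS", product))
            pos += 1500
            k += 1

    # --- host --------------------------------------------------------------
    for i in range(1, params.host_contigs + 1):
        cid = f"H_{i:03d}"
        seq = _random_seq(rng, params.host_contig_size, params.host_gc)
        contigs.append(Contig(cid, seq))
        single[cid] = _simulate_depth(rng, len(seq), params.host_mean_depth, params.read_len)
        coinf[cid] = _simulate_depth(rng, len(seq), params.host_mean_depth, params.read_len)
        labels[cid] = HOST
        repeat_bearing[cid] = False
        for j in range(3):
            features.append(
                FeatureRecord(cid, 200 + j * 2000, 1100 + j * 2000, "+", "CDS", "hypothetical protein")
            )

    taxonomy: dict[str, str | None] = {}
    for cid, label in labels.items():
        taxonomy[cid] = "host" if label == HOST else "Cardinium"

    return SimDataset(
        params=params,
        contigs=contigs,
        single_depths={cid: DepthTrack(cid, arr) for cid, arr in single.items()},
        coinfection_depths={cid: DepthTrack(cid, arr) for cid, arr in coinf.items()},
        features=features,
        taxonomy=taxonomy,
        truth=SimTruth(labels=labels, repeat_bearing=repeat_bearing),
        strainA_genome=genome_a,
        strainB_genome=genome_b,
    )


# ---------------------------------------------------------------------------
# Worked fixture: a tiny, fully hand-checkable dataset.
# ---------------------------------------------------------------------------


def _seq_gc(length: int, gc_bases: int) -> str:
    """Deterministic sequence of ``length`` with exactly ``gc_bases`` G+C."""
    g = gc_bases // 2
    c = gc_bases - g
    at = length - gc_bases
    a = at // 2
    t = at - a
    return "G" * g + "C" * c + "A" * a + "T" * t


@dataclass
class WorkedFixture:
    contigs: list[Contig]
    depth_rows: list[tuple[str, int, int]]  # filter/demux depth (single sample)
    taxonomy: dict[str, str | None]
    features: list[FeatureRecord]
    # hand-enumerated expectations
    expected_filter: dict[str, tuple[bool, tuple[str, ...]]]  # id -> (kept, reasons)
    expected_demux: dict[str, tuple[str, str]]  # id -> (strain, rule)
    expected_plasmid_flagged: tuple[str, ...]
    plasmid_contig_ids: tuple[str, ...]  # the sub-assembly scored for plasmids
    demux_contig_ids: tuple[str, ...]

    def depth_tracks(self) -> dict[str, DepthTrack]:
        lengths = {c.id: c.length for c in self.contigs}
        tracks = {cid: np.zeros(n, dtype=np.int64) for cid, n in lengths.items()}
        for cid, pos, depth in self.depth_rows:
            tracks[cid][pos - 1] = depth
        return {cid: DepthTrack(cid, arr) for cid, arr in tracks.items()}

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_fasta(self.contigs, outdir / "assembly.fasta")
        with open(outdir / "depth.tsv", "w") as fh:
            for cid, pos, depth in self.depth_rows:
                fh.write(f"{cid}\t{pos}\t{depth}\n")
        with open(outdir / "taxonomy.tsv", "w") as fh:
            for cid, label in self.taxonomy.items():
                if label is not None:
                    fh.write(f"{cid}\t{label}\n")
        write_features_gff3(self.features, outdir / "features.gff3")
        with open(outdir / "expected_filter.tsv", "w") as fh:
            fh.write("contig_id\tkept\treasons\n")
            for cid, (kept, reasons) in self.expected_filter.items():
                fh.write(f"{cid}\t{str(kept).lower()}\t{','.join(reasons)}\n")
        with open(outdir / "expected_demux.tsv", "w") as fh:
            fh.write("contig_id\tstrain\trule_fired\n")
            for cid, (strain, rule) in self.expected_demux.items():
                fh.write(f"{cid}\t{strain}\t{rule}\n")
        with open(outdir / "expected_plasmid.tsv", "w") as fh:
            fh.write("contig_id\tflagged\n")
            for cid in self.plasmid_contig_ids:
                fh.write(f"{cid}\t{str(cid in self.expected_plasmid_flagged).lower()}\n")


def make_worked_fixture() -> WorkedFixture:
    """Tiny deterministic dataset whose filter/demux/plasmid outcomes were
    enumerated by hand from the rules.

    Filter contigs (defaults 300 bp / 42% GC / 5x / label Cardinium):

    ========== ====== ===== ===== ========= ==================
    contig      len    %GC   mean  label     expected
    ========== ====== ===== ===== ========= ==================
    f_pass      400    36    10    Cardinium kept
    f_len       250    36    10    Cardinium removed LEN
    f_len_edge  300    36    10    Cardinium kept (boundary)
    f_gc        400    43    10    Cardinium removed GC
    f_gc_edge   400    42    10    Cardinium kept (boundary)
    f_tax       400    36    10    (none)    removed TAX
    f_host      400    45    10    host      removed GC,TAX
    f_cov       400    36    2     Cardinium removed COV
    f_cov_edge  400    36    5.0   Cardinium kept (boundary)
    f_len_gc    250    44    10    Cardinium removed LEN,GC
    ========== ====== ===== ===== ========= ==================

    Demux contigs (band 60-350, window 500 bp):
    d_above 600 bp with 800x over positions 1-300 (mean 400) -> A
    ABOVE_BAND; d_band_uniform 500 bp at 200x uniform (breadth 1.0, so the
    band's uniformity rule keeps it) -> A BAND_UNIFORM; d_below 600 bp with
    120x over positions 1-100 (mean 20) -> B BELOW_BAND; d_zero uncovered
    -> B BELOW_BAND; d_band_localized 1000 bp with 2000x over positions
    1-100 (mean 200, breadth 0.1, localization 1.0) -> B BAND_LOCALIZED.

    Plasmid sub-assembly: p_plasmid 6000 bp at 31.5% GC with parA+parB, four
    hypotheticals and one transposase (flagged); p_chrom 12000 bp at 36% GC
    with housekeeping genes (not flagged); p_small 4000 bp with parA (below
    the 5 kb gate, never evaluated).  Pooled assembly GC is 34.77%, so the
    plasmid's GC deficit is 3.27 points.
    """
    contigs = [
        Contig("f_pass", _seq_gc(400, 144)),
        Contig("f_len", _seq_gc(250, 90)),
        Contig("f_len_edge", _seq_gc(300, 108)),
        Contig("f_gc", _seq_gc(400, 172)),
        Contig("f_gc_edge", _seq_gc(400, 168)),
        Contig("f_tax", _seq_gc(400, 144)),
        Contig("f_host", _seq_gc(400, 180)),
        Contig("f_cov", _seq_gc(400, 144)),
        Contig("f_cov_edge", _seq_gc(400, 144)),
        Contig("f_len_gc", _seq_gc(250, 110)),
        Contig("d_above", _seq_gc(600, 216)),
        Contig("d_band_uniform", _seq_gc(500, 180)),
        Contig("d_below", _seq_gc(600, 216)),
        Contig("d_zero", _seq_gc(600, 216)),
        Contig("d_band_localized", _seq_gc(1000, 360)),
        Contig("p_plasmid", _seq_gc(6000, 1890)),
        Contig("p_chrom", _seq_gc(12000, 4320)),
        Contig("p_small", _seq_gc(4000, 1440)),
    ]
    rows: list[tuple[str, int, int]] = []
    # sparse depths with hand-computed means (missing positions are zero)
    rows += [("f_pass", p, 40) for p in range(1, 101)]  # 100*40/400 = 10
    rows += [("f_len", p, 40) for p in range(1, 63)] + [("f_len", 63, 20)]  # 2500/250 = 10
    rows += [("f_len_edge", p, 40) for p in range(1, 76)]  # 3000/300 = 10
    rows += [("f_gc", p, 40) for p in range(1, 101)]
    rows += [("f_gc_edge", p, 40) for p in range(1, 101)]
    rows += [("f_tax", p, 40) for p in range(1, 101)]
    rows += [("f_host", p, 40) for p in range(1, 101)]
    rows += [("f_cov", p, 10) for p in range(1, 81)]  # 800/400 = 2
    rows += [("f_cov_edge", p, 10) for p in range(1, 201)]  # 2000/400 = 5.0 boundary
    rows += [("f_len_gc", p, 40) for p in range(1, 63)] + [("f_len_gc", 63, 20)]
    rows += [("d_above", p, 800) for p in range(1, 301)]  # 240000/600 = 400
    rows += [("d_band_uniform", p, 200) for p in range(1, 501)]
    rows += [("d_below", p, 120) for p in range(1, 101)]  # 12000/600 = 20
    rows += [("d_band_localized", p, 2000) for p in range(1, 101)]  # mean 200
    taxonomy: dict[str, str | None] = {c.id: "Cardinium" for c in contigs}
    taxonomy["f_tax"] = None
    taxonomy["f_host"] = "host"
    features = [
        FeatureRecord("p_plasmid", 101, 1000, "+", "CDS", "plasmid partitioning protein ParA"),
        FeatureRecord("p_plasmid", 1101, 2000, "-", "CDS", "ParB family partition protein"),
        FeatureRecord("p_plasmid", 2101, 3000, "+", "CDS", "hypothetical protein"),
        FeatureRecord("p_plasmid", 3101, 4000, "+", "CDS", "hypothetical protein"),
        FeatureRecord("p_plasmid", 4101, 5000, "-", "CDS", "hypothetical protein"),
        FeatureRecord("p_plasmid", 5101, 5700, "+", "CDS", "hypothetical protein"),
        FeatureRecord("p_plasmid", 5701, 5990, "+", "CDS", "IS110 family transposase"),
        FeatureRecord("p_chrom", 101, 1000, "+", "CDS", "30S ribosomal protein S3"),
        FeatureRecord("p_chrom", 1101, 2000, "+", "CDS", "DNA gyrase subunit A"),
        FeatureRecord("p_chrom", 2101, 3000, "-", "CDS", "elongation factor Tu"),
        FeatureRecord("p_chrom", 3101, 4000, "+", "CDS", "hypothetical protein"),
        FeatureRecord("p_small", 101, 1000, "+", "CDS", "ParA family protein"),
        FeatureRecord("p_small", 1101, 2000, "+", "CDS", "hypothetical protein"),
    ]
    expected_filter = {
        "f_pass": (True, ()),
        "f_len": (False, ("LEN",)),
        "f_len_edge": (True, ()),
        "f_gc": (False, ("GC",)),
        "f_gc_edge": (True, ()),
        "f_tax": (False, ("TAX",)),
        "f_host": (False, ("GC", "TAX")),
        "f_cov": (False, ("COV",)),
        "f_cov_edge": (True, ()),
        "f_len_gc": (False, ("LEN", "GC")),
    }
    expected_demux = {
        "d_above": ("A", "ABOVE_BAND"),
        "d_band_uniform": ("A", "BAND_UNIFORM"),
        "d_below": ("B", "BELOW_BAND"),
        "d_zero": ("B", "BELOW_BAND"),
        "d_band_localized": ("B", "BAND_LOCALIZED"),
    }
    return WorkedFixture(
        contigs=contigs,
        depth_rows=rows,
        taxonomy=taxonomy,
        features=features,
        expected_filter=expected_filter,
        expected_demux=expected_demux,
        expected_plasmid_flagged=("p_plasmid",),
        plasmid_contig_ids=("p_plasmid", "p_chrom", "p_small"),
        demux_contig_ids=tuple(expected_demux),
    )
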