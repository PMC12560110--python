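# Methods

`symcurate` implements the desk-side computations used to curate draft
genome assemblies of intracellular bacterial symbionts (the motivating
system is *Cardinium hertigii* strains coinfecting *Encarsia* parasitoid
wasps): filtering host and junk contigs out of a metagenomic assembly,
splitting a joint assembly of two coinfecting strains by differential
read coverage, predicting plasmid contigs from annotation traits, and
quantifying genome- and proteome-level relatedness. This note records the
models, the parameters that matter, and the design choices made where the
procedure was genuinely open.

## Contig filtering

A contig is removed from a draft symbiont assembly when **any** of four
rules fires: length < `min_len` (default 300 bp), GC > `max_gc` (default
42%, against a ~36% symbiont background), taxonomy label ≠
`required_label` (default `Cardinium`; labels arrive as a TSV produced by
an external homology search — the search itself is out of scope), or mean
read depth < `min_cov` (default 5×). Boundary semantics are strict
inequalities read literally from the rule wording ("below 300 bp",
"above 42%", "below 5×"): a 300 bp, 42.0% GC, 5.0× contig is kept. GC is
compared at full precision; reports round to two decimals.

One documented caveat: assembler-reported k-mer coverage and read-mapping
depth are not numerically identical. This package always uses
read-mapping depth (from a SAM file or a per-position depth TSV).

## Coverage summaries and the localization statistic

Depth tracks are summarised per contig: mean and median depth, breadth
(fraction of positions with depth ≥ 1), and window statistics over
consecutive `window_bp` = 500 bp windows (a terminal partial window ≥
half a window is kept, otherwise merged; a short contig is one window).

*Localization* is the share of total depth mass held by the
`ceil(top_q · n_windows)` windows with the highest mean depth
(`top_q` = 0.1), defined as 0 for an uncovered contig; a Gini coefficient
of window means is also reported. A uniformly covered contig has
localization ≈ `top_q` and Gini ≈ 0; a contig covered only at one locus
has localization ≈ 1. The binary call `is_localized` requires
localization ≥ `loc_min` = 0.5 **and** breadth ≤ `breadth_max` = 0.5; the
breadth gate prevents short contigs (whose few windows make localization
coarse) from being flagged when they are covered end to end. The original
curation step this replaces was a visual inspection of read pileups with
no published numeric criterion; these statistics are an explicit,
documented proxy chosen so that uniform tracks are never flagged
(verified by simulation) while single-locus coverage always is.

## Strain demultiplexing by differential coverage

Input: a joint assembly of a high-density strain A and low-density strain
B, plus depth from a *single-infection* sample containing only strain A
(and host). Rules, applied to each contig's mean depth:

* mean > `band_hi` (350) → strain A (`ABOVE_BAND`);
* mean < `band_lo` (60) → strain B (`BELOW_BAND`);
* otherwise (inside the band) the uniformity call decides:
  localized → strain B (`BAND_LOCALIZED`), uniform → strain A
  (`BAND_UNIFORM`).

The band takes precedence over the simple high-coverage cut
(`high_cut` = 100) inside [60, 350]: band-level contigs are always
re-assessed, because mobile repeats shared by both strains attract
cross-mapped strain-A reads and can lift a genuinely strain-B contig into
or above the cut while covering only a small part of it. Assignment is
always binary; no "ambiguous" state is emitted. A corollary limitation:
a strain-B contig with genuinely uniform band-level coverage would be
mis-assigned — the procedure reproduces the stated decision rules and
cannot catch that case.

## Plasmid prediction

Contigs over `min_len` = 5 kb are flagged when all three traits common to
known *Cardinium* plasmids hold:

1. **GC** — contig GC at least `gc_delta_min` = 3.0 percentage points
   below the pooled assembly GC. Known plasmids sit near 31.5% against
   ~36% chromosomes (a ~4.5-point gap); 3.0 leaves margin without
   admitting chromosome contigs.
2. **PAR** — ≥ 1 plasmid-partitioning gene (case-insensitive substring
   match of `parA`/`parB`/`partition` in the product) on the contig, and
   > 1 partitioning-gene copy across the whole assembly.
3. **CONTENT** — zero housekeeping-keyword genes (ribosomal proteins,
   tRNA ligases/synthetases, DNA/RNA polymerase, gyrase, elongation
   factors, chaperones) together with either hypothetical-protein
   fraction ≥ 0.5 (empty products count as hypothetical) or ≥ 1 mobile
   genetic element (transposase/integrase/recombinase/phage). The rule
   keys on the housekeeping keyword list only, so an annotated
   non-housekeeping gene (e.g. a pyrophosphohydrolase) does not disqualify
   a contig.

Because fragmented assemblies split plasmids across contigs, all flagged
contigs are pooled into a single candidate with summed length and pooled
GC. When several distinct plasmids coexist they are pooled together —
a documented simplification; no linkage criterion is attempted.

## ANIb

The query genome is cut into consecutive non-overlapping 1020 bp
fragments (terminal remainders kept). Each fragment is locally aligned to
the reference with Smith–Waterman scoring match +2 / mismatch −3 / gap
open −5 / gap extend −2 (a gap of length *k* costs 5 + 2*k*; in the
aligner this is `open_gap_score = −7`, `extend_gap_score = −2`), both
strands. Hits with identity < 30% or fragment coverage < 70% are
discarded; ANI is the mean identity of retained fragments and the aligned
fraction is the share retained. The result is directional
(query → reference); `--symmetric` averages both directions.

No external search tool is shelled out. Candidate reference regions are
located by shared exact 15-mers binned by alignment diagonal (bin 250 bp,
top 4 bins per strand, windows padded by 200 bp plus the fragment
length), and the best-scoring local alignment over those windows is kept.
An exhaustive mode aligns every fragment against the full reference
without seeding; the test suite bounds the seeding approximation at ≤ 2
ANI points against this oracle (in practice the two agree exactly on the
test genomes). Identity is identical columns / alignment columns
(gap columns included); self-ANI of ungapped self-alignment is exactly
100.0.

## Proteome comparison

Protein pairs are aligned locally with BLOSUM62, gap open 11 / extend 1
(gap of length *k* costs 11 + *k*). The *best full-length hit* of a query
in a target proteome is the highest-scoring hit with query coverage ≥ 70%
("full-length or nearly full-length") and raw score ≥ `min_score` = 50;
ties break by higher identity then lexicographically smaller subject id.
E-values are deliberately not used: they depend on database size and
tool calibration, so the "no hit" boundary is a raw-score floor. A
query with no qualifying hit is reported as 0.00 identity. *Unique
proteins* are those longer than 100 residues (strict) with no qualifying
hit in any other proteome. Candidate targets are prefiltered by a shared
exact 3-mer; the suite verifies this prefilter never changes the result
relative to aligning against every target.

## Synthetic coinfection generator

The generator emulates the data structure the pipeline assumes, with
ground truth:

* **Strain A**: iid random chromosome at 36% GC, 200 kb by default
  (a deliberate scale-down of a ~1 Mb symbiont genome; `--full-scale`
  generates 1 Mb). Depth in both samples ~300× (high-density strain).
* **Plasmid**: 20 kb at 31.5% GC, carried by strain A, annotated with
  parA/parB, hypotheticals and a transposase; optionally split into two
  contigs (each keeping a partitioning gene).
* **Strain B**: derived from strain A by iid substitutions at divergence
  *d* = 0.10, so expected ANI is (1 − d)·100. The substitution scheme is
  flux-balanced for base composition (an AT base mutates to G/C with
  probability equal to the GC fraction, else to the other AT base, and
  symmetrically), so divergence does not drift GC toward 50%. Depth 10×
  in the coinfection sample, 0× in the single-infection sample except on
  repeats.
* **Shared repeats**: 3 transposase-like 1 kb elements, each pasted
  verbatim at 2 loci per strain. In the single-infection track, strain-B
  repeat intervals receive the depth observed over strain A's copy of the
  same element — a deterministic idealization of short-read
  multi-mapping, stated rather than calibrated against any mapper.
* **Host**: 8 contigs of 10 kb at 45% GC, ~30× (a symbiont-enriched
  extraction still carries host reads; the paper-trail gives no host
  coverage figure, so this is a one-time realism choice).
* **Depth model**: Lander–Waterman — uniform random 150 bp read starts at
  the strain-specific mean depth, accumulated into per-position counts.
  No FASTQ is emitted; depth tracks are generated directly.
* **Contigs**: each genome is cut at random breakpoints (mean contig
  ~10 kb, minimum 2 kb). Repeat loci and cut positions are aligned to the
  500 bp uniformity-window grid and repeat loci are kept ≥ 6 kb apart, so
  a band-level repeat-inflated contig concentrates its depth in whole
  windows and the localization rescue is deterministic rather than
  balanced on the 0.5 threshold. One strain-B repeat locus is forced onto
  a 4 kb contig so the rescue rule is exercised on every run.

What the generator does *not* model: sequencing error, indels,
GC–coverage bias, chimeric contigs, divergence *within* repeat copies,
or real mapper behaviour on diverged repeats. Passing tests therefore
demonstrate correctness of the decision rules under the stated
statistical assumptions, not performance on real libraries.

A separate hand-built worked fixture (18 contigs, committed under
`tests/data/worked/`, regenerated by `make_worked_fixture()`) pins every
filter boundary case, every demultiplexing rule, and the plasmid traits
to hand-enumerated expectations.

## Numerical and convention choices

* Coordinates are 1-based inclusive in every external format (GFF3/SAM
  convention); anything half-open is internal.
* SAM depth counts primary, non-duplicate, non-supplementary alignments
  with MAPQ ≥ `min_mapq` (default 0 — the upstream mapping protocol
  states no MAPQ filter); CIGAR M/=/X and D consume reference and count
  as covered (samtools-style breadth semantics), N consumes reference
  without covering, insertions and clips never contribute.
* N50 uses the cumulative-sum-crossing definition (sort descending, first
  length where the running total reaches half the assembly size).
* GC excludes ambiguity codes and N from numerator and denominator; an
  all-ambiguous sequence has undefined (NaN) GC. Assembly GC is pooled
  over bases, not a mean of per-contig values.
* Localization ties between equal-mean windows break by window order
  (stable sort), keeping reports deterministic.
* All randomness flows from a single integer seed through
  `numpy.random.default_rng`; identical seeds give byte-identical output
  files.

## Problem sizes in the validation suite

The test suite and `scripts/acceptance.py` run the full pipeline on the
200 kb default generator (≈ 50 contigs), ANI calibration on 50 kb genome
pairs at d ∈ {0.01, 0.05, 0.10}, the seedless Smith–Waterman oracle on a
20 kb toy, and proteome oracle checks on 12–25 random proteins of
110–400 residues — sizes chosen so the whole suite completes in a few
minutes on one CPU while every rule and boundary is still exercised.
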