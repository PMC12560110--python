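# symcurate

Curation toolkit for endosymbiont draft genome assemblies.

Sequencing an intracellular bacterial symbiont from whole-host extractions
yields a metagenomic jumble: symbiont contigs mixed with host DNA, and —
when two symbiont strains coinfect the same host — two genomes tangled in
one assembly. `symcurate` implements the computations used to untangle
such assemblies, motivated by *Cardinium hertigii* strains infecting
*Encarsia* parasitoid wasps at very different densities:

* **Contig filtering** — remove contigs below 300 bp, above 42% GC,
  without a symbiont taxonomy label, or below 5× mean depth (any rule
  suffices; all fired rules are reported).
* **Coverage profiling** — per-contig mean/median depth, breadth, and a
  *localization* statistic (share of depth mass in the top 10% of 500 bp
  windows) that makes repeat-driven coverage inflation measurable.
* **Strain demultiplexing** — assign each contig of a joint coinfection
  assembly to the high-density strain A or low-density strain B using
  depth from a single-infection (A-only) read set: mean > 350× → A,
  mean < 60× → B, and contigs in the 60–350× band go to A only when their
  coverage is uniform — band-level depth concentrated at one locus is the
  signature of a shared mobile repeat cross-attracting strain-A reads,
  and such contigs go to B.
* **Plasmid prediction** — flag contigs > 5 kb showing all three traits of
  known *Cardinium* plasmids: GC ≥ 3 points below the assembly, a
  ParA/ParB-like partitioning gene (with > 1 copy assembly-wide), and no
  housekeeping genes alongside an enrichment of hypothetical proteins or
  mobile elements; flagged contigs pool into one multi-contig candidate.
* **ANIb** — average nucleotide identity: fragment the query into 1020 bp
  pieces, Smith–Waterman each piece against the reference (match +2,
  mismatch −3, gap open 5, extend 2; seed-and-extend, both strands), drop
  hits under 30% identity or 70% fragment coverage, average the rest.
* **Proteome comparison** — best full-length homolog (BLOSUM62, gap
  11/1, query coverage ≥ 70%) identities between proteomes, and detection
  of proteins > 100 aa unique to one proteome.
* **Synthetic coinfection generator** — a seeded simulator of the whole
  scenario (diverged strain pair, shared repeats, low-GC plasmid,
  high-GC host, Lander–Waterman depth tracks) with ground truth, used
  throughout the test suite.

See `docs/methods.md` for the models, parameter defaults, and design
choices.

## Worked example

Simulate a coinfection, then run the curation chain end to end:

```bash
symcurate simulate --seed 1 --out sim/
symcurate stats sim/joint_assembly.fasta
```

```
Total assembly size (bp)  Total number of contigs  Contig N50  % GC
500000                    51                       10500       37.19
```

The joint assembly holds 51 contigs: two ~200 kb symbiont strains, a
20 kb plasmid, and 8 host contigs whose elevated GC lifts the pooled GC
above the symbiont's ~36%.

```bash
symcurate filter sim/joint_assembly.fasta \
    --depth-tsv sim/coinfection_depth.tsv \
    --taxonomy sim/taxonomy.tsv --out-dir filt/
```

`filt/filter_decisions.tsv` keeps 43 contigs and removes the 8 host
contigs (reasons `GC,TAX`): e.g.

```
contig_id  kept   reasons  length  gc_percent  mean_depth  label
A_001      true            2500    36.64       293.53      Cardinium
```

Demultiplex the kept contigs with the single-infection depth track
(restricted to the kept contigs), then predict plasmids on the strain-A
partition:

```bash
symcurate demux filt/filtered.fasta --depth-tsv sim/single_kept.tsv --out-dir dmx/
symcurate plasmid dmx/strainA.fasta sim/features.gff3 --out-dir pls/
cat pls/plasmid_candidate.tsv
```

```
contig_ids  total_length  gc_percent
P_001       20000         31.67
```

Demultiplexing recovers 21 strain-A and 22 strain-B contigs — against the
simulator's `sim/truth.tsv` that is 100% of the labels, including the
repeat-bearing strain-B contig rescued by the localization rule — and the
planted 20 kb low-GC plasmid is the only flagged contig.

ANI between two FASTA files:

```bash
symcurate ani strainA.fasta strainB.fasta
```

reports `ani_percent` ≈ 90 for the default generator's 10% divergence
(ANI ≈ (1 − d) · 100), with the aligned fraction alongside.

Every subcommand accepts a `--config key: value` file (flag > config >
default) and writes a manifest with input checksums and resolved
parameters beside its outputs; identical inputs and seeds reproduce
outputs byte for byte.

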