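"""Trait-based plasmid calls: the three traits, the 5 kb gate, pooling."""

import pytest

from symcurate import PlasmidParams, predict_plasmids, score_contig
from symcurate.io_formats import Contig, FeatureRecord
from symcurate.synthetic_community import SimParams, _seq_gc, generate


def cds(cid, start, product):
    return FeatureRecord(cid, start, start + 899, "+", "CDS", product)


def plasmid_like(cid="pls", length=6000, gc_bases=1890):
    contig = Contig(cid, _seq_gc(length, gc_bases))  # 31.5% GC
    feats = [
        cds(cid, 101, "plasmid partitioning protein ParA"),
        cds(cid, 1101, "ParB family partition protein"),
        cds(cid, 2101, "hypothetical protein"),
        cds(cid, 3101, "hypothetical protein"),
        cds(cid, 4101, "IS110 family transposase"),
    ]
    return contig, feats


class TestScoreContig:
    def test_canonical_plasmid_contig_flagged(self):
        # low-GC, parA/parB-bearing, housekeeping-free contig in a ~36% GC assembly
        contig, feats = plasmid_like()
        call = score_contig(contig, feats, assembly_gc_percent=35.79, assembly_partition_copies=3)
        assert call.flagged and call.traits_met == {"GC", "PAR", "CONTENT"}
        assert call.gc_delta == pytest.approx(35.79 - 31.5)

    def test_below_5kb_never_evaluated(self):
        contig, feats = plasmid_like(length=4000, gc_bases=1260)
        call = score_contig(contig, feats, 35.79, 3)
        assert not call.evaluated and not call.flagged and call.traits_met == set()

    def test_chromosome_like_negative_control(self):
        cid = "chrom"
        contig = Contig(cid, _seq_gc(8000, 2880))  # 36% GC = assembly GC
        feats = [
            cds(cid, 101, "30S ribosomal protein S3"),
            cds(cid, 1101, "DNA gyrase subunit A"),
            cds(cid, 2101, "hypothetical protein"),
        ]
        call = score_contig(contig, feats, 36.0, 3)
        assert not call.flagged and call.traits_met == set()

    def test_par_trait_needs_assembly_copies_above_one(self):
        contig, feats = plasmid_like()
        sole = score_contig(contig, feats[:1] + feats[2:], 35.79, assembly_partition_copies=1)
        assert "PAR" not in sole.traits_met

    def test_content_trait_via_mge_without_hypothetical_majority(self):
        cid = "pls"
        contig = Contig(cid, _seq_gc(6000, 1890))
        feats = [
            cds(cid, 101, "plasmid partitioning protein ParA"),
            cds(cid, 1101, "IS5 family transposase"),
            cds(cid, 2101, "DUF4376 domain-containing protein"),
        ]
        call = score_contig(contig, feats, 35.79, 2)
        assert call.hypothetical_fraction < 0.5 and "CONTENT" in call.traits_met

    def test_annotated_nonhousekeeping_gene_does_not_break_content(self):
        # a contig may carry e.g. a pyrophosphohydrolase and still count as
        # housekeeping-free: the rule keys on the housekeeping keywords only
        cid = "pls"
        contig = Contig(cid, _seq_gc(6000, 1890))
        feats = [
            cds(cid, 101, "plasmid partitioning protein ParA"),
            cds(cid, 1101, "guanosine-3',5'-bis(diphosphate) 3'-pyrophosphohydrolase"),
            cds(cid, 2101, "hypothetical protein"),
            cds(cid, 3101, "hypothetical protein"),
        ]
        call = score_contig(contig, feats, 35.79, 2)
        assert "CONTENT" in call.traits_met

    def test_keyword_matching_case_insensitive(self):
        contig, _ = plasmid_like()
        feats = [cds("pls", 101, "PARA PARTITION ATPASE"), cds("pls", 1101, "hypothetical protein")]
        call = score_contig(contig, feats, 35.79, 2)
        assert "PAR" in call.traits_met


class TestPredictPlasmids:
    def _assembly(self):
        pls, pls_feats = plasmid_like()
        chrom = Contig("chrom", _seq_gc(40000, 14400))  # 36%
        chrom_feats = [
            cds("chrom", 101, "50S ribosomal protein L2"),
            cds("chrom", 1101, "elongation factor Tu"),
        ]
        return [pls, chrom], pls_feats + chrom_feats

    def test_flagged_and_pooled_candidate(self):
        assembly, feats = self._assembly()
        calls, cand = predict_plasmids(assembly, feats)
        assert [c.contig_id for c in calls if c.flagged] == ["pls"]
        assert cand.total_length == 6000 and cand.gc_percent == pytest.approx(31.5)

    def test_no_flags_no_candidate(self):
        assembly, feats = self._assembly()
        assembly = assembly[1:]  # chromosome only
        calls, cand = predict_plasmids(assembly, [f for f in feats if f.contig_id == "chrom"])
        assert cand is None and not any(c.flagged for c in calls)

    def test_flagged_implies_min_len(self):
        assembly, feats = self._assembly()
        calls, _ = predict_plasmids(assembly, feats, PlasmidParams(min_len=10000))
        assert not any(c.flagged for c in calls)

    def test_gc_delta_monotonicity(self):
        assembly, feats = self._assembly()
        flagged = lambda p: {c.contig_id for c in predict_plasmids(assembly, feats, p)[0] if c.flagged}
        loose = flagged(PlasmidParams(gc_delta_min=1.0))
        default = flagged(PlasmidParams())
        tight = flagged(PlasmidParams(gc_delta_min=8.0))
        assert tight <= default <= loose

    @pytest.mark.parametrize("split", [False, True])
    def test_planted_plasmid_perfect_precision_recall(self, split, sim_default):
        """Planted low-GC plasmid (whole or split over two contigs) is
        recovered exactly against the strain-A chromosome contigs."""
        ds = sim_default if not split else generate(SimParams(seed=1, split_plasmid=True))
        strain_a = ds.strain_contigs("STRAIN_A", "PLASMID_A")
        ids = {c.id for c in strain_a}
        feats = [f for f in ds.features if f.contig_id in ids]
        calls, cand = predict_plasmids(strain_a, feats)
        flagged = {c.contig_id for c in calls if c.flagged}
        truth = {c.id for c in strain_a if ds.truth.labels[c.id] == "PLASMID_A"}
        assert flagged == truth  # precision = recall = 1.0
        assert cand.total_length == ds.params.plasmid_size
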