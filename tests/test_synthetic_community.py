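"""The synthetic coinfection generator: determinism, truth, and realism."""

import numpy as np
import pytest

from symcurate import SimParams, compute_ani, generate
from symcurate.errors import SymcurateError
from symcurate.io_formats import Contig
from symcurate.synthetic_community import HOST, PLASMID_A, STRAIN_A, STRAIN_B


class TestGenerate:
    def test_same_seed_byte_identical(self, tmp_path, sim_default):
        a, b = tmp_path / "a", tmp_path / "b"
        sim_default.write(a)
        generate(SimParams(seed=1)).write(b)
        for f in sorted(p.name for p in a.iterdir()):
            assert (a / f).read_bytes() == (b / f).read_bytes(), f

    def test_different_seed_differs(self, sim_default):
        other = generate(SimParams(seed=2))
        assert other.contigs[0].seq != sim_default.contigs[0].seq

    def test_truth_labels_conserved(self, sim_default):
        ds = sim_default
        assert set(ds.truth.labels) == {c.id for c in ds.contigs}
        counts = {}
        for label in ds.truth.labels.values():
            counts[label] = counts.get(label, 0) + 1
        assert counts[HOST] == ds.params.host_contigs
        assert counts[PLASMID_A] == 1
        assert counts[STRAIN_A] > 1 and counts[STRAIN_B] > 1
        # contigs reconstruct the genomes exactly
        a_seq = "".join(c.seq for c in ds.strain_contigs(STRAIN_A))
        assert a_seq == ds.strainA_genome

    def test_depth_tracks_match_contig_lengths(self, sim_default):
        ds = sim_default
        for c in ds.contigs:
            assert len(ds.single_depths[c.id]) == c.length
            assert len(ds.coinfection_depths[c.id]) == c.length

    def test_repeat_free_strain_b_dark_in_single_sample(self, sim_default):
        ds = sim_default
        for c in ds.strain_contigs(STRAIN_B):
            if not ds.truth.repeat_bearing[c.id]:
                assert ds.single_depths[c.id].depths.sum() == 0

    def test_strain_a_mean_depth_within_10_percent(self, sim_default):
        ds = sim_default
        for c in ds.strain_contigs(STRAIN_A):
            mean = ds.single_depths[c.id].depths.mean()
            assert mean == pytest.approx(ds.params.strainA_mean_depth, rel=0.10)

    def test_gc_structure(self, sim_default):
        ds = sim_default

        def pooled_gc(label):
            seq = "".join(c.seq for c in ds.strain_contigs(label))
            return (seq.count("G") + seq.count("C")) / len(seq)

        assert pooled_gc(HOST) == pytest.approx(ds.params.host_gc, abs=0.01)
        assert pooled_gc(PLASMID_A) == pytest.approx(ds.params.plasmid_gc, abs=0.01)
        assert pooled_gc(STRAIN_A) == pytest.approx(ds.params.symbiont_gc, abs=0.01)
        assert pooled_gc(STRAIN_B) == pytest.approx(ds.params.symbiont_gc, abs=0.01)
        # every host contig clears the 42% GC filter threshold
        for c in ds.strain_contigs(HOST):
            assert c.gc > 0.42

    def test_strains_ani_tracks_divergence(self, sim_default):
        """ANI between the two strain genomes is (1 - d) * 100 within 1.5
        points (computed on the first 30 kb to keep this quick)."""
        ds = sim_default
        q = [Contig("a", ds.strainA_genome[:30_000])]
        r = [Contig("b", ds.strainB_genome[:30_000])]
        ani = compute_ani(q, r).ani_percent
        assert ani == pytest.approx((1 - ds.params.divergence_AB) * 100, abs=1.5)

    def test_split_plasmid_emits_two_contigs_with_partition_genes(self):
        ds = generate(SimParams(seed=1, split_plasmid=True))
        pls = ds.strain_contigs(PLASMID_A)
        assert len(pls) == 2
        assert sum(c.length for c in pls) == ds.params.plasmid_size
        for c in pls:
            prods = [f.product.lower() for f in ds.features if f.contig_id == c.id]
            assert any("para" in p or "parb" in p for p in prods)

    def test_infeasible_repeat_content_raises(self):
        with pytest.raises(SymcurateError):
            generate(SimParams(seed=1, strainA_size=10_000, strainB_size=10_000,
                               n_shared_repeats=10, repeat_copies_per_strain=5))

    def test_features_within_contig_bounds(self, sim_default):
        ds = sim_default
        lengths = {c.id: c.length for c in ds.contigs}
        for f in ds.features:
            assert 1 <= f.start <= f.end <= lengths[f.contig_id]


class TestWorkedFixtureFiles:
    def test_committed_files_match_generator(self, tmp_path, worked):
        """The committed fixture under tests/data/worked is exactly what
        make_worked_fixture writes (guards against drift)."""
        from pathlib import Path

        worked_dir = Path(__file__).parent / "data" / "worked"
        worked.write(tmp_path / "w")
        for f in sorted(p.name for p in worked_dir.iterdir()):
            assert (tmp_path / "w" / f).read_bytes() == (worked_dir / f).read_bytes(), f
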