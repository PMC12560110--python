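"""Coverage-based strain assignment: rules, partitions, and recovery."""

import numpy as np
import pytest

from symcurate import DataError, DemuxParams, classify, demux_assembly, summarize
from symcurate.coverage_profile import DepthTrack
from symcurate.io_formats import Contig
from symcurate.synthetic_community import PLASMID_A, STRAIN_A, SimParams, generate


def summary_of(depths, cid="c"):
    return summarize(DepthTrack(cid, np.asarray(depths)))


class TestClassify:
    def test_above_band_uniform_is_strain_a(self):
        call = classify(summary_of([400] * 2000))
        assert (call.strain, call.rule_fired) == ("A", "ABOVE_BAND")

    def test_below_band_is_strain_b(self):
        call = classify(summary_of([20] * 2000))
        assert (call.strain, call.rule_fired) == ("B", "BELOW_BAND")

    def test_band_localized_is_strain_b(self):
        # mean 200, all mass in 5% of the contig: the repeat-inflation case
        depths = [4000] * 100 + [0] * 1900
        s = summary_of(depths)
        assert 60 <= s.mean_depth <= 350 and s.localization > 0.9 and s.breadth == 0.05
        call = classify(s)
        assert (call.strain, call.rule_fired) == ("B", "BAND_LOCALIZED")

    def test_band_uniform_is_strain_a(self):
        call = classify(summary_of([200] * 2000))
        assert (call.strain, call.rule_fired) == ("A", "BAND_UNIFORM")

    def test_band_takes_precedence_over_high_cut(self):
        # mean 200 exceeds the simple >100 cut but sits inside the band:
        # the uniformity rule decides, so a localized contig still goes to B
        depths = [4000] * 100 + [0] * 1900
        assert classify(summary_of(depths)).strain == "B"


class TestDemuxAssembly:
    def _toy(self):
        contigs = [Contig("a", "ACGT" * 500), Contig("b", "ACGT" * 500)]
        tracks = {
            "a": DepthTrack("a", np.full(2000, 400)),
            "b": DepthTrack("b", np.zeros(2000, dtype=int)),
        }
        return contigs, tracks

    def test_partition_exhaustive_and_disjoint(self):
        contigs, tracks = self._toy()
        calls, part_a, part_b = demux_assembly(contigs, tracks)
        assert {c.id for c in part_a} | {c.id for c in part_b} == {"a", "b"}
        assert not ({c.id for c in part_a} & {c.id for c in part_b})
        assert len(calls) == len(contigs)

    def test_all_zero_depths_everything_strain_b(self):
        contigs = [Contig(f"c{i}", "ACGT" * 300) for i in range(4)]
        calls, part_a, part_b = demux_assembly(contigs, {})
        assert not part_a and len(part_b) == 4
        assert all(c.rule_fired == "BELOW_BAND" for c in calls)

    def test_orphan_depth_track_is_error(self):
        contigs, tracks = self._toy()
        tracks["ghost"] = DepthTrack("ghost", np.zeros(10, dtype=int))
        with pytest.raises(DataError, match="ghost"):
            demux_assembly(contigs, tracks)

    def test_calls_invariant_to_contig_order(self):
        contigs, tracks = self._toy()
        fwd, *_ = demux_assembly(contigs, tracks)
        rev, *_ = demux_assembly(list(reversed(contigs)), tracks)
        assert {c.contig_id: c.strain for c in fwd} == {c.contig_id: c.strain for c in rev}

    def test_shared_repeat_contig_rescued_to_b(self):
        # strain-B contig whose only coverage is a 1-kb repeat at strain-A
        # depth: band-level mean, localized -> B
        contig = Contig("rep", "ACGT" * 1000)
        depths = np.zeros(4000, dtype=int)
        depths[1500:2500] = 300  # mean 75, inside the band
        calls, _, part_b = demux_assembly([contig], {"rep": DepthTrack("rep", depths)})
        assert calls[0].rule_fired == "BAND_LOCALIZED"
        assert part_b[0].id == "rep"


class TestSyntheticRecovery:
    def test_label_recovery_on_default_coinfection(self, sim_default):
        """With strain A at ~300x and strain B dark in the single-infection
        sample, every repeat-free contig label is recovered and overall
        recovery clears 95%."""
        ds = sim_default
        symbiont = ds.strain_contigs("STRAIN_A", "STRAIN_B", "PLASMID_A")
        tracks = {c.id: ds.single_depths[c.id] for c in symbiont}
        calls, _, _ = demux_assembly(symbiont, tracks)
        truth = {
            c.id: ("A" if ds.truth.labels[c.id] in (STRAIN_A, PLASMID_A) else "B")
            for c in symbiont
        }
        correct = [c for c in calls if c.strain == truth[c.contig_id]]
        repeat_free = [c for c in calls if not ds.truth.repeat_bearing[c.contig_id]]
        rf_correct = [c for c in repeat_free if c.strain == truth[c.contig_id]]
        assert len(rf_correct) == len(repeat_free)
        assert len(correct) / len(calls) >= 0.95

    def test_wide_separation_recovers_every_repeat_free_contig(self):
        """Strain A at 2x band_hi and strain B below band_lo/3 leaves no
        ambiguity for repeat-free contigs."""
        ds = generate(SimParams(seed=5, strainA_mean_depth=700.0, strainB_mean_depth=10.0))
        symbiont = ds.strain_contigs("STRAIN_A", "STRAIN_B", "PLASMID_A")
        calls, _, _ = demux_assembly(symbiont, {c.id: ds.single_depths[c.id] for c in symbiont})
        truth = {
            c.id: ("A" if ds.truth.labels[c.id] in (STRAIN_A, PLASMID_A) else "B")
            for c in symbiont
        }
        misses = [
            c.contig_id
            for c in calls
            if not ds.truth.repeat_bearing[c.contig_id] and c.strain != truth[c.contig_id]
        ]
        assert misses == []
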