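from collections import defaultdict

import numpy as np
import pytest

from methyltag import methylcall
from methyltag.core import (
    BisulfiteStrand,
    CpGSite,
    Genome,
    MethState,
    Peak,
    ReadMethCall,
)

from conftest import make_fragment, make_mate


def ot_fragment(base: str, qual: int = 40, name="f1"):
    """OT fragment covering the single CpG of TACGT (C at pos 2)."""
    mate = make_mate("TA" + base + "GT", 0, is_read1=True, qual=qual)
    return make_fragment(start=0, end=5, mates=(mate,), name=name)


class TestCallReadMethylation:
    def test_ot_c_is_methylated(self, tiny_genome):
        rc = methylcall.call_read_methylation(ot_fragment("C"), tiny_genome)
        assert rc.calls == [(2, MethState.METH)]

    def test_ot_t_is_unmethylated(self, tiny_genome):
        rc = methylcall.call_read_methylation(ot_fragment("T"), tiny_genome)
        assert rc.calls == [(2, MethState.UNMETH)]

    def test_ot_other_base_is_ambiguous(self, tiny_genome):
        rc = methylcall.call_read_methylation(ot_fragment("A"), tiny_genome)
        assert rc.calls == [(2, MethState.AMBIG)]

    @pytest.mark.parametrize(
        "base,state",
        [("G", MethState.METH), ("A", MethState.UNMETH), ("T", MethState.AMBIG)],
    )
    def test_ob_reads_the_paired_g(self, tiny_genome, base, state):
        mate = make_mate("TAC" + base + "T", 0, is_read1=True)
        frag = make_fragment(
            start=0, end=5, strand=BisulfiteStrand.OB, mates=(mate,)
        )
        rc = methylcall.call_read_methylation(frag, tiny_genome)
        assert rc.calls == [(2, state)]

    def test_low_base_quality_is_ambiguous(self, tiny_genome):
        rc = methylcall.call_read_methylation(
            ot_fragment("C", qual=19), tiny_genome
        )
        assert rc.calls == [(2, MethState.AMBIG)]
        rc = methylcall.call_read_methylation(
            ot_fragment("C", qual=20), tiny_genome
        )
        assert rc.calls == [(2, MethState.METH)]

    def test_mate_overlap_higher_quality_wins(self, tiny_genome):
        m1 = make_mate("TACGT", 0, is_read1=True, qual=20)
        m2 = make_mate("TATGT", 0, is_read1=False, qual=35)
        frag = make_fragment(start=0, end=5, mates=(m1, m2))
        rc = methylcall.call_read_methylation(frag, tiny_genome)
        assert rc.calls == [(2, MethState.UNMETH)]

    def test_mate_overlap_tie_goes_to_read1(self, tiny_genome):
        m1 = make_mate("TACGT", 0, is_read1=True, qual=30)
        m2 = make_mate("TATGT", 0, is_read1=False, qual=30)
        frag = make_fragment(start=0, end=5, mates=(m1, m2))
        rc = methylcall.call_read_methylation(frag, tiny_genome)
        assert rc.calls == [(2, MethState.METH)]

    def test_unknown_contig_raises(self, tiny_genome):
        frag = ot_fragment("C")
        frag.contig = "cX"
        with pytest.raises(KeyError):
            methylcall.call_read_methylation(frag, tiny_genome)

    def test_unsequenced_informative_base_yields_no_call(self, tiny_genome):
        # OB fragment whose only mate stops before the G at pos 3
        mate = make_mate("TAC", 0, is_read1=True)
        frag = make_fragment(
            start=0, end=5, strand=BisulfiteStrand.OB, mates=(mate,)
        )
        rc = methylcall.call_read_methylation(frag, tiny_genome)
        assert rc.calls == []


def rc(fid, state, strand=BisulfiteStrand.OT, pos=2):
    return ReadMethCall(fragment_id=fid, calls=[(pos, state)], bisulfite_strand=strand)


class TestAggregateSites:
    def test_counts_summed(self):
        calls = [
            rc("a", MethState.METH),
            rc("b", MethState.METH),
            rc("c", MethState.UNMETH),
        ]
        (site,) = methylcall.aggregate_sites(calls, contig="c1")
        assert (site.count_meth, site.count_unmeth) == (2, 1)
        assert site.beta == pytest.approx(2 / 3)

    def test_ambig_only_site_omitted(self):
        assert methylcall.aggregate_sites([rc("a", MethState.AMBIG)]) == []

    def test_strand_merge_pools_counts(self):
        calls = [
            rc("a", MethState.METH),
            rc("b", MethState.METH),
            rc("c", MethState.METH, strand=BisulfiteStrand.OB),
            rc("d", MethState.UNMETH, strand=BisulfiteStrand.OB),
        ]
        (site,) = methylcall.aggregate_sites(calls, merge_strands=True, contig="c1")
        assert (site.count_meth, site.count_unmeth) == (3, 1)
        assert site.beta == pytest.approx(0.75)

    def test_stranded_mode_reports_ob_at_g_position(self):
        calls = [
            rc("a", MethState.METH),
            rc("b", MethState.METH, strand=BisulfiteStrand.OB),
        ]
        sites = methylcall.aggregate_sites(calls, merge_strands=False, contig="c1")
        assert [(s.pos0, s.strand) for s in sites] == [(2, "+"), (3, "-")]

    def test_merged_coverage_at_least_each_stranded(self):
        calls = [
            rc("a", MethState.METH),
            rc("b", MethState.UNMETH, strand=BisulfiteStrand.OB),
            rc("c", MethState.METH, strand=BisulfiteStrand.OB),
        ]
        (merged,) = methylcall.aggregate_sites(calls, merge_strands=True)
        stranded = methylcall.aggregate_sites(calls, merge_strands=False)
        assert all(merged.coverage >= s.coverage for s in stranded)


def fixture_sites():
    """20 hand-built sites probing coverage and boundary semantics against
    a peak at [100, 200)."""
    sites = []
    # inside the peak, coverage 1..10
    for i, cov in enumerate(range(1, 11)):
        meth = cov // 2
        sites.append(CpGSite("c1", 110 + 2 * i, meth, cov - meth))
    # boundary cases
    sites.append(CpGSite("c1", 100, 5, 0))  # first base inside
    sites.append(CpGSite("c1", 199, 0, 5))  # last base inside
    sites.append(CpGSite("c1", 200, 5, 5))  # peak.end: outside (half-open)
    sites.append(CpGSite("c1", 99, 5, 5))  # one before the peak
    # far outside, high coverage
    sites.append(CpGSite("c1", 500, 25, 25))
    sites.append(CpGSite("c1", 600, 50, 0))
    # other contig
    sites.append(CpGSite("c2", 150, 5, 5))
    # inside, below the cut
    sites.append(CpGSite("c1", 130, 2, 2))
    sites.append(CpGSite("c1", 132, 1, 2))
    sites.append(CpGSite("c1", 134, 0, 4))
    return sites


class TestFilterSites:
    PEAK = [Peak("c1", 100, 200, "p1")]

    def test_exact_retention_set(self):
        sites = fixture_sites()
        assert len(sites) == 20
        kept = methylcall.filter_sites(sites, self.PEAK, min_coverage=5)
        expected = {
            (s.contig, s.pos0)
            for s in sites
            if s.contig == "c1" and 100 <= s.pos0 < 200 and s.coverage >= 5
        }
        assert {(s.contig, s.pos0) for s in kept} == expected
        # boundary semantics spelled out
        kept_pos = {s.pos0 for s in kept}
        assert 100 in kept_pos and 199 in kept_pos
        assert 200 not in kept_pos and 99 not in kept_pos

    def test_coverage_threshold_boundary(self):
        sites = [CpGSite("c1", 150, 2, 2), CpGSite("c1", 152, 3, 2)]
        kept = methylcall.filter_sites(sites, self.PEAK, min_coverage=5)
        assert [s.pos0 for s in kept] == [152]

    def test_high_coverage_outside_peak_dropped(self):
        kept = methylcall.filter_sites(
            [CpGSite("c1", 500, 25, 25)], self.PEAK, min_coverage=5
        )
        assert kept == []

    def test_retained_sites_annotated_with_peaks(self):
        peaks = [Peak("c1", 100, 200, "p1"), Peak("c1", 150, 300, "p2")]
        (site,) = methylcall.filter_sites([CpGSite("c1", 160, 5, 5)], peaks)
        assert site.peak_ids == ("p1", "p2")

    def test_empty_peak_list_warns_and_returns_empty(self):
        with pytest.warns(UserWarning):
            assert methylcall.filter_sites(fixture_sites(), []) == []


class TestPipelineRecovery:
    def test_noise_free_betas_match_truth_draws_exactly(self, sim_noise_free):
        """On noise-free reads the caller must reproduce the per-CpG
        methylated fraction of the generator's recorded draws exactly."""
        cfg, (genome, peaks, fragments, truth) = sim_noise_free
        calls = methylcall.call_fragments(fragments, genome)
        sites = methylcall.aggregate_sites(calls, contig="chrS")
        truth_counts = defaultdict(lambda: [0, 0])
        for f in fragments:
            for pos, s, obs in truth.fragment_states[f.query_name]:
                if obs:
                    truth_counts[pos][s] += 1
        assert len(sites) == len(truth_counts)
        for s in sites:
            unmeth, meth = truth_counts[s.pos0]
            assert (s.count_meth, s.count_unmeth) == (meth, unmeth)

    def test_count_conservation(self, sim_small):
        """meth + unmeth + ambig calls per CpG equal the number of
        fragments whose sequenced bases span the informative position."""
        cfg, (genome, peaks, fragments, truth) = sim_small
        calls = methylcall.call_fragments(fragments, genome)
        per_pos = defaultdict(lambda: [0, 0, 0])
        for c in calls:
            for pos, st in c.calls:
                i = {MethState.METH: 0, MethState.UNMETH: 1, MethState.AMBIG: 2}[st]
                per_pos[pos][i] += 1
        overlap = defaultdict(int)
        for f in fragments:
            is_ot = f.bisulfite_strand == BisulfiteStrand.OT
            for pos in genome.cpgs_in(
                "chrS", f.start if is_ot else f.start - 1,
                f.end if is_ot else f.end - 1,
            ):
                info = int(pos) + (0 if is_ot else 1)
                if any(m.ref_start <= info < m.ref_end for m in f.mates):
                    overlap[int(pos)] += 1
        for pos, (m, u, a) in per_pos.items():
            assert m + u + a == overlap[pos]
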