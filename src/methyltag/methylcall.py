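"""Strand-aware CpG methylation calling and site-level aggregation.

Only cytosines in a CpG context are considered.  Calling is fragment-level:
one fragment contributes at most one call per CpG (mate overlap is resolved
by base quality, ties to read 1), so duplicate-removed fragments are the
counting unit throughout.
"""

from __future__ import annotations

import warnings
from collections import defaultdict
from typing import Iterable, Optional, Sequence

from intervaltree import IntervalTree

from .core import (
    AlignedFragment,
    BisulfiteStrand,
    CpGSite,
    Genome,
    MethState,
    Peak,
    ReadMethCall,
)


def call_read_methylation(
    fragment: AlignedFragment,
    genome: Genome,
    min_base_quality: int = 20,
) -> ReadMethCall:
    """Call the methylation state of every CpG a fragment reports on.

    OT fragments are read at the C of the CpG ('C' = methylated,
    'T' = unmethylated); OB fragments at the paired G ('G' = methylated,
    'A' = unmethylated).  Any other base, or base quality below
    ``min_base_quality``, yields an ambiguous call.
    """
    if fragment.contig not in genome.sequences:
        raise KeyError(f"contig {fragment.contig!r} absent from genome")
    is_ot = fragment.bisulfite_strand == BisulfiteStrand.OT
    # CpGs whose informative base could fall inside the template span
    lo = fragment.start if is_ot else fragment.start - 1
    hi = fragment.end if is_ot else fragment.end - 1
    calls: list[tuple[int, MethState]] = []
    for pos in genome.cpgs_in(fragment.contig, lo, hi):
        pos = int(pos)
        info = pos if is_ot else pos + 1
        best: Optional[tuple[str, int]] = None
        for mate in fragment.mates:
            obs = mate.base_at(info)
            if obs is None:
                continue
            # higher base quality wins; tie goes to read 1 (mates are
            # ordered read1 first by construction at ingest)
            if best is None or obs[1] > best[1]:
                best = obs
        if best is None:
            continue  # informative base not sequenced by either mate
        base, qual = best
        if qual < min_base_quality:
            state = MethState.AMBIG
        elif is_ot:
            state = {
                "C": MethState.METH,
                "T": MethState.UNMETH,
            }.get(base, MethState.AMBIG)
        else:
            state = {
                "G": MethState.METH,
                "A": MethState.UNMETH,
            }.get(base, MethState.AMBIG)
        calls.append((pos, state))
    return ReadMethCall(
        fragment_id=fragment.query_name,
        calls=calls,
        bisulfite_strand=fragment.bisulfite_strand,
    )


def call_fragments(
    fragments: Iterable[AlignedFragment],
    genome: Genome,
    min_base_quality: int = 20,
) -> list[ReadMethCall]:
    return [
        call_read_methylation(f, genome, min_base_quality) for f in fragments
    ]


def aggregate_sites(
    calls: Iterable[ReadMethCall],
    merge_strands: bool = True,
    contig: str = "",
) -> list[CpGSite]:
    """Sum per-fragment calls into CpG sites.

    Ambiguous calls are excluded from both counts.  With ``merge_strands``
    (the default) OT- and OB-derived evidence pools onto the forward-strand
    C position; betas are recomputed from pooled counts, never averaged.
    In stranded mode OB evidence is reported at the G position with
    strand '-'.
    """
    counts: dict[tuple[int, str], list[int]] = defaultdict(lambda: [0, 0])
    for rc in calls:
        for pos, state in rc.calls:
            if state == MethState.AMBIG:
                continue
            if merge_strands or rc.bisulfite_strand == BisulfiteStrand.OT:
                key = (pos, "+")
            else:
                key = (pos + 1, "-")
            if state == MethState.METH:
                counts[key][0] += 1
            else:
                counts[key][1] += 1
    sites = [
        CpGSite(
            contig=contig,
            pos0=pos,
            count_meth=c[0],
            count_unmeth=c[1],
            strand=strand,
        )
        for (pos, strand), c in counts.items()
        if c[0] + c[1] > 0
    ]
    sites.sort(key=lambda s: (s.contig, s.pos0, s.strand))
    return sites


def filter_sites(
    sites: Iterable[CpGSite],
    peaks: Sequence[Peak],
    min_coverage: int = 5,
) -> list[CpGSite]:
    """Keep CpGs inside peaks with at least ``min_coverage`` informative
    reads; retained sites carry the names of their containing peak(s).

    Peak intervals are half-open, so a site at ``peak.end`` is outside.
    """
    peaks = list(peaks)
    if not peaks:
        warnings.warn("empty peak list: no sites retained")
        return []
    trees: dict[str, IntervalTree] = defaultdict(IntervalTree)
    for p in peaks:
        trees[p.contig].addi(p.start, p.end, p.name)
    kept: list[CpGSite] = []
    for s in sites:
        if s.coverage < min_coverage:
            continue
        hits = trees[s.contig][s.pos0] if s.contig in trees else set()
        if not hits:
            continue
        names = tuple(sorted(iv.data for iv in hits))
        kept.append(
            CpGSite(
                contig=s.contig,
                pos0=s.pos0,
                count_meth=s.count_meth,
                count_unmeth=s.count_unmeth,
                strand=s.strand,
                peak_ids=names,
            )
        )
    return kept
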