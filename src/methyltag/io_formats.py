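"""Readers and writers for the on-disk formats the pipeline touches.

Read-level filters (mapping quality, duplicate removal) are applied at
ingest, so downstream modules only ever see retained fragments.
"""

from __future__ import annotations

import logging
import warnings
from collections import Counter
from pathlib import Path
from typing import Iterable, Optional, Union

import numpy as np
import pysam
from Bio import SeqIO

from .core import (
    AlignedFragment,
    BisulfiteStrand,
    CpGSite,
    Genome,
    MateRead,
    Peak,
)

logger = logging.getLogger(__name__)

PathLike = Union[str, Path]


class FormatError(ValueError):
    """Malformed input file."""


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: PathLike) -> Genome:
    """Load a reference FASTA into a :class:`Genome` with its CpG index.

    Lowercase bases are uppercased; non-ACGT bases are kept but never enter
    the CpG index.  Duplicate contig names are an error.
    """
    path = Path(path)
    with open(path) as fh:
        first = fh.read(1)
        if first != ">":
            raise FormatError(f"{path}: not a FASTA file (no '>' header)")
    sequences: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in sequences:
            raise FormatError(f"{path}: duplicate contig name {rec.id!r}")
        seq = str(rec.seq).upper()
        if not seq:
            raise FormatError(f"{path}: empty record {rec.id!r}")
        sequences[rec.id] = seq
    if not sequences:
        raise FormatError(f"{path}: no FASTA records")
    return Genome(sequences=sequences)


def write_fasta(path: PathLike, genome: Genome, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in genome.sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# narrowPeak / BED


def read_narrowpeak(path: PathLike) -> list[Peak]:
    """Parse a BED6 or 10-column ENCODE narrowPeak file.

    Coordinates are 0-based half-open.  The 10th column, when present and
    >= 0, is the summit offset; -1 means "no summit".  Records with
    start >= end are rejected with a warning rather than an error.
    """
    peaks: list[Peak] = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{ln}: fewer than 3 columns")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as e:
                raise FormatError(f"{path}:{ln}: non-integer coordinate") from e
            if start >= end:
                warnings.warn(f"{path}:{ln}: start >= end, record skipped")
                continue
            name = fields[3] if len(fields) > 3 and fields[3] else "."
            try:
                score = float(fields[4]) if len(fields) > 4 and fields[4] != "." else 0.0
            except ValueError:
                score = 0.0
            summit: Optional[int] = None
            if len(fields) >= 10:
                try:
                    s = int(fields[9])
                except ValueError as e:
                    raise FormatError(f"{path}:{ln}: non-integer summit") from e
                if s >= 0:
                    summit = s
            peaks.append(
                Peak(
                    contig=fields[0],
                    start=start,
                    end=end,
                    name=name,
                    score=score,
                    summit_offset=summit,
                )
            )
    return peaks


def write_narrowpeak(path: PathLike, peaks: Iterable[Peak]) -> None:
    with open(path, "w") as fh:
        for p in peaks:
            summit = p.summit_offset if p.summit_offset is not None else -1
            fh.write(
                f"{p.contig}\t{p.start}\t{p.end}\t{p.name}\t{p.score:g}"
                f"\t.\t0\t-1\t-1\t{summit}\n"
            )


# ---------------------------------------------------------------------------
# Bismark coverage files


def read_bismark_cov(
    path: PathLike,
    merge_strands: bool = False,
    genome: Optional[Genome] = None,
) -> list[CpGSite]:
    """Parse a Bismark ``.cov`` file into CpG sites.

    Columns: chrom, start (1-based), end, methylation %, count methylated,
    count unmethylated.  Beta is recomputed from the counts; the percentage
    column is advisory and only checked for consistency.  With
    ``merge_strands`` and a genome, a record sitting on the G of a CpG is
    folded onto the forward-strand C at ``pos - 1``.
    """
    raw: list[tuple[str, int, int, int, float]] = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise FormatError(f"{path}:{ln}: expected 6 columns")
            contig = fields[0]
            try:
                start1 = int(fields[1])
                pct = float(fields[3])
                n_meth = int(fields[4])
                n_unmeth = int(fields[5])
            except ValueError as e:
                raise FormatError(f"{path}:{ln}: malformed record") from e
            if n_meth < 0 or n_unmeth < 0:
                raise FormatError(f"{path}:{ln}: negative counts")
            cov = n_meth + n_unmeth
            if cov > 0 and abs(100.0 * n_meth / cov - pct) > 0.5:
                warnings.warn(
                    f"{path}:{ln}: % column inconsistent with counts"
                )
            raw.append((contig, start1 - 1, n_meth, n_unmeth, pct))

    if not (merge_strands and genome is not None):
        return [
            CpGSite(contig=c, pos0=p, count_meth=m, count_unmeth=u)
            for c, p, m, u, _ in raw
        ]

    pooled: dict[tuple[str, int], list[int]] = {}
    order: list[tuple[str, int]] = []
    for contig, pos0, n_meth, n_unmeth, _ in raw:
        key = (contig, pos0)
        seq = genome.sequences.get(contig, "")
        if (
            not genome.is_cpg(contig, pos0)
            and 0 < pos0 < len(seq)
            and seq[pos0] == "G"
            and seq[pos0 - 1] == "C"
        ):
            key = (contig, pos0 - 1)  # G-strand record -> forward C
        if key not in pooled:
            pooled[key] = [0, 0]
            order.append(key)
        pooled[key][0] += n_meth
        pooled[key][1] += n_unmeth
    return [
        CpGSite(contig=c, pos0=p, count_meth=pooled[(c, p)][0],
                count_unmeth=pooled[(c, p)][1])
        for c, p in order
    ]


def write_bismark_cov(path: PathLike, sites: Iterable[CpGSite]) -> None:
    with open(path, "w") as fh:
        for s in sites:
            pct = 100.0 * s.beta if s.coverage > 0 else 0.0
            fh.write(
                f"{s.contig}\t{s.pos0 + 1}\t{s.pos0 + 1}\t{pct:g}"
                f"\t{s.count_meth}\t{s.count_unmeth}\n"
            )


# ---------------------------------------------------------------------------
# SAM/BAM alignments


def _infer_bisulfite_strand(read1_reverse: bool) -> BisulfiteStrand:
    # Directional library: read1 forward / read2 reverse -> original top;
    # read1 reverse / read2 forward -> original bottom.
    return BisulfiteStrand.OB if read1_reverse else BisulfiteStrand.OT


def _simple_mate(rec: pysam.AlignedSegment) -> Optional[MateRead]:
    """Represent a gapless aligned mate; None if the alignment has indels."""
    for op, _ in rec.cigartuples or ():
        if op not in (0, 4, 5, 7, 8):  # M, S, H, =, X only
            return None
    seq = rec.query_alignment_sequence
    quals = rec.query_alignment_qualities
    if seq is None or quals is None:
        return None
    return MateRead(
        seq=seq.upper(),
        quals=np.asarray(quals, dtype=np.int64),
        ref_start=rec.reference_start,
        is_read1=rec.is_read1,
    )


def read_alignments(
    path: PathLike,
    mapq_min: int = 30,
    dedup: bool = True,
    stats: Optional[Counter] = None,
) -> list[AlignedFragment]:
    """Load paired bisulfite fragments from SAM/BAM with read-level filters.

    Fragments with mapping quality below ``mapq_min`` are dropped, and
    duplicates — identical (contig, start, end, bisulfite strand) — are
    collapsed keeping the first seen.  Secondary, supplementary, unmapped
    and unpaired records are skipped and counted in ``stats``.
    """
    counters = stats if stats is not None else Counter()
    pending: dict[str, pysam.AlignedSegment] = {}
    fragments: list[AlignedFragment] = []
    save = pysam.set_verbosity(0)
    try:
        with pysam.AlignmentFile(str(path), check_sq=False) as fh:
            for rec in fh:
                if rec.is_secondary or rec.is_supplementary:
                    counters["skipped_secondary"] += 1
                    continue
                if rec.is_unmapped or not rec.is_paired or rec.mate_is_unmapped:
                    counters["skipped_unpaired"] += 1
                    continue
                other = pending.pop(rec.query_name, None)
                if other is None:
                    pending[rec.query_name] = rec
                    continue
                frag = _pair_to_fragment(rec, other, counters)
                if frag is not None:
                    fragments.append(frag)
    finally:
        pysam.set_verbosity(save)
    counters["orphan_mates"] += len(pending)

    kept: list[AlignedFragment] = []
    seen: set[tuple] = set()
    for frag in fragments:
        if frag.mapq < mapq_min:
            counters["dropped_mapq"] += 1
            continue
        if dedup:
            key = frag.dedup_key()
            if key in seen:
                counters["dropped_duplicate"] += 1
                continue
            seen.add(key)
        kept.append(frag)
    counters["retained"] = len(kept)
    return kept


def _pair_to_fragment(
    a: pysam.AlignedSegment, b: pysam.AlignedSegment, counters: Counter
) -> Optional[AlignedFragment]:
    read1, read2 = (a, b) if a.is_read1 else (b, a)
    if not read1.is_read1 or not read2.is_read2:
        counters["dropped_bad_flags"] += 1
        return None
    if read1.reference_name != read2.reference_name:
        counters["dropped_interchrom"] += 1
        return None
    # Unknown flag combination for a directional library: both mates on the
    # same strand.
    if read1.is_reverse == read2.is_reverse:
        counters["dropped_bad_flags"] += 1
        warnings.warn(
            f"{read1.query_name}: mates on the same strand, fragment dropped"
        )
        return None
    strand = _infer_bisulfite_strand(read1.is_reverse)
    mates = []
    for rec in (read1, read2):
        mate = _simple_mate(rec)
        if mate is None:
            counters["dropped_gapped"] += 1
            return None
        mates.append(mate)
    start = min(m.ref_start for m in mates)
    end = max(m.ref_end for m in mates)
    return AlignedFragment(
        query_name=read1.query_name,
        contig=read1.reference_name,
        start=start,
        end=end,
        bisulfite_strand=strand,
        mapq=min(read1.mapping_quality, read2.mapping_quality),
        mates=tuple(mates),
    )


def write_sam(
    path: PathLike,
    fragments: Iterable[AlignedFragment],
    contig_lengths: dict[str, int],
) -> None:
    """Write fragments as a proper-paired SAM file.

    Flags encode the bisulfite strand exactly as :func:`read_alignments`
    infers it: OT = read1 forward / read2 reverse, OB = the converse.
    """
    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": n, "LN": ln} for n, ln in contig_lengths.items()],
    }
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        tid = {n: i for i, n in enumerate(contig_lengths)}
        for frag in fragments:
            r1_reverse = frag.bisulfite_strand == BisulfiteStrand.OB
            for mate in frag.mates:
                rec = pysam.AlignedSegment(out.header)
                rec.query_name = frag.query_name
                rec.reference_id = tid[frag.contig]
                rec.reference_start = mate.ref_start
                rec.mapping_quality = frag.mapq
                rec.query_sequence = mate.seq
                rec.query_qualities = pysam.qualitystring_to_array(
                    "".join(chr(q + 33) for q in mate.quals)
                )
                rec.cigartuples = [(0, len(mate.seq))]
                is_rev = r1_reverse if mate.is_read1 else not r1_reverse
                flag = 0x1 | 0x2  # paired, proper pair
                flag |= 0x40 if mate.is_read1 else 0x80
                if is_rev:
                    flag |= 0x10
                else:
                    flag |= 0x20  # mate reverse
                rec.flag = flag
                other = next(m for m in frag.mates if m is not mate)
                rec.next_reference_id = tid[frag.contig]
                rec.next_reference_start = other.ref_start
                tlen = frag.end - frag.start
                rec.template_length = tlen if mate.ref_start <= other.ref_start else -tlen
                out.write(rec)
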