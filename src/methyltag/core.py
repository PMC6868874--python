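"""Core domain types shared across the pipeline.

All internal coordinates are 0-based, half-open.  SAM input (1-based) and
Bismark coverage input (1-based) are converted at ingest; BED/narrowPeak are
already 0-based half-open.  A CpG site is always addressed by the position of
the C on the forward strand, whichever strand the evidence came from.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Optional

import numpy as np

_CPG_RE = re.compile(r"(?=CG)")


class BisulfiteStrand(str, Enum):
    """Original-top (OT) or original-bottom (OB) strand of a directional
    bisulfite library.  Methylation is read at the C of the CpG on OT
    fragments and at the paired G (C position + 1) on OB fragments."""

    OT = "OT"
    OB = "OB"


class MethState(str, Enum):
    METH = "M"
    UNMETH = "U"
    AMBIG = "X"


@dataclass
class Genome:
    """Reference sequences plus a per-contig index of forward-strand CpGs.

    ``cpg_index[contig]`` is a sorted int array of 0-based positions ``p``
    with ``sequences[contig][p:p+2] == "CG"``.  Overlapping CpGs (CGCG) each
    get their own entry.  Non-ACGT bases are retained in the sequence but
    never indexed.
    """

    sequences: dict[str, str]
    cpg_index: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.cpg_index:
            self.cpg_index = {
                name: np.fromiter(
                    (m.start() for m in _CPG_RE.finditer(seq)), dtype=np.int64
                )
                for name, seq in self.sequences.items()
            }

    @classmethod
    def from_sequences(cls, sequences: dict[str, str]) -> "Genome":
        return cls(sequences={k: v.upper() for k, v in sequences.items()})

    def cpgs_in(self, contig: str, start: int, end: int) -> np.ndarray:
        """CpG C-positions with ``start <= p < end`` on ``contig``."""
        idx = self.cpg_index[contig]
        lo, hi = np.searchsorted(idx, [start, end])
        return idx[lo:hi]

    def is_cpg(self, contig: str, pos0: int) -> bool:
        idx = self.cpg_index.get(contig)
        if idx is None or len(idx) == 0:
            return False
        i = int(np.searchsorted(idx, pos0))
        return i < len(idx) and idx[i] == pos0


@dataclass
class MateRead:
    """One aligned mate of a paired fragment (gapless alignment)."""

    seq: str
    quals: np.ndarray  # phred scores, same length as seq
    ref_start: int
    is_read1: bool

    @property
    def ref_end(self) -> int:
        return self.ref_start + len(self.seq)

    def base_at(self, ref_pos: int) -> Optional[tuple[str, int]]:
        i = ref_pos - self.ref_start
        if 0 <= i < len(self.seq):
            return self.seq[i], int(self.quals[i])
        return None


@dataclass
class AlignedFragment:
    """A retained paired-end bisulfite fragment (template span)."""

    query_name: str
    contig: str
    start: int  # 0-based inclusive
    end: int  # 0-based exclusive
    bisulfite_strand: BisulfiteStrand
    mapq: int
    mates: tuple[MateRead, ...] = ()

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(
                f"fragment {self.query_name}: start {self.start} >= end {self.end}"
            )
        if self.mapq < 0:
            raise ValueError("mapq must be >= 0")

    @property
    def length(self) -> int:
        return self.end - self.start

    def dedup_key(self) -> tuple:
        # bisulfite_strand is part of the key: OT/OB fragments at identical
        # coordinates are distinct molecules under directional chemistry.
        return (self.contig, self.start, self.end, self.bisulfite_strand)


@dataclass
class Peak:
    """An accessibility/occupancy interval (narrowPeak/BED)."""

    contig: str
    start: int
    end: int
    name: str = "."
    score: float = 0.0
    summit_offset: Optional[int] = None

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"peak {self.name}: start >= end")
        if self.summit_offset is not None and not (
            0 <= self.summit_offset < self.end - self.start
        ):
            raise ValueError(f"peak {self.name}: summit_offset out of range")

    @property
    def width(self) -> int:
        return self.end - self.start


@dataclass
class CpGSite:
    """One CpG with methylated / unmethylated informative read counts.

    ``beta`` (the methylation fraction) is undefined at coverage 0 and
    returned as ``nan`` there.
    """

    contig: str
    pos0: int
    count_meth: int
    count_unmeth: int
    strand: str = "+"  # "+" for forward-C / destranded, "-" for OB-only sites
    peak_ids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.count_meth < 0 or self.count_unmeth < 0:
            raise ValueError("negative methylation counts")

    @property
    def coverage(self) -> int:
        return self.count_meth + self.count_unmeth

    @property
    def beta(self) -> float:
        cov = self.coverage
        return self.count_meth / cov if cov > 0 else float("nan")


@dataclass
class ReadMethCall:
    """Per-CpG methylation states observed on one fragment."""

    fragment_id: str
    calls: list[tuple[int, MethState]]  # (cpg_pos0, state), one per CpG
    bisulfite_strand: BisulfiteStrand = BisulfiteStrand.OT

    def states(self) -> dict[int, MethState]:
        return dict(self.calls)


def sites_to_frame(sites: Iterable[CpGSite]):
    """Tabulate CpG sites as a DataFrame (contig, pos0, counts, beta)."""
    import pandas as pd

    rows = [
        {
            "contig": s.contig,
            "pos0": s.pos0,
            "count_meth": s.count_meth,
            "count_unmeth": s.count_unmeth,
            "coverage": s.coverage,
            "beta": s.beta,
            "strand": s.strand,
            "peak_ids": ",".join(s.peak_ids),
        }
        for s in sites
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "contig",
            "pos0",
            "count_meth",
            "count_unmeth",
            "coverage",
            "beta",
            "strand",
            "peak_ids",
        ],
    )
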