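"""Per-peak methylation summaries, cross-assay comparison, genomic
annotation and library QC statistics."""

from __future__ import annotations

import warnings
from collections import Counter, defaultdict
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core import AlignedFragment, CpGSite, Peak


@dataclass
class PeakMethylation:
    peak_id: str
    n_cpgs_used: int
    mean_beta: float


@dataclass
class GeneModel:
    """Minimal gene model: TSS for promoter windows, body for intragenic."""

    gene_id: str
    contig: str
    strand: str
    tss: int  # 0-based position of the transcription start site
    start: int
    end: int


def peak_mean_methylation(
    peaks: Sequence[Peak], filtered_sites: Iterable[CpGSite]
) -> list[PeakMethylation]:
    """Unweighted mean of site betas per peak (each CpG one vote).

    Sites must already carry their peak annotations (from
    :func:`methylcall.filter_sites`); peaks with no qualifying CpG are
    omitted from the output.
    """
    betas: dict[str, list[float]] = defaultdict(list)
    for s in filtered_sites:
        for pid in s.peak_ids:
            betas[pid].append(s.beta)
    out = []
    for p in peaks:
        if p.name in betas:
            vals = betas[p.name]
            out.append(
                PeakMethylation(
                    peak_id=p.name,
                    n_cpgs_used=len(vals),
                    mean_beta=float(np.mean(vals)),
                )
            )
    return out


QUADRANTS = ("bottom-left", "top-left", "top-right", "bottom-right")


def quadrant_counts(
    table_a: Mapping[str, float] | Sequence[PeakMethylation],
    table_b: Mapping[str, float] | Sequence[PeakMethylation],
    threshold: float = 0.5,
) -> tuple[Counter, dict[str, str]]:
    """2x2 classification of shared peaks by mean methylation in two assays.

    Assay A is the x-axis, assay B the y-axis; "low" means mean beta
    strictly below ``threshold`` (values at the threshold go to the high
    side).  Returns quadrant counts and the per-peak label.
    """
    a = _as_beta_map(table_a)
    b = _as_beta_map(table_b)
    shared = sorted(set(a) & set(b))
    if not shared:
        raise ValueError("no shared peaks between the two tables")
    labels: dict[str, str] = {}
    counts: Counter = Counter({q: 0 for q in QUADRANTS})
    for pid in shared:
        low_a = a[pid] < threshold
        low_b = b[pid] < threshold
        if low_a and low_b:
            q = "bottom-left"
        elif low_a:
            q = "top-left"
        elif low_b:
            q = "bottom-right"
        else:
            q = "top-right"
        labels[pid] = q
        counts[q] += 1
    return counts, labels


def _as_beta_map(table) -> dict[str, float]:
    if isinstance(table, Mapping):
        return dict(table)
    return {pm.peak_id: pm.mean_beta for pm in table}


def _merge_intervals(
    intervals: Iterable[tuple[int, int]]
) -> list[tuple[int, int]]:
    merged: list[list[int]] = []
    for s, e in sorted(intervals):
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


def interval_jaccard(
    peaks_a: Sequence[Peak], peaks_b: Sequence[Peak]
) -> float:
    """Jaccard index of two peak sets: intersected bp / union bp, after
    merging each set to disjoint intervals per contig."""
    if not peaks_a and not peaks_b:
        raise ValueError("both peak sets are empty")
    by_contig_a: dict[str, list[tuple[int, int]]] = defaultdict(list)
    by_contig_b: dict[str, list[tuple[int, int]]] = defaultdict(list)
    for p in peaks_a:
        by_contig_a[p.contig].append((p.start, p.end))
    for p in peaks_b:
        by_contig_b[p.contig].append((p.start, p.end))
    inter = union = 0
    for contig in set(by_contig_a) | set(by_contig_b):
        ma = _merge_intervals(by_contig_a.get(contig, []))
        mb = _merge_intervals(by_contig_b.get(contig, []))
        len_a = sum(e - s for s, e in ma)
        len_b = sum(e - s for s, e in mb)
        i = _intersection_bp(ma, mb)
        inter += i
        union += len_a + len_b - i
    return inter / union if union else 0.0


def _intersection_bp(
    a: list[tuple[int, int]], b: list[tuple[int, int]]
) -> int:
    i = j = total = 0
    while i < len(a) and j < len(b):
        s = max(a[i][0], b[j][0])
        e = min(a[i][1], b[j][1])
        if e > s:
            total += e - s
        if a[i][1] < b[j][1]:
            i += 1
        else:
            j += 1
    return total


def binned_pearson(
    fragments_a: Sequence[AlignedFragment],
    fragments_b: Sequence[AlignedFragment],
    contig_lengths: Mapping[str, int],
    bin_size: int = 10_000,
) -> float:
    """Pearson correlation of fragment counts in fixed genomic bins.

    Each fragment is assigned to the bin of its midpoint.  A zero-variance
    count vector makes the correlation undefined and raises.
    """
    va = _bin_counts(fragments_a, contig_lengths, bin_size)
    vb = _bin_counts(fragments_b, contig_lengths, bin_size)
    if np.ptp(va) == 0 or np.ptp(vb) == 0:
        raise ValueError("constant coverage vector: correlation undefined")
    r, _ = stats.pearsonr(va, vb)
    return float(r)


def _bin_counts(
    fragments: Sequence[AlignedFragment],
    contig_lengths: Mapping[str, int],
    bin_size: int,
) -> np.ndarray:
    offsets: dict[str, int] = {}
    total_bins = 0
    for contig, ln in contig_lengths.items():
        offsets[contig] = total_bins
        total_bins += -(-ln // bin_size)
    counts = np.zeros(total_bins, dtype=np.int64)
    for f in fragments:
        if f.contig not in offsets:
            continue
        mid = (f.start + f.end) // 2
        counts[offsets[f.contig] + mid // bin_size] += 1
    return counts


def annotate_regions(
    regions: Sequence[Peak],
    gene_models: Sequence[GeneModel],
    promoter_flank: int = 3000,
    intergenic_min_dist: int = 1000,
) -> pd.DataFrame:
    """Label regions promoter / intragenic / intergenic, in that precedence.

    Promoter means overlap with [TSS - flank, TSS + flank]; intragenic
    means overlap with a gene body.  Intergenic regions additionally get a
    ``distal`` flag when their distance to the nearest promoter window
    exceeds ``intergenic_min_dist``.
    """
    prom: dict[str, list[tuple[int, int]]] = defaultdict(list)
    body: dict[str, list[tuple[int, int]]] = defaultdict(list)
    for g in gene_models:
        prom[g.contig].append(
            (max(0, g.tss - promoter_flank), g.tss + promoter_flank + 1)
        )
        body[g.contig].append((g.start, g.end))
    known = {g.contig for g in gene_models}
    rows = []
    for r in regions:
        if r.contig not in known:
            warnings.warn(
                f"region contig {r.contig!r} absent from gene models"
            )
            label, distal = "intergenic", True
        elif _overlaps_any(r, prom[r.contig]):
            label, distal = "promoter", False
        elif _overlaps_any(r, body[r.contig]):
            label, distal = "intragenic", False
        else:
            d = _dist_to_nearest(r, prom[r.contig])
            label, distal = "intergenic", d > intergenic_min_dist
        rows.append(
            {
                "region": r.name,
                "contig": r.contig,
                "start": r.start,
                "end": r.end,
                "annotation": label,
                "distal": distal,
            }
        )
    return pd.DataFrame(rows)


def _overlaps_any(r: Peak, intervals: list[tuple[int, int]]) -> bool:
    return any(r.start < e and s < r.end for s, e in intervals)


def _dist_to_nearest(r: Peak, intervals: list[tuple[int, int]]) -> int:
    best = np.inf
    for s, e in intervals:
        if r.start < e and s < r.end:
            return 0
        best = min(best, s - r.end if s >= r.end else r.start - e)
    return int(best) if np.isfinite(best) else 10**9


def fragment_length_histogram(
    fragments: Iterable[AlignedFragment], max_length: int = 1000
) -> tuple[dict[int, int], dict[str, float]]:
    """Histogram of template lengths (end - start), capped at
    ``max_length``; returns the counts and mean/median summaries."""
    lengths = [f.length for f in fragments if f.length <= max_length]
    hist = dict(sorted(Counter(lengths).items()))
    summary = {
        "n": float(len(lengths)),
        "mean": float(np.mean(lengths)) if lengths else float("nan"),
        "median": float(np.median(lengths)) if lengths else float("nan"),
    }
    return hist, summary
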