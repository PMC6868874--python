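"""PWM motif scanning with exact score-distribution thresholds, CpG-offset
mapping inside motif hits (e.g. the C2/C12 positions of the 19-bp CTCF
motif), per-offset methylation comparison, and per-fragment co-methylation
testing.

Scores are log-odds in bits: score(window) = sum_k log2(p_k(base)/bg(base)).
The p-value threshold is computed from the exact distribution of that score
under the background model by position-wise convolution on a discretized
score grid — the same construction FIMO uses — not by sampling.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
from scipy import stats

from .core import CpGSite, Genome, MethState, Peak, ReadMethCall

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}


@dataclass
class MotifMatrix:
    """Position probability matrix (rows A, C, G, T) with its background."""

    probs: np.ndarray  # shape (4, W)
    background: np.ndarray  # shape (4,)
    pseudocount: float = 1.0
    name: str = "motif"

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.probs.ndim != 2 or self.probs.shape[0] != 4:
            raise ValueError("probability matrix must be 4 x W")
        if not np.allclose(self.probs.sum(axis=0), 1.0, atol=1e-9):
            raise ValueError("matrix columns must sum to 1")
        if np.any(self.probs <= 0):
            raise ValueError("matrix entries must be positive (pseudocount)")

    @property
    def width(self) -> int:
        return self.probs.shape[1]

    @property
    def log_odds(self) -> np.ndarray:
        """4 x W log2(p / background) score matrix."""
        return np.log2(self.probs / self.background[:, None])

    def reverse_complement(self) -> "MotifMatrix":
        return MotifMatrix(
            probs=self.probs[::-1, ::-1].copy(),
            background=self.background[::-1].copy(),
            pseudocount=self.pseudocount,
            name=self.name + "_rc",
        )


@dataclass
class MotifHit:
    contig: str
    start0: int
    strand: str  # '+' or '-'
    score: float
    width: int
    # 1-based motif positions whose genomic sequence (in motif orientation)
    # carries a CpG, with the forward-strand C coordinate of each
    cpg_offsets: list[tuple[int, int]] = field(default_factory=list)

    @property
    def end0(self) -> int:
        return self.start0 + self.width


def pwm_from_counts(
    count_matrix: np.ndarray,
    pseudocount: float = 1.0,
    background: Optional[Sequence[float]] = None,
    name: str = "motif",
) -> MotifMatrix:
    """Column-normalize a 4 x W count matrix with a pseudocount:
    p = (count + pseudocount) / (colsum + 4 * pseudocount)."""
    counts = np.asarray(count_matrix, dtype=float)
    if counts.ndim != 2 or counts.shape[0] != 4 or counts.shape[1] < 1:
        raise ValueError("count matrix must be 4 x W with W >= 1")
    if np.any(counts < 0):
        raise ValueError("negative counts")
    if pseudocount == 0 and np.any(counts == 0):
        raise ValueError("zero count with zero pseudocount: log-odds undefined")
    bg = (
        np.full(4, 0.25)
        if background is None
        else np.asarray(background, dtype=float)
    )
    if bg.shape != (4,) or np.any(bg <= 0) or abs(bg.sum() - 1) > 1e-9:
        raise ValueError("background must be 4 positive frequencies summing to 1")
    probs = (counts + pseudocount) / (counts.sum(axis=0) + 4.0 * pseudocount)
    return MotifMatrix(probs=probs, background=bg, pseudocount=pseudocount, name=name)


def read_jaspar_pfm(path, pseudocount: float = 1.0,
                    background: Optional[Sequence[float]] = None) -> MotifMatrix:
    """Parse JASPAR PFM text (plain 4-row or bracketed ``A [ .. ]`` dialect)."""
    name = "motif"
    rows: list[list[float]] = []
    order: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                name = line[1:].split()[0] if line[1:].split() else name
                continue
            letter = None
            if line[0].upper() in "ACGT" and (len(line) == 1 or not line[1].isdigit()):
                letter = line[0].upper()
                line = line[1:]
            line = line.replace("[", " ").replace("]", " ")
            vals = [float(tok) for tok in line.split()]
            if letter is not None:
                order.append(letter)
            rows.append(vals)
    if len(rows) != 4:
        raise ValueError(f"{path}: expected 4 matrix rows, got {len(rows)}")
    if order and sorted(order) == list("ACGT"):
        rows = [rows[order.index(b)] for b in "ACGT"]
    return pwm_from_counts(
        np.array(rows), pseudocount=pseudocount, background=background, name=name
    )


# ---------------------------------------------------------------------------
# exact score distribution / threshold


def score_distribution(
    matrix: MotifMatrix, bin_width: float = 0.01
) -> tuple[np.ndarray, np.ndarray]:
    """Exact distribution of the log-odds score under the background model.

    The per-position scores are rounded to an integer grid of ``bin_width``
    bits and convolved across positions; returns (grid scores ascending,
    probabilities).  Exact up to the grid rounding (one bin per position at
    most, so within W * bin_width of the true score).
    """
    lodds = matrix.log_odds
    q = np.rint(lodds / bin_width).astype(np.int64)
    bg = matrix.background
    probs = np.array([1.0])
    cur_min = 0
    for k in range(matrix.width):
        col = q[:, k]
        new_min = cur_min + int(col.min())
        new_max = cur_min + len(probs) - 1 + int(col.max())
        new = np.zeros(new_max - new_min + 1)
        for b in range(4):
            shift = cur_min + int(col[b]) - new_min
            new[shift : shift + len(probs)] += bg[b] * probs
        probs = new
        cur_min = new_min
    scores = (np.arange(len(probs)) + cur_min) * bin_width
    return scores, probs


def pwm_score_threshold(
    matrix: MotifMatrix, pvalue: float = 1e-4, bin_width: float = 0.01
) -> float:
    """Smallest score threshold whose background tail probability is at
    most ``pvalue`` (hits with score >= threshold are reported)."""
    if not (0.0 < pvalue <= 1.0):
        raise ValueError("pvalue must be in (0, 1]")
    scores, probs = score_distribution(matrix, bin_width)
    tail = np.cumsum(probs[::-1])[::-1]  # P(score >= scores[i])
    ok = np.nonzero(tail <= pvalue + 1e-12)[0]
    if len(ok) == 0:
        return float(scores[-1] + bin_width)  # nothing passes
    return float(scores[ok[0]])


# ---------------------------------------------------------------------------
# scanning


def _encode(seq: str) -> np.ndarray:
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    out = np.full(len(arr), -1, dtype=np.int64)
    for base, i in _BASE_INDEX.items():
        out[arr == ord(base)] = i
    return out


def _window_scores(
    enc: np.ndarray, lodds: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Scores of every window and a validity mask (no non-ACGT base)."""
    W = lodds.shape[1]
    n = len(enc) - W + 1
    if n <= 0:
        return np.empty(0), np.empty(0, dtype=bool)
    scores = np.zeros(n)
    valid = np.ones(n, dtype=bool)
    safe = np.where(enc >= 0, enc, 0)
    for k in range(W):
        scores += lodds[:, k][safe[k : k + n]]
        valid &= enc[k : k + n] >= 0
    return scores, valid


def scan_motifs(
    genome: Genome,
    regions: Optional[Sequence[Peak]],
    matrix: MotifMatrix,
    threshold: float,
    annotate_cpgs: bool = True,
) -> list[MotifHit]:
    """Scan both strands of the given regions (whole contigs when
    ``regions`` is None) and return hits scoring at least ``threshold``.

    Minus-strand hits score the reverse complement of the window and are
    reported in forward coordinates.  Windows containing non-ACGT bases
    are skipped.
    """
    if regions is None:
        regions = [
            Peak(contig=c, start=0, end=len(s), name=c)
            for c, s in genome.sequences.items()
        ]
    lodds_fwd = matrix.log_odds
    lodds_rev = matrix.reverse_complement().log_odds
    W = matrix.width
    hits: list[MotifHit] = []
    for region in regions:
        seq = genome.sequences[region.contig][region.start : region.end]
        enc = _encode(seq)
        for strand, lodds in (("+", lodds_fwd), ("-", lodds_rev)):
            scores, valid = _window_scores(enc, lodds)
            for i in np.nonzero(valid & (scores >= threshold))[0]:
                hit = MotifHit(
                    contig=region.contig,
                    start0=region.start + int(i),
                    strand=strand,
                    score=float(scores[i]),
                    width=W,
                )
                if annotate_cpgs:
                    hit.cpg_offsets = hit_cpg_offsets(hit, genome)
                hits.append(hit)
    hits.sort(key=lambda h: (h.contig, h.start0, h.strand))
    return hits


def hit_cpg_offsets(hit: MotifHit, genome: Genome) -> list[tuple[int, int]]:
    """CpG positions inside a hit, as (1-based motif offset, forward-strand
    C coordinate).

    For a minus-strand hit the offset counts from the motif's 5' end on
    the minus strand: a forward CpG whose C sits at genomic position p
    maps to offset ``start + W - 1 - p``.
    """
    W = hit.width
    out: list[tuple[int, int]] = []
    for p in genome.cpgs_in(hit.contig, hit.start0, hit.start0 + W - 1):
        p = int(p)
        if hit.strand == "+":
            k = p - hit.start0 + 1
        else:
            k = hit.start0 + W - 1 - p
        if 1 <= k <= W - 1:
            out.append((k, p))
    out.sort()
    return out


# ---------------------------------------------------------------------------
# motif-position methylation


def position_methylation(
    hits: Sequence[MotifHit],
    sites: Sequence[CpGSite],
    offsets: tuple[int, ...] = (2, 12),
    unique_cpg: bool = False,
) -> dict:
    """Collect site betas by motif offset and compare offsets pairwise.

    For each requested offset, the betas of filtered sites whose
    coordinate maps to that offset in at least one hit are collected (one
    contribution per (hit, offset); ``unique_cpg`` collapses each CpG to
    its best-scoring hit first).  Offsets are compared with a two-sample
    rank-sum test (normal approximation, tie-corrected).
    """
    beta_map = {(s.contig, s.pos0): s.beta for s in sites}
    chosen: dict[tuple[str, int], MotifHit] = {}
    if unique_cpg:
        for h in hits:
            for _, coord in h.cpg_offsets:
                key = (h.contig, coord)
                if key not in chosen or h.score > chosen[key].score:
                    chosen[key] = h
    vectors: dict[int, list[float]] = {k: [] for k in offsets}
    for h in hits:
        for k, coord in h.cpg_offsets:
            if k not in vectors:
                continue
            if unique_cpg and chosen.get((h.contig, coord)) is not h:
                continue
            beta = beta_map.get((h.contig, coord))
            if beta is not None and not math.isnan(beta):
                vectors[k].append(beta)
    arrays = {k: np.asarray(v) for k, v in vectors.items()}
    result: dict = {
        "betas": arrays,
        "medians": {
            k: (float(np.median(v)) if len(v) else float("nan"))
            for k, v in arrays.items()
        },
        "comparisons": {},
    }
    keys = list(offsets)
    for i in range(len(keys)):
        for j in range(i + 1, len(keys)):
            a, b = arrays[keys[i]], arrays[keys[j]]
            if len(a) == 0 or len(b) == 0:
                continue
            u, p = stats.mannwhitneyu(
                a, b, alternative="two-sided", method="asymptotic"
            )
            result["comparisons"][(keys[i], keys[j])] = {
                "U": float(u),
                "pvalue": float(p),
            }
    return result


def paired_rank_test(betas_a: Sequence[float], betas_b: Sequence[float]) -> dict:
    """Paired (signed-rank) comparison of the same CpGs in two assays."""
    a = np.asarray(betas_a, dtype=float)
    b = np.asarray(betas_b, dtype=float)
    if a.shape != b.shape or len(a) == 0:
        raise ValueError("paired vectors must be non-empty and equal length")
    if np.allclose(a, b):
        return {"W": 0.0, "pvalue": 1.0}
    w, p = stats.wilcoxon(a, b)
    return {"W": float(w), "pvalue": float(p)}


# ---------------------------------------------------------------------------
# per-fragment co-methylation


@dataclass
class ComethTable:
    """Joint methylation states of a CpG pair on the same fragment."""

    mm: int
    mu: int
    um: int
    uu: int
    chi_square: Optional[float] = None
    pvalue: Optional[float] = None
    df: int = 1

    @property
    def n(self) -> int:
        return self.mm + self.mu + self.um + self.uu

    @property
    def observed_mm_fraction(self) -> float:
        return self.mm / self.n if self.n else float("nan")

    @property
    def marginal_a(self) -> float:
        return (self.mm + self.mu) / self.n if self.n else float("nan")

    @property
    def marginal_b(self) -> float:
        return (self.mm + self.um) / self.n if self.n else float("nan")

    @property
    def expected_mm_fraction(self) -> float:
        return self.marginal_a * self.marginal_b

    def counts(self) -> dict[str, int]:
        return {"MM": self.mm, "MU": self.mu, "UM": self.um, "UU": self.uu}


def _pearson_chi2_2x2(mm: int, mu: int, um: int, uu: int):
    n = mm + mu + um + uu
    pa = (mm + mu) / n
    pb = (mm + um) / n
    if pa in (0.0, 1.0) or pb in (0.0, 1.0):
        return None, None
    exp = {
        "MM": n * pa * pb,
        "MU": n * pa * (1 - pb),
        "UM": n * (1 - pa) * pb,
        "UU": n * (1 - pa) * (1 - pb),
    }
    obs = {"MM": mm, "MU": mu, "UM": um, "UU": uu}
    chi2 = sum((obs[k] - exp[k]) ** 2 / exp[k] for k in exp)
    return chi2, float(stats.chi2.sf(chi2, df=1))


def comethylation_table(mm: int, mu: int, um: int, uu: int) -> ComethTable:
    """Build a ComethTable from joint counts; Pearson chi-square (df = 1,
    no continuity correction) against independence of the two CpGs'
    states, expected counts from the table's own marginals."""
    if min(mm, mu, um, uu) < 0:
        raise ValueError("negative counts")
    table = ComethTable(mm=mm, mu=mu, um=um, uu=uu)
    if table.n >= 2:
        table.chi_square, table.pvalue = _pearson_chi2_2x2(mm, mu, um, uu)
    return table


def comethylation_test(
    read_calls: Iterable[ReadMethCall], cpg_pair: tuple[int, int]
) -> ComethTable:
    """Joint-state table for fragments that call BOTH CpGs of ``cpg_pair``
    unambiguously, with the independence chi-square.

    Fewer than 2 informative fragments or a degenerate marginal leaves
    ``chi_square`` undefined (None).
    """
    pos_a, pos_b = cpg_pair
    mm = mu = um = uu = 0
    for rc in read_calls:
        st = rc.states()
        sa, sb = st.get(pos_a), st.get(pos_b)
        if sa in (None, MethState.AMBIG) or sb in (None, MethState.AMBIG):
            continue
        if sa == MethState.METH:
            if sb == MethState.METH:
                mm += 1
            else:
                mu += 1
        else:
            if sb == MethState.METH:
                um += 1
            else:
                uu += 1
    return comethylation_table(mm, mu, um, uu)


def pooled_comethylation(
    read_calls: Sequence[ReadMethCall],
    hits: Sequence[MotifHit],
    offsets: tuple[int, int] = (2, 12),
) -> ComethTable:
    """Pool joint C2/C12-style states over every hit carrying both offsets
    and test the pooled table (the default, genome-wide reading)."""
    calls_at: dict[int, dict[str, MethState]] = {}
    for rc in read_calls:
        for pos, state in rc.calls:
            calls_at.setdefault(pos, {})[rc.fragment_id] = state
    mm = mu = um = uu = 0
    for h in hits:
        offmap = dict(h.cpg_offsets)
        if offsets[0] not in offmap or offsets[1] not in offmap:
            continue
        ca = calls_at.get(offmap[offsets[0]], {})
        cb = calls_at.get(offmap[offsets[1]], {})
        for fid in set(ca) & set(cb):
            sa, sb = ca[fid], cb[fid]
            if MethState.AMBIG in (sa, sb):
                continue
            if sa == MethState.METH and sb == MethState.METH:
                mm += 1
            elif sa == MethState.METH:
                mu += 1
            elif sb == MethState.METH:
                um += 1
            else:
                uu += 1
    return comethylation_table(mm, mu, um, uu)
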