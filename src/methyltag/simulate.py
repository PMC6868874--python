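"""Synthetic bisulfite-tagmentation data generator.

Produces a toy genome with a controlled CpG density, non-overlapping
accessibility peaks, a mixture-methylome truth table (mostly-low,
intermediate, mostly-high CpG classes), and aligned directional
paired-end fragments whose read bases follow bisulfite chemistry:

* OT (original top) fragments report a CpG at its C — methylated C stays
  ``C`` (unless conversion fails in reverse, rate ``failure_rate``),
  unmethylated C reads ``T`` with probability ``conversion_rate``.
* OB (original bottom) fragments report a CpG at its paired G — methylated
  reads ``G``, converted unmethylated reads ``A``.
* Cytosines (or, on OB, guanines) outside a CpG context are always
  converted.

Reads are emitted already aligned (correct SAM coordinates, proper-pair
flags consistent with strand inference at ingest); alignment itself is out
of scope.  Per-CpG truth draws are recorded per fragment so callers can be
checked read-by-read against the generative process.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy.special import ndtri

from .core import AlignedFragment, BisulfiteStrand, Genome, MateRead, Peak
from . import io_formats

_BASES = np.array(list("ACGT"))


@dataclass
class SimulationConfig:
    """All knobs of the generator; defaults define the standard conditions.

    ``cometh_rho`` correlates the Bernoulli methylation draws of designated
    CpG pairs within one fragment through a Gaussian copula (marginals are
    preserved exactly); ``cometh_pairs`` lists the (pos_a, pos_b) pairs it
    applies to.
    """

    seed: int = 0
    genome_length: int = 200_000
    n_contigs: int = 1
    cpg_rate: float = 0.02
    n_peaks: int = 50
    peak_width_mean: float = 400.0
    peak_width_sd: float = 100.0
    mixture_weights: tuple[float, float, float] = (0.7, 0.2, 0.1)
    depth_in_peak: float = 60.0
    depth_background: float = 2.0
    fragment_length_mean: float = 180.0
    fragment_length_sd: float = 50.0
    fragment_length_min: int = 50
    fragment_length_max: int = 1000
    conversion_rate: float = 0.99
    failure_rate: float = 0.01
    sequencing_error: float = 0.001
    read_length: int = 50
    cometh_rho: float = 0.0
    cometh_pairs: tuple[tuple[int, int], ...] = ()
    duplication_rate: float = 0.0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if abs(sum(self.mixture_weights) - 1.0) > 1e-9:
            raise ValueError("mixture weights must sum to 1")
        if not (0.0 < self.conversion_rate <= 1.0):
            raise ValueError("conversion_rate must be in (0, 1]")
        if not (0.0 <= self.failure_rate < 1.0):
            raise ValueError("failure_rate must be in [0, 1)")
        if not (-1.0 < self.cometh_rho < 1.0):
            raise ValueError("cometh_rho must be in (-1, 1)")
        if self.fragment_length_min < self.read_length:
            raise ValueError("fragment_length_min must be >= read_length")
        if self.genome_length < 1000:
            raise ValueError("genome_length too small")

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        d["mixture_weights"] = list(self.mixture_weights)
        d["cometh_pairs"] = [list(p) for p in self.cometh_pairs]
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        if "mixture_weights" in d:
            d["mixture_weights"] = tuple(d["mixture_weights"])
        if "cometh_pairs" in d:
            d["cometh_pairs"] = tuple(tuple(p) for p in d["cometh_pairs"])
        return cls(**d)


@dataclass
class TruthTable:
    """Ground truth of one simulation.

    ``cpg`` has one row per CpG (class label and true beta);
    ``fragments`` one row per emitted fragment (coordinates, strand,
    origin peak or background); ``fragment_states`` maps fragment id to
    the per-CpG draws ``(pos0, state, observed)`` where ``observed`` marks
    draws whose informative base was actually sequenced by a mate.
    """

    cpg: pd.DataFrame
    fragments: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            columns=["fragment_id", "contig", "start", "end", "strand", "origin"]
        )
    )
    fragment_states: dict[str, list[tuple[int, int, bool]]] = field(
        default_factory=dict
    )

    def beta_at(self) -> dict[int, float]:
        return dict(zip(self.cpg["pos0"], self.cpg["true_beta"]))

    def write(self, outdir) -> None:
        outdir = Path(outdir)
        self.cpg.to_csv(outdir / "truth_cpg.tsv", sep="\t", index=False)
        frag = self.fragments.copy()
        frag["states"] = [
            ";".join(
                f"{p}:{s}:{int(o)}" for p, s, o in self.fragment_states.get(fid, [])
            )
            for fid in frag["fragment_id"]
        ]
        frag.to_csv(outdir / "truth_frag.tsv", sep="\t", index=False)


# ---------------------------------------------------------------------------
# genome + truth methylome


def _cpg_free_background(rng: np.random.Generator, length: int) -> np.ndarray:
    seq = rng.integers(0, 4, size=length)  # 0=A 1=C 2=G 3=T
    not_g = np.array([0, 1, 3])
    for i in range(1, length):
        if seq[i - 1] == 1 and seq[i] == 2:
            seq[i] = not_g[rng.integers(0, 3)]
    return seq


def _draw_class_betas(
    rng: np.random.Generator, classes: np.ndarray
) -> np.ndarray:
    """Per-class true betas: boundary-light laws emulating a bimodal bulk
    methylome (low class piled near 0, high near 1, intermediate centred)."""
    n = len(classes)
    betas = np.empty(n)
    low = classes == 0
    mid = classes == 1
    high = classes == 2
    eps = 1e-6
    betas[low] = np.minimum(0.2 * rng.beta(1.5, 6.0, size=low.sum()), 0.2 - eps)
    betas[mid] = 0.2 + 0.6 * rng.beta(2.0, 2.0, size=mid.sum())
    betas[high] = np.maximum(
        1.0 - 0.2 * rng.beta(1.5, 6.0, size=high.sum()), 0.8 + eps
    )
    return betas


def _place_peaks(
    rng: np.random.Generator, config: SimulationConfig, contig: str
) -> list[Peak]:
    L = config.genome_length
    widths = np.clip(
        rng.normal(config.peak_width_mean, config.peak_width_sd, config.n_peaks),
        150,
        None,
    ).astype(int)
    if widths.sum() > 0.8 * L:
        raise ValueError("infeasible peak packing: total width > 0.8 x genome")
    taken: list[tuple[int, int]] = []
    peaks: list[Peak] = []
    gap = 200  # keep peaks clearly separated
    for i, w in enumerate(widths):
        for _ in range(1000):
            start = int(rng.integers(0, L - w))
            if all(start >= e + gap or start + w + gap <= s for s, e in taken):
                taken.append((start, start + w))
                peaks.append(
                    Peak(
                        contig=contig,
                        start=start,
                        end=start + int(w),
                        name=f"peak_{i:03d}",
                        score=1000.0,
                        summit_offset=int(w) // 2,
                    )
                )
                break
        else:
            raise ValueError("could not place non-overlapping peaks")
    peaks.sort(key=lambda p: p.start)
    return peaks


def simulate_genome(
    config: SimulationConfig,
) -> tuple[Genome, list[Peak], TruthTable]:
    """Build the toy genome, peak set, and per-CpG truth methylome.

    The background sequence is generated CpG-free (any G following a C is
    resampled), then ``round(cpg_rate * length)`` CG dinucleotides are
    planted at random positions, so the realized CpG count tracks the
    target density.  Deterministic given ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    contig = "chrS"
    seq = _cpg_free_background(rng, config.genome_length)
    n_cpg = int(round(config.cpg_rate * config.genome_length))
    positions = np.sort(
        rng.choice(config.genome_length - 1, size=n_cpg, replace=False)
    )
    seq[positions] = 1  # C
    seq[positions + 1] = 2  # G
    genome = Genome(sequences={contig: "".join(_BASES[seq])})

    peaks = _place_peaks(rng, config, contig) if config.n_peaks > 0 else []

    cpgs = genome.cpg_index[contig]
    classes = rng.choice(3, size=len(cpgs), p=list(config.mixture_weights))
    betas = _draw_class_betas(rng, classes)
    truth = TruthTable(
        cpg=pd.DataFrame(
            {
                "contig": contig,
                "pos0": cpgs,
                "meth_class": np.array(["low", "intermediate", "high"])[classes],
                "true_beta": betas,
            }
        )
    )
    return genome, peaks, truth


# ---------------------------------------------------------------------------
# fragments + reads


def draw_pair_states(
    rng: np.random.Generator,
    beta_a: float,
    beta_b: float,
    rho: float,
    size: int = 1,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw correlated Bernoulli methylation states for a CpG pair.

    Gaussian copula: latent standard normals with correlation ``rho`` are
    thresholded at each CpG's quantile, so the marginal methylation rates
    are exactly ``beta_a`` and ``beta_b`` for any ``rho``.
    """
    z1 = rng.standard_normal(size)
    z2 = rho * z1 + np.sqrt(1.0 - rho * rho) * rng.standard_normal(size)
    s1 = (z1 < ndtri(beta_a)).astype(np.int64) if 0 < beta_a < 1 else np.full(size, int(beta_a >= 1))
    s2 = (z2 < ndtri(beta_b)).astype(np.int64) if 0 < beta_b < 1 else np.full(size, int(beta_b >= 1))
    return s1, s2


def _informative_cpgs(
    genome: Genome, contig: str, start: int, end: int, strand: BisulfiteStrand
) -> np.ndarray:
    """CpGs whose informative base lies within the fragment span."""
    if strand == BisulfiteStrand.OT:
        return genome.cpgs_in(contig, start, end)
    # OB reads the G at pos0+1, so CpGs with start <= pos0+1 < end qualify
    return genome.cpgs_in(contig, start - 1, end - 1)


def _convert_sequence(
    rng: np.random.Generator,
    ref: str,
    frag_start: int,
    strand: BisulfiteStrand,
    states: dict[int, int],
    config: SimulationConfig,
) -> str:
    out = list(ref)
    if strand == BisulfiteStrand.OT:
        for i, base in enumerate(ref):
            if base != "C":
                continue
            pos = frag_start + i
            s = states.get(pos)
            if s is None:  # non-CpG cytosine: always converted
                out[i] = "T"
            elif s == 1:
                out[i] = "T" if rng.random() < config.failure_rate else "C"
            else:
                out[i] = "T" if rng.random() < config.conversion_rate else "C"
    else:
        for i, base in enumerate(ref):
            if base != "G":
                continue
            pos = frag_start + i
            s = states.get(pos - 1)  # CpG addressed by its forward C
            if s is None:
                out[i] = "A"
            elif s == 1:
                out[i] = "A" if rng.random() < config.failure_rate else "G"
            else:
                out[i] = "A" if rng.random() < config.conversion_rate else "G"
    return "".join(out)


def _apply_sequencing_error(
    rng: np.random.Generator, seq: str, rate: float
) -> str:
    if rate <= 0:
        return seq
    arr = list(seq)
    hits = np.nonzero(rng.random(len(arr)) < rate)[0]
    for i in hits:
        choices = [b for b in "ACGT" if b != arr[i]]
        arr[i] = choices[rng.integers(0, 3)]
    return "".join(arr)


def _fragment_coords(
    rng: np.random.Generator,
    config: SimulationConfig,
    region_start: int,
    region_end: int,
    L: int,
    anchored: bool,
) -> tuple[int, int]:
    flen = int(
        np.clip(
            rng.normal(config.fragment_length_mean, config.fragment_length_sd),
            config.fragment_length_min,
            config.fragment_length_max,
        )
    )
    if anchored:
        lo = region_start - flen + 1
        hi = region_end - 1
        start = int(rng.integers(lo, hi + 1))
    else:
        start = int(rng.integers(0, max(1, L - flen)))
    start = max(0, min(start, L - flen))
    return start, start + flen


def simulate_reads(
    config: SimulationConfig,
    genome: Genome,
    peaks: Sequence[Peak],
    truth: TruthTable,
    rng: Optional[np.random.Generator] = None,
) -> tuple[list[AlignedFragment], TruthTable]:
    """Sample aligned fragments at ``depth_in_peak`` over peaks and
    ``depth_background`` elsewhere, and synthesize their bisulfite reads.

    Fragment starts for a peak are uniform over a window padded by the
    fragment length, which makes the expected coverage flat across the
    whole peak.  Per covered CpG one Bernoulli(true beta) state is drawn
    per fragment (jointly, through the copula, for designated
    co-methylation pairs); states are recorded in the truth table with an
    ``observed`` flag marking those whose informative base falls inside a
    sequenced mate.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    contig = next(iter(genome.sequences))
    L = len(genome.sequences[contig])
    beta_at = truth.beta_at()
    pair_of: dict[int, int] = {}
    for a, b in config.cometh_pairs:
        pair_of[a] = b
    rl = config.read_length

    plan: list[tuple[str, bool, int, int]] = []  # origin, anchored, rstart, rend
    fl = config.fragment_length_mean
    # depth targets sequenced-base coverage: each fragment only reads
    # min(2 * read_length, fragment_length) of its span
    seq_bp = min(2.0 * rl, fl)
    for peak in peaks:
        n = int(round(config.depth_in_peak * (peak.width + fl - 1) / seq_bp))
        plan.extend([(peak.name, True, peak.start, peak.end)] * n)
    n_bg = int(round(config.depth_background * L / seq_bp))
    plan.extend([("background", False, 0, L)] * n_bg)

    fragments: list[AlignedFragment] = []
    frag_rows = []
    states_map: dict[str, list[tuple[int, int, bool]]] = {}
    quals = np.full(rl, 40, dtype=np.int64)

    for idx, (origin, anchored, rstart, rend) in enumerate(plan):
        start, end = _fragment_coords(rng, config, rstart, rend, L, anchored)
        strand = (
            BisulfiteStrand.OT if rng.random() < 0.5 else BisulfiteStrand.OB
        )
        fid = f"frag{idx:07d}"
        cpgs = _informative_cpgs(genome, contig, start, end, strand)

        states: dict[int, int] = {}
        done: set[int] = set()
        for pos in cpgs:
            pos = int(pos)
            if pos in done:
                continue
            mate_pos = pair_of.get(pos)
            if (
                mate_pos is not None
                and config.cometh_rho != 0.0
                and mate_pos in set(int(p) for p in cpgs)
            ):
                s1, s2 = draw_pair_states(
                    rng, beta_at[pos], beta_at[mate_pos], config.cometh_rho
                )
                states[pos] = int(s1[0])
                states[mate_pos] = int(s2[0])
                done.update((pos, mate_pos))
            else:
                states[pos] = int(rng.random() < beta_at[pos])
                done.add(pos)

        # chemistry on the forward-strand reference, then slice the mates
        ref = genome.sequences[contig][start:end]
        conv = _convert_sequence(rng, ref, start, strand, states, config)
        seq1 = _apply_sequencing_error(rng, conv[:rl], config.sequencing_error)
        seq2 = _apply_sequencing_error(rng, conv[-rl:], config.sequencing_error)
        if strand == BisulfiteStrand.OT:
            mates = (
                MateRead(seq=seq1, quals=quals, ref_start=start, is_read1=True),
                MateRead(seq=seq2, quals=quals, ref_start=end - rl, is_read1=False),
            )
        else:
            mates = (
                MateRead(seq=seq2, quals=quals, ref_start=end - rl, is_read1=True),
                MateRead(seq=seq1, quals=quals, ref_start=start, is_read1=False),
            )
        fragments.append(
            AlignedFragment(
                query_name=fid,
                contig=contig,
                start=start,
                end=end,
                bisulfite_strand=strand,
                mapq=40,
                mates=mates,
            )
        )
        recorded = []
        for pos, s in sorted(states.items()):
            info = pos if strand == BisulfiteStrand.OT else pos + 1
            observed = any(m.ref_start <= info < m.ref_end for m in mates)
            recorded.append((pos, s, observed))
        states_map[fid] = recorded
        frag_rows.append(
            {
                "fragment_id": fid,
                "contig": contig,
                "start": start,
                "end": end,
                "strand": strand.value,
                "origin": origin,
            }
        )

    if config.duplication_rate > 0:
        n0 = len(fragments)
        for i in range(n0):
            if rng.random() < config.duplication_rate:
                src = fragments[i]
                dup_id = src.query_name + "_dup"
                fragments.append(dataclasses.replace(src, query_name=dup_id))
                states_map[dup_id] = states_map[src.query_name]
                row = dict(frag_rows[i])
                row["fragment_id"] = dup_id
                frag_rows.append(row)

    truth.fragments = pd.DataFrame(
        frag_rows,
        columns=["fragment_id", "contig", "start", "end", "strand", "origin"],
    )
    truth.fragment_states = states_map
    return fragments, truth


def simulate_dataset(
    config: SimulationConfig,
) -> tuple[Genome, list[Peak], list[AlignedFragment], TruthTable]:
    """Convenience wrapper: genome + peaks + reads in one call."""
    genome, peaks, truth = simulate_genome(config)
    fragments, truth = simulate_reads(config, genome, peaks, truth)
    return genome, peaks, fragments, truth


def write_dataset(
    outdir,
    genome: Genome,
    peaks: Sequence[Peak],
    fragments: Sequence[AlignedFragment],
    truth: TruthTable,
    config: Optional[SimulationConfig] = None,
) -> None:
    """Write ref.fa, peaks.narrowPeak, reads.sam and the truth TSVs."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    io_formats.write_fasta(outdir / "ref.fa", genome)
    io_formats.write_narrowpeak(outdir / "peaks.narrowPeak", peaks)
    io_formats.write_sam(
        outdir / "reads.sam",
        fragments,
        {n: len(s) for n, s in genome.sequences.items()},
    )
    truth.write(outdir)
    if config is not None:
        config.to_yaml(outdir / "config.yaml")
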