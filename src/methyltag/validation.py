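"""End-to-end validation experiments on synthetic data.

Each function simulates (or constructs) its inputs, runs the relevant part
of the pipeline, and returns measured quantities — recovery of the truth
methylome by the caller, calibration of the co-methylation test, accuracy
of the cluster-membership probability, and exact agreement of the motif
scanner with brute-force enumeration.  They are the backing computations
for the acceptance checks and for reproducing the package's headline
numbers from scratch.
"""

from __future__ import annotations

from collections import defaultdict

import numpy as np

from . import methylcall, motifs, peaks as peaks_mod
from .core import CpGSite, Genome, Peak
from .groups import (
    GROUP_BOUNDS,
    cluster_membership_probability,
    group_counts,
    group_summary,
)
from .simulate import SimulationConfig, draw_pair_states, simulate_dataset


# ---------------------------------------------------------------------------
# caller recovery


def _called_sites(cfg: SimulationConfig):
    genome, peaks, fragments, truth = simulate_dataset(cfg)
    calls = methylcall.call_fragments(fragments, genome)
    sites = methylcall.aggregate_sites(calls, contig="chrS")
    return genome, peaks, fragments, truth, sites


def noise_free_recovery(seed: int) -> dict:
    """Noise-free chemistry at the standard scale: per-CpG counts must
    equal the truth draws exactly at every covered CpG."""
    cfg = SimulationConfig(
        seed=seed,
        conversion_rate=1.0,
        failure_rate=0.0,
        sequencing_error=0.0,
    )
    genome, peaks, fragments, truth, sites = _called_sites(cfg)
    truth_counts: dict[int, list[int]] = defaultdict(lambda: [0, 0])
    for f in fragments:
        for pos, state, observed in truth.fragment_states[f.query_name]:
            if observed:
                truth_counts[pos][state] += 1
    n_exact = sum(
        (s.count_meth, s.count_unmeth)
        == (truth_counts[s.pos0][1], truth_counts[s.pos0][0])
        for s in sites
    )
    return {
        "n_sites": len(sites),
        "n_exact": n_exact,
        "exact_fraction": n_exact / len(sites) if sites else float("nan"),
    }


def noisy_recovery(
    seed: int, min_coverage: int = 20, n_replicates: int = 12
) -> dict:
    """Default noise levels: RMSE of estimated vs true beta over CpGs with
    at least ``min_coverage`` reads, against the binomial sampling floor
    sqrt(mean b(1-b)/cov) (RMS-aggregated, the scale an RMSE lives on).

    The RMSE is pooled over ``n_replicates`` independent simulations at
    identical default conditions: a single run yields only ~700 qualifying
    CpGs and the squared-error mean is chi-square heavy-tailed, so pooling
    is needed for the ratio to be measured to ~0.02.
    """
    err2, var = [], []
    for rep in range(n_replicates):
        cfg = SimulationConfig(seed=seed + 1000 * rep)
        genome, peaks, fragments, truth, sites = _called_sites(cfg)
        beta_true = truth.beta_at()
        for s in sites:
            if s.coverage >= min_coverage:
                b = beta_true[s.pos0]
                err2.append((s.beta - b) ** 2)
                var.append(b * (1.0 - b) / s.coverage)
    rmse = float(np.sqrt(np.mean(err2)))
    floor = float(np.sqrt(np.mean(var)))
    return {
        "n_sites": len(err2),
        "n_replicates": n_replicates,
        "rmse": rmse,
        "binomial_floor": floor,
        "ratio": rmse / floor,
    }


def mean_peak_coverage(seed: int) -> dict:
    """Realized sequenced-base coverage over peak CpGs vs the depth target."""
    cfg = SimulationConfig(seed=seed)
    genome, peaks, fragments, truth, sites = _called_sites(cfg)
    filt = methylcall.filter_sites(sites, peaks, min_coverage=1)
    cov = float(np.mean([s.coverage for s in filt]))
    return {
        "mean_coverage": cov,
        "target": cfg.depth_in_peak + cfg.depth_background,
        "n_sites": len(filt),
    }


# ---------------------------------------------------------------------------
# site filter semantics


def filter_fixture_sites() -> tuple[list[CpGSite], list[Peak]]:
    """20 hand-built sites probing the coverage cut and the half-open peak
    boundaries against one peak at [100, 200)."""
    sites = []
    for i, cov in enumerate(range(1, 11)):
        meth = cov // 2
        sites.append(CpGSite("c1", 110 + 2 * i, meth, cov - meth))
    sites += [
        CpGSite("c1", 100, 5, 0),  # first base inside
        CpGSite("c1", 199, 0, 5),  # last base inside
        CpGSite("c1", 200, 5, 5),  # peak.end -> outside
        CpGSite("c1", 99, 5, 5),  # just before the peak
        CpGSite("c1", 500, 25, 25),
        CpGSite("c1", 600, 50, 0),
        CpGSite("c2", 150, 5, 5),
        CpGSite("c1", 130, 2, 2),
        CpGSite("c1", 132, 1, 2),
        CpGSite("c1", 134, 0, 4),
    ]
    return sites, [Peak("c1", 100, 200, "p1")]


def filter_semantics() -> dict:
    sites, peaks = filter_fixture_sites()
    kept = methylcall.filter_sites(sites, peaks, min_coverage=5)
    expected = {
        (s.contig, s.pos0)
        for s in sites
        if s.contig == "c1" and 100 <= s.pos0 < 200 and s.coverage >= 5
    }
    got = {(s.contig, s.pos0) for s in kept}
    return {
        "n_input": len(sites),
        "n_retained": len(kept),
        "n_expected": len(expected),
        "exact_match": got == expected,
    }


# ---------------------------------------------------------------------------
# grouping recovery


def grouping_recovery(seed: int) -> dict:
    """Simulate at ~30x peak depth so grouped sites fall in the 5-50 read
    band, then compare estimated low/intermediate/high label proportions
    with the generating mixture weights (z-scores under multinomial SD)."""
    cfg = SimulationConfig(seed=seed, depth_in_peak=30.0)
    genome, peaks, fragments, truth, sites = _called_sites(cfg)
    filt = methylcall.filter_sites(sites, peaks, min_coverage=5)
    summary = group_summary(filt)
    counts = dict(zip(*[group_counts(summary)[c] for c in ("label", "n")]))
    grouped = counts["G1"] + counts["G2"] + counts["G3"] + counts["G4"]
    props = {
        "low": (counts["G1"] + counts["G2"]) / grouped,
        "intermediate": counts["G3"] / grouped,
        "high": counts["G4"] / grouped,
    }
    weights = dict(zip(("low", "intermediate", "high"), cfg.mixture_weights))
    zmax = max(
        abs(props[k] - weights[k])
        / np.sqrt(weights[k] * (1 - weights[k]) / grouped)
        for k in props
    )
    med_prob = float(summary["membership_probability"].dropna().median())
    return {
        "n_grouped": grouped,
        "proportions": props,
        "weights": weights,
        "max_abs_z": float(zmax),
        "median_membership_probability": med_prob,
    }


# ---------------------------------------------------------------------------
# cluster probability accuracy


def cluster_probability_accuracy(seed: int) -> dict:
    """Max |error| of the erf-based probability against a high-precision
    normal CDF on a (b, n, bounds) grid, and against exact 1e5-draw
    binomial resampling at cells where the normal model is applicable."""
    import mpmath

    mpmath.mp.dps = 30
    worst_cdf = 0.0
    for b in np.linspace(0.01, 0.99, 25):
        for n in (2, 5, 10, 50, 200, 1000):
            s = float(np.sqrt(b * (1 - b) / (n - 1)))
            for lo, hi in set(GROUP_BOUNDS.values()):
                got = cluster_membership_probability(float(b), n, lo, hi)
                want = float(
                    mpmath.ncdf((hi - b) / s) - mpmath.ncdf((lo - b) / s)
                )
                worst_cdf = max(worst_cdf, abs(got - want))

    rng = np.random.default_rng(seed)
    cells = [
        (0.5, 10, 0.15, 0.85),
        (0.4, 10, 0.1, 0.9),
        (0.1, 50, 0.0, 0.2),
        (0.5, 50, 0.2, 0.8),
        (0.9, 50, 0.8, 1.0),
        (0.1, 200, 0.0, 0.2),
        (0.5, 200, 0.2, 0.8),
        (0.9, 200, 0.8, 1.0),
    ]
    worst_mc = 0.0
    for b, n, lo, hi in cells:
        draws = rng.binomial(n - 1, b, size=100_000) / (n - 1)
        emp = float(np.mean((draws >= lo) & (draws < hi)))
        got = cluster_membership_probability(b, n, lo, hi)
        worst_mc = max(worst_mc, abs(got - emp))
    return {"max_abs_error_cdf": worst_cdf, "max_abs_error_mc": worst_mc}


# ---------------------------------------------------------------------------
# scanner vs enumeration


_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}
_IDX = {"A": 0, "C": 1, "G": 2, "T": 3}


def _brute_force_hits(seq: str, matrix: motifs.MotifMatrix, threshold: float):
    lodds = matrix.log_odds
    W = matrix.width
    out = []
    for i in range(len(seq) - W + 1):
        win = seq[i : i + W]
        if any(c not in "ACGT" for c in win):
            continue
        rc = "".join(_COMP[c] for c in reversed(win))
        for strand, s in (("+", win), ("-", rc)):
            score = sum(lodds[_IDX[c], k] for k, c in enumerate(s))
            if score >= threshold:
                out.append((i, strand, round(score, 9)))
    return sorted(out)


def scanner_validation(seed: int, n_seeds: int = 20, seq_len: int = 2000) -> dict:
    """Exact agreement of the vectorized scanner with exhaustive window
    enumeration for random motifs of width 2-6 over random sequences, plus
    the strand-consistency check against a reverse-complemented genome."""
    import itertools

    agree = 0
    strand_ok = 0
    threshold_ok = 0
    for rep in range(n_seeds):
        rng = np.random.default_rng(seed + rep)
        width = 2 + rep % 5
        seq = "".join(rng.choice(list("ACGT"), size=seq_len))
        matrix = motifs.pwm_from_counts(
            rng.integers(0, 20, size=(4, width)), pseudocount=1
        )
        t = motifs.pwm_score_threshold(matrix, pvalue=1e-3)
        genome = Genome.from_sequences({"c1": seq})
        hits = motifs.scan_motifs(genome, None, matrix, t, annotate_cpgs=True)
        got = sorted((h.start0, h.strand, round(h.score, 9)) for h in hits)
        if got == _brute_force_hits(seq, matrix, t):
            agree += 1

        # exact tail by enumerating all 4^W words
        tail = 0.0
        for word in itertools.product(range(4), repeat=width):
            score = sum(matrix.log_odds[b, k] for k, b in enumerate(word))
            if score >= t + 0.01 * width:
                tail += float(np.prod([matrix.background[b] for b in word]))
        if tail <= 1e-3 + 1e-12:
            threshold_ok += 1

        rc_seq = "".join(_COMP[c] for c in reversed(seq))
        rc_genome = Genome.from_sequences({"c1": rc_seq})
        rc_hits = motifs.scan_motifs(rc_genome, None, matrix, t)
        minus_coords = {
            c for h in hits if h.strand == "-" for _, c in h.cpg_offsets
        }
        mapped = {
            seq_len - 2 - c
            for h in rc_hits
            if h.strand == "+"
            for _, c in h.cpg_offsets
        }
        if minus_coords == mapped:
            strand_ok += 1
    return {
        "n_seeds": n_seeds,
        "scanner_agreement_fraction": agree / n_seeds,
        "threshold_bound_fraction": threshold_ok / n_seeds,
        "strand_consistency_fraction": strand_ok / n_seeds,
    }


# ---------------------------------------------------------------------------
# co-methylation calibration


def comethylation_calibration(
    seed: int,
    n_replicates: int = 500,
    n_pairs: int = 600,
    beta_a: float = 0.3,
    beta_b: float = 0.4,
    alpha: float = 0.05,
) -> dict:
    """Calibration of the 2x2 independence chi-square on the generator's
    own pair-draw model: null rejection rate at rho=0, and the fraction of
    rho=0.3 replicates with observed > expected joint methylation."""
    rng = np.random.default_rng(seed)
    rejections = 0
    for _ in range(n_replicates):
        s1, s2 = draw_pair_states(rng, beta_a, beta_b, rho=0.0, size=n_pairs)
        t = _table_from_states(s1, s2)
        if t.pvalue is not None and t.pvalue < alpha:
            rejections += 1
    excess = 0
    for _ in range(n_replicates):
        s1, s2 = draw_pair_states(rng, beta_a, beta_b, rho=0.3, size=n_pairs)
        t = _table_from_states(s1, s2)
        if t.observed_mm_fraction > t.expected_mm_fraction:
            excess += 1
    hand = motifs.comethylation_table(mm=10, mu=10, um=10, uu=70)
    return {
        "null_rejection_rate": rejections / n_replicates,
        "alpha": alpha,
        "binomial_sd": float(
            np.sqrt(alpha * (1 - alpha) / n_replicates)
        ),
        "rho_excess_fraction": excess / n_replicates,
        "hand_table_chi_square": hand.chi_square,
    }


def _table_from_states(s1: np.ndarray, s2: np.ndarray) -> motifs.ComethTable:
    mm = int(np.sum((s1 == 1) & (s2 == 1)))
    mu = int(np.sum((s1 == 1) & (s2 == 0)))
    um = int(np.sum((s1 == 0) & (s2 == 1)))
    uu = int(np.sum((s1 == 0) & (s2 == 0)))
    return motifs.comethylation_table(mm, mu, um, uu)


# ---------------------------------------------------------------------------
# QC arithmetic


def qc_validation() -> dict:
    """Worked-arithmetic QC checks: Jaccard of [0,100) vs [50,150),
    quadrants of a table against itself, and self-correlation of binned
    fragment counts."""
    jac = peaks_mod.interval_jaccard(
        [Peak("c1", 0, 100)], [Peak("c1", 50, 150)]
    )
    table = {"a": 0.1, "b": 0.9, "c": 0.4, "d": 0.6}
    counts, _ = peaks_mod.quadrant_counts(table, table)
    off_diag = counts["top-left"] + counts["bottom-right"]

    from .core import AlignedFragment, BisulfiteStrand, MateRead

    def frag(mid, name):
        quals = np.full(10, 40, dtype=np.int64)
        mate = MateRead(seq="A" * 10, quals=quals, ref_start=mid - 5, is_read1=True)
        return AlignedFragment(
            query_name=name, contig="c1", start=mid - 5, end=mid + 5,
            bisulfite_strand=BisulfiteStrand.OT, mapq=40, mates=(mate,),
        )

    frags = [frag(500, "a"), frag(1500, "b"), frag(1500, "c"), frag(2500, "d")]
    r_self = peaks_mod.binned_pearson(frags, frags, {"c1": 3000}, bin_size=1000)
    return {
        "jaccard_worked_example": jac,
        "quadrant_self_off_diagonal": off_diag,
        "binned_pearson_self": r_self,
    }
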