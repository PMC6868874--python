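import itertools

import numpy as np
import pytest

from methyltag import motifs
from methyltag.core import Genome, MethState, Peak, ReadMethCall, CpGSite

BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}
COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def revcomp(seq: str) -> str:
    return "".join(COMP[c] for c in reversed(seq))


def random_matrix(rng, width):
    counts = rng.integers(0, 20, size=(4, width))
    return motifs.pwm_from_counts(counts, pseudocount=1)


def brute_force_hits(seq, matrix, threshold):
    """Exhaustive window enumeration on both strands (oracle)."""
    lodds = matrix.log_odds
    W = matrix.width
    out = []
    for i in range(len(seq) - W + 1):
        win = seq[i : i + W]
        if any(c not in "ACGT" for c in win):
            continue
        for strand, s in (("+", win), ("-", revcomp(win))):
            score = sum(lodds[BASE_INDEX[c], k] for k, c in enumerate(s))
            if score >= threshold:
                out.append((i, strand, round(score, 9)))
    return sorted(out)


def exact_tail(matrix, threshold):
    """P(score >= threshold) under the background by full enumeration."""
    lodds = matrix.log_odds
    bg = matrix.background
    total = 0.0
    for word in itertools.product(range(4), repeat=matrix.width):
        score = sum(lodds[b, k] for k, b in enumerate(word))
        if score >= threshold:
            total += float(np.prod([bg[b] for b in word]))
    return total


class TestPwmFromCounts:
    def test_pseudocount_normalization(self):
        m = motifs.pwm_from_counts(np.array([[8], [0], [0], [0]]), pseudocount=1)
        assert np.allclose(m.probs[:, 0], [9 / 12, 1 / 12, 1 / 12, 1 / 12])

    def test_uniform_counts_column(self):
        m = motifs.pwm_from_counts(np.full((4, 1), 3), pseudocount=1)
        assert np.allclose(m.probs[:, 0], 0.25)

    def test_zero_pseudocount_with_zero_count_raises(self):
        with pytest.raises(ValueError):
            motifs.pwm_from_counts(np.array([[8], [0], [0], [0]]), pseudocount=0)

    def test_negative_counts_raise(self):
        with pytest.raises(ValueError):
            motifs.pwm_from_counts(np.array([[-1], [1], [1], [1]]))

    def test_jaspar_pfm_dialects(self, tmp_path):
        plain = tmp_path / "plain.pfm"
        plain.write_text(">M1 test\n1 2\n3 4\n5 6\n7 8\n")
        bracket = tmp_path / "bracket.pfm"
        bracket.write_text(
            ">M1 test\nA [ 1 2 ]\nC [ 3 4 ]\nG [ 5 6 ]\nT [ 7 8 ]\n"
        )
        m1 = motifs.read_jaspar_pfm(plain)
        m2 = motifs.read_jaspar_pfm(bracket)
        assert np.allclose(m1.probs, m2.probs)
        assert m1.width == 2


class TestScoreThreshold:
    def test_width_one_quantile(self):
        # pvalue 0.25 under uniform background admits exactly the best base
        m = motifs.pwm_from_counts(np.array([[17], [1], [1], [1]]), pseudocount=0.0001)
        t = motifs.pwm_score_threshold(m, pvalue=0.25)
        scores = sorted(m.log_odds[:, 0], reverse=True)
        assert scores[0] >= t - 0.011
        assert all(s < t for s in scores[1:])

    def test_pvalue_one_admits_everything(self):
        rng = np.random.default_rng(0)
        m = random_matrix(rng, 2)
        t = motifs.pwm_score_threshold(m, pvalue=1.0)
        min_score = min(
            sum(m.log_odds[b, k] for k, b in enumerate(word))
            for word in itertools.product(range(4), repeat=2)
        )
        assert t <= min_score + 0.011

    def test_tail_probability_non_increasing(self):
        rng = np.random.default_rng(1)
        m = random_matrix(rng, 4)
        scores, probs = motifs.score_distribution(m)
        tail = np.cumsum(probs[::-1])[::-1]
        assert np.all(np.diff(tail) <= 1e-12)

    @pytest.mark.parametrize("width", [2, 3, 4, 5, 6])
    def test_dp_matches_enumeration(self, width):
        rng = np.random.default_rng(width)
        m = random_matrix(rng, width)
        for pvalue in (0.5, 0.1, 0.01):
            t = motifs.pwm_score_threshold(m, pvalue=pvalue)
            # the exact tail at the DP threshold must satisfy the bound up
            # to one grid bin of score
            assert exact_tail(m, t + 0.01 * width) <= pvalue + 1e-9

    def test_invalid_pvalue_raises(self):
        m = random_matrix(np.random.default_rng(2), 3)
        with pytest.raises(ValueError):
            motifs.pwm_score_threshold(m, pvalue=0.0)


class TestScanMotifs:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_exhaustive_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        seq = "".join(rng.choice(list("ACGT"), size=500))
        genome = Genome.from_sequences({"c1": seq})
        for width in (3, 6, 9):
            m = random_matrix(rng, width)
            t = motifs.pwm_score_threshold(m, pvalue=0.05)
            hits = motifs.scan_motifs(genome, None, m, t, annotate_cpgs=False)
            got = sorted((h.start0, h.strand, round(h.score, 9)) for h in hits)
            assert got == brute_force_hits(seq, m, t)

    def test_near_consensus_palindromic_acgt(self):
        counts = np.zeros((4, 4))
        for k, base in enumerate("ACGT"):
            counts[:, k] = 1
            counts[BASE_INDEX[base], k] = 97
        m = motifs.pwm_from_counts(counts, pseudocount=0.0001)
        genome = Genome.from_sequences({"c1": "TTTTTACGTTTTT"})
        # the single consensus word has background probability 1/256, so
        # the p-value must admit at least that much tail
        t = motifs.pwm_score_threshold(m, pvalue=1 / 256)
        hits = motifs.scan_motifs(genome, None, m, t)
        # ACGT is its own reverse complement: one + and one - hit, same locus
        assert [(h.start0, h.strand) for h in hits] == [(5, "+"), (5, "-")]

    def test_all_n_sequence_has_no_hits(self):
        genome = Genome.from_sequences({"c1": "N" * 100})
        m = random_matrix(np.random.default_rng(3), 4)
        assert motifs.scan_motifs(genome, None, m, -100.0) == []

    def test_region_shorter_than_motif_is_empty(self):
        genome = Genome.from_sequences({"c1": "ACGTACGT"})
        m = random_matrix(np.random.default_rng(4), 6)
        hits = motifs.scan_motifs(
            genome, [Peak("c1", 0, 4, "tiny")], m, -100.0
        )
        assert hits == []

    def test_minus_strand_coords_match_revcomp_scan(self):
        """Forward CpG coordinates recovered from minus hits equal those
        from scanning the reverse-complemented genome with the forward
        matrix."""
        rng = np.random.default_rng(5)
        seq = "".join(rng.choice(list("ACGT"), size=400))
        L = len(seq)
        genome = Genome.from_sequences({"c1": seq})
        rc_genome = Genome.from_sequences({"c1": revcomp(seq)})
        m = random_matrix(rng, 5)
        W = m.width
        t = motifs.pwm_score_threshold(m, pvalue=0.02)
        minus = [
            h for h in motifs.scan_motifs(genome, None, m, t) if h.strand == "-"
        ]
        rc_plus = [
            h
            for h in motifs.scan_motifs(rc_genome, None, m, t)
            if h.strand == "+"
        ]
        got = {
            (h.start0, frozenset(c for _, c in h.cpg_offsets)) for h in minus
        }
        mapped = {
            (
                L - h.start0 - W,
                frozenset(L - 2 - c for _, c in h.cpg_offsets),
            )
            for h in rc_plus
        }
        assert got == mapped


class TestHitCpgOffsets:
    GENOME = Genome.from_sequences({"c1": "AAACGTTT"})  # CpG C at pos 3

    def test_plus_hit_offset(self):
        hit = motifs.MotifHit("c1", 1, "+", 0.0, width=6)
        assert motifs.hit_cpg_offsets(hit, self.GENOME) == [(3, 3)]

    def test_minus_hit_same_coordinate_mirrored_offset(self):
        hit = motifs.MotifHit("c1", 1, "-", 0.0, width=6)
        # offset = W - k_forward = 6 - 3 = 3 here (palindromic center)
        assert motifs.hit_cpg_offsets(hit, self.GENOME) == [(3, 3)]

    def test_minus_offset_by_reverse_complement_enumeration(self):
        # CpG C at pos 2 of CCGTTT; on the minus strand (AAACGG read 5'->3')
        # the CpG C appears at motif position W - k = 6 - 2 = 4
        genome = Genome.from_sequences({"c1": "CCGTTT"})
        plus = motifs.hit_cpg_offsets(
            motifs.MotifHit("c1", 0, "+", 0.0, width=6), genome
        )
        minus = motifs.hit_cpg_offsets(
            motifs.MotifHit("c1", 0, "-", 0.0, width=6), genome
        )
        assert plus == [(2, 1)]
        assert minus == [(4, 1)]
        rc = revcomp(genome.sequences["c1"])
        assert rc[4 - 1 : 4 + 1] == "CG"  # 1-based offset 4 on minus strand

    def test_hit_without_cpg_is_empty(self):
        genome = Genome.from_sequences({"c1": "ATATATAT"})
        hit = motifs.MotifHit("c1", 0, "+", 0.0, width=6)
        assert motifs.hit_cpg_offsets(hit, genome) == []

    def test_cpg_split_by_motif_edge_not_reported(self):
        # CpG whose G falls outside the motif window is not an offset
        genome = Genome.from_sequences({"c1": "AAAACG"})
        hit = motifs.MotifHit("c1", 0, "+", 0.0, width=5)
        assert motifs.hit_cpg_offsets(hit, genome) == []


def make_hit(coords: dict[int, int], width=19, score=10.0, strand="+"):
    h = motifs.MotifHit("c1", 0, strand, score, width=width)
    h.cpg_offsets = sorted(coords.items())
    return h


def make_sites(betas: dict[int, float], cov=10):
    return [
        CpGSite("c1", pos, round(b * cov), cov - round(b * cov))
        for pos, b in betas.items()
    ]


class TestPositionMethylation:
    def test_extreme_separation(self):
        hits = [make_hit({2: 100 + i, 12: 200 + i}) for i in range(3)]
        betas = {100 + i: 0.0 for i in range(3)}
        betas.update({200 + i: 1.0 for i in range(3)})
        res = motifs.position_methylation(hits, make_sites(betas))
        assert res["medians"][2] == 0.0
        assert res["medians"][12] == 1.0
        assert res["comparisons"][(2, 12)]["U"] == 0.0

    def test_identical_vectors_near_null(self):
        hits = [make_hit({2: 100 + i, 12: 200 + i}) for i in range(4)]
        betas = {100 + i: 0.5 for i in range(4)}
        betas.update({200 + i: 0.5 for i in range(4)})
        res = motifs.position_methylation(hits, make_sites(betas))
        # U at its null mean n1*n2/2
        assert res["comparisons"][(2, 12)]["U"] == pytest.approx(8.0)

    def test_statistic_matches_hand_ranks(self):
        # {0.1,0.2,0.3} vs {0.2,0.3,0.4}: U = #(x>y) + 0.5 #(x==y) = 2
        hits = [make_hit({2: 100 + i, 12: 200 + i}) for i in range(3)]
        betas = dict(zip([100, 101, 102], [0.1, 0.2, 0.3]))
        betas.update(dict(zip([200, 201, 202], [0.2, 0.3, 0.4])))
        res = motifs.position_methylation(hits, make_sites(betas))
        assert res["comparisons"][(2, 12)]["U"] == pytest.approx(2.0)

    def test_missing_offset_skips_comparison(self):
        hits = [make_hit({2: 100})]
        res = motifs.position_methylation(hits, make_sites({100: 0.5}))
        assert len(res["betas"][12]) == 0
        assert res["comparisons"] == {}

    def test_unique_cpg_collapses_to_best_hit(self):
        strong = make_hit({2: 100}, score=20.0)
        weak = make_hit({2: 100}, score=5.0)
        res = motifs.position_methylation(
            [strong, weak], make_sites({100: 0.5}), unique_cpg=True
        )
        assert len(res["betas"][2]) == 1

    def test_paired_rank_test_identical_is_null(self):
        res = motifs.paired_rank_test([0.1, 0.2], [0.1, 0.2])
        assert res["pvalue"] == 1.0


def read_call(fid, state_a, state_b, pos_a=10, pos_b=20):
    return ReadMethCall(
        fragment_id=fid, calls=[(pos_a, state_a), (pos_b, state_b)]
    )


class TestComethylation:
    def test_hand_computed_chi_square(self):
        t = motifs.comethylation_table(mm=10, mu=10, um=10, uu=70)
        assert t.chi_square == pytest.approx(14.0625)
        assert t.expected_mm_fraction == pytest.approx(0.04)
        assert t.observed_mm_fraction == pytest.approx(0.10)

    def test_independent_table_is_zero(self):
        t = motifs.comethylation_table(mm=4, mu=16, um=16, uu=64)
        assert t.chi_square == pytest.approx(0.0)

    def test_degenerate_marginal_undefined(self):
        t = motifs.comethylation_table(mm=50, mu=0, um=0, uu=0)
        assert t.chi_square is None

    def test_counted_from_read_calls(self):
        M, U, X = MethState.METH, MethState.UNMETH, MethState.AMBIG
        calls = (
            [read_call(f"mm{i}", M, M) for i in range(10)]
            + [read_call(f"mu{i}", M, U) for i in range(10)]
            + [read_call(f"um{i}", U, M) for i in range(10)]
            + [read_call(f"uu{i}", U, U) for i in range(70)]
            + [read_call("amb", X, M)]  # ambiguous at one CpG: not counted
            + [ReadMethCall("partial", [(10, M)])]  # covers only one CpG
        )
        t = motifs.comethylation_test(calls, (10, 20))
        assert t.counts() == {"MM": 10, "MU": 10, "UM": 10, "UU": 70}
        assert t.chi_square == pytest.approx(14.0625)

    def test_too_few_fragments_undefined(self):
        t = motifs.comethylation_test(
            [read_call("a", MethState.METH, MethState.METH)], (10, 20)
        )
        assert t.chi_square is None

    def test_pooled_over_hits(self):
        M, U = MethState.METH, MethState.UNMETH
        hits = [make_hit({2: 10, 12: 20}), make_hit({2: 110, 12: 120})]
        calls = [
            read_call("a", M, M, 10, 20),
            read_call("b", U, U, 10, 20),
            read_call("c", M, U, 110, 120),
            read_call("d", U, M, 110, 120),
        ]
        t = motifs.pooled_comethylation(calls, hits)
        assert t.counts() == {"MM": 1, "MU": 1, "UM": 1, "UU": 1}
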