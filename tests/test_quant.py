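"""Pseudo-sequence construction, the BSJ read-counting rule, the
ambiguity screen and the treat/mock classification."""

import numpy as np
import pandas as pd
import pytest

from _oracles import rc, read_counts_oracle
from circqc.io import revcomp
from circqc.quant import (AmbiguityFlag, CircCandidate, MatchParams, PairQuant,
                          build_pseudo_seq, check_pair_inclusion, count_bsj_reads,
                          quantify_pair, read_matches_bsj, screen_ambiguity)


def _random_genome(rng, lengths):
    return {f"chr{i + 1}": "".join(np.array(list("ACGT"))[rng.integers(0, 4, n)])
            for i, n in enumerate(lengths)}


# ---------------------------------------------------------------------------
# pseudo-sequence
# ---------------------------------------------------------------------------

class TestPseudoSeq:
    def test_plus_strand_concatenation(self, rng):
        genome = _random_genome(rng, [1000])
        cand = CircCandidate("c1", "chr1", 301, 500, "+", "g")
        ps = build_pseudo_seq(cand, genome)
        assert ps.sequence == genome["chr1"][450:500] + genome["chr1"][300:350]
        assert ps.junction_index == 50
        assert len(ps.sequence) == 100

    def test_minus_strand_is_reverse_complement_of_mirror(self, rng):
        genome = _random_genome(rng, [1000])
        plus = build_pseudo_seq(CircCandidate("p", "chr1", 301, 500, "+", "g"), genome)
        minus = build_pseudo_seq(CircCandidate("m", "chr1", 500, 301, "-", "g"), genome)
        # the − strand candidate with swapped roles reads the same region
        # 5'→3' on the other strand: donor side is revcomp of the + strand
        # acceptor side and vice versa
        assert minus.sequence == revcomp(plus.sequence)

    def test_truncated_donor_flank_adjusts_junction_index(self, rng):
        genome = _random_genome(rng, [400])
        cand = CircCandidate("c1", "chr1", 5, 30, "+", "g")  # donor near the left edge
        with pytest.warns(UserWarning, match="truncated"):
            ps = build_pseudo_seq(cand, genome)
        assert ps.junction_index == 30
        assert ps.sequence == genome["chr1"][:30] + genome["chr1"][4:54]

    def test_orientation_invariant_enforced(self):
        with pytest.raises(ValueError, match="donor_pos"):
            CircCandidate("bad", "chr1", 101, 30, "+", "g")
        with pytest.raises(ValueError, match="donor_pos"):
            CircCandidate("bad", "chr1", 30, 101, "-", "g")


# ---------------------------------------------------------------------------
# read counting rule
# ---------------------------------------------------------------------------

class TestCountRule:
    @pytest.fixture()
    def pseudo(self, rng):
        genome = _random_genome(rng, [2000])
        return build_pseudo_seq(CircCandidate("c1", "chr1", 901, 1500, "+", "g"), genome)

    def test_identical_read_counted(self, pseudo):
        assert count_bsj_reads([pseudo.sequence], pseudo) == 1

    def test_low_coverage_and_span_rejected(self, pseudo):
        # matches positions 1..55 only: coverage 55% < 80, right span 5 < 10
        assert count_bsj_reads([pseudo.sequence[:55]], pseudo) == 0

    def test_partial_read_with_sufficient_span_counted(self, pseudo):
        # positions 11..95: 85 nt coverage, spans 40/45 around the junction
        read = pseudo.sequence[10:95]
        assert count_bsj_reads([read], pseudo) == 1
        assert read_counts_oracle(read, pseudo.sequence, pseudo.junction_index)

    def test_reverse_complement_read_counted_when_enabled(self, pseudo):
        read = rc(pseudo.sequence[5:95])
        assert count_bsj_reads([read], pseudo) == 1
        assert count_bsj_reads([read], pseudo, check_revcomp=False) == 0

    def test_each_read_counted_once(self, pseudo):
        reads = [pseudo.sequence] * 5
        assert count_bsj_reads(reads, pseudo) == 5
        assert count_bsj_reads([], pseudo) == 0

    def test_matches_dp_oracle_on_mixed_fixture(self, rng):
        """Seed-and-verify counting agrees with the exhaustive DP oracle
        on exact, mutated, gapped, half-matching and random reads."""
        genome = _random_genome(rng, [6000])
        cands = [CircCandidate(f"c{i}", "chr1", 200 * i + 101, 200 * i + 700, "+", "g")
                 for i in range(1, 21)]
        pseudos = [build_pseudo_seq(c, genome) for c in cands]
        bases = np.array(list("ACGT"))
        reads = []
        for k in range(120):
            ps = pseudos[k % len(pseudos)]
            s = ps.sequence
            kind = k % 6
            if kind == 0:
                reads.append(s[rng.integers(0, 10):][:90])
            elif kind == 1:  # a few substitutions
                arr = list(s[5:95])
                for pos in rng.integers(0, 90, rng.integers(1, 5)):
                    arr[pos] = bases[rng.integers(0, 4)]
                reads.append("".join(arr))
            elif kind == 2:  # small deletion
                mid = int(rng.integers(20, 70))
                reads.append(s[:mid] + s[mid + int(rng.integers(1, 3)):])
            elif kind == 3:  # donor half only
                reads.append(s[:55])
            elif kind == 4:  # reverse complement
                reads.append(rc(s[3:93]))
            else:  # random
                reads.append("".join(bases[rng.integers(0, 4, 90)]))
        params = MatchParams()
        for ps in pseudos:
            impl = count_bsj_reads(reads, ps)
            orac = sum(read_counts_oracle(r, ps.sequence, ps.junction_index)
                       for r in reads)
            assert impl == orac, ps.circ_id


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------

class TestClassification:
    def test_rpm_arithmetic(self):
        pq = PairQuant("c", 7, 7, 3_500_000, 3_500_000)
        assert pq.mock_rpm == pytest.approx(2.0)

    def test_ratio_one_boundary_is_not_depleted(self):
        pq = PairQuant("c", 5, 5, 10_000, 10_000)
        assert pq.ratio == pytest.approx(1.0)
        assert pq.depletion_class == "not-depleted"

    def test_single_mock_read_excluded(self):
        assert PairQuant("c", 1, 5, 10_000, 10_000).depletion_class == "excluded"

    def test_zero_treated_is_depleted(self):
        pq = PairQuant("c", 5, 0, 10_000, 10_000)
        assert pq.ratio == 0.0
        assert pq.depletion_class == "depleted"

    def test_zero_totals_rejected(self):
        with pytest.raises(ValueError):
            PairQuant("c", 5, 5, 0, 10_000)

    @pytest.mark.parametrize("k", [2, 10, 1000])
    def test_scale_invariance(self, k):
        base = PairQuant("c", 6, 3, 20_000, 10_000)
        scaled = PairQuant("c", 6 * k, 3 * k, 20_000 * k, 10_000 * k)
        assert scaled.ratio == pytest.approx(base.ratio)
        assert scaled.depletion_class == base.depletion_class


class TestQuantifyPair:
    def test_permutation_invariance(self, rng):
        genome = _random_genome(rng, [4000])
        cands = [CircCandidate(f"c{i}", "chr1", 300 * i + 101, 300 * i + 800, "+", "g")
                 for i in range(1, 9)]
        pseudos = {c.circ_id: build_pseudo_seq(c, genome) for c in cands}
        reads = [(f"r{i}_{j}", pseudos[c.circ_id].sequence[5:95])
                 for i, c in enumerate(cands) for j in range(i + 1)]
        q1 = quantify_pair(cands, genome, reads, 10_000, reads, 10_000,
                           exclude_linear=False)
        perm = list(reversed(cands))
        q2 = quantify_pair(perm, genome, reads, 10_000, reads, 10_000,
                           exclude_linear=False)
        merged = q1.set_index("circ_id").sort_index()
        pd.testing.assert_frame_equal(merged, q2.set_index("circ_id").sort_index())
        # counts follow construction: candidate i received i reads
        for i, c in enumerate(cands):
            assert merged.loc[c.circ_id, "mock_count"] == i + 1

    def test_linear_reads_excluded_by_filter(self, rng):
        genome = _random_genome(rng, [4000])
        cand = CircCandidate("c1", "chr1", 501, 1500, "+", "g")
        ps = build_pseudo_seq(cand, genome)
        circ_read = ps.sequence[5:95]
        linear_read = genome["chr1"][1000:1090]
        q = quantify_pair([cand], genome, [("a", circ_read), ("b", linear_read)],
                          1000, [], 1000)
        assert q.loc[0, "mock_count"] == 1

    def test_zero_total_errors(self, rng):
        genome = _random_genome(rng, [1000])
        cand = CircCandidate("c1", "chr1", 301, 500, "+", "g")
        with pytest.raises(ValueError):
            quantify_pair([cand], genome, [], 0, [], 100)


class TestInclusion:
    def _quant(self, n_mock, n_overlap):
        return pd.DataFrame({
            "circ_id": [f"c{i}" for i in range(n_mock)],
            "mock_count": [2] * n_mock,
            "treated_count": [1] * n_overlap + [0] * (n_mock - n_overlap),
        })

    def test_pass_case(self):
        out = check_pair_inclusion(self._quant(601, 300))
        assert out["pass"] and out["n_mock_detected"] == 601

    def test_exactly_600_fails(self):
        assert not check_pair_inclusion(self._quant(600, 500))["pass"]

    def test_low_overlap_fails(self):
        out = check_pair_inclusion(self._quant(900, 200))
        assert not out["pass"]
        assert out["overlap_frac"] == pytest.approx(2 / 9)


# ---------------------------------------------------------------------------
# ambiguity screen
# ---------------------------------------------------------------------------

class TestAmbiguityScreen:
    def test_unique_candidate_is_clean(self, rng):
        genome = _random_genome(rng, [8000])
        cand = CircCandidate("c1", "chr1", 1001, 3000, "+", "g")
        ps = build_pseudo_seq(cand, genome)
        flag = screen_ambiguity(cand, ps, genome)
        assert not flag.ambiguous

    def test_tandem_duplication_gives_colinear_explanation(self, rng):
        genome = _random_genome(rng, [8000])
        cand = CircCandidate("c1", "chr1", 1001, 3000, "+", "g")
        ps = build_pseudo_seq(cand, genome)
        # plant the full pseudo-sequence contiguously elsewhere in the genome
        g2 = dict(genome)
        g2["chr1"] = genome["chr1"][:5000] + ps.sequence + genome["chr1"][5100:]
        flag = screen_ambiguity(cand, build_pseudo_seq(cand, g2), g2)
        assert flag.has_colinear_explanation

    def test_duplicated_donor_flank_gives_multiple_hits(self, rng):
        genome = _random_genome(rng, [8000])
        cand = CircCandidate("c1", "chr1", 1001, 3000, "+", "g")
        ps = build_pseudo_seq(cand, genome)
        donor_half = ps.sequence[:50]
        g2 = dict(genome)
        g2["chr1"] = genome["chr1"][:6000] + donor_half + genome["chr1"][6050:]
        flag = screen_ambiguity(cand, build_pseudo_seq(cand, g2), g2)
        assert flag.has_multiple_hits

    def test_ambiguous_property(self):
        assert AmbiguityFlag("c", True, False).ambiguous
        assert AmbiguityFlag("c", False, True).ambiguous
        assert not AmbiguityFlag("c", False, False).ambiguous
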