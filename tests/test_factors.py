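"""Factor annotation: boundary/isoform/AS flags, RCS counting, RBP
flanks, junction-spanning sites, evolutionary rates and factor counts."""

import numpy as np
import pandas as pd
import pytest

from _oracles import rc, rc_matches_oracle
from circqc.factors import (SiteInterval, annotate_AS, annotate_boundaries,
                            build_factor_matrix, count_functional_features,
                            count_rcs, count_supporting_factors, evo_rate_regions,
                            find_g4, rbp_flank_overlap, span_filter,
                            _maximal_rc_matches, _rc_matches_within)
from circqc.io import Annotation, ScoreTrack
from circqc.quant import CircCandidate
from circqc.simulate import simulate_candidates


def _skip_gene_annotation() -> Annotation:
    """One + strand gene: t1 has exons 101-200, 301-400, 501-600;
    t2 skips the middle exon."""
    ann = Annotation()
    for s, e in [(101, 200), (301, 400), (501, 600)]:
        ann.add_exon("gA", "gA.t1", "chr1", "+", s, e)
    for s, e in [(101, 200), (501, 600)]:
        ann.add_exon("gA", "gA.t2", "chr1", "+", s, e)
    return ann.finalize()


class TestBoundaries:
    def test_exon_pair_from_one_transcript_sets_all_flags(self):
        ann = _skip_gene_annotation()
        cand = CircCandidate("c", "chr1", 301, 600, "+", "gA")
        don, acc, both, same = annotate_boundaries(cand, ann)
        assert don and acc and both and same

    def test_shifted_donor_clears_flags(self):
        ann = _skip_gene_annotation()
        cand = CircCandidate("c", "chr1", 301, 601, "+", "gA")
        don, acc, both, same = annotate_boundaries(cand, ann)
        assert not don and acc and not both and not same

    def test_cross_isoform_boundaries_not_same_isoform(self):
        ann = Annotation()
        # t1: exons 101-200, 301-400; t2: 121-200, 301-380 (alt acceptor+donor)
        for s, e in [(101, 200), (301, 400)]:
            ann.add_exon("gB", "gB.t1", "chr1", "+", s, e)
        for s, e in [(121, 200), (301, 380)]:
            ann.add_exon("gB", "gB.t2", "chr1", "+", s, e)
        ann.finalize()
        cand = CircCandidate("c", "chr1", 101, 380, "+", "gB")  # acc t1-only, don t2-only
        don, acc, both, same = annotate_boundaries(cand, ann)
        assert both and not same

    def test_candidate_outside_genes_all_false(self):
        ann = _skip_gene_annotation()
        cand = CircCandidate("c", "chr1", 5001, 5500, "+", "nope")
        assert annotate_boundaries(cand, ann) == (False, False, False, False)


class TestAlternativeSplicing:
    def test_skipped_exon_boundaries_are_AS(self):
        ann = _skip_gene_annotation()
        cand = CircCandidate("c", "chr1", 301, 400, "+", "gA")  # the skipped exon
        d, a, both = annotate_AS(cand, ann)
        assert d and a and both

    def test_constitutive_single_isoform_not_AS(self):
        ann = Annotation()
        for s, e in [(101, 200), (301, 400), (501, 600)]:
            ann.add_exon("gC", "gC.t1", "chr1", "+", s, e)
        ann.finalize()
        cand = CircCandidate("c", "chr1", 301, 400, "+", "gC")
        assert annotate_AS(cand, ann) == (False, False, False)

    def test_donor_with_two_partner_acceptors_is_AS(self):
        ann = _skip_gene_annotation()
        # donor 200 pairs with acceptor 301 (t1) and 501 (t2): rule (a)
        cand = CircCandidate("c", "chr1", 101, 200, "+", "gA")
        d, a, both = annotate_AS(cand, ann)
        assert d and not a and not both

    def test_unannotated_site_is_not_AS(self):
        ann = _skip_gene_annotation()
        cand = CircCandidate("c", "chr1", 305, 405, "+", "gA")
        assert annotate_AS(cand, ann) == (False, False, False)

    def test_rules_can_be_disabled(self):
        ann = _skip_gene_annotation()
        cand = CircCandidate("c", "chr1", 301, 400, "+", "gA")
        assert annotate_AS(cand, ann, use_skip_rule=False) == (False, False, False)


class TestRCS:
    def _flanked_genome(self, rng, insert_up="", insert_down="", flank=1000):
        bases = np.array(list("ACGT"))
        chrom = "".join(bases[rng.integers(0, 4, 4000)])
        # acceptor at 1501, donor at 2500: upstream flank [501,1500],
        # downstream flank [2501,3500]
        up = chrom[500:1500]
        down = chrom[2500:3500]
        if insert_up:
            up = up[:100] + insert_up + up[100 + len(insert_up):]
        if insert_down:
            down = down[:700] + insert_down + down[700 + len(insert_down):]
        chrom = chrom[:500] + up + chrom[1500:2500] + down + chrom[3500:]
        return {"chr1": chrom}, CircCandidate("c", "chr1", 1501, 2500, "+", "g")

    def test_planted_across_pair_detected(self, rng):
        probe = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 40)])
        genome, cand = self._flanked_genome(rng, insert_up=probe, insert_down=rc(probe))
        across, within = count_rcs(cand, genome, window=1000, min_len=30)
        assert across >= 1

    def test_random_flanks_have_no_matches(self, rng):
        genome, cand = self._flanked_genome(rng)
        across, within = count_rcs(cand, genome, window=1000, min_len=30)
        assert across == 0 and within == 0

    def test_planted_hairpin_counts_within_only(self, rng):
        probe = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 35)])
        hairpin = probe + "AACCAA" + rc(probe)
        genome, cand = self._flanked_genome(rng, insert_up=hairpin)
        across0, _ = count_rcs(cand, genome, window=1000, min_len=30)
        _, within = count_rcs(cand, genome, window=1000, min_len=30)
        assert within >= 1 and across0 == 0

    def test_matches_brute_force_oracle(self, rng):
        bases = np.array(list("ACGT"))
        for trial in range(5):
            a = "".join(bases[rng.integers(0, 4, 1000)])
            b = "".join(bases[rng.integers(0, 4, 1000)])
            # plant two cross matches and one hairpin
            probe1 = "".join(bases[rng.integers(0, 4, 40)])
            probe2 = "".join(bases[rng.integers(0, 4, 32)])
            a = a[:100] + probe1 + a[140:600] + probe2 + a[632:]
            b = b[:300] + rc(probe1) + b[340:800] + rc(probe2) + b[832:]
            impl = _maximal_rc_matches(a, b, 30)
            assert impl == rc_matches_oracle(a, b, 30)

    def test_within_counts_unordered_pairs(self, rng):
        bases = np.array(list("ACGT"))
        probe = "".join(bases[rng.integers(0, 4, 40)])
        f = ("".join(bases[rng.integers(0, 4, 200)]) + probe
             + "".join(bases[rng.integers(0, 4, 100)]) + rc(probe)
             + "".join(bases[rng.integers(0, 4, 200)]))
        assert _rc_matches_within(f, 30) == 1


class TestRBPFlank:
    def _sites(self, rows):
        return pd.DataFrame(rows, columns=["chrom", "start", "end", "name"])

    def test_site_downstream_of_donor(self):
        cand = CircCandidate("c", "chr1", 1000, 5000, "+", "g")
        sites = self._sites([("chr1", 5100, 5120, "s1")])
        flag, dist = rbp_flank_overlap(cand, sites, flank=1000)
        assert flag and dist == 100

    def test_site_just_beyond_flank(self):
        cand = CircCandidate("c", "chr1", 1000, 5000, "+", "g")
        sites = self._sites([("chr1", 6001, 6020, "s1")])
        flag, dist = rbp_flank_overlap(cand, sites, flank=1000)
        assert not flag and dist == 1001

    def test_site_covering_coordinate_distance_zero(self):
        cand = CircCandidate("c", "chr1", 1000, 5000, "+", "g")
        sites = self._sites([("chr1", 4990, 5010, "s1")])
        flag, dist = rbp_flank_overlap(cand, sites, flank=1000)
        assert flag and dist == 0

    def test_empty_table_missing_distance(self):
        cand = CircCandidate("c", "chr1", 1000, 5000, "+", "g")
        flag, dist = rbp_flank_overlap(cand, self._sites([]), flank=1000)
        assert not flag and np.isnan(dist)


class TestSpanFilter:
    def test_rbp_passes_mirna_fails(self):
        sites = [SiteInterval("c", "RBP", 48, 57), SiteInterval("c", "miRNA", 48, 57)]
        flags = span_filter(sites)
        assert flags["RBP"] and not flags["miRNA"]

    def test_mirna_boundary_site_passes(self):
        assert span_filter([SiteInterval("c", "miRNA", 46, 55)])["miRNA"]

    def test_g4_without_left_span_fails(self):
        assert not span_filter([SiteInterval("c", "G4", 52, 80)])["G4"]

    def test_interval_outside_pseudo_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            span_filter([SiteInterval("c", "G4", 90, 120)])

    def test_invariant_under_non_spanning_additions(self):
        base = [SiteInterval("c", "miRNA", 40, 60)]
        extra = base + [SiteInterval("c", "miRNA", 60, 80),
                        SiteInterval("c", "miRNA", 1, 20)]
        assert span_filter(base) == span_filter(extra)


class TestEvoRates:
    def test_constant_track(self):
        cand = CircCandidate("c", "chr1", 301, 500, "+", "g")
        genome = {"chr1": "A" * 1000}
        track = ScoreTrack.constant(genome, 0.5)
        out = evo_rate_regions(cand, track)
        for region in ("acceptor_exon", "acceptor_intron", "donor_exon", "donor_intron"):
            assert out[region] == pytest.approx(0.5)
            assert out[f"{region}_n"] == 10

    def test_position_index_track_gives_window_means(self):
        cand = CircCandidate("c", "chr1", 301, 500, "+", "g")
        track = ScoreTrack({"chr1": {p: float(p) for p in range(1, 1001)}})
        out = evo_rate_regions(cand, track)
        assert out["acceptor_exon"] == pytest.approx(np.mean(range(301, 311)))
        assert out["acceptor_intron"] == pytest.approx(np.mean(range(291, 301)))
        assert out["donor_exon"] == pytest.approx(np.mean(range(491, 501)))
        assert out["donor_intron"] == pytest.approx(np.mean(range(501, 511)))

    def test_minus_strand_windows_mirrored(self):
        cand = CircCandidate("c", "chr1", 500, 301, "-", "g")
        track = ScoreTrack({"chr1": {p: float(p) for p in range(1, 1001)}})
        out = evo_rate_regions(cand, track)
        assert out["acceptor_exon"] == pytest.approx(np.mean(range(491, 501)))
        assert out["donor_intron"] == pytest.approx(np.mean(range(291, 301)))

    def test_partial_coverage_reported(self):
        cand = CircCandidate("c", "chr1", 301, 500, "+", "g")
        track = ScoreTrack({"chr1": {p: 1.0 for p in range(301, 306)}})
        out = evo_rate_regions(cand, track)
        assert out["acceptor_exon"] == pytest.approx(1.0)
        assert out["acceptor_exon_n"] == 5
        assert np.isnan(out["donor_exon"])


class TestCounts:
    def test_functional_feature_count(self):
        assert count_functional_features([True] * 9) == 9
        flags = dict.fromkeys(range(9), False)
        flags[3] = True
        assert count_functional_features(flags) == 1
        assert count_functional_features([np.nan] * 9) == 0
        with pytest.raises(ValueError):
            count_functional_features([True] * 7)

    def test_supporting_factor_count(self):
        full = {"multi_tool": True, "full_length": True, "n_samples": 5,
                "both_annotated": True, "same_isoform": True, "both_AS": True,
                "n_functional_features": 4}
        assert count_supporting_factors(full) == 7
        none = {"multi_tool": False, "full_length": False, "n_samples": 1,
                "both_annotated": False, "same_isoform": False, "both_AS": False,
                "n_functional_features": 2}
        assert count_supporting_factors(none) == 0
        only_samples = dict(none, n_samples=3)
        assert count_supporting_factors(only_samples) == 1  # cutoff is ≥3

    def test_g4_detector_motif(self):
        hits = find_g4("AATTGGGAGGGTGGGAGGGTT")
        assert hits and hits[0] == (5, 19)
        assert find_g4("ACGTACGTACGT") == []


class TestFactorMatrix:
    def test_construction_flags_match_generator_truth(self, small_config,
                                                      reference, candidate_set):
        """Catalog-built candidates are 100% both-annotated (as sampled)
        and perturbed artifacts 0%, with same-isoform matching the
        generator's record exactly."""
        genome, ann = reference
        cands, truth = candidate_set
        fm = build_factor_matrix(cands, annotation=ann)
        merged = fm.merge(truth, on="circ_id")
        assert (merged["both_annotated"] == merged["gen_both_annotated"]).all()
        assert (merged["same_isoform"] == merged["gen_same_isoform"]).all()
        assert (merged["both_AS"] == merged["gen_both_AS"]).all()
        assert merged["n_functional_features"].between(0, 9).all()
        assert merged["n_supporting_factors"].between(0, 7).all()

    def test_idempotent(self, reference, candidate_set):
        genome, ann = reference
        cands, _ = candidate_set
        f1 = build_factor_matrix(cands, annotation=ann)
        f2 = build_factor_matrix(cands, annotation=ann)
        pd.testing.assert_frame_equal(f1, f2)
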