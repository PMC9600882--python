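"""Consensus-to-PWM conversion, intergenic extraction, and site scanning."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from caproflux import regulon, simulate
from caproflux.io import Feature, MalformedAnnotationError, reverse_complement
from caproflux.regulon import (
    GenomicInterval,
    consensus_to_pwm,
    extract_intergenic,
    hamming_to_consensus,
    scan_sequences,
    scan_string,
    site_report,
)

REX = simulate.REX_CONSENSUS


class TestConsensusToPwm:
    def test_n_column_is_neutral_under_uniform_background(self):
        m = consensus_to_pwm("N")
        assert np.allclose(m.pwm, 0.0)

    def test_single_base_column_rewards_match_and_penalizes_rest(self):
        m = consensus_to_pwm("A", epsilon=1e-4)
        assert m.pwm[0, 0] == pytest.approx(np.log2((1 - 3e-4) / 0.25))
        assert (m.pwm[0, 1:] < -10).all()

    def test_rex_seed_has_18_columns_with_4_neutral(self):
        m = consensus_to_pwm(REX)
        assert m.length == 18
        neutral = np.isclose(m.pwm, 0.0).all(axis=1).sum()
        assert neutral == 4

    def test_probabilities_sum_to_one_per_position(self):
        m = consensus_to_pwm("TGGTNNNACCA")
        assert np.allclose(m.probs.sum(axis=1), 1.0)

    def test_invalid_character_is_a_parse_error(self):
        with pytest.raises(ValueError, match="invalid IUPAC"):
            consensus_to_pwm("TTGXTAA")

    def test_counts_matrix_shape_and_scale(self):
        m = consensus_to_pwm(REX)
        counts = m.counts_matrix(scale=100)
        assert counts.shape == (18, 4)
        assert counts.dtype.kind == "i"

    def test_consensus_conforming_string_scores_maximally(self):
        m = consensus_to_pwm(REX)
        assert m.score("TTGTTAAGGGGTTAACAA") == pytest.approx(m.max_score)

    @given(pos=st.integers(0, 17))
    @settings(deadline=None, derandomize=True)
    def test_every_informative_mismatch_strictly_lowers_the_score(self, pos):
        m = consensus_to_pwm(REX)
        site = list("TTGTTAAGGGGTTAACAA")
        original = site[pos]
        site[pos] = {"A": "C", "C": "A", "G": "T", "T": "G"}[original]
        mutated = m.score("".join(site))
        if REX[pos] == "N":
            assert mutated == pytest.approx(m.max_score)
        else:
            assert mutated < m.max_score


class TestHamming:
    @pytest.mark.parametrize(
        "site,expected",
        [
            ("TTGCTAAAACTTTAACAA", 1),  # operon leader of the elongation genes
            ("TTTTTAACCGCTTAATCA", 3),  # pentose-phosphate gene site
            ("TTGTTAAGGGGTTAACAA", 0),
        ],
    )
    def test_mismatch_counts_against_rex_seed(self, site, expected):
        assert hamming_to_consensus(site, REX) == expected

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            hamming_to_consensus("ACGT", REX)

    def test_reported_site_scores_track_mismatch_ordering(self):
        """The published 1-mismatch site must outscore the 3-mismatch site."""
        m = consensus_to_pwm(REX)
        assert m.score("TTGCTAAAACTTTAACAA") > m.score("TTTTTAACCGCTTAATCA")


class TestPalindromy:
    def test_rex_seed_is_its_own_reverse_complement(self):
        m = consensus_to_pwm(REX)
        assert m.is_palindromic
        core = "TTGTTAAGGGGTTAACAA"
        assert hamming_to_consensus(reverse_complement(core), REX) == 0

    def test_lldr_seed_is_palindromic_too(self):
        assert consensus_to_pwm(simulate.LLDR_CONSENSUS).is_palindromic

    def test_promoter_like_motif_is_not(self):
        assert not consensus_to_pwm("TTGACANNNTATAAT").is_palindromic


def _genome(seq_len=600, genes=()):
    return {"chr": "A" * seq_len}, [
        Feature("chr", "CDS", s, e, strand, gid) for (s, e, strand, gid) in genes
    ]


class TestExtractIntergenic:
    def test_gap_between_tandem_plus_genes_points_at_second(self):
        seqs, feats = _genome(600, [(0, 200, "+", "g1"), (300, 500, "+", "g2")])
        ivs = extract_intergenic(feats, seqs)
        gap = next(iv for iv in ivs if iv.start == 200)
        assert (gap.end, gap.downstream_plus) == (300, "g2")
        assert gap.downstream_minus is None

    def test_divergent_pair_serves_both_genes(self):
        # e.g. the lactate racemase / lactate permease pair transcribed apart
        seqs, feats = _genome(600, [(0, 200, "-", "larA"), (300, 500, "+", "lldP")])
        gap = next(iv for iv in extract_intergenic(feats, seqs) if iv.start == 200)
        assert gap.downstream_plus == "lldP"
        assert gap.downstream_minus == "larA"
        assert gap.downstream_minus_end == 200

    def test_geneless_sequence_yields_one_full_interval(self):
        ivs = extract_intergenic([], {"chr": "ACGT" * 50})
        assert len(ivs) == 1
        assert (ivs[0].start, ivs[0].end) == (0, 200)

    def test_out_of_range_feature_is_malformed(self):
        seqs, feats = _genome(100, [(50, 200, "+", "g1")])
        with pytest.raises(MalformedAnnotationError):
            extract_intergenic(feats, seqs)

    def test_unknown_sequence_id_is_named(self):
        feats = [Feature("missing", "CDS", 0, 10, "+", "g1")]
        with pytest.raises(MalformedAnnotationError, match="missing"):
            extract_intergenic(feats, {"chr": "ACGT"})


class TestScan:
    def test_planted_exact_site_is_the_only_hit(self):
        rng = np.random.default_rng(11)
        m = consensus_to_pwm(REX)
        site = "TTGTTAAGGGGTTAACAA"
        for _ in range(20):  # draw a background with no stray hits
            bg = "".join(rng.choice(list("ACGT"), 300))
            seq = bg[:100] + site + bg[118:]
            if len(scan_string(m, seq, 0.7)) == 1:
                break
        iv = GenomicInterval("chr", 1000, 1000 + len(seq), seq,
                             downstream_plus="g", downstream_plus_start=1000 + len(seq))
        hits = scan_sequences(m, [iv], threshold=0.7)
        assert len(hits) == 1
        assert hits[0].start == 1100
        assert hits[0].offset == 1100 - (1000 + len(seq))
        assert hits[0].offset < 0  # upstream sites carry negative offsets

    def test_palindromic_site_reported_once_not_twice(self):
        m = consensus_to_pwm(REX)
        seq = "C" * 50 + "TTGTTAAGGGGTTAACAA" + "C" * 50
        hits = scan_string(m, seq, threshold=0.9)
        assert len(hits) == 1
        assert hits[0][1] == "+"

    def test_non_palindromic_motif_scans_both_strands(self):
        m = consensus_to_pwm("TTGACANNNTATAAT")
        core = "TTGACAGGGTATAAT"
        seq = "C" * 40 + reverse_complement(core) + "C" * 40
        hits = scan_string(m, seq, threshold=0.9)
        assert [h[1] for h in hits] == ["-"]
        hits_fwd = scan_string(m, "C" * 40 + core + "C" * 40, threshold=0.9)
        assert [h[1] for h in hits_fwd] == ["+"]

    def test_minus_strand_offset_is_negative_upstream(self):
        m = consensus_to_pwm("TTGACANNNTATAAT")
        core = reverse_complement("TTGACAGGGTATAAT")
        seq = "C" * 30 + core + "C" * 30
        iv = GenomicInterval("chr", 500, 500 + len(seq), seq,
                             downstream_minus="g", downstream_minus_end=500)
        hits = scan_sequences(m, [iv], threshold=0.9)
        assert hits[0].strand == "-"
        assert hits[0].offset == 500 - (500 + 30 + 15)

    def test_interval_shorter_than_motif_is_skipped(self):
        m = consensus_to_pwm(REX)
        iv = GenomicInterval("chr", 0, 5, "ACGTA")
        assert scan_sequences(m, [iv]) == []

    def test_threshold_must_be_a_valid_fraction(self):
        m = consensus_to_pwm(REX)
        with pytest.raises(ValueError):
            scan_string(m, "ACGT" * 10, threshold=0.0)

    @pytest.mark.parametrize("seed", range(8))
    def test_scanning_is_strand_symmetric(self, seed):
        """Reverse-complementing the sequence mirrors the hit set exactly."""
        m = consensus_to_pwm("TTGACANNNTATAAT")
        rng = np.random.default_rng(seed)
        seq = "".join(rng.choice(list("ACGT"), 400))
        fwd = scan_string(m, seq, threshold=0.6)
        rev = scan_string(m, reverse_complement(seq), threshold=0.6)
        n, L = len(seq), m.length
        mirrored = sorted(
            (n - L - pos, {"+": "-", "-": "+"}[strand], round(score, 9))
            for pos, strand, score in rev
        )
        assert mirrored == sorted((p, s, round(sc, 9)) for p, s, sc in fwd)


class TestSiteReport:
    def test_records_sorted_by_score_then_leftmost(self):
        from caproflux.regulon import SiteHit

        hits = [
            SiteHit("chr", 50, 68, "+", "A" * 18, 10.0, 0.9, "g1", -30),
            SiteHit("chr", 10, 28, "+", "C" * 18, 12.0, 0.95, "g2", -12),
            SiteHit("chr", 5, 23, "+", "G" * 18, 10.0, 0.9, "g3", -40),
        ]
        df = site_report(hits)
        assert list(df["start"]) == [10, 5, 50]
        assert list(df["operon_first_gene"]) == ["g2", "g3", "g1"]

    def test_empty_report_is_valid(self):
        df = site_report([])
        assert len(df) == 0
        assert "score" in df.columns
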