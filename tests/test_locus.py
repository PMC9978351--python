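"""Strand-aware cleavage arithmetic, PSS classification, digest and primer
location — including the printed locus constants."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from replikit._seq import revcomp
from replikit.locus import (
    T7_LEADER,
    CleavageSite,
    OrfSpan,
    PSSRecord,
    TranscriptSubstrate,
    amplicon_fragment,
    classify_pss,
    classify_table,
    digest,
    fragment_sizes,
    load_locus_coords,
    load_pss_table,
    load_primers,
    locate_amplicon,
    orf_aa_count,
    substrate_length,
    tss_distance,
)

# the antisense-RNA in vitro substrate: reverse strand, templated span
# 32,483..32,329, three non-templated T7 Gs at the 5' end
ASRNA1_SUBSTRATE = TranscriptSubstrate("-", 32_483, 32_329, extra5=3,
                                       phospho_state="monophosphate")


class TestSubstrateArithmetic:
    def test_in_vitro_substrate_is_158_nt(self):
        assert substrate_length(ASRNA1_SUBSTRATE) == 158

    def test_native_antisense_rna_is_153_nt(self):
        assert substrate_length(TranscriptSubstrate("-", 32_481, 32_329)) == 153

    def test_single_nt_span(self):
        assert substrate_length(TranscriptSubstrate("+", 10, 10)) == 1

    def test_invalid_reverse_orientation_rejected(self):
        with pytest.raises(ValueError):
            TranscriptSubstrate("-", 100, 200)

    @pytest.mark.parametrize(
        "cuts,expected",
        [
            ([32_426], [60, 98]),
            ([32_418], [68, 90]),
            ([32_426, 32_418], [60, 8, 90]),
        ],
    )
    def test_cleavage_fragment_sizes(self, cuts, expected):
        assert fragment_sizes(ASRNA1_SUBSTRATE, cuts) == expected

    def test_cut_outside_span_names_coordinate(self):
        with pytest.raises(ValueError, match="32600"):
            fragment_sizes(ASRNA1_SUBSTRATE, [32_600])

    def test_cut_strand_mismatch_rejected(self):
        with pytest.raises(ValueError, match="strand"):
            fragment_sizes(ASRNA1_SUBSTRATE, [CleavageSite(32_426, "+")])

    def test_orf_amino_acid_counts(self):
        assert orf_aa_count(OrfSpan(32_289, 32_483)) == 64
        assert orf_aa_count(OrfSpan(1, 6)) == 1
        with pytest.raises(ValueError, match="multiple of 3"):
            orf_aa_count(OrfSpan(1, 4))

    def test_tss_distance(self):
        assert tss_distance(32_177, 32_481) == 304
        assert tss_distance(7, 7) == 0
        assert tss_distance(3, 11) == tss_distance(11, 3)

    @given(
        st.integers(1, 5_000), st.integers(2, 400), st.integers(0, 5),
        st.data(),
    )
    def test_fragment_conservation_and_strand_symmetry(self, start, span, extra, data):
        """Fragments always sum to the substrate length, and a reverse-strand
        problem equals its coordinate-mirrored forward-strand counterpart."""
        fwd = TranscriptSubstrate("+", start, start + span - 1, extra5=extra)
        n_cuts = data.draw(st.integers(1, min(5, span - 1)))
        offsets = data.draw(
            st.lists(st.integers(1, span - 1), min_size=n_cuts, max_size=n_cuts,
                     unique=True)
        )
        cuts_fwd = [start + o for o in offsets]
        frags = fragment_sizes(fwd, cuts_fwd)
        assert sum(frags) == substrate_length(fwd)
        # mirror: reverse strand with 5' end at the high coordinate
        rev = TranscriptSubstrate("-", start + span - 1, start, extra5=extra)
        cuts_rev = [start + span - 1 - o for o in offsets]
        assert fragment_sizes(rev, cuts_rev) == frags


class TestClassification:
    def test_printed_examples(self):
        assert classify_pss(
            PSSRecord(32_418, "-", "TU7031", fc_wt_ts=4.16, padj_wt_ts=0.00),
            "wt_vs_ts",
        ) == "rnase_e_site"
        assert classify_pss(
            PSSRecord(32_463, "-", "TU7031", fc_wt_ts=-1.02, padj_wt_ts=0.03),
            "wt_vs_ts",
        ) == "stabilized_in_ts"
        assert classify_pss(
            PSSRecord(32_469, "+", "TU7030", fc_wt_ts=1.33, padj_wt_ts=0.42),
            "wt_vs_ts",
        ) == "unclassified"

    def test_missing_values_unclassified(self):
        assert classify_pss(PSSRecord(1, "+", "TU7030"), "wt_vs_ts") == "unclassified"

    def test_unknown_comparison_rejected(self):
        with pytest.raises(ValueError):
            classify_pss(PSSRecord(1, "+", "TU7030"), "ts_vs_5p")

    def test_packaged_table_counts(self):
        t = classify_table()
        assert len(t) == 14
        assert (t.tu.isin(["TU7029", "TU7030"])).sum() == 10
        assert (t.tu == "TU7031").sum() == 4
        sig = t[(t.tu == "TU7031") & (t.category_wt_vs_ts == "rnase_e_site")]
        assert sorted(sig.position) == [32_418, 32_426]

    def test_fixture_round_trip(self):
        df = load_pss_table()
        assert df.padj_wt_ts.dropna().between(0, 1).all()
        coords = load_locus_coords()
        assert coords["ssr7036_tss"] == 32_177
        assert coords["asrna1_tss"] == 32_481
        primers = load_primers()
        assert primers.set_index("id").loc["P37", "sequence"] == "CTTTAGGTGGGCGTTGACCT"


def _rand_seq(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))


def _site_free(rng, n, site="AAGCTT"):
    while True:
        s = _rand_seq(rng, n)
        if site not in s:
            return s


class TestDigest:
    def test_no_site_linear_whole_sequence(self, rng):
        seq = _site_free(rng, 500)
        assert digest(seq) == [(1, 500, 500)]

    def test_circular_two_sites_two_fragments(self, rng):
        seq = _site_free(rng, 994) + "AAGCTT"
        seq = seq[:300] + "AAGCTT" + seq[300:]
        frags = digest(seq, circular=True)
        assert len(frags) == 2
        assert sum(f[2] for f in frags) == len(seq)

    def test_planted_sites_give_expected_fragment_lengths(self, rng):
        body = _site_free(rng, 10_000 - 12)
        # sites starting at 1-based positions 1,000 and 3,550
        seq = body[:999] + "AAGCTT" + body[999:3543] + "AAGCTT" + body[3543:]
        assert "AAGCTT" not in body
        frags = digest(seq, circular=True)
        assert sorted(f[2] for f in frags) == [2_550, 7_450]

    def test_matches_biopython_restriction_oracle(self, rng):
        from Bio.Restriction import HindIII
        from Bio.Seq import Seq

        for trial in range(5):
            seq = _rand_seq(np.random.default_rng(trial), 6_000)
            ours = sorted(f[2] for f in digest(seq, circular=False))
            theirs = sorted(
                len(f) for f in HindIII.catalyze(Seq(seq), linear=True)
            )
            assert ours == theirs

    def test_conservation_property(self, rng):
        for trial in range(10):
            seq = _rand_seq(np.random.default_rng(100 + trial), 3_000)
            for circ in (False, True):
                frags = digest(seq, circular=circ)
                assert sum(f[2] for f in frags) == 3_000


class TestAmplicon:
    def _template(self, rng):
        fwd = "CTTTAGGTGGGCGTTGACCT"
        rev_core = "TAATAGTAATGACAGGCAG"  # genomic top strand at primer site
        seq = _site_free(rng, 4_000)
        seq = seq[:1_000] + fwd + seq[1_000:2_500] + rev_core + seq[2_500:]
        return seq, fwd, rev_core

    def test_planted_primer_pair_located(self, rng):
        seq, fwd, rev_core = self._template(rng)
        span = locate_amplicon(seq, fwd, revcomp(rev_core))
        assert span == (1_001, 1_001 + 20 + 1_500 + 19 - 1)

    def test_t7_tagged_primer_same_span(self, rng):
        seq, fwd, rev_core = self._template(rng)
        plain = locate_amplicon(seq, fwd, revcomp(rev_core))
        tagged = locate_amplicon(seq, fwd, T7_LEADER + revcomp(rev_core))
        assert plain == tagged

    def test_absent_primer_raises(self, rng):
        seq, fwd, rev_core = self._template(rng)
        with pytest.raises(ValueError, match="no exact match"):
            locate_amplicon(seq, "GGGGGGGGGGGGGGGGG", revcomp(rev_core))

    def test_probe_fragment_length_synthetic_locus(self, rng):
        """On a synthetic circular plasmid the digest fragment containing the
        probe amplicon has the planted 2,550 bp length."""
        fwd = "CTTTAGGTGGGCGTTGACCT"
        rev_core = "TAATAGTAATGACAGGCAG"
        body = _site_free(np.random.default_rng(55), 20_000)
        seq = (
            body[:2_000] + "AAGCTT"          # cut a
            + body[2_000:2_800] + fwd         # amplicon inside fragment a..b
            + body[2_800:3_600] + rev_core
            + body[3_600:4_505] + "AAGCTT"    # cut b: 2,550 nt after cut a
            + body[4_505:]
        )
        frags = digest(seq, circular=True)
        span = locate_amplicon(seq, fwd, revcomp(rev_core))
        frag = amplicon_fragment(frags, span)
        assert frag[2] == 2_550
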