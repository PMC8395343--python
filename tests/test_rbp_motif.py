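"""Motif scanning, regional enrichment, and SNP-induced motif changes."""

import re

import numpy as np
import pytest
from hypothesis import given, strategies as st

from splicescope.rbp_motif import (
    EFFECT_CREATE,
    EFFECT_DISRUPT,
    EFFECT_NONE,
    IUPAC,
    MotifModel,
    regional_enrichment,
    scan_motif,
    snp_motif_effect,
)


def motif(*patterns, name="M", regions=("exon",)):
    return MotifModel(name, tuple(patterns), tuple(regions))


def regex_scan(seq, patterns):
    """Independent oracle: IUPAC patterns as regular expressions with
    overlapping matches via lookahead."""
    offsets = set()
    for pat in patterns:
        expanded = "".join(
            f"[{''.join(sorted(IUPAC[sym]))}]" for sym in pat.upper()
        )
        offsets.update(m.start() for m in re.finditer(f"(?={expanded})", seq))
    return sorted(offsets)


class TestScanMotif:
    def test_direct_match(self):
        hits = scan_motif("AAGGACGGAA", motif("GGACGGA"))
        assert [h.offset for h in hits] == [2]

    def test_iupac_n_matches_any_base(self):
        hits = scan_motif("TTGGAGGATT", motif("GGNGGA"))
        assert [h.offset for h in hits] == [2]

    def test_pattern_longer_than_sequence_gives_no_hits(self):
        assert scan_motif("ACG", motif("ACGTACG")) == []

    def test_overlapping_matches_all_reported(self):
        assert [h.offset for h in scan_motif("AAAAA", motif("AAA"))] == [0, 1, 2]

    def test_non_acgtn_base_rejected_with_position(self):
        with pytest.raises(ValueError, match="position 2"):
            scan_motif("ACXGT", motif("ACG"))

    @given(st.integers(min_value=0, max_value=2**32 - 1))
    def test_matches_regex_oracle_on_random_sequences(self, seed):
        rng = np.random.default_rng(seed)
        seq = "".join(rng.choice(list("ACGT"), size=300))
        patterns = ("GGAGGA", "GRNGGA", "TGCATG", "CYCYC")
        m = motif(*patterns)
        assert [h.offset for h in scan_motif(seq, m)] == regex_scan(seq, patterns)

    def test_invalid_pattern_alphabet_rejected(self):
        with pytest.raises(ValueError):
            motif("ACGQ")

    def test_empty_pattern_set_rejected(self):
        with pytest.raises(ValueError):
            MotifModel("M", (), ("exon",))


class TestSnpMotifEffect:
    SEQ = "TTTTGGAGGATTTT"  # GGAGGA at offset 4

    def test_breaking_a_match_is_disrupt(self):
        m = motif("GGAGGA")
        assert snp_motif_effect(m, self.SEQ, 6, "A", "C") == EFFECT_DISRUPT

    def test_completing_a_match_is_create(self):
        seq = "TTTTGGTGGATTTT"  # one base off
        m = motif("GGAGGA")
        assert snp_motif_effect(m, seq, 6, "T", "A") == EFFECT_CREATE

    def test_snp_outside_any_footprint_is_none(self):
        m = motif("GGAGGA")
        assert snp_motif_effect(m, self.SEQ, 12, "T", "A") == EFFECT_NONE

    def test_degenerate_slot_substitution_can_be_neutral(self):
        m = motif("GGNGGA")
        # N slot tolerates any base: no disruption possible there
        assert snp_motif_effect(m, self.SEQ, 6, "A", "C") == EFFECT_NONE

    def test_ref_mismatch_with_sequence_is_error(self):
        with pytest.raises(ValueError, match="reference allele"):
            snp_motif_effect(motif("GGAGGA"), self.SEQ, 6, "G", "C")

    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_effect_is_antisymmetric_under_allele_swap(self, seed):
        rng = np.random.default_rng(seed)
        seq = "".join(rng.choice(list("ACGT"), size=60))
        off = int(rng.integers(60))
        base = seq[off]
        alt = "ACGT"[("ACGT".index(base) + 1) % 4]
        m = motif("GGAGGA", "TGCATG")
        forward = snp_motif_effect(m, seq, off, base, alt)
        back_seq = seq[:off] + alt + seq[off + 1 :]
        backward = snp_motif_effect(m, back_seq, off, alt, base)
        pairing = {
            EFFECT_DISRUPT: EFFECT_CREATE,
            EFFECT_CREATE: EFFECT_DISRUPT,
            EFFECT_NONE: EFFECT_NONE,
        }
        assert backward == pairing[forward]


class TestRegionalEnrichment:
    def _seqs(self, n, with_motif, rng):
        out = []
        for i in range(n):
            seq = list("".join(rng.choice(list("ACT"), size=80)))  # no G: no chance hits
            if i < with_motif:
                seq[20:26] = "GGAGGA"
            out.append("".join(seq))
        return out

    def test_planted_imbalance_is_detected(self):
        rng = np.random.default_rng(0)
        m = motif("GGAGGA")
        fg = self._seqs(50, 45, rng)  # 90 %
        bg = self._seqs(50, 5, rng)   # 10 %
        log2e, p, fg_hit, bg_hit = regional_enrichment(m, fg, bg)
        assert (fg_hit, bg_hit) == (45, 5)
        assert log2e > 0 and p < 0.01

    def test_identical_fractions_give_zero_enrichment(self):
        rng = np.random.default_rng(1)
        m = motif("GGAGGA")
        fg = self._seqs(20, 10, rng)
        bg = self._seqs(20, 10, rng)
        log2e, p, _, _ = regional_enrichment(m, fg, bg)
        assert log2e == 0.0 and p == pytest.approx(1.0)

    def test_zero_foreground_fraction_is_capped(self):
        rng = np.random.default_rng(2)
        m = motif("GGAGGA")
        log2e, _, _, _ = regional_enrichment(m, self._seqs(10, 0, rng), self._seqs(10, 8, rng))
        assert log2e == -20.0

    def test_fisher_p_symmetric_under_label_swap(self):
        rng = np.random.default_rng(3)
        m = motif("GGAGGA")
        fg = self._seqs(30, 22, rng)
        bg = self._seqs(25, 6, rng)
        l1, p1, _, _ = regional_enrichment(m, fg, bg)
        l2, p2, _, _ = regional_enrichment(m, bg, fg)
        assert p1 == pytest.approx(p2)
        assert l1 == pytest.approx(-l2)

    def test_fisher_matches_hypergeometric_enumeration(self):
        from scipy.stats import hypergeom

        rng = np.random.default_rng(4)
        m = motif("GGAGGA")
        fg = self._seqs(12, 9, rng)
        bg = self._seqs(12, 2, rng)
        _, p, a, c = regional_enrichment(m, fg, bg)
        # two-sided Fisher = sum of hypergeometric outcomes no more likely
        # than the observed table
        n_fg, n_bg, k = 12, 12, a + c
        probs = [hypergeom.pmf(x, n_fg + n_bg, k, n_fg) for x in range(k + 1)]
        expected = sum(q for q in probs if q <= probs[a] * (1 + 1e-9))
        assert p == pytest.approx(expected, rel=1e-6)
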