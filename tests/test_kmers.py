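"""Gapped k-mer enumeration and strand-symmetrized counting.

The counting engine is checked against an independent regex-based oracle
(pattern and reverse complement as lookahead regexes on the forward strand)
and against exact combinatorial identities.
"""

import re

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from kmerfact.io_regions import RegionSequenceSet
from kmerfact.kmers import (
    CellKmerMatrix,
    KmerPattern,
    PatternUniverse,
    build_matrix,
    count_patterns,
    enumerate_patterns,
    reverse_complement,
)


def universe_size(max_span: int) -> int:
    """Closed form for the gapped universe: 4 + sum_{k>=2} 16 * 5^(k-2)."""
    return 4 + sum(16 * 5 ** (k - 2) for k in range(2, max_span + 1))


def naive_count(sequences, pattern: str) -> int:
    """Independent oracle: overlapping regex matches of pattern + RC."""
    pats = {pattern, reverse_complement(pattern)}
    total = 0
    for p in pats:
        rx = re.compile("(?=" + p.replace("N", ".") + ")")
        for seq in sequences:
            for segment in re.split(r"[^ACGT]+", seq):
                total += len(rx.findall(segment))
    return total


class TestPatternType:
    def test_fields(self):
        p = KmerPattern("ANGT")
        assert (p.span, p.n_specified, p.is_gapped) == (4, 3, True)
        assert not p.is_palindrome
        assert not p.canonical  # RC "ACNT" sorts first
        assert KmerPattern("ACNT").canonical

    @pytest.mark.parametrize("bad", ["", "NAC", "ACN", "AXG"])
    def test_invalid_patterns_rejected(self, bad):
        with pytest.raises(ValueError):
            KmerPattern(bad)

    def test_reverse_complement_maps_n_to_n(self):
        assert reverse_complement("ANGT") == "ACNT"


class TestEnumeration:
    @pytest.mark.parametrize("span, expected", [(1, 4), (2, 20), (3, 100), (4, 500)])
    def test_universe_matches_closed_form(self, span, expected):
        pats = enumerate_patterns(span, gapped=True, canonicalize=False)
        assert len(pats) == expected == universe_size(span)

    def test_ungapped_universe(self):
        pats = enumerate_patterns(3, gapped=False, canonicalize=False)
        assert len(pats) == 4 + 16 + 64
        assert all(not p.is_gapped for p in pats)

    def test_span1_canonical(self):
        pats = enumerate_patterns(1, canonicalize=True)
        assert {p.pattern for p in pats} == {"A", "C"}

    def test_canonicalization_halves_up_to_palindromes(self):
        full = enumerate_patterns(4, canonicalize=False)
        canon = enumerate_patterns(4, canonicalize=True)
        n_palindromes = sum(p.is_palindrome for p in full)
        assert 2 * len(canon) == len(full) + n_palindromes
        assert all(p.canonical for p in canon)
        # every pattern maps to exactly one canonical representative
        reps = {min(p.pattern, reverse_complement(p.pattern)) for p in full}
        assert reps == {p.pattern for p in canon}

    def test_endpoints_always_specified(self):
        assert all(
            p.pattern[0] != "N" and p.pattern[-1] != "N"
            for p in enumerate_patterns(4, canonicalize=False)
        )


class TestCounting:
    @pytest.mark.parametrize(
        "seqs, pattern, expected",
        [
            (["ACGT"], "AC", 2),   # forward AC at 0, RC GT at 2
            (["ACGT"], "ANG", 2),  # ACG at 0; RC CNT matches CGT at 1
            (["ACGT"], "AT", 0),   # palindromic pattern, no occurrence
            (["AATT"], "AT", 1),   # palindromes count once per site
            (["ACGT", "ACGT"], "AC", 4),
        ],
    )
    def test_worked_examples(self, seqs, pattern, expected):
        counts, _ = count_patterns(seqs, [pattern])
        assert counts[0] == expected

    def test_masked_characters_break_scans(self):
        # no k-mer may span the masked gap: segments are "AC" and "GT"
        counts, positions = count_patterns(["ACgtGT"], ["AC", "CG"])
        assert counts[0] == 2  # AC + RC(AC)=GT, one each
        assert counts[1] == 0  # CG only arises across the mask
        assert positions[2] == 2  # two span-2 windows total

    def test_invalid_characters_raise(self):
        with pytest.raises(ValueError, match="non-DNA"):
            count_patterns(["ACXT"], ["AC"])

    def test_oracle_equivalence_random_sequences(self, rng):
        """Streaming table counts equal the regex oracle for gapped patterns."""
        seqs = ["".join(rng.choice(list("ACGT"), size=rng.integers(50, 300)))
                for _ in range(10)]
        pats = [p.pattern for p in enumerate_patterns(4, canonicalize=True)]
        counts, _ = count_patterns(seqs, pats)
        for pattern, got in zip(pats, counts):
            assert got == naive_count(seqs, pattern), pattern

    def test_strand_symmetry_exact(self, rng):
        seqs = ["".join(rng.choice(list("ACGT"), size=200)) for _ in range(5)]
        rc_seqs = [reverse_complement(s) for s in seqs]
        pats = [p.pattern for p in enumerate_patterns(3, canonicalize=True)]
        fwd, _ = count_patterns(seqs, pats)
        rev, _ = count_patterns(rc_seqs, pats)
        assert (fwd == rev).all()

    @settings(deadline=None, max_examples=25)
    @given(st.text(alphabet="ACGT", min_size=8, max_size=120), st.integers(1, 4))
    def test_ungapped_sum_identity(self, seq, k):
        """Canonical ungapped span-k counts sum to L - k + 1 exactly."""
        pats = [p.pattern for p in enumerate_patterns(k, gapped=False, canonicalize=True)
                if p.span == k]
        counts, _ = count_patterns([seq], pats)
        assert counts.sum() == len(seq) - k + 1


class TestMatrix:
    def _cells(self, seq_lists):
        return [RegionSequenceSet(cell_id=f"c{i}", sequences=s)
                for i, s in enumerate(seq_lists)]

    def test_identical_cells_identical_columns(self):
        u = PatternUniverse(3)
        mat = build_matrix(self._cells([["ACGTACGT"], ["ACGTACGT"]]), u)
        np.testing.assert_array_equal(mat.counts[:, 0], mat.counts[:, 1])
        np.testing.assert_allclose(mat.frequencies[:, 0], mat.frequencies[:, 1])

    def test_duplicating_sequences_leaves_frequencies_unchanged(self):
        u = PatternUniverse(3)
        mat = build_matrix(self._cells([["ACGTAC"], ["ACGTAC", "ACGTAC"]]), u)
        np.testing.assert_allclose(mat.frequencies[:, 0], mat.frequencies[:, 1])

    def test_span_specific_frequency_denominator(self):
        u = PatternUniverse(2)
        mat = build_matrix(self._cells([["ACGT"], ["AACC"]]), u)
        i = mat.patterns.index("AC")
        # "ACGT" has 3 span-2 windows and AC occurs twice (AC + RC GT)
        assert mat.counts[i, 0] == 2
        assert mat.frequencies[i, 0] == pytest.approx(2 / 3)

    def test_zero_sequence_cell_raises_with_name(self):
        u = PatternUniverse(2)
        with pytest.raises(ValueError, match="c1"):
            build_matrix(self._cells([["ACGT"], []]), u)

    def test_single_cell_rejected(self):
        with pytest.raises(ValueError):
            build_matrix(self._cells([["ACGT"]]), PatternUniverse(2))
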