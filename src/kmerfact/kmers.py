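"""Gapped k-mer feature space and both-strand counting.

The feature space is the set of gapped DNA words up to a maximum span
(default 8): words over ``{A,C,G,T,N}`` where ``N`` matches any base, ``N``
is allowed only at interior positions, and both endpoints are specified.
Counting is strand-symmetrized: each canonical pattern accumulates forward
occurrences of itself plus forward occurrences of its reverse complement,
with palindromic patterns counted once per site.  Under this accounting the
canonical ungapped span-k counts of an unmasked sequence of length L sum
exactly to L - k + 1.

The counting engine scans each sequence once per span to build an ungapped
k-mer count table (4^k entries), then marginalizes gap positions to obtain
every gapped pattern count in one pass (5^k table) — memory is O(5^max_span)
per cell regardless of sequence length or pattern count.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from functools import cached_property
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .io_regions import RegionSequenceSet

__all__ = [
    "KmerPattern",
    "PatternUniverse",
    "CellKmerMatrix",
    "reverse_complement",
    "enumerate_patterns",
    "count_patterns",
    "build_matrix",
    "write_matrix_tsv",
    "write_matrix_mtx",
]

# digit order A=0, C=1, G=2, N=3, T=4 matches ASCII lexicographic order, so
# integer code comparisons are string comparisons
_ALPHABET = "ACGNT"
_N_DIGIT = 3
_COMPLEMENT5 = np.array([4, 2, 1, 3, 0], dtype=np.int8)  # A<->T, C<->G, N->N
_RC_STR = str.maketrans("ACGTN", "TGCAN")

_SEGMENT_RE = re.compile(r"[^ACGT]+")
_VALID_CHARS = set("ACGTNacgtn")


def reverse_complement(pattern: str) -> str:
    """Reverse complement of a (possibly gapped) DNA word; N maps to N."""
    return pattern.translate(_RC_STR)[::-1]


@dataclass(frozen=True, slots=True)
class KmerPattern:
    """A gapped DNA word over ``{A,C,G,T,N}`` — one feature of the k-mer space."""

    pattern: str

    def __post_init__(self) -> None:
        p = self.pattern
        if not p or any(c not in "ACGTN" for c in p):
            raise ValueError(f"invalid pattern: {p!r}")
        if p[0] == "N" or p[-1] == "N":
            raise ValueError(f"pattern endpoints must be specified: {p!r}")

    @property
    def span(self) -> int:
        return len(self.pattern)

    @property
    def n_specified(self) -> int:
        return sum(c != "N" for c in self.pattern)

    @property
    def is_gapped(self) -> bool:
        return "N" in self.pattern

    @property
    def is_palindrome(self) -> bool:
        return self.pattern == reverse_complement(self.pattern)

    @property
    def canonical(self) -> bool:
        return self.pattern <= reverse_complement(self.pattern)

    def __str__(self) -> str:
        return self.pattern


# ---------------------------------------------------------------------------
# pattern universe
# ---------------------------------------------------------------------------

def _span_digits(k: int) -> np.ndarray:
    """All 5^k digit vectors of length k, in base-5 code order."""
    codes = np.arange(5 ** k, dtype=np.int64)
    place = 5 ** np.arange(k - 1, -1, -1, dtype=np.int64)
    return ((codes[:, None] // place) % 5).astype(np.int8)


def _digits_to_codes(digits: np.ndarray) -> np.ndarray:
    k = digits.shape[1]
    place = 5 ** np.arange(k - 1, -1, -1, dtype=np.int64)
    return digits.astype(np.int64) @ place


def _rc_digits(digits: np.ndarray) -> np.ndarray:
    return _COMPLEMENT5[digits[:, ::-1]]


class PatternUniverse:
    """The enumerated gapped k-mer feature space for spans 1..max_span.

    Precomputes, per span, the base-5 codes of the retained patterns, their
    reverse-complement codes and palindrome flags, so per-cell counting is a
    pair of table gathers.
    """

    def __init__(self, max_span: int = 8, gapped: bool = True, canonicalize: bool = True):
        if not 1 <= max_span <= 12:
            raise ValueError("max_span must be in 1..12")
        self.max_span = max_span
        self.gapped = gapped
        self.canonicalize = canonicalize
        self.spans: list[int] = []
        self._fwd_codes: dict[int, np.ndarray] = {}
        self._rc_codes: dict[int, np.ndarray] = {}
        self._palindrome: dict[int, np.ndarray] = {}
        self._strings: dict[int, list[str]] = {}
        for k in range(1, max_span + 1):
            digits = _span_digits(k)
            keep = (digits[:, 0] != _N_DIGIT) & (digits[:, -1] != _N_DIGIT)
            if not gapped:
                keep &= ~(digits == _N_DIGIT).any(axis=1)
            digits = digits[keep]
            rc = _rc_digits(digits)
            codes = _digits_to_codes(digits)
            rc_codes = _digits_to_codes(rc)
            if canonicalize:
                canon = codes <= rc_codes
                digits, codes, rc_codes = digits[canon], codes[canon], rc_codes[canon]
            self.spans.append(k)
            self._fwd_codes[k] = codes
            self._rc_codes[k] = rc_codes
            self._palindrome[k] = codes == rc_codes
            lut = np.frombuffer(_ALPHABET.encode(), dtype=np.uint8)
            chars = lut[digits]
            self._strings[k] = [bytes(row).decode() for row in chars]

    @cached_property
    def pattern_strings(self) -> list[str]:
        out: list[str] = []
        for k in self.spans:
            out.extend(self._strings[k])
        return out

    @cached_property
    def pattern_spans(self) -> np.ndarray:
        return np.concatenate(
            [np.full(len(self._strings[k]), k, dtype=np.int32) for k in self.spans]
        )

    def __len__(self) -> int:
        return sum(len(self._strings[k]) for k in self.spans)

    def gather_counts(self, tables: dict[int, np.ndarray]) -> np.ndarray:
        """Strand-symmetrized counts for every pattern from per-span tables."""
        parts = []
        for k in self.spans:
            t = tables[k]
            fwd = t[self._fwd_codes[k]]
            rc = t[self._rc_codes[k]]
            parts.append(np.where(self._palindrome[k], fwd, fwd + rc))
        return np.concatenate(parts)


def enumerate_patterns(
    max_span: int = 8, gapped: bool = True, canonicalize: bool = True
) -> list[KmerPattern]:
    """Enumerate the gapped k-mer universe as pattern objects.

    With ``canonicalize`` exactly one of each reverse-complement pair is kept
    (the lexicographically smaller; palindromes once).  The uncanonicalized
    gapped universe has ``4 + sum_{k=2..max} 16 * 5^(k-2)`` members
    (312,500 at max_span 8).
    """
    universe = PatternUniverse(max_span, gapped=gapped, canonicalize=canonicalize)
    return [KmerPattern(p) for p in universe.pattern_strings]


# ---------------------------------------------------------------------------
# scanning
# ---------------------------------------------------------------------------

_ENC4 = np.full(256, -1, dtype=np.int8)
for _i, _c in enumerate("ACGT"):
    _ENC4[ord(_c)] = _i


def _scan_segments(seq: str) -> list[str]:
    """Split a sequence into pure-ACGT scan segments.

    Any character outside A/C/G/T — N, or lowercase repeat-masked bases when
    masking was preserved — breaks the scan so no k-mer spans it.  Characters
    outside the DNA alphabet entirely raise ``ValueError``.
    """
    bad = set(seq) - _VALID_CHARS
    if bad:
        raise ValueError(f"sequence contains non-DNA characters: {sorted(bad)!r}")
    return [s for s in _SEGMENT_RE.split(seq) if s]


def _expand_table(counts4: np.ndarray, k: int) -> np.ndarray:
    """Marginalize an ungapped 4^k count table to the gapped 5^k table.

    Along each position axis the order [A,C,G,T] becomes [A,C,G,N,T] with the
    N slot holding the sum over bases, so that the flat base-5 index of any
    gapped word reads off its occurrence count directly.
    """
    t = counts4.reshape((4,) * k)
    for axis in range(k):
        total = t.sum(axis=axis, keepdims=True)
        idx = [slice(None)] * k
        idx_a = list(idx); idx_a[axis] = slice(0, 3)
        idx_t = list(idx); idx_t[axis] = slice(3, 4)
        t = np.concatenate([t[tuple(idx_a)], total, t[tuple(idx_t)]], axis=axis)
    return t.reshape(-1)


def _span_tables(segments: Sequence[str], max_span: int) -> tuple[dict[int, np.ndarray], np.ndarray]:
    """Per-span gapped count tables and scan-position counts for one cell.

    Returns ``(tables, positions)`` where ``tables[k]`` is the 5^k gapped
    occurrence table and ``positions[k]`` the number of span-k windows
    scanned (index 0 unused).
    """
    positions = np.zeros(max_span + 1, dtype=np.int64)
    counts4 = {k: np.zeros(4 ** k, dtype=np.int64) for k in range(1, max_span + 1)}
    for seg in segments:
        enc = _ENC4[np.frombuffer(seg.encode(), dtype=np.uint8)].astype(np.int64)
        if (enc < 0).any():
            raise ValueError("scan segment contains non-ACGT characters")
        L = len(enc)
        code = None
        for k in range(1, max_span + 1):
            if L < k:
                break
            positions[k] += L - k + 1
            if code is None:
                code = enc.copy()
            else:
                code = code[:-1] * 4 + enc[k - 1:]
            counts4[k] += np.bincount(code, minlength=4 ** k)
    tables = {k: _expand_table(counts4[k], k) for k in range(1, max_span + 1)}
    return tables, positions


def count_patterns(
    sequences: RegionSequenceSet | Sequence[str],
    patterns: Sequence[KmerPattern | str],
) -> tuple[np.ndarray, np.ndarray]:
    """Count strand-symmetrized occurrences of each pattern in one cell.

    ``sequences`` may be a :class:`RegionSequenceSet` or raw strings; masked
    (lowercase) and ambiguous characters act as scan breaks.  Returns
    ``(counts, scan_positions)`` with ``counts`` aligned to ``patterns`` and
    ``scan_positions[k]`` the number of span-k windows scanned.
    """
    seqs = sequences.sequences if isinstance(sequences, RegionSequenceSet) else list(sequences)
    pats = [p.pattern if isinstance(p, KmerPattern) else str(p) for p in patterns]
    for p in pats:
        KmerPattern(p)  # validate
    max_span = max((len(p) for p in pats), default=1)
    segments = [s for seq in seqs for s in _scan_segments(seq)]
    tables, positions = _span_tables(segments, max_span)
    out = np.zeros(len(pats), dtype=np.int64)
    trans = str.maketrans(_ALPHABET, "01234")
    for i, p in enumerate(pats):
        k = len(p)
        code = int(p.translate(trans), 5)
        rc = reverse_complement(p)
        rc_code = int(rc.translate(trans), 5)
        out[i] = tables[k][code]
        if rc_code != code:
            out[i] += tables[k][rc_code]
    return out, positions


# ---------------------------------------------------------------------------
# matrix
# ---------------------------------------------------------------------------

@dataclass
class CellKmerMatrix:
    """K-mer occurrence counts (patterns x cells) with per-cell scan sizes.

    ``frequencies`` divides each count by the number of positions scanned for
    that pattern's span in that cell, so cells with different numbers of
    accessible loci are comparable.
    """

    patterns: list[str]
    cells: list[str]
    counts: np.ndarray  # (n_patterns, n_cells) int
    scan_positions: np.ndarray  # (n_cells, max_span + 1) int
    pattern_spans: np.ndarray  # (n_patterns,) int

    @property
    def frequencies(self) -> np.ndarray:
        denom = self.scan_positions[:, self.pattern_spans].T.astype(float)
        with np.errstate(divide="ignore", invalid="ignore"):
            f = self.counts / denom
        return np.nan_to_num(f, nan=0.0, posinf=0.0)

    def subset_patterns(self, keep: np.ndarray) -> "CellKmerMatrix":
        return CellKmerMatrix(
            patterns=[p for p, k in zip(self.patterns, keep) if k],
            cells=self.cells,
            counts=self.counts[keep],
            scan_positions=self.scan_positions,
            pattern_spans=self.pattern_spans[keep],
        )


def build_matrix(
    cells: Sequence[RegionSequenceSet],
    universe: PatternUniverse,
) -> CellKmerMatrix:
    """Count the full pattern universe in every cell.

    Raises on cells with zero scannable positions (no usable sequence).
    """
    if len(cells) < 2:
        raise ValueError("need at least 2 cells to build a matrix")
    n_pat = len(universe)
    counts = np.zeros((n_pat, len(cells)), dtype=np.int64)
    scan_pos = np.zeros((len(cells), universe.max_span + 1), dtype=np.int64)
    for j, cell in enumerate(cells):
        segments = [s for seq in cell.sequences for s in _scan_segments(seq)]
        tables, positions = _span_tables(segments, universe.max_span)
        if positions[1] == 0:
            raise ValueError(f"cell {cell.cell_id!r} has zero scannable positions")
        counts[:, j] = universe.gather_counts(tables)
        scan_pos[j] = positions
    return CellKmerMatrix(
        patterns=universe.pattern_strings,
        cells=[c.cell_id for c in cells],
        counts=counts,
        scan_positions=scan_pos,
        pattern_spans=universe.pattern_spans,
    )


def write_matrix_tsv(matrix: CellKmerMatrix, path: str | Path) -> None:
    import pandas as pd

    pd.DataFrame(matrix.frequencies, index=matrix.patterns, columns=matrix.cells) \
        .to_csv(path, sep="\t", index_label="pattern")


def write_matrix_mtx(matrix: CellKmerMatrix, prefix: str | Path) -> None:
    """Write counts as MatrixMarket triple (matrix.mtx, patterns.txt, cells.txt)."""
    from scipy import io as spio
    from scipy import sparse

    prefix = Path(prefix)
    spio.mmwrite(str(prefix / "matrix.mtx"), sparse.coo_matrix(matrix.counts))
    (prefix / "patterns.txt").write_text("\n".join(matrix.patterns) + "\n")
    (prefix / "cells.txt").write_text("\n".join(matrix.cells) + "\n")
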