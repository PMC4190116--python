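"""Pairwise global alignment and percent identity.

This is the in-house stand-in for the heuristic database search used in
barcode-gap identification workflows: every query/reference comparison is a
full semi-global alignment (Needleman–Wunsch with free end gaps) under a fixed
scoring scheme, and *percent identity* is the fraction of matching columns
among all compared columns.

Identity semantics
------------------
* End-gap columns (the unaligned overhangs allowed for free) are excluded from
  the denominator, so an exact-but-shorter clone still scores 100%.
* Internal gap columns count against identity.
* IUPAC ambiguity codes match whenever the two symbols' base sets intersect
  (``N`` matches everything); a gap never matches.

The dynamic-programming engine is :class:`Bio.Align.PairwiseAligner` with a
custom IUPAC intersection substitution matrix; traceback is deterministic
(the aligner's first optimal alignment).
"""

from __future__ import annotations

import functools
from dataclasses import dataclass

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

from .errors import ValidationError
from .refdb import IUPAC_DNA, normalize_sequence

#: 4-bit base sets for the IUPAC nucleotide codes (A=1, C=2, G=4, T=8).
IUPAC_MASKS: dict[str, int] = {
    "A": 1, "C": 2, "G": 4, "T": 8,
    "R": 1 | 4, "Y": 2 | 8, "S": 4 | 2, "W": 1 | 8,
    "K": 4 | 8, "M": 1 | 2,
    "B": 2 | 4 | 8, "D": 1 | 4 | 8, "H": 1 | 2 | 8, "V": 1 | 2 | 4,
    "N": 1 | 2 | 4 | 8,
}

_MASK_LUT = np.zeros(256, dtype=np.uint8)
for _ch, _m in IUPAC_MASKS.items():
    _MASK_LUT[ord(_ch)] = _m


@dataclass(frozen=True)
class ScoringScheme:
    """Alignment scoring: match/mismatch plus linear-ish gap penalties.

    End gaps are always free (semi-global alignment); these parameters govern
    matches, mismatches and internal gaps only.
    """

    match: int = 1
    mismatch: int = -1
    gap_open: int = -2
    gap_extend: int = -2


DEFAULT_SCORING = ScoringScheme()


@dataclass(frozen=True)
class AlignmentResult:
    """A pairwise alignment with its column classification and identity."""

    aligned_a: str
    aligned_b: str
    score: int
    matches: int
    mismatches: int
    internal_gap_columns: int
    end_gap_columns: int
    identity: float

    def __len__(self) -> int:
        return len(self.aligned_a)


def bases_match(x: str, y: str) -> bool:
    """True iff the two IUPAC symbols' base sets intersect; gaps never match."""
    if x == "-" or y == "-":
        return False
    try:
        return bool(IUPAC_MASKS[x] & IUPAC_MASKS[y])
    except KeyError as exc:
        raise ValidationError(f"not an IUPAC nucleotide code: {exc}") from exc


def encode_masks(seq: str) -> np.ndarray:
    """Encode a DNA string as a vector of 4-bit IUPAC base-set masks."""
    arr = _MASK_LUT[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    if (arr == 0).any():
        pos = int(np.argmax(arr == 0))
        raise ValidationError(
            f"illegal character {seq[pos]!r} at position {pos + 1}"
        )
    return arr


def ungapped_identity(a: str, b: str) -> float:
    """Identity of the ungapped (position-by-position) alignment of two
    equal-length sequences. A cheap exact lower bound used for screening."""
    if len(a) != len(b):
        raise ValidationError("ungapped identity requires equal lengths")
    ma, mb = encode_masks(a), encode_masks(b)
    return float(np.count_nonzero(ma & mb)) / len(a)


@functools.lru_cache(maxsize=8)
def _aligner(scoring: ScoringScheme) -> Align.PairwiseAligner:
    letters = "".join(sorted(IUPAC_DNA))
    matrix = substitution_matrices.Array(letters, dims=2)
    for x in letters:
        for y in letters:
            matrix[x, y] = (
                scoring.match if IUPAC_MASKS[x] & IUPAC_MASKS[y] else scoring.mismatch
            )
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = matrix
    aligner.open_gap_score = scoring.gap_open
    aligner.extend_gap_score = scoring.gap_extend
    # free end gaps: semi-global alignment
    aligner.open_end_insertion_score = 0
    aligner.extend_end_insertion_score = 0
    aligner.open_end_deletion_score = 0
    aligner.extend_end_deletion_score = 0
    return aligner


def classify_columns(aligned_a: str, aligned_b: str) -> tuple[int, int, int, int]:
    """Count (matches, mismatches, internal gap columns, end gap columns).

    End gaps are the columns before the first, and after the last, column in
    which both sequences carry a residue.
    """
    n = len(aligned_a)
    if n != len(aligned_b):
        raise ValidationError("aligned strings differ in length")
    both = [i for i in range(n) if aligned_a[i] != "-" and aligned_b[i] != "-"]
    if not both:
        return 0, 0, 0, n
    first, last = both[0], both[-1]
    end_gaps = first + (n - 1 - last)
    matches = mismatches = internal_gaps = 0
    for i in range(first, last + 1):
        x, y = aligned_a[i], aligned_b[i]
        if x == "-" or y == "-":
            internal_gaps += 1
        elif bases_match(x, y):
            matches += 1
        else:
            mismatches += 1
    return matches, mismatches, internal_gaps, end_gaps


def global_align(
    a: str, b: str, scoring: ScoringScheme = DEFAULT_SCORING
) -> AlignmentResult:
    """Optimal semi-global alignment of two IUPAC DNA sequences.

    Raises :class:`ValidationError` on empty or non-IUPAC input.
    """
    a = normalize_sequence(a, context="sequence a")
    b = normalize_sequence(b, context="sequence b")
    alignment = _aligner(scoring).align(a, b)[0]
    aligned_a, aligned_b = alignment[0], alignment[1]
    matches, mismatches, internal_gaps, end_gaps = classify_columns(
        aligned_a, aligned_b
    )
    compared = len(aligned_a) - end_gaps
    identity = matches / compared if compared else 0.0
    return AlignmentResult(
        aligned_a=aligned_a,
        aligned_b=aligned_b,
        score=int(round(alignment.score)),
        matches=matches,
        mismatches=mismatches,
        internal_gap_columns=internal_gaps,
        end_gap_columns=end_gaps,
        identity=identity,
    )


def percent_identity(
    a: str, b: str, scoring: ScoringScheme = DEFAULT_SCORING
) -> float:
    """Percent identity of the optimal semi-global alignment (0–100).

    The unrounded value; reports render it to one decimal place.
    """
    return 100.0 * global_align(a, b, scoring).identity


def format_identity(pct: float) -> str:
    """Render a percent identity the way assignment reports print it."""
    return f"{pct:.1f}"
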