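"""Independent oracles used by the test suite.

These deliberately re-derive results by a different route than the package:
a plain-Python free-end-gap DP for alignment scores, a full recursive
enumeration of alignments for very short sequences, and a breadth-first
connected-components pass for single-linkage clustering.
"""

from __future__ import annotations

import random

MATCH, MISMATCH, GAP = 1, -1, -2


def oracle_semiglobal_score(a: str, b: str) -> int:
    """Optimal semi-global score by a plain tabular DP (end gaps free)."""
    n, m = len(a), len(b)
    dp = [[0] * (m + 1) for _ in range(n + 1)]
    for i in range(n + 1):
        dp[i][0] = 0
    for j in range(m + 1):
        dp[0][j] = 0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            sub = MATCH if a[i - 1] == b[j - 1] else MISMATCH
            dp[i][j] = max(
                dp[i - 1][j - 1] + sub, dp[i - 1][j] + GAP, dp[i][j - 1] + GAP
            )
    best = 0
    for i in range(n + 1):
        best = max(best, dp[i][m])
    for j in range(m + 1):
        best = max(best, dp[n][j])
    return best


def enumerate_alignments(a: str, b: str):
    """All gapped alignments of a and b (exponential; tiny inputs only)."""
    if not a and not b:
        yield ("", "")
        return
    if a:
        for xa, xb in enumerate_alignments(a[1:], b):
            yield (a[0] + xa, "-" + xb)
    if b:
        for xa, xb in enumerate_alignments(a, b[1:]):
            yield ("-" + xa, b[0] + xb)
    if a and b:
        for xa, xb in enumerate_alignments(a[1:], b[1:]):
            yield (a[0] + xa, b[0] + xb)


def _end_run_columns(aligned: str) -> set[int]:
    """Columns belonging to the leading/trailing gap run of one sequence."""
    cols: set[int] = set()
    i = 0
    while i < len(aligned) and aligned[i] == "-":
        cols.add(i)
        i += 1
    i = len(aligned) - 1
    while i >= 0 and aligned[i] == "-":
        cols.add(i)
        i -= 1
    return cols


def score_alignment_free_ends(aligned_a: str, aligned_b: str) -> int:
    """Score a gapped alignment; a sequence's leading/trailing gap runs are
    free, every other gap column costs the gap penalty."""
    free = _end_run_columns(aligned_a) | _end_run_columns(aligned_b)
    score = 0
    for i, (x, y) in enumerate(zip(aligned_a, aligned_b)):
        if x == "-" or y == "-":
            if i not in free:
                score += GAP
        elif x == y:
            score += MATCH
        else:
            score += MISMATCH
    return score


def oracle_enumeration_score(a: str, b: str) -> int:
    return max(
        score_alignment_free_ends(xa, xb) for xa, xb in enumerate_alignments(a, b)
    )


def bfs_single_linkage(n: int, linked) -> list[frozenset]:
    """Connected components of the linkage relation, by BFS."""
    seen = [False] * n
    components = []
    for start in range(n):
        if seen[start]:
            continue
        queue, comp = [start], set()
        seen[start] = True
        while queue:
            i = queue.pop()
            comp.add(i)
            for j in range(n):
                if not seen[j] and linked(i, j):
                    seen[j] = True
                    queue.append(j)
        components.append(frozenset(comp))
    return components


def random_dna(rng: random.Random, length: int) -> str:
    return "".join(rng.choice("ACGT") for _ in range(length))


def with_substitutions(rng: random.Random, seq: str, positions: list[int]) -> str:
    out = list(seq)
    for p in positions:
        out[p] = rng.choice([c for c in "ACGT" if c != out[p]])
    return "".join(out)
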