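"""Dereplication of clone reads into MOTUs (molecular operational taxonomic
units) and per-MOTU consensus building.

Clone libraries carry sequencing/cloning noise of one or two substitutions per
read, so reads from one source plant form a tight cloud around the true
template. Reads are grouped by single-linkage clustering: two reads link when
their optimal semi-global alignment has at most ``max_mismatches`` mismatch
columns and no internal gap run longer than ``max_mismatches``. Single linkage
means chains can extend a cluster beyond that radius; that is accepted
behaviour, not a defect.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ValidationError
from .identity import (
    DEFAULT_SCORING,
    ScoringScheme,
    encode_masks,
    global_align,
)
from .refdb import MARKERS, normalize_sequence


@dataclass(frozen=True)
class CloneRead:
    """One cloned barcode sequence from a (site, date, marker) library.

    ``truth_species`` is only populated by the simulator, for evaluation;
    contaminant reads carry a ``contaminant:``-prefixed label there.
    """

    read_id: str
    site: str
    date: str
    marker: str
    sequence: str
    truth_species: str | None = None

    def validate(self) -> "CloneRead":
        if self.marker not in MARKERS:
            raise ValidationError(
                f"read {self.read_id!r}: marker {self.marker!r} not in {MARKERS}"
            )
        normalize_sequence(self.sequence, context=f"read {self.read_id!r}")
        return self


@dataclass
class MOTU:
    """A cluster of near-identical clone reads treated as one putative taxon."""

    motu_id: str
    members: list[CloneRead]
    representative: str
    consensus: str

    @property
    def n_clones(self) -> int:
        return len(self.members)

    @property
    def site(self) -> str:
        return self.members[0].site

    @property
    def date(self) -> str:
        return self.members[0].date

    @property
    def marker(self) -> str:
        return self.members[0].marker


# Equal-length reads of at least this length are linked by Hamming distance
# directly: for length-conserved amplicons (substitution-only divergence) the
# optimal alignment under the default scheme never pays for internal gaps, so
# the ungapped mismatch count is the alignment mismatch count. Shorter or
# unequal-length reads always get the full alignment-based test.
_HAMMING_ONLY_MIN_LEN = 100


def _max_gap_run(aligned: str, first: int, last: int) -> int:
    run = best = 0
    for i in range(first, last + 1):
        if aligned[i] == "-":
            run += 1
            best = max(best, run)
        else:
            run = 0
    return best


def reads_linked(
    a: CloneRead,
    b: CloneRead,
    max_mismatches: int = 2,
    scoring: ScoringScheme = DEFAULT_SCORING,
) -> bool:
    """Linkage test on the optimal alignment of two reads.

    The sequence pair is put in a canonical order first: co-optimal
    alignments can differ between (a, b) and (b, a), and the linkage
    relation must be symmetric.
    """
    seq_a, seq_b = sorted((a.sequence, b.sequence))
    result = global_align(seq_a, seq_b, scoring)
    if result.mismatches > max_mismatches:
        return False
    n = len(result.aligned_a)
    both = [
        i
        for i in range(n)
        if result.aligned_a[i] != "-" and result.aligned_b[i] != "-"
    ]
    if not both:
        return False
    first, last = both[0], both[-1]
    longest = max(
        _max_gap_run(result.aligned_a, first, last),
        _max_gap_run(result.aligned_b, first, last),
    )
    return longest <= max_mismatches


def _representative(sequences: list[str]) -> str:
    counts = Counter(sequences)
    top = max(counts.values())
    return min(s for s, c in counts.items() if c == top)


def _consensus_equal_length(sequences: list[str], representative: str) -> str:
    arr = np.array([list(s) for s in sequences])
    out = []
    for j in range(arr.shape[1]):
        col = Counter(arr[:, j])
        top = max(col.values())
        winners = {base for base, c in col.items() if c == top}
        rep_base = representative[j]
        out.append(rep_base if rep_base in winners else min(winners))
    return "".join(out)


def consensus(motu: MOTU, scoring: ScoringScheme = DEFAULT_SCORING) -> str:
    """Column-wise majority consensus of a MOTU's members.

    For equal-length members this is a straight per-column majority vote with
    ties resolved toward the representative's base. Otherwise each member is
    aligned to the representative and the vote is taken per representative
    position (insertions relative to the representative are dropped; a column
    where the majority is a deletion is dropped too).
    """
    if not motu.members:
        raise ValidationError("consensus of an empty MOTU is undefined")
    sequences = [m.sequence for m in motu.members]
    if len(set(sequences)) == 1:
        return sequences[0]
    if len({len(s) for s in sequences}) == 1:
        return _consensus_equal_length(sequences, motu.representative)

    rep = motu.representative
    columns: list[Counter] = [Counter() for _ in rep]
    for seq in sequences:
        result = global_align(rep, seq, scoring)
        pos = -1
        for x, y in zip(result.aligned_a, result.aligned_b):
            if x == "-":
                continue  # insertion relative to representative
            pos += 1
            columns[pos][y] += 1  # y may be '-' (deletion)
    out = []
    for j, col in enumerate(columns):
        top = max(col.values())
        winners = {base for base, c in col.items() if c == top}
        pick = rep[j] if rep[j] in winners else min(winners)
        if pick != "-":
            out.append(pick)
    return "".join(out)


def cluster_motus(
    reads: list[CloneRead],
    max_mismatches: int = 2,
    scoring: ScoringScheme = DEFAULT_SCORING,
) -> list[MOTU]:
    """Single-linkage clustering of one library's reads into MOTUs.

    All reads must share (site, date, marker). MOTUs are sorted by descending
    clone count, then lexicographically by representative sequence, and their
    ids are assigned after sorting; the result is invariant to input order.
    With ``max_mismatches=0`` this reduces to exact dereplication.
    """
    if not reads:
        return []
    reads = [r.validate() for r in reads]
    keys = {(r.site, r.date, r.marker) for r in reads}
    if len(keys) > 1:
        raise ValidationError(
            f"cluster_motus requires one (site, date, marker) library, got {sorted(keys)}"
        )

    n = len(reads)
    order = sorted(range(n), key=lambda i: (reads[i].read_id, reads[i].sequence))
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i: int, j: int) -> None:
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[ri] = rj

    masks = [encode_masks(r.sequence) for r in reads]
    for ii in range(n):
        i = order[ii]
        for jj in range(ii + 1, n):
            j = order[jj]
            if find(i) == find(j):
                continue
            a, b = reads[i], reads[j]
            if (
                len(a.sequence) == len(b.sequence)
                and len(a.sequence) >= _HAMMING_ONLY_MIN_LEN
            ):
                hamming = len(a.sequence) - int(
                    np.count_nonzero(masks[i] & masks[j])
                )
                if hamming <= max_mismatches:
                    union(i, j)
                continue
            if reads_linked(a, b, max_mismatches, scoring):
                union(i, j)

    clusters: dict[int, list[CloneRead]] = {}
    for i in range(n):
        clusters.setdefault(find(i), []).append(reads[i])

    motus = []
    for members in clusters.values():
        members = sorted(members, key=lambda r: (r.read_id, r.sequence))
        rep = _representative([m.sequence for m in members])
        motu = MOTU(motu_id="", members=members, representative=rep, consensus="")
        motu.consensus = consensus(motu, scoring)
        motus.append(motu)
    motus.sort(key=lambda m: (-m.n_clones, m.representative))
    for k, motu in enumerate(motus, start=1):
        motu.motu_id = f"M{k:03d}"
    return motus


def write_motus(
    motus: list[MOTU], fasta_path: str | Path, tsv_path: str | Path
) -> None:
    """Write MOTU consensus sequences (FASTA) and a clone-count table (TSV)."""
    with open(fasta_path, "w") as fh:
        for m in motus:
            fh.write(f">{m.site}|{m.date}|{m.marker}|{m.motu_id}\n")
            for i in range(0, len(m.consensus), 80):
                fh.write(m.consensus[i : i + 80] + "\n")
    pd.DataFrame(
        [
            {
                "motu_id": m.motu_id,
                "site": m.site,
                "date": m.date,
                "marker": m.marker,
                "n_clones": m.n_clones,
            }
            for m in motus
        ],
        columns=["motu_id", "site", "date", "marker", "n_clones"],
    ).to_csv(tsv_path, sep="\t", index=False)
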