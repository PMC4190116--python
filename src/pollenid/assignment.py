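"""Taxonomic assignment of MOTUs against the reference database.

Each MOTU consensus is compared with every reference record of its marker and
receives a ranked hit list of percent identities. Calls follow a fixed
identity threshold (default 99%):

* no hit at or above threshold        → ``unidentifiable``
* one species among qualifying hits   → species-level call
* several species, one genus          → genus-level call (``"Genus sp."``)
* several genera                      → ``ambiguous_multi_genus`` (hit list kept)

rbcL frequently leaves congeneric ties at or above threshold; the more
variable trnH-psbA spacer usually resolves them. ``reconcile_markers``
combines the two single-marker calls, preferring the more specific one and,
at equal specificity, the configured precedence marker (trnH-psbA by
default). Species-level disagreement between markers is flagged as a
conflict, never silently merged.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import edlib

from .errors import ValidationError
from .identity import (
    DEFAULT_SCORING,
    ScoringScheme,
    encode_masks,
    percent_identity,
)
from .refdb import ReferenceDB, normalize_sequence

CALL_SPECIES = "species"
CALL_GENUS = "genus"
CALL_AMBIGUOUS = "ambiguous_multi_genus"
CALL_UNIDENTIFIABLE = "unidentifiable"

_SPECIFICITY = {
    CALL_SPECIES: 3,
    CALL_GENUS: 2,
    CALL_AMBIGUOUS: 1,
    CALL_UNIDENTIFIABLE: 0,
}

#: Candidate window for the exact-alignment pass of ``match_reference``:
#: the full alignment runs for references whose screening identity reaches
#: within this many points of the best screen AND is at least
#: ``EXACT_MIN_PCT``; everything else keeps its screening value. References
#: below 94% can never influence a 99%-threshold call, so their exact
#: identities are not worth a full dynamic program each.
PREFILTER_MARGIN_PCT = 5.0
EXACT_MIN_PCT = 94.0


@dataclass(frozen=True)
class MatchHit:
    """One reference species with its percent identity to the query."""

    species: str
    genus: str
    identity_pct: float
    marker: str


@dataclass
class AssignmentResult:
    """Ranked hits plus the final taxonomic call for one MOTU × marker."""

    motu_id: str
    marker: str
    hits: list[MatchHit]
    call_level: str
    call_name: str
    qualifying_hits: list[MatchHit]
    threshold_pct: float = 99.0
    conflict_with: str | None = None

    @property
    def conflict(self) -> bool:
        return self.conflict_with is not None


def _screen_identities(query: str, refs) -> list[float]:
    """Cheap per-reference identity screen (fraction, 0–1).

    Equal-length pairs use the exact ungapped identity; unequal lengths fall
    back to a global edit-distance bound. Both are the identities of *valid*
    alignments, so a screened-out reference still reports a meaningful value.
    """
    qmask = encode_masks(query)
    lq = len(query)
    out = []
    for ref in refs:
        if len(ref.sequence) == lq:
            rmask = encode_masks(ref.sequence)
            out.append(float((qmask & rmask).astype(bool).sum()) / lq)
        else:
            d = edlib.align(query, ref.sequence, mode="NW", task="distance")[
                "editDistance"
            ]
            lmax = max(lq, len(ref.sequence))
            out.append(max(0.0, (lmax - d) / lmax))
    return out


def match_reference(
    query: str,
    db: ReferenceDB,
    marker: str,
    scoring: ScoringScheme = DEFAULT_SCORING,
    prefilter: bool = True,
) -> list[MatchHit]:
    """One hit per (species, marker) reference, sorted by identity then name.

    With ``prefilter`` (the default), the full semi-global alignment is run
    only for references whose screening identity reaches within
    :data:`PREFILTER_MARGIN_PCT` points of the best screen; distant references
    report their screening identity. ``prefilter=False`` aligns everything.
    """
    query = normalize_sequence(query, context="query")
    refs = db.for_marker(marker)
    if not refs:
        raise ValidationError(f"reference database has no records for {marker!r}")

    if prefilter:
        screens = _screen_identities(query, refs)
        cutoff = max(
            max(screens) - PREFILTER_MARGIN_PCT / 100.0, EXACT_MIN_PCT / 100.0
        )
    else:
        screens = [None] * len(refs)
        cutoff = None

    hits = []
    for ref, screen in zip(refs, screens):
        if screen is None or screen >= cutoff:
            pct = percent_identity(query, ref.sequence, scoring)
        else:
            pct = 100.0 * screen
        hits.append(
            MatchHit(
                species=ref.species,
                genus=ref.genus,
                identity_pct=pct,
                marker=marker,
            )
        )
    hits.sort(key=lambda h: (-h.identity_pct, h.species))
    return hits


def _check_sorted(hits: list[MatchHit]) -> None:
    for prev, cur in zip(hits, hits[1:]):
        if cur.identity_pct > prev.identity_pct or (
            cur.identity_pct == prev.identity_pct and cur.species < prev.species
        ):
            raise ValidationError(
                "hits must be sorted by identity desc, species asc "
                "(as produced by match_reference)"
            )


def assign_taxonomy(
    hits: list[MatchHit],
    threshold_pct: float = 99.0,
    motu_id: str = "",
    species_rule: str = "unique_qualifying",
) -> AssignmentResult:
    """Apply the identity threshold and collapse hits into a taxonomic call.

    ``species_rule`` chooses how strict a species-level call is:

    * ``"unique_qualifying"`` (default): all hits at/above threshold must name
      one single species — a 99.6% congener beside a 100% hit demotes the call
      to genus level.
    * ``"top_hit"``: only the top-identity stratum must be a single species.

    Threshold comparison uses unrounded identities; the one-decimal rendering
    in reports is display-only.
    """
    if not 0.0 < threshold_pct <= 100.0:
        raise ValidationError(f"threshold_pct out of range: {threshold_pct}")
    if species_rule not in ("unique_qualifying", "top_hit"):
        raise ValidationError(f"unknown species_rule {species_rule!r}")
    _check_sorted(hits)
    marker = hits[0].marker if hits else ""
    qualifying = [h for h in hits if h.identity_pct >= threshold_pct]

    if not qualifying:
        level, name = CALL_UNIDENTIFIABLE, "unidentifiable"
    else:
        if species_rule == "top_hit":
            top = qualifying[0].identity_pct
            pool = [h for h in qualifying if h.identity_pct == top]
        else:
            pool = qualifying
        species = {h.species for h in pool}
        genera = {h.genus for h in pool}
        if len(species) == 1:
            level, name = CALL_SPECIES, pool[0].species
        elif len(genera) == 1:
            level, name = CALL_GENUS, f"{pool[0].genus} sp."
        else:
            level, name = CALL_AMBIGUOUS, "ambiguous"

    return AssignmentResult(
        motu_id=motu_id,
        marker=marker,
        hits=hits,
        call_level=level,
        call_name=name,
        qualifying_hits=qualifying,
        threshold_pct=threshold_pct,
    )


def reconcile_markers(
    r_rbcl: AssignmentResult | None,
    r_trnh: AssignmentResult | None,
    precedence: str = "trnH-psbA",
) -> AssignmentResult:
    """Combine the two single-marker calls for one putative taxon.

    The more specific call wins (species > genus > ambiguous > unidentifiable);
    at equal specificity the ``precedence`` marker wins. Two species-level
    calls that disagree yield the precedence marker's call with
    ``conflict_with`` set to the other name.
    """
    if r_rbcl is None and r_trnh is None:
        raise ValidationError("reconcile_markers needs at least one marker result")
    if r_rbcl is None:
        return r_trnh
    if r_trnh is None:
        return r_rbcl

    preferred, other = (
        (r_trnh, r_rbcl) if precedence == "trnH-psbA" else (r_rbcl, r_trnh)
    )
    s_pref = _SPECIFICITY[preferred.call_level]
    s_other = _SPECIFICITY[other.call_level]
    if s_other > s_pref:
        winner, loser = other, preferred
    else:
        winner, loser = preferred, other

    if (
        winner.call_level == CALL_SPECIES
        and loser.call_level == CALL_SPECIES
        and winner.call_name != loser.call_name
    ):
        return replace(winner, conflict_with=loser.call_name)
    return winner


def flag_for_external_lookup(result: AssignmentResult) -> bool:
    """True iff the MOTU should be escalated to an external (e.g. public
    nucleotide collection) search — only sub-threshold MOTUs are."""
    return result.call_level == CALL_UNIDENTIFIABLE


def hits_display(result: AssignmentResult) -> str:
    """Human-readable hit list: all qualifying hits, else the top three."""
    shown = result.qualifying_hits if result.qualifying_hits else result.hits[:3]
    return " ".join(f"{h.species} ({h.identity_pct:.1f})" for h in shown)
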