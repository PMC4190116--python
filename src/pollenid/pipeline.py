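"""End-to-end drivers: configuration, per-library assignment, two-marker
reconciliation, community tables and scenario evaluation.

The stages mirror how a mixed-pollen barcoding study is analysed: clone
libraries are clustered into MOTUs per (site, date, marker); each MOTU
consensus is matched against the reference database and called through the
identity threshold; the two markers' calls for one sample are then paired by
genus and reconciled into a single taxon list; taxon lists across sites and
dates become the presence/absence community matrix.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from .assignment import (
    CALL_AMBIGUOUS,
    CALL_GENUS,
    CALL_SPECIES,
    CALL_UNIDENTIFIABLE,
    AssignmentResult,
    assign_taxonomy,
    hits_display,
    match_reference,
    reconcile_markers,
)
from .community import build_presence_absence, genus_of, make_composition
from .errors import ValidationError
from .identity import ScoringScheme, percent_identity
from .motu import MOTU, CloneRead, cluster_motus
from .refdb import MARKER_RBCL, MARKER_TRNH, MARKERS, ReferenceDB

logger = logging.getLogger("pollenid")


@dataclass(frozen=True)
class PipelineConfig:
    """Tunable parameters of the identification pipeline.

    Defaults encode the published analysis conditions: a 99% identity
    threshold for taxonomic assignment, a 2-mismatch MOTU clustering radius
    matching the observed 1–2 substitutions per clone, trnH-psbA precedence
    at equal call specificity, and 1,000 rarefaction iterations.
    """

    threshold_pct: float = 99.0
    motu_max_mismatches: int = 2
    scoring: ScoringScheme = field(default_factory=ScoringScheme)
    marker_precedence: str = MARKER_TRNH
    species_rule: str = "unique_qualifying"
    n_iterations: int = 1000
    count_unidentifiable: bool = True
    seed: int = 0

    def validate(self) -> "PipelineConfig":
        if not 0.0 < self.threshold_pct <= 100.0:
            raise ValidationError(f"threshold_pct out of range: {self.threshold_pct}")
        if self.motu_max_mismatches < 0:
            raise ValidationError("motu_max_mismatches must be >= 0")
        if self.marker_precedence not in MARKERS:
            raise ValidationError(
                f"marker_precedence must be one of {MARKERS}"
            )
        if self.n_iterations < 1:
            raise ValidationError("n_iterations must be >= 1")
        return self

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["scoring"] = dataclasses.asdict(self.scoring)
        return d

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        data = dict(data)
        if "scoring" in data and isinstance(data["scoring"], dict):
            data["scoring"] = ScoringScheme(**data["scoring"])
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data).validate()

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:12]


@dataclass
class SampleResult:
    """MOTUs and their assignments for one (site, date, marker) library."""

    site: str
    date: str
    marker: str
    n_reads: int
    motus: list[MOTU]
    assignments: dict[str, AssignmentResult]  # motu_id -> result


@dataclass
class ReconciledTaxon:
    """One taxon row of a per-sample report, combined across markers."""

    site: str
    date: str
    call_name: str
    call_level: str
    n_clones: dict[str, int]  # marker -> clones
    motu_ids: dict[str, list[str]]
    conflict_with: str | None = None


def assign_library(
    reads: list[CloneRead], db: ReferenceDB, config: PipelineConfig
) -> SampleResult:
    """Cluster one library into MOTUs and assign each consensus."""
    config = config.validate()
    if not reads:
        raise ValidationError("empty clone library")
    site, date, marker = reads[0].site, reads[0].date, reads[0].marker
    motus = cluster_motus(reads, config.motu_max_mismatches, config.scoring)
    assignments = {}
    for motu in motus:
        hits = match_reference(motu.consensus, db, marker, config.scoring)
        assignments[motu.motu_id] = assign_taxonomy(
            hits,
            threshold_pct=config.threshold_pct,
            motu_id=motu.motu_id,
            species_rule=config.species_rule,
        )
    logger.info(
        "assigned %s|%s|%s: %d reads -> %d MOTUs",
        site, date, marker, len(reads), len(motus),
    )
    return SampleResult(
        site=site,
        date=date,
        marker=marker,
        n_reads=len(reads),
        motus=motus,
        assignments=assignments,
    )


def _genus_keys(result: AssignmentResult) -> set[str]:
    if result.call_level in (CALL_SPECIES, CALL_GENUS):
        return {genus_of(result.call_name)}
    if result.call_level == CALL_AMBIGUOUS:
        return {h.genus for h in result.qualifying_hits}
    return set()


def reconcile_sample(
    per_marker: dict[str, SampleResult], config: PipelineConfig
) -> list[ReconciledTaxon]:
    """Pair the two markers' MOTU calls for one (site, date) and reconcile.

    Pairing is by genus compatibility: an assignment pairs with an
    other-marker assignment whose qualifying genera intersect its own
    (identical call names are preferred). Unpaired calls pass through;
    unidentifiable MOTUs are pooled into one "unidentifiable" row per sample.
    Rows sharing the reconciled name are merged, summing clone counts.
    """
    config = config.validate()
    if not per_marker:
        raise ValidationError("reconcile_sample needs at least one marker result")
    sites = {(r.site, r.date) for r in per_marker.values()}
    if len(sites) > 1:
        raise ValidationError(f"mixed samples in reconcile_sample: {sorted(sites)}")
    site, date = next(iter(sites))

    def identified(res: SampleResult | None):
        if res is None:
            return []
        return [
            (m, res.assignments[m.motu_id])
            for m in res.motus
            if res.assignments[m.motu_id].call_level != CALL_UNIDENTIFIABLE
        ]

    r_rbcl = per_marker.get(MARKER_RBCL)
    r_trnh = per_marker.get(MARKER_TRNH)
    rbcl_items = identified(r_rbcl)
    trnh_items = identified(r_trnh)

    consumed: set[int] = set()
    rows: list[ReconciledTaxon] = []

    for motu_t, res_t in trnh_items:
        keys_t = _genus_keys(res_t)
        partner = None
        # prefer an identical call, then any genus-compatible partner
        for want_same_name in (True, False):
            for idx, (motu_r, res_r) in enumerate(rbcl_items):
                if idx in consumed:
                    continue
                if want_same_name and res_r.call_name != res_t.call_name:
                    continue
                if _genus_keys(res_r) & keys_t:
                    partner = idx
                    break
            if partner is not None:
                break
        if partner is not None:
            motu_r, res_r = rbcl_items[partner]
            consumed.add(partner)
            final = reconcile_markers(res_r, res_t, config.marker_precedence)
            rows.append(
                ReconciledTaxon(
                    site=site,
                    date=date,
                    call_name=final.call_name,
                    call_level=final.call_level,
                    n_clones={
                        MARKER_RBCL: motu_r.n_clones,
                        MARKER_TRNH: motu_t.n_clones,
                    },
                    motu_ids={
                        MARKER_RBCL: [motu_r.motu_id],
                        MARKER_TRNH: [motu_t.motu_id],
                    },
                    conflict_with=final.conflict_with,
                )
            )
        else:
            final = reconcile_markers(None, res_t, config.marker_precedence)
            rows.append(
                ReconciledTaxon(
                    site=site,
                    date=date,
                    call_name=final.call_name,
                    call_level=final.call_level,
                    n_clones={MARKER_TRNH: motu_t.n_clones},
                    motu_ids={MARKER_TRNH: [motu_t.motu_id]},
                )
            )
    for idx, (motu_r, res_r) in enumerate(rbcl_items):
        if idx in consumed:
            continue
        final = reconcile_markers(res_r, None, config.marker_precedence)
        rows.append(
            ReconciledTaxon(
                site=site,
                date=date,
                call_name=final.call_name,
                call_level=final.call_level,
                n_clones={MARKER_RBCL: motu_r.n_clones},
                motu_ids={MARKER_RBCL: [motu_r.motu_id]},
            )
        )

    # pool unidentifiable MOTUs per sample
    unid_clones: dict[str, int] = {}
    unid_ids: dict[str, list[str]] = {}
    for marker, res in per_marker.items():
        if res is None:
            continue
        for m in res.motus:
            if res.assignments[m.motu_id].call_level == CALL_UNIDENTIFIABLE:
                unid_clones[marker] = unid_clones.get(marker, 0) + m.n_clones
                unid_ids.setdefault(marker, []).append(m.motu_id)
    if unid_clones:
        rows.append(
            ReconciledTaxon(
                site=site,
                date=date,
                call_name="unidentifiable",
                call_level=CALL_UNIDENTIFIABLE,
                n_clones=unid_clones,
                motu_ids=unid_ids,
            )
        )

    # merge rows that resolved to the same taxon
    merged: dict[str, ReconciledTaxon] = {}
    for row in rows:
        prev = merged.get(row.call_name)
        if prev is None:
            merged[row.call_name] = row
        else:
            for marker, n in row.n_clones.items():
                prev.n_clones[marker] = prev.n_clones.get(marker, 0) + n
                prev.motu_ids.setdefault(marker, []).extend(
                    row.motu_ids.get(marker, [])
                )
            if row.conflict_with and not prev.conflict_with:
                prev.conflict_with = row.conflict_with
    return sorted(merged.values(), key=lambda r: (r.call_level != CALL_SPECIES, r.call_name))


@dataclass
class StudyResult:
    """Everything the pipeline produced for a multi-sample study."""

    samples: dict[tuple, SampleResult]  # (site, date, marker)
    reconciled: dict[tuple, list[ReconciledTaxon]]  # (site, date)
    composition: pd.DataFrame
    dates: list[str]

    def sampling_of(self, date: str) -> str:
        return ["I", "II", "III"][self.dates.index(date)]


def run_study(
    db: ReferenceDB,
    libraries: dict[tuple, list[CloneRead]],
    config: PipelineConfig,
    dates: list[str] | None = None,
) -> StudyResult:
    """Assign every (site, date, marker) library and build the study tables."""
    config = config.validate()
    logger.info("pipeline config %s", config.config_hash())
    if dates is None:
        dates = sorted({key[1] for key in libraries})
    if len(dates) > 3:
        raise ValidationError("at most three sampling dates are supported")

    samples: dict[tuple, SampleResult] = {}
    for key in sorted(libraries):
        samples[key] = assign_library(libraries[key], db, config)

    reconciled: dict[tuple, list[ReconciledTaxon]] = {}
    for (site, date) in sorted({(k[0], k[1]) for k in libraries}):
        per_marker = {
            marker: samples[(site, date, marker)]
            for marker in MARKERS
            if (site, date, marker) in samples
        }
        reconciled[(site, date)] = reconcile_sample(per_marker, config)

    rows = []
    sampling = {d: ["I", "II", "III"][i] for i, d in enumerate(dates)}
    for (site, date), taxa in reconciled.items():
        for taxon in taxa:
            if taxon.call_level == CALL_UNIDENTIFIABLE:
                continue
            for marker, n in taxon.n_clones.items():
                rows.append(
                    {
                        "taxon": taxon.call_name,
                        "site": site,
                        "sampling": sampling[date],
                        "marker": marker,
                        "n_clones": n,
                    }
                )
    return StudyResult(
        samples=samples,
        reconciled=reconciled,
        composition=make_composition(rows),
        dates=list(dates),
    )


def study_presence_absence(result: StudyResult, db: ReferenceDB):
    """Presence/absence matrix of a study, with status metadata pulled from
    the reference database (genus-level calls take the status of their top
    qualifying hit; pollination/flowering are not simulated and left blank)."""
    metadata: dict[str, dict] = {}
    status_by_species = {r.species: r.status for r in db.records}
    for taxa in result.reconciled.values():
        for taxon in taxa:
            if taxon.call_level == CALL_UNIDENTIFIABLE:
                continue
            if taxon.call_name in metadata:
                continue
            if taxon.call_name in status_by_species:
                status = status_by_species[taxon.call_name]
            else:
                genus = genus_of(taxon.call_name)
                candidates = sorted(
                    s for s in status_by_species if genus_of(s) == genus
                )
                status = status_by_species[candidates[0]] if candidates else "common"
            metadata[taxon.call_name] = {
                "status": status,
                "pollination": "",
                "flowering_period": "",
            }
    return build_presence_absence(result.composition, metadata)


def write_sample_report(
    per_marker: dict[str, SampleResult],
    reconciled: list[ReconciledTaxon],
    path: str | Path,
) -> None:
    """Per-sample TSV: one row per MOTU × marker with its hit list and call,
    plus the reconciled taxon name it contributes to."""
    motu_taxon = {}
    for taxon in reconciled:
        for marker, ids in taxon.motu_ids.items():
            for motu_id in ids:
                motu_taxon[(marker, motu_id)] = taxon.call_name
    rows = []
    for marker in MARKERS:
        res = per_marker.get(marker)
        if res is None:
            continue
        for motu in res.motus:
            a = res.assignments[motu.motu_id]
            rows.append(
                {
                    "site": res.site,
                    "date": res.date,
                    "marker": marker,
                    "motu_id": motu.motu_id,
                    "n_clones": motu.n_clones,
                    "hits": hits_display(a),
                    "call_level": a.call_level,
                    "call_name": a.call_name,
                    "reconciled_taxon": motu_taxon.get((marker, motu.motu_id), ""),
                }
            )
    pd.DataFrame(
        rows,
        columns=[
            "site", "date", "marker", "motu_id", "n_clones",
            "hits", "call_level", "call_name", "reconciled_taxon",
        ],
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# scenario evaluation (simulation ground truth vs pipeline output)


def nearest_congener_identity(
    db: ReferenceDB, species: str, marker: str
) -> float:
    """Max percent identity between a species' reference and any congener's
    reference for one marker; 0 when the species has no congener."""
    rec = db.lookup(species, marker)
    if rec is None:
        raise ValidationError(f"{species!r} has no {marker} record")
    best = 0.0
    for other in db.for_marker(marker):
        if other.species == species or other.genus != rec.genus:
            continue
        best = max(best, percent_identity(rec.sequence, other.sequence))
    return best


def evaluate_scenario(scenario, result: StudyResult, config: PipelineConfig) -> dict:
    """Score pipeline output against the simulator's truth labels.

    Returns per-study fractions: genus-level exactness (samples whose
    recovered genus set equals the truth genus set, with no false genera),
    species-level recall restricted to truth species whose nearest congener
    sits below the identity threshold on the precedence marker, the fraction
    of contaminant-only MOTUs called unidentifiable, and clone-count
    conservation across all reports.
    """
    from .simulate import CONTAMINANT_PREFIX

    config = config.validate()
    genus_exact = []
    recall_hits = 0
    recall_total = 0
    contaminant_motus = 0
    contaminant_unidentifiable = 0
    conservation_ok = []

    resolvable_cache: dict[str, bool] = {}

    def resolvable(species: str) -> bool:
        if species not in resolvable_cache:
            resolvable_cache[species] = (
                nearest_congener_identity(
                    scenario.db, species, config.marker_precedence
                )
                < config.threshold_pct
            )
        return resolvable_cache[species]

    for key, sample in result.samples.items():
        library = scenario.libraries[key]
        conservation_ok.append(
            sum(m.n_clones for m in sample.motus) == len(library)
        )
        for motu in sample.motus:
            truths = {m.truth_species for m in motu.members}
            if all(t and t.startswith(CONTAMINANT_PREFIX) for t in truths):
                contaminant_motus += 1
                level = sample.assignments[motu.motu_id].call_level
                if level == CALL_UNIDENTIFIABLE:
                    contaminant_unidentifiable += 1

    for (site, date), taxa in result.reconciled.items():
        truth_species = set()
        for marker in MARKERS:
            for read in scenario.libraries.get((site, date, marker), []):
                t = read.truth_species
                if t and not t.startswith(CONTAMINANT_PREFIX):
                    truth_species.add(t)
        truth_genera = {genus_of(s) for s in truth_species}
        recovered_species = {
            t.call_name for t in taxa if t.call_level == CALL_SPECIES
        }
        recovered_genera = {
            genus_of(t.call_name)
            for t in taxa
            if t.call_level in (CALL_SPECIES, CALL_GENUS)
        }
        genus_exact.append(recovered_genera == truth_genera)
        for species in truth_species:
            if resolvable(species):
                recall_total += 1
                recall_hits += species in recovered_species

    return {
        "n_samples": len(genus_exact),
        "genus_exact_fraction": sum(genus_exact) / len(genus_exact),
        "species_recall": recall_hits / recall_total if recall_total else float("nan"),
        "n_resolvable_species": recall_total,
        "contaminant_motus": contaminant_motus,
        "contaminant_unidentifiable_fraction": (
            contaminant_unidentifiable / contaminant_motus
            if contaminant_motus
            else float("nan")
        ),
        "clone_conservation_fraction": sum(conservation_ok) / len(conservation_ok),
    }
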