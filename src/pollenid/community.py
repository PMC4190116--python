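"""Community composition: clone-count tables, the presence/absence matrix
across sites and sampling dates, and its summary statistics.

The package ships a transcription of the study-design exemplar matrix
(52 taxa × 3 sites × 3 samplings, with per-taxon flowering period,
pollination mode and local status) as a plain TSV fixture; statistics such as
per-site richness, shared taxa between sites, persistence across samplings
and status/genus counts are recomputed from it, never hard-coded.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import pandas as pd

from .errors import ValidationError

SAMPLINGS = ("I", "II", "III")

COMPOSITION_COLUMNS = ["taxon", "site", "sampling", "marker", "n_clones"]

#: taxon labels that are not taxa and never enter community tables
NON_TAXON_LABELS = ("unidentifiable", "ambiguous")

_FIXTURE_SITE_NAMES = {"AlpeMoncodeno": "Alpe Moncodeno"}


def make_composition(rows: list[dict]) -> pd.DataFrame:
    """Build and validate a long-format clone-count table."""
    df = pd.DataFrame(rows, columns=COMPOSITION_COLUMNS)
    if len(df):
        if (df["n_clones"] < 1).any():
            raise ValidationError("composition n_clones must be >= 1")
        dup = df.duplicated(subset=["taxon", "site", "sampling", "marker"])
        if dup.any():
            raise ValidationError(
                f"duplicate composition row: {df[dup].iloc[0].to_dict()}"
            )
        bad = ~df["sampling"].isin(SAMPLINGS)
        if bad.any():
            raise ValidationError(
                f"unknown sampling {df.loc[bad, 'sampling'].iloc[0]!r}"
            )
    return df


@dataclass
class PresenceAbsenceMatrix:
    """Boolean taxa × (site, sampling) table with per-taxon metadata.

    ``presence`` is indexed by taxon name with a (site, sampling) column
    MultiIndex; ``metadata`` is indexed by taxon with columns
    ``status``, ``pollination``, ``flowering_period``.
    """

    presence: pd.DataFrame
    metadata: pd.DataFrame

    def __post_init__(self) -> None:
        if len(self.presence):
            if not self.presence.any(axis=1).all():
                empty = self.presence.index[~self.presence.any(axis=1)][0]
                raise ValidationError(f"taxon {empty!r} present in no cell")
            missing = set(self.presence.index) - set(self.metadata.index)
            if missing:
                raise ValidationError(f"metadata missing for taxa: {sorted(missing)}")

    @property
    def sites(self) -> list[str]:
        return list(dict.fromkeys(self.presence.columns.get_level_values(0)))

    @property
    def taxa(self) -> list[str]:
        return list(self.presence.index)

    def taxa_at(self, site: str) -> set[str]:
        if site not in self.sites:
            raise ValidationError(f"unknown site {site!r}")
        sub = self.presence[site]
        return set(sub.index[sub.any(axis=1)])


def build_presence_absence(
    composition: pd.DataFrame, metadata: dict[str, dict]
) -> PresenceAbsenceMatrix:
    """Collapse a per-marker clone-count table to presence/absence.

    A taxon is present in a (site, sampling) cell when either marker detected
    it there. Unidentifiable (and ambiguous) MOTU rows are excluded.
    ``metadata`` maps taxon → dict with status / pollination /
    flowering_period; conflicting metadata for one taxon is an error upstream
    (a dict can hold only one entry per taxon, so callers merge explicitly).
    """
    df = composition[~composition["taxon"].isin(NON_TAXON_LABELS)]
    if df.empty:
        return PresenceAbsenceMatrix(
            presence=pd.DataFrame(
                index=pd.Index([], name="taxon"),
                columns=pd.MultiIndex.from_tuples([], names=["site", "sampling"]),
            ),
            metadata=pd.DataFrame(
                columns=["status", "pollination", "flowering_period"]
            ),
        )
    cells = df.groupby(["taxon", "site", "sampling"]).size().reset_index()
    taxa = sorted(cells["taxon"].unique())
    sites = sorted(cells["site"].unique())
    columns = pd.MultiIndex.from_product(
        [sites, list(SAMPLINGS)], names=["site", "sampling"]
    )
    presence = pd.DataFrame(False, index=pd.Index(taxa, name="taxon"), columns=columns)
    for _, row in cells.iterrows():
        presence.loc[row["taxon"], (row["site"], row["sampling"])] = True

    missing = [t for t in taxa if t not in metadata]
    if missing:
        raise ValidationError(f"no metadata for taxa: {missing}")
    meta = pd.DataFrame.from_dict(
        {t: metadata[t] for t in taxa}, orient="index"
    ).reindex(columns=["status", "pollination", "flowering_period"])
    meta.index.name = "taxon"
    return PresenceAbsenceMatrix(presence=presence, metadata=meta)


def read_matrix(path_or_buffer) -> PresenceAbsenceMatrix:
    """Read a wide presence/absence TSV (as written by :func:`write_matrix`)."""
    df = pd.read_csv(path_or_buffer, sep="\t", keep_default_na=False)
    required = {"species", "status", "pollination", "flowering_period"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"matrix TSV missing columns: {sorted(missing)}")
    meta = df.set_index("species")[["status", "pollination", "flowering_period"]]
    meta.index.name = "taxon"
    pres_cols = [c for c in df.columns if "_" in c and c.split("_")[-1] in SAMPLINGS]
    tuples = []
    for c in pres_cols:
        site_key, sampling = c.rsplit("_", 1)
        tuples.append((_FIXTURE_SITE_NAMES.get(site_key, site_key), sampling))
    presence = df.set_index("species")[pres_cols] == "+"
    presence.columns = pd.MultiIndex.from_tuples(tuples, names=["site", "sampling"])
    presence.index.name = "taxon"
    return PresenceAbsenceMatrix(presence=presence, metadata=meta)


def load_table4() -> PresenceAbsenceMatrix:
    """Load the packaged 52-taxon exemplar presence/absence matrix."""
    with resources.files("pollenid.data").joinpath(
        "table4_presence_absence.tsv"
    ).open() as fh:
        return read_matrix(fh)


def richness_per_site(m: PresenceAbsenceMatrix) -> dict[str, int]:
    """Number of taxa detected in at least one sampling, per site."""
    return {site: len(m.taxa_at(site)) for site in m.sites}


def shared_taxa(m: PresenceAbsenceMatrix, site_a: str, site_b: str) -> int:
    """Number of taxa detected at both sites (any sampling)."""
    return len(m.taxa_at(site_a) & m.taxa_at(site_b))


def persistence_classes(m: PresenceAbsenceMatrix, site: str) -> dict[int, int]:
    """How many of the site's taxa were seen in exactly 1, 2 or 3 samplings."""
    sub = m.presence[site]
    if sub.shape[1] != len(SAMPLINGS):
        raise ValidationError(
            f"site {site!r} does not have {len(SAMPLINGS)} samplings"
        )
    counts = sub.sum(axis=1)
    counts = counts[counts > 0]
    return {k: int((counts == k).sum()) for k in (1, 2, 3)}


def status_counts(m: PresenceAbsenceMatrix) -> dict[str, int]:
    """Distinct taxa per local-distribution status (common / rare / alien)."""
    if m.presence.empty:
        return {}
    return m.metadata.loc[m.taxa, "status"].value_counts().to_dict()


def total_taxa(m: PresenceAbsenceMatrix) -> int:
    return len(m.taxa)


def genus_of(taxon: str) -> str:
    """Genus of a taxon label; 'Genus sp.' composites collapse to the genus."""
    return taxon.split()[0]


def genus_count(m: PresenceAbsenceMatrix) -> int:
    """Number of distinct genera among the matrix's taxa."""
    return len({genus_of(t) for t in m.taxa})


def summarize(m: PresenceAbsenceMatrix) -> dict:
    """All summary statistics in one dictionary (the console/report payload)."""
    sites = m.sites
    out = {
        "total_taxa": total_taxa(m),
        "genus_count": genus_count(m),
        "richness": richness_per_site(m),
        "status_counts": status_counts(m),
        "shared": {},
        "persistence": {},
    }
    for i, a in enumerate(sites):
        for b in sites[i + 1 :]:
            out["shared"][f"{a} ∩ {b}"] = shared_taxa(m, a, b)
    for site in sites:
        out["persistence"][site] = persistence_classes(m, site)
    return out


def write_matrix(m: PresenceAbsenceMatrix, tsv_path: str | Path) -> None:
    """Write the matrix in the fixture's wide TSV layout ('+' / empty)."""
    wide = m.metadata.loc[m.taxa, ["flowering_period", "pollination", "status"]].copy()
    for site, sampling in m.presence.columns:
        col = f"{site.replace(' ', '')}_{sampling}"
        wide[col] = ["+" if v else "" for v in m.presence[(site, sampling)]]
    wide.insert(0, "species", m.taxa)
    wide.to_csv(tsv_path, sep="\t", index=False)


def to_long(m: PresenceAbsenceMatrix) -> pd.DataFrame:
    """Long-format (taxon, site, sampling, present) view of the matrix."""
    long = (
        m.presence.stack(["site", "sampling"], future_stack=True)
        .rename("present")
        .reset_index()
    )
    return long[long["present"]].reset_index(drop=True)
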