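"""Synthetic reference databases and clone libraries.

The generator emulates the statistical structure the assignment pipeline
assumes, so every downstream stage is testable without any sequence download:

* a reference set with nested divergence — congeners nearly identical
  (pairwise identity typically 99–100%), distinct genera essentially
  unrelated (independent random ancestors);
* per-sample clone libraries of ~100 reads, each read a species template
  carrying exactly 1–2 random substitutions (the error footprint of cloning
  plus dye-terminator sequencing of single inserts);
* optional off-database contaminants, constructed by rejection so that they
  sit below the 99% identity threshold against every reference.

Every clone keeps its true source species as a ``truth_species`` label so the
recovery of the mixture can be scored exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .assignment import match_reference
from .errors import ValidationError
from .identity import DEFAULT_SCORING
from .motu import CloneRead
from .refdb import (
    MARKER_RBCL,
    MARKER_TRNH,
    MARKERS,
    ReferenceDB,
    ReferenceRecord,
)

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

CONTAMINANT_PREFIX = "contaminant:"


@dataclass(frozen=True)
class SimulationConfig:
    """Shape of the synthetic reference database.

    ``congener_divergence`` is the substitutions-per-site distance of a
    derived species from its genus ancestor (drawn uniformly per species);
    the first species of each genus *is* the ancestor, so two congeners sit
    roughly one-to-two draws apart — the 99–100% identity band. Genus
    ancestors are independent uniform random sequences, so inter-genus
    divergence (~0.75) always exceeds ``intergenus_divergence.min``; the
    configured range acts as a validity constraint on the config.
    """

    n_species: int
    n_genera: int
    seq_len_rbcl: int = 627
    seq_len_trnh: int = 634
    congener_divergence: tuple[float, float] = (0.002, 0.01)
    intergenus_divergence: tuple[float, float] = (0.05, 0.20)
    status_probs: dict = field(
        default_factory=lambda: {"common": 0.80, "rare": 0.17, "alien": 0.03}
    )
    seed: int = 0

    def validate(self) -> "SimulationConfig":
        if self.n_species < 1 or self.n_genera < 1:
            raise ValidationError("n_species and n_genera must be positive")
        if self.n_species < self.n_genera:
            raise ValidationError(
                f"n_species ({self.n_species}) < n_genera ({self.n_genera})"
            )
        lo, hi = self.congener_divergence
        if not 0 <= lo <= hi:
            raise ValidationError("bad congener_divergence range")
        if not hi < self.intergenus_divergence[0]:
            raise ValidationError(
                "congener_divergence.max must be below intergenus_divergence.min"
            )
        total = sum(self.status_probs.values())
        if abs(total - 1.0) > 1e-9:
            raise ValidationError(f"status_probs sum to {total}, expected 1")
        return self


@dataclass(frozen=True)
class MixtureSpec:
    """One pollen mixture: which species, at what relative clone abundance."""

    site: str
    date: str
    composition: dict  # species -> relative abundance
    n_clones: int = 100
    subs_per_clone: tuple[int, int] = (1, 2)
    contaminant_fraction: float = 0.0

    def validate(self) -> "MixtureSpec":
        if not self.composition:
            raise ValidationError("empty mixture composition")
        if any(w <= 0 for w in self.composition.values()):
            raise ValidationError("mixture abundances must be positive")
        if abs(sum(self.composition.values()) - 1.0) > 1e-9:
            raise ValidationError("mixture abundances must sum to 1")
        if self.n_clones < 1:
            raise ValidationError("n_clones must be >= 1")
        lo, hi = self.subs_per_clone
        if lo < 0 or hi < lo:
            raise ValidationError("bad subs_per_clone range")
        if not 0.0 <= self.contaminant_fraction < 1.0:
            raise ValidationError("contaminant_fraction must be in [0, 1)")
        return self


def _random_seq(rng: np.random.Generator, length: int) -> np.ndarray:
    return rng.choice(_BASES, size=length)


def _mutate(
    rng: np.random.Generator, template: np.ndarray, n_subs: int
) -> np.ndarray:
    """Introduce exactly ``n_subs`` substitutions at distinct positions, each
    to a base different from the original."""
    seq = template.copy()
    if n_subs == 0:
        return seq
    positions = rng.choice(len(seq), size=n_subs, replace=False)
    for p in positions:
        choices = _BASES[_BASES != seq[p]]
        seq[p] = rng.choice(choices)
    return seq


def _to_str(arr: np.ndarray) -> str:
    return arr.tobytes().decode("ascii")


def generate_reference_set(cfg: SimulationConfig) -> ReferenceDB:
    """Build a two-marker reference database with nested divergence levels.

    Deterministic under ``cfg.seed``. Species are distributed over genera as
    evenly as possible; each species carries one rbcL and one trnH-psbA
    record sharing status and accession.
    """
    cfg = cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    lengths = {MARKER_RBCL: cfg.seq_len_rbcl, MARKER_TRNH: cfg.seq_len_trnh}

    # species counts per genus, as even as possible
    base, extra = divmod(cfg.n_species, cfg.n_genera)
    per_genus = [base + (1 if g < extra else 0) for g in range(cfg.n_genera)]

    statuses = list(cfg.status_probs)
    probs = np.array([cfg.status_probs[s] for s in statuses], dtype=float)
    probs = probs / probs.sum()

    records = []
    idx = 0
    for g, n_in_genus in enumerate(per_genus):
        genus = f"Genus{g + 1:04d}"
        ancestors = {m: _random_seq(rng, lengths[m]) for m in MARKERS}
        for k in range(n_in_genus):
            idx += 1
            species = f"{genus} sp{k + 1:03d}"
            status = statuses[rng.choice(len(statuses), p=probs)]
            if k == 0:
                seqs = {m: ancestors[m] for m in MARKERS}
            else:
                d = rng.uniform(*cfg.congener_divergence)
                seqs = {
                    m: _mutate(rng, ancestors[m], int(round(d * lengths[m])))
                    for m in MARKERS
                }
            for m in MARKERS:
                tag = "R" if m == MARKER_RBCL else "T"
                records.append(
                    ReferenceRecord(
                        record_id=f"SYN{idx:05d}{tag}",
                        species=species,
                        marker=m,
                        status=status,
                        accession=f"SYN{idx:06d}",
                        sequence=_to_str(seqs[m]),
                    )
                )
    return ReferenceDB(records)


def _make_contaminant(
    rng: np.random.Generator,
    db: ReferenceDB,
    marker: str,
    length: int,
    threshold_pct: float = 99.0,
) -> str:
    """Random sequence rejected until it is below threshold identity to every
    reference — by construction these MOTUs must come out unidentifiable."""
    for _ in range(100):
        seq = _to_str(_random_seq(rng, length))
        hits = match_reference(seq, db, marker, DEFAULT_SCORING)
        if hits[0].identity_pct < threshold_pct:
            return seq
    raise RuntimeError("could not construct a sub-threshold contaminant")


def generate_clone_library(
    db: ReferenceDB, mix: MixtureSpec, marker: str, seed: int
) -> list[CloneRead]:
    """Simulate one (site, date, marker) clone library.

    Clone species are a multinomial draw from the mixture composition; each
    clone copies its species template with a uniform 1–2 (configurable)
    substitutions. A ``contaminant_fraction`` chance replaces a clone with an
    off-database sequence.
    """
    mix = mix.validate()
    if marker not in MARKERS:
        raise ValidationError(f"unknown marker {marker!r}")
    missing = [s for s in mix.composition if db.lookup(s, marker) is None]
    if missing:
        raise ValidationError(
            f"species not in reference database for {marker}: {missing}"
        )
    rng = np.random.default_rng(seed)
    species_names = sorted(mix.composition)
    weights = np.array([mix.composition[s] for s in species_names], dtype=float)
    weights = weights / weights.sum()
    templates = {
        s: np.frombuffer(db.lookup(s, marker).sequence.encode(), dtype=np.uint8)
        for s in species_names
    }
    length = len(next(iter(templates.values())))

    reads = []
    n_contaminants = 0
    for i in range(mix.n_clones):
        read_id = f"{mix.site}|{mix.date}|{marker}|clone{i + 1:03d}"
        if mix.contaminant_fraction and rng.random() < mix.contaminant_fraction:
            n_contaminants += 1
            seq = _make_contaminant(rng, db, marker, length)
            truth = f"{CONTAMINANT_PREFIX}{n_contaminants:02d}"
        else:
            sp = species_names[rng.choice(len(species_names), p=weights)]
            k = int(rng.integers(mix.subs_per_clone[0], mix.subs_per_clone[1] + 1))
            seq = _to_str(_mutate(rng, templates[sp], k))
            truth = sp
        reads.append(
            CloneRead(
                read_id=read_id,
                site=mix.site,
                date=mix.date,
                marker=marker,
                sequence=seq,
                truth_species=truth,
            )
        )
    return reads


@dataclass
class StudyScenario:
    """A full simulated study: reference database, mixtures and libraries."""

    db: ReferenceDB
    mixtures: dict  # (site, date) -> MixtureSpec
    libraries: dict  # (site, date, marker) -> list[CloneRead]


def generate_study_scenario(
    cfg: SimulationConfig,
    site_floras: dict,
    dates: list[str],
    seed: int,
    n_clones: int = 100,
    species_range: tuple[int, int] = (12, 18),
    subs_per_clone: tuple[int, int] = (1, 2),
    contaminant_fraction: float = 0.0,
) -> StudyScenario:
    """Simulate the full sampling design: per (site, date) one mixture of
    12–18 species drawn from the site's flora, shared by both markers
    (both are amplified from the same pooled DNA), then one clone library
    per marker.

    ``site_floras`` maps site name → list of species available there (must be
    a subset of the generated reference database). Relative abundances are a
    flat-Dirichlet draw, giving the skewed clone counts real mixtures show.
    """
    db = generate_reference_set(cfg)
    rng = np.random.default_rng(seed)
    all_species = db.species
    for site, pool in site_floras.items():
        if not pool:
            raise ValidationError(f"empty species pool for site {site!r}")
        unknown = sorted(set(pool) - all_species)
        if unknown:
            raise ValidationError(f"site {site!r}: species not in database: {unknown}")

    mixtures = {}
    libraries = {}
    for site in sorted(site_floras):
        pool = sorted(site_floras[site])
        for date in dates:
            lo, hi = species_range
            n_taxa = int(rng.integers(min(lo, len(pool)), min(hi, len(pool)) + 1))
            chosen = sorted(
                rng.choice(len(pool), size=n_taxa, replace=False).tolist()
            )
            species = [pool[i] for i in chosen]
            abund = rng.dirichlet(np.ones(n_taxa))
            composition = dict(zip(species, (abund / abund.sum()).tolist()))
            # renormalise exactly to 1 to satisfy the MixtureSpec invariant
            total = sum(composition.values())
            composition = {s: w / total for s, w in composition.items()}
            mix = MixtureSpec(
                site=site,
                date=date,
                composition=composition,
                n_clones=n_clones,
                subs_per_clone=subs_per_clone,
                contaminant_fraction=contaminant_fraction,
            )
            mixtures[(site, date)] = mix
            for marker in MARKERS:
                lib_seed = int(rng.integers(0, 2**31 - 1))
                libraries[(site, date, marker)] = generate_clone_library(
                    db, mix, marker, lib_seed
                )
    return StudyScenario(db=db, mixtures=mixtures, libraries=libraries)


#: The sampling design the generator emulates by default: three alpine
#: apiary sites sampled on three dates spanning the main flowering season.
STUDY_SITES = ("SiteA", "SiteB", "SiteC")
STUDY_DATES = ("2011-05-20", "2011-06-09", "2011-06-29")


def species_names(cfg: SimulationConfig) -> list[str]:
    """The species names :func:`generate_reference_set` will produce for a
    config, without generating any sequence."""
    base, extra = divmod(cfg.n_species, cfg.n_genera)
    names = []
    for g in range(cfg.n_genera):
        genus = f"Genus{g + 1:04d}"
        for k in range(base + (1 if g < extra else 0)):
            names.append(f"{genus} sp{k + 1:03d}")
    return names


def default_study_config(seed: int = 0) -> SimulationConfig:
    """Reference-database shape of the emulated study: 693 species. The
    genus count (450) gives roughly a third of species a congener in the
    database, reproducing the observed mix of clean species-level matches
    and ≥99% congeneric ties."""
    return SimulationConfig(n_species=693, n_genera=450, seed=seed)


def default_study_scenario(
    seed: int = 0, contaminant_fraction: float = 0.05
) -> StudyScenario:
    """The full emulated sampling design: a 693-species database, three
    sites with partially overlapping floras (~80 species shared between
    neighbours), three dates, 100 clones per mixture and marker."""
    cfg = default_study_config(seed)
    names = species_names(cfg)
    rng = np.random.default_rng(seed + 1)
    shuffled = [names[i] for i in rng.permutation(len(names))]
    floras = {
        STUDY_SITES[0]: shuffled[0:260],
        STUDY_SITES[1]: shuffled[180:440],
        STUDY_SITES[2]: shuffled[360:620],
    }
    return generate_study_scenario(
        cfg,
        floras,
        list(STUDY_DATES),
        seed=seed + 2,
        contaminant_fraction=contaminant_fraction,
    )


def write_clone_library(reads: list[CloneRead], path: str | Path) -> None:
    """Write a clone library as FASTA with ``site|date|marker|truth`` headers."""
    with open(path, "w") as fh:
        for r in reads:
            truth = r.truth_species or ""
            fh.write(f">{r.read_id} truth_species={truth}\n")
            for i in range(0, len(r.sequence), 80):
                fh.write(r.sequence[i : i + 80] + "\n")


def read_clone_library(path: str | Path) -> list[CloneRead]:
    """Read a clone library FASTA written by :func:`write_clone_library`."""
    from Bio import SeqIO

    reads = []
    for rec in SeqIO.parse(str(path), "fasta"):
        parts = rec.id.split("|")
        if len(parts) < 3:
            raise ValidationError(
                f"clone FASTA id {rec.id!r} is not site|date|marker|read"
            )
        truth = None
        if "truth_species=" in rec.description:
            # species labels contain spaces: take the rest of the line
            truth = rec.description.split("truth_species=", 1)[1].strip() or None
        reads.append(
            CloneRead(
                read_id=rec.id,
                site=parts[0],
                date=parts[1],
                marker=parts[2],
                sequence=str(rec.seq),
                truth_species=truth,
            )
        )
    return reads
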