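import numpy as np
import pytest

from pollenid.errors import ValidationError
from pollenid.identity import percent_identity
from pollenid.simulate import (
    CONTAMINANT_PREFIX,
    MixtureSpec,
    SimulationConfig,
    generate_clone_library,
    generate_reference_set,
    generate_study_scenario,
    read_clone_library,
    species_names,
    write_clone_library,
)


def _mask_hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


@pytest.fixture()
def tiny_db():
    cfg = SimulationConfig(
        n_species=6, n_genera=3, seq_len_rbcl=150, seq_len_trnh=160, seed=21
    )
    return cfg, generate_reference_set(cfg)


class TestReferenceSet:
    def test_congener_identity_band(self):
        """Two congeners at divergence 0.004 over 500 nt sit at ~99.6%."""
        cfg = SimulationConfig(
            n_species=2,
            n_genera=1,
            seq_len_rbcl=500,
            seq_len_trnh=500,
            congener_divergence=(0.004, 0.004),
            seed=1,
        )
        db = generate_reference_set(cfg)
        recs = db.for_marker("rbcL")
        pct = percent_identity(recs[0].sequence, recs[1].sequence)
        assert pct == pytest.approx(99.6, abs=0.2)

    def test_deterministic_under_seed(self):
        cfg = SimulationConfig(n_species=10, n_genera=4, seq_len_rbcl=120,
                               seq_len_trnh=130, seed=7)
        assert generate_reference_set(cfg) == generate_reference_set(cfg)

    def test_distinct_genera_are_distant(self):
        """With one species per genus, full-length pairwise identities stay
        far below the congener band (Monte Carlo over 20 pairs). Divergence
        between equal-length references is measured position-by-position;
        the overlap identity of an optimal free-end alignment of unrelated
        sequences is a short-segment statistic, not a divergence measure."""
        from pollenid.identity import ungapped_identity

        cfg = SimulationConfig(
            n_species=8, n_genera=8, seq_len_rbcl=300, seq_len_trnh=300, seed=3
        )
        db = generate_reference_set(cfg)
        recs = db.for_marker("rbcL")
        rng = np.random.default_rng(0)
        pairs = {
            tuple(sorted(rng.choice(len(recs), 2, replace=False))) for _ in range(20)
        }
        for i, j in pairs:
            if i == j:
                continue
            assert ungapped_identity(recs[i].sequence, recs[j].sequence) <= 0.95

    def test_species_counts_and_names(self):
        cfg = SimulationConfig(n_species=7, n_genera=3, seq_len_rbcl=90,
                               seq_len_trnh=90, seed=2)
        db = generate_reference_set(cfg)
        assert len(db) == 14  # one record per species per marker
        assert sorted(db.species) == sorted(species_names(cfg))

    def test_more_genera_than_species_rejected(self):
        with pytest.raises(ValidationError):
            SimulationConfig(n_species=2, n_genera=3).validate()


class TestCloneLibrary:
    def test_every_clone_within_stated_substitution_range(self, tiny_db):
        cfg, db = tiny_db
        species = sorted(db.species)[:3]
        mix = MixtureSpec(
            site="S", date="D", composition={s: 1 / 3 for s in species}, n_clones=60
        )
        reads = generate_clone_library(db, mix, "rbcL", seed=5)
        assert len(reads) == 60
        for read in reads:
            template = db.lookup(read.truth_species, "rbcL").sequence
            assert _mask_hamming(read.sequence, template) in (1, 2)

    def test_zero_substitutions_reproduce_templates(self, tiny_db):
        cfg, db = tiny_db
        sp = sorted(db.species)[0]
        mix = MixtureSpec(
            site="S", date="D", composition={sp: 1.0}, n_clones=10,
            subs_per_clone=(0, 0),
        )
        reads = generate_clone_library(db, mix, "trnH-psbA", seed=1)
        template = db.lookup(sp, "trnH-psbA").sequence
        assert all(r.sequence == template for r in reads)

    def test_multinomial_composition(self, tiny_db):
        cfg, db = tiny_db
        a, b = sorted(db.species)[:2]
        mix = MixtureSpec(
            site="S", date="D", composition={a: 0.5, b: 0.5}, n_clones=10000
        )
        reads = generate_clone_library(db, mix, "rbcL", seed=9)
        n_a = sum(r.truth_species == a for r in reads)
        sigma = (10000 * 0.25) ** 0.5
        assert abs(n_a - 5000) <= 3 * sigma

    def test_truth_label_conservation(self, tiny_db):
        cfg, db = tiny_db
        species = sorted(db.species)[:4]
        mix = MixtureSpec(
            site="S", date="D", composition={s: 0.25 for s in species}, n_clones=37
        )
        reads = generate_clone_library(db, mix, "rbcL", seed=2)
        assert sum(1 for r in reads if r.truth_species) == 37

    def test_contaminants_are_sub_threshold_against_whole_database(self, tiny_db):
        from pollenid.assignment import match_reference

        cfg, db = tiny_db
        species = sorted(db.species)[:2]
        mix = MixtureSpec(
            site="S", date="D", composition={s: 0.5 for s in species},
            n_clones=100, contaminant_fraction=0.05,
        )
        reads = generate_clone_library(db, mix, "rbcL", seed=3)
        contaminants = [
            r for r in reads if r.truth_species.startswith(CONTAMINANT_PREFIX)
        ]
        # binomial(100, 0.05): stay within ~3 sigma of 5
        assert 0 < len(contaminants) <= 12
        for read in contaminants:
            hits = match_reference(read.sequence, db, "rbcL")
            assert hits[0].identity_pct < 99.0

    def test_unknown_species_rejected_by_name(self, tiny_db):
        cfg, db = tiny_db
        mix = MixtureSpec(site="S", date="D", composition={"Nullius nomen": 1.0})
        with pytest.raises(ValidationError, match="Nullius nomen"):
            generate_clone_library(db, mix, "rbcL", seed=0)

    def test_fasta_round_trip(self, tiny_db, tmp_path):
        cfg, db = tiny_db
        sp = sorted(db.species)[0]
        mix = MixtureSpec(site="S", date="D", composition={sp: 1.0}, n_clones=5)
        reads = generate_clone_library(db, mix, "rbcL", seed=4)
        write_clone_library(reads, tmp_path / "lib.fasta")
        back = read_clone_library(tmp_path / "lib.fasta")
        assert [(r.read_id, r.sequence, r.truth_species) for r in back] == [
            (r.read_id, r.sequence, r.truth_species) for r in reads
        ]


class TestStudyScenario:
    def _small_scenario(self, seed=11):
        cfg = SimulationConfig(
            n_species=30, n_genera=20, seq_len_rbcl=150, seq_len_trnh=160, seed=seed
        )
        names = species_names(cfg)
        floras = {"SiteA": names[:20], "SiteB": names[10:30]}
        return generate_study_scenario(
            cfg, floras, ["d1", "d2", "d3"], seed=seed, n_clones=20,
            species_range=(5, 8),
        )

    def test_sites_dates_markers_multiply_out(self):
        scenario = self._small_scenario()
        assert len(scenario.libraries) == 2 * 3 * 2
        assert len(scenario.mixtures) == 6

    def test_markers_share_one_composition(self):
        scenario = self._small_scenario()
        for (site, date), mix in scenario.mixtures.items():
            rbcl = {r.truth_species for r in scenario.libraries[(site, date, "rbcL")]}
            assert rbcl <= set(mix.composition)

    def test_deterministic_under_seed(self):
        a = self._small_scenario(seed=13)
        b = self._small_scenario(seed=13)
        for key in a.libraries:
            assert [r.sequence for r in a.libraries[key]] == [
                r.sequence for r in b.libraries[key]
            ]

    def test_empty_pool_rejected(self):
        cfg = SimulationConfig(n_species=4, n_genera=2, seq_len_rbcl=80,
                               seq_len_trnh=80, seed=1)
        with pytest.raises(ValidationError, match="empty"):
            generate_study_scenario(cfg, {"SiteA": []}, ["d1"], seed=0)
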