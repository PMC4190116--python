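import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def pipeline_config():
    from pollenid.pipeline import PipelineConfig

    return PipelineConfig()


@pytest.fixture(scope="session")
def study(pipeline_config):
    """One full simulated study under the emulated conditions (693-species
    database, 3 sites × 3 dates × 2 markers, 100 clones per library,
    1–2 substitutions per clone, 5% contaminants), run once per session."""
    from pollenid.pipeline import run_study
    from pollenid.simulate import default_study_scenario

    scenario = default_study_scenario(seed=20140101, contaminant_fraction=0.05)
    result = run_study(scenario.db, scenario.libraries, pipeline_config)
    return scenario, result


@pytest.fixture()
def small_db():
    """A hand-made two-marker database with a congeneric pair."""
    import random

    from pollenid.refdb import ReferenceDB, ReferenceRecord

    rng = random.Random(11)
    from helpers import random_dna, with_substitutions

    acer_r = random_dna(rng, 500)
    acer_t = random_dna(rng, 510)
    fagus_r = random_dna(rng, 500)
    fagus_t = random_dna(rng, 510)
    records = [
        ReferenceRecord("r1", "Acer campestre", "rbcL", "common", "A1", acer_r),
        ReferenceRecord(
            "r2", "Acer platanoides", "rbcL", "common", "A2",
            with_substitutions(rng, acer_r, [10, 200]),
        ),
        ReferenceRecord("r3", "Fagus sylvatica", "rbcL", "common", "F1", fagus_r),
        ReferenceRecord("t1", "Acer campestre", "trnH-psbA", "common", "A1", acer_t),
        ReferenceRecord(
            "t2", "Acer platanoides", "trnH-psbA", "common", "A2",
            with_substitutions(rng, acer_t, [5, 100, 200, 300, 400, 450, 60]),
        ),
        ReferenceRecord("t3", "Fagus sylvatica", "trnH-psbA", "common", "F1", fagus_t),
    ]
    return ReferenceDB(records)
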