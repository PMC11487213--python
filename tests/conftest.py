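import pytest

from comorbnet import (
    Cohort,
    DiseaseSpec,
    EncounterRecord,
    PlantedPair,
    Sex,
    SimulationConfig,
    simulate_cohort,
)


def rec(i, age, sex, codes):
    return EncounterRecord(f"R{i}", age, sex, frozenset(codes))


@pytest.fixture
def toy_cohort():
    """Six hand-built records exercising every cleaning rule.

    R1 is a minor; R2 has a single code; R3 carries the symptom code R50 which
    the chapter filter removes, leaving two valid codes. After cleaning, four
    records survive and R50 is gone.
    """
    return Cohort([
        rec(1, 17, Sex.FEMALE, {"E04", "I10"}),         # dropped: age < 18
        rec(2, 50, Sex.MALE, {"E04"}),                  # dropped: < 2 codes
        rec(3, 60, Sex.FEMALE, {"E04", "R50", "I10"}),  # survives, R50 stripped
        rec(4, 45, Sex.MALE, {"E05", "E11", "I10"}),
        rec(5, 71, Sex.FEMALE, {"C73", "E04", "I10"}),
        rec(6, 33, Sex.MALE, {"E03", "E11"}),
    ])


# Planted ground truth shared by recovery tests: three pairs at cosine
# targets 0.1/0.3/0.5, one male-enriched and one female-enriched disease,
# one disease with a strong age slope, and null diseases for the
# false-positive rate. No sex/age effects on planted-pair members so their
# population cosine matches the solved expectation exactly.
RECOVERY_DISEASES = [
    DiseaseSpec("I10", 0.20), DiseaseSpec("I25", 0.20),   # target 0.5
    DiseaseSpec("E11", 0.15), DiseaseSpec("E78", 0.15),   # target 0.3
    DiseaseSpec("K29", 0.05), DiseaseSpec("K80", 0.05),   # target 0.1
    DiseaseSpec("N40", 0.08, sex_log_odds_shift=1.2),     # male-enriched
    DiseaseSpec("M81", 0.08, sex_log_odds_shift=-1.2),    # female-enriched
    DiseaseSpec("I70", 0.10, age_slope_per_decade=0.5),   # rises with age
] + [DiseaseSpec(f"G{i:02d}", 0.06) for i in range(20, 31)]  # null block

RECOVERY_PAIRS = [
    PlantedPair("I10", "I25", 0.5),
    PlantedPair("E11", "E78", 0.3),
    PlantedPair("K29", "K80", 0.1),
]


@pytest.fixture(scope="session")
def recovery_config():
    return SimulationConfig(
        n_records=20_000, seed=20231115,
        diseases=RECOVERY_DISEASES, planted_pairs=RECOVERY_PAIRS,
    )


@pytest.fixture(scope="session")
def recovery_cohort(recovery_config):
    return simulate_cohort(recovery_config)
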