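from pathlib import Path

import pytest

from pathburden import (
    GeneSetSpec,
    SyntheticCohortConfig,
    generate_cohorts,
)

DATA = Path(__file__).parent / "data"


@pytest.fixture(scope="session")
def toy_vcf() -> Path:
    return DATA / "toy.vcf"


@pytest.fixture(scope="session")
def gmt12() -> Path:
    return DATA / "pathways12.gmt"


# Metadata of the toy VCF after per-ALT decomposition, hand-transcribed
# from the fixture for independent filter enumeration:
# (consequence class, POP_AC, POP_AN)
TOY_RECORD_META = [
    ("stop_gain", 10, 280_000),          # r1
    ("other", 0, 280_000),               # r2 missense
    ("stop_gain", 11, 280_000),          # r3 too common
    ("canonical_splice", 0, 280_000),    # r4 ALT=T
    ("frameshift_insertion", 5, 280_000),  # r4 ALT=TGG
    ("start_loss", 2, 140_000),          # r5, different AN
]


@pytest.fixture(scope="session")
def small_scenario():
    """Small multi-cohort scenario with one strongly planted pathway."""
    cfg = SyntheticCohortConfig(
        cohort_sizes={"case": 30, "compA": 100, "compB": 150},
        case_cohort="case",
        n_genes=120,
        baseline_rate=0.02,
        geneset_spec=GeneSetSpec(n_sets=12, min_size=5, max_size=20),
        seed=42,
    )
    cfg = SyntheticCohortConfig(
        cohort_sizes=cfg.cohort_sizes,
        case_cohort="case",
        n_genes=cfg.n_genes,
        baseline_rate=cfg.baseline_rate,
        planted_effects=(("SET0003", 10.0),),
        geneset_spec=cfg.geneset_spec,
        seed=42,
    )
    return cfg, generate_cohorts(cfg)
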