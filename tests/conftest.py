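import numpy as np
import pytest

from predictebc import Cohort, ModelConfig, PatientRecord
from predictebc.engine import ERParams, MarkerParams


def make_record(**kw) -> PatientRecord:
    """A complete reference-category ER+ patient, overridable per field."""
    base = dict(
        id="r1",
        age_dx=55.0,
        size_mm=8.0,
        grade=0.0,
        nodes_pos=0.0,
        nodes_sampled=20.0,
        er="pos",
        her2=None,
        ki67=None,
        detection="symptomatic",
        therapy="none",
        follow_up_years=12.0,
        outcome="censored",
    )
    base.update(kw)
    return PatientRecord(**base)


@pytest.fixture
def record_factory():
    return make_record


@pytest.fixture
def default_config() -> ModelConfig:
    return ModelConfig.default()


def flat_config(
    bc_hazard: float = 0.02,
    oc_hazard: float = 0.0,
    hr_node: float = 1.0,
    hr_size: float = 1.0,
    hr_grade: float = 1.0,
    hr_screen: float = 1.0,
    marker_hr: float = 1.0,
    treatment=None,
    horizon: int = 10,
) -> ModelConfig:
    """Constant-hazard configuration for closed-form checks."""
    baseline = [bc_hazard] * horizon
    params = dict(hr_node=hr_node, hr_size=hr_size, hr_grade=hr_grade,
                  hr_screen=hr_screen)
    return ModelConfig(
        er_pos=ERParams(**params, baseline_annual_hazard=list(baseline)),
        er_neg=ERParams(**params, baseline_annual_hazard=list(baseline)),
        ki67=MarkerParams(hr=marker_hr, prevalence=0.412),
        her2=MarkerParams(hr=marker_hr, prevalence=0.10),
        life_table={a: oc_hazard for a in range(20, 101)},
        treatment=treatment or {"endocrine": 1.0, "chemo": 1.0},
        horizon_years=horizon,
    )


@pytest.fixture
def flat_config_factory():
    return flat_config


def small_cohort(n: int = 6) -> Cohort:
    recs = []
    rng = np.random.default_rng(7)
    for i in range(n):
        recs.append(
            make_record(
                id=f"c{i}",
                size_mm=float(5 + 5 * i),
                grade=float(i % 3),
                nodes_pos=float(i % 4),
                nodes_sampled=20.0,
                er="pos" if i % 2 == 0 else "neg",
                her2=float(i % 2),
                ki67=float((i + 1) % 2),
                follow_up_years=float(rng.uniform(1, 14)),
                outcome=["censored", "bc_death", "other_death"][i % 3],
            )
        )
    return Cohort(recs, provenance="unit-test cohort")


@pytest.fixture
def cohort6() -> Cohort:
    return small_cohort()
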