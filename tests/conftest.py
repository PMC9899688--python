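import pytest

from longmediate.mediation import AnalysisSpec
from longmediate.synthetic import GeneratorConfig, generate
from longmediate.trial_data import Patient, TrialDataset, Visit, analysis_set


@pytest.fixture(scope="session")
def clean_cohort():
    """Small noise-bearing cohort without missingness (fast, deterministic)."""
    return generate(GeneratorConfig(n_patients=150, seed=11, missing_rate=0.0))


@pytest.fixture(scope="session")
def missing_cohort():
    """Cohort with 10% per-visit missingness for complete-case logic."""
    return generate(GeneratorConfig(n_patients=200, seed=23, missing_rate=0.10))


@pytest.fixture(scope="session")
def default_cohort():
    """Default calibration at the default size."""
    return generate(GeneratorConfig(seed=7))


@pytest.fixture
def spec_joint_cum():
    return AnalysisSpec(
        mediators=(("sbp", "cumulative_mean"), ("egfr", "cumulative_mean"))
    )


@pytest.fixture
def spec_sbp_cum():
    return AnalysisSpec(mediators=(("sbp", "cumulative_mean"),))


def make_patient(pid="p1", arm=1, weeks=(0, 4, 8, 12), sbp=None, dbp=None,
                 egfr=None, uacr=None, attributes=None):
    """Hand-build a patient from per-week value lists (None = missing)."""
    def pick(series, i):
        if series is None:
            return None
        return series[i]

    visits = [
        Visit(week=w, uacr=pick(uacr, i), sbp=pick(sbp, i), dbp=pick(dbp, i),
              egfr=pick(egfr, i))
        for i, w in enumerate(weeks)
    ]
    return Patient(id=pid, arm=arm, visits=visits, attributes=attributes or {})


@pytest.fixture
def endpoint_set(default_cohort):
    return analysis_set(default_cohort, 52)
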