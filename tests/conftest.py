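import numpy as np
import pytest
from hypothesis import settings

from petdsb.cohort import generate_study
from petdsb.dosimetry import TubeSAFTable
from petdsb.stats import summarize_study

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_study():
    """One default 32-volunteer synthetic study (fixed seed)."""
    return generate_study(seed=101)


@pytest.fixture(scope="session")
def study_results(default_study):
    return summarize_study(default_study)


@pytest.fixture(scope="session")
def saf_table():
    """Tube SAFs at 1e5 histories for the predefined volumes."""
    return TubeSAFTable.compute(n_histories=100_000, seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def oversize_recovery():
    """240-FDG-volunteer oversized study: (median excess, slope * median
    total dose) for dose-slope parameter recovery."""
    from petdsb.cohort import ArmSpec, CohortParams, FociGeneratorParams
    from petdsb.stats import damage_rates_table, excess_rates

    arms = (
        ArmSpec("SA1", 60, 60, (26.0, 3.1, 22, 32), (77.0, 11.3, 63, 100), (25.2, 3.8, 20.3, 33.4)),
        ArmSpec("SA3", 60, 60, (24.8, 2.7, 21, 30), (72.9, 9.7, 59, 87), (23.7, 2.5, 19.5, 28.1)),
    )
    study = generate_study(seed=17, cohort_params=CohortParams(arms=arms), saf_histories=20_000)
    rates = damage_rates_table(study.foci)
    excess = excess_rates(rates)
    med_excess = float(np.nanmedian(excess["excess_pct"]))
    med_dose = float(np.median([r.D_total_mGy[60] for r in study.dose_reports.values()]))
    expected = FociGeneratorParams().dose_slope_pct_per_mGy * med_dose
    return med_excess, expected
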