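import numpy as np
import pandas as pd
import pytest

import leadlag as ll

ANALYSIS_COVARIATES = ("maternal_education", "blood_lead", "deprivation",
                       "greenspace", "ecat")


@pytest.fixture(scope="session")
def bump_curve():
    return ll.TrueLagCurve.bump(144)


@pytest.fixture(scope="session")
def bump_cohort(bump_curve):
    """One full synthetic cohort under the default study conditions."""
    return ll.simulate_cohort(ll.SimulationConfig(seed=42), bump_curve)


@pytest.fixture(scope="session")
def bump_cohort_fit(bump_cohort):
    panel = ll.build_covariate_panel(bump_cohort.covariates,
                                     bump_cohort.covariate_visits)
    covars = panel.values.loc[bump_cohort.subjects].reset_index()
    spec = ll.ModelSpec(covariate_names=ANALYSIS_COVARIATES)
    fit = ll.fit_with_refit_rule(bump_cohort.exposure,
                                 bump_cohort.outcomes["score"].values,
                                 covars, spec=spec)
    return fit


@pytest.fixture()
def toy_monitor():
    """Hand-checkable two-month series: Jan {2, 4}, Feb {6}."""
    df = pd.DataFrame({
        "date": pd.to_datetime(["2001-01-05", "2001-01-20", "2001-02-10"]),
        "concentration": [2.0, 4.0, 6.0],
    })
    return ll.MonitorSeries(df, monitor_id="toy")


def make_constant_history(subject_id="S1", birth="2002-03-15", estimate=2.0):
    birth = pd.Timestamp(birth)
    return ll.ResidenceHistory(
        subject_id=subject_id, birth_date=birth,
        intervals=[(birth, birth + pd.DateOffset(years=12), estimate)])


def constant_factor_table(start_year=2001, end_year=2016, value=1.0):
    factors = {(y, m): value for y in range(start_year, end_year + 1)
               for m in range(1, 13)}
    return ll.ScalingFactorTable(factors, baseline_mean=1.0,
                                 baseline_window=(pd.Timestamp("2001-01-01"),
                                                  pd.Timestamp("2005-12-31")))
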