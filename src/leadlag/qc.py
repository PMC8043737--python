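"""Outcome-validity exclusions and covariate construction.

Behavioral t-scores come with three publisher validity indices: F ("fake
bad", overly negative rating), C (inconsistent responding) and R (patterned
or inattentive responding).  A record is analysis-valid iff F <= 6, C <= 17
and 66 <= R <= 125; boundary values are valid.  Time-varying covariates
(deprivation, greenspace, traffic-pollution ECAT) are averaged over the six
follow-up visits, using whichever visits are available.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

F_MAX = 6
C_MAX = 17
R_MIN = 66
R_MAX = 125


@dataclass
class CovariatePanel:
    """Per-subject analysis covariates plus visit provenance."""

    values: pd.DataFrame       # indexed by subject_id
    provenance: pd.DataFrame   # number of visits behind each average


def filter_valid_basc(indices: pd.DataFrame, f_max: int = F_MAX,
                      c_max: int = C_MAX, r_min: int = R_MIN,
                      r_max: int = R_MAX) -> tuple[list, pd.DataFrame]:
    """Keep subjects with valid F/C/R indices; ledger the rest.

    ``indices`` needs columns subject_id, f_index, c_index, r_index.
    Returns (kept subject ids, ledger DataFrame with one row per
    subject-reason pair).  Missing indices are their own exclusion reason.
    """
    reasons = []
    kept = []
    for row in indices.itertuples(index=False):
        sid = row.subject_id
        f, c, r = row.f_index, row.c_index, row.r_index
        why = []
        if pd.isna(f) or pd.isna(c) or pd.isna(r):
            why.append("missing validity index")
        else:
            if f > f_max:
                why.append(f"F-index >{f_max}")
            if c > c_max:
                why.append(f"C-index >{c_max}")
            if r > r_max or r < r_min:
                why.append(f"R-index outside [{r_min},{r_max}]")
        if why:
            reasons.extend((sid, w) for w in why)
        else:
            kept.append(sid)
    ledger = pd.DataFrame(reasons, columns=["subject_id", "reason"])
    return kept, ledger


def average_visit_covariates(visits: pd.DataFrame,
                             value_cols: tuple = ("deprivation", "greenspace",
                                                  "ecat")) -> CovariatePanel:
    """Average each covariate over the available visits per subject.

    ``visits`` is long: subject_id, visit_age, then one column per
    covariate.  Subjects with no non-missing visit for a covariate get NaN
    (excluded later at fit time); provenance records the visit count behind
    each mean.
    """
    value_cols = [c for c in value_cols if c in visits.columns]
    g = visits.groupby("subject_id")[value_cols]
    means = g.mean()
    counts = g.count()
    return CovariatePanel(values=means, provenance=counts)


def build_covariate_panel(subject_covariates: pd.DataFrame,
                          visits: pd.DataFrame) -> CovariatePanel:
    """Join fixed subject covariates (education, blood lead) with six-visit
    averages into one analysis panel indexed by subject_id."""
    averaged = average_visit_covariates(visits)
    fixed = subject_covariates.set_index("subject_id")
    # visit-averaged columns supersede any same-named subject-level column
    fixed = fixed.drop(columns=[c for c in averaged.values.columns
                                if c in fixed.columns])
    values = fixed.join(averaged.values, how="left")
    if "deprivation" in values and values["deprivation"].notna().any():
        bad = values["deprivation"].dropna()
        if ((bad < 0) | (bad > 1)).any():
            raise ValueError("deprivation index outside [0, 1]")
    if "greenspace" in values and values["greenspace"].notna().any():
        bad = values["greenspace"].dropna()
        if ((bad < -1) | (bad > 1)).any():
            raise ValueError("NDVI outside [-1, 1]")
    return CovariatePanel(values=values, provenance=averaged.provenance)
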