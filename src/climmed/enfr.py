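"""Published marginal counts from the 2018 ENFR anthropometric subsample.

Cell counts of the study population (n = 16,410 adults with measured
anthropometry) cross-tabulated by overweight status, as published for
the survey: sex, education, physical-activity level, plus the age
summary. The fruit/vegetable row of the published table is
typographically corrupted in available sources and is deliberately not
included here.

These counts let the descriptive and contingency-table machinery run
against the real survey margins without access to the request-only
microdata.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

#: counts as {variable: {level: (not overweight, overweight)}}
TABLE1_COUNTS: dict[str, dict[str, tuple[int, int]]] = {
    "sex": {
        "male": (1988, 4972),
        "female": (3280, 6170),
    },
    "education": {
        "incomplete_primary": (365, 1282),
        "incomplete_secondary": (1656, 4250),
        "complete_secondary": (2165, 3847),
        "university": (1082, 1763),
    },
    "pa_level": {
        "low": (2125, 5549),
        "moderate": (1985, 3855),
        "high": (1158, 1738),
    },
}

#: group sizes by overweight status (no, yes) and the grand total
GROUP_TOTALS = (5268, 11142)
N_TOTAL = 16410

#: age mean (SD) by overweight status and overall
AGE_SUMMARY = {
    "no": (40.1, 18.2),
    "yes": (49.0, 17.1),
    "total": (46.1, 17.9),
}

#: mediator-missingness count in the mediation analysis set
N_MISSING_FV = 455


def contingency(variable: str) -> np.ndarray:
    """Levels × outcome (no, yes) count matrix for one variable."""
    if variable not in TABLE1_COUNTS:
        raise KeyError(f"no published counts for {variable!r}")
    return np.array(list(TABLE1_COUNTS[variable].values()), dtype=float)


def expand_counts(variable: str) -> pd.DataFrame:
    """Expand a variable's counts to individual rows (variable, overweight).

    Useful for checking model fits against closed-form contingency-table
    quantities: a logistic fit on the expanded rows must reproduce the
    table's log odds ratios exactly.
    """
    rows = []
    for level, (n_no, n_yes) in TABLE1_COUNTS[variable].items():
        rows.append(pd.DataFrame({variable: level, "overweight": "no"}, index=range(n_no)))
        rows.append(pd.DataFrame({variable: level, "overweight": "yes"}, index=range(n_yes)))
    return pd.concat(rows, ignore_index=True)
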