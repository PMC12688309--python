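"""Cohort table schema shared across modules.

One row per surveyed adult. Categorical columns hold lower-case string
tokens; ``fv_adequate`` may be missing (NaN in memory, empty field on
disk). ``mean_temp_c`` is the annual provincial mean 2 m air temperature
in degrees Celsius and is constant within a province.
"""

from __future__ import annotations

COHORT_COLUMNS = [
    "province_id",
    "mean_temp_c",
    "sex",
    "age",
    "education",
    "fv_adequate",
    "pa_level",
    "overweight",
    "obesity",
]

#: Category levels in canonical order; the first entry is the default
#: reference level used by the model design builder.
CATEGORY_LEVELS: dict[str, list[str]] = {
    "sex": ["male", "female"],
    "education": [
        "university",
        "incomplete_primary",
        "incomplete_secondary",
        "complete_secondary",
    ],
    "pa_level": ["low", "moderate", "high"],
    "fv_adequate": ["no", "yes"],
    "overweight": ["no", "yes"],
    "obesity": ["no", "yes"],
}

DEFAULT_REFERENCES = {k: v[0] for k, v in CATEGORY_LEVELS.items()}

NUMERIC_COLUMNS = ["mean_temp_c", "age"]

#: Order of the non-reference education tokens as they appear in
#: coefficient dictionaries (matches the survey's attainment ordering).
EDUCATION_EFFECT_KEYS = [
    "education[incomplete_primary]",
    "education[incomplete_secondary]",
    "education[complete_secondary]",
]

#: Canonical covariate-effect keys for the structural equations.
COVARIATE_KEYS = ["sex[female]", "age"] + EDUCATION_EFFECT_KEYS
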