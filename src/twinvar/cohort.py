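"""Cohort preparation: exclusion flowchart, weight-status classification,
stratification, and stratum-level summary statistics.

Exclusions follow the registry flowcharts: incomplete pairs first, then
opposite-sex dizygotic pairs, then pairs in which either member has an extreme
BMI (outside the open interval (15, 50) kg/m^2 by default).  Summary
statistics (obesity %, overweight %, mean BMI) are computed on the whole twin
population of a stratum — including members of opposite-sex pairs and of
incomplete pairs — because those proxies only need individual-level BMI.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Optional, Tuple

import numpy as np
import pandas as pd

from .errors import ConfigError, DataError
from .types import (
    DZ_OPPOSITE_SEX,
    ExclusionLog,
    NOT_OVERWEIGHT,
    OBESE,
    OVERWEIGHT_NOT_OBESE,
    SEXES,
    StratumKey,
    StratumSummary,
)

ADULT_OVERWEIGHT_BMI = 25.0
ADULT_OBESITY_BMI = 30.0
DEFAULT_ADULT_AGE = 18
DEFAULT_BMI_LOW = 15.0
DEFAULT_BMI_HIGH = 50.0

_STRATUM_COLS = ["survey_year", "sex", "birth_year"]


# ---------------------------------------------------------------------------
# exclusions


def exclude_pairs(
    pairs: pd.DataFrame,
    bmi_low: float = DEFAULT_BMI_LOW,
    bmi_high: float = DEFAULT_BMI_HIGH,
    n_individuals_input: Optional[int] = None,
) -> Tuple[pd.DataFrame, ExclusionLog]:
    """Apply the pair-selection flowchart to one survey's pairs.

    Removes, in order: incomplete pairs, opposite-sex dizygotic pairs, and
    pairs with either member's BMI strictly below ``bmi_low`` or strictly
    above ``bmi_high`` (a member at exactly 15 or 50 kg/m^2 is retained).
    Returns the eligible pairs and the flowchart accounting.
    """
    if bmi_low >= bmi_high:
        raise ConfigError(f"bmi_low ({bmi_low}) must be below bmi_high ({bmi_high})")

    complete = pairs[pairs["complete"].to_numpy(dtype=bool)]
    n_complete = len(complete)
    same_sex = complete[(complete["zygosity"] != DZ_OPPOSITE_SEX).to_numpy()]
    n_os = n_complete - len(same_sex)
    extreme = (
        (same_sex["bmi1"] < bmi_low) | (same_sex["bmi1"] > bmi_high)
        | (same_sex["bmi2"] < bmi_low) | (same_sex["bmi2"] > bmi_high)
    ).to_numpy()
    eligible = same_sex[~extreme]

    if n_individuals_input is None:
        n_individuals_input = 2 * n_complete + (len(pairs) - n_complete)
    log = ExclusionLog(
        n_individuals_input=int(n_individuals_input),
        n_pairs_incomplete=int(len(pairs) - n_complete),
        n_pairs_complete=int(n_complete),
        n_pairs_opposite_sex_removed=int(n_os),
        n_pairs_extreme_bmi_removed=int(extreme.sum()),
        n_pairs_eligible=int(len(eligible)),
    )
    log.check()
    return eligible.reset_index(drop=True), log


def filter_extreme_individuals(
    records: pd.DataFrame,
    bmi_low: float = DEFAULT_BMI_LOW,
    bmi_high: float = DEFAULT_BMI_HIGH,
) -> pd.DataFrame:
    """Drop individuals with extreme BMI (strict bounds); used before summaries."""
    bmi = records["bmi"].to_numpy()
    return records[(bmi >= bmi_low) & (bmi <= bmi_high)]


# ---------------------------------------------------------------------------
# weight-status classification (WHO adult cut-offs; IOTF child cut-points)

_IOTF_CACHE: Optional[pd.DataFrame] = None


def iotf_table() -> pd.DataFrame:
    """The packaged IOTF (Cole et al.) age- and sex-specific BMI cut-points.

    Half-year ages 2.0–17.5; the cut-offs project the adult 25 and 30 kg/m^2
    thresholds onto childhood ages.
    """
    global _IOTF_CACHE
    if _IOTF_CACHE is None:
        with resources.files("twinvar.data").joinpath("iotf_cutoffs.csv").open() as fh:
            _IOTF_CACHE = pd.read_csv(fh)
    return _IOTF_CACHE


def _iotf_lookup(sex: np.ndarray, age: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    """Overweight/obesity cut-offs at the nearest tabulated half-year age."""
    tab = iotf_table()
    if np.any(age < 2):
        raise ConfigError(
            "age below the youngest tabulated IOTF age (2 years); "
            "child cut-points are undefined there"
        )
    half_age = np.clip(np.round(np.asarray(age, dtype=float) * 2) / 2, 2.0, 17.5)
    ow = np.empty(len(half_age))
    ob = np.empty(len(half_age))
    for s in SEXES:
        sub = tab[tab["sex"] == s].set_index("age_years")
        m = sex == s
        ow[m] = sub["cutoff_overweight"].reindex(half_age[m]).to_numpy()
        ob[m] = sub["cutoff_obesity"].reindex(half_age[m]).to_numpy()
    return ow, ob


def weight_status_codes(
    bmi: np.ndarray,
    age: np.ndarray,
    sex: np.ndarray,
    adult_age: int = DEFAULT_ADULT_AGE,
) -> np.ndarray:
    """Vectorized classification: 0 not overweight, 1 overweight (not obese), 2 obese.

    Adults (age >= ``adult_age``) use BMI >= 25 / >= 30; younger individuals
    use the packaged IOTF cut-points at the nearest half-year age.
    """
    bmi = np.asarray(bmi, dtype=float)
    age = np.asarray(age)
    sex = np.asarray(sex)
    ow_cut = np.full(bmi.shape, ADULT_OVERWEIGHT_BMI)
    ob_cut = np.full(bmi.shape, ADULT_OBESITY_BMI)
    child = age < adult_age
    if child.any():
        ow_cut[child], ob_cut[child] = _iotf_lookup(sex[child], age[child])
    return (bmi >= ow_cut).astype(np.int64) + (bmi >= ob_cut)


def classify_weight_status(
    bmi: float, age: float, sex: str = "M", adult_age: int = DEFAULT_ADULT_AGE
) -> str:
    """Scalar weight-status label for one individual."""
    if bmi <= 0:
        raise DataError(f"non-positive BMI: {bmi}")
    code = int(weight_status_codes(np.array([bmi]), np.array([age]), np.array([sex]), adult_age)[0])
    return (NOT_OVERWEIGHT, OVERWEIGHT_NOT_OBESE, OBESE)[code]


# ---------------------------------------------------------------------------
# stratification and summaries


def stratify(df: pd.DataFrame):
    """Group records (or pairs) by stratum (survey_year, sex, birth_year).

    Individual records always land in their own sex's stratum, so an
    opposite-sex pair contributes its male member to the male stratum and its
    female member to the female stratum.  Pair frames must already be
    restricted to same-sex pairs before stratified model fitting.
    """
    return df.groupby(_STRATUM_COLS, sort=True)


def stratum_keys(df: pd.DataFrame) -> list:
    return [StratumKey(int(s), sex, int(b)) for (s, sex, b) in stratify(df).groups.keys()]


def summarize_strata(
    records: pd.DataFrame,
    adult_age: int = DEFAULT_ADULT_AGE,
) -> pd.DataFrame:
    """Per-stratum obesity %, overweight %, and mean BMI from all individuals.

    ``overweight_pct`` is prevalence at the lower cut-off (BMI >= 25 for
    adults), so it includes obese individuals — the WHO convention; obesity is
    therefore a subset of overweight for every individual.
    """
    if len(records) == 0:
        raise DataError("no records to summarize")
    age = (records["survey_year"] - records["birth_year"]).to_numpy()
    codes = weight_status_codes(records["bmi"].to_numpy(), age, records["sex"].to_numpy(), adult_age)
    work = records[_STRATUM_COLS].copy()
    work["bmi"] = records["bmi"].to_numpy()
    work["is_ow"] = codes >= 1
    work["is_ob"] = codes == 2
    out = (
        work.groupby(_STRATUM_COLS, sort=True)
        .agg(n_individuals=("bmi", "size"), mean_bmi=("bmi", "mean"),
             obesity_pct=("is_ob", "mean"), overweight_pct=("is_ow", "mean"))
        .reset_index()
    )
    out["obesity_pct"] *= 100.0
    out["overweight_pct"] *= 100.0
    out["age"] = out["survey_year"] - out["birth_year"]
    return out


def summarize_stratum(records: pd.DataFrame, adult_age: int = DEFAULT_ADULT_AGE) -> StratumSummary:
    """Summary for a frame holding exactly one stratum's individuals."""
    out = summarize_strata(records, adult_age=adult_age)
    if len(out) != 1:
        raise DataError(f"expected a single stratum, found {len(out)}")
    r = out.iloc[0]
    return StratumSummary(
        key=StratumKey(int(r.survey_year), r.sex, int(r.birth_year)),
        n_individuals=int(r.n_individuals),
        n_pairs_eligible=0,
        obesity_pct=float(r.obesity_pct),
        overweight_pct=float(r.overweight_pct),
        mean_bmi=float(r.mean_bmi),
    )
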