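"""Reading and writing the tabular formats the pipeline consumes and produces.

Cohort input is delimited text (UTF-8, header row) with one row per surveyed
individual and the columns in :data:`COHORT_COLUMNS`.  Column names can be
remapped and the height unit switched to centimetres through a
:class:`TableDialect`.  BMI is always recomputed from height and weight so the
derived column has a single source of truth.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Optional, Tuple

import numpy as np
import pandas as pd

from .errors import ConfigError, DataError
from .types import (
    DZ_OPPOSITE_SEX,
    FEMALE,
    MALE,
    ReadLog,
    TwinPair,
    TwinRecord,
    ZYGOSITIES,
)

#: Required cohort columns (canonical names).
COHORT_COLUMNS = [
    "person_id",
    "pair_id",
    "zygosity",
    "sex",
    "birth_year",
    "survey_year",
    "height_m",
    "weight_kg",
]

_SEX_ALIASES = {
    "M": MALE, "male": MALE, "m": MALE, "1": MALE,
    "F": FEMALE, "female": FEMALE, "f": FEMALE, "2": FEMALE,
}


@dataclass
class TableDialect:
    """How a cohort file deviates from the canonical schema.

    ``column_map`` maps canonical name -> name used in the file;
    ``height_unit`` is ``"m"`` or ``"cm"``.
    """

    delimiter: str = ","
    column_map: dict = field(default_factory=dict)
    height_unit: str = "m"

    def __post_init__(self):
        if self.height_unit not in ("m", "cm"):
            raise ConfigError(f"height_unit must be 'm' or 'cm', got {self.height_unit!r}")


def read_cohort(path, dialect: Optional[TableDialect] = None) -> Tuple[pd.DataFrame, ReadLog]:
    """Read a cohort file into the canonical cohort frame.

    Rows whose height or weight does not parse as a positive number are
    dropped and counted in the returned :class:`~twinvar.types.ReadLog`.

    Raises
    ------
    ConfigError
        If a required column is missing.
    DataError
        If the same person appears twice within a survey.
    """
    dialect = dialect or TableDialect()
    if not os.path.exists(path):
        raise ConfigError(f"cohort file not found: {path}")
    raw = pd.read_csv(path, sep=dialect.delimiter, dtype={"person_id": str, "pair_id": str})
    rename = {v: k for k, v in dialect.column_map.items()}
    raw = raw.rename(columns=rename)
    missing = [c for c in COHORT_COLUMNS if c not in raw.columns]
    if missing:
        raise ConfigError(f"missing required column(s): {', '.join(missing)}")
    return cohort_from_frame(raw[COHORT_COLUMNS], height_unit=dialect.height_unit)


def cohort_from_frame(df: pd.DataFrame, height_unit: str = "m") -> Tuple[pd.DataFrame, ReadLog]:
    """Validate and normalize an in-memory cohort frame.

    Returns the canonical frame (with a recomputed ``bmi`` column) and a read
    log counting rows dropped for unparseable anthropometry.
    """
    df = df.copy()
    n_in = len(df)
    for col in ("height_m", "weight_kg"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
    for col in ("birth_year", "survey_year"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
    bad_years = df["birth_year"].isna() | df["survey_year"].isna()
    if bad_years.any():
        raise DataError(f"{int(bad_years.sum())} rows with unparseable birth/survey year")

    ok = (df["height_m"] > 0) & (df["weight_kg"] > 0)
    df = df.loc[ok.to_numpy()].reset_index(drop=True)
    log = ReadLog(n_rows_read=n_in, n_dropped_unparseable=int(n_in - len(df)))

    df["birth_year"] = df["birth_year"].astype(np.int64)
    df["survey_year"] = df["survey_year"].astype(np.int64)
    if height_unit == "cm":
        df["height_m"] = df["height_m"] / 100.0

    sex = df["sex"].astype(str).map(_SEX_ALIASES)
    if sex.isna().any():
        bad = sorted(df.loc[sex.isna(), "sex"].astype(str).unique())
        raise DataError(f"unrecognized sex value(s): {bad}")
    df["sex"] = sex

    bad_zyg = ~df["zygosity"].isin(ZYGOSITIES)
    if bad_zyg.any():
        raise DataError(
            f"unrecognized zygosity value(s): {sorted(df.loc[bad_zyg, 'zygosity'].unique())}"
        )

    if (df["survey_year"] < df["birth_year"]).any():
        raise DataError("record with survey_year < birth_year (negative age)")

    if df.duplicated(subset=["person_id", "survey_year"]).any():
        dup = df.loc[df.duplicated(subset=["person_id", "survey_year"]), "person_id"].iloc[0]
        raise DataError(f"duplicate (person_id, survey_year), e.g. person {dup!r}")

    df["bmi"] = df["weight_kg"].to_numpy() / df["height_m"].to_numpy() ** 2
    return df, log


def write_cohort(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False, columns=[c for c in df.columns if c != "bmi"])


# ---------------------------------------------------------------------------
# pairing


PAIR_COLUMNS = [
    "pair_id", "survey_year", "zygosity", "sex", "birth_year",
    "person_id1", "person_id2", "bmi1", "bmi2", "complete",
]


def pair_records(df: pd.DataFrame) -> pd.DataFrame:
    """Group individual records into twin-pair units.

    One output row per (pair_id, survey_year).  Singleton records (co-twin not
    responding) yield incomplete pairs with ``bmi2`` missing — they are
    retained because the raw-data twin likelihood can use them.  ``sex`` is the
    pair sex for same-sex pairs and ``"OS"`` for opposite-sex pairs.

    Raises :class:`DataError` on more than two records per pair or on pairs
    whose members disagree on zygosity, birth year, or (same-sex) sex.
    """
    if len(df) == 0:
        return pd.DataFrame(columns=PAIR_COLUMNS)

    if pd.api.types.is_integer_dtype(df["pair_id"]):
        # fast path: pack (pair_id, survey) into one integer key
        surveys = np.sort(df["survey_year"].unique())
        si = np.searchsorted(surveys, df["survey_year"].to_numpy())
        raw = df["pair_id"].to_numpy(dtype=np.int64) * len(surveys) + si
        _, codes = np.unique(raw, return_inverse=True)
    else:
        key = df["pair_id"].astype(str) + "\x1f" + df["survey_year"].astype(str)
        codes, _ = pd.factorize(key, sort=False)
    n_groups = codes.max() + 1
    counts = np.bincount(codes, minlength=n_groups)
    order = np.argsort(codes, kind="stable")
    starts = np.zeros(n_groups, dtype=np.int64)
    starts[1:] = np.cumsum(counts)[:-1]
    if counts.max() > 2:
        gi = int(np.argmax(counts >= 3))
        bad = df["pair_id"].to_numpy()[order[starts[gi]]]
        raise DataError(f"more than two records share pair_id {bad!r} within a survey")
    i1 = order[starts]
    has2 = counts == 2
    i2 = order[starts[has2] + 1]

    zyg = df["zygosity"].to_numpy()
    sex = df["sex"].to_numpy()
    by = df["birth_year"].to_numpy()
    bmi = df["bmi"].to_numpy()

    if not np.array_equal(zyg[i1[has2]], zyg[i2]):
        raise DataError("pair with members of different zygosity")
    if not np.array_equal(by[i1[has2]], by[i2]):
        raise DataError("pair with members of different birth year")
    ss = zyg[i1[has2]] != DZ_OPPOSITE_SEX
    if not np.array_equal(sex[i1[has2]][ss], sex[i2][ss]):
        raise DataError("same-sex pair with members of different sex")
    if np.any(sex[i1[has2]][~ss] == sex[i2][~ss]):
        raise DataError("opposite-sex pair with members of the same sex")

    pair_sex = sex[i1].astype(object)
    pair_sex[zyg[i1] == DZ_OPPOSITE_SEX] = "OS"
    bmi2 = np.full(n_groups, np.nan)
    bmi2[has2] = bmi[i2]
    pid2 = np.full(n_groups, None, dtype=object)
    pid2[has2] = df["person_id"].to_numpy()[i2]

    return pd.DataFrame(
        {
            "pair_id": df["pair_id"].to_numpy()[i1],
            "survey_year": df["survey_year"].to_numpy()[i1],
            "zygosity": zyg[i1],
            "sex": pair_sex,
            "birth_year": by[i1],
            "person_id1": df["person_id"].to_numpy()[i1],
            "person_id2": pid2,
            "bmi1": bmi[i1],
            "bmi2": bmi2,
            "complete": has2,
        }
    )


def to_records(df: pd.DataFrame) -> list:
    """Typed row views (small cohorts only; the pipeline stays vectorized)."""
    return [
        TwinRecord(
            person_id=r.person_id, pair_id=r.pair_id, zygosity=r.zygosity, sex=r.sex,
            birth_year=int(r.birth_year), survey_year=int(r.survey_year),
            height=float(r.height_m), weight=float(r.weight_kg),
        )
        for r in df.itertuples(index=False)
    ]


def to_pairs(pairs_df: pd.DataFrame, cohort_df: pd.DataFrame) -> list:
    """Typed pair views built from a pairs frame and its source cohort."""
    recs = {(r.person_id, r.survey_year): r for r in to_records(cohort_df)}
    out = []
    for p in pairs_df.itertuples(index=False):
        members = [recs[(p.person_id1, p.survey_year)]]
        if p.complete:
            members.append(recs[(p.person_id2, p.survey_year)])
        out.append(
            TwinPair(
                pair_id=p.pair_id,
                zygosity=p.zygosity,
                members=members,
                sex=None if p.sex == "OS" else p.sex,
            )
        )
    return out


# ---------------------------------------------------------------------------
# result tables

STRATUM_TABLE_COLUMNS = [
    "survey_year", "sex", "birth_year", "age", "n_individuals", "n_pairs",
    "n_pairs_mz", "n_pairs_dz", "obesity_pct", "overweight_pct", "mean_bmi",
    "model", "agv", "agsd", "agsd_se", "esd", "esd_se", "loglik",
    "heritability", "flagged",
]


def write_stratum_table(table: pd.DataFrame, path) -> None:
    """Write the per-stratum summary + fit table (Table-S1-shaped) as CSV.

    Floats are written at full repr precision so the table round-trips
    losslessly through :func:`read_stratum_table`.
    """
    cols = [c for c in STRATUM_TABLE_COLUMNS if c in table.columns]
    table.to_csv(path, index=False, columns=cols)


def read_stratum_table(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_meta_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=False)
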