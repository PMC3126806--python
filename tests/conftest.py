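"""Shared fixtures: programmatic cohort builders (no data files)."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from twinvar.types import DZ_OPPOSITE_SEX, DZ_SAME_SEX, FEMALE, MALE, MZ

settings.register_profile("suite", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("suite")


def make_cohort(rows):
    """Cohort frame from (person, pair, zyg, sex, by, sy, h, w) tuples."""
    cols = ["person_id", "pair_id", "zygosity", "sex", "birth_year",
            "survey_year", "height_m", "weight_kg"]
    return pd.DataFrame(rows, columns=cols)


def make_pairs(
    n_mz_m=0, n_dz_m=0, n_mz_f=0, n_dz_f=0, n_os=0,
    n_extreme=0, n_incomplete=0, survey_year=1994, birth_year=1960,
    bmi=22.0, extreme_bmi=55.0, start_id=0,
):
    """Pairs frame with given class counts (for exclusion-flowchart tests).

    Extreme pairs are same-sex DZ with one member's BMI at ``extreme_bmi``;
    incomplete pairs are singleton MZ records.
    """
    rows = []
    i = start_id

    def add(n, zyg, sex, b1, b2, complete=True):
        nonlocal i
        for _ in range(n):
            rows.append(
                dict(pair_id=i, survey_year=survey_year, zygosity=zyg, sex=sex,
                     birth_year=birth_year, person_id1=i * 10 + 1,
                     person_id2=(i * 10 + 2) if complete else None,
                     bmi1=b1, bmi2=b2 if complete else np.nan, complete=complete)
            )
            i += 1

    add(n_mz_m, MZ, MALE, bmi, bmi)
    add(n_dz_m, DZ_SAME_SEX, MALE, bmi, bmi)
    add(n_mz_f, MZ, FEMALE, bmi, bmi)
    add(n_dz_f, DZ_SAME_SEX, FEMALE, bmi, bmi)
    add(n_os, DZ_OPPOSITE_SEX, "OS", bmi, bmi)
    add(n_extreme, DZ_SAME_SEX, MALE, bmi, extreme_bmi)
    add(n_incomplete, MZ, MALE, bmi, np.nan, complete=False)
    return pd.DataFrame(rows)


def draw_ae_pairs(rng, n, mu, var_a, var_e, share):
    """Bivariate AE pair phenotypes with genetic sharing ``share``."""
    v = var_a + var_e
    c = share * var_a
    s = np.sqrt(v)
    z1 = rng.standard_normal(n)
    z2 = rng.standard_normal(n)
    return mu + s * z1, mu + (c / s) * z1 + np.sqrt(v - c * c / v) * z2


@pytest.fixture
def ae_dataset():
    """Factory: sufficient statistics for simulated AE twin data."""
    from twinvar.twin_model import ZygosityData

    def make(n_mz, n_dz, mu=22.0, var_a=9.0, var_e=3.0, seed=0, singles_mz=(), singles_dz=()):
        rng = np.random.default_rng(seed)
        x1, x2 = draw_ae_pairs(rng, n_mz, mu, var_a, var_e, 1.0)
        y1, y2 = draw_ae_pairs(rng, n_dz, mu, var_a, var_e, 0.5)
        return (
            ZygosityData.from_arrays(x1, x2, singles=singles_mz or None),
            ZygosityData.from_arrays(y1, y2, singles=singles_dz or None),
            (x1, x2, y1, y2),
        )

    return make


@pytest.fixture
def small_cohort():
    """Six records forming three complete same-sex pairs in one survey."""
    return make_cohort([
        ("p1", "a", MZ, MALE, 1960, 1994, 1.80, 75.0),
        ("p2", "a", MZ, MALE, 1960, 1994, 1.78, 72.0),
        ("p3", "b", DZ_SAME_SEX, FEMALE, 1955, 1994, 1.65, 60.0),
        ("p4", "b", DZ_SAME_SEX, FEMALE, 1955, 1994, 1.68, 65.0),
        ("p5", "c", DZ_OPPOSITE_SEX, MALE, 1970, 1994, 1.82, 80.0),
        ("p6", "c", DZ_OPPOSITE_SEX, FEMALE, 1970, 1994, 1.66, 58.0),
    ])
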