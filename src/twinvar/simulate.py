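"""Synthetic twin-cohort generator.

Generates two survey waves of MZ / same-sex DZ / opposite-sex DZ twin pairs
whose BMI follows an AE variance structure in every sex x birth-year stratum,
with the additive genetic SD (AGSD) tied to an obesity-promoting environment
index by a linear law:

* ``agsd_law="obesity_pct"``: AGSD = alpha + beta * target obesity prevalence
  (percent), the gene-environment-interaction hypothesis under test;
* ``agsd_law="mean_bmi"``: AGSD = alpha + beta * stratum mean BMI, solved as a
  fixed point jointly with the mean calibration below.

The stratum mean is calibrated against the adult obesity threshold so that the
realized prevalence fluctuates around its target:
``mu = 30 - z_{1-p} * sqrt(agsd^2 + esd^2)`` with ``p`` the target fraction.

The default target-prevalence profile is a sex-specific convex decline across
birth year (recent cohorts are younger at survey and leaner) plus a
deterministic per-(sex, birth-year) cohort-heterogeneity term keyed by a fixed
constant, NOT by the run seed: the targets are part of the study design and
stay identical across replicates.  The heterogeneity (and the profile's
curvature) is what makes the proxy effect identifiable alongside the age and
survey moderators; a profile exactly linear in birth year would be collinear
with them (see the methods note).

BMI is generated directly on the phenotype scale; height is drawn from fixed
sex-specific normals and weight back-computed so the I/O schema is exercised.
A single seed drives per-stratum substreams (``default_rng((seed, ordinal))``
over the deterministic stratum enumeration) so strata are independently
reproducible and output is byte-identical for a fixed seed.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .cohort import DEFAULT_ADULT_AGE, _iotf_lookup
from .errors import ConfigError
from .types import DZ_OPPOSITE_SEX, DZ_SAME_SEX, FEMALE, MALE, MZ, StratumKey

#: Fixed sex-specific height distributions (m) used to dress BMI up as
#: height/weight; decorative for the analysis, which touches only BMI.
HEIGHT_MEAN = {MALE: 1.79, FEMALE: 1.66}
HEIGHT_SD = {MALE: 0.065, FEMALE: 0.060}

ADULT_OBESITY_BMI = 30.0


@dataclass
class GeneratorConfig:
    """Study-design parameters of the synthetic cohort.

    Defaults emulate the two registry waves: 1994 covering births 1953-1982
    and 2002 covering 1931-1982 (164 sex x birth-year strata), ~45% MZ among
    same-sex pairs, ~30% opposite-sex pairs, ~72% person overlap between
    waves, target obesity prevalence ~1-15% with AGSD ~2.7-4.1 kg/m^2 and
    heritability in the 0.6-0.8 band.
    """

    surveys: Tuple[Tuple[int, int, int], ...] = ((1994, 1953, 1982), (2002, 1931, 1982))
    n_pairs_per_stratum: int = 150
    mz_fraction: float = 0.45            # of same-sex pairs
    opposite_sex_fraction: float = 0.30  # of all pairs
    # target-prevalence profile
    prevalence_mode: str = "cohort"      # "cohort" | "linear" | "explicit"
    prevalence_min: float = 1.0          # percent, most recent cohort
    prevalence_max: float = 14.0         # percent, oldest cohort
    prevalence_shape: Dict[str, float] = field(
        default_factory=lambda: {MALE: 1.8, FEMALE: 2.2}
    )
    heterogeneity_sd: float = 2.5        # percentage points, per (sex, birth year)
    heterogeneity_key: int = 711031      # fixed; independent of the run seed
    prevalence_floor: float = 0.5        # percent; a target of 0 is unattainable
    prevalence_ceiling: float = 30.0
    explicit_prevalence: Optional[dict] = None  # (survey, sex, birth_year) -> pct
    # AGSD law and E component
    agsd_law: str = "obesity_pct"        # "obesity_pct" | "mean_bmi"
    baseline_alpha: float = 2.5          # kg/m^2 (AGSD at proxy 0)
    slope_beta: float = 0.095            # kg/m^2 per proxy unit
    sigma_e: float = 1.7                 # kg/m^2, unique environmental SD
    overlap_fraction: float = 0.72       # persons re-emitted in the second wave
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.mz_fraction <= 1.0:
            raise ConfigError("mz_fraction must be in [0, 1]")
        if not 0.0 <= self.opposite_sex_fraction < 1.0:
            raise ConfigError("opposite_sex_fraction must be in [0, 1)")
        if not 0.0 <= self.overlap_fraction <= 1.0:
            raise ConfigError("overlap_fraction must be in [0, 1]")
        if self.sigma_e <= 0:
            raise ConfigError("sigma_e must be positive")
        if self.prevalence_mode not in ("cohort", "linear", "explicit"):
            raise ConfigError(f"unknown prevalence_mode {self.prevalence_mode!r}")
        if self.agsd_law not in ("obesity_pct", "mean_bmi"):
            raise ConfigError(f"unknown agsd_law {self.agsd_law!r}")
        if not 0.0 <= self.prevalence_floor < 100.0:
            raise ConfigError("prevalence_floor must be in [0, 100)")
        for p in (self.prevalence_min, self.prevalence_max):
            if not 0.0 <= p < 100.0:
                raise ConfigError("target prevalences must be in [0, 100)")


@dataclass
class StratumTruth:
    """Generating values for one stratum (emitted alongside the cohort)."""

    key: StratumKey
    target_obesity_pct: float
    true_agsd: float
    true_esd: float
    true_mu: float

    @property
    def total_sd(self) -> float:
        return math.hypot(self.true_agsd, self.true_esd)

    @property
    def heritability(self) -> float:
        return self.true_agsd**2 / (self.true_agsd**2 + self.true_esd**2)


# ---------------------------------------------------------------------------
# calibration


def _birth_span(config: GeneratorConfig) -> Tuple[int, int]:
    lo = min(s[1] for s in config.surveys)
    hi = max(s[2] for s in config.surveys)
    return lo, hi


def target_prevalence(config: GeneratorConfig, key: StratumKey) -> float:
    """Target obesity prevalence (percent) for one stratum; seed-independent."""
    if config.prevalence_mode == "explicit":
        if config.explicit_prevalence is None:
            raise ConfigError("explicit prevalence_mode requires explicit_prevalence")
        p = float(config.explicit_prevalence[(key.survey_year, key.sex, key.birth_year)])
        if not 0.0 <= p < 100.0:
            raise ConfigError(f"explicit target prevalence {p} outside [0, 100)")
        return max(p, config.prevalence_floor)

    lo, hi = _birth_span(config)
    t = (hi - key.birth_year) / max(hi - lo, 1)  # 0 for newest cohort, 1 for oldest
    if config.prevalence_mode == "cohort":
        shape = config.prevalence_shape[key.sex]
        base = config.prevalence_min + (config.prevalence_max - config.prevalence_min) * t**shape
    else:  # linear ramp in birth year
        base = config.prevalence_min + (config.prevalence_max - config.prevalence_min) * t
    if config.heterogeneity_sd > 0:
        sub = np.random.default_rng(
            (config.heterogeneity_key, key.birth_year, 0 if key.sex == MALE else 1)
        )
        base += config.heterogeneity_sd * float(sub.standard_normal())
    return min(max(base, config.prevalence_floor), config.prevalence_ceiling)


def obesity_threshold(key: StratumKey, adult_age: int = DEFAULT_ADULT_AGE) -> float:
    """Obesity cut-off in force for a stratum: 30 kg/m^2 for adults, the IOTF
    age- and sex-specific cut-point below ``adult_age``."""
    if key.age >= adult_age:
        return ADULT_OBESITY_BMI
    _, ob = _iotf_lookup(np.array([key.sex]), np.array([key.age]))
    return float(ob[0])


def calibrate_stratum(config: GeneratorConfig, key: StratumKey) -> StratumTruth:
    """Derive (AGSD, ESD, mu) for one stratum from its target prevalence.

    The mean is placed so that a Normal(mu, agsd^2 + esd^2) phenotype exceeds
    the stratum's obesity threshold with the target probability; it is the
    age-appropriate threshold (IOTF below adult age) so that the prevalence
    the pipeline later measures is an unbiased estimate of the target in
    every stratum, adolescents included.  A target of 50% puts the mean
    exactly at the threshold.
    """
    p = target_prevalence(config, key)
    if p <= 0.0:
        warnings.warn("target prevalence 0 is attainable only in the limit; using the floor")
        p = max(config.prevalence_floor, 1e-3)
    cut = obesity_threshold(key)
    esd = config.sigma_e
    if config.agsd_law == "obesity_pct":
        agsd = config.baseline_alpha + config.slope_beta * p
        if agsd <= 0:
            raise ConfigError("AGSD law yields a non-positive SD; adjust alpha/beta")
        mu = cut - stats.norm.ppf(1.0 - p / 100.0) * math.hypot(agsd, esd)
    else:  # AGSD linear in the calibrated stratum mean BMI: joint root-find
        z = stats.norm.ppf(1.0 - p / 100.0)

        def gap(a: float) -> float:
            return a - config.baseline_alpha - config.slope_beta * (cut - z * math.hypot(a, esd))

        if gap(1e-9) >= 0.0 or gap(1e3) <= 0.0:
            raise ConfigError("mean-BMI AGSD law has no positive solution; adjust alpha/beta")
        agsd = optimize.brentq(gap, 1e-9, 1e3, xtol=1e-12)
        mu = cut - z * math.hypot(agsd, esd)
    return StratumTruth(key=key, target_obesity_pct=p, true_agsd=agsd, true_esd=esd, true_mu=mu)


# ---------------------------------------------------------------------------
# simulation


def _draw_pairs(rng, n: int, mu: float, a: float, e: float, share: float):
    """n pairs from the bivariate AE structure with genetic sharing ``share``."""
    v = a * a + e * e
    c = share * a * a
    s = math.sqrt(v)
    z1 = rng.standard_normal(n)
    z2 = rng.standard_normal(n)
    x1 = mu + s * z1
    x2 = mu + (c / s) * z1 + math.sqrt(v - c * c / v) * z2
    return x1, x2


def _draw_os_pairs(rng, n: int, tm: StratumTruth, tf: StratumTruth):
    """Opposite-sex pairs: sex-specific marginals, 0.5 genetic correlation."""
    g = math.sqrt(0.5)
    zg = rng.standard_normal(n)
    gm = g * zg + g * rng.standard_normal(n)
    gf = g * zg + g * rng.standard_normal(n)
    xm = tm.true_mu + tm.true_agsd * gm + tm.true_esd * rng.standard_normal(n)
    xf = tf.true_mu + tf.true_agsd * gf + tf.true_esd * rng.standard_normal(n)
    return xm, xf


def _interleave(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    out = np.empty(a.size + b.size, dtype=a.dtype)
    out[0::2] = a
    out[1::2] = b
    return out


def _encode_pair_ids(origin, cls: int, sex_code: int, birth_year: int, ordinals) -> np.ndarray:
    """Deterministic integer pair ids; ``origin`` marks the wave that minted them."""
    base = ((np.asarray(origin, dtype=np.int64) * 3 + cls) * 2 + sex_code) * 100 + (
        birth_year - 1900
    )
    return base * 1_000_000 + np.asarray(ordinals, dtype=np.int64)


def simulate_stratum(
    truth: StratumTruth,
    n_mz: int,
    n_dz_ss: int,
    n_dz_os: int,
    rng,
    truth_other: Optional[StratumTruth] = None,
) -> pd.DataFrame:
    """Records for one stratum (plus optional opposite-sex pairs).

    Opposite-sex pairs put the male member first; their second member follows
    ``truth_other`` when given (the co-stratum of the other sex), otherwise
    the same truth.  Pair/person ids are local to this call.
    """
    parts = _simulate_class_arrays(truth, n_mz, n_dz_ss, n_dz_os, rng,
                                   truth_other or truth, origin=0)
    return _frames_from_parts(parts)


def _simulate_class_arrays(truth, n_mz, n_dz_ss, n_dz_os, rng, truth_os_f, origin):
    """Generate per-class record arrays for one (survey, birth-year, sex) cell."""
    if min(n_mz, n_dz_ss, n_dz_os) < 0:
        raise ConfigError("pair counts must be non-negative")
    key = truth.key
    sex_code = 0 if key.sex == MALE else 1
    out = []
    for cls, n, share in ((0, n_mz, 1.0), (1, n_dz_ss, 0.5)):
        if n == 0:
            continue
        x1, x2 = _draw_pairs(rng, n, truth.true_mu, truth.true_agsd, truth.true_esd, share)
        pid = _encode_pair_ids(np.full(n, origin), cls, sex_code, key.birth_year, np.arange(n))
        out.append(
            _records(pid, x1, x2, (MZ if cls == 0 else DZ_SAME_SEX),
                     np.array([key.sex, key.sex]), key, rng)
        )
    if n_dz_os:
        xm, xf = _draw_os_pairs(rng, n_dz_os, truth, truth_os_f)
        pid = _encode_pair_ids(np.full(n_dz_os, origin), 2, 0, key.birth_year, np.arange(n_dz_os))
        out.append(_records(pid, xm, xf, DZ_OPPOSITE_SEX, np.array([MALE, FEMALE]), key, rng))
    return out


def _records(pair_ids, x1, x2, zygosity, member_sexes, key, rng):
    """Two interleaved record rows per pair, heights drawn per member sex."""
    n = len(pair_ids)
    bmi = _interleave(x1, x2)
    sex = np.tile(member_sexes, n)
    hmean = np.where(sex == MALE, HEIGHT_MEAN[MALE], HEIGHT_MEAN[FEMALE])
    hsd = np.where(sex == MALE, HEIGHT_SD[MALE], HEIGHT_SD[FEMALE])
    height = hmean + hsd * rng.standard_normal(2 * n)
    return {
        "person_id": _interleave(pair_ids * 10 + 1, pair_ids * 10 + 2),
        "pair_id": np.repeat(pair_ids, 2),
        "zygosity": zygosity,
        "sex": sex,
        "birth_year": key.birth_year,
        "survey_year": key.survey_year,
        "height_m": height,
        "weight_kg": bmi * height**2,
        "bmi": bmi,
    }


def _frames_from_parts(parts: List[dict]) -> pd.DataFrame:
    cols = ["person_id", "pair_id", "zygosity", "sex", "birth_year", "survey_year",
            "height_m", "weight_kg", "bmi"]
    data = {}
    for c in cols:
        pieces = []
        for p in parts:
            val = p[c]
            n = len(p["person_id"])
            if np.ndim(val) == 0:
                pieces.append(np.full(n, val))
            else:
                pieces.append(np.asarray(val))
        data[c] = np.concatenate(pieces)
    return pd.DataFrame(data)


def _class_counts(config: GeneratorConfig) -> Tuple[int, int, int]:
    n = config.n_pairs_per_stratum
    n_os = int(round(n * config.opposite_sex_fraction))
    n_ss = n - n_os
    n_mz = int(round(n_ss * config.mz_fraction))
    return n_mz, n_ss - n_mz, n_os


def simulate_cohort(config: GeneratorConfig) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Generate the full two-wave cohort and its truth table.

    Returns ``(cohort, truth)``: the cohort frame in the canonical I/O schema
    (plus the generated ``bmi`` column) and one truth row per stratum.
    ``overlap_fraction`` of the first wave's persons are re-emitted in the
    second wave under the same person/pair ids with BMI redrawn from the
    second wave's stratum truth (ids overlap; values are resampled).
    """
    n_mz, n_dz, n_os = _class_counts(config)
    survey_order = sorted(config.surveys)
    if config.overlap_fraction > 0 and len(survey_order) > 1:
        r0 = range(survey_order[0][1], survey_order[0][2] + 1)
        r1 = range(survey_order[1][1], survey_order[1][2] + 1)
        if not set(r0) & set(r1):
            raise ConfigError("overlap requested but survey birth-year ranges are disjoint")

    truths: Dict[StratumKey, StratumTruth] = {}
    parts: List[dict] = []
    ordinal = 0
    for si, (sy, by_lo, by_hi) in enumerate(survey_order):
        prev_range = range(survey_order[0][1], survey_order[0][2] + 1) if si == 1 else range(0)
        for by in range(by_lo, by_hi + 1):
            overlapped = si == 1 and config.overlap_fraction > 0 and by in prev_range
            tm = calibrate_stratum(config, StratumKey(sy, MALE, by))
            tf = calibrate_stratum(config, StratumKey(sy, FEMALE, by))
            truths[tm.key] = tm
            truths[tf.key] = tf
            for truth in (tm, tf):
                rng = np.random.default_rng((config.seed, ordinal))
                ordinal += 1
                new = _simulate_class_arrays(truth, n_mz, n_dz, 0, rng, tf, origin=si)
                parts.extend(_apply_overlap(new, overlapped, config.overlap_fraction))
            rng = np.random.default_rng((config.seed, ordinal))
            ordinal += 1
            os_part = _simulate_class_arrays(tm, 0, 0, n_os, rng, tf, origin=si)
            parts.extend(_apply_overlap(os_part, overlapped, config.overlap_fraction))

    cohort = _frames_from_parts(parts)
    truth_rows = [
        {
            "survey_year": t.key.survey_year, "sex": t.key.sex,
            "birth_year": t.key.birth_year, "target_obesity_pct": t.target_obesity_pct,
            "true_agsd": t.true_agsd, "true_esd": t.true_esd, "true_mu": t.true_mu,
            "true_heritability": t.heritability,
        }
        for t in truths.values()
    ]
    truth = pd.DataFrame(truth_rows).sort_values(
        ["survey_year", "sex", "birth_year"], ignore_index=True
    )
    return cohort, truth


def _apply_overlap(class_parts: List[dict], overlapped: bool, frac: float) -> List[dict]:
    """Re-point the first ``frac`` of each class's second-wave pairs at the
    ids minted by the first wave (same ordinals, origin 0)."""
    if not overlapped:
        return class_parts
    for part in class_parts:
        pair_ids = part["pair_id"]
        n_pairs = len(pair_ids) // 2
        k = int(round(frac * n_pairs))
        if k == 0:
            continue
        # origin bit lives in the leading digit group: subtracting moves
        # origin 1 -> 0 while preserving class/sex/birth-year/ordinal
        shift = 3 * 2 * 100 * 1_000_000
        take = np.zeros(n_pairs, dtype=bool)
        take[:k] = True
        rows = np.repeat(take, 2)
        part["pair_id"] = np.where(rows, pair_ids - shift, pair_ids)
        part["person_id"] = np.where(rows, part["person_id"] - shift * 10, part["person_id"])
    return class_parts


def write_truth_table(truth: pd.DataFrame, path) -> None:
    truth.to_csv(path, index=False)
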