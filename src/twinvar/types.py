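"""Domain types for the twin-cohort analysis.

The package's working representation of a cohort is a :class:`pandas.DataFrame`
with the columns of :data:`twinvar.io.COHORT_COLUMNS`; the dataclasses here are
typed views of single rows / pair units plus the result containers produced by
the fitting and meta-regression stages.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

MZ = "MZ"
DZ_SAME_SEX = "DZ_same_sex"
DZ_OPPOSITE_SEX = "DZ_opposite_sex"
ZYGOSITIES = (MZ, DZ_SAME_SEX, DZ_OPPOSITE_SEX)

MALE = "M"
FEMALE = "F"
SEXES = (MALE, FEMALE)

NOT_OVERWEIGHT = "not_overweight"
OVERWEIGHT_NOT_OBESE = "overweight_not_obese"
OBESE = "obese"
WEIGHT_STATUS = (NOT_OVERWEIGHT, OVERWEIGHT_NOT_OBESE, OBESE)


@dataclass(frozen=True)
class StratumKey:
    """Identifies one analysis subgroup: survey wave x sex x single birth year."""

    survey_year: int
    sex: str
    birth_year: int

    @property
    def age(self) -> int:
        return self.survey_year - self.birth_year


@dataclass
class TwinRecord:
    """One surveyed individual.

    ``bmi`` is always derived as weight / height^2 (kg/m^2); it is never read
    from an input column.
    """

    person_id: str
    pair_id: str
    zygosity: str
    sex: str
    birth_year: int
    survey_year: int
    height: float  # metres
    weight: float  # kilograms

    @property
    def bmi(self) -> float:
        return self.weight / self.height**2

    @property
    def age(self) -> int:
        return self.survey_year - self.birth_year


@dataclass
class TwinPair:
    """A pair unit; the likelihood unit of the twin model.

    ``members`` holds one record when the co-twin did not respond (an
    incomplete pair, which the raw-data likelihood can still use).
    """

    pair_id: str
    zygosity: str
    members: list
    sex: Optional[str] = None  # undefined (None) for opposite-sex pairs

    @property
    def complete(self) -> bool:
        return len(self.members) == 2


@dataclass
class ReadLog:
    """Accounting of a cohort read: rows seen vs rows usable."""

    n_rows_read: int = 0
    n_dropped_unparseable: int = 0

    @property
    def n_records(self) -> int:
        return self.n_rows_read - self.n_dropped_unparseable


@dataclass
class ExclusionLog:
    """Pair-selection flowchart arithmetic for one survey wave."""

    n_individuals_input: int
    n_pairs_incomplete: int
    n_pairs_complete: int
    n_pairs_opposite_sex_removed: int
    n_pairs_extreme_bmi_removed: int
    n_pairs_eligible: int

    def check(self) -> None:
        assert self.n_pairs_eligible == (
            self.n_pairs_complete
            - self.n_pairs_opposite_sex_removed
            - self.n_pairs_extreme_bmi_removed
        )


@dataclass
class StratumSummary:
    """Whole-population summary statistics for one stratum.

    Computed on all individuals with valid BMI (including members of
    opposite-sex pairs) after extreme-BMI removal; see the methods note.
    """

    key: StratumKey
    n_individuals: int
    n_pairs_eligible: int
    obesity_pct: float
    overweight_pct: float
    mean_bmi: float

    @property
    def age(self) -> int:
        return self.key.age


@dataclass
class VarianceFit:
    """Fitted variance components for one stratum.

    Variances are in (kg/m^2)^2; ``agsd = sqrt(var_a)`` and ``esd =
    sqrt(var_e)`` are the additive genetic and unique environmental standard
    deviations on the BMI scale. Standard errors come from the observed
    information matrix in the path-coefficient parameterization, where the
    magnitude of the additive path coefficient equals the AGSD.
    """

    model: str
    mu: float
    var_a: float
    var_c: float
    var_d: float
    var_e: float
    agsd: float
    agsd_se: float
    esd: float
    esd_se: float
    loglik: float
    n_pairs_mz: int
    n_pairs_dz: int
    converged: bool = True
    se_valid: bool = True
    boundary: bool = False
    notes: str = ""

    @property
    def total_variance(self) -> float:
        return self.var_a + self.var_c + self.var_d + self.var_e

    @property
    def heritability(self) -> float:
        tot = self.total_variance
        return self.var_a / tot if tot > 0 else float("nan")

    @property
    def valid(self) -> bool:
        return self.converged and self.se_valid


@dataclass
class MetaDataset:
    """Design for one random-effects meta-regression (one proxy, one outcome)."""

    y: "object"  # (k,) outcome per stratum: agsd or esd
    v: "object"  # (k,) within-stratum variance of y (se^2)
    X: "object"  # (k, p) design matrix
    columns: list = field(default_factory=list)
    proxy: str = ""
    outcome: str = "A"

    @property
    def k(self) -> int:
        return len(self.y)

    @property
    def p(self) -> int:
        return self.X.shape[1]


@dataclass
class MetaRegressionResult:
    """Coefficients and heterogeneity for one meta-regression model."""

    columns: list
    beta: "object"
    se_beta: "object"
    z: "object"
    p_value: "object"
    tau2: float
    q_residual: float
    weights: "object"
    proxy: str = ""
    outcome: str = "A"
    method: str = "DL"

    def coef(self, name: str) -> float:
        return float(self.beta[self.columns.index(name)])

    def pval(self, name: str) -> float:
        return float(self.p_value[self.columns.index(name)])
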