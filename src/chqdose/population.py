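"""Age-stratified virtual populations for pediatric clearance scaling.

Virtual subjects carry the physiological covariates that drive pediatric
drug clearance: age, sex, body weight, and maturation fractions for the
three named chloroquine elimination pathways (CYP3A4, CYP2C8, renal
filtration). Maturation is modelled with sigmoid fraction-of-adult
functions: the CYP pathways mature on postnatal age, glomerular filtration
on postmenstrual age (term birth, 40 weeks, is assumed). All fractions are
clamped to exactly 1.0 from the adult age boundary (18 y) upward.

Body weights are drawn around a bundled synthetic growth-reference table of
median weight by age and sex (adults use a fixed 75 kg median so that the
mean adult dose under a 44 mg/kg schedule is about 44 mg/kg x 75 kg), with
a configurable log-normal inter-individual spread (default CV 15%, 0
allowed for deterministic tests).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "AgeGroupSpec",
    "Subject",
    "PopulationSpec",
    "SigmoidMaturation",
    "PmaSigmoidMaturation",
    "OntogenyParams",
    "DEFAULT_ONTOGENY",
    "AGE_GROUPS",
    "NEONATE",
    "INFANT_1_6_MO",
    "CHILD_6_MO_5_Y",
    "CHILD_5_12_Y",
    "ADULT",
    "ADULT_AGE_YEARS",
    "ontogeny_cyp3a4",
    "ontogeny_cyp2c8",
    "gfr_maturation",
    "load_growth_table",
    "sample_weight",
    "sample_population",
    "population_to_frame",
]

ADULT_AGE_YEARS = 18.0
WEEKS_PER_YEAR = 365.25 / 7.0
TERM_PMA_WEEKS = 40.0
ADULT_MEDIAN_WEIGHT_KG = 75.0


@dataclass(frozen=True)
class AgeGroupSpec:
    """Half-open age band [age_min, age_max) in years."""

    label: str
    age_min: float
    age_max: float

    def __post_init__(self) -> None:
        if self.age_min < 0:
            raise ValueError(f"age_min must be >= 0, got {self.age_min}")
        if not self.age_min < self.age_max:
            raise ValueError(
                f"age_min must be < age_max, got [{self.age_min}, {self.age_max})"
            )


NEONATE = AgeGroupSpec("0-1 mo", 0.0, 1.0 / 12.0)
INFANT_1_6_MO = AgeGroupSpec("1-6 mo", 1.0 / 12.0, 0.5)
CHILD_6_MO_5_Y = AgeGroupSpec("6 mo-5 y", 0.5, 5.0)
CHILD_5_12_Y = AgeGroupSpec("5-12 y", 5.0, 12.0)
ADULT = AgeGroupSpec("adult", 18.0, 65.0)

#: The five study age bands, keyed by label.
AGE_GROUPS: dict[str, AgeGroupSpec] = {
    g.label: g for g in (NEONATE, INFANT_1_6_MO, CHILD_6_MO_5_Y, CHILD_5_12_Y, ADULT)
}


@dataclass(frozen=True)
class Subject:
    """One virtual individual."""

    subject_id: int
    age: float  # years
    sex: str  # "female" | "male"
    weight: float  # kg
    f_cyp3a4: float  # fraction of adult activity per unit scaled size
    f_cyp2c8: float
    f_gfr: float

    def __post_init__(self) -> None:
        if self.weight <= 0:
            raise ValueError(f"weight must be > 0, got {self.weight}")
        for name in ("f_cyp3a4", "f_cyp2c8", "f_gfr"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.sex not in ("female", "male"):
            raise ValueError(f"sex must be 'female' or 'male', got {self.sex!r}")


@dataclass(frozen=True)
class PopulationSpec:
    """Trial-structured sampling plan for one age group."""

    age_group: AgeGroupSpec
    n_trials: int
    n_per_trial: int
    prop_female: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trials < 1 or self.n_per_trial < 1:
            raise ValueError("n_trials and n_per_trial must be >= 1")
        if not 0.0 <= self.prop_female <= 1.0:
            raise ValueError("prop_female must be in [0, 1]")


# ---------------------------------------------------------------------------
# Maturation functions
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SigmoidMaturation:
    """Fraction-of-adult sigmoid on postnatal age (years).

    f(age) = f_birth + (1 - f_birth) * age^hill / (age^hill + age50^hill),
    clamped to exactly 1 from ``ADULT_AGE_YEARS`` upward.
    """

    f_birth: float
    age50_years: float
    hill: float

    def __call__(self, age):
        age = _check_age(age)
        a = np.power(age, self.hill)
        f = self.f_birth + (1.0 - self.f_birth) * a / (a + self.age50_years**self.hill)
        return _clamp_adult(f, age)


@dataclass(frozen=True)
class PmaSigmoidMaturation:
    """Fraction-of-adult sigmoid on postmenstrual age (weeks), term birth assumed.

    f(age) = PMA^hill / (PMA^hill + pma50^hill) with PMA = 40 wk + postnatal
    age; clamped to exactly 1 from ``ADULT_AGE_YEARS`` upward.
    """

    pma50_weeks: float
    hill: float
    term_pma_weeks: float = TERM_PMA_WEEKS

    def __call__(self, age):
        age = _check_age(age)
        pma = self.term_pma_weeks + age * WEEKS_PER_YEAR
        p = np.power(pma, self.hill)
        f = p / (p + self.pma50_weeks**self.hill)
        return _clamp_adult(f, age)


def _check_age(age):
    age = np.asarray(age, dtype=float)
    if np.any(age < 0):
        raise ValueError("age must be >= 0")
    return age


def _clamp_adult(f, age):
    out = np.where(age >= ADULT_AGE_YEARS, 1.0, np.minimum(f, 1.0))
    if out.ndim == 0:
        return float(out)
    return out


@dataclass(frozen=True)
class OntogenyParams:
    """Maturation parameter set for the three named elimination pathways.

    Defaults: the CYP3A4 sigmoid follows in-vivo ontogeny estimates
    (F_birth 0.11, age50 0.64 y, Hill 1.91); renal filtration follows the
    standard postmenstrual-age sigmoid (PMA50 47.7 wk, Hill 3.4); the
    CYP2C8 sigmoid (F_birth 0.15, age50 0.60 y, Hill 1.2) was fixed at
    design time so the composite clearance maturation reproduces the
    expected pediatric age trend (immature below 6 months, near-adult
    weight-normalized clearance by late infancy).
    """

    cyp3a4: SigmoidMaturation = field(
        default_factory=lambda: SigmoidMaturation(0.11, 0.64, 1.91)
    )
    cyp2c8: SigmoidMaturation = field(
        default_factory=lambda: SigmoidMaturation(0.15, 0.60, 1.2)
    )
    gfr: PmaSigmoidMaturation = field(
        default_factory=lambda: PmaSigmoidMaturation(47.7, 3.4)
    )


DEFAULT_ONTOGENY = OntogenyParams()


def ontogeny_cyp3a4(age, params: OntogenyParams = DEFAULT_ONTOGENY):
    """CYP3A4 fraction-of-adult activity at ``age`` (years)."""
    return params.cyp3a4(age)


def ontogeny_cyp2c8(age, params: OntogenyParams = DEFAULT_ONTOGENY):
    """CYP2C8 fraction-of-adult activity at ``age`` (years)."""
    return params.cyp2c8(age)


def gfr_maturation(age, params: OntogenyParams = DEFAULT_ONTOGENY):
    """Fraction of adult size-normalized glomerular filtration at ``age``."""
    return params.gfr(age)


# ---------------------------------------------------------------------------
# Body weight
# ---------------------------------------------------------------------------

_GROWTH_TABLE_CACHE: pd.DataFrame | None = None


def load_growth_table(path=None) -> pd.DataFrame:
    """Load the growth-reference table (age_years, sex, median_weight_kg).

    The bundled default is a synthetic representative table of median
    weights by age and sex approximating public growth references; it is
    not a digitized copy of any single published chart.
    """
    global _GROWTH_TABLE_CACHE
    if path is not None:
        return pd.read_csv(path)
    if _GROWTH_TABLE_CACHE is None:
        ref = resources.files("chqdose.data") / "growth_reference_synthetic.csv"
        with resources.as_file(ref) as p:
            _GROWTH_TABLE_CACHE = pd.read_csv(p)
    return _GROWTH_TABLE_CACHE


def median_weight(age: float, sex: str, growth_table: pd.DataFrame | None = None) -> float:
    """Median weight (kg) at ``age`` for ``sex``, interpolated from the table.

    Adults (age >= 18 y) use the fixed 75 kg median. Ages outside the
    table range are clamped to the nearest row with a warning.
    """
    if age < 0:
        raise ValueError("age must be >= 0")
    if age >= ADULT_AGE_YEARS:
        return ADULT_MEDIAN_WEIGHT_KG
    table = load_growth_table() if growth_table is None else growth_table
    rows = table[table["sex"] == sex].sort_values("age_years")
    if rows.empty:
        raise ValueError(f"no growth-table rows for sex {sex!r}")
    ages = rows["age_years"].to_numpy()
    if age < ages[0] or age > ages[-1]:
        warnings.warn(
            f"age {age} y outside growth table range "
            f"[{ages[0]}, {ages[-1]}]; clamping to nearest row",
            stacklevel=2,
        )
        age = float(np.clip(age, ages[0], ages[-1]))
    return float(np.interp(age, ages, rows["median_weight_kg"].to_numpy()))


def sample_weight(
    age: float,
    sex: str,
    rng: np.random.Generator,
    cv: float = 0.15,
    growth_table: pd.DataFrame | None = None,
) -> float:
    """Draw a body weight around the age/sex median with log-normal spread.

    ``cv`` is the coefficient of variation of the log-normal; the draw is
    median-preserving, so ``cv=0`` returns the table median exactly.
    """
    med = median_weight(age, sex, growth_table)
    if cv == 0:
        return med
    sigma = float(np.sqrt(np.log1p(cv**2)))
    return med * float(np.exp(rng.normal(0.0, sigma)))


# ---------------------------------------------------------------------------
# Population sampling
# ---------------------------------------------------------------------------


def sample_population(
    spec: PopulationSpec,
    ontogeny: OntogenyParams = DEFAULT_ONTOGENY,
    weight_cv: float = 0.15,
    growth_table: pd.DataFrame | None = None,
) -> list[list[Subject]]:
    """Sample ``n_trials`` trials of ``n_per_trial`` subjects each.

    Ages are uniform within the group's [age_min, age_max); sex is Bernoulli
    with probability ``prop_female``; the result is a pure function of the
    spec (same seed, same subjects).
    """
    rng = np.random.default_rng(spec.seed)
    group = spec.age_group
    trials: list[list[Subject]] = []
    sid = 0
    for _ in range(spec.n_trials):
        trial: list[Subject] = []
        for _ in range(spec.n_per_trial):
            age = float(rng.uniform(group.age_min, group.age_max))
            sex = "female" if rng.random() < spec.prop_female else "male"
            weight = sample_weight(age, sex, rng, cv=weight_cv, growth_table=growth_table)
            trial.append(
                Subject(
                    subject_id=sid,
                    age=age,
                    sex=sex,
                    weight=weight,
                    f_cyp3a4=float(ontogeny.cyp3a4(age)),
                    f_cyp2c8=float(ontogeny.cyp2c8(age)),
                    f_gfr=float(ontogeny.gfr(age)),
                )
            )
            sid += 1
        trials.append(trial)
    return trials


def population_to_frame(trials: Sequence[Sequence[Subject]]) -> pd.DataFrame:
    """Flatten trials into the export table (one row per subject)."""
    records = [
        {
            "trial_id": t,
            "subject_id": s.subject_id,
            "age_years": s.age,
            "sex": s.sex,
            "weight_kg": s.weight,
            "f_cyp3a4": s.f_cyp3a4,
            "f_cyp2c8": s.f_cyp2c8,
            "f_gfr": s.f_gfr,
        }
        for t, trial in enumerate(trials)
        for s in trial
    ]
    return pd.DataFrame.from_records(records)
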