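"""Domain model for an IBD fecal organic-acid cohort.

One :class:`SubjectRecord` per participant carries demographics (group, sex,
age, BMI), a six-month weight-change figure, medication flags, a diet-type
label, food-frequency-questionnaire (FFQ) consumption categories, and the
fecal organic-acid panel in µg per g dry stool mass.

The module also houses the categorization rules applied before encoding:

* BMI classes — underweight (< 18.5 kg/m²), normal (18.5–24.99), excessive
  (> 24.99); both printed boundaries belong to "normal".
* weight change over six months — loss (< −5 %), stable (−5 % to +5 %
  inclusive), gain (> +5 %).
* fiber consumption — low / normal / high, derived from the diet type or,
  when a gram-per-day figure is available, from the < 25 g/day and
  > 30 g/day cut-offs.
* detection-limit censoring for the capillary-electrophoresis acid assay
  (LOQ 26 µg/g dry mass; LOD = LOQ/3; values under the LOD are replaced by
  LOD/2, values between LOD and LOQ are flagged but retained).
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field, fields
from typing import Iterable, Mapping, Optional, Union

__all__ = [
    "GROUPS", "SEXES", "DIET_TYPES", "FFQ_LEVELS", "ACIDS", "MED_FLAGS",
    "DEFAULT_PRODUCT_GROUPS", "BMI_CATEGORIES", "WEIGHT_CHANGE_CATEGORIES",
    "FIBER_CATEGORIES",
    "Censored", "AcidProfile", "DetectionLimits", "SubjectRecord",
    "compute_bmi", "categorize_bmi", "categorize_weight_change",
    "categorize_fiber", "censor_concentration", "extract_to_dry_mass",
    "read_cohort", "write_cohort",
]

GROUPS = ("UC", "CD", "control")
SEXES = ("male", "female")
DIET_TYPES = ("standard", "easily_digestible", "low_fiber", "high_fiber", "other")
FFQ_LEVELS = ("daily", "weekly", "monthly", "none")
ACIDS = ("acetic", "propionic", "butyric", "isobutyric", "valeric",
         "isovaleric", "phosphoric")
MED_FLAGS = ("steroids", "antibiotics", "immunosuppressants", "asa5",
             "anti_tnf", "other_meds")
DEFAULT_PRODUCT_GROUPS = ("fresh_vegetables_fruits", "dried_fruits",
                          "whole_grain", "legumes", "alcohol", "dairy")

BMI_CATEGORIES = ("underweight", "normal", "excessive")
WEIGHT_CHANGE_CATEGORIES = ("loss", "stable", "gain")
FIBER_CATEGORIES = ("low", "normal", "high")


class DomainError(ValueError):
    """Raised when an input violates a domain precondition."""


@dataclass(frozen=True)
class Censored:
    """A concentration below a detection bound.

    ``value`` is the number carried into downstream statistics (the raw
    measurement for below-LOQ observations, LOD/2 for below-LOD ones);
    ``bound`` records which limit applies (``"below_loq"`` or
    ``"below_lod"``).
    """

    value: float
    bound: str

    def __post_init__(self) -> None:
        if self.bound not in ("below_loq", "below_lod"):
            raise DomainError(f"unknown censoring bound {self.bound!r}")
        if self.value < 0:
            raise DomainError("censored value must be non-negative")


Concentration = Union[float, Censored]


def _numeric(conc: Concentration) -> float:
    return conc.value if isinstance(conc, Censored) else float(conc)


@dataclass(frozen=True)
class AcidProfile:
    """Fecal organic-acid concentrations in µg/g dry mass.

    Keys are restricted to the seven assayed acids; values are non-negative
    reals or :class:`Censored` markers.
    """

    concentrations: Mapping[str, Concentration]

    def __post_init__(self) -> None:
        for name, conc in self.concentrations.items():
            if name not in ACIDS:
                raise DomainError(f"unknown acid {name!r}")
            if not isinstance(conc, Censored) and conc < 0:
                raise DomainError(f"negative concentration for {name}")

    def value(self, acid: str) -> Optional[float]:
        """Numeric concentration used in statistics (None if unmeasured)."""
        conc = self.concentrations.get(acid)
        return None if conc is None else _numeric(conc)

    def __getitem__(self, acid: str) -> Concentration:
        return self.concentrations[acid]


@dataclass(frozen=True)
class DetectionLimits:
    """Assay detection limits; the LOD is fixed at one third of the LOQ."""

    loq: float = 26.0
    lod: Optional[float] = None
    max_rsd: float = 0.15

    def __post_init__(self) -> None:
        if self.loq <= 0:
            raise DomainError("loq must be positive")
        if not 0 < self.max_rsd < 1:
            raise DomainError("max_rsd must lie in (0, 1)")
        if self.lod is None:
            object.__setattr__(self, "lod", self.loq / 3.0)
        elif abs(self.lod - self.loq / 3.0) > 1e-9 * self.loq:
            raise DomainError("lod must equal loq/3")


@dataclass
class SubjectRecord:
    """One participant's demographic, clinical, dietary and acid data."""

    id: str
    group: str
    sex: str
    age: float
    bmi: float
    weight_change_pct: Optional[float]
    steroids: bool
    antibiotics: bool
    immunosuppressants: bool
    asa5: bool
    anti_tnf: bool
    other_meds: bool
    diet_type: str
    ffq: dict = field(default_factory=dict)
    acids: AcidProfile = field(default_factory=lambda: AcidProfile({}))

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise DomainError(f"unknown group {self.group!r}")
        if self.sex not in SEXES:
            raise DomainError(f"unknown sex {self.sex!r}")
        if self.bmi <= 0:
            raise DomainError("bmi must be positive")
        if self.age <= 0:
            raise DomainError("age must be positive")
        if self.age < 18:
            warnings.warn(f"subject {self.id}: age {self.age} below the adult "
                          "enrolment threshold", stacklevel=2)
        if self.diet_type not in DIET_TYPES:
            raise DomainError(f"unknown diet type {self.diet_type!r}")
        for product, level in self.ffq.items():
            if product not in DEFAULT_PRODUCT_GROUPS:
                raise DomainError(f"unknown FFQ product group {product!r}")
            if level not in FFQ_LEVELS:
                raise DomainError(f"unknown FFQ level {level!r}")


# --------------------------------------------------------------------------
# categorization rules
# --------------------------------------------------------------------------

def compute_bmi(weight_kg: float, height_m: float) -> float:
    """Body mass index: weight divided by height squared (kg/m²)."""
    if weight_kg <= 0 or height_m <= 0:
        raise DomainError("weight and height must be positive")
    return weight_kg / height_m ** 2


def categorize_bmi(bmi: float) -> str:
    """Classify a BMI into underweight / normal / excessive.

    The normal band is the closed interval [18.5, 24.99] kg/m²; everything
    below is underweight and everything above is excessive weight.
    """
    if bmi <= 0:
        raise DomainError("bmi must be positive")
    if bmi < 18.5:
        return "underweight"
    if bmi <= 24.99:
        return "normal"
    return "excessive"


def categorize_weight_change(pct: float) -> str:
    """Classify six-month weight change: beyond ±5 % counts as loss/gain."""
    if pct < -5:
        return "loss"
    if pct > 5:
        return "gain"
    return "stable"


def categorize_fiber(diet_type: str,
                     ffq: Optional[Mapping[str, str]] = None,
                     grams_per_day: Optional[float] = None) -> str:
    """Fiber-consumption class: low / normal / high.

    A reported gram-per-day intake, when available, takes precedence
    (< 25 g/day → low, > 30 g/day → high, otherwise normal). Failing that
    the diet type decides: low-fiber and easily-digestible diets are low,
    a high-fiber diet is high, and standard (or unclassified "other")
    diets are normal.
    """
    if diet_type not in DIET_TYPES:
        raise DomainError(f"unknown diet type {diet_type!r}")
    if grams_per_day is not None:
        if grams_per_day < 25:
            return "low"
        if grams_per_day > 30:
            return "high"
        return "normal"
    if diet_type in ("low_fiber", "easily_digestible"):
        return "low"
    if diet_type == "high_fiber":
        return "high"
    return "normal"


def censor_concentration(raw: float, limits: DetectionLimits) -> Concentration:
    """Apply LOQ/LOD censoring to a raw concentration.

    At or above the LOQ the value passes through unchanged. Between the LOD
    and the LOQ it is flagged below-LOQ but retained (median splits keep
    it). Below the LOD it is flagged and replaced by LOD/2, the usual
    substitution for non-detects in analytical chemistry.
    """
    if raw < 0:
        raise DomainError("concentration must be non-negative")
    if raw >= limits.loq:
        return float(raw)
    if raw >= limits.lod:
        return Censored(float(raw), "below_loq")
    return Censored(limits.lod / 2.0, "below_lod")


def extract_to_dry_mass(conc_extract: float, extract_volume: float,
                        sample_mass: float) -> float:
    """Convert an extract concentration (µg/mL) to µg per g dry stool mass.

    With the calibration-curve floor of 7.8 µg/mL, a 1.0 mL extract and a
    0.3 g sample this reproduces the assay's 26 µg/g quantification limit.
    """
    if conc_extract <= 0 or extract_volume <= 0 or sample_mass <= 0:
        raise DomainError("all inputs must be positive")
    return conc_extract * extract_volume / sample_mass


# --------------------------------------------------------------------------
# CSV interface
# --------------------------------------------------------------------------

_SCALAR_FIELDS = ("id", "group", "sex", "age", "bmi", "weight_change_pct",
                  "steroids", "antibiotics", "immunosuppressants", "asa5",
                  "anti_tnf", "other_meds", "diet_type")


def _header(product_groups: Iterable[str]) -> list:
    cols = list(_SCALAR_FIELDS)
    cols += [f"ffq_{p}" for p in product_groups]
    cols += [f"acid_{a}_ugg" for a in ACIDS]
    return cols


def write_cohort(records: Iterable[SubjectRecord], path,
                 product_groups: Iterable[str] = DEFAULT_PRODUCT_GROUPS) -> None:
    """Write subject records to CSV; empty cells denote missing values."""
    product_groups = tuple(product_groups)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(_header(product_groups))
        for rec in records:
            row = [rec.id, rec.group, rec.sex, repr(float(rec.age)),
                   repr(float(rec.bmi)),
                   "" if rec.weight_change_pct is None
                   else repr(float(rec.weight_change_pct))]
            row += [str(int(getattr(rec, f))) for f in MED_FLAGS]
            row.append(rec.diet_type)
            row += [rec.ffq.get(p, "") for p in product_groups]
            for acid in ACIDS:
                conc = rec.acids.concentrations.get(acid)
                if conc is None:
                    row.append("")
                elif isinstance(conc, Censored):
                    tag = "LOD" if conc.bound == "below_lod" else "LOQ"
                    row.append(f"<{tag}:{conc.value!r}")
                else:
                    row.append(repr(float(conc)))
            writer.writerow(row)


def _parse_conc(cell: str) -> Optional[Concentration]:
    if cell == "":
        return None
    if cell.startswith("<LOD:"):
        return Censored(float(cell[5:]), "below_lod")
    if cell.startswith("<LOQ:"):
        return Censored(float(cell[5:]), "below_loq")
    return float(cell)


def read_cohort(path) -> list:
    """Read subject records from the CSV written by :func:`write_cohort`."""
    records = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise DomainError(f"{path}: empty file")
        for row in reader:
            ffq = {}
            acids = {}
            for col, cell in row.items():
                if col.startswith("ffq_") and cell != "":
                    ffq[col[4:]] = cell
                elif col.startswith("acid_") and col.endswith("_ugg"):
                    conc = _parse_conc(cell)
                    if conc is not None:
                        acids[col[5:-4]] = conc
            records.append(SubjectRecord(
                id=row["id"], group=row["group"], sex=row["sex"],
                age=float(row["age"]), bmi=float(row["bmi"]),
                weight_change_pct=(None if row["weight_change_pct"] == ""
                                   else float(row["weight_change_pct"])),
                steroids=row["steroids"] == "1",
                antibiotics=row["antibiotics"] == "1",
                immunosuppressants=row["immunosuppressants"] == "1",
                asa5=row["asa5"] == "1",
                anti_tnf=row["anti_tnf"] == "1",
                other_meds=row["other_meds"] == "1",
                diet_type=row["diet_type"], ffq=ffq,
                acids=AcidProfile(acids)))
    return records
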