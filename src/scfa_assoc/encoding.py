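"""Binary/categorical encoding of a cohort into an indicator table.

Continuous parameters (age, each acid concentration) are dichotomized at
their sample median into "under"/"above"; categorical parameters (BMI
class, weight-change class, diet type, fiber class, medication flags, FFQ
consumption groups) are expanded into one 0/1 column per observed level.
The resulting subjects × levels indicator matrix, with row/column masses
taken against the grand total, is the input of the correspondence
analysis. A Burt cross-tabulation (levels × levels) is available as an
alternative input; both give the same standard column coordinates.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Callable, Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .cohort import (ACIDS, BMI_CATEGORIES, DIET_TYPES, FFQ_LEVELS,
                     FIBER_CATEGORIES, MED_FLAGS, WEIGHT_CHANGE_CATEGORIES,
                     SubjectRecord, categorize_bmi, categorize_fiber,
                     categorize_weight_change)

logger = logging.getLogger(__name__)

__all__ = ["EncodingError", "ParameterDef", "CategoryScheme", "IndicatorTable",
           "median_split", "encode_cohort", "indicator_from_frame",
           "PARAMETER_REGISTRY", "DEFAULT_PARAMETERS"]


class EncodingError(ValueError):
    pass


def median_split(values: Sequence[Optional[float]],
                 tie_rule: str = "under"):
    """Split values at the sample median.

    Returns ``(median, labels)`` where labels are "under"/"above" (None for
    missing inputs). The median is the ordinary sample median (mean of the
    middle two for even n). A value exactly at the median goes to "under"
    by default, so the "above" group is strictly above; ``tie_rule="above"``
    flips that.
    """
    if tie_rule not in ("under", "above"):
        raise EncodingError(f"unknown tie rule {tie_rule!r}")
    present = [v for v in values if v is not None]
    if len(present) < 2:
        raise EncodingError("median split needs at least 2 non-missing values")
    med = float(np.median(present))
    if tie_rule == "under":
        labels = [None if v is None else ("above" if v > med else "under")
                  for v in values]
    else:
        labels = [None if v is None else ("under" if v < med else "above")
                  for v in values]
    return med, labels


# --------------------------------------------------------------------------
# parameter registry: how to pull each analysis parameter out of a record
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ParameterDef:
    """One analysis parameter: a name, its kind, and an extractor."""

    name: str
    kind: str                      # "median_split" | "categorical"
    extractor: Callable[[SubjectRecord], Optional[object]]
    levels: Optional[tuple] = None  # fixed level order for categorical


def _acid_extractor(acid: str):
    return lambda rec: rec.acids.value(acid)


def _ffq_extractor(product: str):
    return lambda rec: rec.ffq.get(product)


def _med_extractor(flag: str):
    return lambda rec: "yes" if getattr(rec, flag) else "no"


def _build_registry() -> dict:
    reg = {
        "age": ParameterDef("age", "median_split", lambda r: r.age),
        "bmi_category": ParameterDef(
            "bmi_category", "categorical", lambda r: categorize_bmi(r.bmi),
            BMI_CATEGORIES),
        "weight_change": ParameterDef(
            "weight_change", "categorical",
            lambda r: (None if r.weight_change_pct is None
                       else categorize_weight_change(r.weight_change_pct)),
            WEIGHT_CHANGE_CATEGORIES),
        "diet_type": ParameterDef(
            "diet_type", "categorical", lambda r: r.diet_type, DIET_TYPES),
        "fiber": ParameterDef(
            "fiber", "categorical",
            lambda r: categorize_fiber(r.diet_type, r.ffq), FIBER_CATEGORIES),
        "sex": ParameterDef("sex", "categorical", lambda r: r.sex,
                            ("male", "female")),
    }
    for flag in MED_FLAGS:
        reg[flag] = ParameterDef(flag, "categorical", _med_extractor(flag),
                                 ("yes", "no"))
    for product in ("fresh_vegetables_fruits", "dried_fruits", "whole_grain",
                    "legumes", "alcohol", "dairy"):
        reg[f"ffq_{product}"] = ParameterDef(
            f"ffq_{product}", "categorical", _ffq_extractor(product),
            FFQ_LEVELS)
    for acid in ACIDS:
        reg[f"acid_{acid}"] = ParameterDef(
            f"acid_{acid}", "median_split", _acid_extractor(acid))
    return reg


PARAMETER_REGISTRY = _build_registry()

# Default analysis set: the parameters of the published association map —
# age, BMI class, weight change, diet type, three medication flags, three
# FFQ product groups, and the seven acids (17 parameters).
DEFAULT_PARAMETERS = (
    "age", "bmi_category", "weight_change", "diet_type",
    "steroids", "antibiotics", "other_meds",
    "ffq_alcohol", "ffq_whole_grain", "ffq_legumes",
) + tuple(f"acid_{a}" for a in ACIDS)


# --------------------------------------------------------------------------
# encoded containers
# --------------------------------------------------------------------------

@dataclass
class CategoryScheme:
    """Realized encoding: per parameter its kind, levels and median."""

    parameters: dict = field(default_factory=dict)
    tie_rule: str = "under"

    def add(self, name: str, kind: str, levels: Sequence[str],
            median: Optional[float] = None) -> None:
        self.parameters[name] = {"kind": kind, "levels": list(levels),
                                 "median": median}

    def median(self, name: str) -> Optional[float]:
        return self.parameters[name]["median"]

    def to_json(self) -> str:
        return json.dumps({"tie_rule": self.tie_rule,
                           "parameters": self.parameters}, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "CategoryScheme":
        obj = json.loads(text)
        return cls(parameters=obj["parameters"], tie_rule=obj["tie_rule"])


@dataclass
class IndicatorTable:
    """Subjects × (parameter, level) 0/1 matrix with CA masses."""

    data: pd.DataFrame  # columns: MultiIndex (parameter, level)

    @property
    def grand_total(self) -> float:
        return float(self.data.to_numpy().sum())

    @property
    def row_masses(self) -> pd.Series:
        return self.data.sum(axis=1) / self.grand_total

    @property
    def col_masses(self) -> pd.Series:
        return self.data.sum(axis=0) / self.grand_total

    @property
    def parameters(self) -> tuple:
        seen = dict.fromkeys(self.data.columns.get_level_values(0))
        return tuple(seen)

    def levels_of(self, parameter: str) -> tuple:
        return tuple(lvl for par, lvl in self.data.columns if par == parameter)

    def drop_parameter(self, parameter: str) -> "IndicatorTable":
        if parameter not in self.parameters:
            raise EncodingError(f"parameter {parameter!r} not in table")
        keep = [c for c in self.data.columns if c[0] != parameter]
        return IndicatorTable(self.data[keep])

    def subset(self, parameters: Iterable[str]) -> "IndicatorTable":
        wanted = set(parameters)
        keep = [c for c in self.data.columns if c[0] in wanted]
        return IndicatorTable(self.data[keep])

    def burt(self) -> pd.DataFrame:
        """Burt table: cross-tabulation of every level against every level."""
        z = self.data.to_numpy(dtype=float)
        b = z.T @ z
        return pd.DataFrame(b, index=self.data.columns,
                            columns=self.data.columns)

    def to_tsv(self, path) -> None:
        flat = self.data.copy()
        flat.columns = [f"{p}={l}" for p, l in self.data.columns]
        flat.to_csv(path, sep="\t", index_label="subject")


def _one_hot(values: Sequence[Optional[str]], levels: Sequence[str],
             parameter: str, index) -> pd.DataFrame:
    cols = {}
    for lvl in levels:
        cols[(parameter, lvl)] = [1 if v == lvl else 0 for v in values]
    frame = pd.DataFrame(cols, index=index, dtype=np.int64)
    frame.columns = pd.MultiIndex.from_tuples(frame.columns,
                                              names=["parameter", "level"])
    return frame


def encode_cohort(records: Sequence[SubjectRecord],
                  parameters: Sequence[str] = DEFAULT_PARAMETERS,
                  tie_rule: str = "under"):
    """Encode subject records into a (CategoryScheme, IndicatorTable) pair.

    Continuous parameters are median-split (the realized median lands in
    the scheme); categorical parameters are expanded level by level in
    registry order. Levels observed zero times are dropped with a warning;
    a subject missing a parameter simply contributes all-zero cells for it.
    Column order follows the config order, then level order, so the output
    is deterministic.
    """
    if len(records) < 2:
        raise EncodingError("need at least 2 records")
    scheme = CategoryScheme(tie_rule=tie_rule)
    blocks = []
    index = pd.Index([rec.id for rec in records], name="subject")
    for name in parameters:
        pdef = PARAMETER_REGISTRY.get(name)
        if pdef is None:
            raise EncodingError(f"unknown parameter {name!r}")
        raw = [pdef.extractor(rec) for rec in records]
        if all(v is None for v in raw):
            raise EncodingError(f"parameter {name!r} absent from all records")
        if pdef.kind == "median_split":
            med, labels = median_split(raw, tie_rule=tie_rule)
            levels = ("under", "above")
            scheme.add(name, "median_split", levels, median=med)
            block = _one_hot(labels, levels, name, index)
        else:
            levels = pdef.levels
            scheme.add(name, "categorical", levels)
            block = _one_hot(raw, levels, name, index)
        counts = block.sum(axis=0)
        empty = counts[counts == 0].index.tolist()
        if empty:
            logger.warning("dropping zero-count levels: %s", empty)
            block = block.drop(columns=empty)
            scheme.parameters[name]["levels"] = [
                lvl for lvl in scheme.parameters[name]["levels"]
                if (name, lvl) not in empty]
        n_missing = int(sum(v is None for v in raw))
        if n_missing:
            logger.info("parameter %s: %d subjects missing (all-zero cells)",
                        name, n_missing)
        blocks.append(block)
    table = IndicatorTable(pd.concat(blocks, axis=1))
    return scheme, table


def indicator_from_frame(frame: pd.DataFrame) -> IndicatorTable:
    """Build an indicator table from a DataFrame of categorical columns.

    Each column becomes a parameter; each distinct value (in order of first
    appearance, ties by string sort for determinism) becomes a level.
    """
    blocks = []
    for col in frame.columns:
        values = frame[col].astype(str).tolist()
        levels = sorted(set(values))
        blocks.append(_one_hot(values, levels, str(col), frame.index))
    return IndicatorTable(pd.concat(blocks, axis=1))
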