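"""Iterative parameter pruning for the correspondence-analysis model.

The analysis demands that the first two CA dimensions explain at least
half of the total inertia. Starting from the full encoded parameter set,
the model is refitted repeatedly; while the two-dimensional fraction
falls short, the parameter with the lowest quality of representation is
discarded and the CA refitted. A parameter's quality is the
column-mass-weighted mean of its levels' first-two-dimension cos²
(a max-over-levels aggregate is available). The loop stops when the
threshold is met or when only ``min_params`` parameters remain, in which
case the result is flagged rather than raised.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import pandas as pd

from .ca import CAModel, fit_ca, inertia_explained, quality2
from .encoding import IndicatorTable

__all__ = ["SelectionStep", "SelectionTrace", "parameter_quality",
           "select_model"]


@dataclass(frozen=True)
class SelectionStep:
    parameters: tuple
    inertia2: float
    discarded: Optional[str]        # None on the final step
    discarded_quality: Optional[float]


@dataclass
class SelectionTrace:
    steps: List[SelectionStep] = field(default_factory=list)
    threshold: float = 0.5
    threshold_met: bool = False

    @property
    def discarded(self) -> tuple:
        return tuple(s.discarded for s in self.steps if s.discarded)

    @property
    def final_parameters(self) -> tuple:
        return self.steps[-1].parameters

    def to_json(self) -> str:
        return json.dumps({
            "threshold": self.threshold,
            "threshold_met": self.threshold_met,
            "steps": [{"parameters": list(s.parameters),
                       "inertia2": s.inertia2,
                       "discarded": s.discarded,
                       "discarded_quality": s.discarded_quality}
                      for s in self.steps]}, indent=2)


def parameter_quality(model: CAModel, table: IndicatorTable,
                      aggregate: str = "mass_weighted") -> pd.Series:
    """Per-parameter quality of representation in the first two dimensions.

    ``mass_weighted`` (default) averages the levels' cos² with their column
    masses as weights, matching the weighting CA itself applies to column
    points; ``max`` takes the best-represented level instead.
    """
    if aggregate not in ("mass_weighted", "max"):
        raise ValueError(f"unknown aggregate {aggregate!r}")
    ndims = min(2, model.rank)
    if ndims:
        q2 = model.col_cos2.iloc[:, :ndims].sum(axis=1)
    else:
        q2 = pd.Series(0.0, index=model.col_cos2.index)
    q2 = q2.where(~model.at_centroid, 0.0)
    params = q2.index.get_level_values(0)
    if aggregate == "max":
        out = q2.groupby(params, sort=False).max()
    else:
        w = model.col_masses
        out = ((q2 * w).groupby(params, sort=False).sum()
               / w.groupby(params, sort=False).sum())
    out.name = "quality"
    return out


def select_model(table: IndicatorTable, threshold: float = 0.5,
                 min_params: int = 4,
                 aggregate: str = "mass_weighted",
                 fraction_scale: str = "raw"
                 ) -> Tuple[CAModel, SelectionTrace]:
    """Prune parameters until two CA dimensions carry `threshold` inertia.

    The stopping fraction is the plain indicator-matrix inertia ratio by
    default; ``fraction_scale="burt"`` measures it on the Burt scale
    (squared principal inertias — what classic MCA software reports),
    which concentrates inertia in the leading dimensions and therefore
    stops the loop much earlier with larger retained sets. Level
    geometry (coordinates, cos²) always comes from the indicator fit;
    the two variants share singular vectors, so the pruned subspace is
    the same.

    Ties in the lowest quality are broken by discarding the later
    parameter in table (config) order. Terminates after at most
    (initial parameters − min_params) discards; if the threshold is still
    unmet at ``min_params`` parameters the trace is flagged.
    """
    if not 0 < threshold <= 1:
        raise ValueError("threshold must lie in (0, 1]")
    if len(table.parameters) < min_params:
        raise ValueError("fewer parameters than min_params")
    trace = SelectionTrace(threshold=threshold)
    current = table
    while True:
        model = fit_ca(current)
        frac = inertia_explained(model, 2, scale=fraction_scale)
        params = current.parameters
        if frac >= threshold:
            trace.steps.append(SelectionStep(params, frac, None, None))
            trace.threshold_met = True
            return model, trace
        if len(params) <= min_params:
            trace.steps.append(SelectionStep(params, frac, None, None))
            trace.threshold_met = False
            return model, trace
        quality = parameter_quality(model, current, aggregate=aggregate)
        # lowest quality loses; tie -> later parameter in config order
        worst, worst_q = None, None
        for par in params:
            q = quality.loc[par]
            if worst_q is None or q <= worst_q:
                worst, worst_q = par, q
        trace.steps.append(SelectionStep(params, frac, worst, float(worst_q)))
        current = current.drop_parameter(worst)
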