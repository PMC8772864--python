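"""Pairwise association weights on the two-dimensional CA plane.

Levels whose coordinates are large in absolute value (> 0.3 on either of
the first two dimensions) are taken to be associated with one another.
For a pair of such levels A, B with plane coordinates p_A, p_B the
association weight is

    w(A, B) = ‖p_A‖ · ‖p_B‖ · cos θ = x_A x_B + y_A y_B ,

the planar dot product, where θ is the angle between the rays from the
origin to the two points. The sign of w equals the sign of cos θ, so
inverse relationships (points on opposite sides of the origin) come out
negative. Pairs of levels of the same parameter are excluded: their
opposition is an artifact of the one-level-per-subject encoding.

An alternative reading of the weight — the per-dimension coordinate
products additionally scaled by cos θ, summed — is available behind the
``formula="product_cos"`` flag.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from itertools import combinations
from typing import List, Sequence, Tuple

import pandas as pd

from .ca import CAModel

__all__ = ["AssociationPair", "AssociationReport", "qualifying_levels",
           "angle_cosine", "association_weight", "build_report"]

Point = Tuple[float, float]


def _norm(p: Point) -> float:
    return math.hypot(p[0], p[1])


def qualifying_levels(model: CAModel, cutoff: float = 0.3) -> list:
    """Levels with |coordinate| > cutoff on either of the first 2 dimensions.

    The rule is a strict maximum over the two per-dimension absolute
    coordinates, not the vector norm.
    """
    plane = model.plane_coords()
    mask = plane.abs().max(axis=1) > cutoff
    return list(plane.index[mask])


def angle_cosine(p_a: Point, p_b: Point) -> float:
    """Cosine of the angle between the origin rays through two points."""
    na, nb = _norm(p_a), _norm(p_b)
    if na == 0.0 or nb == 0.0:
        raise ValueError("angle undefined for a point at the origin")
    c = (p_a[0] * p_b[0] + p_a[1] * p_b[1]) / (na * nb)
    return max(-1.0, min(1.0, c))


def association_weight(p_a: Point, p_b: Point, formula: str = "dot") -> float:
    """Signed association weight of two points on the CA plane.

    ``dot`` (default): ‖p_A‖·‖p_B‖·cosθ, i.e. the planar dot product.
    ``product_cos``: (x_A·x_B + y_A·y_B)·cosθ — the per-dimension
    coordinate products scaled once more by the cosine.
    """
    if _norm(p_a) == 0.0 or _norm(p_b) == 0.0:
        raise ValueError("weight undefined for a point at the origin")
    dot = p_a[0] * p_b[0] + p_a[1] * p_b[1]
    if formula == "dot":
        return dot
    if formula == "product_cos":
        return dot * angle_cosine(p_a, p_b)
    raise ValueError(f"unknown weight formula {formula!r}")


@dataclass(frozen=True)
class AssociationPair:
    level_a: tuple
    level_b: tuple
    coords_a: Point
    coords_b: Point
    cosine: float
    weight: float


@dataclass
class AssociationReport:
    cutoff: float
    formula: str
    pairs: List[AssociationPair] = field(default_factory=list)

    def find(self, level_a: tuple, level_b: tuple):
        """The pair for two levels in either order, or None."""
        want = {level_a, level_b}
        for pair in self.pairs:
            if {pair.level_a, pair.level_b} == want:
                return pair
        return None

    def to_frame(self) -> pd.DataFrame:
        rows = [{
            "level_a": f"{p.level_a[0]}={p.level_a[1]}",
            "level_b": f"{p.level_b[0]}={p.level_b[1]}",
            "x1_a": p.coords_a[0], "x2_a": p.coords_a[1],
            "x1_b": p.coords_b[0], "x2_b": p.coords_b[1],
            "cosine": p.cosine, "weight": p.weight,
        } for p in self.pairs]
        return pd.DataFrame(rows, columns=["level_a", "level_b", "x1_a",
                                           "x2_a", "x1_b", "x2_b", "cosine",
                                           "weight"])

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    def to_json(self) -> str:
        return json.dumps({"cutoff": self.cutoff, "formula": self.formula,
                           "pairs": self.to_frame().to_dict("records")},
                          indent=2)


def build_report(model: CAModel, cutoff: float = 0.3,
                 formula: str = "dot") -> AssociationReport:
    """Association weights for every qualifying cross-parameter level pair.

    Pairs are ordered by descending |weight|. Levels are (parameter, level)
    tuples; two levels of the same parameter never form a pair.
    """
    levels = qualifying_levels(model, cutoff=cutoff)
    plane = model.plane_coords()
    report = AssociationReport(cutoff=cutoff, formula=formula)
    for la, lb in combinations(levels, 2):
        if la[0] == lb[0]:  # same parameter
            continue
        pa = (float(plane.loc[la, "dim1"]), float(plane.loc[la, "dim2"]))
        pb = (float(plane.loc[lb, "dim1"]), float(plane.loc[lb, "dim2"]))
        report.pairs.append(AssociationPair(
            la, lb, pa, pb,
            cosine=angle_cosine(pa, pb),
            weight=association_weight(pa, pb, formula=formula)))
    report.pairs.sort(key=lambda p: -abs(p.weight))
    return report


def plot_plane(model: CAModel, path, cutoff: float = 0.3) -> None:
    """Scatter the levels on the first two CA dimensions (numbered points)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    plane = model.plane_coords()
    fig, ax = plt.subplots(figsize=(7, 6))
    ax.axhline(0, color="0.8", lw=0.8)
    ax.axvline(0, color="0.8", lw=0.8)
    qualifying = set(qualifying_levels(model, cutoff))
    for i, (lvl, row) in enumerate(plane.iterrows(), start=1):
        color = "tab:red" if lvl in qualifying else "0.5"
        ax.plot(row["dim1"], row["dim2"], "o", ms=4, color=color)
        ax.annotate(str(i), (row["dim1"], row["dim2"]), fontsize=7,
                    xytext=(2, 2), textcoords="offset points")
    ax.set_xlabel("dimension 1")
    ax.set_ylabel("dimension 2")
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)
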