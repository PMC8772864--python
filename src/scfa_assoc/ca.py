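"""Correspondence analysis of a non-negative table.

Given a table N with grand total n, the correspondence matrix is
P = N/n with row masses r = P·1 and column masses c = Pᵀ·1. The analysis
is the SVD of the standardized residuals

    S_ij = (P_ij − r_i c_j) / sqrt(r_i c_j) ,   S = U Σ Vᵀ,

with principal inertias λ_k = σ_k² summing to the total inertia, which
equals the table's χ² statistic divided by n. Column principal
coordinates are G = D_c^{-1/2} V Σ (rows analogously); the quality of
representation (cos²) of a column in dimension k is G_jk² divided by the
column profile's squared χ²-distance to the centroid. Applied to a
subjects × levels indicator matrix this is the indicator-matrix variant
of multiple correspondence analysis; applied to a Burt table it yields
the same standard column coordinates with squared singular values.

Sign convention: each singular-vector pair is flipped so that the
largest-magnitude column loading is positive, making results reproducible
across runs and LAPACK builds.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
import pandas as pd

from .encoding import IndicatorTable

__all__ = ["CAError", "CAModel", "fit_ca", "inertia_explained", "quality2"]

# singular values below this fraction of the matrix scale are noise rank
_RANK_TOL = 1e-12
# a column this close (χ²-distance²) to the centroid has undefined cos²
_CENTROID_TOL = 1e-12


class CAError(ValueError):
    pass


@dataclass
class CAModel:
    """Fitted correspondence analysis.

    ``col_coords``/``row_coords`` are principal coordinates over the kept
    dimensions; ``col_cos2`` holds per-dimension qualities of
    representation; ``col_dist2`` the squared χ²-distance of each column
    profile to the centroid; ``at_centroid`` flags columns at (numerically)
    zero distance, whose cos² is defined as 0.
    """

    singular_values: np.ndarray
    principal_inertias: np.ndarray
    total_inertia: float
    row_coords: pd.DataFrame
    col_coords: pd.DataFrame
    col_cos2: pd.DataFrame
    col_masses: pd.Series
    col_dist2: pd.Series
    at_centroid: pd.Series

    @property
    def rank(self) -> int:
        return len(self.singular_values)

    def plane_coords(self, level=None) -> pd.DataFrame:
        """Coordinates in the first two dimensions, zero-padded for rank<2."""
        coords = pd.DataFrame(0.0, index=self.col_coords.index,
                              columns=["dim1", "dim2"])
        for k in range(min(2, self.rank)):
            coords.iloc[:, k] = self.col_coords.iloc[:, k]
        if level is not None:
            return coords.loc[level]
        return coords

    def to_json(self) -> str:
        return json.dumps({
            "singular_values": self.singular_values.tolist(),
            "principal_inertias": self.principal_inertias.tolist(),
            "total_inertia": self.total_inertia,
            "col_coords": {str(k): v for k, v in
                           self.col_coords.T.to_dict("list").items()},
            "col_cos2": {str(k): v for k, v in
                         self.col_cos2.T.to_dict("list").items()},
            "col_masses": {str(k): v for k, v in self.col_masses.items()},
        }, indent=2)


def _as_frame(table) -> pd.DataFrame:
    if isinstance(table, IndicatorTable):
        return table.data.astype(float)
    if isinstance(table, pd.DataFrame):
        return table.astype(float)
    arr = np.asarray(table, dtype=float)
    return pd.DataFrame(arr)


def fit_ca(table) -> CAModel:
    """Fit a correspondence analysis to a non-negative table.

    Accepts an :class:`IndicatorTable`, DataFrame or array. Rows or columns
    with zero mass are an error (drop them first). A table of exactly
    independent rows and columns yields a model with zero total inertia
    and no usable dimensions.
    """
    frame = _as_frame(table)
    mat = frame.to_numpy()
    if mat.shape[0] < 2 or mat.shape[1] < 2:
        raise CAError("table must be at least 2x2")
    if (mat < 0).any():
        raise CAError("table entries must be non-negative")
    n = mat.sum()
    if n <= 0:
        raise CAError("table must have positive grand total")
    p = mat / n
    r = p.sum(axis=1)
    c = p.sum(axis=0)
    if (r <= 0).any() or (c <= 0).any():
        raise CAError("zero-mass rows/columns must be dropped before fitting")

    expected = np.outer(r, c)
    s = (p - expected) / np.sqrt(expected)
    u, sig, vt = np.linalg.svd(s, full_matrices=False)

    keep = sig > max(_RANK_TOL, sig[0] * 1e-12) if sig.size else np.array([], bool)
    u, sig, vt = u[:, keep], sig[keep], vt[keep, :]

    # deterministic sign: largest-|v| loading of each dimension is positive
    for k in range(sig.size):
        j = int(np.argmax(np.abs(vt[k])))
        if vt[k, j] < 0:
            vt[k] *= -1.0
            u[:, k] *= -1.0

    lam = sig ** 2
    dims = [f"dim{k + 1}" for k in range(sig.size)]
    col_coords = pd.DataFrame((vt.T * sig) / np.sqrt(c)[:, None],
                              index=frame.columns, columns=dims)
    row_coords = pd.DataFrame((u * sig) / np.sqrt(r)[:, None],
                              index=frame.index, columns=dims)

    # squared chi-distance of each column profile to the centroid,
    # computed from the profiles themselves (not from the kept dimensions)
    profiles = p / c
    dist2 = ((profiles - r[:, None]) ** 2 / r[:, None]).sum(axis=0)
    at_centroid = dist2 <= _CENTROID_TOL
    with np.errstate(divide="ignore", invalid="ignore"):
        cos2 = col_coords.to_numpy() ** 2 / dist2[:, None]
    cos2[at_centroid, :] = 0.0
    cos2_df = pd.DataFrame(cos2, index=frame.columns, columns=dims)

    return CAModel(
        singular_values=sig,
        principal_inertias=lam,
        total_inertia=float(lam.sum()),
        row_coords=row_coords,
        col_coords=col_coords,
        col_cos2=cos2_df,
        col_masses=pd.Series(c, index=frame.columns, name="mass"),
        col_dist2=pd.Series(dist2, index=frame.columns, name="dist2"),
        at_centroid=pd.Series(at_centroid, index=frame.columns,
                              name="at_centroid"),
    )


def inertia_explained(model: CAModel, dims: int, scale: str = "raw") -> float:
    """Cumulative fraction of total inertia in the first `dims` dimensions.

    ``scale="raw"`` is the plain ratio (λ₁+…+λ_d)/Σλ_k. ``scale="burt"``
    uses squared inertias, (λ₁²+…+λ_d²)/Σλ_k² — the fraction the same
    dimensions carry in the correspondence analysis of the Burt table,
    which shares its singular vectors with the indicator analysis but
    squares its principal inertias. Raw indicator-matrix percentages are
    well known to understate the structure of a multi-parameter encoding;
    Burt-scale percentages are what classic MCA software prints.

    A zero-inertia model (exact independence) explains everything by
    convention, so the result is 1.0.
    """
    if dims < 1:
        raise CAError("dims must be >= 1")
    if scale not in ("raw", "burt"):
        raise CAError(f"unknown inertia scale {scale!r}")
    if model.total_inertia == 0.0:
        return 1.0
    k = min(dims, model.rank)
    lam = model.principal_inertias
    if scale == "burt":
        lam = lam ** 2
    return float(lam[:k].sum() / lam.sum())


def quality2(model: CAModel, level) -> Tuple[float, bool]:
    """Quality of representation of a column in the first two dimensions.

    Returns ``(cos²(dim1) + cos²(dim2), at_centroid_flag)``; a column at
    the centroid has zero distance, so its quality is defined as 0 and
    flagged.
    """
    if level not in model.col_cos2.index:
        raise CAError(f"unknown level {level!r}")
    if bool(model.at_centroid.loc[level]):
        return 0.0, True
    row = model.col_cos2.loc[level]
    q = float(row.iloc[:min(2, model.rank)].sum())
    return q, False
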