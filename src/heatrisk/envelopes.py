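"""Heat-envelope extraction: BIO5 values over a range polygon, reduced to
the envelope summaries [env_min, env_max] used throughout the screening.

A species' heat envelope for an epoch is the observed range of BIO5
values across the grid cells of its range polygon; the envelope's upper
bound is the thermal maximum (TM).  No density trimming or quantiles are
applied — the envelope is strictly the observed [min, max].
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal

import numpy as np
import shapely
from shapely.geometry.base import BaseGeometry

from .geo_io import ClimateGrid

__all__ = [
    "ValueSample",
    "HeatEnvelope",
    "EmptyExtractionError",
    "extract_cell_values",
    "compute_envelope",
    "thermal_max_delta",
]

Epoch = Literal["historical", "current"]
InclusionRule = Literal["center", "all_touched"]


class EmptyExtractionError(ValueError):
    """Raised when a polygon covers zero valid grid cells."""


@dataclass
class ValueSample:
    """BIO5 values of the valid cells included by a polygon (row-major).

    ``cells`` keeps the (row, col) index of each value so future layers
    can be sampled at exactly the same cells.  Weights default to
    uniform; optional cos(latitude) weights approximate cell area on
    geographic grids (min/max are weight-invariant, only overlap
    proportions are affected).
    """

    values: np.ndarray
    cells: np.ndarray  # (n, 2) int array of (row, col)
    weights: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        self.cells = np.asarray(self.cells, dtype=np.intp).reshape(-1, 2)
        if self.values.size == 0:
            raise EmptyExtractionError("sample has no cells")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("sample contains non-finite values")
        if self.weights is None:
            self.weights = np.ones_like(self.values)
        self.weights = np.asarray(self.weights, dtype=np.float64)
        if self.weights.shape != self.values.shape or np.any(self.weights <= 0):
            raise ValueError("weights must be positive and match values")

    @property
    def n_cells(self) -> int:
        return int(self.values.size)


@dataclass(frozen=True)
class HeatEnvelope:
    """[min, max] of BIO5 over a range; env_max is the thermal maximum."""

    env_min: float
    env_max: float
    epoch: str
    sample: ValueSample | None = None

    def __post_init__(self) -> None:
        if self.env_min > self.env_max:
            raise ValueError("env_min exceeds env_max")

    @property
    def width(self) -> float:
        return self.env_max - self.env_min

    @property
    def thermal_maximum(self) -> float:
        return self.env_max


def extract_cell_values(
    grid: ClimateGrid,
    polygon: BaseGeometry,
    inclusion_rule: InclusionRule = "center",
    area_weighting: bool = False,
    context: str = "",
) -> ValueSample:
    """Extract valid-cell BIO5 values covered by ``polygon``.

    The default inclusion rule keeps cells whose *center* falls inside the
    polygon (the common zonal-statistics convention); ``all_touched``
    keeps any cell whose rectangle intersects the polygon and is intended
    for very small ranges that miss every center.  Cells are returned in
    row-major order.  ``context`` (e.g. "species/epoch") is used in error
    messages only.
    """
    nrows, ncols = grid.shape
    t = grid.transform

    # restrict the test to the cell window of the polygon bounds
    minx, miny, maxx, maxy = polygon.bounds
    corners = [t.rowcol(x, y) for x in (minx, maxx) for y in (miny, maxy)]
    r0 = max(0, min(r for r, _ in corners))
    r1 = min(nrows - 1, max(r for r, _ in corners))
    c0 = max(0, min(c for _, c in corners))
    c1 = min(ncols - 1, max(c for _, c in corners))
    if r0 > r1 or c0 > c1:
        raise EmptyExtractionError(
            f"polygon does not intersect the grid ({context or 'unnamed'})")

    rows, cols = np.meshgrid(np.arange(r0, r1 + 1), np.arange(c0, c1 + 1),
                             indexing="ij")
    rows, cols = rows.ravel(), cols.ravel()
    xs = t.a * (cols + 0.5) + t.b * (rows + 0.5) + t.c
    ys = t.d * (cols + 0.5) + t.e * (rows + 0.5) + t.f

    if inclusion_rule == "center":
        inside = shapely.contains_xy(polygon, xs, ys)
    elif inclusion_rule == "all_touched":
        if t.b != 0 or t.d != 0:
            raise ValueError("all_touched requires an axis-aligned grid")
        hx, hy = abs(t.a) / 2, abs(t.e) / 2
        boxes = shapely.box(xs - hx, ys - hy, xs + hx, ys + hy)
        inside = shapely.intersects(polygon, boxes)
    else:
        raise ValueError(f"unknown inclusion rule {inclusion_rule!r}")

    valid = ~grid.nodata_mask[rows, cols]
    keep = inside & valid
    if not np.any(keep):
        if inclusion_rule == "center" and np.any(inside):
            raise EmptyExtractionError(
                f"polygon covers only nodata cells ({context or 'unnamed'})")
        raise EmptyExtractionError(
            f"zero cells included for {context or 'unnamed polygon'}")
    if inclusion_rule == "all_touched":
        warnings.warn(
            "all_touched inclusion biases very small ranges toward wider "
            "envelopes; use only when the center rule is empty",
            stacklevel=2,
        )

    # row-major ordering over the kept cells
    order = np.lexsort((cols[keep], rows[keep]))
    rr, cc = rows[keep][order], cols[keep][order]
    values = grid.values[rr, cc]
    weights = None
    if area_weighting:
        lat = t.d * (cc + 0.5) + t.e * (rr + 0.5) + t.f
        weights = np.cos(np.deg2rad(lat))
    return ValueSample(values, np.column_stack([rr, cc]), weights)


def compute_envelope(sample: ValueSample, epoch: Epoch) -> HeatEnvelope:
    """Reduce a cell-value sample to its heat envelope for ``epoch``."""
    return HeatEnvelope(float(sample.values.min()), float(sample.values.max()),
                        epoch=epoch, sample=sample)


def thermal_max_delta(hist: HeatEnvelope, curr: HeatEnvelope) -> float:
    """Δ = historical TM − current TM.

    Δ reflects whether a species still occupies the hottest parts of its
    historical range (Δ ≈ 0) or has retracted to cooler regions (Δ > 0).
    """
    if hist.epoch != "historical" or curr.epoch != "current":
        raise ValueError("arguments must be (historical, current) envelopes")
    return hist.env_max - curr.env_max
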