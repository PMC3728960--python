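"""Spatial sampling designs and per-unit location counts.

A study region is a rectangle (optionally clipped by a simple polygon) in
planar, projected meters.  Sampling units are equal-radius circles placed
either by simple random sampling with replacement (overlap allowed) or on a
square lattice with a seeded random start (nonoverlapping).  Counting is
point-in-closed-disc: a GPS fix exactly on the boundary belongs to the unit,
and a fix inside k overlapping units contributes to all k, so unit counts
are never constrained to sum to the number of fixes — the Poisson-sampling
property the count regression relies on.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

__all__ = [
    "Region",
    "UnitTable",
    "random_units",
    "systematic_units",
    "count_locations",
    "LOCATION_COLUMNS",
]

#: required columns of a GPS location table
LOCATION_COLUMNS = ("animal_id", "time", "x", "y")

#: unit-table columns that are not covariates
RESERVED_UNIT_COLUMNS = ("unit_id", "center_x", "center_y", "radius", "count")


@dataclass(frozen=True)
class Region:
    """Rectangular study region in planar meters, optionally clipped by a polygon."""

    xmin: float
    ymin: float
    xmax: float
    ymax: float
    polygon: object | None = None  # shapely Polygon

    def __post_init__(self):
        if not (self.xmax > self.xmin and self.ymax > self.ymin):
            raise ValueError("region must satisfy xmax > xmin and ymax > ymin")
        if self.polygon is not None:
            from shapely.geometry import Polygon, box

            poly = self.polygon
            if not isinstance(poly, Polygon):
                poly = Polygon(poly)
                object.__setattr__(self, "polygon", poly)
            if not poly.is_valid or not poly.is_simple:
                raise ValueError("region polygon must be simple (non-self-intersecting)")
            if not box(self.xmin, self.ymin, self.xmax, self.ymax).buffer(1e-9).contains(poly):
                raise ValueError("region polygon must lie within the bounding box")

    @property
    def width(self) -> float:
        return self.xmax - self.xmin

    @property
    def height(self) -> float:
        return self.ymax - self.ymin

    @property
    def area(self) -> float:
        if self.polygon is not None:
            return float(self.polygon.area)
        return self.width * self.height

    def contains(self, x, y):
        """Vectorized point-in-region test (boundary inclusive)."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        inside = (x >= self.xmin) & (x <= self.xmax) & (y >= self.ymin) & (y <= self.ymax)
        if self.polygon is not None:
            from shapely import points as shp_points

            mask = np.zeros_like(inside)
            if inside.any():
                pts = shp_points(np.column_stack([x[inside].ravel(), y[inside].ravel()]))
                hit = np.array([self.polygon.covers(p) for p in np.atleast_1d(pts)])
                mask[inside] = hit.reshape(mask[inside].shape)
            inside = mask
        return inside


@dataclass
class UnitTable:
    """A set of equal-radius circular sampling units with covariates and counts.

    ``frame`` holds one row per unit with columns ``unit_id, center_x,
    center_y, radius``, then covariate columns, then (once counted) ``count``.
    """

    frame: pd.DataFrame
    design_kind: str = "user_supplied"
    covariate_names: tuple = field(default=None)

    def __post_init__(self):
        f = self.frame
        missing = [c for c in ("unit_id", "center_x", "center_y", "radius") if c not in f.columns]
        if missing:
            raise ValueError(f"unit table missing column(s): {', '.join(missing)}")
        radii = f["radius"].to_numpy(dtype=float)
        if not np.all(radii > 0):
            raise ValueError("unit radius must be > 0")
        if np.unique(radii).size > 1:
            raise ValueError("all sampling units must share one radius")
        if self.covariate_names is None:
            self.covariate_names = tuple(
                c for c in f.columns if c not in RESERVED_UNIT_COLUMNS
            )
        else:
            self.covariate_names = tuple(self.covariate_names)
            absent = [c for c in self.covariate_names if c not in f.columns]
            if absent:
                raise ValueError(f"unknown covariate column(s): {', '.join(absent)}")
        for c in self.covariate_names:
            vals = pd.to_numeric(f[c], errors="coerce")
            if vals.isna().any():
                raise ValueError(f"covariate column contains non-numeric values: {c}")
        if "count" in f.columns:
            _validate_counts(f["count"].to_numpy())

    @property
    def n_units(self) -> int:
        return len(self.frame)

    @property
    def radius(self) -> float:
        return float(self.frame["radius"].iloc[0])

    @property
    def centers(self) -> np.ndarray:
        return self.frame[["center_x", "center_y"]].to_numpy(dtype=float)

    @property
    def counts(self) -> np.ndarray | None:
        if "count" not in self.frame.columns:
            return None
        return self.frame["count"].to_numpy(dtype=int)

    def covariates(self, names=None) -> np.ndarray:
        names = self.covariate_names if names is None else list(names)
        absent = [c for c in names if c not in self.frame.columns]
        if absent:
            raise ValueError(f"unknown covariate column(s): {', '.join(absent)}")
        return self.frame[list(names)].to_numpy(dtype=float)

    def with_counts(self, counts) -> "UnitTable":
        counts = _validate_counts(np.asarray(counts))
        if counts.shape[0] != self.n_units:
            raise ValueError("count vector length does not match number of units")
        f = self.frame.copy()
        f["count"] = counts
        return UnitTable(f, design_kind=self.design_kind, covariate_names=self.covariate_names)


def _validate_counts(counts: np.ndarray) -> np.ndarray:
    arr = np.asarray(counts)
    if not np.all(np.isfinite(arr.astype(float))):
        raise ValueError("counts must be finite")
    if np.any(arr.astype(float) < 0) or np.any(arr.astype(float) != np.round(arr.astype(float))):
        raise ValueError("counts must be non-negative integers")
    return arr.astype(int)


def _units_frame(cx, cy, radius) -> pd.DataFrame:
    n = len(cx)
    return pd.DataFrame(
        {
            "unit_id": [f"u{i:05d}" for i in range(n)],
            "center_x": cx,
            "center_y": cy,
            "radius": float(radius),
        }
    )


def random_units(region: Region, n: int, radius: float, seed=None) -> UnitTable:
    """Simple random sample, with replacement, of circular units (overlap allowed).

    Centers are uniform over the region; with a polygon boundary, rejection
    sampling from the bounding box gives uniformity on the polygon.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if radius <= 0:
        raise ValueError("radius must be > 0")
    if radius > min(region.width, region.height) / 2:
        raise ValueError("region too small for units of this radius")
    rng = np.random.default_rng(seed)
    xs = np.empty(n)
    ys = np.empty(n)
    got = 0
    while got < n:
        m = max(n - got, 16)
        cx = rng.uniform(region.xmin, region.xmax, m)
        cy = rng.uniform(region.ymin, region.ymax, m)
        keep = region.contains(cx, cy)
        k = min(int(keep.sum()), n - got)
        xs[got : got + k] = cx[keep][:k]
        ys[got : got + k] = cy[keep][:k]
        got += k
    return UnitTable(_units_frame(xs, ys, radius), design_kind="random_replacement")


def systematic_units(region: Region, spacing: float, radius: float, seed=None) -> UnitTable:
    """Square lattice of nonoverlapping circular units with a seeded random start."""
    if radius <= 0:
        raise ValueError("radius must be > 0")
    if spacing < 2 * radius:
        raise ValueError("units would overlap: spacing must be >= 2*radius")
    rng = np.random.default_rng(seed)
    off_x, off_y = rng.uniform(0.0, spacing, size=2)
    xs = np.arange(region.xmin + off_x, region.xmax, spacing)
    ys = np.arange(region.ymin + off_y, region.ymax, spacing)
    cx, cy = np.meshgrid(xs, ys)
    cx, cy = cx.ravel(), cy.ravel()
    keep = region.contains(cx, cy)
    cx, cy = cx[keep], cy[keep]
    if cx.size == 0:
        raise ValueError("no lattice centers fall inside the region")
    return UnitTable(_units_frame(cx, cy, radius), design_kind="systematic_random_start")


def count_locations(units: UnitTable, locations: pd.DataFrame, animal_filter=None) -> UnitTable:
    """Count filtered GPS fixes in each unit's closed disc.

    A fix at distance exactly ``radius`` is counted; a fix inside several
    overlapping units is counted in every one, so the total over units can
    exceed the number of distinct fixes under a random-with-replacement
    design.  An empty location table yields all-zero counts.
    """
    loc = locations
    missing = [c for c in ("x", "y") if c not in loc.columns]
    if missing:
        raise ValueError(f"location table missing column(s): {', '.join(missing)}")
    if animal_filter is not None:
        if "animal_id" not in loc.columns:
            raise ValueError("location table missing column(s): animal_id")
        loc = loc[loc["animal_id"].isin(set(animal_filter))]
    if len(loc) == 0:
        return units.with_counts(np.zeros(units.n_units, dtype=int))
    pts = loc[["x", "y"]].to_numpy(dtype=float)
    if not np.all(np.isfinite(pts)):
        raise ValueError("location coordinates must be finite")
    tree = cKDTree(pts)
    # query_ball_point is boundary-inclusive (distance <= r), matching the closed-disc rule
    counts = tree.query_ball_point(units.centers, r=units.radius, return_length=True)
    return units.with_counts(np.asarray(counts, dtype=int))
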