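"""Gridded prediction surfaces: kriging on a grid, back-transformation,
forest masking and distributional summaries.

Grids are regular, planar-km, north-up: arrays are (n_rows, n_cols) with row
0 the northernmost row; values apply at cell centres (no block averaging).
Back-transformation is the naive anti-log, value = conversion * 10**pred,
matching a log10 valuation pipeline; an optional lognormal bias correction
multiplies by 10**(ln(10) * se**2 / 2).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .kriging import KrigingConfig, OrdinaryKriging
from .variogram import VariogramModel

__all__ = [
    "GridSpec",
    "PredictionSurface",
    "SurfaceSummary",
    "grid_from_bounds",
    "predict_grid",
    "back_transform",
    "apply_mask",
    "summarize",
]

NODATA = -9999.0


@dataclass(frozen=True)
class GridSpec:
    """Regular grid: lower-left origin, square cells of ``cell_size_km``."""

    origin_x: float
    origin_y: float
    cell_size_km: float
    n_cols: int
    n_rows: int

    def __post_init__(self) -> None:
        if self.cell_size_km <= 0:
            raise ValueError("cell_size_km must be > 0")
        if self.n_cols < 1 or self.n_rows < 1:
            raise ValueError("grid must have at least one cell")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    @property
    def n_cells(self) -> int:
        return self.n_rows * self.n_cols

    def cell_centers(self) -> np.ndarray:
        """(n_cells, 2) centre coordinates in row-major, north-up order."""
        cs = self.cell_size_km
        xs = self.origin_x + cs * (np.arange(self.n_cols) + 0.5)
        ys = self.origin_y + cs * (self.n_rows - np.arange(self.n_rows) - 0.5)
        xx, yy = np.meshgrid(xs, ys)
        return np.column_stack([xx.ravel(), yy.ravel()])


def grid_from_bounds(points, cell_size_km: float = 0.5, pad_km: float = 0.0) -> GridSpec:
    """Smallest grid of square cells covering the points' bounding box."""
    points = np.atleast_2d(np.asarray(points, dtype=float))
    x0, y0 = points.min(axis=0) - pad_km
    x1, y1 = points.max(axis=0) + pad_km
    n_cols = max(1, int(np.ceil((x1 - x0) / cell_size_km)))
    n_rows = max(1, int(np.ceil((y1 - y0) / cell_size_km)))
    return GridSpec(float(x0), float(y0), cell_size_km, n_cols, n_rows)


@dataclass
class PredictionSurface:
    """Kriged grid on the log10 scale, optionally back-transformed and masked.

    All arrays are (n_rows, n_cols); ``mask`` is True where the cell is kept
    (forest).  ``value_usd_ha`` is None until :func:`back_transform` runs.
    """

    grid: GridSpec
    pred_log10: np.ndarray
    se_log10: np.ndarray
    mask: np.ndarray
    value_usd_ha: np.ndarray | None = None
    conversion: float | None = None

    def __post_init__(self) -> None:
        shp = self.grid.shape
        for name in ("pred_log10", "se_log10", "mask"):
            arr = getattr(self, name)
            if arr.shape != shp:
                raise ValueError(f"{name} shape {arr.shape} != grid shape {shp}")
        if self.value_usd_ha is not None and self.value_usd_ha.shape != shp:
            raise ValueError("value_usd_ha shape mismatch")


@dataclass(frozen=True)
class SurfaceSummary:
    """Distributional summary of the unmasked back-transformed cells.

    The interval [q025, q975] is the empirical 2.5-97.5 percentile band of
    the per-cell value distribution (which is typically heavily skewed, so
    the lower bound can coincide with the bulk of the mass).
    """

    mean_usd_ha: float
    q025_usd_ha: float
    q975_usd_ha: float
    min_usd_ha: float
    max_usd_ha: float
    n_cells: int

    def to_dict(self) -> dict:
        return {
            "mean_usd_ha": self.mean_usd_ha,
            "q025_usd_ha": self.q025_usd_ha,
            "q975_usd_ha": self.q975_usd_ha,
            "min_usd_ha": self.min_usd_ha,
            "max_usd_ha": self.max_usd_ha,
            "n_cells": self.n_cells,
        }


def predict_grid(
    points,
    log_values,
    model: VariogramModel,
    grid: GridSpec,
    config: KrigingConfig | None = None,
) -> PredictionSurface:
    """Ordinary kriging of log10 values at every cell centre of ``grid``."""
    config = config or KrigingConfig()
    ok = OrdinaryKriging(
        variogram=model,
        neighborhood=config.neighborhood,
        n_neighbors=config.n_neighbors,
        min_neighbors=config.min_neighbors,
        max_radius_km=config.max_radius_km,
    ).fit(points, log_values)
    pred, se = ok.predict(grid.cell_centers(), return_std=True)
    return PredictionSurface(
        grid=grid,
        pred_log10=pred.reshape(grid.shape),
        se_log10=se.reshape(grid.shape),
        mask=np.ones(grid.shape, dtype=bool),
    )


def back_transform(
    surface: PredictionSurface,
    conversion: float = 0.35,
    bias_correct: bool = False,
) -> PredictionSurface:
    """Anti-log the kriged log10 predictions to US$/ha.

    value = conversion * 10**pred_log10; with ``bias_correct`` the lognormal
    mean correction 10**(ln(10)/2 * se_log10**2) is applied as well.
    """
    if not (0.0 < conversion <= 1.0):
        raise ValueError("conversion must be in (0, 1]")
    value = conversion * np.power(10.0, surface.pred_log10)
    if bias_correct:
        value = value * np.power(10.0, 0.5 * np.log(10.0) * surface.se_log10**2)
    return replace(surface, value_usd_ha=value, conversion=conversion)


def apply_mask(surface: PredictionSurface, mask: np.ndarray) -> PredictionSurface:
    """Intersect the surface's mask with a forest mask of the same grid."""
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != surface.grid.shape:
        raise ValueError(
            f"mask shape {mask.shape} does not match grid shape {surface.grid.shape}"
        )
    combined = surface.mask & mask
    if not combined.any():
        raise ValueError("empty surface: mask removes every cell")
    return replace(surface, mask=combined)


def summarize(surface: PredictionSurface) -> SurfaceSummary:
    """Mean, empirical 2.5/97.5 percentiles and extremes over unmasked cells."""
    if surface.value_usd_ha is None:
        raise ValueError("surface has not been back-transformed")
    vals = surface.value_usd_ha[surface.mask]
    if vals.size == 0:
        raise ValueError("empty surface: no unmasked cells")
    return SurfaceSummary(
        mean_usd_ha=float(vals.mean()),
        q025_usd_ha=float(np.quantile(vals, 0.025)),
        q975_usd_ha=float(np.quantile(vals, 0.975)),
        min_usd_ha=float(vals.min()),
        max_usd_ha=float(vals.max()),
        n_cells=int(vals.size),
    )
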