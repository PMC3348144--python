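"""File I/O: survey/price/valued-plot CSVs and ESRI ASCII grids.

All tabular formats are comma-separated UTF-8 with a header row.  Rasters use
the ESRI ASCII grid format (plain text, nodata -9999), which any GIS reads.
Readers validate schemas and report offending rows with line numbers
(header = line 1, first data row = line 2).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .surfaces import NODATA, GridSpec, PredictionSurface

__all__ = [
    "read_survey",
    "write_survey",
    "read_prices",
    "write_prices",
    "write_valued",
    "read_ascii_grid",
    "write_ascii_grid",
    "write_surface",
]

SURVEY_COLUMNS = ["plot_id", "x_km", "y_km", "genus", "volume_m3"]
PRICE_COLUMNS = ["genus", "year", "usd_per_m3"]


def _read_csv(path, required: list[str]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise ValueError(f"{path}: file is empty") from None
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns: {missing}")
    if df.empty:
        raise ValueError(f"{path}: no data rows")
    return df


def read_survey(path) -> pd.DataFrame:
    """Read a plot survey CSV (plot_id, x_km, y_km, genus, volume_m3)."""
    df = _read_csv(path, SURVEY_COLUMNS)
    for col in ("x_km", "y_km", "volume_m3"):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna() & df[col].notna() | df[col].isna()
        if bad.any():
            line = int(df.index[bad][0]) + 2
            raise ValueError(f"{path}: non-numeric or missing {col} at line {line}")
        df[col] = vals
    neg = df["volume_m3"] < 0
    if neg.any():
        line = int(df.index[neg][0]) + 2
        raise ValueError(f"{path}: negative volume_m3 at line {line}")
    return df[SURVEY_COLUMNS]


def write_survey(survey: pd.DataFrame, path) -> None:
    survey[SURVEY_COLUMNS].to_csv(path, index=False)


def read_prices(path) -> pd.DataFrame:
    """Read raw per-year price records (genus, year, usd_per_m3)."""
    df = _read_csv(path, PRICE_COLUMNS)
    vals = pd.to_numeric(df["usd_per_m3"], errors="coerce")
    bad = vals.isna()
    if bad.any():
        line = int(df.index[bad][0]) + 2
        raise ValueError(f"{path}: non-numeric usd_per_m3 at line {line}")
    df["usd_per_m3"] = vals
    nonpos = df["usd_per_m3"] <= 0
    if nonpos.any():
        line = int(df.index[nonpos][0]) + 2
        raise ValueError(f"{path}: non-positive usd_per_m3 at line {line}")
    return df[PRICE_COLUMNS]


def write_prices(prices: pd.DataFrame, path) -> None:
    prices.to_csv(path, index=False)


def write_valued(valued: pd.DataFrame, path) -> None:
    """Write valued plots (plot_id, x_km, y_km, total_usd_ha[, log10_total])."""
    cols = ["plot_id", "x_km", "y_km", "total_usd_ha"]
    if "log10_total" in valued.columns:
        cols.append("log10_total")
    valued[cols].to_csv(path, index=False)


def write_ascii_grid(array: np.ndarray, grid: GridSpec, path, nodata: float = NODATA) -> None:
    """Write a (n_rows, n_cols) north-up array as an ESRI ASCII grid."""
    array = np.asarray(array, dtype=float)
    if array.shape != grid.shape:
        raise ValueError(f"array shape {array.shape} != grid shape {grid.shape}")
    out = np.where(np.isfinite(array), array, nodata)
    header = (
        f"ncols {grid.n_cols}\n"
        f"nrows {grid.n_rows}\n"
        f"xllcorner {grid.origin_x}\n"
        f"yllcorner {grid.origin_y}\n"
        f"cellsize {grid.cell_size_km}\n"
        f"NODATA_value {nodata}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        for row in out:  # row 0 is the northernmost row, as the format expects
            fh.write(" ".join(format(v, ".10g") for v in row) + "\n")


def read_ascii_grid(path) -> tuple[np.ndarray, GridSpec, float]:
    """Read an ESRI ASCII grid; returns (array with NaN at nodata, grid, nodata)."""
    path = Path(path)
    with open(path) as fh:
        header = {}
        pos = fh.tell()
        for _ in range(6):
            pos = fh.tell()
            line = fh.readline()
            parts = line.split()
            if len(parts) == 2 and not _is_number(parts[0]):
                header[parts[0].lower()] = float(parts[1])
            else:
                fh.seek(pos)
                break
        required = {"ncols", "nrows", "xllcorner", "yllcorner", "cellsize"}
        missing = required - set(header)
        if missing:
            raise ValueError(f"{path}: ASCII grid header missing {sorted(missing)}")
        nodata = header.get("nodata_value", NODATA)
        data = np.loadtxt(fh)
    grid = GridSpec(
        origin_x=header["xllcorner"],
        origin_y=header["yllcorner"],
        cell_size_km=header["cellsize"],
        n_cols=int(header["ncols"]),
        n_rows=int(header["nrows"]),
    )
    data = np.atleast_2d(data)
    if data.shape != grid.shape:
        raise ValueError(f"{path}: data shape {data.shape} != header shape {grid.shape}")
    data = np.where(data == nodata, np.nan, data)
    return data, grid, nodata


def _is_number(tok: str) -> bool:
    try:
        float(tok)
    except ValueError:
        return False
    return True


def write_surface(surface: PredictionSurface, out_dir, stem: str) -> list[Path]:
    """Write a prediction surface as ASCII grids plus a per-cell CSV.

    Emits ``<stem>_pred_log10.asc``, ``<stem>_se_log10.asc``, ``<stem>_mask.asc``
    and, if back-transformed, ``<stem>_value_usd_ha.asc`` (masked cells as
    nodata), plus ``<stem>_cells.csv`` with one row per unmasked cell.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    grid = surface.grid
    written = []

    def _emit(name: str, arr: np.ndarray) -> None:
        p = out_dir / f"{stem}_{name}.asc"
        write_ascii_grid(arr, grid, p)
        written.append(p)

    _emit("pred_log10", surface.pred_log10)
    _emit("se_log10", surface.se_log10)
    _emit("mask", surface.mask.astype(float))
    if surface.value_usd_ha is not None:
        _emit("value_usd_ha", np.where(surface.mask, surface.value_usd_ha, np.nan))

    centers = grid.cell_centers()
    keep = surface.mask.ravel()
    df = pd.DataFrame(
        {
            "x_km": centers[keep, 0],
            "y_km": centers[keep, 1],
            "pred_log10": surface.pred_log10.ravel()[keep],
            "se_log10": surface.se_log10.ravel()[keep],
        }
    )
    if surface.value_usd_ha is not None:
        df["value_usd_ha"] = surface.value_usd_ha.ravel()[keep]
    csv_path = out_dir / f"{stem}_cells.csv"
    df.to_csv(csv_path, index=False)
    written.append(csv_path)
    return written
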