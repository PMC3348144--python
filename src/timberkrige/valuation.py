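"""Plot-level timber valuation.

Turns a plot survey (per-genus standing volumes on 1-ha plots) and a genus
price table (averaged export prices, US$/m3) into per-plot values:

    genus value (US$/ha) = volume_m3 * price_usd_per_m3 * conversion
    total value          = sum of genus values within the plot
    log_total            = log10(total)   for plots with total > 0

``conversion`` is the sawn-wood recovery fraction aligning standing volumes
with sawn-wood export prices (default 0.35).  It is a pure multiplicative
factor, i.e. a constant shift on the log10 scale, so kriging can run on
unscaled log values with the factor applied at back-transformation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "DEFAULT_CONVERSION",
    "average_prices",
    "value_plots",
    "log_transform",
    "survey_diagnostics",
]

logger = logging.getLogger(__name__)

DEFAULT_CONVERSION = 0.35


def average_prices(raw: pd.DataFrame) -> pd.DataFrame:
    """Average per-year export prices into one price per genus.

    ``raw`` has columns (genus, year, usd_per_m3); the result has columns
    (genus, price_usd_per_m3, years) with the unweighted arithmetic mean
    across the years present.  Genera with no price rows simply do not appear;
    a warning is logged naming them if the input carries an explicit genus
    list in ``raw.attrs['genera']``.
    """
    required = {"genus", "year", "usd_per_m3"}
    missing = required - set(raw.columns)
    if missing:
        raise ValueError(f"price table missing columns: {sorted(missing)}")
    if raw.empty:
        raise ValueError("price table is empty")
    if (raw["usd_per_m3"] <= 0).any():
        raise ValueError("prices must be strictly positive")
    grouped = raw.groupby("genus", sort=True)
    out = grouped.agg(
        price_usd_per_m3=("usd_per_m3", "mean"),
        years=("year", lambda y: "-".join(str(v) for v in sorted(set(y)))),
    ).reset_index()
    expected = raw.attrs.get("genera")
    if expected is not None:
        dropped = sorted(set(expected) - set(out["genus"]))
        if dropped:
            logger.warning("genera with no price rows excluded: %s", ", ".join(dropped))
    return out


def _norm_genus(s: pd.Series) -> pd.Series:
    return s.astype(str).str.strip().str.casefold()


def value_plots(
    survey: pd.DataFrame,
    prices: pd.DataFrame,
    conversion: float = DEFAULT_CONVERSION,
) -> pd.DataFrame:
    """Per-plot valuation: one row per plot with per-genus and total US$/ha.

    Duplicate (plot, genus) rows are summed before valuation (surveys record
    individual trees within plots).  Genus names are matched to the price
    table case-insensitively after whitespace trimming; surveyed genera with
    no price are dropped with a logged warning.  Because plots are 1 ha,
    volume * price is already US$/ha.

    Returns a frame with columns plot_id, x_km, y_km, one ``value_<genus>``
    column per priced genus, total_usd_ha, and ``attrs`` recording the
    conversion factor applied.
    """
    if not (0.0 < conversion <= 1.0):
        raise ValueError("conversion must be in (0, 1]")
    required = {"plot_id", "x_km", "y_km", "genus", "volume_m3"}
    missing = required - set(survey.columns)
    if missing:
        raise ValueError(f"survey missing columns: {sorted(missing)}")
    if (survey["volume_m3"] < 0).any():
        bad = survey.index[survey["volume_m3"] < 0][0]
        raise ValueError(f"negative volume at survey row {bad}")

    plots = survey.attrs.get("plots")
    if plots is None:
        plots = (
            survey[["plot_id", "x_km", "y_km"]]
            .drop_duplicates("plot_id")
            .reset_index(drop=True)
        )
    plots = plots[["plot_id", "x_km", "y_km"]].copy()

    price_map = dict(
        zip(_norm_genus(prices["genus"]), prices["price_usd_per_m3"].astype(float))
    )
    pretty = dict(zip(_norm_genus(prices["genus"]), prices["genus"]))

    out = plots.set_index("plot_id")
    if len(survey):
        sv = survey.copy()
        sv["_g"] = _norm_genus(sv["genus"])
        surveyed = set(sv["_g"])
        unpriced = surveyed - set(price_map)
        if unpriced:
            names = sorted(sv.loc[sv["_g"].isin(unpriced), "genus"].unique())
            logger.warning("surveyed genera with no price dropped: %s", ", ".join(names))
        sv = sv[sv["_g"].isin(price_map)]
        if not surveyed - unpriced:
            raise ValueError("no surveyed genus has a price; nothing to value")
        agg = sv.groupby(["plot_id", "_g"])["volume_m3"].sum().reset_index()
        agg["value"] = (
            agg["volume_m3"] * agg["_g"].map(price_map) * conversion
        )
        wide = agg.pivot(index="plot_id", columns="_g", values="value")
        wide.columns = [f"value_{pretty[g]}" for g in wide.columns]
        out = out.join(wide)
    value_cols = [c for c in out.columns if c.startswith("value_")]
    out[value_cols] = out[value_cols].fillna(0.0)
    out["total_usd_ha"] = out[value_cols].sum(axis=1) if value_cols else 0.0
    out = out.reset_index()
    out.attrs["conversion"] = conversion
    return out


def log_transform(
    valued: pd.DataFrame,
    policy: str = "exclude",
    epsilon: float = 1.0,
) -> pd.DataFrame:
    """Populate log10_total, handling plots whose total value is zero.

    policy='exclude' (default) drops zero-value plots from the kriging data
    set; policy='offset' instead uses log10(total + epsilon) for every plot.
    The retained-plot count is logged and stored in ``attrs['n_retained']``.
    """
    if "total_usd_ha" not in valued.columns:
        raise ValueError("valued frame lacks total_usd_ha")
    if policy not in ("exclude", "offset"):
        raise ValueError("policy must be 'exclude' or 'offset'")
    out = valued.copy()
    if policy == "offset":
        out["log10_total"] = np.log10(out["total_usd_ha"] + epsilon)
    else:
        positive = out["total_usd_ha"] > 0
        if not positive.any():
            raise ValueError("all plots have non-positive total value")
        out = out[positive].reset_index(drop=True)
        out["log10_total"] = np.log10(out["total_usd_ha"])
    out.attrs.update(valued.attrs)
    out.attrs["n_retained"] = len(out)
    logger.info("log transform retained %d of %d plots", len(out), len(valued))
    return out


@dataclass(frozen=True)
class SurveyDiagnostics:
    per_genus: pd.DataFrame  # genus, n_locations, total_volume_m3, volume_share
    max_volume_share: float
    max_share_genus: str


def survey_diagnostics(survey: pd.DataFrame) -> SurveyDiagnostics:
    """Occupied-plot counts, total volumes and volume shares per genus.

    Shares are of total recorded *volume* (the data model carries no
    within-plot tree counts, so an individual-level share is not computable
    here and is not what this reports).
    """
    if survey.empty:
        raise ValueError("survey is empty")
    per = (
        survey.groupby("genus")
        .agg(
            n_locations=("plot_id", "nunique"),
            total_volume_m3=("volume_m3", "sum"),
        )
        .reset_index()
    )
    total_vol = per["total_volume_m3"].sum()
    per["volume_share"] = per["total_volume_m3"] / total_vol if total_vol > 0 else 0.0
    top = per.loc[per["volume_share"].idxmax()]
    return SurveyDiagnostics(
        per_genus=per,
        max_volume_share=float(top["volume_share"]),
        max_share_genus=str(top["genus"]),
    )
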