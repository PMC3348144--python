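"""Synthetic forest-inventory survey generator.

Emulates the statistical structure the downstream analysis assumes: a large
set of 1-ha plots scattered over a planar km domain, a handful of commercial
genera with highly uneven prevalence (tens to ~1100 occupied plots out of
~2465), log-normal per-plot standing volumes whose log-scale fluctuations are
spatially autocorrelated out to a couple of hundred km, and a broad regional
trend putting the highest values in one corner of the domain.

Everything is a pure function of (config, seed); two calls with the same seed
return identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.spatial.distance import squareform, pdist

from .variogram import FAMILIES, model_correlation

__all__ = [
    "FieldSpec",
    "GenusSpec",
    "SyntheticSurveyConfig",
    "simulate_gaussian_field",
    "simulate_survey",
    "default_price_table",
    "default_survey_config",
    "make_forest_mask",
    "TABLE_PRICES_USD_M3",
    "TABLE_N_LOCATIONS",
]

# Averaged 2006-2007 export prices (US$/m3) and occupied-plot counts for the
# 11 commercial genera the analysis runs on.
TABLE_PRICES_USD_M3: dict[str, float] = {
    "Dicorynia": 158.0,
    "Goupia": 257.0,
    "Hymenaea": 569.0,
    "Hymenolobium": 96.0,
    "Manilkara": 281.0,
    "Mora": 216.0,
    "Nectandra": 292.0,
    "Peltogyne": 143.0,
    "Swartzia": 105.0,
    "Swietenia": 1096.0,
    "Tabebuia": 317.0,
}

TABLE_N_LOCATIONS: dict[str, int] = {
    "Dicorynia": 21,
    "Goupia": 824,
    "Hymenaea": 945,
    "Hymenolobium": 261,
    "Manilkara": 598,
    "Mora": 98,
    "Nectandra": 1100,
    "Peltogyne": 255,
    "Swartzia": 909,
    "Swietenia": 57,
    "Tabebuia": 757,
}


@dataclass(frozen=True)
class FieldSpec:
    """Second-order structure of a stationary Gaussian random field.

    ``mean`` and ``trend_per_km`` act on the log scale downstream: the field
    value at location (x, y) is mean + trend_per_km * x + structured noise
    with variance ``nugget + partial_sill``.
    """

    family: str = "spherical"
    nugget: float = 0.0
    partial_sill: float = 1.0
    range_km: float = 200.0
    mean: float = 0.0
    trend_per_km: float = 0.0

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}")
        if self.nugget < 0 or self.partial_sill < 0:
            raise ValueError("nugget and partial_sill must be >= 0")
        if self.nugget + self.partial_sill < 0:
            raise ValueError("total variance must be >= 0")
        if self.range_km <= 0:
            raise ValueError("range_km must be > 0")


@dataclass(frozen=True)
class GenusSpec:
    """Prevalence and volume distribution of one genus.

    A plot contains the genus with probability ``prevalence``; when present,
    its standing volume is exp(volume_log_mean + volume_log_sd * field) m3,
    where ``field`` is a unit-variance draw from ``field_spec``'s spatial
    structure (natural-log scale).
    """

    genus: str
    prevalence: float
    volume_log_mean: float = 1.2
    volume_log_sd: float = 0.8
    field: FieldSpec = field(default_factory=FieldSpec)

    def __post_init__(self) -> None:
        if not (0.0 < self.prevalence <= 1.0):
            raise ValueError("prevalence must be in (0, 1]")
        if self.volume_log_sd < 0:
            raise ValueError("volume_log_sd must be >= 0")


@dataclass(frozen=True)
class SyntheticSurveyConfig:
    n_plots: int = 2465
    domain: tuple[float, float, float, float] = (0.0, 3500.0, 0.0, 2500.0)
    genera: tuple[GenusSpec, ...] = ()
    clustered_presence: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_plots < 2:
            raise ValueError("n_plots must be >= 2")
        x0, x1, y0, y1 = self.domain
        if not (x1 > x0 and y1 > y0):
            raise ValueError("domain must have positive area")
        names = [g.genus for g in self.genera]
        if len(set(names)) != len(names):
            raise ValueError("genus names must be unique")


def _covariance(points: np.ndarray, spec: FieldSpec) -> np.ndarray:
    d = squareform(pdist(points))
    cov = spec.partial_sill * model_correlation(spec.family, d, spec.range_km)
    cov[np.diag_indices_from(cov)] += spec.nugget
    return cov


def simulate_gaussian_field(locations, spec: FieldSpec, seed) -> np.ndarray:
    """One draw of a Gaussian random field at the given locations.

    The covariance is C(h) = partial_sill * rho(h) with rho from the named
    family, plus the nugget on the diagonal; the draw is mean + trend + L @ eps
    with L the (jittered) Cholesky factor.  Same seed, same output.
    """
    points = np.atleast_2d(np.asarray(locations, dtype=float))
    if points.shape[1] != 2:
        raise ValueError("locations must be (n, 2)")
    rng = np.random.default_rng(seed)
    n = len(points)
    base = spec.mean + spec.trend_per_km * points[:, 0]
    total_var = spec.nugget + spec.partial_sill
    if total_var == 0.0:
        return base
    cov = _covariance(points, spec)
    jitter = 1e-10 * total_var
    try:
        L = np.linalg.cholesky(cov + jitter * np.eye(n))
    except np.linalg.LinAlgError as exc:
        raise ValueError(f"covariance for {spec} is not positive definite") from exc
    return base + L @ rng.standard_normal(n)


def simulate_survey(config: SyntheticSurveyConfig) -> pd.DataFrame:
    """Generate a plot survey table: one row per (plot, present genus).

    Columns: plot_id, x_km, y_km, genus, volume_m3.  Plots are uniform in the
    domain.  Presence is i.i.d. Bernoulli(prevalence) per genus by default;
    with ``clustered_presence`` a second latent field is thresholded at the
    prevalence quantile so occupied plots clump spatially.  Plots with no
    genus present still appear in the coordinate frame (see ``attrs['plots']``).
    """
    rng = np.random.default_rng(config.seed)
    x0, x1, y0, y1 = config.domain
    xs = rng.uniform(x0, x1, config.n_plots)
    ys = rng.uniform(y0, y1, config.n_plots)
    points = np.column_stack([xs, ys])
    plots = pd.DataFrame(
        {"plot_id": np.arange(config.n_plots), "x_km": xs, "y_km": ys}
    )

    records = []
    for g in config.genera:
        sub_seed = rng.integers(0, 2**31 - 1)
        vol_seed = rng.integers(0, 2**31 - 1)
        if config.clustered_presence:
            latent_spec = replace(g.field, mean=0.0, trend_per_km=0.0, nugget=0.0,
                                  partial_sill=1.0)
            latent = simulate_gaussian_field(points, latent_spec, sub_seed)
            cut = np.quantile(latent, 1.0 - g.prevalence)
            present = latent > cut if g.prevalence < 1.0 else np.ones(len(points), bool)
        else:
            present = rng.uniform(size=config.n_plots) < g.prevalence
        if not present.any():
            continue
        # a GRF restricted to the occupied plots is the GRF at those plots,
        # so simulate volumes only where the genus is present
        occ = points[present]
        unit = replace(g.field, mean=0.0, trend_per_km=0.0)
        sd_total = np.sqrt(unit.nugget + unit.partial_sill)
        z = simulate_gaussian_field(occ, unit, vol_seed)
        z = z / sd_total if sd_total > 0 else z
        logvol = (
            g.volume_log_mean
            + g.field.mean
            + g.field.trend_per_km * occ[:, 0]
            + g.volume_log_sd * z
        )
        vols = np.exp(logvol)
        sel = plots.loc[present, ["plot_id", "x_km", "y_km"]].reset_index(drop=True)
        sel["genus"] = g.genus
        sel["volume_m3"] = vols
        records.append(sel)

    if records:
        survey = pd.concat(records, ignore_index=True)
    else:
        survey = pd.DataFrame(columns=["plot_id", "x_km", "y_km", "genus", "volume_m3"])
        survey = survey.astype({"plot_id": int, "x_km": float, "y_km": float,
                                "genus": str, "volume_m3": float})
    survey = survey.sort_values(["plot_id", "genus"], kind="stable").reset_index(drop=True)
    survey.attrs["plots"] = plots
    return survey


def default_price_table() -> pd.DataFrame:
    """Averaged export prices (US$/m3, 2006-2007) for the 11 study genera."""
    return pd.DataFrame(
        {
            "genus": list(TABLE_PRICES_USD_M3),
            "price_usd_per_m3": list(TABLE_PRICES_USD_M3.values()),
            "years": ["2006-2007"] * len(TABLE_PRICES_USD_M3),
        }
    )


def default_survey_config(seed: int = 0, n_plots: int = 2465,
                          clustered_presence: bool = False) -> SyntheticSurveyConfig:
    """The default fixture: 2465 plots, 11 genera at the survey's prevalences.

    Volume log-means put mean occupied-plot volumes near 4.7 m3 (the level
    implied by per-genus totals like 101.24 m3 over 21 plots).  The log-scale
    spatial structure has an effective range of 200 km plus a weak west-to-east
    trend so the high-value corner and the long-range correlogram signal both
    appear.
    """
    genera = tuple(
        GenusSpec(
            genus=name,
            prevalence=count / 2465.0,
            volume_log_mean=1.23,
            volume_log_sd=0.8,
            field=FieldSpec(
                family="spherical",
                nugget=0.1,
                partial_sill=0.9,
                range_km=200.0,
                mean=0.0,
                trend_per_km=2.0e-4,
            ),
        )
        for name, count in TABLE_N_LOCATIONS.items()
    )
    return SyntheticSurveyConfig(
        n_plots=n_plots,
        domain=(0.0, 3500.0, 0.0, 2500.0),
        genera=genera,
        clustered_presence=clustered_presence,
        seed=seed,
    )


def make_forest_mask(grid, holes=()) -> np.ndarray:
    """Boolean forest mask on a grid: True = forest, False inside any hole.

    ``holes`` are (x_min, x_max, y_min, y_max) rectangles in km; a cell is
    non-forest when its centre falls inside a rectangle.
    """
    centers = grid.cell_centers()
    mask = np.ones(len(centers), dtype=bool)
    for (hx0, hx1, hy0, hy1) in holes:
        inside = (
            (centers[:, 0] >= hx0)
            & (centers[:, 0] <= hx1)
            & (centers[:, 1] >= hy0)
            & (centers[:, 1] <= hy1)
        )
        mask &= ~inside
    return mask.reshape(grid.shape)
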