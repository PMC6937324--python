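"""Per-site climate scalars for the Q model.

Weather enters the model through a single multiplicative scalar ``r_e`` that
rescales the decomposer metabolic rate ``u0``.  It is built from annual
weather as the product of

* a temperature reduction function in [0, 1] — an Arrhenius-type response
  normalised to 1 at a cap temperature (a Lloyd–Taylor parameterisation is
  available behind a flag),
* a moisture reduction function in [0, 1] driven by the soil water saturation
  fraction from a single-bucket annual water balance (precipitation in,
  actual evapotranspiration out, capped at the water-holding capacity).

Because only relative climate differences between sites matter to the
calibration, the raw product is normalised so that its average over all
sites equals one.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "R_GAS",
    "WeatherYear",
    "ClimateScalars",
    "temperature_response",
    "moisture_response",
    "default_moisture_curve",
    "potential_evapotranspiration",
    "water_balance",
    "whc_from_texture",
    "combine_and_normalize",
    "compute_climate_scalars",
]

logger = logging.getLogger(__name__)

#: Universal gas constant, J mol^-1 K^-1.
R_GAS = 8.314

#: Default activation energy (kJ mol^-1), the average measured on bare-fallow
#: soils; close to the classic soil-respiration value of 53 kJ mol^-1.
DEFAULT_EA_KJ = 59.46

#: Temperature (deg C) above which the response is clamped to 1.
DEFAULT_T_CAP = 35.14

#: Saturation fraction at which the default moisture curve peaks.
DEFAULT_S_OPT = 0.65

#: Empirical scaling of Penman-Monteith PET calibrated on the Rothamsted
#: bare fallow.
DEFAULT_PET_SCALE = 0.9


@dataclass(frozen=True)
class WeatherYear:
    """One year of annual-average weather for a site."""

    year: int
    tmean: float  # deg C
    precip: float  # mm
    pet_inputs: Mapping[str, float] | None = None

    def __post_init__(self) -> None:
        if self.precip < 0:
            raise ValueError(f"precip must be >= 0, got {self.precip}")


@dataclass(frozen=True)
class ClimateScalars:
    """Per-site summary of the climate reduction terms."""

    site_id: str
    re_temp: float
    r_moist: float
    re_raw: float
    re_norm: float


def temperature_response(
    tmean: float | np.ndarray,
    ea_kj: float = DEFAULT_EA_KJ,
    t_cap: float = DEFAULT_T_CAP,
    form: str = "arrhenius",
) -> float | np.ndarray:
    """Temperature reduction function in [0, 1].

    ``form="arrhenius"`` (default): ``exp(-(Ea/R) * (1/T - 1/T_cap))`` with
    temperatures in kelvin, clamped to 1 above the cap.  ``form="lloyd_taylor"``
    uses the classic soil-respiration parameterisation
    ``exp(308.56 * (1/56.02 - 1/(T + 273.15 - 227.13)))`` normalised to 1 at
    the same cap.  Both are continuous at the cap and monotone below it.
    """
    if ea_kj <= 0:
        raise ValueError(f"activation energy must be positive, got {ea_kj}")
    t = np.asarray(tmean, dtype=float)
    if np.any(t <= -273.15):
        raise ValueError("temperature below absolute zero")
    if form == "arrhenius":
        c = ea_kj * 1000.0 / R_GAS
        out = np.exp(-c * (1.0 / (t + 273.15) - 1.0 / (t_cap + 273.15)))
    elif form == "lloyd_taylor":
        def lt(x: np.ndarray) -> np.ndarray:
            return np.exp(308.56 * (1.0 / 56.02 - 1.0 / (x + 273.15 - 227.13)))

        out = lt(t) / lt(np.asarray(t_cap, dtype=float))
    else:
        raise ValueError(f"unknown temperature response form {form!r}")
    out = np.minimum(out, 1.0)
    return out if out.ndim else float(out)


def default_moisture_curve(
    saturation: np.ndarray,
    s_opt: float = DEFAULT_S_OPT,
    shape: float = 1.3,
    wet_floor: float = 0.6,
) -> np.ndarray:
    """Unimodal saturation response: 0 when dry, 1 at the optimum ``s_opt``.

    Below the optimum the response rises as ``(s/s_opt)**shape`` (moisture
    limitation); above it, oxygen limitation reduces it linearly down to
    ``wet_floor`` at full saturation.  This is a documented, pluggable
    default standing in for laboratory-derived saturation responses whose
    coefficient tables are external to this package.
    """
    s = np.asarray(saturation, dtype=float)
    rising = (s / s_opt) ** shape
    falling = 1.0 - (1.0 - wet_floor) * (s - s_opt) / (1.0 - s_opt)
    return np.where(s <= s_opt, rising, falling)


def moisture_response(
    saturation: float | np.ndarray,
    curve: Callable[[np.ndarray], np.ndarray] | None = None,
) -> float | np.ndarray:
    """Moisture reduction function in [0, 1] of the saturation fraction."""
    s = np.asarray(saturation, dtype=float)
    if np.any((s < 0) | (s > 1)):
        raise ValueError("saturation fraction must lie in [0, 1]")
    out = np.clip((curve or default_moisture_curve)(s), 0.0, 1.0)
    return out if out.ndim else float(out)


def _svp_kpa(t: np.ndarray) -> np.ndarray:
    """Saturation vapour pressure (kPa) at air temperature t (deg C)."""
    return 0.6108 * np.exp(17.27 * t / (t + 237.3))


def potential_evapotranspiration(
    pet_inputs: Mapping[str, float | np.ndarray],
    scale: float = DEFAULT_PET_SCALE,
) -> float | np.ndarray:
    """Annual potential evapotranspiration (mm) from annual-mean drivers.

    Uses the Penman-Monteith reference-crop formulation on annual averages
    (net radiation ``rad`` in MJ m-2 day-1, relative humidity ``rh`` in
    [0, 1], wind speed ``wind`` in m s-1 at 2 m, mean temperature
    ``tmean_c``), multiplied by 365 days and by the empirical ``scale``.

    When radiation/humidity/wind are missing the function falls back to the
    Holdridge biotemperature rule ``58.93 mm * max(tmean, 0)`` with a logged
    warning — a coarse but standard annual approximation.
    """
    t = np.asarray(pet_inputs["tmean_c"], dtype=float)
    needed = ("rad", "rh", "wind")
    if not all(k in pet_inputs and pet_inputs[k] is not None for k in needed):
        logger.warning(
            "PET inputs incomplete (need %s); falling back to the "
            "temperature-based Holdridge approximation",
            needed,
        )
        out = scale * 58.93 * np.maximum(t, 0.0)
        return out if out.ndim else float(out)
    rad = np.asarray(pet_inputs["rad"], dtype=float)
    rh = np.asarray(pet_inputs["rh"], dtype=float)
    wind = np.asarray(pet_inputs["wind"], dtype=float)
    if np.any(rad < 0) or np.any((rh < 0) | (rh > 1)):
        raise ValueError("rad must be >= 0 and rh in [0, 1]")
    gamma = 0.0665  # psychrometric constant, kPa/degC, sea level
    es = _svp_kpa(t)
    ea = rh * es
    delta = 4098.0 * es / (t + 237.3) ** 2
    et0_daily = (
        0.408 * delta * rad + gamma * (900.0 / (t + 273.0)) * wind * (es - ea)
    ) / (delta + gamma * (1.0 + 0.34 * wind))
    out = scale * 365.0 * np.maximum(et0_daily, 0.0)
    return out if out.ndim else float(out)


def whc_from_texture(
    clay_percent: float,
    silt_percent: float,
    sand_percent: float,
    depth_cm: float,
    coeffs: tuple[float, float, float] = (0.20, 0.25, 0.06),
) -> float:
    """Plant-available water-holding capacity (mm) from texture.

    A linear pedotransfer rule: the available volumetric water fraction is a
    texture-weighted sum ``(a*clay + b*silt + c*sand)/100`` with default
    coefficients typical of temperate mineral soils, times soil depth.
    """
    if depth_cm <= 0:
        raise ValueError(f"depth must be positive, got {depth_cm}")
    a, b, c = coeffs
    theta = (a * clay_percent + b * silt_percent + c * sand_percent) / 100.0
    return theta * depth_cm * 10.0  # 10 mm of water per cm of soil per unit theta


def water_balance(
    precip: np.ndarray,
    pet: np.ndarray,
    whc: float,
    store0: float | None = None,
) -> pd.DataFrame:
    """Annual single-bucket soil water balance.

    Each year the bucket receives precipitation; actual evapotranspiration is
    the potential demand throttled by bucket fullness,
    ``aet = min(pet, pet * (store + precip)/whc)``, and water beyond capacity
    drains.  Returns a DataFrame with columns ``store`` (end-of-year, mm),
    ``aet``, ``drainage`` and ``saturation`` (= store/whc in [0, 1]).  The
    identity ``precip = aet + drainage + delta_store`` holds every year.

    The store starts full by default (``store0 = whc``), the usual state of a
    temperate soil at the end of winter recharge.
    """
    if whc <= 0:
        raise ValueError(f"water-holding capacity must be positive, got {whc}")
    precip = np.asarray(precip, dtype=float)
    pet = np.asarray(pet, dtype=float)
    if precip.shape != pet.shape:
        raise ValueError("precip and pet series must be aligned")
    store = whc if store0 is None else float(np.clip(store0, 0.0, whc))
    rows = []
    for p, e in zip(precip, pet):
        avail = store + p
        aet = min(e, e * avail / whc, avail)
        remaining = avail - aet
        drainage = max(0.0, remaining - whc)
        new_store = min(max(remaining - drainage, 0.0), whc)
        rows.append((new_store, aet, drainage, new_store / whc))
        store = new_store
    return pd.DataFrame(rows, columns=["store", "aet", "drainage", "saturation"])


def combine_and_normalize(per_year: pd.DataFrame) -> pd.DataFrame:
    """Combine temperature and moisture terms and normalise across sites.

    ``per_year`` must hold columns ``site_id``, ``year``, ``re_temp`` and
    ``r_moist``.  Adds ``re_raw = re_temp * r_moist`` per site-year, averages
    it over years within each site, and divides by the grand mean over sites
    so that the across-site mean of ``re_norm`` is exactly one.  The
    site-level ``re_norm`` is broadcast back onto every row.
    """
    out = per_year.copy()
    out["re_raw"] = out["re_temp"] * out["r_moist"]
    site_mean = out.groupby("site_id")["re_raw"].mean()
    grand = site_mean.mean()
    if not np.isfinite(grand) or grand <= 0:
        raise ValueError("cannot normalise: mean climate scalar is not positive")
    re_norm = site_mean / grand
    out["re_norm"] = out["site_id"].map(re_norm)
    return out


def compute_climate_scalars(
    weather: pd.DataFrame,
    sites: pd.DataFrame,
    pet_scale: float = DEFAULT_PET_SCALE,
    curve: Callable[[np.ndarray], np.ndarray] | None = None,
    temperature_form: str = "arrhenius",
) -> pd.DataFrame:
    """Full weather -> climate-scalar pipeline for a network of sites.

    ``weather`` columns: ``site_id, year, tmean_c, precip_mm`` and optional
    ``rad, rh, wind``.  ``sites`` columns: ``site_id, clay_percent,
    silt_percent, sand_percent, depth_cm``.  Returns one row per site-year
    with ``re_temp, r_moist, re_raw, re_norm``.
    """
    frames = []
    for site_id, grp in weather.groupby("site_id", sort=True):
        grp = grp.sort_values("year")
        meta = sites.loc[sites["site_id"] == site_id]
        if meta.empty:
            raise KeyError(f"no site metadata for {site_id!r}")
        meta = meta.iloc[0]
        whc = whc_from_texture(
            meta["clay_percent"],
            meta["silt_percent"],
            meta["sand_percent"],
            meta["depth_cm"],
        )
        pet_inputs = {"tmean_c": grp["tmean_c"].to_numpy()}
        for k in ("rad", "rh", "wind"):
            if k in grp.columns and grp[k].notna().all():
                pet_inputs[k] = grp[k].to_numpy()
        pet = potential_evapotranspiration(pet_inputs, scale=pet_scale)
        wb = water_balance(grp["precip_mm"].to_numpy(), np.asarray(pet), whc)
        frames.append(
            pd.DataFrame(
                {
                    "site_id": site_id,
                    "year": grp["year"].to_numpy(),
                    "re_temp": np.asarray(
                        temperature_response(
                            grp["tmean_c"].to_numpy(), form=temperature_form
                        )
                    ),
                    "r_moist": np.asarray(
                        moisture_response(wb["saturation"].to_numpy(), curve=curve)
                    ),
                }
            )
        )
    return combine_and_normalize(pd.concat(frames, ignore_index=True))
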