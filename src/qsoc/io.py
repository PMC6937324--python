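"""CSV/JSON/YAML schemas shared by the CLI, the analysis drivers and tests.

Schemas (all plain CSV):

* sites: ``site_id, clay_percent, silt_percent, sand_percent, depth_cm,
  css, start_year, end_year``
* observations: ``site_id, year, soc_stock_mg_ha, sd_mg_ha`` and optional
  ``plant_fraction``
* weather: ``site_id, year, tmean_c, precip_mm`` and optional
  ``rad, rh, wind``
* climate scalars: ``site_id, year, re_temp, r_moist, re_raw, re_norm``
* posterior: one row per chain element (``chain, iteration``, parameters,
  ``log_post``, per-site ``rmse[...]`` columns)

Synthetic and user-supplied data are interchangeable through these files.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .calibrate import ObservationSeries, PosteriorChain, SiteDataset
from .synthetic import SiteProfile

__all__ = [
    "write_network",
    "read_sites",
    "read_observations",
    "load_site_datasets",
    "write_posterior",
    "read_posterior_summary",
    "load_config",
]


def write_network(
    profiles: Sequence[SiteProfile],
    datasets: Sequence[SiteDataset],
    weather: pd.DataFrame | None,
    outdir: str | Path,
) -> dict[str, Path]:
    """Write sites/observations/weather CSVs for a (synthetic) network."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    sites = pd.DataFrame(
        [
            {
                "site_id": p.site_id,
                "clay_percent": p.clay_percent,
                "silt_percent": p.silt_percent,
                "sand_percent": p.sand_percent,
                "depth_cm": p.depth_cm,
                "css": p.css,
                "start_year": p.start_year,
                "end_year": p.end_year,
            }
            for p in profiles
        ]
    )
    paths["sites"] = outdir / "sites.csv"
    sites.to_csv(paths["sites"], index=False)
    rows = []
    for ds in datasets:
        obs = ds.observations
        pf = dict(zip(obs.pf_times, obs.pf_values)) if obs.pf_times is not None else {}
        for t, y in zip(obs.times, obs.soc):
            rows.append(
                {
                    "site_id": ds.site_id,
                    "year": t,
                    "soc_stock_mg_ha": y,
                    "sd_mg_ha": obs.sd,
                    "plant_fraction": pf.get(t, np.nan),
                }
            )
    paths["observations"] = outdir / "observations.csv"
    pd.DataFrame(rows).to_csv(paths["observations"], index=False)
    if weather is not None:
        paths["weather"] = outdir / "weather.csv"
        weather.to_csv(paths["weather"], index=False)
    return paths


def read_sites(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def read_observations(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def load_site_datasets(
    sites_path: str | Path,
    observations_path: str | Path,
    climate_path: str | Path | None = None,
) -> list[SiteDataset]:
    """Assemble :class:`SiteDataset` objects from the CSV schemas.

    When a climate-scalar CSV is given, each site's ``re`` is its
    ``re_norm``; otherwise ``re = 1`` (climate-neutral calibration).
    """
    sites = pd.read_csv(sites_path)
    obs = pd.read_csv(observations_path)
    re_by_site = {}
    if climate_path is not None:
        climate = pd.read_csv(climate_path)
        re_by_site = climate.groupby("site_id")["re_norm"].first().to_dict()
    datasets = []
    for rec in sites.itertuples(index=False):
        grp = obs[obs["site_id"] == rec.site_id].sort_values("year")
        if grp.empty:
            raise ValueError(f"no observations for site {rec.site_id!r}")
        pf_times = pf_values = None
        if "plant_fraction" in grp.columns and grp["plant_fraction"].notna().any():
            mask = grp["plant_fraction"].notna()
            pf_times = grp.loc[mask, "year"].to_numpy(float)
            pf_values = grp.loc[mask, "plant_fraction"].to_numpy(float)
        series = ObservationSeries(
            times=grp["year"].to_numpy(float),
            soc=grp["soc_stock_mg_ha"].to_numpy(float),
            sd=float(grp["sd_mg_ha"].mean()),
            pf_times=pf_times,
            pf_values=pf_values,
        )
        datasets.append(
            SiteDataset(
                site_id=rec.site_id,
                clay_percent=float(rec.clay_percent),
                css=float(rec.css),
                re=float(re_by_site.get(rec.site_id, 1.0)),
                observations=series,
            )
        )
    return datasets


def write_posterior(
    chains: Sequence[PosteriorChain],
    csv_path: str | Path,
    summary_path: str | Path | None = None,
) -> None:
    """Write the flattened chain CSV and an optional JSON summary."""
    from .calibrate import posterior_dataframe, summarize_posterior

    posterior_dataframe(chains).to_csv(csv_path, index=False)
    if summary_path is not None:
        summary = summarize_posterior(chains)
        payload = {
            name: {
                "median": row["median"],
                "ci_lower": row["ci_lower"],
                "ci_upper": row["ci_upper"],
                "rhat": None if np.isnan(row["rhat"]) else row["rhat"],
            }
            for name, row in summary.iterrows()
        }
        Path(summary_path).write_text(json.dumps(payload, indent=2))


def read_posterior_summary(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())


def load_config(path: str | Path | None) -> dict:
    """Load a JSON or YAML config file (empty dict when no path given)."""
    if path is None:
        return {}
    text = Path(path).read_text()
    if str(path).endswith(".json"):
        return json.loads(text)
    return yaml.safe_load(text) or {}
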