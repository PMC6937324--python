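"""Long-horizon SOC projections and fit reports from a calibrated chain.

Projections push every retained posterior draw through the closed-form
stock equation at multi-century horizons, using the site's long-term mean
normalised climate scalar, and report empirical medians and 95 % credible
intervals.  Because the model has no inert pool, projected stocks decline
continuously at every horizon — they never flatten onto a floor.

Fit reports summarise how the chain describes the observed series: the
best-RMSE trajectory, the envelope of trajectories within the 95 % RMSE
quantile, and RMSE summaries (mode, mean, percent of the final stock).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .calibrate import PosteriorChain, SiteDataset, posterior_dataframe
from .model import effective_beta, plant_fraction, soc_stock

__all__ = ["project_stocks", "report_fit", "FitReport"]

DEFAULT_HORIZONS = (300, 1000, 3000)
DEFAULT_THIN = 10


def _site_draws(
    chains: Sequence[PosteriorChain], site_id: str, thin: int
) -> pd.DataFrame:
    """Post-burn-in draws of the parameters relevant to one site."""
    df = posterior_dataframe(chains)
    df = df[df["iteration"] >= chains[0].burn_in]
    df = df.iloc[::thin].reset_index(drop=True)
    cols = {"u0": df["u0"], "eta11": df["eta11"]}
    for p in ("q0", "e0", "beta0"):
        key = f"{p}[{site_id}]"
        cols[p] = df[key] if key in df.columns else df[p]
    if f"rmse[{site_id}]" in df.columns:
        cols["rmse"] = df[f"rmse[{site_id}]"]
    return pd.DataFrame(cols)


def project_stocks(
    chains: Sequence[PosteriorChain],
    site_id: str,
    css: float,
    clay_percent: float,
    re_clim: float,
    horizons: Sequence[float] = DEFAULT_HORIZONS,
    thin: int = DEFAULT_THIN,
    ci: float = 0.95,
) -> pd.DataFrame:
    """Median and credible interval of the SOC stock at each horizon.

    Every (thinned) post-burn-in draw is evaluated at each horizon with the
    site's constant mean normalised climate scalar ``re_clim``; quantiles
    are empirical percentiles over draws.  Returns one row per horizon with
    ``median, ci_lower, ci_upper`` (Mg C/ha).
    """
    horizons = np.asarray(horizons, dtype=float)
    if np.any(horizons < 0):
        raise ValueError("horizons must be non-negative")
    draws = _site_draws(chains, site_id, thin)
    if len(draws) < 1:
        raise ValueError("no posterior draws available")
    alpha = (1.0 - ci) / 2.0
    stocks = np.empty((len(draws), horizons.size))
    for i, row in enumerate(draws.itertuples(index=False)):
        beta = effective_beta(row.beta0, clay_percent)
        stocks[i] = soc_stock(
            horizons, css, row.q0, beta, row.eta11, row.u0, row.e0, re_clim
        )
    return pd.DataFrame(
        {
            "site_id": site_id,
            "horizon": horizons,
            "median": np.median(stocks, axis=0),
            "ci_lower": np.quantile(stocks, alpha, axis=0),
            "ci_upper": np.quantile(stocks, 1.0 - alpha, axis=0),
        }
    )


@dataclass(frozen=True)
class FitReport:
    """Trajectory-level summary of a calibrated site."""

    site_id: str
    times: np.ndarray
    best: np.ndarray  # trajectory of the minimum-RMSE draw
    env_lower: np.ndarray  # envelope of draws within the 95 % RMSE quantile
    env_upper: np.ndarray
    pf_best: np.ndarray | None
    rmse_best: float
    rmse_mode: float
    rmse_mean: float
    rmse_percent_final: float  # RMSE as percent of the final observed stock

    def to_frame(self) -> pd.DataFrame:
        out = pd.DataFrame(
            {
                "time": self.times,
                "best": self.best,
                "env_lower": self.env_lower,
                "env_upper": self.env_upper,
            }
        )
        if self.pf_best is not None:
            out["pf_best"] = self.pf_best
        return out


def _distribution_mode(values: np.ndarray) -> float:
    """Mode of a continuous sample via a Freedman-Diaconis histogram."""
    values = np.asarray(values, dtype=float)
    iqr = np.subtract(*np.percentile(values, [75, 25]))
    width = 2.0 * iqr / max(1.0, values.size ** (1.0 / 3.0))
    if width <= 0:
        return float(np.median(values))
    bins = max(1, int(np.ceil((values.max() - values.min()) / width)))
    hist, edges = np.histogram(values, bins=bins)
    j = int(np.argmax(hist))
    return float(0.5 * (edges[j] + edges[j + 1]))


def report_fit(
    chains: Sequence[PosteriorChain],
    site: SiteDataset,
    thin: int = DEFAULT_THIN,
    rmse_quantile: float = 0.95,
    n_time: int = 101,
) -> FitReport:
    """Best-fit trajectory, 95 %-RMSE envelope and RMSE summaries for a site."""
    draws = _site_draws(chains, site.site_id, thin)
    if "rmse" not in draws.columns:
        raise ValueError("chains carry no RMSE track for this site")
    times = np.linspace(0.0, float(site.observations.times[-1]), n_time)
    rmse_vals = draws["rmse"].to_numpy()
    keep = rmse_vals <= np.quantile(rmse_vals, rmse_quantile)
    trajectories = np.empty((int(keep.sum()), times.size))
    k = 0
    best_i = int(np.argmin(rmse_vals))
    best_traj = None
    pf_best = None
    for i, row in enumerate(draws.itertuples(index=False)):
        beta = effective_beta(row.beta0, site.clay_percent)
        if keep[i]:
            trajectories[k] = soc_stock(
                times, site.css, row.q0, beta, row.eta11, row.u0, row.e0, site.re
            )
            k += 1
        if i == best_i:
            best_traj = soc_stock(
                times, site.css, row.q0, beta, row.eta11, row.u0, row.e0, site.re
            )
            pf_best = plant_fraction(
                times, row.q0, beta, row.e0, row.u0, site.re
            )
    final_stock = float(site.observations.soc[-1])
    rmse_mean = float(rmse_vals.mean())
    return FitReport(
        site_id=site.site_id,
        times=times,
        best=np.asarray(best_traj),
        env_lower=trajectories.min(axis=0),
        env_upper=trajectories.max(axis=0),
        pf_best=np.asarray(pf_best) if pf_best is not None else None,
        rmse_best=float(rmse_vals[best_i]),
        rmse_mode=_distribution_mode(rmse_vals),
        rmse_mean=rmse_mean,
        rmse_percent_final=100.0 * rmse_mean / final_stock,
    )
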