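"""Hierarchical Bayesian calibration of the Q model on multi-site data.

The calibration treats the kinetic parameters ``u0`` and ``eta11`` as
*generic* (one value shared by every site) and ``q0``, ``e0`` and ``beta0``
as *local* (one value per site).  The error model is Gaussian and
independent, with one error standard deviation per observation series (the
average of the replicate standard deviations); SOC-stock and plant-fraction
series enter the likelihood simultaneously.  Irregular SOC series are
linearly interpolated to annual resolution before fitting.

Sampling is a seeded, blocked random-walk Metropolis-Hastings scheme:
the generic pair is proposed jointly against the pooled likelihood, each
site's local triple jointly against its own site, and one full-vector
proposal per sweep captures cross-block correlation.  Proposal covariances
and scales adapt during burn-in only (targeting 20-40 % acceptance) and are
frozen afterwards, so the retained draws come from a fixed kernel.
Convergence is monitored with the Gelman-Rubin potential-scale-reduction
statistic across independent chains.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .model import GenericKinetics, LocalParams
from .priors import PriorSpec, build_priors

__all__ = [
    "ObservationSeries",
    "SiteDataset",
    "ParameterSet",
    "MCMCConfig",
    "PosteriorChain",
    "interpolate_annual",
    "log_likelihood",
    "rmse",
    "run_mcmc",
    "gelman_rubin",
    "summarize_posterior",
    "posterior_dataframe",
]

_LOG_SQRT_2PI = 0.5 * math.log(2.0 * math.pi)
LOCAL_NAMES = ("q0", "e0", "beta0")


@dataclass(frozen=True)
class ObservationSeries:
    """Irregular observations of one site.

    ``times`` are years since the start of the fallow; ``soc`` the measured
    SOC stocks (Mg C/ha); ``sd`` the series error (average replicate
    standard deviation).  Plant-fraction observations (fraction of the
    initial plant-derived carbon remaining) are optional.
    """

    times: np.ndarray
    soc: np.ndarray
    sd: float
    pf_times: np.ndarray | None = None
    pf_values: np.ndarray | None = None
    pf_sd: float | None = None

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        soc = np.asarray(self.soc, dtype=float)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "soc", soc)
        if times.size != soc.size:
            raise ValueError("times and soc must have equal length")
        if times.size and times[0] < 0:
            raise ValueError("observation times must be non-negative")
        if np.any(np.diff(times) <= 0):
            raise ValueError("observation times must be strictly increasing")
        if not self.sd > 0:
            raise ValueError(f"series sd must be positive, got {self.sd}")
        if self.pf_times is not None:
            object.__setattr__(
                self, "pf_times", np.asarray(self.pf_times, dtype=float)
            )
            object.__setattr__(
                self, "pf_values", np.asarray(self.pf_values, dtype=float)
            )
            if self.pf_sd is None:
                # fallback: 10 % of the initial fraction
                object.__setattr__(
                    self, "pf_sd", 0.1 * float(self.pf_values[0])
                )


def interpolate_annual(
    times: np.ndarray, values: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Linearly interpolate an irregular series to annual resolution.

    Output abscissae are the integer years between the first and last
    observation, with the (possibly non-integer) endpoints preserved exactly.
    """
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    if times.size < 2:
        raise ValueError("need at least two observations to interpolate")
    grid = np.arange(math.ceil(times[0]), math.floor(times[-1]) + 1, dtype=float)
    grid = np.unique(np.concatenate(([times[0]], grid, [times[-1]])))
    return grid, np.interp(grid, times, values)


@dataclass(frozen=True)
class SiteDataset:
    """Everything the likelihood needs to know about one site."""

    site_id: str
    clay_percent: float
    css: float
    re: float
    observations: ObservationSeries

    def annualized(self) -> tuple[np.ndarray, np.ndarray]:
        return interpolate_annual(self.observations.times, self.observations.soc)


@dataclass(frozen=True)
class ParameterSet:
    """One full draw: shared generic kinetics plus per-site locals."""

    generic: GenericKinetics
    locals: Mapping[str, LocalParams]


@dataclass(frozen=True)
class MCMCConfig:
    n_chains: int = 4
    n_iter: int = 100_000
    burn_in: int = 10_000
    seed: int | None = None
    target_accept: float = 0.3
    adapt_interval: int = 100
    joint_block: bool = True
    joint_updates: int = 3
    share_locals: bool = False
    flat_likelihood: bool = False
    rate_convention: str = "eq4_consistent"
    use_raw_times: bool = False
    init_max_tries: int = 1000


@dataclass
class PosteriorChain:
    """One chain of the sampler: draws plus per-element diagnostics."""

    chain_id: int
    param_names: tuple[str, ...]
    site_ids: tuple[str, ...]
    draws: np.ndarray  # (n_iter, n_params)
    log_post: np.ndarray  # (n_iter,)
    rmse: np.ndarray  # (n_iter, n_sites)
    burn_in: int

    def __len__(self) -> int:
        return self.draws.shape[0]

    def post_burn(self) -> np.ndarray:
        return self.draws[self.burn_in :]

    def parameter(self, name: str, post_burn: bool = True) -> np.ndarray:
        j = self.param_names.index(name)
        col = self.draws[:, j]
        return col[self.burn_in :] if post_burn else col


# ---------------------------------------------------------------------------
# likelihood internals

@dataclass(frozen=True)
class _SiteData:
    """Pre-extracted arrays for fast repeated likelihood evaluation."""

    t_soc: np.ndarray
    y_soc: np.ndarray
    sd_soc: float
    t_rmse: np.ndarray
    y_rmse: np.ndarray
    t_pf: np.ndarray | None
    y_pf: np.ndarray | None
    sd_pf: float | None
    clay: float
    css: float
    re: float


def _prepare_site(site: SiteDataset, use_raw_times: bool) -> _SiteData:
    obs = site.observations
    ta, ya = interpolate_annual(obs.times, obs.soc)
    t_soc, y_soc = (obs.times, obs.soc) if use_raw_times else (ta, ya)
    return _SiteData(
        t_soc=t_soc,
        y_soc=y_soc,
        sd_soc=float(obs.sd),
        t_rmse=ta,
        y_rmse=ya,
        t_pf=obs.pf_times,
        y_pf=obs.pf_values,
        sd_pf=None if obs.pf_sd is None else float(obs.pf_sd),
        clay=float(site.clay_percent),
        css=float(site.css),
        re=float(site.re),
    )


def _site_loglik_rmse(
    u0: float,
    eta11: float,
    q0: float,
    e0: float,
    beta0: float,
    sd: _SiteData,
    rate_convention: str = "eq4_consistent",
) -> tuple[float, float]:
    """Gaussian log likelihood and annualised RMSE of one site.

    Invalid parameter combinations yield ``(-inf, inf)`` — rejected, never
    raised, so the sampler can treat them as zero-probability.
    """
    if not (u0 > 0 and eta11 > 0 and q0 > 0 and 0 < e0 < 1 and beta0 > 0):
        return -math.inf, math.inf
    beta = beta0 + 0.01 * sd.clay
    expo = (1.0 - e0) / (eta11 * e0) - beta
    if expo <= 0 or (1.0 - e0 - eta11 * e0 * beta) <= 0:
        return -math.inf, math.inf
    q0b = q0**beta
    rate = eta11 * u0 * sd.re * q0b
    # stock residuals on the likelihood series
    ratio = (1.0 + beta * rate * sd.t_soc) ** (-expo / beta)
    resid = sd.css * ratio - sd.y_soc
    ll = -resid.size * (math.log(sd.sd_soc) + _LOG_SQRT_2PI) - 0.5 * float(
        resid @ resid
    ) / (sd.sd_soc * sd.sd_soc)
    # RMSE always on the annualised series
    if sd.t_soc is sd.t_rmse:
        rms = math.sqrt(float(resid @ resid) / resid.size)
    else:
        ratio_a = (1.0 + beta * rate * sd.t_rmse) ** (-expo / beta)
        ra = sd.css * ratio_a - sd.y_rmse
        rms = math.sqrt(float(ra @ ra) / ra.size)
    if sd.t_pf is not None:
        if rate_convention == "eq4_consistent":
            k = u0 * sd.re * q0b / e0
        else:
            k = e0 / (u0 * sd.re * q0b)
        rp = np.exp(-k * sd.t_pf) - sd.y_pf
        ll += -rp.size * (math.log(sd.sd_pf) + _LOG_SQRT_2PI) - 0.5 * float(
            rp @ rp
        ) / (sd.sd_pf * sd.sd_pf)
    return ll, rms


def log_likelihood(
    params: ParameterSet,
    sites: Sequence[SiteDataset],
    rate_convention: str = "eq4_consistent",
    use_raw_times: bool = False,
) -> float:
    """Pooled Gaussian log likelihood over sites and both observables.

    Returns ``-inf`` (rather than raising) for invalid parameter sets.
    """
    total = 0.0
    for site in sites:
        lp = params.locals[site.site_id]
        ll, _ = _site_loglik_rmse(
            params.generic.u0,
            params.generic.eta11,
            lp.q0,
            lp.e0,
            lp.beta0,
            _prepare_site(site, use_raw_times),
            rate_convention,
        )
        if ll == -math.inf:
            return -math.inf
        total += ll
    return total


def rmse(params: ParameterSet, site: SiteDataset) -> float:
    """Root-mean-square SOC-stock error over the site's annualised series."""
    if site.observations.times.size == 0:
        raise ValueError("empty observation series")
    lp = params.locals[site.site_id]
    _, rms = _site_loglik_rmse(
        params.generic.u0,
        params.generic.eta11,
        lp.q0,
        lp.e0,
        lp.beta0,
        _prepare_site(site, use_raw_times=False),
    )
    return rms


# ---------------------------------------------------------------------------
# sampler

def _param_layout(
    site_ids: Sequence[str], share_locals: bool
) -> tuple[tuple[str, ...], list[str]]:
    """Names of the sampled vector and the prior key of each entry."""
    names: list[str] = ["u0", "eta11"]
    prior_keys: list[str] = ["u0", "eta11"]
    if share_locals:
        names += list(LOCAL_NAMES)
        prior_keys += list(LOCAL_NAMES)
    else:
        for sid in site_ids:
            names += [f"{p}[{sid}]" for p in LOCAL_NAMES]
            prior_keys += list(LOCAL_NAMES)
    return tuple(names), prior_keys


def _run_single_chain(
    chain_id: int,
    rng: np.random.Generator,
    site_data: list[_SiteData],
    site_ids: tuple[str, ...],
    priors: dict[str, PriorSpec],
    cfg: MCMCConfig,
) -> PosteriorChain:
    n_sites = len(site_data)
    names, prior_keys = _param_layout(site_ids, cfg.share_locals)
    p = len(names)
    prior_by_idx = [priors[k] for k in prior_keys]
    prior_sd = np.array([pr.sd for pr in prior_by_idx])

    def local_slice(s: int) -> np.ndarray:
        if cfg.share_locals:
            return np.arange(2, 5)
        return np.arange(2 + 3 * s, 5 + 3 * s)

    def eval_site(theta: np.ndarray, s: int) -> tuple[float, float]:
        if cfg.flat_likelihood:
            return 0.0, 0.0
        q0, e0, beta0 = theta[local_slice(s)]
        return _site_loglik_rmse(
            theta[0], theta[1], q0, e0, beta0, site_data[s], cfg.rate_convention
        )

    # blocks: (indices, affected site list or None for all)
    blocks: list[tuple[np.ndarray, list[int] | None]] = [
        (np.array([0, 1]), None)
    ]
    if cfg.share_locals:
        blocks.append((np.arange(2, 5), None))
    else:
        for s in range(n_sites):
            blocks.append((local_slice(s), [s]))
    if cfg.joint_block:
        # several full-vector updates per sweep: they carry the global
        # cross-block correlations (e.g. eta11 with every site's e0)
        for _ in range(max(1, cfg.joint_updates)):
            blocks.append((np.arange(p), None))
    n_blocks = len(blocks)
    total_dim = sum(len(idx) for idx, _ in blocks)

    # initialisation: independent prior draw, rejection-resampled to validity
    theta = None
    for _ in range(cfg.init_max_tries):
        cand = np.array([pr.sample(rng) for pr in prior_by_idx])
        if cfg.flat_likelihood or all(
            eval_site(cand, s)[0] > -math.inf for s in range(n_sites)
        ):
            theta = cand
            break
    if theta is None:
        raise RuntimeError(
            "could not initialise chain: likelihood is -inf at every prior "
            f"draw after {cfg.init_max_tries} tries; check data and priors"
        )

    site_ll = np.empty(n_sites)
    site_rmse = np.empty(n_sites)
    for s in range(n_sites):
        site_ll[s], site_rmse[s] = eval_site(theta, s)
    log_prior = sum(pr.logpdf(v) for pr, v in zip(prior_by_idx, theta))

    # proposal state
    log_s = np.zeros(n_blocks)
    chols = [np.diag(0.1 * prior_sd[idx]) for idx, _ in blocks]
    acc = np.zeros(n_blocks)
    # Welford accumulators for the empirical covariance (burn-in only)
    count = 0
    mean = np.zeros(p)
    m2 = np.zeros((p, p))

    draws = np.empty((cfg.n_iter, p))
    log_post = np.empty(cfg.n_iter)
    rmse_track = np.empty((cfg.n_iter, n_sites))

    for i in range(cfg.n_iter):
        z = rng.standard_normal(total_dim)
        uu = rng.random(n_blocks)
        off = 0
        for b, (idx, aff) in enumerate(blocks):
            d = idx.size
            step = chols[b] @ z[off : off + d]
            off += d
            new_vals = theta[idx] + step
            lp_new = 0.0
            for j, v in zip(idx, new_vals):
                lp_new += prior_by_idx[j].logpdf(v)
            if lp_new == -math.inf:
                continue
            lp_old = 0.0
            for j in idx:
                lp_old += prior_by_idx[j].logpdf(theta[j])
            theta_prop = theta.copy()
            theta_prop[idx] = new_vals
            delta = lp_new - lp_old
            if cfg.flat_likelihood:
                new_ll = new_rms = None
                sites_touched: list[int] = []
            else:
                sites_touched = aff if aff is not None else list(range(n_sites))
                new_ll = np.empty(len(sites_touched))
                new_rms = np.empty(len(sites_touched))
                ok = True
                for k, s in enumerate(sites_touched):
                    new_ll[k], new_rms[k] = eval_site(theta_prop, s)
                    if new_ll[k] == -math.inf:
                        ok = False
                        break
                if not ok:
                    continue
                delta += float(new_ll.sum()) - float(site_ll[sites_touched].sum())
            if math.log(uu[b]) < delta:
                theta = theta_prop
                log_prior += lp_new - lp_old
                for k, s in enumerate(sites_touched):
                    site_ll[s] = new_ll[k]
                    site_rmse[s] = new_rms[k]
                acc[b] += 1
        draws[i] = theta
        log_post[i] = log_prior + float(site_ll.sum())
        rmse_track[i] = site_rmse

        if i < cfg.burn_in:
            if i == cfg.burn_in // 2:
                # drop the initial transient from the covariance estimate
                count = 0
                mean[:] = 0.0
                m2[:] = 0.0
            count += 1
            delta_v = theta - mean
            mean += delta_v / count
            m2 += np.outer(delta_v, theta - mean)
            if (i + 1) % cfg.adapt_interval == 0:
                batch = (i + 1) // cfg.adapt_interval
                gain = min(1.0, 2.0 / math.sqrt(batch))
                rates = acc / cfg.adapt_interval
                log_s += gain * (rates - cfg.target_accept)
                acc[:] = 0.0
                if count > 10 * max(len(idx) for idx, _ in blocks):
                    cov = m2 / (count - 1)
                    for b, (idx, _) in enumerate(blocks):
                        d = idx.size
                        sub = cov[np.ix_(idx, idx)] + 1e-10 * np.diag(
                            prior_sd[idx] ** 2
                        )
                        scaled = (
                            math.exp(2.0 * log_s[b]) * (2.38**2 / d)
                        ) * sub
                        try:
                            chols[b] = np.linalg.cholesky(scaled)
                        except np.linalg.LinAlgError:
                            chols[b] = np.diag(
                                math.exp(log_s[b]) * 0.1 * prior_sd[idx]
                            )
        elif i == cfg.burn_in:
            acc[:] = 0.0  # frozen kernel from here on

    return PosteriorChain(
        chain_id=chain_id,
        param_names=names,
        site_ids=site_ids,
        draws=draws,
        log_post=log_post,
        rmse=rmse_track,
        burn_in=cfg.burn_in,
    )


def run_mcmc(
    sites: Sequence[SiteDataset],
    config: MCMCConfig | None = None,
    priors: dict[str, PriorSpec] | None = None,
) -> list[PosteriorChain]:
    """Run independent Metropolis-Hastings chains on a set of sites.

    Fully reproducible from ``config.seed``: chains use generators spawned
    from a single seed sequence and are run sequentially.
    """
    cfg = config or MCMCConfig()
    if not sites:
        raise ValueError("need at least one site")
    for site in sites:
        if site.observations.times.size < 2:
            raise ValueError(
                f"site {site.site_id!r} needs at least two observations"
            )
    if not 0 <= cfg.burn_in < cfg.n_iter:
        raise ValueError("burn_in must lie in [0, n_iter)")
    priors = priors or build_priors()
    site_ids = tuple(site.site_id for site in sites)
    site_data = [_prepare_site(site, cfg.use_raw_times) for site in sites]
    seeds = np.random.SeedSequence(cfg.seed).spawn(cfg.n_chains)
    return [
        _run_single_chain(
            c, np.random.default_rng(seeds[c]), site_data, site_ids, priors, cfg
        )
        for c in range(cfg.n_chains)
    ]


# ---------------------------------------------------------------------------
# diagnostics and summaries

def gelman_rubin(chains: Sequence[PosteriorChain], name: str) -> float:
    """Gelman-Rubin potential-scale-reduction statistic for one parameter.

    ``sqrt(Vhat / W)`` with ``Vhat = (n-1)/n * W + B/n``, where ``W`` is the
    mean within-chain variance and ``B/n`` the variance of the chain means,
    computed on post-burn-in draws.
    """
    if len(chains) < 2:
        raise ValueError("Gelman-Rubin needs at least two chains")
    cols = [c.parameter(name) for c in chains]
    n = min(len(col) for col in cols)
    if n < 10:
        raise ValueError("need at least 10 post-burn-in draws per chain")
    x = np.stack([col[:n] for col in cols])  # (m, n)
    w = float(np.mean(np.var(x, axis=1, ddof=1)))
    b_over_n = float(np.var(np.mean(x, axis=1), ddof=1))
    if w == 0.0:
        return 1.0  # degenerate chains: no variance anywhere
    v_hat = (n - 1) / n * w + b_over_n
    return math.sqrt(v_hat / w)


def posterior_dataframe(chains: Sequence[PosteriorChain]) -> pd.DataFrame:
    """Flatten chains into a tidy frame (one row per element)."""
    frames = []
    for c in chains:
        df = pd.DataFrame(c.draws, columns=list(c.param_names))
        df.insert(0, "iteration", np.arange(len(c)))
        df.insert(0, "chain", c.chain_id)
        df["log_post"] = c.log_post
        for s, sid in enumerate(c.site_ids):
            df[f"rmse[{sid}]"] = c.rmse[:, s]
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


def summarize_posterior(
    chains: Sequence[PosteriorChain], ci: float = 0.95
) -> pd.DataFrame:
    """Medians, central credible intervals and R-hat per parameter."""
    alpha = (1.0 - ci) / 2.0
    rows = []
    for name in chains[0].param_names:
        pooled = np.concatenate([c.parameter(name) for c in chains])
        rows.append(
            {
                "parameter": name,
                "median": float(np.median(pooled)),
                "ci_lower": float(np.quantile(pooled, alpha)),
                "ci_upper": float(np.quantile(pooled, 1.0 - alpha)),
                "rhat": gelman_rubin(chains, name) if len(chains) > 1 else np.nan,
            }
        )
    return pd.DataFrame(rows).set_index("parameter")


def parameter_set_from_row(
    row: Mapping[str, float], site_ids: Sequence[str], share_locals: bool = False
) -> ParameterSet:
    """Rebuild a :class:`ParameterSet` from one posterior draw/row."""
    generic = GenericKinetics(u0=float(row["u0"]), eta11=float(row["eta11"]))
    locals_: dict[str, LocalParams] = {}
    for sid in site_ids:
        if share_locals:
            lp = LocalParams(*(float(row[p]) for p in LOCAL_NAMES))
        else:
            lp = LocalParams(*(float(row[f"{p}[{sid}]"]) for p in LOCAL_NAMES))
        locals_[sid] = lp
    return ParameterSet(generic=generic, locals=locals_)
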