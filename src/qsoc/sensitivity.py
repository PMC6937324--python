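"""Hornberger-Spear-Young (HSY) generalised sensitivity analysis.

Given a Markov chain of parameter sets with an RMSE attached to each
element, the chain is split into a *behavioral* bin (the best-performing
fraction, below an RMSE quantile threshold) and a *non-behavioral* bin.
For each parameter, the Kolmogorov-Smirnov distance between the two bins'
empirical distributions measures how strongly the parameter discriminates
good fits from bad ones — a rough but robust sensitivity index.  Per-site
distances are averaged across sites to rank parameters.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["HsyPartition", "hsy_partition", "ks_sensitivity", "rank_parameters"]


@dataclass(frozen=True)
class HsyPartition:
    """Index partition of a chain into behavioral / non-behavioral bins."""

    threshold: float
    behavioral: np.ndarray
    non_behavioral: np.ndarray


def hsy_partition(rmse: np.ndarray, quantile: float = 0.05) -> HsyPartition:
    """Split chain elements at an RMSE quantile.

    The behavioral bin holds the ``ceil(quantile * n)`` elements of smallest
    RMSE (empirical order statistic, lower interpolation); ties at the
    threshold are resolved by first occurrence so the bin size is exact.
    """
    if not 0.0 < quantile < 1.0:
        raise ValueError(f"quantile must lie in (0, 1), got {quantile}")
    rmse = np.asarray(rmse, dtype=float)
    n = rmse.size
    if n == 0:
        raise ValueError("empty chain")
    k = math.ceil(quantile * n)
    order = np.argsort(rmse, kind="stable")
    return HsyPartition(
        threshold=float(rmse[order[k - 1]]),
        behavioral=np.sort(order[:k]),
        non_behavioral=np.sort(order[k:]),
    )


def ks_sensitivity(partition: HsyPartition, values: np.ndarray) -> float:
    """Kolmogorov-Smirnov distance between the bins for one parameter.

    The supremum distance between the empirical CDFs of the parameter's
    values in the behavioral and non-behavioral bins; in [0, 1] and
    invariant under strictly monotone transforms of the values.
    """
    values = np.asarray(values, dtype=float)
    a = values[partition.behavioral]
    b = values[partition.non_behavioral]
    if a.size == 0 or b.size == 0:
        raise ValueError("both HSY bins must be non-empty")
    return float(stats.ks_2samp(a, b, method="asymp").statistic)


def rank_parameters(ks_table: pd.DataFrame) -> pd.Series:
    """Average per-site KS distances and sort parameters by sensitivity.

    ``ks_table`` has one row per site and one column per parameter; the
    result is the column-wise arithmetic mean, sorted descending.
    """
    if ks_table.empty:
        raise ValueError("need at least one site")
    return ks_table.mean(axis=0).sort_values(ascending=False)
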