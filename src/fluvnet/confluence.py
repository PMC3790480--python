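"""Paired contrasts at stream confluences.

Each confluence contributes a triplet: two tributaries immediately
upstream and the recipient stream below the junction.  For every metric
(diversity, evenness, hydromorphic variables) the tributary pair is
averaged and compared with the recipient by a Wilcoxon signed-rank test;
diversity shifts are then correlated with hydromorphic shifts by
Spearman rank correlation.
"""

from __future__ import annotations

import logging
import warnings
from itertools import permutations

import numpy as np
import pandas as pd
from scipy import stats

from .errors import SiteLookupError
from .network import ConfluenceTriplet

__all__ = [
    "triplet_contrasts",
    "wilcoxon_signed_rank",
    "spearman",
    "confluence_tests",
    "delta_correlations",
]

log = logging.getLogger(__name__)


def triplet_contrasts(
    triplets: list[ConfluenceTriplet], metrics: pd.DataFrame
) -> pd.DataFrame:
    """Upstream mean, downstream value and delta per triplet and metric.

    ``metrics`` is a site x metric frame; delta = downstream - mean of the
    two tributaries.  Metrics missing for any member of a triplet yield a
    missing delta (logged).
    """
    rows = []
    for t in triplets:
        for sid in (t.tributary_a, t.tributary_b, t.recipient):
            if sid not in metrics.index:
                raise SiteLookupError(f"triplet site {sid!r} missing from metrics")
        for metric in metrics.columns:
            up = metrics.loc[[t.tributary_a, t.tributary_b], metric].to_numpy(float)
            down = float(metrics.loc[t.recipient, metric])
            if np.isnan(up).any() or np.isnan(down):
                log.warning("triplet %s: metric %s missing", t.recipient, metric)
                upstream_mean = delta = np.nan
            else:
                upstream_mean = float(up.mean())
                delta = down - upstream_mean
            rows.append(
                {
                    "recipient": t.recipient,
                    "metric": metric,
                    "upstream_mean": upstream_mean,
                    "downstream": down,
                    "delta": delta,
                }
            )
    return pd.DataFrame(rows)


def _exact_wilcoxon_p(ranks: np.ndarray, w_plus: float) -> float:
    """Exact two-sided p by dynamic programming over sign assignments.

    Ranks may be midranks (half-integers); doubling makes them integral so
    the distribution of the doubled positive-rank sum is enumerable.
    """
    doubled = np.round(2 * ranks).astype(int)
    total = int(doubled.sum())
    dist = np.zeros(total + 1)
    dist[0] = 1.0
    for d in doubled:
        shifted = np.zeros_like(dist)
        shifted[d:] = dist[: total + 1 - d]
        dist = 0.5 * (dist + shifted)
    w2 = int(round(2 * w_plus))
    cdf = dist[: w2 + 1].sum()
    sf = dist[w2:].sum()
    return float(min(1.0, 2 * min(cdf, sf)))


def wilcoxon_signed_rank(
    upstream: np.ndarray,
    downstream: np.ndarray | None = None,
    exact_max_n: int = 25,
    correction: bool = True,
) -> tuple[float, float, int]:
    """Wilcoxon signed-rank test for paired samples.

    Returns (W, two-sided p, n) where W is the positive-difference rank
    sum and n the number of non-zero differences.  Zero differences are
    dropped; ties get midranks.  The p-value is exact (sign-assignment
    enumeration) for n <= ``exact_max_n``, otherwise a normal
    approximation with tie correction and optional continuity correction.
    """
    upstream = np.asarray(upstream, dtype=float)
    if downstream is None:
        d = upstream
    else:
        d = np.asarray(downstream, dtype=float) - upstream
    d = d[d != 0]
    n = d.size
    if n == 0:
        warnings.warn("all paired differences are zero; p = 1")
        return 0.0, 1.0, 0
    ranks = stats.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    if n <= exact_max_n:
        p = _exact_wilcoxon_p(ranks, w_plus)
    else:
        mean = ranks.sum() / 2.0
        var = float(np.sum(ranks**2)) / 4.0  # reduces to n(n+1)(2n+1)/24 sans ties
        z_num = w_plus - mean
        if correction:
            z_num -= 0.5 * np.sign(z_num)
        z = z_num / np.sqrt(var)
        p = float(2 * stats.norm.sf(abs(z)))
    return w_plus, min(1.0, p), n


def _exact_spearman_p(rho: float, n: int) -> float:
    base = np.arange(1, n + 1, dtype=float)
    perms = np.array(list(permutations(range(n))), dtype=float) + 1
    denom = n * (n**2 - 1) / 6.0
    rhos = 1 - np.sum((perms - base) ** 2, axis=1) / denom
    return float(np.mean(np.abs(rhos) >= abs(rho) - 1e-12))


def spearman(x: np.ndarray, y: np.ndarray, exact_max_n: int = 9) -> tuple[float, float]:
    """Spearman rank correlation with two-sided p.

    Exact permutation p for n <= ``exact_max_n`` (untied data), otherwise
    the t approximation.  A constant input yields (nan, nan).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("spearman needs two equal-length vectors, n >= 3")
    if np.all(x == x[0]) or np.all(y == y[0]):
        warnings.warn("constant vector: Spearman rho undefined")
        return float("nan"), float("nan")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    n = x.size
    no_ties = len(np.unique(x)) == n and len(np.unique(y)) == n
    if n <= exact_max_n and no_ties:
        return rho, _exact_spearman_p(rho, n)
    if abs(rho) >= 1.0:
        return rho, 0.0
    t = rho * np.sqrt((n - 2) / (1 - rho**2))
    return rho, float(2 * stats.t.sf(abs(t), df=n - 2))


def confluence_tests(contrasts: pd.DataFrame) -> pd.DataFrame:
    """Per-metric Wilcoxon test of upstream means vs downstream values."""
    rows = []
    for metric, sub in contrasts.groupby("metric", sort=False):
        ok = sub.dropna(subset=["upstream_mean", "downstream"])
        w, p, n = wilcoxon_signed_rank(
            ok["upstream_mean"].to_numpy(), ok["downstream"].to_numpy()
        )
        rows.append(
            {
                "metric": metric,
                "n_triplets": len(ok),
                "median_delta": float(ok["delta"].median()),
                "W": w,
                "p": p,
                "n_nonzero": n,
            }
        )
    return pd.DataFrame(rows)


def delta_correlations(
    contrasts: pd.DataFrame,
    diversity_metrics: list[str],
    physical_metrics: list[str],
) -> pd.DataFrame:
    """Spearman correlation of diversity deltas with hydromorphic deltas."""
    wide = contrasts.pivot(index="recipient", columns="metric", values="delta")
    rows = []
    for dm in diversity_metrics:
        for pm in physical_metrics:
            sub = wide[[dm, pm]].dropna()
            rho, p = spearman(sub[pm].to_numpy(), sub[dm].to_numpy())
            rows.append(
                {"diversity_delta": dm, "physical_delta": pm, "rho": rho, "p": p, "n": len(sub)}
            )
    return pd.DataFrame(rows)
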