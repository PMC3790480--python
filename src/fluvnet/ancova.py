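"""Distance decay, permutation ANCOVA, and similarity density estimation.

Community similarity between site pairs is regressed on distance within
each group (headwater-headwater vs midsized-midsized); the group effect
is then tested while controlling for distance via an ANCOVA with
sequential (distance-first) sums of squares.  Because pairwise
similarities are not independent observations, significance comes from a
permutation null: the site-to-community assignment is permuted (a joint
row/column relabelling of the similarity matrix), which preserves the
similarity structure while breaking its link to the site attributes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import AlignmentError, ConfigurationError

__all__ = [
    "linear_decay_fit",
    "ancova_F",
    "permutation_ancova",
    "similarity_density",
    "AncovaResult",
    "nrr_bandwidth",
]

log = logging.getLogger(__name__)


def linear_decay_fit(
    pairs: pd.DataFrame, group: str, index: str, distance: str = "d_hydro_m"
) -> dict[str, float]:
    """OLS fit of similarity against distance for one group of pairs."""
    sub = pairs[pairs["group"] == group]
    if len(sub) < 3:
        raise ValueError(f"group {group!r} has fewer than 3 pairs")
    d = sub[distance].to_numpy(float)
    if np.ptp(d) == 0:
        raise np.linalg.LinAlgError("distances are constant; slope not identifiable")
    res = stats.linregress(d, sub[index].to_numpy(float))
    return {
        "slope": float(res.slope),
        "intercept": float(res.intercept),
        "r2": float(res.rvalue**2),
        "p": float(res.pvalue),
        "n": int(len(sub)),
    }


def _sequential_f(d: np.ndarray, g: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Sequential-SS F statistics for y ~ distance + group (distance first)."""
    n = y.size
    x = np.column_stack([np.ones(n), d, g])
    q, _ = np.linalg.qr(x)
    coef = q.T @ y
    tss = float(np.sum((y - y.mean()) ** 2))
    ss_after_d = float(coef[1] ** 2)
    ss_after_g = float(coef[2] ** 2)
    ss_resid = max(tss - ss_after_d - ss_after_g, 0.0)
    df_resid = n - 3
    ms_resid = ss_resid / df_resid
    if ms_resid <= 0.0:  # complete separation: F unbounded
        big = 1.0 / np.finfo(float).eps
        return (big if ss_after_d > 0 else 0.0), (big if ss_after_g > 0 else 0.0)
    return ss_after_d / ms_resid, ss_after_g / ms_resid


def ancova_F(
    pairs: pd.DataFrame, index: str, distance: str = "d_hydro_m"
) -> tuple[float, float]:
    """F statistics (distance, group) for the additive two-term ANCOVA."""
    groups = pairs["group"].unique()
    if len(groups) < 2:
        raise ConfigurationError("ANCOVA needs pairs from both groups")
    d = pairs[distance].to_numpy(float)
    g = (pairs["group"] == sorted(groups)[1]).to_numpy(float)
    y = pairs[index].to_numpy(float)
    return _sequential_f(d, g, y)


@dataclass
class AncovaResult:
    index_name: str
    distance_metric: str
    F_distance: float
    F_group: float
    p_distance: float
    p_group: float
    n_perm: int
    group_fits: dict[str, dict[str, float]]
    n_pairs: int


def permutation_ancova(
    pairs: pd.DataFrame,
    sim_matrix: pd.DataFrame,
    index: str,
    distance: str = "d_hydro_m",
    n_perm: int = 999,
    rng: np.random.Generator | None = None,
) -> AncovaResult:
    """ANCOVA of similarity on distance + group with a permutation null.

    Each permutation relabels which community sits at which site
    (``sim[i,j] -> sim[perm(i), perm(j)]``); group labels, distances and
    the flow-connectivity exclusions stay with the sites, so the retained
    pair set is fixed and only the similarity values are reshuffled.
    p = (1 + #{F* >= F_obs}) / (n_perm + 1), never below the floor
    1/(n_perm + 1).
    """
    if n_perm < 1:
        raise ConfigurationError(f"n_perm must be >= 1, got {n_perm}")
    rng = np.random.default_rng() if rng is None else rng

    ids = list(sim_matrix.index)
    pos = {s: k for k, s in enumerate(ids)}
    try:
        ia = np.array([pos[s] for s in pairs["site_a"]])
        ib = np.array([pos[s] for s in pairs["site_b"]])
    except KeyError as e:
        raise AlignmentError(f"pair site {e.args[0]!r} missing from matrix") from None

    s = sim_matrix.to_numpy(float)
    d = pairs[distance].to_numpy(float)
    groups = sorted(pairs["group"].unique())
    if len(groups) < 2:
        raise ConfigurationError("ANCOVA needs pairs from both groups")
    g = (pairs["group"] == groups[1]).to_numpy(float)

    y_obs = s[ia, ib]
    f_d_obs, f_g_obs = _sequential_f(d, g, y_obs)

    exceed_d = exceed_g = 0
    n_sites = s.shape[0]
    for _ in range(n_perm):
        perm = rng.permutation(n_sites)
        y = s[perm[ia], perm[ib]]
        f_d, f_g = _sequential_f(d, g, y)
        exceed_d += f_d >= f_d_obs
        exceed_g += f_g >= f_g_obs

    p_d = (1 + exceed_d) / (n_perm + 1)
    p_g = (1 + exceed_g) / (n_perm + 1)

    pw = pairs.copy()
    pw[index] = y_obs
    group_fits = {
        grp: linear_decay_fit(pw, grp, index, distance) for grp in groups
    }
    return AncovaResult(
        index_name=index,
        distance_metric=distance,
        F_distance=float(f_d_obs),
        F_group=float(f_g_obs),
        p_distance=float(p_d),
        p_group=float(p_g),
        n_perm=n_perm,
        group_fits=group_fits,
        n_pairs=len(pairs),
    )


def nrr_bandwidth(values: np.ndarray) -> float:
    """Normal-reference-rule bandwidth 1.06 * sigma-hat * n^(-1/5).

    sigma-hat is the robust min of the sample SD and IQR/1.349.
    """
    values = np.asarray(values, dtype=float)
    n = values.size
    sd = float(np.std(values, ddof=1))
    iqr = float(np.subtract(*np.percentile(values, [75, 25])))
    sigma = min(sd, iqr / 1.349) if iqr > 0 else sd
    if sigma <= 0:
        raise ValueError("zero spread: bandwidth undefined")
    return 1.06 * sigma * n ** (-0.2)


def similarity_density(
    values: np.ndarray, n_grid: int = 512, pad: float = 3.0
) -> tuple[np.ndarray, np.ndarray]:
    """Gaussian kernel density of similarity values on a regular grid."""
    values = np.asarray(values, dtype=float)
    if np.unique(values).size < 2:
        log.warning("degenerate similarity distribution (single value)")
        raise ValueError("need at least 2 distinct values for a density estimate")
    h = nrr_bandwidth(values)
    lo = values.min() - pad * h
    hi = values.max() + pad * h
    grid = np.linspace(lo, hi, n_grid)
    z = (grid[:, None] - values[None, :]) / h
    dens = np.exp(-0.5 * z**2).sum(axis=1) / (values.size * h * np.sqrt(2 * np.pi))
    return grid, dens
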