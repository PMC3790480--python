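"""Pairwise community similarity and the analysis pair table.

Three overlap indices with different sensitivity to rare taxa:

* Sorensen  — presence/absence, 2a / (2a + b + c);
* Horn      — Shannon-entropy based, 1 - [2 H((p+q)/2) - H(p) - H(q)] / (2 ln 2);
* Morisita-Horn — dominance weighted, 2 sum(p q) / (sum p^2 + sum q^2).

Matrix entries are averages over repeated rarefactions of both communities
to a common depth, mirroring the alpha-diversity treatment of unequal
sequencing effort.  Flow-connected site pairs are excluded from the pair
table, because downstream dispersal would otherwise inflate similarity
among the larger, better-connected streams.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import xlogy

from .errors import AlignmentError, DepthError
from .network import StreamNetwork
from .otu import OTUTable, rarefy

__all__ = [
    "sorensen",
    "horn",
    "morisita_horn",
    "rarefied_similarity",
    "rarefied_similarity_matrices",
    "SimilarityMatrix",
    "build_pair_table",
    "INDICES",
]

log = logging.getLogger(__name__)

INDICES = ["sorensen", "horn", "morisita_horn"]


def _check(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("count vectors must have equal length")
    if x.sum() <= 0 or y.sum() <= 0:
        raise ValueError("similarity undefined for an empty community")
    return x, y


def sorensen(x: np.ndarray, y: np.ndarray) -> float:
    """Presence/absence overlap 2a / (2a + b + c)."""
    x, y = _check(x, y)
    px, py = x > 0, y > 0
    a = int(np.sum(px & py))
    b = int(np.sum(px & ~py))
    c = int(np.sum(~px & py))
    return 2 * a / (2 * a + b + c)


def _entropy(p: np.ndarray) -> float:
    return float(-np.sum(xlogy(p, p)))


def horn(x: np.ndarray, y: np.ndarray) -> float:
    """Shannon-entropy overlap of the two relative-abundance vectors."""
    x, y = _check(x, y)
    p = x / x.sum()
    q = y / y.sum()
    m = (p + q) / 2
    val = 1.0 - (2 * _entropy(m) - _entropy(p) - _entropy(q)) / (2 * np.log(2))
    return float(min(1.0, max(0.0, val)))


def morisita_horn(x: np.ndarray, y: np.ndarray) -> float:
    """Dominance-weighted overlap 2 sum(pq) / (sum p^2 + sum q^2)."""
    x, y = _check(x, y)
    p = x / x.sum()
    q = y / y.sum()
    return float(2 * np.dot(p, q) / (np.dot(p, p) + np.dot(q, q)))


_INDEX_FUNCS = {"sorensen": sorensen, "horn": horn, "morisita_horn": morisita_horn}


def rarefied_similarity(
    x: np.ndarray,
    y: np.ndarray,
    m: int,
    resamples: int = 1000,
    rng: np.random.Generator | None = None,
) -> dict[str, dict[str, float]]:
    """Mean of each index over ``resamples`` independent pair rarefactions.

    Within each iteration x and y are rarefied independently to depth
    ``m`` before the indices are evaluated.  Returns per-index mean and
    Monte-Carlo standard error.
    """
    rng = np.random.default_rng() if rng is None else rng
    x = np.asarray(x)
    y = np.asarray(y)
    if x.sum() < m or y.sum() < m:
        raise DepthError(f"both communities need >= {m} reads")
    draws = {name: np.empty(resamples) for name in INDICES}
    for r in range(resamples):
        xr = rarefy(x, m, rng)
        yr = rarefy(y, m, rng)
        for name, func in _INDEX_FUNCS.items():
            draws[name][r] = func(xr, yr)
    return {
        name: {
            "mean": float(v.mean()),
            "se": float(v.std(ddof=1) / np.sqrt(resamples)) if resamples > 1 else 0.0,
        }
        for name, v in draws.items()
    }


# -- vectorised matrices ---------------------------------------------------


def _pairwise_sorensen(counts: np.ndarray) -> np.ndarray:
    b = (counts > 0).astype(np.float32)
    shared = b @ b.T
    richness = b.sum(axis=1)
    denom = richness[:, None] + richness[None, :]
    return 2 * shared / denom


def _pairwise_morisita_horn(p: np.ndarray) -> np.ndarray:
    cross = p @ p.T
    sq = np.einsum("ij,ij->i", p, p)
    return 2 * cross / (sq[:, None] + sq[None, :])


def _pairwise_horn(p: np.ndarray) -> np.ndarray:
    # float32 keeps the entropy sums accurate to ~1e-6, ample for means
    p = p.astype(np.float32)
    n = p.shape[0]
    h = -np.sum(xlogy(p, p), axis=1)
    out = np.ones((n, n), dtype=np.float64)
    for i in range(n - 1):
        mix = (p[i] + p[i + 1 :]) / 2.0
        h_mix = -np.sum(xlogy(mix, mix), axis=1)
        vals = 1.0 - (2 * h_mix - h[i] - h[i + 1 :]) / (2 * np.log(2))
        np.clip(vals, 0.0, 1.0, out=vals)
        out[i, i + 1 :] = vals
        out[i + 1 :, i] = vals
    return out


@dataclass
class SimilarityMatrix:
    """Rarefaction-averaged similarity matrix for one index."""

    index_name: str
    values: pd.DataFrame  # square, symmetric, unit diagonal
    resamples: int
    depth: int


def rarefied_similarity_matrices(
    table: OTUTable,
    m: int,
    resamples: int = 1000,
    rng: np.random.Generator | None = None,
) -> dict[str, SimilarityMatrix]:
    """All-pairs rarefaction-averaged similarity for the three indices.

    Each replicate rarefies every sample independently to depth ``m`` and
    evaluates all three indices on all pairs; entries are the means over
    replicates.  Pre-drawing one rarefaction per sample per replicate
    keeps the per-pair marginals identical to `rarefied_similarity` while
    making the all-pairs computation tractable.
    """
    rng = np.random.default_rng() if rng is None else rng
    ids = table.sample_ids
    counts = table.counts.to_numpy()
    if (counts.sum(axis=1) < m).any():
        shallow = [ids[i] for i in np.where(counts.sum(axis=1) < m)[0]]
        raise DepthError(f"samples below depth {m}: {shallow}")
    n, s = counts.shape
    acc = {name: np.zeros((n, n)) for name in INDICES}
    rarefied = np.empty((n, s), dtype=np.int64)
    for _ in range(resamples):
        for i in range(n):
            rarefied[i] = rarefy(counts[i], m, rng)
        keep = rarefied.sum(axis=0) > 0  # drop globally absent OTUs this replicate
        sub = rarefied[:, keep]
        p = (sub / m).astype(np.float64)
        acc["sorensen"] += _pairwise_sorensen(sub)
        acc["morisita_horn"] += _pairwise_morisita_horn(p)
        acc["horn"] += _pairwise_horn(p)
    out = {}
    for name in INDICES:
        mat = acc[name] / resamples
        np.fill_diagonal(mat, 1.0)
        df = pd.DataFrame(mat, index=ids, columns=ids)
        out[name] = SimilarityMatrix(name, df, resamples, m)
    return out


def build_pair_table(
    net: StreamNetwork,
    groups: dict[str, str],
    matrices: dict[str, SimilarityMatrix],
    sampled_sites=None,
) -> pd.DataFrame:
    """Long-format table of retained within-group site pairs.

    One row per unordered pair of same-group sites that are NOT
    flow-connected, with hydrologic and Euclidean distances and the three
    similarity values attached.  Cross-group and flow-connected pairs are
    dropped; a sample is never paired with itself.
    """
    sampled = list(sampled_sites) if sampled_sites is not None else sorted(groups)
    for name, sim in matrices.items():
        missing = [s for s in sampled if s not in sim.values.index]
        if missing:
            raise AlignmentError(
                f"{name} similarity matrix lacks sites {missing[:5]}"
            )
    for s in sampled:
        if s not in net:
            raise AlignmentError(f"site {s!r} not in network")

    rows = []
    for a, b in itertools.combinations(sampled, 2):
        if groups[a] != groups[b]:
            continue
        if net.flow_connected(a, b):
            continue
        row = {
            "site_a": a,
            "site_b": b,
            "group": "HH" if groups[a] == "headwater" else "MM",
            "d_hydro_m": net.hydrologic_distance(a, b),
            "d_euclid_m": net.euclidean_distance(a, b),
        }
        for name, sim in matrices.items():
            row[name] = float(sim.values.loc[a, b])
        rows.append(row)
    return pd.DataFrame(
        rows,
        columns=["site_a", "site_b", "group", "d_hydro_m", "d_euclid_m", *matrices],
    )
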