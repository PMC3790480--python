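"""Alpha diversity: Hill numbers and relative logarithmic evenness.

Hill numbers express diversity of order q as an effective number of
equally abundant taxa: q=0 is richness, q=1 the exponential of the
Shannon entropy and q=2 the inverse Simpson concentration.  Relative
logarithmic evenness RLE_{a,b} = ln(bD) / ln(aD); RLE_{0,1} coincides
with Pielou's J'.  Profiles are computed as means over repeated
rarefactions to a common depth.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DepthError
from .otu import OTUTable, rarefy

__all__ = ["hill_diversity", "rle", "rarefied_profile", "INDEX_NAMES"]

log = logging.getLogger(__name__)

INDEX_NAMES = ["richness", "shannon_diversity", "simpson_diversity", "rle_01", "rle_12"]


def hill_diversity(counts: np.ndarray, q: int) -> float:
    """Hill number of order q in {0, 1, 2} for one community."""
    counts = np.asarray(counts, dtype=float)
    if counts.sum() <= 0:
        raise ValueError("community has no reads")
    p = counts[counts > 0]
    p = p / p.sum()
    if q == 0:
        return float(p.size)
    if q == 1:
        return float(np.exp(-np.sum(p * np.log(p))))
    if q == 2:
        return float(1.0 / np.sum(p**2))
    raise ValueError(f"unsupported Hill order {q}; use 0, 1 or 2")


def rle(counts: np.ndarray, a: int, b: int) -> float:
    """Relative logarithmic evenness ln(bD)/ln(aD); NaN for monocultures."""
    if not a < b:
        raise ValueError("rle requires a < b")
    da = hill_diversity(counts, a)
    db = hill_diversity(counts, b)
    if np.isclose(np.log(da), 0.0):
        warnings.warn("RLE undefined for a single-OTU community; returning NaN")
        return float("nan")
    return float(np.log(db) / np.log(da))


def _indices(counts: np.ndarray) -> np.ndarray:
    d0 = hill_diversity(counts, 0)
    d1 = hill_diversity(counts, 1)
    d2 = hill_diversity(counts, 2)
    rle01 = np.log(d1) / np.log(d0) if d0 > 1 else np.nan
    rle12 = np.log(d2) / np.log(d1) if d1 > 1 else np.nan
    return np.array([d0, d1, d2, rle01, rle12])


@dataclass
class DiversityProfile:
    """Per-sample rarefied diversity/evenness means with standard errors."""

    values: pd.DataFrame  # sample x index means
    se: pd.DataFrame  # matching Monte-Carlo standard errors
    depth: int
    resamples: int

    def to_frame(self) -> pd.DataFrame:
        out = self.values.copy()
        for c in self.se.columns:
            out[f"{c}_se"] = self.se[c]
        out.insert(0, "depth", self.depth)
        out.insert(1, "resamples", self.resamples)
        return out


def rarefied_profile(
    table: OTUTable,
    m: int,
    resamples: int = 100,
    rng: np.random.Generator | None = None,
    drop_shallow: bool = True,
) -> DiversityProfile:
    """Mean diversity/evenness over ``resamples`` independent rarefactions.

    Samples whose total read count is below ``m`` are dropped with a
    warning when ``drop_shallow`` is set, otherwise a DepthError is raised.
    A sample already at depth ``m`` is deterministic (single evaluation).
    """
    rng = np.random.default_rng() if rng is None else rng
    totals = table.sample_totals
    shallow = totals.index[totals < m].tolist()
    if shallow:
        if not drop_shallow:
            raise DepthError(f"samples below depth {m}: {shallow}")
        log.warning("dropping %d samples below depth %d: %s", len(shallow), m, shallow)
    keep = [s for s in table.sample_ids if s not in set(shallow)]

    means = np.empty((len(keep), len(INDEX_NAMES)))
    ses = np.zeros_like(means)
    counts = table.counts.loc[keep].to_numpy()
    for i, sid in enumerate(keep):
        vec = counts[i]
        nz = vec[vec > 0]
        if nz.sum() == m:
            means[i] = _indices(nz)
            continue
        draws = np.empty((resamples, len(INDEX_NAMES)))
        for r in range(resamples):
            draws[r] = _indices(rarefy(nz, m, rng))
        means[i] = draws.mean(axis=0)
        ses[i] = draws.std(axis=0, ddof=1) / np.sqrt(resamples)
    values = pd.DataFrame(means, index=pd.Index(keep, name="sample_id"), columns=INDEX_NAMES)
    se = pd.DataFrame(ses, index=values.index, columns=INDEX_NAMES)
    return DiversityProfile(values, se, depth=m, resamples=resamples)
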