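"""OTU count tables: I/O, rarefaction and the core/satellite partition.

Counts live in a pandas DataFrame (samples x OTUs, non-negative integers).
Rarefaction draws reads without replacement, i.e. a multivariate
hypergeometric subsample, which is the standard correction for unequal
sequencing effort.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .errors import ConfigurationError, DepthError, FormatError

__all__ = [
    "OTUTable",
    "CoreSatellitePartition",
    "read_otu_table",
    "write_otu_table",
    "read_taxon_flags",
    "rarefy",
    "expected_rarefied_richness",
    "core_satellite_partition",
    "group_read_fraction",
    "cyanobacteria_fraction",
]

log = logging.getLogger(__name__)


@dataclass
class OTUTable:
    """Sample x OTU count matrix with optional per-OTU taxon flags."""

    counts: pd.DataFrame
    taxon_flags: pd.DataFrame | None = None  # indexed by otu_id, boolean columns

    def __post_init__(self) -> None:
        df = self.counts
        if df.index.has_duplicates:
            raise FormatError("duplicate sample ids")
        if df.columns.has_duplicates:
            raise FormatError("duplicate OTU ids")
        values = df.to_numpy()
        if not np.issubdtype(values.dtype, np.integer):
            if not np.allclose(values, np.round(values)):
                raise FormatError("OTU counts must be integers")
            df = df.astype(np.int64)
            object.__setattr__(self, "counts", df)
            values = df.to_numpy()
        if (values < 0).any():
            r, c = np.argwhere(values < 0)[0]
            raise FormatError(
                f"negative count at sample {df.index[r]!r}, OTU {df.columns[c]!r}"
            )
        if (values.sum(axis=1) < 1).any():
            empty = df.index[values.sum(axis=1) < 1].tolist()
            raise FormatError(f"samples with zero reads: {empty}")
        if (values.sum(axis=0) < 1).any():
            raise FormatError("OTUs with zero reads across all samples")
        if self.taxon_flags is not None:
            missing = self.counts.columns.difference(self.taxon_flags.index)
            if len(missing):
                raise FormatError(
                    f"taxon flags missing for {len(missing)} OTUs, e.g. {missing[0]!r}"
                )

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def otu_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def sample_totals(self) -> pd.Series:
        return self.counts.sum(axis=1)

    def subset_samples(self, sample_ids) -> "OTUTable":
        sub = self.counts.loc[list(sample_ids)]
        sub = sub.loc[:, sub.sum(axis=0) > 0]
        flags = None
        if self.taxon_flags is not None:
            flags = self.taxon_flags.loc[sub.columns]
        return OTUTable(sub, flags)


@dataclass
class CoreSatellitePartition:
    """Occupancy-based split of OTUs into regionally common (core) and
    occasionally occurring (satellite) taxa."""

    core_otus: set[str]
    satellite_otus: set[str]
    occupancy: pd.Series
    threshold: float = 0.5


def read_otu_table(path: str, flags_path: str | None = None) -> OTUTable:
    """Read a TSV OTU table: first column sample id, remaining columns OTUs."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    bad = df.columns[[not np.issubdtype(t, np.number) for t in df.dtypes]]
    if len(bad):
        raise FormatError(f"non-numeric OTU columns: {list(bad)}")
    for col in df.columns:
        vals = df[col].to_numpy()
        if not np.allclose(vals, np.round(vals)):
            row = df.index[~np.isclose(vals, np.round(vals))][0]
            raise FormatError(f"non-integer count at sample {row!r}, OTU {col!r}")
        if (vals < 0).any():
            row = df.index[vals < 0][0]
            raise FormatError(f"negative count at sample {row!r}, OTU {col!r}")
    flags = read_taxon_flags(flags_path) if flags_path else None
    return OTUTable(df.astype(np.int64), flags)


def write_otu_table(table: OTUTable, path: str) -> None:
    table.counts.to_csv(path, sep="\t", index_label="sample_id")


def read_taxon_flags(path: str) -> pd.DataFrame:
    """Read per-OTU flags (e.g. ``is_cyanobacteria`` in {0,1})."""
    flags = pd.read_csv(path, sep="\t", index_col=0)
    flags.index = flags.index.astype(str)
    return flags.astype(bool)


def rarefy(counts: np.ndarray, m: int, rng: np.random.Generator) -> np.ndarray:
    """Subsample one community to exactly ``m`` reads without replacement."""
    counts = np.asarray(counts)
    total = int(counts.sum())
    if m < 1:
        raise DepthError(f"rarefaction depth must be >= 1, got {m}")
    if m > total:
        raise DepthError(f"depth {m} exceeds sample total {total}")
    if m == total:
        return counts.astype(np.int64, copy=True)
    return rng.multivariate_hypergeometric(counts.astype(np.int64), m)


def expected_rarefied_richness(counts: np.ndarray, m: int) -> float:
    """Closed-form expected number of OTUs in an ``m``-read subsample.

    E[S_m] = sum_i 1 - C(N - N_i, m) / C(N, m), the hypergeometric
    probability that OTU i survives the subsampling.
    """
    counts = np.asarray(counts, dtype=np.int64)
    counts = counts[counts > 0]
    total = int(counts.sum())
    if m > total:
        raise DepthError(f"depth {m} exceeds sample total {total}")

    def log_binom(n, k):
        return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)

    rest = total - counts
    p_absent = np.where(
        rest >= m, np.exp(log_binom(rest, m) - log_binom(total, m)), 0.0
    )
    return float(np.sum(1.0 - p_absent))


def core_satellite_partition(
    table: OTUTable, threshold: float = 0.5
) -> CoreSatellitePartition:
    """Split OTUs into core (occupancy >= threshold) and satellite taxa.

    Occupancy is the fraction of samples in which an OTU has at least one
    read, computed on the unrarefied table.
    """
    if len(table.sample_ids) < 2:
        raise ConfigurationError("core/satellite partition needs >= 2 samples")
    occupancy = (table.counts > 0).mean(axis=0)
    core = set(occupancy.index[occupancy >= threshold])
    satellite = set(occupancy.index) - core
    return CoreSatellitePartition(core, satellite, occupancy, threshold)


def group_read_fraction(table: OTUTable, otu_set) -> pd.Series:
    """Per-sample fraction of reads belonging to ``otu_set``."""
    otus = set(otu_set)
    unknown = otus - set(table.otu_ids)
    if unknown:
        raise ConfigurationError(f"OTUs not in table: {sorted(unknown)[:5]}")
    totals = table.sample_totals
    in_group = table.counts.loc[:, table.counts.columns.isin(otus)].sum(axis=1)
    return in_group / totals


def cyanobacteria_fraction(table: OTUTable, flag: str = "is_cyanobacteria") -> pd.Series:
    """Per-sample fraction of reads in OTUs flagged as cyanobacteria."""
    if table.taxon_flags is None or flag not in table.taxon_flags.columns:
        raise ConfigurationError(f"taxon flag {flag!r} not available")
    flagged = table.taxon_flags.index[table.taxon_flags[flag]]
    return group_read_fraction(table, set(flagged) & set(table.otu_ids))
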