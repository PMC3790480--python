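"""Synthetic dendritic metacommunity generator.

Produces the three pipeline inputs — a rooted stream network, a site
covariate table and a sample x OTU count table — with the statistical
structure the analysis assumes about real benthic biofilm surveys:

* terrestrial inputs dominate headwater communities: each site receives
  a site-specific "terrestrial" satellite pool with a weight
  w(A) = w0 * A^(-w1) that decays with catchment area A, which makes
  headwaters richer, more variable and compositionally idiosyncratic;
* a shared regional core pool (lognormal abundances) underlies every
  site, so the core read fraction rises downstream as w(A) shrinks;
* a one-step upstream mass effect mixes each junction with the mean of
  its immediate upstream communities, homogenising larger streams;
* covariates (SUVA254, channel slope, Froude number via velocity and
  depth) trend with log10 catchment size; the cyanobacteria read
  fraction is drawn independently of area.

Reads are multinomial draws at per-sample depths of at least 4698, so
rarefaction to that common depth is always possible.  A ``SynthTruth``
record keeps the generating parameters for recovery tests.
"""

from __future__ import annotations

import dataclasses
import json
import math
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .network import SiteNode, StreamNetwork, write_network
from .otu import OTUTable, write_otu_table

__all__ = [
    "SynthConfig",
    "SynthTruth",
    "generate_network",
    "generate_covariates",
    "generate_metacommunity",
    "simulate_survey",
]

_G = 9.81  # gravitational acceleration, m s^-2


def _default_covariate_trends() -> dict[str, dict[str, float]]:
    # mean = intercept + slope * log10(A); "log10" scale exponentiates.
    return {
        "suva254": {"intercept": 3.6, "slope": -0.8, "sd": 0.5, "scale": "linear"},
        "doc": {"intercept": 2.0, "slope": 0.0, "sd": 0.4, "scale": "linear"},
        "slope": {"intercept": -1.3, "slope": -0.35, "sd": 0.20, "scale": "log10"},
        "velocity_ms": {"intercept": -0.6, "slope": 0.25, "sd": 0.12, "scale": "log10"},
        "depth_m": {"intercept": -0.9, "slope": 0.20, "sd": 0.12, "scale": "log10"},
        "forest_cover": {"intercept": 0.85, "slope": -0.03, "sd": 0.08, "scale": "linear"},
    }


@dataclass
class SynthConfig:
    """Parameters of the synthetic survey; defaults mirror the study design
    (114 sites, sequencing depth >= 4698 reads)."""

    n_headwaters: int = 57
    add_outlet_site: bool = True  # one extra mainstem site below the top junction
    depth_min: int = 4698
    depth_max: int = 14094
    # species pools
    s_core: int = 300
    core_lognorm_mu: float = 0.0
    core_lognorm_sigma: float = 1.6
    s_satellite: int = 1500
    satellite_subset: int = 300
    satellite_concentration: float = 1.0
    # mixing
    terrestrial_w0: float = 0.55
    terrestrial_w1: float = 0.60
    terrestrial_weight_sd: float = 0.30  # lognormal site-to-site scatter of w
    upstream_mass_effect: float = 0.20
    site_noise_sigma: float = 0.30
    # network geometry
    leaf_area_median_km2: float = 1.0
    leaf_area_sigma: float = 0.6
    increment_area_median_km2: float = 1.8
    increment_area_sigma: float = 0.5
    edge_length_median_m: float = 900.0
    edge_length_sigma: float = 0.5
    # covariates
    covariate_trends: dict = field(default_factory=_default_covariate_trends)
    cyano_n_otus: int = 12
    cyano_beta_a: float = 2.0
    cyano_beta_b: float = 10.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_headwaters < 2:
            raise ConfigurationError("n_headwaters must be >= 2")
        if self.depth_min < 1 or self.depth_max < self.depth_min:
            raise ConfigurationError("invalid sequencing depth range")
        for name in ("s_core", "s_satellite", "satellite_subset"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")
        if self.cyano_n_otus < 0:
            raise ConfigurationError("cyano_n_otus must be >= 0 (0 disables the flag)")
        if self.satellite_subset > self.s_satellite:
            raise ConfigurationError("satellite_subset exceeds the satellite pool")
        if not (0 <= self.upstream_mass_effect < 1):
            raise ConfigurationError("upstream_mass_effect must be in [0, 1)")
        if self.terrestrial_w0 < 0 or self.terrestrial_w1 < 0:
            raise ConfigurationError("terrestrial weight parameters must be >= 0")
        if self.cyano_n_otus > self.s_core:
            raise ConfigurationError("cyano_n_otus exceeds the core pool")


@dataclass
class SynthTruth:
    """Ground truth of one simulated survey, for recovery tests."""

    seed: int
    terrestrial_weight: dict[str, float]
    upstream_mass_effect: float
    group_labels: dict[str, str]
    covariate_slopes: dict[str, float]
    config: dict

    def to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=1, sort_keys=True)


# -- network ---------------------------------------------------------------


class _Node:
    __slots__ = ("children", "id", "area", "length", "x", "y")

    def __init__(self):
        self.children: list[_Node] = []
        self.id = ""
        self.area = 0.0
        self.length = 0.0
        self.x = self.y = 0.0


def _random_topology(n_leaves: int, rng: np.random.Generator) -> _Node:
    node = _Node()
    if n_leaves == 1:
        return node
    left = int(rng.integers(1, n_leaves))
    node.children = [_random_topology(left, rng), _random_topology(n_leaves - left, rng)]
    return node


def generate_network(
    n_headwaters: int,
    rng: np.random.Generator,
    config: SynthConfig | None = None,
) -> StreamNetwork:
    """Random recursive bifurcation tree with downstream-summed areas.

    Leaf catchment areas are lognormal; each junction adds a local
    increment to the sum of its upstream areas, so areas grow strictly
    downstream.  Planar coordinates come from a recursive sector
    embedding with straight edges whose lengths equal the hydrologic
    edge lengths, so Euclidean distance never exceeds hydrologic
    distance.  With ``add_outlet_site`` an extra mainstem site is
    appended below the top junction (57 headwaters then yield 114 sites).
    """
    cfg = config or SynthConfig(n_headwaters=n_headwaters)
    if n_headwaters < 2:
        raise ConfigurationError("n_headwaters must be >= 2")
    root = _random_topology(n_headwaters, rng)

    # areas, postorder
    def assign_area(node: _Node) -> float:
        if not node.children:
            node.area = float(
                cfg.leaf_area_median_km2
                * math.exp(rng.normal(0.0, cfg.leaf_area_sigma))
            )
        else:
            upstream = sum(assign_area(c) for c in node.children)
            node.area = upstream + float(
                cfg.increment_area_median_km2
                * math.exp(rng.normal(0.0, cfg.increment_area_sigma))
            )
        return node.area

    assign_area(root)

    if cfg.add_outlet_site:
        outlet = _Node()
        outlet.children = [root]
        outlet.area = root.area + float(
            cfg.increment_area_median_km2 * math.exp(rng.normal(0.0, cfg.increment_area_sigma))
        )
        root = outlet

    # ids in topological order (outlet first), geometry by sector embedding
    counter = [0]

    def assign_ids(node: _Node) -> None:
        node.id = f"S{counter[0]:03d}"
        counter[0] += 1
        for c in node.children:
            assign_ids(c)

    assign_ids(root)

    root.x, root.y = 0.0, 0.0

    def embed(node: _Node, direction: float, sector: float) -> None:
        k = len(node.children)
        if k == 0:
            return
        offsets = [0.0] if k == 1 else [-sector / 4, sector / 4]
        for child, off in zip(node.children, offsets):
            child.length = float(
                cfg.edge_length_median_m * math.exp(rng.normal(0.0, cfg.edge_length_sigma))
            )
            child_dir = direction + off + rng.normal(0.0, sector / 12)
            child.x = node.x + child.length * math.cos(child_dir)
            child.y = node.y + child.length * math.sin(child_dir)
            embed(child, child_dir, sector / max(k, 1))

    embed(root, math.pi / 2, math.pi * 0.9)

    sites: list[SiteNode] = []
    edges: list[tuple[str, str, float]] = []

    def collect(node: _Node, parent: _Node | None) -> None:
        elevation = 600.0 + 0.08 * math.hypot(node.x, node.y) + rng.normal(0.0, 15.0)
        sites.append(
            SiteNode(node.id, node.x, node.y, elevation, node.area)
        )
        if parent is not None:
            edges.append((node.id, parent.id, node.length))
        for c in node.children:
            collect(c, node)

    collect(root, None)
    return StreamNetwork(sites, edges)


# -- covariates ------------------------------------------------------------


def generate_covariates(
    net: StreamNetwork, config: SynthConfig, rng: np.random.Generator
) -> pd.DataFrame:
    """Environmental covariates trending with log10 catchment size.

    The Froude number is derived as v / sqrt(g d) from the generated
    velocity and depth (a generator convention); the cyanobacteria
    fraction is Beta-distributed independently of area.  The covariates
    are also written into each site's ``env`` map.
    """
    ids = sorted(net.sites)
    log_a = np.array([math.log10(net.site(s).catchment_area_km2) for s in ids])
    out = pd.DataFrame(index=pd.Index(ids, name="site_id"))
    for name, tr in config.covariate_trends.items():
        mean = tr["intercept"] + tr["slope"] * log_a
        vals = mean + rng.normal(0.0, tr["sd"], size=len(ids))
        if tr["scale"] == "log10":
            vals = 10.0**vals
        if name == "forest_cover":
            vals = np.clip(vals, 0.0, 1.0)
        if name == "doc":
            vals = np.maximum(vals, 0.05)
        out[name] = vals
    out["froude"] = out["velocity_ms"] / np.sqrt(_G * out["depth_m"])
    out["cyano_fraction"] = rng.beta(
        config.cyano_beta_a, config.cyano_beta_b, size=len(ids)
    )
    for sid in ids:
        net.site(sid).env.update(out.loc[sid].to_dict())
    return out


# -- metacommunity ---------------------------------------------------------


def _terrestrial_weight(
    area: float, cfg: SynthConfig, rng: np.random.Generator | None = None
) -> float:
    w = cfg.terrestrial_w0 * area ** (-cfg.terrestrial_w1)
    if rng is not None and cfg.terrestrial_weight_sd > 0:
        # site-to-site scatter in terrestrial input (divergent local flow
        # paths); multiplicative, so headwaters spread most in absolute terms
        w *= math.exp(rng.normal(0.0, cfg.terrestrial_weight_sd))
    return float(np.clip(w, 0.0, 1.0))


def generate_metacommunity(
    net: StreamNetwork, config: SynthConfig, rng: np.random.Generator
) -> tuple[OTUTable, SynthTruth]:
    """Simulate the sample x OTU count table over the network.

    Each site's relative-abundance vector is a mixture of (i) the shared
    core pool with multiplicative lognormal site noise, (ii) a
    site-specific terrestrial pool (a Dirichlet-weighted random subset of
    the satellite pool) with weight w(A), and (iii) for non-headwater
    nodes the mean of the immediate upstream communities with weight u.
    Reads are a multinomial draw at a per-site depth in
    [depth_min, depth_max].
    """
    config.validate()
    core_ids = [f"CORE{i:04d}" for i in range(config.s_core)]
    sat_ids = [f"SAT{i:04d}" for i in range(config.s_satellite)]
    all_ids = core_ids + sat_ids
    s_total = len(all_ids)

    core_abund = rng.lognormal(config.core_lognorm_mu, config.core_lognorm_sigma, config.s_core)
    core_p = core_abund / core_abund.sum()
    cyano_mask = np.zeros(s_total, dtype=bool)
    if config.cyano_n_otus:
        cyano_idx = rng.choice(config.s_core, size=config.cyano_n_otus, replace=False)
        cyano_mask[cyano_idx] = True

    comp: dict[str, np.ndarray] = {}
    counts = {}
    weights: dict[str, float] = {}
    for sid in net.upstream_order():  # children before parents
        site = net.site(sid)
        w = _terrestrial_weight(site.catchment_area_km2, config, rng)
        kids = net.children[sid]
        u = config.upstream_mass_effect if kids else 0.0
        if w + u > 1.0:
            w = 1.0 - u
        weights[sid] = w

        p = np.zeros(s_total)
        core_site = core_p * np.exp(rng.normal(0.0, config.site_noise_sigma, config.s_core))
        p[: config.s_core] = (1.0 - w - u) * core_site / core_site.sum()

        sub = rng.choice(config.s_satellite, size=config.satellite_subset, replace=False)
        local = rng.gamma(config.satellite_concentration, 1.0, config.satellite_subset)
        p[config.s_core + sub] += w * local / local.sum()

        if kids:
            # Upstream mass effect acts through the core component only:
            # downstream establishment favours the regionally well-adapted
            # core taxa, which is what enriches the core downstream.
            upstream = np.mean([comp[k] for k in kids], axis=0)
            upstream[config.s_core:] = 0.0
            if upstream.sum() > 0:
                p += u * upstream / upstream.sum()

        # impose the exogenous cyanobacteria fraction (independent of area)
        c = float(site.env.get("cyano_fraction", 0.0))
        cy_sum = p[cyano_mask].sum()
        rest_sum = p[~cyano_mask].sum()
        if cy_sum > 0 and rest_sum > 0 and 0 < c < 1:
            p[cyano_mask] *= c / cy_sum
            p[~cyano_mask] *= (1.0 - c) / rest_sum
        p /= p.sum()
        comp[sid] = p

        depth = int(rng.integers(config.depth_min, config.depth_max + 1))
        counts[sid] = rng.multinomial(depth, p)

    ids = sorted(net.sites)
    mat = pd.DataFrame(
        np.vstack([counts[s] for s in ids]),
        index=pd.Index(ids, name="sample_id"),
        columns=all_ids,
    )
    mat = mat.loc[:, mat.sum(axis=0) > 0]
    col_pos = {name: i for i, name in enumerate(all_ids)}
    flags = pd.DataFrame(
        {"is_cyanobacteria": cyano_mask[[col_pos[c] for c in mat.columns]]},
        index=pd.Index(mat.columns, name="otu_id"),
    )
    table = OTUTable(mat, flags)

    groups = net.classify_headwaters(ids)
    truth = SynthTruth(
        seed=config.seed,
        terrestrial_weight=weights,
        upstream_mass_effect=config.upstream_mass_effect,
        group_labels=groups,
        covariate_slopes={k: v["slope"] for k, v in config.covariate_trends.items()},
        config={
            k: v for k, v in dataclasses.asdict(config).items() if k != "covariate_trends"
        },
    )
    return table, truth


def simulate_survey(config: SynthConfig, outdir: str) -> tuple[StreamNetwork, OTUTable, SynthTruth]:
    """Generate and write a complete synthetic survey; deterministic per seed.

    Writes ``edges.tsv``, ``sites.tsv``, ``otu_table.tsv``,
    ``taxon_flags.tsv`` and ``truth.json`` into ``outdir``.
    """
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence([config.seed]))
    net = generate_network(config.n_headwaters, rng, config)
    generate_covariates(net, config, rng)
    table, truth = generate_metacommunity(net, config, rng)

    os.makedirs(outdir, exist_ok=True)
    write_network(net, os.path.join(outdir, "edges.tsv"), os.path.join(outdir, "sites.tsv"))
    write_otu_table(table, os.path.join(outdir, "otu_table.tsv"))
    table.taxon_flags.astype(int).to_csv(
        os.path.join(outdir, "taxon_flags.tsv"), sep="\t", index_label="otu_id"
    )
    truth.to_json(os.path.join(outdir, "truth.json"))
    return net, table, truth
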