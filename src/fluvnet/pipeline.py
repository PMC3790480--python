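"""End-to-end orchestration of the network biodiversity analysis.

``run`` executes the stages in order — network validation, rarefied
alpha-diversity profiles, confluence contrasts, downstream trend fits,
core/satellite partition, rarefaction-averaged similarity with the pair
table, permutation ANCOVA and forward selection of environmental
predictors — writing one TSV per stage plus a machine-readable
``summary.json``.  A single global seed is expanded into per-stage
substreams by stable hashing of the stage name, so each stage is
reproducible independently of execution order.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import __version__
from .alpha import INDEX_NAMES, rarefied_profile
from .ancova import ancova_F, linear_decay_fit, permutation_ancova, similarity_density
from .beta import INDICES, build_pair_table, rarefied_similarity_matrices
from .confluence import confluence_tests, delta_correlations, triplet_contrasts
from .errors import ConfigurationError, DepthError
from .network import StreamNetwork, read_network, site_env_frame
from .otu import (
    OTUTable,
    core_satellite_partition,
    cyanobacteria_fraction,
    group_read_fraction,
    read_otu_table,
)
from .selection import forward_select
from .simulate import SynthConfig, simulate_survey
from .trends import fit_location_scale, fraction_trend, percentile_curves

__all__ = ["RunConfig", "run", "stage_rng"]

log = logging.getLogger(__name__)

PHYSICAL_METRICS = ["froude", "depth_m", "velocity_ms", "slope"]
STAGES = [
    "inputs",
    "alpha",
    "confluence",
    "trends",
    "core_satellite",
    "beta",
    "ancova",
    "selection",
]


@dataclass
class RunConfig:
    """Configuration of a full pipeline run."""

    outdir: str
    seed: int = 0
    simulate: SynthConfig | None = None
    edges_path: str | None = None
    sites_path: str | None = None
    otu_path: str | None = None
    flags_path: str | None = None
    depth_policy: str = "min-sample"  # or "fixed"
    depth: int | None = None
    r_alpha: int = 100
    r_beta: int = 1000
    n_perm: int = 999
    alpha_level: float = 0.05

    def validate(self) -> None:
        if self.simulate is None and not (
            self.edges_path and self.sites_path and self.otu_path
        ):
            raise ConfigurationError(
                "either a simulate config or edges/sites/otu paths are required"
            )
        for name in ("r_alpha", "r_beta", "n_perm"):
            if getattr(self, name) < 1:
                raise ConfigurationError(f"{name} must be >= 1")
        if self.depth_policy not in ("min-sample", "fixed"):
            raise ConfigurationError(f"unknown depth policy {self.depth_policy!r}")
        if self.depth_policy == "fixed" and not self.depth:
            raise ConfigurationError("fixed depth policy requires a depth")


def stage_rng(seed: int, stage: str) -> np.random.Generator:
    """Per-stage generator: global seed + CRC32 of the stage name."""
    return np.random.default_rng(
        np.random.SeedSequence([seed, zlib.crc32(stage.encode())])
    )


def _load_inputs(cfg: RunConfig) -> tuple[StreamNetwork, OTUTable]:
    if cfg.simulate is not None:
        sim_cfg = dataclasses.replace(cfg.simulate, seed=cfg.seed)
        net, table, _ = simulate_survey(sim_cfg, os.path.join(cfg.outdir, "inputs"))
        return net, table
    net = read_network(cfg.edges_path, cfg.sites_path)
    table = read_otu_table(cfg.otu_path, cfg.flags_path)
    return net, table


def run(cfg: RunConfig) -> dict:
    """Execute every stage and return the summary dictionary."""
    cfg.validate()
    os.makedirs(cfg.outdir, exist_ok=True)
    summary: dict = {
        "fluvnet_version": __version__,
        "seed": cfg.seed,
        "numpy_version": np.__version__,
    }

    # ---- stage: inputs ----------------------------------------------------
    net, table = _load_inputs(cfg)
    sampled = [s for s in table.sample_ids if s in net]
    missing = set(table.sample_ids) - set(sampled)
    if missing:
        raise ConfigurationError(f"samples without a network site: {sorted(missing)[:5]}")
    totals = table.sample_totals
    if cfg.depth_policy == "fixed":
        m = int(cfg.depth)
        shallow = totals.index[totals < m].tolist()
        if shallow:
            raise DepthError(f"samples below fixed depth {m}: {shallow}")
    else:
        m = int(totals.min())
    env = site_env_frame(net, sampled)
    orders = net.strahler_orders()
    groups = net.classify_headwaters(sampled)
    summary["inputs"] = {
        "n_sites": len(sampled),
        "depth": m,
        "n_otus": len(table.otu_ids),
        "total_reads": int(totals.sum()),
        "n_headwaters": sum(1 for g in groups.values() if g == "headwater"),
        "n_midsized": sum(1 for g in groups.values() if g == "midsized"),
        "strahler_order_range": [int(min(orders.values())), int(max(orders.values()))],
    }
    log.info("inputs: %s", summary["inputs"])

    # ---- stage: alpha -----------------------------------------------------
    profile = rarefied_profile(table, m, cfg.r_alpha, stage_rng(cfg.seed, "alpha"))
    profile.to_frame().to_csv(
        os.path.join(cfg.outdir, "alpha_diversity.tsv"), sep="\t", index_label="sample_id"
    )
    summary["alpha"] = {
        "depth": m,
        "resamples": cfg.r_alpha,
        "mean": {k: float(profile.values[k].mean()) for k in INDEX_NAMES},
    }

    # ---- stage: confluence ------------------------------------------------
    triplets = net.find_triplets(sampled)
    metrics = profile.values.join(env[PHYSICAL_METRICS])
    contrasts = triplet_contrasts(triplets, metrics)
    tests = confluence_tests(contrasts)
    correlations = delta_correlations(contrasts, INDEX_NAMES, PHYSICAL_METRICS)
    contrasts.to_csv(os.path.join(cfg.outdir, "confluence_contrasts.tsv"), sep="\t", index=False)
    tests.to_csv(os.path.join(cfg.outdir, "confluence_tests.tsv"), sep="\t", index=False)
    correlations.to_csv(
        os.path.join(cfg.outdir, "confluence_correlations.tsv"), sep="\t", index=False
    )
    summary["confluence"] = {
        "n_triplets": len(triplets),
        "wilcoxon": {
            r["metric"]: {"W": r["W"], "p": r["p"], "median_delta": r["median_delta"]}
            for r in tests.to_dict("records")
        },
    }

    # ---- stage: trends ----------------------------------------------------
    log_a = np.log10(env["catchment_area_km2"].to_numpy())
    trend_rows = []
    curve_frames = []
    x_grid = np.linspace(log_a.min(), log_a.max(), 100)
    summary["trends"] = {}
    for index in INDEX_NAMES:
        y = profile.values[index].reindex(env.index).to_numpy()
        fit = fit_location_scale(log_a, y, response=index)
        trend_rows.append(
            {
                "response": index,
                "beta0": fit.beta[0],
                "beta1": fit.beta1,
                "gamma0": fit.gamma[0],
                "gamma1": fit.gamma1,
                "loglik": fit.loglik,
                "p_location": fit.p_location,
                "p_scale": fit.p_scale,
                "converged": fit.converged,
            }
        )
        curves = percentile_curves(fit, x_grid)
        cf = pd.DataFrame({"log10_area": x_grid, "response": index})
        for level, vals in curves.items():
            cf[f"p{level:g}"] = vals
        cf["mu"] = fit.mu(x_grid)
        curve_frames.append(cf)
        summary["trends"][index] = {
            "beta1": fit.beta1,
            "gamma1": fit.gamma1,
            "p_location": fit.p_location,
            "p_scale": fit.p_scale,
        }
    pd.DataFrame(trend_rows).to_csv(
        os.path.join(cfg.outdir, "trend_fits.tsv"), sep="\t", index=False
    )
    pd.concat(curve_frames).to_csv(
        os.path.join(cfg.outdir, "percentile_curves.tsv"), sep="\t", index=False
    )

    # ---- stage: core_satellite ---------------------------------------------
    part = core_satellite_partition(table)
    core_frac = group_read_fraction(table, part.core_otus)
    frac_df = pd.DataFrame(
        {
            "core_fraction": core_frac,
            "satellite_fraction": 1.0 - core_frac,
            "log10_area": log_a,
        },
        index=env.index,
    )
    core_trend = fraction_trend(frac_df["core_fraction"].to_numpy(), log_a)
    frac_df.to_csv(os.path.join(cfg.outdir, "core_satellite_fractions.tsv"), sep="\t")
    summary["core_satellite"] = {
        "n_core": len(part.core_otus),
        "n_satellite": len(part.satellite_otus),
        "core_fraction_mean": float(core_frac.mean()),
        "core_fraction_sd": float(core_frac.std(ddof=1)),
        "core_trend": core_trend,
    }

    # ---- stage: beta --------------------------------------------------------
    matrices = rarefied_similarity_matrices(
        table, m, cfg.r_beta, stage_rng(cfg.seed, "beta")
    )
    for name, sim in matrices.items():
        sim.values.to_csv(
            os.path.join(cfg.outdir, f"similarity_{name}.tsv"), sep="\t", index_label="site_id"
        )
    pair_table = build_pair_table(net, groups, matrices, sampled)
    pair_table.to_csv(os.path.join(cfg.outdir, "pair_table.tsv"), sep="\t", index=False)
    summary["beta"] = {
        "resamples": cfg.r_beta,
        "n_pairs_hh": int((pair_table["group"] == "HH").sum()),
        "n_pairs_mm": int((pair_table["group"] == "MM").sum()),
        "mean_similarity": {
            name: {
                grp: float(pair_table.loc[pair_table["group"] == grp, name].mean())
                for grp in ("HH", "MM")
            }
            for name in INDICES
        },
    }

    # ---- stage: ancova -------------------------------------------------------
    rng_anc = stage_rng(cfg.seed, "ancova")
    ancova_rows = []
    density_frames = []
    summary["ancova"] = {}
    for index in INDICES:
        for metric in ("d_hydro_m", "d_euclid_m"):
            res = permutation_ancova(
                pair_table,
                matrices[index].values,
                index,
                metric,
                n_perm=cfg.n_perm,
                rng=rng_anc,
            )
            row = {
                "index": index,
                "distance": metric,
                "F_distance": res.F_distance,
                "F_group": res.F_group,
                "p_distance": res.p_distance,
                "p_group": res.p_group,
                "n_perm": res.n_perm,
            }
            for grp, fitd in res.group_fits.items():
                row[f"slope_{grp}"] = fitd["slope"]
                row[f"intercept_{grp}"] = fitd["intercept"]
            ancova_rows.append(row)
            summary["ancova"][f"{index}:{metric}"] = {
                "F_distance": res.F_distance,
                "F_group": res.F_group,
                "p_distance": res.p_distance,
                "p_group": res.p_group,
            }
        for grp in ("HH", "MM"):
            vals = pair_table.loc[pair_table["group"] == grp, index].to_numpy()
            if np.unique(vals).size >= 2:
                grid, dens = similarity_density(vals)
                density_frames.append(
                    pd.DataFrame(
                        {"index": index, "group": grp, "similarity": grid, "density": dens}
                    )
                )
    pd.DataFrame(ancova_rows).to_csv(
        os.path.join(cfg.outdir, "ancova_results.tsv"), sep="\t", index=False
    )
    if density_frames:
        pd.concat(density_frames).to_csv(
            os.path.join(cfg.outdir, "similarity_density.tsv"), sep="\t", index=False
        )

    # ---- stage: selection -----------------------------------------------------
    recipients = {t.recipient for t in triplets}
    tributaries = {t.tributary_a for t in triplets} | {t.tributary_b for t in triplets}
    position = pd.Series(
        [1.0 if s in recipients else 0.0 for s in env.index], index=env.index
    )
    candidates = pd.DataFrame(
        {
            "catchment_size_log10": log_a,
            "position_to_confluence": position,
        },
        index=env.index,
    )
    for c in ("suva254", "doc", "slope", "froude", "forest_cover"):
        if c in env.columns:
            candidates[c] = env[c]
    try:
        candidates["cyanobacteria"] = cyanobacteria_fraction(table).reindex(env.index)
    except ConfigurationError:
        log.info("no cyanobacteria flags available; candidate skipped")
    # only triplet members have a defined confluence position
    if not (recipients or tributaries):
        candidates = candidates.drop(columns=["position_to_confluence"])

    selection_rows = []
    summary["selection"] = {}
    for index in INDEX_NAMES:
        y = profile.values[index].reindex(env.index).to_numpy()
        res = forward_select(
            y, candidates, alpha=cfg.alpha_level, response=index
        )
        for rec in res.to_frame().to_dict("records"):
            rec["response"] = index
            selection_rows.append(rec)
        summary["selection"][index] = {
            "selected": res.selected,
            "cumulative_r2": res.cumulative_r2,
            "b": {v: float(res.coefficients[v]) for v in res.selected},
        }
    pd.DataFrame(
        selection_rows, columns=["response", "variable", "cumulative_r2", "entry_p", "b"]
    ).to_csv(os.path.join(cfg.outdir, "env_selection.tsv"), sep="\t", index=False)

    with open(os.path.join(cfg.outdir, "summary.json"), "w") as fh:
        json.dump(summary, fh, indent=1, sort_keys=True, default=float)
    log.info("run complete: %s", cfg.outdir)
    return summary
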