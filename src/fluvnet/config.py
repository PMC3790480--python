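"""YAML configuration loading for the CLI.

A run config file has the shape::

    seed: 1
    outdir: results/run1
    simulate:            # either a generator block ...
      n_headwaters: 57
      terrestrial_w0: 0.45
    inputs:              # ... or explicit input paths
      edges: edges.tsv
      sites: sites.tsv
      otu_table: otu_table.tsv
      taxon_flags: taxon_flags.tsv
    depth_policy: min-sample
    r_alpha: 100
    r_beta: 1000
    n_perm: 999
    alpha_level: 0.05
"""

from __future__ import annotations

import dataclasses

import yaml

from .errors import ConfigurationError
from .pipeline import RunConfig
from .simulate import SynthConfig

__all__ = ["load_run_config", "load_synth_config"]


def _build(cls, data: dict, context: str):
    valid = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - valid
    if unknown:
        raise ConfigurationError(f"unknown {context} keys: {sorted(unknown)}")
    return cls(**data)


def load_synth_config(data: dict | str) -> SynthConfig:
    if isinstance(data, str):
        with open(data) as fh:
            data = yaml.safe_load(fh) or {}
        data = data.get("simulate", data)
    return _build(SynthConfig, data, "simulate")


def load_run_config(path: str, outdir: str | None = None, seed: int | None = None) -> RunConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    sim = data.pop("simulate", None)
    inputs = data.pop("inputs", {}) or {}
    kwargs = dict(
        outdir=outdir or data.pop("outdir", "fluvnet_out"),
        simulate=load_synth_config(sim) if sim is not None else None,
        edges_path=inputs.get("edges"),
        sites_path=inputs.get("sites"),
        otu_path=inputs.get("otu_table"),
        flags_path=inputs.get("taxon_flags"),
    )
    kwargs.update(data)
    if seed is not None:
        kwargs["seed"] = seed
    cfg = _build(RunConfig, kwargs, "run")
    if cfg.simulate is not None and seed is not None:
        cfg.simulate.seed = seed
    return cfg
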