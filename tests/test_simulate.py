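"""Synthetic survey generator: topology, covariates, metacommunity
structure and determinism."""

import dataclasses
import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from fluvnet.alpha import rarefied_profile
from fluvnet.beta import morisita_horn, sorensen
from fluvnet.errors import ConfigurationError
from fluvnet.otu import rarefy
from fluvnet.simulate import (
    SynthConfig,
    generate_covariates,
    generate_metacommunity,
    generate_network,
    simulate_survey,
)


def _small_cfg(seed=0, **kw):
    base = dict(
        n_headwaters=12,
        add_outlet_site=False,
        depth_min=800,
        depth_max=1600,
        s_core=80,
        s_satellite=300,
        satellite_subset=60,
        cyano_n_otus=5,
        seed=seed,
    )
    base.update(kw)
    return SynthConfig(**base)


class TestNetworkGeneration:
    def test_two_headwaters_give_three_sites_order_two(self):
        rng = np.random.default_rng(0)
        net = generate_network(2, rng, _small_cfg())
        assert len(net) == 3
        assert net.strahler_orders()[net.outlet] == 2

    def test_node_count_is_2n_minus_1(self):
        rng = np.random.default_rng(1)
        net = generate_network(57, rng, SynthConfig(add_outlet_site=False))
        leaves = [s for s in net.sites if not net.children[s]]
        junctions = [s for s in net.sites if net.children[s]]
        assert len(leaves) == 57
        assert len(junctions) == 56
        assert len(net) == 113

    def test_outlet_site_option_adds_one(self):
        rng = np.random.default_rng(2)
        net = generate_network(57, rng, SynthConfig(add_outlet_site=True))
        assert len(net) == 114

    @pytest.mark.parametrize("seed", range(8))
    def test_areas_nondecreasing_downstream(self, seed):
        rng = np.random.default_rng(seed)
        net = generate_network(int(rng.integers(3, 30)), rng, _small_cfg())
        for child, parent in net.parent.items():
            assert (
                net.site(parent).catchment_area_km2
                >= net.site(child).catchment_area_km2
            )


class TestCovariates:
    def test_zero_noise_gives_perfect_monotone_suva(self):
        cfg = _small_cfg()
        for tr in cfg.covariate_trends.values():
            tr["sd"] = 0.0
        rng = np.random.default_rng(3)
        net = generate_network(12, rng, cfg)
        env = generate_covariates(net, cfg, rng)
        log_a = np.log10([net.site(s).catchment_area_km2 for s in env.index])
        rho, _ = stats.spearmanr(env["suva254"], log_a)
        assert rho == pytest.approx(-1.0)

    def test_configured_slopes_recovered_by_ols(self):
        cfg = SynthConfig(seed=0)
        slopes = []
        for seed in range(25):
            rng = np.random.default_rng(seed)
            net = generate_network(40, rng, cfg)
            env = generate_covariates(net, cfg, rng)
            log_a = np.log10([net.site(s).catchment_area_km2 for s in env.index])
            slopes.append(stats.linregress(log_a, env["suva254"]).slope)
        slopes = np.array(slopes)
        se = slopes.std(ddof=1) / np.sqrt(len(slopes))
        assert abs(slopes.mean() - cfg.covariate_trends["suva254"]["slope"]) < 3 * se

    def test_froude_increases_and_cyano_independent_of_area(self):
        cfg = SynthConfig(seed=0)
        rng = np.random.default_rng(4)
        net = generate_network(57, rng, cfg)
        env = generate_covariates(net, cfg, rng)
        log_a = np.log10([net.site(s).catchment_area_km2 for s in env.index])
        rho_f, p_f = stats.spearmanr(env["froude"], log_a)
        assert rho_f > 0 and p_f < 0.01
        rho_c, _ = stats.spearmanr(env["cyano_fraction"], log_a)
        assert abs(rho_c) < 0.2


class TestMetacommunity:
    def test_pure_core_gives_near_identical_communities(self):
        cfg = _small_cfg(terrestrial_w0=0.0, upstream_mass_effect=0.0,
                         site_noise_sigma=0.0, terrestrial_weight_sd=0.0,
                         cyano_n_otus=0, depth_min=5000, depth_max=5000)
        rng = np.random.default_rng(5)
        net = generate_network(12, rng, cfg)
        generate_covariates(net, cfg, rng)
        table, _ = generate_metacommunity(net, cfg, rng)
        ids = table.sample_ids
        x = table.counts.loc[ids[0]].to_numpy()
        y = table.counts.loc[ids[5]].to_numpy()
        assert morisita_horn(x, y) > 0.98  # 1 - O(1/depth)

    def test_disjoint_terrestrial_pools_make_dissimilar_headwaters(self):
        cfg = _small_cfg(terrestrial_w0=1.0, terrestrial_w1=0.0,
                         terrestrial_weight_sd=0.0, upstream_mass_effect=0.0,
                         cyano_n_otus=0, s_satellite=1000, satellite_subset=25)
        rng = np.random.default_rng(6)
        net = generate_network(12, rng, cfg)
        generate_covariates(net, cfg, rng)
        table, _ = generate_metacommunity(net, cfg, rng)
        leaves = [s for s in table.sample_ids if not net.children[s]]
        x = table.counts.loc[leaves[0]].to_numpy()
        y = table.counts.loc[leaves[1]].to_numpy()
        # 25-species subsets of a 1000-species pool rarely overlap
        assert sorensen(x, y) < 0.15

    def test_headwaters_richer_and_less_similar_than_midstream(self):
        hits_alpha = hits_beta = 0
        n_seeds = 6
        for seed in range(n_seeds):
            cfg = SynthConfig(seed=seed)
            net, table, truth = simulate_survey(cfg, f"/tmp/fluvnet_struct_{seed}")
            m = int(table.sample_totals.min())
            prof = rarefied_profile(table, m, 20, np.random.default_rng(0))
            groups = truth.group_labels
            hw = [s for s, g in groups.items() if g == "headwater"]
            mid = [s for s, g in groups.items() if g == "midsized"]
            hits_alpha += (
                prof.values.loc[hw, "richness"].mean()
                > prof.values.loc[mid, "richness"].mean()
            )
            rng = np.random.default_rng(1)
            rar = {s: rarefy(table.counts.loc[s].to_numpy(), m, rng) for s in hw[:20] + mid[:20]}
            import itertools

            def mean_sim(sites):
                return np.mean(
                    [
                        morisita_horn(rar[a], rar[b])
                        for a, b in itertools.combinations(sites, 2)
                        if not net.flow_connected(a, b)
                    ]
                )

            hits_beta += mean_sim(hw[:20]) < mean_sim(mid[:20])
        assert hits_alpha == n_seeds
        assert hits_beta == n_seeds

    def test_steeper_terrestrial_decay_steepens_core_trend(self):
        from fluvnet.otu import core_satellite_partition, group_read_fraction
        from fluvnet.trends import fraction_trend

        med_slopes = []
        for w1 in (0.3, 0.6, 0.9):
            slopes = []
            for seed in range(3):
                cfg = _small_cfg(seed=seed, n_headwaters=20, terrestrial_w1=w1)
                rng = np.random.default_rng(np.random.SeedSequence([seed]))
                net = generate_network(20, rng, cfg)
                generate_covariates(net, cfg, rng)
                table, _ = generate_metacommunity(net, cfg, rng)
                log_a = np.log10(
                    [net.site(s).catchment_area_km2 for s in table.sample_ids]
                )
                part = core_satellite_partition(table)
                frac = group_read_fraction(table, part.core_otus).to_numpy()
                slopes.append(fraction_trend(frac, log_a)["slope"])
            med_slopes.append(np.median(slopes))
        assert med_slopes[0] < med_slopes[1] < med_slopes[2]


class TestSurveyFiles:
    def test_same_seed_identical_files(self, tmp_path):
        cfg = _small_cfg(seed=11)
        d1, d2 = tmp_path / "a", tmp_path / "b"
        simulate_survey(cfg, str(d1))
        simulate_survey(dataclasses.replace(cfg), str(d2))
        for name in ("edges.tsv", "sites.tsv", "otu_table.tsv", "taxon_flags.tsv", "truth.json"):
            h1 = hashlib.sha256((d1 / name).read_bytes()).hexdigest()
            h2 = hashlib.sha256((d2 / name).read_bytes()).hexdigest()
            assert h1 == h2, name

    def test_default_config_writes_114_sites_and_triplets(self, tmp_path):
        net, table, truth = simulate_survey(SynthConfig(seed=3), str(tmp_path / "s"))
        sites = pd.read_csv(tmp_path / "s" / "sites.tsv", sep="\t")
        assert len(sites) == 114
        triplets = net.find_triplets(table.sample_ids)
        assert len(triplets) >= 30
        assert table.sample_totals.min() >= 4698

    def test_emitted_tables_pass_validators(self, tmp_path):
        from fluvnet.network import read_network
        from fluvnet.otu import read_otu_table

        cfg = _small_cfg(seed=13)
        simulate_survey(cfg, str(tmp_path))
        net = read_network(str(tmp_path / "edges.tsv"), str(tmp_path / "sites.tsv"))
        table = read_otu_table(
            str(tmp_path / "otu_table.tsv"), str(tmp_path / "taxon_flags.tsv")
        )
        assert set(table.sample_ids) <= set(net.sites)
        truth = json.loads((tmp_path / "truth.json").read_text())
        groups = net.classify_headwaters(table.sample_ids)
        assert groups == truth["group_labels"]

    def test_invalid_config_rejected(self):
        with pytest.raises(ConfigurationError):
            SynthConfig(upstream_mass_effect=1.2).validate()
        with pytest.raises(ConfigurationError):
            SynthConfig(satellite_subset=10_000).validate()
        with pytest.raises(ConfigurationError):
            SynthConfig(cyano_n_otus=-1).validate()
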