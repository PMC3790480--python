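"""Distance decay, sequential-SS ANCOVA, permutation null and KDE."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from fluvnet.ancova import (
    ancova_F,
    linear_decay_fit,
    nrr_bandwidth,
    permutation_ancova,
    similarity_density,
)
from fluvnet.errors import ConfigurationError


def _pairs(d, g, y):
    groups = np.where(np.asarray(g) > 0, "MM", "HH")
    n = len(d)
    return pd.DataFrame(
        {
            "site_a": [f"a{i}" for i in range(n)],
            "site_b": [f"b{i}" for i in range(n)],
            "group": groups,
            "d_hydro_m": d,
            "d_euclid_m": d,
            "sim": y,
        }
    )


class TestLinearDecay:
    def test_constant_similarity_zero_slope(self):
        pairs = _pairs(np.arange(10.0), np.zeros(10), np.full(10, 0.6))
        fit = linear_decay_fit(pairs, "HH", "sim")
        assert fit["slope"] == pytest.approx(0.0)
        assert fit["r2"] == pytest.approx(0.0)

    def test_exact_line_recovered(self):
        d = np.linspace(0, 30000, 25)
        y = 0.9 - 1e-5 * d
        fit = linear_decay_fit(_pairs(d, np.zeros(25), y), "HH", "sim")
        assert fit["slope"] == pytest.approx(-1e-5, abs=1e-10)
        assert fit["intercept"] == pytest.approx(0.9, abs=1e-10)

    def test_matches_closed_form_ols(self):
        rng = np.random.default_rng(0)
        d = rng.uniform(0, 1e4, 40)
        y = rng.uniform(0, 1, 40)
        fit = linear_decay_fit(_pairs(d, np.zeros(40), y), "HH", "sim")
        slope = np.cov(d, y, ddof=1)[0, 1] / np.var(d, ddof=1)
        assert fit["slope"] == pytest.approx(slope)
        assert fit["intercept"] == pytest.approx(y.mean() - slope * d.mean())


class TestSequentialF:
    def test_matches_hand_computed_anova_table(self):
        # 8 pairs, additive construction with known sequential SS
        d = np.array([0.0, 1, 2, 3, 0, 1, 2, 3])
        g = np.array([0.0, 0, 0, 0, 1, 1, 1, 1])
        y = 0.8 - 0.05 * d - 0.2 * g + np.array([1, -1, 1, -1, -1, 1, -1, 1]) * 0.01
        pairs = _pairs(d, g, y)
        f_d, f_g = ancova_F(pairs, "sim")
        # brute-force sequential sums of squares via explicit projections
        n = len(y)

        def rss(x):
            beta, *_ = np.linalg.lstsq(x, y, rcond=None)
            return float(np.sum((y - x @ beta) ** 2))

        x0 = np.ones((n, 1))
        x1 = np.column_stack([np.ones(n), d])
        x2 = np.column_stack([np.ones(n), d, g])
        ss_d = rss(x0) - rss(x1)
        ss_g = rss(x1) - rss(x2)
        ms_resid = rss(x2) / (n - 3)
        assert f_d == pytest.approx(ss_d / ms_resid)
        assert f_g == pytest.approx(ss_g / ms_resid)

    def test_f_group_equals_squared_t_when_balanced_centred(self):
        rng = np.random.default_rng(1)
        n = 60
        d = np.tile(rng.uniform(-1, 1, n // 2), 2)
        d = d - d.mean()
        g = np.repeat([0.0, 1.0], n // 2)
        y = 0.5 + 0.1 * d - 0.15 * g + rng.normal(0, 0.05, n)
        _, f_g = ancova_F(_pairs(d, g, y), "sim")
        x = np.column_stack([np.ones(n), d, g])
        beta, *_ = np.linalg.lstsq(x, y, rcond=None)
        resid = y - x @ beta
        sigma2 = resid @ resid / (n - 3)
        cov = sigma2 * np.linalg.inv(x.T @ x)
        t = beta[2] / np.sqrt(cov[2, 2])
        assert f_g == pytest.approx(t**2, rel=1e-6)

    def test_single_group_rejected(self):
        pairs = _pairs(np.arange(5.0), np.zeros(5), np.ones(5) * 0.5)
        with pytest.raises(ConfigurationError):
            ancova_F(pairs, "sim")


def _exchangeable_setup(rng, n_sites=16):
    ids = [f"s{i}" for i in range(n_sites)]
    base = rng.uniform(0.2, 0.8, size=(n_sites, n_sites))
    sim = (base + base.T) / 2
    np.fill_diagonal(sim, 1.0)
    sim_df = pd.DataFrame(sim, index=ids, columns=ids)
    groups = np.array(["HH"] * (n_sites // 2) + ["MM"] * (n_sites - n_sites // 2))
    rng.shuffle(groups)
    rows = []
    for i in range(n_sites):
        for j in range(i + 1, n_sites):
            if groups[i] != groups[j]:
                continue
            rows.append(
                {
                    "site_a": ids[i],
                    "site_b": ids[j],
                    "group": groups[i],
                    "d_hydro_m": rng.uniform(100, 5000),
                    "d_euclid_m": rng.uniform(100, 5000),
                }
            )
    return pd.DataFrame(rows), sim_df


class TestPermutationAncova:
    def test_seed_determinism(self):
        rng = np.random.default_rng(12)
        pairs, sim = _exchangeable_setup(rng)
        res_a = permutation_ancova(pairs, sim, index="i", n_perm=99, rng=np.random.default_rng(5))
        res_b = permutation_ancova(pairs, sim, index="i", n_perm=99, rng=np.random.default_rng(5))
        assert res_a.p_group == res_b.p_group
        assert res_a.p_distance == res_b.p_distance

    def test_complete_separation_reaches_floor(self):
        # all HH similarities low, all MM high, distances neutral; with
        # 10+10 sites a random permutation reproducing the partition (the
        # only way to attain F_obs) has probability ~1e-5
        rng = np.random.default_rng(2)
        n = 20
        ids = [f"s{i}" for i in range(n)]
        groups = ["HH"] * (n // 2) + ["MM"] * (n // 2)
        sim = np.zeros((n, n))
        for i in range(n):
            for j in range(n):
                if i == j:
                    sim[i, j] = 1.0
                elif groups[i] == groups[j] == "HH":
                    sim[i, j] = 0.2
                elif groups[i] == groups[j] == "MM":
                    sim[i, j] = 0.8
                else:
                    sim[i, j] = 0.5
        sim_df = pd.DataFrame(sim, index=ids, columns=ids)
        rows = []
        for i in range(n):
            for j in range(i + 1, n):
                if groups[i] == groups[j]:
                    rows.append(
                        {
                            "site_a": ids[i],
                            "site_b": ids[j],
                            "group": groups[i],
                            "d_hydro_m": rng.uniform(100, 200),
                            "d_euclid_m": rng.uniform(100, 200),
                        }
                    )
        pairs = pd.DataFrame(rows)
        res = permutation_ancova(
            pairs, sim_df, index="separated", distance="d_hydro_m", n_perm=999,
            rng=np.random.default_rng(3),
        )
        assert res.p_group == pytest.approx(1.0 / 1000.0)

    def test_relabelling_invariance(self):
        rng = np.random.default_rng(9)
        pairs, sim = _exchangeable_setup(rng)
        res1 = permutation_ancova(pairs, sim, index="i", n_perm=199, rng=np.random.default_rng(7))
        # apply a consistent site relabelling to matrix and pair table
        ids = list(sim.index)
        mapping = {old: f"r{k}" for k, old in enumerate(ids)}
        sim2 = sim.copy()
        sim2.index = [mapping[i] for i in sim.index]
        sim2.columns = [mapping[c] for c in sim.columns]
        pairs2 = pairs.copy()
        pairs2["site_a"] = pairs2["site_a"].map(mapping)
        pairs2["site_b"] = pairs2["site_b"].map(mapping)
        res2 = permutation_ancova(pairs2, sim2, index="i", n_perm=199, rng=np.random.default_rng(7))
        assert res1.p_group == res2.p_group
        assert res1.F_group == pytest.approx(res2.F_group)


class TestSimilarityDensity:
    def test_bandwidth_formula(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=100)
        x = (x - x.mean()) / x.std(ddof=1)
        sd = x.std(ddof=1)
        iqr = np.subtract(*np.percentile(x, [75, 25]))
        sigma = min(sd, iqr / 1.349)
        assert nrr_bandwidth(x) == pytest.approx(1.06 * sigma * 100 ** (-0.2))

    def test_density_integrates_to_one(self):
        rng = np.random.default_rng(1)
        grid, dens = similarity_density(rng.beta(2, 3, size=400))
        assert np.trapezoid(dens, grid) == pytest.approx(1.0, abs=1e-3)

    def test_kde_consistency_on_standard_normal(self):
        rng = np.random.default_rng(2)
        grid, dens = similarity_density(rng.normal(size=10_000), n_grid=256)
        phi = stats.norm.pdf(grid)
        assert np.max(np.abs(dens - phi)) < 0.02

    def test_degenerate_input_raises(self):
        with pytest.raises(ValueError):
            similarity_density(np.ones(10))
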