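# fluvnet

Network-scale analysis of microbial biodiversity in dendritic river
systems, for microbial ecologists working with amplicon OTU tables
sampled across a stream network.

River networks accumulate water downstream, but microbial diversity in
benthic biofilms need not follow: terrestrial inputs make headwaters
locally rich and compositionally idiosyncratic, while downstream
communities converge on a regional core. `fluvnet` implements the full
analysis chain for testing these patterns on a survey of *n* sites over
a rooted stream network:

* **Alpha diversity** as Hill numbers ⁰D (richness), ¹D = exp(H) (Shannon
  diversity) and ²D = 1/Σpᵢ² (Simpson diversity), with relative
  logarithmic evenness RLE_{a,b} = ln(ᵇD)/ln(ᵃD) (RLE₀,₁ = Pielou's J′),
  averaged over repeated rarefaction (sampling without replacement) to a
  common read depth.
* **Confluence contrasts** — paired Wilcoxon signed-rank tests of each
  recipient stream against the mean of its two tributaries, and Spearman
  correlations of diversity shifts with hydromorphic shifts.
* **Downstream trends** — Gaussian location-scale regression
  y ~ N(β₀+β₁x, exp(γ₀+γ₁x)²) on x = log₁₀ catchment area, testing the
  decline of both the mean (β₁) and the dispersion (γ₁) with 1-df
  likelihood-ratio tests, plus Gaussian percentile curves.
* **Core/satellite partition** — OTUs present in ≥50% of samples are
  core; per-sample core read fractions are regressed on log₁₀ area.
* **Beta diversity** — Sørensen, Horn and Morisita–Horn pairwise
  similarities, each matrix entry averaged over 1000 paired
  rarefactions; flow-connected site pairs are excluded, and
  headwater–headwater vs midsized–midsized similarity is tested with a
  permutation ANCOVA (sequential sums of squares, distance first;
  999 permutations of the site→community assignment).
* **Environmental forward selection** with partial standardized
  regression coefficients.
* **A synthetic survey generator** — random bifurcating networks,
  covariates trending with catchment size, and a metacommunity mixing a
  shared core pool, site-specific terrestrial pools that decay
  downstream as w(A) = w₀·A^(−w₁), and an upstream mass effect — used to
  validate every stage against known ground truth.

See `docs/methods.md` for the models, assumptions and numerical choices.

## Worked example

Simulate a survey at the default design (114 sites, ≥4698 reads per
sample) and run every stage:

```python
from fluvnet import RunConfig, SynthConfig, run

summary = run(RunConfig(outdir="out", seed=1, simulate=SynthConfig(),
                        r_alpha=100, r_beta=1000, n_perm=999))

tr = summary["trends"]["shannon_diversity"]
print(f"Shannon location slope {tr['beta1']:.1f} (p={tr['p_location']:.1e}), "
      f"scale slope {tr['gamma1']:.2f} (p={tr['p_scale']:.1e})")
ms = summary["beta"]["mean_similarity"]["sorensen"]
print(f"mean Sorensen: headwaters {ms['HH']:.2f} vs mid-sized {ms['MM']:.2f}")
print("ANCOVA p_group:", summary["ancova"]["sorensen:d_hydro_m"]["p_group"])
```

prints

```
Shannon location slope -53.7 (p=7.4e-20), scale slope -0.39 (p=6.3e-04)
mean Sorensen: headwaters 0.41 vs mid-sized 0.55
ANCOVA p_group: 0.001
```

i.e. on this synthetic survey Shannon diversity falls by ~54 effective
OTUs per tenfold increase in catchment area and its spread contracts
(both significant); headwater communities are less similar to each other
than mid-sized-stream communities are, and the group difference survives
controlling for distance (permutation p at its floor, 1/1000).

The same pipeline runs from the shell on files
(`edges.tsv`, `sites.tsv`, `otu_table.tsv`, `taxon_flags.tsv`):

```bash
fluvnet simulate --seed 1 --out survey/
fluvnet validate --in survey/
fluvnet run-all --config run.yaml --seed 1 --out out/
fluvnet report --in out/
```

Stage subcommands (`alpha`, `confluence`, `trend`, `beta`, `ancova`,
`select`) re-run a single stage from saved intermediates; `report`
renders trend, confluence and distance-decay figures. Every stage writes
TSV outputs plus a machine-readable `summary.json`; all randomness is
controlled by one seed expanded into per-stage substreams.

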