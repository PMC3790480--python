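# Methods

`fluvnet` analyses microbial community tables sampled over a dendritic
stream network. This note records the models, the estimators, the
numerical choices, and what the synthetic data generator does and does
not emulate.

## Network model

A survey is a rooted tree: sites are nodes, edges point downstream
(child → parent), the root is the catchment outlet. Validation enforces
a single outlet, at most two upstream branches per junction, strictly
positive edge lengths, and catchment area non-decreasing downstream.

* **Strahler order** — leaves are order 1; two equal orders *i* merging
  give *i*+1, unequal orders carry the larger through; a pass-through
  node keeps the upstream order.
* **Flow connectivity** — two sites are flow-connected iff one lies on
  the other's downstream path to the outlet.
* **Hydrologic distance** — along-network path length through the lowest
  common downstream junction; Euclidean distance is the planar chord.
  When coordinates embed edges as straight segments the chord never
  exceeds the path length.
* **Headwater rule** — the threshold *T* is the largest catchment area
  among sampled first-order sites; a site is a headwater iff its area
  ≤ *T* (inclusive, so the defining first-order site itself is a
  headwater), all others are mid-sized streams.
* **Confluence triplets** — a junction qualifies when both immediate
  upstream neighbours are sampled and a sampled recipient exists at or
  below the junction (the nearest one; ties between junctions claiming
  the same recipient go to the closer junction, keeping recipients
  disjoint).

## Alpha diversity

Diversity is reported as Hill numbers (effective species counts):
⁰D = richness, ¹D = exp(Shannon entropy), ²D = inverse Simpson
concentration, always on natural logarithms (the number equivalents are
base-invariant). Evenness is the relative logarithmic evenness
RLE_{a,b} = ln(ᵇD)/ln(ᵃD); RLE₀,₁ equals Pielou's J′ and is undefined
(returned as NaN with a warning) for single-OTU communities.

To remove sequencing-effort bias every sample is rarefied — subsampled
without replacement (multivariate hypergeometric) — to a common depth
*m*, by default the minimum sample total. Profile entries are means over
R independent rarefactions (default R = 100, configurable) with
Monte-Carlo standard errors; a sample already at depth *m* is evaluated
once. The closed form E[S_m] = Σᵢ (1 − C(N−Nᵢ, m)/C(N, m)) serves as the
independent oracle for the rarefied richness.

## Beta similarity

Three pairwise overlap indices with increasing weight on dominant taxa:
Sørensen 2a/(2a+b+c) on presences; Horn
1 − [2H(m̄) − H(p) − H(q)]/(2 ln 2) with m̄ = (p+q)/2 on relative
abundances; Morisita–Horn 2Σpq/(Σp² + Σq²). Matrix entries are averages
over R rarefaction replicates (default R = 1000); within a replicate
every sample is rarefied independently, and all pairs are evaluated on
the same replicate's draws. This preserves the per-pair marginal
distribution of the pair-at-a-time estimator while making the all-pairs
computation tractable at survey scale.

The analysis pair table keeps only same-group (headwater–headwater or
midsized–midsized) pairs that are **not** flow-connected; downstream
transport would otherwise inflate similarity among the larger,
better-connected streams. Cross-group pairs and self-pairs never enter.

## Confluence contrasts

Per triplet and metric, delta = recipient value − mean of the two
tributaries. Deltas are tested with a Wilcoxon signed-rank test: zero
differences dropped, midranks for ties, exact two-sided p by dynamic
programming over sign assignments for n ≤ 25 (midranks doubled to make
the rank sums integral), otherwise a normal approximation with the
tie-corrected variance Σrᵢ²/4 and a 0.5 continuity correction.
Diversity deltas are correlated with hydromorphic deltas (Froude number,
depth, velocity, slope) by Spearman rank correlation — exact permutation
p for n ≤ 9 without ties, t approximation otherwise.

## Downstream trends

Diversity and evenness are regressed on x = log₁₀ catchment area with a
Gaussian location-scale model, y ~ N(β₀+β₁x, exp(γ₀+γ₁x)²), so a
downstream decline in *spread* is estimable alongside the decline in
*mean*. Fitting is maximum likelihood (BFGS from the OLS start
β = OLS, γ₀ = ln RMSE, γ₁ = 0; Nelder–Mead polish if BFGS stalls;
gradient tolerance 1e-8). β₁ and γ₁ are tested with 1-df likelihood
ratio tests; the γ₁ = 0 restriction has a closed-form homoscedastic
likelihood. log σ is floored at ln 1e-8; a zero-residual response
returns a flagged degenerate fit with zero slopes. An optional quadratic
location term is available. Percentile curves are μ̂(x) + z_p σ̂(x) for
p ∈ {5, 25, 75, 95}%.

Core/satellite partition: an OTU is *core* when present (≥1 read) in at
least 50% of samples, on the unrarefied table (presence at full depth is
the stable choice; the threshold is a parameter). Per-sample core and
satellite read fractions sum to one and are regressed on log₁₀ area by
OLS.

## Environmental forward selection

Candidates are z-scored; at each step the candidate with the largest R²
gain enters if its partial-F p-value is below α = 0.05 (ties broken by
gain then variable name; candidates collinear with the selected set are
skipped with a warning). An optional stricter double-stopping rule caps
the search at the adjusted R² of the all-candidates model (off by
default). The final model's coefficients on z-scored response and
predictors are the reported partial standardized coefficients. The
binary "position to confluence" covariate is coded tributary = 0,
recipient = 1. A pairwise-complete Spearman matrix accompanies the
selection for collinearity inspection.

## Distance decay and permutation ANCOVA

Within each group, similarity is regressed on distance (hydrologic or
Euclidean) by OLS. The group effect is tested controlling for distance
with an additive ANCOVA using sequential sums of squares, distance
first; F = MS_term / MS_residual from the two-term model.

Pairwise similarities are not independent, so significance comes from a
permutation null: each of the n_perm (default 999) permutations
relabels which community sits at which site — a joint row/column
permutation of the fixed similarity matrix — while group labels,
distances and the flow-connectivity exclusions stay with the sites. The
retained pair set is therefore fixed and only the similarity values are
reshuffled; re-rarefying per permutation would be distributionally
equivalent for this null and ~1000× more expensive.
p = (1 + #{F* ≥ F_obs})/(n_perm + 1), floored at 1/(n_perm+1), never 0.
Note that permutations preserving the group partition reproduce F_obs
exactly, so the floor is attainable only when such permutations are
vanishingly rare (e.g. ≥10 sites per group).

Similarity densities per group use a Gaussian KDE with the normal
reference rule h = 1.06 σ̂ n^(−1/5), σ̂ = min(SD, IQR/1.349).

## Synthetic survey generator

The generator emulates the statistical structure of a benthic-biofilm
network survey; it is the test bed for every stage and supplies ground
truth for recovery checks.

* **Topology** — a uniformly random recursive bifurcation over
  `n_headwaters` leaves (57 by default; with the default extra mainstem
  gauge below the top junction the survey has 114 sites). Leaf areas are
  lognormal (median 1 km²); junction areas are the upstream sum plus a
  lognormal local increment (median 1.8 km²), so areas rise strictly
  downstream, spanning roughly 0.25–200 km² with Strahler orders 1–5.
  Coordinates come from a recursive angular-sector embedding with
  straight edges; edge lengths are lognormal (median 900 m).
* **Covariates** — SUVA₂₅₄ (slope −0.8 per log₁₀ km², SD 0.5),
  channel slope (log-scale slope −0.35) decline downstream; velocity and
  depth rise on the log scale (0.25 and 0.20) so the derived Froude
  number v/√(g·d) rises; DOC is flat; forest cover declines weakly. The
  cyanobacteria read fraction is Beta(2, 10) independent of area.
* **Metacommunity** — each site's composition mixes (i) a shared
  regional core pool (300 taxa, lognormal abundances σ = 1.6, perturbed
  per site by lognormal noise σ = 0.3), (ii) a site-specific terrestrial
  pool (a 300-taxon subset of a 1500-taxon satellite pool with
  exponential weights) carrying weight w(A) = 0.55·A^(−0.6), with
  lognormal site-to-site scatter (σ = 0.3) representing divergent local
  flow paths, and (iii) for junctions, an upstream mass effect of weight
  u = 0.2 taken from the mean of the immediate upstream communities
  restricted to the core pool — downstream establishment favours the
  regionally well-adapted core taxa, which is what enriches the core
  downstream while satellites thin out. Reads are multinomial at a
  uniform random depth in [4698, 14094].

  The terrestrial gradient makes headwaters richer, more even, more
  variable and compositionally idiosyncratic; its decay plus the
  core-restricted mass effect produce the downstream decline of the mean
  and the dispersion of diversity, the rising core read fraction, and
  the lower among-headwater similarity, at effect sizes a field survey
  of this design could plausibly show.

* **What it does not emulate** — taxonomy beyond a cyanobacteria flag,
  lakes, temporal succession, hydrodynamic realism (discharge routing,
  Horton ratios), spatially autocorrelated environmental noise, and
  PCR/sequencing artefacts (chimeras, noise reads). Passing tests
  therefore demonstrate that the pipeline recovers the intended
  statistical structure from count data of realistic shape — not that
  the generator reproduces any particular real survey.

## Determinism and problem sizes

A single run seed is expanded into per-stage substreams by hashing the
stage name (CRC32) into a `SeedSequence`, so each stage is reproducible
in isolation. All Monte-Carlo outputs carry standard errors. Default
problem sizes follow the study design (114 sites, depth ≥ 4698,
1000-resample similarity averaging, 999 permutations); the repeated-seed
validation suites run with similarity averaging reduced to 100
resamples, which leaves the pair-table means essentially unchanged
(Monte-Carlo SE of an averaged similarity entry is below 0.01 at
R = 100).

## Known limitations

* The location-scale model is a deliberate simplification of
  distributional regression: linear terms only, Gaussian family; skewed
  responses (richness at shallow depths) are approximated.
* Bounded evenness responses are fitted untransformed; values near 1 can
  produce mild heteroscedasticity misfit.
* Forward selection inherits the usual selection-inference caveats; the
  entry p-values are not corrected for the search.
* The permutation null treats the rarefaction-averaged similarity matrix
  as fixed; uncertainty from the averaging itself is quantified by the
  reported Monte-Carlo SEs, not propagated into the permutation p.
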