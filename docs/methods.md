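# Methods

`mobnet` analyses wetland methanotroph (MOB, methane-oxidising bacteria)
communities profiled with the *pmoA* functional marker gene. It takes four
tables — an ASV count table with site/depth/plot metadata, an ASV taxonomy
map, a soil-property table, and two-point headspace CH₄ incubation records —
and produces potential methane-oxidation rates, diversity and ordination
statistics, co-occurrence networks with keystone detection and robustness,
per-sample network-complexity indices, and a PLS path model linking soil
chemistry, MOB groups and function. A seeded synthetic-study generator stands
in for field data so every stage is testable end to end.

## Potential methane-oxidation rates (PMOR)

Soil (Ws = 5 g dry weight by default) is incubated in sealed vials with
VH = 0.115 L of headspace starting near 2 % CH₄ (c(t₁) = 20 mmol mol⁻¹);
the mixing ratio is re-measured on day 15. The two-point depletion slope
dc/dt = (c(t₁) − c(t₂))/(t₂ − t₁) (mmol mol⁻¹ day⁻¹) is converted to mass
per gram of dry soil through the ideal gas law:

    PMOR = dc/dt · MM · (PA · VH) / (R · (T_ST + T)) / Ws

with MM = 16.04 g mol⁻¹, PA the atmospheric pressure (kPa), R = 8.314
m³ Pa K⁻¹ mol⁻¹, T_ST = 273.15 K and T the incubation temperature in °C
(default 25), plus the unit conversions mmol→mol, kPa→Pa, L→m³ and g→ng, so
the output is ng CH₄ g⁻¹ (dry soil) day⁻¹. The factor
(PA·VH)/(R·(T_ST + T)) is simply the moles of headspace air at the
incubation temperature; writing T in °C makes T_ST/(T_ST + T) the standard
ideal-gas temperature correction and keeps the formula dimensionally
consistent. A unit slope at the default constants gives
1.508 × 10⁴ ng g⁻¹ day⁻¹.

Only the two-point slope is supported (no multi-point regression); replicate
vials are computed separately and summarised afterwards as mean ± SD. A
blank-control slope can be subtracted via `blank_dcdt` (default 0: sterile
blanks show no depletion). A positive PMOR means net CH₄ consumption;
production is reported with a negative sign rather than clipped.

## Community statistics

* **Filtering** removes ASVs with fewer than 10 reads total (strict: exactly
  10 is kept). **Rarefaction** subsamples every sample to 1252 reads without
  replacement (multivariate hypergeometric draw), dropping shallower samples
  with a warning; the expected rarefied count of an ASV is depth·count/total.
* **Richness** is the number of ASVs with count > 0. **Relative abundances**
  can be aggregated to genus or MOB class (type I / type II / unclassified);
  unmapped ASVs fall into `unclassified` so rows always sum to one.
* **Dissimilarity** is Bray–Curtis; group structure is tested with one-way
  PERMANOVA (Anderson's pseudo-F, label permutations,
  p = (1 + #{F* ≥ F})/(1 + n_perm), 999 permutations by default).
* **CAP / db-RDA**: the distance matrix is decomposed into principal
  coordinates — with a Lingoes correction (add c = −λ_min to all squared
  off-diagonal distances) whenever negative eigenvalues appear, as they do
  for Bray–Curtis — and the coordinates are regressed on standardised soil
  predictors; the SVD of the fitted matrix gives constrained axes and
  eigenvalues. Under a Euclidean distance this reduces exactly to classical
  RDA, which is how the routine is validated. Per-predictor significance
  uses residualised row permutations; **forward selection** greedily adds
  the candidate with the largest gain in constrained inertia while its
  permutation p < 0.05, then reports VIF_j = 1/(1 − R²_j) for the selection
  (collinear predictors are flagged infinite).
* **Group contrasts** use one-way ANOVA with Tukey HSD (Tukey–Kramer for
  unequal n, via the studentized-range distribution) and an insert-absorb
  compact letter display; qPCR copy numbers are log₁₀-transformed first and
  zero copies are rejected as invalid.

## Drivers

Random forests (scikit-learn, 500 trees by default) predict a response
(class share or PMOR) from the eight soil variables. Importance is the
%-increase in MSE when one predictor's column is permuted (the
`randomForest` %IncMSE convention); its significance comes from refitting
the forest on permuted responses (`n_perm` refits) and asking how often the
null importance reaches the observed one. The model's "% variance
explained" is the out-of-bag R² × 100. Regressions are OLS with optional
log₁₀ transforms; logs of non-positive values raise an error naming the
offending sample (a pseudo-count mode is deliberately not silently applied).
Correlation heatmaps are Spearman by default with pairwise deletion of
missing values and 0.05/0.01/0.001 significance stars.

## Co-occurrence networks

Edges are Spearman correlations with |ρ| > 0.6 and p < 0.01 between ASV
count vectors, computed within a sample subset (typically one site). The
absolute value is used because negative associations are real and reported;
raw p-values are used by default (a Benjamini–Hochberg mode exists). ASVs
present in fewer than 5 samples, or constant, are excluded before
correlation — Spearman p-values are not meaningful for sparser vectors —
and isolated ASVs are dropped from the node set.

The topology summary reports nodes, edges, %positive/%negative edges,
average degree 2E/N, natural connectivity, mean neighbourhood connectivity
(average over nodes of their neighbours' mean degree), modularity of the
seeded Louvain partition, average geodesic distance over connected pairs
only, density and connectance E/(N(N−1)/2), global clustering
(transitivity), Freeman degree and betweenness centralisation, and the mean
normalised degree centrality.

**Natural connectivity** is ln((1/N) Σᵢ exp(λᵢ)) over the eigenvalues of the
unweighted adjacency matrix, computed with a log-sum-exp for stability — a
redundancy measure counting weighted closed walks. **Robustness** removes
random node subsets at a grid of fractions (100 iterations each, seeded) and
tracks the decline of natural connectivity (mean ± SD).

**Scale-free classification** fits log₁₀ P(k) against log₁₀ k by OLS on a
logarithmically binned degree distribution, fitting from the modal bin
outward (the power-law regime); a network is `scale_free` when R² ≥ 0.8 and
the exponent is negative. Binning matters: the unbinned tail of a
preferential-attachment graph is so noisy that R² rarely exceeds 0.5 even
when the underlying law is exact.

**Zi–Pi roles**: with a module partition (seeded Louvain by default, or any
user-supplied partition), Zi is the within-module degree z-score (0 when the
module's SD is zero, avoiding ±∞) and Pi = 1 − Σₜ (k_{i,t}/k_i)² the
participation coefficient. Thresholds 2.5 and 0.62 split nodes into
peripherals, connectors, module hubs and network hubs; keystones are the
non-peripherals. Degree-zero nodes have no defined Pi and are excluded.

**Per-sample subnetworks** are the induced subgraphs on ASVs with count > 0
in a sample; the **complexity index** is the mean of ten z-standardised
subnetwork properties (nodes, edges, average degree, neighbourhood
connectivity, density, connectance, clustering, and the three
centralisation statistics); a property with zero variance across samples
contributes 0 for everyone.

## PLS path modelling

Latent variables (nutrients {TOC, TN, TP, NH₄⁺, NO₃⁻}, ions {pH, EC}, the
type I and type II shares, community {CAP1, richness}, pmoA
{log₁₀ copies}, PMORs) are estimated by the Lohmöller iteration: mode A
(reflective) outer weights for all blocks, path weighting scheme for the
inner approximation (centroid and factorial available), iterated until the
largest outer-weight change is < 1e-7 (max 300 iterations; non-convergence
raises with diagnostics). Path coefficients are the OLS regressions of each
endogenous latent score on its predecessors; indirect effects are sums of
products along directed chains of length ≥ 2; GoF = √(mean communality ×
mean R²). Sign indeterminacy is resolved by aligning every latent score
positively with its first manifest, making results deterministic.
Significance uses a case-resampling bootstrap (1000 resamples by default)
with percentile CIs; stars mark CI exclusion of zero at 95/99/99.9 %
coverage. With single-indicator blocks the procedure reduces to regressions
of standardised indicators, which is the oracle used in testing.

The default inner wiring sends nutrients and ions to the MOB groups and
community, those to pmoA abundance, and ions, the groups and pmoA to
PMORs. It is a best-effort reconstruction of the study design and is fully
user-configurable (any acyclic inner matrix over user-defined blocks).

## Synthetic-data generator

The generator emulates the downstream product of a four-site × four-depth
wetland survey (8 plots per site, 128 samples, 300 ASVs by default):

* **Soil**: two sites are fresh and nutrient-rich (pH ≈ 7.0–7.2,
  EC ≈ 250–320 µS cm⁻¹, TOC ≈ 6–8.5 %), two saline/alkaline and
  nutrient-poor (pH ≈ 8.6–8.9, EC ≈ 1500–2100 µS cm⁻¹, TOC ≈ 1–1.6 %).
  Within-site pH and EC noise is bivariate normal with correlation 0.8;
  nutrients decay ~12 % per depth layer with log-normal noise.
* **Counts**: each ASV belongs to a type I genus (Methylobacter,
  Methylomonas, Methylosarcina, type Id), a type II genus (Methylocystis
  dominant, type IIb), or is unclassified (6 %). Expected class shares
  follow a softmax in the standardised soil ion score with slopes +1.2
  (type I) and −1.2 (type II); counts are Dirichlet-multinomial
  (concentration 150) with log-normal library sizes around 16 × 1252 reads,
  so rarefaction to 1252 always succeeds. Slopes may be zeroed for null
  simulations but never sign-flipped.
* **Function**: the target PMOR is log-linear in the centred type II share
  (+1.0) and the standardised EC (−0.30) around a base rate of
  380 ng g⁻¹ day⁻¹, giving site means spanning roughly 170–780 ng g⁻¹ day⁻¹
  across seeds. Day-15 mixing ratios are back-computed through the inverse
  of the rate formula (three vials per sample with 4 % replicate noise);
  targets implying negative mixing ratios raise. qPCR copies are log-normal
  around a site trend.

Each table draws from its own integer-seeded RNG stream, so one seed fully
determines the study. The generator reproduces the *statistical* structure
the analysis assumes — opposed ion/nutrient gradients, ion-driven class
turnover, function tied to composition — but not several features of real
amplicon data: no phylogenetic correlation among ASVs, no spatial
autocorrelation between neighbouring plots, no sequencing-error or chimera
artefacts, and much weaker within-site co-abundance structure than real
communities show (so per-site synthetic networks are far sparser than
field networks). Passing tests therefore demonstrate correctness of the
computations and recoverability of configured effects, not performance on
field data.

## Numerical choices and problem sizes

* Rarefaction uses `numpy`'s multivariate hypergeometric sampler (true
  sampling without replacement), not multinomial approximation.
* PERMANOVA, RDA permutation tests, robustness, Louvain, the RF null and the
  bootstrap all take explicit integer seeds; derived streams use
  `default_rng([seed, stream])`.
* PCoA eigenvalues below 1e-8 are treated as null axes; Lingoes correction
  triggers below −1e-8.
* The test suite and the acceptance script run the calibration studies at
  moderate sizes chosen to keep the whole suite in a few minutes on one
  core: 500 null PERMANOVA datasets (n = 20, 199 permutations), 200
  bootstrap meta-replicates (n = 40, 199 resamples), 50-seed graph
  classification checks, and the full 128-sample default study for
  parameter recovery.

## Known limitations

* The per-site co-occurrence networks of the default synthetic study are
  small (tens of nodes); real per-site networks with hundreds of nodes are
  only exercised through random-graph tests of the topology routines.
* RF importance ranks pH and EC nearly interchangeably because the
  generator couples them (r = 0.8); recovery tests treat the ion pair as
  one axis.
* The PLS-PM inner wiring between community, pmoA and PMORs is a
  configurable best guess; path estimates for type I/type II latents can
  exceed |1| when both enter one regression, as expected under collinearity.
* Tukey letters use the studentized-range approximation; exact small-sample
  resampling letters are out of scope.
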