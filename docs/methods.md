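# Methods

This note documents the models, null schemes, parameter choices and known
limitations behind `phyllonet`. It is the companion to the API docstrings:
everything here is implemented and exercised by the test suite; no result
is stated that the tests or `scripts/acceptance.py` do not themselves
compute.

## Data model and preprocessing

The central object is a samples × taxa count matrix with unique ordered
ids; rows may alternatively hold proportions (flagged `is_relative`).
Sample metadata carries the two-factor design: host species and habitat
size (1-ha, 10-ha, 100-ha, continuous), with habitat class derived
deterministically (1-/10-ha → small, 100-ha/continuous → large).
Phylogenies are rooted, branch-length-bearing scikit-bio `TreeNode`s whose
tips are taxon ids.

Samples below a minimum depth (default 500 reads) are removed, and the
remainder rarefied to an even depth (default 514) by multivariate
hypergeometric subsampling — without replacement, the standard rarefaction
semantics. Samples shallower than the target are dropped with a log entry
rather than raising, because removing shallow samples before rarefying is
part of the protocol the defaults encode. All stochastic steps consume an
explicit integer seed; the pipeline derives per-stage seeds by hashing
(stage name, run seed) so stages are independently reproducible.

Downstream stages split by data type: diversity and assembly run on the
rarefied counts (null models and Faith PD assume integer reads at even
depth); network construction runs on relative abundances of the
depth-filtered, unrarefied counts (rank correlations are depth-invariant,
and discarding reads would only lose power).

## Diversity

Alpha diversity reports the Hill family — observed richness, exp-Shannon
(order 1) and inverse Simpson (order 2) — plus Chao1 in the bias-corrected
form S_obs + F₁(F₁−1)/(2(F₂+1)) (defined when F₂ = 0) and Faith PD (sum of
branch lengths spanning the present tips and the root). Beta diversity is
Bray–Curtis on relative abundances and the **normalized** weighted UniFrac
Σ l_b |p_A − p_B| / Σ l_b (p_A + p_B), bounded in [0, 1].

PCoA is classical Gower double-centering of −d²/2 with full
eigendecomposition; negative eigenvalues are reported, never silently
dropped, and proportion explained is computed over the positive spectrum
only. PERMANOVA uses the distance-based pseudo-F with
SS_T = Σ_{i<j} d²/N and SS_W = Σ_g Σ_{i<j∈g} d²/n_g; p-values follow the
add-one convention (1 + #{F_perm ≥ F_obs})/(n_perm + 1) so p = 0 is
impossible; pairwise mode applies Bonferroni. PERMDISP measures distances
to group centroids in PCoA space, subtracting squared components on
imaginary (negative-eigenvalue) axes and clipping at zero; significance
permutes group labels of those distances, which in the one-way layout is
equivalent to permuting least-squares residuals. Centroids (not spatial
medians) are used for tractability.

## Indicator species

IndVal_t = max_g A_tg · B_tg with A the group-mean relative abundance share
and B the occupancy fraction; abundances are converted to per-sample
proportions first, making the index invariant to sequencing depth. Ties in
the best group go to the lowest group index. Significance permutes group
labels (add-one convention); taxa absent everywhere get IndVal 0, p = 1.
IndVal is reported on the 0–1 scale.

## Assembly processes

βMNTD is the abundance-weighted mean nearest-taxon patristic distance
between two communities. βNTI standardizes the observed βMNTD against a
null that shuffles taxon labels across all tree tips (999 replicates by
default); a degenerate null (sd = 0, e.g. a star tree where all shuffles
are equivalent) defines βNTI = 0. RC_bray compares the observed
Bray–Curtis to 1000 null pairs built by drawing each sample's observed
richness of taxa with probability proportional to regional occurrence
frequency, seeding each drawn taxon with one read, and filling to the
observed depth proportionally to regional relative abundance;
RC = 2[(#null < obs) + ½(#null = obs)]/n_null − 1 ∈ [−1, 1].

Classification: βNTI > +2 variable selection; βNTI < −2 homogeneous
selection; else RC > 0.95 dispersal limitation, RC < −0.95 homogenizing
dispersal, else drift. Boundary values (βNTI exactly ±2, RC exactly ±0.95)
fall on the stochastic/drift side. Habitat-level fractions pool sample
pairs from both hosts within a habitat group (per-host mode available);
groups with fewer than two samples are omitted with a warning.

## Synthetic metacommunities

The generator emulates the survey structure the analyses assume: 2 hosts ×
4 habitat sizes × 5 samples (40 samples) over 300 taxa by default — a
deliberately scaled-down layout so the full pipeline runs in minutes; the
field-scale shape (~146 samples, thousands of ASVs) is reachable through
`SimulationParams`. Components:

- **Phylogeny**: pure-birth (Yule, rate 1) ultrametric tree.
- **Regional pool**: log-normal abundance spectrum (σ = 1.5).
- **Selection**: host- and habitat-affinity traits evolve by Brownian
  motion on the tree (rate 1, standardized); a sample's expected
  composition is pool × exp(−s/2 (z − θ)²) for its host/habitat optima θ.
  Brownian conservatism is what lets βNTI see selection.
- **Dispersal and drift**: each sample mixes the selected regional pool
  (weight m) with a site-local pool obtained by `drift_steps` rounds of
  multinomial resampling of 2000 individuals (Hubbell-style neutral
  drift).
- **Reads**: multinomial draws at log-normal depths (mean ≈ 7000, clipped
  to [500, 41000]) — matching the depth profile of a typical processed
  nifH dataset.
- **Planted indicators**: a fraction f of taxa (the most extreme on the
  host-affinity trait, hence clade-clustered) are restricted to one host
  and assigned a common abundance (pool median × boost 20). The common
  value keeps the planted mass balanced between hosts, so background taxa
  are not compositionally distorted into false indicators; genus labels
  form one block per host ("Hassallia"-like vs "Fischerella"-like).
- **Co-fluctuation modules** (off by default): per sample, contiguous
  clade blocks are scaled by exp(N(0, block_sd²)), planting the positive
  co-occurrence structure network tests need.

Scenario presets define the five assembly regimes. Two need non-obvious
choices: *homogeneous selection* uses an extreme shared optimum (+1.5) with
drift-driven membership turnover, because taxa near a central optimum are
polyphyletic under Brownian motion, and identical memberships make
observed βMNTD equal its null (every taxon's nearest neighbour is itself);
*dispersal limitation* uses moderate drift (60 steps of 500 individuals,
m = 0.02) because extreme drift evens the regional pool until the
Raup–Crick null reproduces the observed dissimilarity. At desk scale
(depth 514) the presets yield: homogenizing dispersal modal (~95%),
variable selection modal (~50–70%), drift modal (~70–90%), while
homogeneous selection (~13–50%) and dispersal limitation (~7–35%) are
strongly elevated over their neutral baselines (<5%) without always being
modal — a power limit of rarefied 514-read communities, not of the
classifier.

What the generator does **not** emulate: sequence-level errors and
chimeras, quantitative environmental gradients (habitat effects are
categorical), interaction-driven dynamics (co-occurrence is planted as
shared latent fluctuation, not mechanistic interaction), and temporal
structure. Passing recovery tests therefore demonstrates correctness of
the inference machinery under its own assumptions, not field validity.

## Co-occurrence networks

Taxa below 0.05% mean relative abundance are removed. Spearman ρ (mid-rank
ties) is computed for all remaining pairs on relative abundances; edges
require two-sided p < 0.01 **and** BH q < 0.05 (q computed over all tested
pairs), optionally |ρ| above a random-matrix-theory threshold: the
smallest cutoff in 0.30–0.90 (step 0.01) where the thresholded matrix's
nearest-neighbour eigenvalue spacings fit Poisson statistics better than
the Wigner–Dyson surmise (chi-squared on spacing histograms; spacings are
normalized to unit mean; repeated eigenvalues count as zero spacings,
which is precisely the clustered spectrum of a modular matrix). If no
transition exists (e.g. an identity matrix) the upper bound is returned
with a warning. Constant taxa are skipped with a warning (ρ undefined).

Nodes are taxa with ≥ 1 retained edge; weights are |ρ| with the sign kept
as an attribute. Modules come from greedy modularity maximization
(deterministic); Zi–Pi roles use Zi = (k_within − mean)/sd within the
module (0 when sd = 0) and Pi = 1 − Σ_s (k_is/k_i)², with module hubs at
Zi > 2.5, Pi ≤ 0.65. The network-hub category is retained even when empty.
Topology reports path length and diameter on the largest connected
component (unweighted), heterogeneity as the coefficient of variation of
degree, and Freeman degree centralization (0 with warning when V < 3).
Cohesion corrects each pairwise Pearson correlation by a taxon-shuffle
null mean, splits each taxon's mean corrected correlation into positive
and negative connectedness, and sums abundance-weighted connectedness per
sample; group differences use a label-permutation test. An optional
bootstrap stability filter (off by default) keeps edges called in ≥ 80% of
sample resamples and reports a Brown-style combined p (Fisher statistic
with an empirical scale correction for resample dependence).

## Robustness

Average efficiency is the mean of 1/d over ordered node pairs
(disconnected pairs contribute 0); natural connectivity is
ln((1/V) Σ exp(λ)) over unweighted adjacency eigenvalues — weights affect
only the `edge_strong` removal order. Removal proceeds in 10% steps to
90% (metrics degenerate at 100%); deterministic strategies randomize ties
under the seed, and every point recomputes the metric on a freshly built
residual graph (no incremental updates to drift). The `node_hub` sequence
covers module hubs only — empty, with a warning, for networks without
hubs — and its fraction axis is relative to hub count. Replicates default
to 100. On dense modular networks, degree-targeted removal can transiently
*raise* efficiency (surviving modules are small and dense) before the
collapse — the same non-monotone pattern attack simulations show on real
small-habitat networks.

## Pipeline

`run_pipeline` executes prep → diversity → indicator → assembly →
per-subset networks (host × habitat class) → robustness, writes all tables
as TSV plus a JSON manifest (stages, seed, config hash), and fails fast
naming the offending stage. Identical config + seed reproduces identical
numeric outputs. Table emission mirrors the three standard report shapes:
process × habitat fractions (columns sum to 100), per-network topology
with module-hub/peripheral counts and sharing statistics, and per-hub key
species (degree, betweenness, closeness, eigenvector centrality on the
unweighted graph, abundance, module, Z-value) — empty when a network has
no hubs.

## Numerical choices and problem sizes

- Permutation p-values everywhere use the add-one convention.
- βNTI needs n_null ≥ 99 (z-scores unstable below); library defaults are
  999 (βNTI) and 1000 (RC_bray). The acceptance script and recovery tests
  use 199/201 replicates and 5–20 simulation seeds — sizes chosen so the
  whole battery runs in minutes while keeping Monte-Carlo error well
  inside the asserted margins.
- RC equality ties use a 1e-12 tolerance and count half.
- Chao1 rejects non-integer input rather than silently mis-estimating.
- Degenerate cases are defined, not NaN: βNTI under a zero-variance null
  is 0; Zi in a uniform-degree module is 0; isolated nodes are peripheral
  with Pi = 0.

## Known limitations

- Rank correlation ignores compositional coupling; SparCC/SPIEC-EASI
  style compositionally aware inference is out of scope by design.
- The RMT transition detector uses a simple chi-squared comparison on
  spacing histograms; it is a threshold heuristic, not a full spectral
  unfolding study.
- PERMANOVA offers single-factor and marginal two-factor modes only.
- The cohesion null (independent column shuffles) removes all
  between-taxon association, including any induced purely by
  compositionality.
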