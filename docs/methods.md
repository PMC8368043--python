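# Methods

This note documents the models implemented in `wapflux`, their assumptions,
the parameter defaults and why they were chosen, what the synthetic-data
generator does and does not emulate, and the numerical choices that matter
when reproducing results. Everything quantitative stated here is computed by
the test suite or by `scripts/acceptance.py`; nothing is asserted that the
code does not verify.

## O2/Ar-based net community production

Argon has nearly the same solubility and diffusivity as oxygen but no
biological source or sink, so the per-mil deviation of the measured O2/Ar
ratio from its air-equilibrium value isolates the biological oxygen signal:

    Δ(O2/Ar) = [(O2/Ar)_sample / (O2/Ar)_sat − 1] × 100 %

Under steady state, with negligible vertical mixing and entrainment, the
air–sea flux of biological oxygen equals net community production:

    NCP = k · [O2]_sat · Δ(O2/Ar)      (mmol O2 m⁻² d⁻¹)

Assumptions and choices:

* **Steady state.** No time-derivative or vertical-flux correction terms are
  added; the estimates represent mixed-layer fluxes only, and no statement is
  made about sequestration timescales.
* **Negative NCP is retained.** Δ(O2/Ar) < 0 (net heterotrophy) is physically
  meaningful and is never clamped.
* **Solubility.** [O2]_sat uses the combined-fit solubility polynomial in
  scaled temperature Ts = ln[(298.15 − t)/(273.15 + t)] and salinity (the
  mL L⁻¹ coefficient set), converted to mmol m⁻³ with the O2 molar volume
  22.3916 L mol⁻¹. Valid for −2…40 °C and 0…42 PSU; out-of-range inputs
  raise. The unit tests check the transcription against an independent
  re-typing of the coefficients and the monotonicity in both arguments.
* **Gas transfer.** k = a·u² (Sc/660)^(−1/2), with a = 0.251 cm h⁻¹ (m s⁻¹)⁻²
  by default (configurable — the literature carries several closely related
  quadratic coefficients) and the O2 Schmidt-number quartic for seawater.
  Converted to m d⁻¹ (×0.24).
* **Ventilation-history weighting.** Because the mixed layer integrates gas
  exchange over days to weeks, k is a weighted mean over a wind-speed history
  (default window 30 d, Δt = 1 d, both configurable). With
  f_j = min(k_j Δt / z_mld, 1) the weight of day *i* is the product of
  (1 − f_j) over all more recent days *j*, normalised to sum to one — each
  day's contribution is the fraction of the layer not yet ventilated since
  then. Limits: a constant history reproduces the instantaneous k; as
  z_mld → 0 the most recent day carries all weight. The weighted k always
  lies between the minimum and maximum instantaneous k of the history.
* **Volumetric NCP** is areal NCP divided by mixed layer depth. Whether this
  division is the right notion of "volumetric" is a modelling choice; it is
  implemented as stated and flagged here.
* **Mixed layer depth** is the shallowest depth where σθ exceeds its value at
  the 10-m reference by 0.03 kg m⁻³, linearly interpolated between CTD
  levels; if the threshold is never crossed the deepest level is returned
  with an explicit flag rather than silently.
* **PAR.** Sub-surface PAR is 0.92 × mast PAR. Mean mixed-layer PAR uses
  depth-averaged exponential attenuation,
  PAR_mld = PAR(0⁻)(1 − e^(−kd·z))/(kd·z), with kd supplied by the user (or a
  chlorophyll-derived estimate); this is the simplest physically standard
  choice and is configurable because attenuation models differ.

## Three-end-member water-mass mixing

Surface water is modelled as a mixture of sea-ice melt (salinity 7,
δ¹⁸O 2.1 ‰), meteoric water (0, −16 ‰) and Circumpolar Deep Water
(34.73, 0.1 ‰). Mass conservation plus the two tracers give a 3×3 linear
system whose solution are the three fractions. Numerical notes:

* δ¹⁸O is carried in per-mil; the balance is linear in per-mil to first
  order.
* Fractions are returned **unclipped** with an in-simplex flag: measurement
  noise can push solutions slightly outside [0, 1], and truncating would
  silently break mass balance. Users choose the handling.
* The end-member matrix is checked for invertibility at construction.
* Forward mixing followed by inversion is the identity to solver precision;
  the test suite verifies max |error| < 1e−10 over 1000 random simplex
  points.

## Quantitative microbiome profiling

Read counts are compositional; QMP rescales them to 18S gene copies per liter
so abundances are comparable across samples.

* **Spike-in route.** QMP_i = (reads_i / reads_spike) × copies_added /
  volume. The spike read fraction is the QC statistic: ≤ 0.1 % fails (the
  internal standard is unusable), and fractions outside the empirically
  usable 0.7–5.7 % window warn without failing. Copies added per ng of spike
  gDNA is a required configuration constant (default 1e5 copies ng⁻¹, a
  documented placeholder): it rescales all values uniformly, so every
  downstream statistic that matters (correlations, modules, regressions) is
  invariant to it.
* **Pigment route.** Where no usable spike exists, total cryptophyte 18S
  copies mL⁻¹ are predicted from Alloxanthin (µg L⁻¹) by the empirical linear
  calibration y = 2.05×10⁶ x (valid 0.01–6.22 µg L⁻¹; outside the range the
  code warns of extrapolation), and the whole sample is scaled so its
  cryptophyte reads match that total. Cryptophyte ASVs are selected by a
  taxonomy match rule (default substring "Cryptophyta").
* **Routing.** `qmp_auto` sends each sample through the spike route if its
  spike passes QC, otherwise through the pigment route if Alloxanthin is in
  the calibrated range; samples failing both are dropped with a recorded
  reason. Both routes preserve within-sample abundance ratios exactly, and
  spike normalisation is invariant to sequencing depth by construction.
* The spike reads are the sole reference in the denominator (rather than
  total reads); with spike fractions of a few percent the distinction is
  small, but it is a declared convention.

## Rarefaction and alpha diversity

Counts are rarefied (subsampled without replacement, multivariate
hypergeometric, single seeded draw by default; a multi-draw averaging mode
exists but is off) to an even depth — by default the minimum retained sample
total. Samples below the depth are dropped, which is how low-count libraries
are excluded (a depth floor, not hard-coded sample names). On the rarefied
table:

* Shannon H′ = −Σ p_i ln p_i (natural log), over observed ASVs.
* Pielou J = H′ / ln S, undefined (NaN) when S < 2.
* Chao1 = S + f1(f1 − 1)/(2(f2 + 1)), the bias-corrected variant (the common
  ecology-package default); the classic f1²/(2 f2) form is available by flag.

The diversity–SST trend is an ordinary least squares fit reporting slope,
95 % CI, the two-sided p value, and the percent change of the fitted index
over a 4 °C warming relative to the fitted value at the coldest observed SST.
The test suite verifies the indices against brute-force reimplementations (to
1e−12) and against scikit-bio, and checks that the trend test's type-I error
is ≈5 % at α = 0.05 under a null simulation.

## Co-abundance modules

Module detection follows the weighted-correlation-network template on the
log-transformed QMP matrix (log(x + 1); the pseudocount is configurable
because zero-handling is a genuine free choice at copies-per-liter scale —
one unit is negligible relative to observed abundances of 1e4–1e8).

* **Prevalence filter:** an ASV is kept iff it exceeds 3 reads (strictly) in
  at least 20 % of samples.
* **Adjacency:** unsigned, a_ij = |cor(x_i, x_j)|^β with Pearson correlation.
  Signed mode exists behind the config. Constant columns are dropped with a
  warning.
* **Soft power selection:** for β = 1…20, connectivities are binned into 10
  equal-width bins and log10 p(k) is regressed on log10 k; the fit index is
  R² signed by the negated slope sign. The selected β is the smallest one
  reaching R² ≥ 0.9 **among powers that keep mean connectivity ≥ 1** — very
  high powers can score spuriously well on the log-log fit while driving the
  network to numerical zero. If no power qualifies, the smallest power where
  the R² curve saturates (marginal gain < 0.02 once R² ≥ 0.5) is used, with
  a warning. Simulated block-plus-noise matrices routinely plateau below the
  0.9 target; real community data typically reach it at low powers.
* **TOM:** TOM_ij = (Σ_u a_iu a_uj + a_ij)/(min(k_i, k_j) + 1 − a_ij) with
  zero diagonal adjacency; verified against an O(n³) triple loop to 1e−12.
* **Tree cut:** average-linkage clustering of 1 − TOM, cut at 0.95 × the
  largest merge height. This is a deliberate simplification of the dynamic
  hybrid tree cut: on matrices with block structure the within-block merges
  sit well below the band of noise merges near the maximum height, so a cut
  slightly under the maximum isolates the blocks, while on structure-free
  input nearly all points become singletons and end up grey. Clusters below
  `min_module_size` (default 10) are greyed. Unassigned ASVs whose
  correlation with a module eigenvalue exceeds 0.3 are then reassigned to
  that module (PAM-like rescue; threshold configurable, disable with
  `reassign_kme=None`). Modules are named by descending size with the
  conventional colour order, so the largest module is always *turquoise*.
  Exact equality with any particular upstream implementation's dendrogram is
  explicitly not a goal.
* **Eigenvalues:** first principal component of the standardized member
  profiles, scaled to unit variance, sign-oriented so it correlates
  positively with the mean member profile (the eigenvalue then reads as "the
  assemblage's overall abundance"). Module–trait correlations are Pearson r
  with two-sided t-test p values and pairwise deletion of missing trait
  values (pairs with n < 4, or a constant series, are reported missing).
* **Membership and hubs:** kME_i is the correlation of ASV i with its own
  module's eigenvalue; kIN_i the sum of adjacency to same-module members;
  hubs are the top-10 by kIN (all members, with a warning, for smaller
  modules). `membership_vs_ncp` correlates per-ASV NCP correlations against
  kME within a module — a positive relationship means the module's most
  central taxa track NCP most closely.
* Optional module merging by eigenvalue similarity exists
  (`merge_eigen_cut`) but is off by default.
* Samples are treated as independent replicates in a single run.

## Symbolic regression of NCP

Candidate NCP formulas are evolved as expression trees over the module
eigenvalues and physical drivers (MLD, PAR, PAR_mld, salinity, SST, f_sim,
f_met, grid X/Y).

* **Representation:** binary trees over {+, −, ×, protected ÷} with feature
  terminals and ephemeral constants (initialised U(−2, 2), mutated by
  Gaussian perturbation). Protected division returns 1 when
  |denominator| < 1e−9. Complexity = node count. Optional exp/log operators
  are deliberately excluded from the default set to keep solutions
  interpretable.
* **Search:** generational GP — tournament selection (size 3), subtree
  crossover (p = 0.7), subtree/constant mutation (p = 0.25), max depth 5,
  population 400, 50 generations, one elite carried over. Every evaluated
  tree may update a (complexity, training-MSE) Pareto archive in which higher
  complexity must strictly lower MSE; the archive, not the final population,
  is the output.
* **Linear scaling:** each tree's raw output h(x) enters predictions as
  a + b·h(x) with (a, b) fitted by least squares on the training half. This
  standard device removes output offset/scale from the search space and
  makes the evolved structure, not its calibration, the object of selection.
* **Protocol:** features are z-scored on the training half (mixed units) and
  the same transform applied to validation; the data are split into even
  halves by a seeded shuffle (odd n gives validation the extra row); the
  front is re-evaluated on the validation half and ranked by validation MSE.
  The report includes each solution's expression, complexity, train/validation
  MSE, validation R² and the feature-selection frequency across the front.
* **Determinism:** the split seed and run seed fully determine the result.
* The solver is a standard Pareto-GP; the modelling protocol (inputs, split,
  complexity-vs-MSE ranking) is the scientific content, and all solver
  hyperparameters are exposed in `GpConfig`.

## Synthetic surveys and what they do (not) show

The generator produces a ~112-sample, 300-ASV survey with a complete truth
channel. Design choices, with the reasoning:

* **Environment:** SST ~ N(0.8, 1.5²) clipped to [−1.8, 6] °C, MLD lognormal
  (median 30 m, clipped 5–120 m), mast PAR U(15, 60), kd U(0.08, 0.20) m⁻¹,
  grid coordinates uniform over a 220 × 900 survey box — magnitudes typical
  of summer polar shelf surveys. Freshwater fractions are Dirichlet
  (1.5, 1.5, 40), making CDW-derived water dominant (median f_cdw > 0.8, as
  for most shelf samples); salinity and δ¹⁸O are produced by the *forward*
  mixing rule so the inversion is testable as a round trip.
* **Community:** three default blocks of 60/30/20 ASVs driven by −SST, +SST
  and +MLD respectively (a cold-water diatom-like assemblage, a warm-water
  cryptophyte assemblage, a deep-mixing heterotroph assemblage — the
  canonical driver signs for these guilds), among 190 unstructured ASVs.
  Each block's latent factor is sign × 0.5 × z(driver) plus noise
  orthogonalised against the driver, so the planted factor–driver correlation
  is exactly ±0.5 rather than 0.5 in expectation — the truth channel should
  not carry avoidable sampling error. Member log-abundance is
  loading × (factor + noise) with the noise variance set so the pairwise
  within-block correlation equals the requested value (default 0.7).
* **Absolute abundances, emergent totals.** The planted structure lives in
  copies per liter — the quantity QMP recovers — so per-sample totals rise
  when assemblages bloom. The expected spike read fraction follows
  mechanistically from the fixed spike mass, the emergent total and the
  recorded volume, φ = C/(C + T·V), with totals clipped just enough to keep
  φ in the observed 0.7–5.7 % window. (An earlier softmax-relative design
  was rejected: compositional closure distorted every log-QMP profile and
  silently attenuated the planted correlations.)
* **Counts:** multinomial at a lognormal depth (clipped to 30k–100k reads,
  median ≈ 55k, matching typical library sizes), over (spike, community)
  probabilities. Counts are therefore compositional even though the truth is
  not — exactly the distortion the spike-in is designed to undo.
* **NCP:** the default generating rule is volumetric
  NCP = (50 + 20·MET − 0.3·MLD)/MLD — an areal flux linear in the bloom
  factor, diluted by mixed layer depth. This keeps the implied Δ(O2/Ar) in a
  realistic band (about −15…+30 %); a rule linear in volumetric units with a
  strong MLD term can imply Δ below −100 % at deep-MLD samples, which is
  unphysical (the generator raises in that case rather than emitting an
  impossible track). Observed NCP adds N(0, noise_sd²), default
  0.05 mmol O2 m⁻³ d⁻¹. The underway Δ(O2/Ar) track is obtained by
  *inverting* the flux equation per sample given generated 30-day Weibull
  wind histories, so the forward pipeline must reproduce the planted areal
  NCP to solver precision (< 1e−9 relative, verified).
* **What passing tests show** — that every stage implements its stated
  mathematics, that the stages compose (QMP → modules → GP recovers planted
  assemblages, drivers and formulas), and that the pipeline is deterministic.
  **What they do not show** — performance on real surveys: the generator has
  Gaussian log-abundance noise (no overdispersion beyond multinomial
  sampling), no taxonomic bias or PCR amplification noise, independent noise
  ASVs (no diffuse correlation background), exact end-member values, and a
  noise model for NCP far simpler than instrument reality. Real-data module
  counts, R² values and correlation magnitudes will differ.

## Pipeline and reproducibility

Stages exchange plain-text tables keyed by sample identifier; `wapflux run`
executes them in dependency order, validates inputs (alignment, non-negative
counts, SST ∈ [−5, 30] °C, salinity ∈ [0, 42], MLD > 0), and writes a
manifest with the configuration, per-stage row counts and SHA-256 hashes of
every output. Re-running with the same configuration reproduces every output
hash (verified in the tests). One global seed propagates to all stages.

## Problem sizes

Defaults throughout are the study-scale sizes: 112 samples, 300 ASVs, GP
population 400 × 50 generations. The repeated-run checks (the GP overfitting
guard's 20 seeded noise runs) use population 200 × 25 generations; the
trend-test calibration uses 1000 replicates of n = 50. The full test suite
runs in well under a minute on one CPU.

## Known limitations

* The tree cut is a documented simplification of the dynamic hybrid
  algorithm; module boundaries on weakly separated data will differ from the
  reference R implementation.
* The scale-free criterion is often unattainable on small or strongly
  blocked matrices; the saturation fallback then decides, and the chosen
  power is worth inspecting (`power_fit_table` is returned for this).
* The pigment calibration is linear through the origin and taxon-specific;
  outside its concentration range it extrapolates with a warning.
* Out-of-simplex mixing fractions are flagged, not resolved; end-member
  uncertainty is not propagated.
* GP results depend on seeds by nature; the Pareto archive tames but does not
  remove run-to-run variability in expression *form* (metrics are stable).
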