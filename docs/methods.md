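# Methods

## The model

`msvdq` treats a multicenter questionnaire dataset as a collection of
*sources* (sites), each of which induces an empirical probability
distribution over a low-dimensional representation of its participants.
Coherence between sources is then a purely distributional question, answered
in three steps.

**1. Distribution fingerprints.** Each source's (reduced, filtered) point
cloud is binned on a grid shared by all sources: per dimension,
`bins_per_dim + 1` equally spaced edges spanning the pooled min..max of all
sources, upper edge inclusive. Counts are flattened row-major and normalized
to probability vectors. Sharing the grid is what makes the vectors
comparable; the default is 10 bins per dimension (1000 bins for the 3-D
reduced space). Histograms, not kernel estimates, are used throughout.

**2. Jensen–Shannon geometry.** For probability vectors p, q the package
uses the Jensen–Shannon *distance*
`d(p,q) = sqrt(½ KL(p‖m) + ½ KL(q‖m))`, `m = ½(p+q)`, base-2 logarithms,
`0·log 0 ≡ 0`. With base-2 logs the distance is a metric bounded by 1,
reaching 1 exactly when the supports are disjoint. √JSD matrices are
Hilbertian, so classical (Torgerson) multidimensional scaling
(`B = −½ J D² J`, eigen-decomposition, coordinates = eigenvectors scaled by
root eigenvalues) reproduces the distances essentially exactly; eigenvalues
that are negative within numerical noise (magnitude ≤ 1e-10 of the largest)
are clipped to zero, and a *strongly* negative eigenvalue (beyond 1e-6 of
the largest) raises, since it can only come from corrupted input. Each axis
is sign-fixed so its largest-magnitude coordinate is positive, making the
embedding byte-stable.

**3. Simplex summary metrics.** The sources are the vertices of the
embedded simplex; the *informed average distribution* is their centroid,
weighted by retained case counts (an unweighted variant is available). With
`d_i` the vertex–centroid distances and `c_s = sqrt((s−1)/(2s))` the
vertex–centroid radius of the *unit-edge regular* simplex — the
maximal-separation configuration —

* `SPO_i = min(1, d_i / c_s)` per source,
* `GPD = min(1, (Σ w_i d_i / Σ w_i) / c_s)`.

This normalization is the unique linear scaling that leaves identical
sources at 0 and puts the all-disjoint equal-weight configuration exactly
at 1, for any number of sources. The clip guards the unequal-weight corner:
a very light source can sit farther than `c_s` from a heavily weighted
centroid. The MSV plot shows the two (or three) highest-eigenvalue axes of
the same embedding, one circle per source with radius proportional to its
case count.

## The two branches

**Values branch** (how differently the sites *answered*). Free-text and
multichoice questions are excluded — they carry almost no usable variability
and a lot of missingness. Categorical/ordinal answers are encoded as the
0-based index in their declared category order, continuous answers parsed as
floats. Blanks are filled by chained-equations imputation: initialise with
column means; visit incomplete columns in ascending missing count; regress
each on all other columns (current imputations filled in) with a fixed-λ
ridge (default λ = 1e-3) fitted on the rows where the target is observed,
pooled over all sites; overwrite the missing cells with predictions; stop
when the largest imputed-cell change falls below `tol·SD(column)` (default
tol = 1e-3) or after `max_iter = 10` sweeps. Categorical columns are finally
rounded to the nearest valid code. The fixed-penalty ridge keeps the
estimator's contract — a linear fit with L2 shrinkage — while staying fully
deterministic; observed cells are never altered. The completed matrix is
standardized and reduced by PCA to `k = 3` axes (correlation PCA is the
default because questionnaire encodings have heterogeneous scales).

**Completeness branch** (how differently the sites *skipped*). Every cell
receives one of three codes: 2 = observed; 1 = dependent / not-applicable
missing — the question's branch rule (parent question + activating values,
declared in the codebook) put it out of scope given the parent's answer;
0 = ordinary missing. When the parent of a blank child is itself blank, the
child's applicability is unknowable from the data; the default resolves it
through the parent's own code (a not-applicable parent propagates
not-applicability down the chain), and a conservative mode
(`cascade="ordinary"`) codes every such child as ordinary missing, which
never understates data-collection faults. The three-code matrix is reduced
by multiple correspondence analysis — correspondence analysis of the
complete disjunctive (indicator) matrix via SVD of the standardized
residuals — to `k = 3` axes. Sections with no missingness at all are
reported as GPD = 0, all SPO = 0, with a `no-missingness` flag instead of a
degenerate MCA.

**Shared tail.** Both branches then filter outliers *within each site* with
the local outlier factor (k-distance neighborhood, reachability distances,
`LOF = mean neighbor lrd / own lrd`; defaults k = 20 neighbors, threshold
1.5). Filtering per site means a site that is globally different is never
trimmed; at most 10% of a site's rows are ever removed (largest scores
first, the excess is flagged), protecting the density estimate of sites as
small as ~140. Coincident points are kept finite by flooring lrd
denominators at 1e-12, which yields the correct limiting score of 1.
Histograms, √JSD, simplex and SPO/GPD follow as above. Everything runs
top-down: once globally, then per questionnaire section. Imputation and
cell coding are done once on the full matrix and sliced per section, so a
section's result does not depend on which *other* scopes were requested
(it does, necessarily, depend on the other columns through pooled
imputation whenever blanks exist). Sections with ≤ 3 analyzable variables
skip the reduction and are histogrammed on the encoded variables directly,
with bins per dimension reduced so the total bin count stays ≤ 1000.

## Per-variable contributions

"Most influential questions" are ranked by a contribution score: for PCA,
`Σ_axes explained_a · loading_ja²`; for MCA, the per-axis category
contributions `c_j·G_ja²/λ_a` (which sum to 1 over categories within an
axis) aggregated to their parent variable and weighted by explained
inertia. Ties keep codebook order; the top 20 are reported by default.

## The synthetic generator

The generator emulates the structure the analysis assumes, with one
pseudo-random stream per (site, variable) derived from the master seed by
spawn keys — adding a variable or site never perturbs other draws.
Continuous variables are Gaussian with per-variable base mean/SD; ordinals
threshold a latent standard normal at equal-probability cut points (so a
mean shift of the latent applies to ordinals too); categoricals draw from
per-variable base probabilities, perturbed per site by a Dirichlet with
concentration `α·p_base` when a shift is configured. Site shifts move
continuous/latent means by δ·SD. Skip logic is generated by per-section
gate questions (yes/no, activation probability 0.6): gated children are
blank — *structurally* — whenever the drawn parent answer is "no".
Ordinary missingness is applied afterwards at per-(site, section) rates,
MCAR by default or MNAR with `logit(P(miss)) = logit(rate) + strength·z`
(z the standardized cell value), the simplest value-dependent mechanism.
The generator returns the injected ground truth (structural and ordinary
blank masks, shift records) for exact downstream checks.

The default scenario (`make_paper_replica`) fixes 4 sites of
142/158/197/155 participants, 130 variables in 9 sections
(18, 8, 12, 16, 18, 10, 16, 12, 20 — mixes of categorical, ordinal and
continuous chosen to resemble survey sections: all-ordinal batteries for
the psychometric scales, mixed types elsewhere), 24 gated children so the
expected not-applicable share is 24·0.4/130 = 7.4% of cells, a base
ordinary-missing rate of 0.08 plus a 0.42 rate for site C in the
interpersonal-communication and health-services sections — together ≈ 9.6%
ordinary missingness — and moderate site-specific shifts (δ between 0.5 and
1.0, α between 10 and 25) in a few sections per site. These values are the
scenario's definition, chosen once; the seeded default (`seed = 73596`) is
fixed for reproducibility.

What the generator does *not* emulate: real item wording and clinical score
distributions (EQ-5D-5L, BSI-18, HCEQ scoring), correlated item batteries
(variables are independent within a site given their section), longitudinal
waves, or interviewer effects. Passing tests therefore demonstrate that the
pipeline detects the *kinds* of incoherence it injects — mean/probability
shifts and missingness concentration — not that real cohorts carry them.

## Numerical choices and degenerate inputs

* Probability vectors are validated to sum to 1 within 1e-12 (densities) /
  1e-9 (metric inputs); √JSD values are clipped into [0, 1] against
  round-off.
* Zero-variance columns (PCA) and single-level columns (MCA) are dropped
  with warnings; a dimension with zero pooled range collapses to a single
  unit-width bin; points outside the shared grid are clamped in with a
  warning.
* All decompositions carry the largest-magnitude-positive sign convention,
  so identical inputs give byte-identical outputs across runs.
* Percentage displays round half away from zero to 1 decimal (whole-percent
  style for the overall complete share), matching common table conventions.

## Known limitations

* **Sampling floor of the GPD.** With 10³ histogram bins and ~150 cases per
  site, two samples of the *same* law already sit at √JSD ≈ 0.8, so the
  global values-branch GPD has a noise floor around 0.7 at this scale
  (exactly 0 only for literally identical point sets). GPD values at these
  sample sizes are therefore comparative, not absolute: rankings across
  sections and sites are meaningful, the distance to 0 is not. Per-section
  analyses with few variables (dense low-dimensional histograms) have much
  lower floors. This mirrors the method's documented sensitivity to sample
  size.
* Pooled imputation stabilises the variance structure but can pull a
  heavily missing site toward the pooled mean, *reducing* its apparent
  values-branch outlyingness exactly where its completeness-branch
  outlyingness is largest — the two branches are complementary and should
  be read together.
* The indicator-matrix MCA dialect understates explained inertia (a known
  property); contributions are used for ranking only.
* Single imputation, not multiple; no factor rotation; no temporal
  variability metrics.
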