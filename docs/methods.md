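# Methods

## Mixture designs and the composition simplex

A composition is a vector of q strain-inoculation proportions, non-negative
and summing to 1; the design region is the (q−1)-simplex. The {q, m}
simplex-lattice design enumerates all compositions whose entries are multiples
of 1/m — C(q+m−1, m) points — in lexicographic descending order, so repeated
generation and file export are byte-identical. Designs can be augmented with
the overall centroid (1/q, …) and axial check points ((q+1)/(2q) on one axis,
1/(2q) elsewhere); augmentation is idempotent (duplicates are never added).

Input vectors are accepted when every entry is in [0, 1] and the sum is within
1e−6 of 1 — the tolerance a CSV round-trip of thirds needs — and are then
renormalized so the stored sum is exactly 1 in floating point (the residual is
absorbed into the largest entry). Stored compositions always satisfy
|Σx − 1| ≤ 1e−9.

When a design standing in for the original bench experiment is needed (the
study's own run table is not published in machine-readable form), the default
is the {3, 3} lattice plus centroid with triplicate runs: 10 distinct points
are the minimum giving both lack-of-fit degrees of freedom for a 7-term
special cubic and pure-error replication.

## Scheffé polynomial models

Because proportions sum to one, an intercept is not identifiable and the
canonical Scheffé form is used: q linear terms (equal to the vertex
responses), C(q,2) binary blending terms, and, for the special cubic, C(q,3)
ternary terms. Term order is fixed as linear → pairs (lexicographic) →
triples, and model JSON files record term names explicitly.

Fitting is ordinary least squares without an intercept (statsmodels `OLS`).
Diagnostics follow the mixture-model convention of commercial design software:
R² and the model F-test use the total sum of squares *corrected for the mean*,
with model degrees of freedom p − 1 (the linear terms jointly absorb the
mean). Consequences worth knowing: a constant response gives R² = 0, and a
perfect fit gives R² = 1. Raw (not prediction) R² is reported. When the
design contains replicated points, the residual is partitioned into
lack-of-fit and pure error and the lack-of-fit F-test is reported; without
replicates those fields are absent rather than zero. Per-term two-sided
t-tests come straight from the OLS fit, uncorrected for multiplicity.

A rank-deficient model matrix (e.g. all points on one edge, making every
ternary monomial zero) raises an error naming the dependent columns,
identified by column-pivoted QR.

Models carry a units string; the shipped fixtures are the study's fitted
special cubics for total phenolic content (mg GAE/mL; values ≈ 1.1–1.4) and
lactic acid (g/L; ≈ 4.2), transcribed exactly as printed, no rescaling.

## GA over the simplex

The sum-to-one constraint is handled structurally rather than by penalty:

* initialization: flat Dirichlet(1, …, 1) — uniform on the simplex;
* selection: size-2 tournament;
* crossover (rate 0.8): convex blend x = λa + (1−λ)b, λ ~ U(0,1), closed
  under the simplex;
* mutation: additive Gaussian (SD 0.05 in proportion units) followed by exact
  Euclidean projection onto the simplex (O(q log q) sort-based algorithm);
* elitism: the best 2 individuals pass unchanged, so the best-fitness history
  is non-decreasing;
* stopping: 200 generations, or 50 generations without improvement > 1e−10.

Population size defaults to 50. All randomness comes from one
`numpy.random.default_rng(seed)`, so identical config + seed reproduces the
result bit-for-bit. A fitness returning NaN/inf raises an error carrying the
offending composition.

The defaults are this package's own; the original study ran a commercial
solver at unstated defaults, so generation-by-generation trajectories are not
comparable — only the optimum location is. An exhaustive lattice search
(`grid_maximize`, default step 0.005 ≙ 20 301 points for q = 3, guarded at
10⁷ points) serves as an independent oracle; ties break lexicographically.
Both optimizers agree that the phenolic-content model peaks near
(0.335, 0.310, 0.355) and the lactic-acid model at the pure third-strain
vertex — the surface there is nearly linear with the third vertex coefficient
largest, so the maximum sits on the boundary.

## Fuzzy comprehensive sensory evaluation

Panel grade counts (attributes × grades, each attribute rated by the same n
panelists) are normalized row-wise by exact division into the rating matrix
R. With attribute weights X (default 0.2/0.25/0.3/0.25 for
appearance/aroma/taste/typicality) and grade scores P (default 100/75/50/25),
the comprehensive score is Y = X·R·Pᵀ. Y is a convex combination of grade
scores, hence always within [min P, max P]; it is affine-equivariant in P and
monotone under moving rating mass to better grades.

Rating matrices are stored attribute-major (one row per attribute); the
shipped FWJ-SL05 worked-example matrix is transcribed from a source that
prints the transpose, and its provenance note records a known internal
inconsistency in that source (prose counts 7/1/2/0 normalize to
(0.7, 0.1, 0.2, 0), while the printed matrix row is (0.7, 0.2, 0.1, 0); the
printed matrix, which reproduces the published score of 88.5, is shipped
verbatim rather than silently "corrected").

## Volatile-compound screening

GC-MS tables carry absolute concentrations (mg/L); GC-IMS tables carry
relative intensities. "ND" (not detected) is a distinct missing marker, not
zero: ND contributes 0 to category totals, is excluded from detected counts,
and yields no OAV.

* OAV = concentration / odor threshold; scale-invariant under common
  rescaling of both.
* rOAV, for relative quantification, is max-normalized within a sample:
  rOAVᵢ = 100·(Iᵢ/Tᵢ)/maxⱼ(Iⱼ/Tⱼ), so the most potent compound scores exactly
  100. (The literature cites this quantity without printing a formula;
  max-normalization is adopted here as a documented convention.)
* Key-aroma screening keeps compounds with VIP > 1 **and** max-over-samples
  OAV (or rOAV) > 1, both inequalities strict; records lacking VIP or
  threshold are excluded with a logged reason, never an error. Output is
  ordered by descending activity, ties by name, for deterministic reports.
* Retention indices use the linear van den Dool convention,
  RI = 100·(n + (rt − rtₙ)/(rtₙ₊₁ − rtₙ)), and require the peak to be
  bracketed by consecutive n-alkanes.

The shipped GC-MS fixture is a verbatim transcription of the study's
five-sample table (59 compounds; means only, SDs dropped). Its threshold and
VIP columns are intentionally empty — the study's thresholds live in
unpublished supplementary material — so OAV examples in the tests use a
threshold back-calculated from the one published OAV (β-phellandrene,
OAV 58.08 at 2.32 mg/L ⇒ 0.03995 mg/L).

## Synthetic data

The generators emulate the structure of the bench data with known truth:

* **Mixture responses**: truth polynomial + i.i.d. Gaussian noise per
  replicate. Default noise SDs are 0.02 mg GAE/mL (phenolics) and 0.13 g/L
  (lactic acid), matching the magnitude of published triplicate SDs; default
  replication is triplicate. Gaussian additive noise is a deliberate
  simplification: real assay noise may scale with the mean and replicates
  share batch effects, so passing recovery tests demonstrates correctness of
  the estimator, not realism of the error model.
* **Sensory counts**: one multinomial(n, probs) draw per attribute row —
  panelists are treated as exchangeable and independent, which real trained
  panels are not.
* **VOC tables**: log-normal concentrations (median 0.2 mg/L, σ = 1 on the
  log scale), log-uniform thresholds over [1e−4, 1] mg/L, a configurable
  fraction of compounds multiplied by a fermentation effect in fermented
  samples, and a random ND mask. A planted key set gets VIP ∈ (1.1, 2] and a
  threshold below its minimum concentration; all other compounds get VIP < 1
  or thresholds above their maximum concentration, so the screen must recover
  the planted set exactly — a sharp construction that makes the test binary
  rather than statistical.

Each generator consumes one integer seed through a single
`numpy.random.default_rng`; sub-stream order is documented in the docstrings.

## Numerical choices and limitations

* Exhaustive-grid verification size (step 0.005, q = 3) and the Monte-Carlo
  repetition counts in the test suite (100–2000 replicates) were chosen as the
  smallest sizes at which the checked statistics are stable.
* Optimization of the two responses is single-objective, one model at a time;
  no Pareto treatment of phenolics vs lactic acid.
* Only the special cubic (not the full cubic) is supported; no D-optimal or
  constrained-region designs.
* VIP scores are inputs (from an external OPLS-DA); the package does not fit
  latent-variable models.
* The lack-of-fit test requires balanced detection of replicate groups;
  points are matched after rounding to 10 decimals.
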