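# Methods

## Scope and model

`phenoscreen` quantifies chemical–genetic interactions in image-based
compound screens run across a panel of isogenic cell lines. The screen
design is D compounds × L cell lines × R replicates (R = 2 is the
reference configuration), each well read out as a vector of phenotypic
features (cell number, nuclear/cell morphology, DNA/actin intensity and
texture) on a generalized-log scale.

For each feature *f* and replicate, the well values are collapsed to a
compound × line matrix and decomposed by Tukey median polish,

    y[d, c] = m + a[d] + b[c] + π[d, c],

so the robust row/column effects absorb compound and genotype main
effects and the residuals π are the interaction coefficients — the
deviation of the observed phenotype from independent combination of drug
and genotype effects. A negative cell-number coefficient is a
genotype-specific growth defect. The polish alternates row and column
median subtraction until the relative change in the sum of absolute
residuals falls below `tol` (default 1e-4); missing matrix cells are
ignored by the medians and stay missing; the even-length median is the
mean of the two central order statistics. The reconstruction identity
`y = m + a + b + π` is maintained exactly at every step.

Two numerical facts about median polish worth knowing:

* The decomposition is unique only up to the iteration path. Residuals
  are exactly invariant to global or whole-row shifts (absorbed by the
  first row sweep) but a whole-column shift can move intermediate row
  medians and change the converged residuals by a small amount (~1e-3 on
  unit-scale matrices). Tests assert exact invariance where it holds and
  a small tolerance where it does not.
* Residual noise at a planted-interaction cell is *inflated*, not
  shrunk: the cell's own noise stays while noisy row/column medians of
  the other cells are subtracted. For an L = 8 × D = 50 matrix the
  variance inflation is ≈ 1.35, i.e. the per-replicate coefficient noise
  is ≈ 1.16 σ. With σ = 0.2 and R = 2 the pooled-coefficient noise floor
  is ≈ 0.164, which bounds the achievable recovery RMSE from below.

## Cell-number normalization

Cell lines proliferate at different rates, so before polishing, the glog
cell-number values of each line are range-normalized:
`(x − kill) / (vehicle_median − kill)`, anchored at the per-line median of
the vehicle wells (→ 1) and of the strong-kill reference wells (→ 0).
Values outside [0, 1] are allowed. The kill anchor uses the per-line
median of the reference wells. The normalization is increasing, so the
sign convention of interaction coefficients is preserved.

## Significance calls

Replicate interaction coefficients are tested against μ = 0 with an
empirical-Bayes moderated one-sample t-test. Per unit (compound, line),
the sample variance s² over R replicates (d = R − 1 df) is shrunk toward
a prior, s̃² = (d₀s₀² + d·s²)/(d₀ + d), and t = x̄/(s̃/√R) with d₀ + d
degrees of freedom, capped at the total residual df of the feature's
units. The prior (d₀, s₀²) is estimated by moment matching on
log-variances: with e = log s² − ψ(d/2) + log(d/2), the moments are
E[e] = log s₀² + log(d₀/2) − ψ(d₀/2) and Var[e] = ψ′(d/2) + ψ′(d₀/2);
trigamma inversion is a Newton iteration with the standard asymptotic
guards. When the observed spread of log-variances does not exceed the
pure sampling spread the prior is degenerate: d₀ = ∞ and s₀² is the mean
observed variance, which makes the moderated t in the identical-variance
limit coincide with the ordinary one-sample t. Outside that limit the
closed forms agree with limma's `lmFit`/`eBayes` to machine precision,
which the test suite verifies both against an independently coded oracle
and against limma itself through `Rscript`.

P-values are adjusted per feature across all (compound, line) units by
Benjamini–Hochberg (statsmodels implementation behind `bh_adjust`);
interactions with adjusted p < 0.01 are called significant. In null
simulations the realized false-discovery proportion is measured per
feature family — the unit BH is applied to — and averages ≈ 0.01.

Power at the reference configuration is worth stating honestly: with
R = 2 the per-unit df is 1, so everything rides on the prior df. For
strong planted effects (|γ| = 2) at low noise (σ = 0.1) power exceeds
0.95; for |γ| ≈ 0.5–1 at σ = 0.2 power is ≈ 0.6 and limited by the
moderation df, not by the estimator.

## Feature selection

Features are selected by the stepwise residual-correlation procedure.
Starting from cell number, each iteration regresses every feature (OLS
with intercept, per replicate) on the already-selected features and
scores each feature by the Pearson correlation of the two replicates'
residual vectors — a surrogate for reproducible information not yet
captured. The best-scoring unselected feature is added; the procedure
stops when fewer than half of *all* features score positive. Two
implementation decisions matter:

* The stopping denominator includes the already-selected features, whose
  residuals are (numerically) zero and therefore count as non-positive.
  Residual vectors with norm below 1e-8 of the feature's scale are
  treated as undefined rather than scored, so numerical noise in exactly
  explained features cannot masquerade as signal. With this reading the
  procedure terminates at the planted dimension with high probability
  (the alternative reading — candidates only — sits exactly on the 50%
  boundary and terminates by coin flip).
* Ties are broken by feature name; the procedure is fully deterministic.

The benchmark generator (`gen_selection_tables`) plants 20 orthogonal
latent signals observed in both replicates (replicate correlation 0.9 at
the defaults), 40 exact linear combinations of the *observed* signal
features plus small independent noise — redundant by construction, and
strictly dominated in score by any unselected pure signal — and 40 pure
noise features, over 500 wells.

## Imaging

Nuclei are segmented from the DNA channel by local-mean adaptive
thresholding (10 × 10-pixel window; offset 10% of the dynamic range, so
a blank image yields no foreground; 1 px Gaussian presmoothing), with
hole filling (nuclei larger than the averaging window detect as rings)
and removal of objects under 20 px. The nucleus count is the cell-count
proxy. Cells are obtained by propagating the nucleus labels into an
actin mask (adaptive threshold at a 50-px window, united with the
nuclei) with a seeded watershed on the actin gradient — one region per
seed, regions disjoint and confined to the mask, which is the contract
the tests pin down; the exact frontier is not. Per-cell features cover
nuclear and cell geometry (area, perimeter, eccentricity, equivalent
radius, elongation), intensity statistics, and Haralick-style textures
(32 gray levels within the region, 1-px offset, four directions pooled,
background pairs stripped from the co-occurrence matrix; a constant
region has zero contrast). Wells aggregate per-cell features by the mean,
plus a cell-to-cell sd for the intensity features; an empty well reports
count 0 and missing aggregates. Border cropping (150 px on each side for
2048² acquisitions) removes illumination falloff.

## Synthetic screens

The generator is the package's study-condition definition, not a fixture
dump. Well values follow μ_f + α_df + β_cf + γ_dcf + ε with ε ~ N(0, σ_f)
on the glog scale; defaults: effect sds 0.5, interaction magnitudes
|γ| ∈ [0.5, 2] with random sign on a configurable sparse fraction
(default 2%), σ = 0.2 — sized so planted interactions are recoverable
with two replicates. Each plate carries vehicle (16), kill-reference (8)
and pathway-reference (4) spike-in wells; layouts auto-extend to extra
plates rather than truncate. Synthetic well images place non-overlapping
elliptical nuclei with enclosing actin bodies on a jittered grid
(packing violations raise an error), with multiplicative texture,
Gaussian noise and an optional dark border; phenotype presets cover
apoptotic-like (small bright nuclei), enlarged and elongated
morphologies. What the images do *not* emulate: optics (PSF, chromatic
effects), cell-to-cell contact and overlap, illumination gradients beyond
the border option, and real stain variability — so imaging tests show
the pipeline's correctness on geometrically clean fields, not its
robustness on real micrographs. Likewise the feature tables assume
Gaussian, symmetric noise on the transformed scale and no plate/batch
effects.

For resolution-index studies, `gen_class_structured_truth` builds a
screen of 8 target classes × 5 member compounds plus 30 inert compounds
(sparse actives, matching the ~15% interacting fraction of real
bioactive libraries; with dense actives the polish column medians absorb
class structure and leak a common mode into single-view profiles). Each
class carries a rank-one signature ψ (over lines) ⊗ φ (over features);
half the classes act through cell number across genotypes, half through
morphology, plus per-member jitter.

## Profiles, clustering, network, resolution index

Compound profiles are the pooled (replicate-mean) interaction
coefficients flattened over (line, feature) cells, in three views:
`combined` (all features × all lines), `genotypes_only` (cell number ×
all lines) and `phenotypes_only` (all features × the reference line).
Dissimilarity is 1 − Pearson correlation (pairwise-complete; constant
profiles are flagged undefined and excluded). Clustering is complete
linkage (scipy); reported clusters cut the tree at height 0.6 and keep
sizes 3–9. The interaction map keeps compounds hitting at most 3
genotypes and at least 2 distinct features, drawing an edge per
(compound, genotype) with at least one significant feature; the graph
exports to GraphML and a flat edge list, the dendrogram to Newick (with
label quoting).

The resolution index ΔAUC integrates each pair class's ECDF of profile
correlations exactly over the fixed interval [−1, 1] (so the index is
comparable across feature views) and reports AUC(non-shared) −
AUC(shared): positive when shared-selectivity (or similar-structure,
Tanimoto distance strictly below 0.6) pairs are more correlated. Signed
correlations are used, matching the ECDF-shift reading of the index.

## Drug combinations and proteasome statistic

Plate-reader values are log-transformed (natural log; the base cancels);
NPI = (log p̄ − log x)/(log p̄ − log n̄) with control log-means p̄, n̄,
and the effect is E = 1 − NPI (0 at the untreated level, 1 at full
kill). Bliss independence per dose: E_AB = E_A + E_B − E_A:B, with the
interaction term estimated by plugging in arm means; E_A:B < 0 is
synergy. The default test exploits the fact that on the log-raw scale
independence is exactly the four-mean contrast
l̄_A + l̄_B − l̄_AB − l̄_neg = 0, and forms a Welch t from the four
variance components with Welch–Satterthwaite df. Including the
negative-control mean matters: the naive two-sample comparison of
E-scale values leaves the per-plate control-mean sampling error
unaccounted and is anticonservative (measured type-I ≈ 0.084 at 16
control wells vs. 0.048 for the contrast form at α = 0.05). A plug-in
one-sample variant (combination replicates against the constant
mean(E_A) + mean(E_B)) is kept as an option. Analysis is strictly
per dose; no pooling across the dilution series.

Proteasome inhibition is 100·(1 − (PT/PC)/(VT/VC)) — treated/control
proteasome activity corrected by treated/control viability — so vehicle
gives 0%, complete inhibition 100%, and proportional (purely cytotoxic)
loss cancels to 0%. Replicates are tested by a one-sample, one-sided t
against 0; zero-variance limits are reported explicitly (t = ±∞ with
p ∈ {0, 1}, and t = 0, p = 0.5 when all values are exactly zero).

## Problem sizes used by the test suite

Simulation-backed tests run at desk scale, chosen to keep Monte-Carlo
error well inside the asserted margins: interaction null calibration uses
100 screens of 50 × 8 × 10 × 2; power uses 60 × 8 × 10 with 50 planted
effects; feature selection uses 500 wells × 100 features over 20 seeds;
the resolution-index ordering uses 70-compound screens over 20 seeds;
combination calibration uses 500 grids (type I) and 200 grids (power);
imaging recovery covers k = 1..50 cells on 360² fields.

## Known limitations

* Median-polish noise inflation bounds coefficient RMSE at
  ≈ 1.16 σ/√R regardless of implementation (see above).
* With R = 2 the moderated test's power for moderate effects depends
  strongly on the estimated prior df, which is itself noisy at a single
  residual df per unit; prior-recovery tests therefore judge the moment
  estimators by their median over simulations.
* The feature list is a representative family set, not a reproduction of
  any specific 385-feature catalogue; QC rules (blank/saturated wells)
  are generic failure modes, not a reconstruction of any screen's
  criteria.
* Structural distances are consumed, never computed from chemical
  structures; the synthetic distance matrix only guarantees the
  class-separation property the classifier needs.
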