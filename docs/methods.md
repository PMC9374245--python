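# Methods

This note documents the statistical procedures implemented in
`skullmorph`, the choices made where the methodology is genuinely open,
and what the bundled synthetic data generator does and does not emulate.

## Superimposition

**Generalised Procrustes Analysis.** Configurations are centred, scaled
to unit centroid size, and iteratively rotated to the running consensus;
the consensus is the coordinate-wise mean, renormalised to unit centroid
size while scaling is enabled. This is *partial* Procrustes: no further
scaling happens inside the rotation step, matching the default of the
standard geometric-morphometrics toolchains. Convergence is declared
when the root-mean-square consensus change drops below `tol = 1e-8`
(default), with `max_iter = 100`; non-convergence sets a flag rather
than raising, since a nearly converged alignment is still usable.
Reflections are disallowed in every fit (rotations are constrained to
determinant +1): left/right anatomy must never flip, and the Procrustes
distance between a shape and its mirror image is deliberately non-zero.

Because any joint rotation of a GPA solution is equally optimal, the
final alignment is put in a canonical orientation — principal axes of
the consensus, with deterministic axis signs and determinant +1 — so
that results are invariant to input order and to rigid pre-motion of the
raw data. With highly symmetric consensus shapes (near-equal principal
axes) this canonicalisation is still deterministic but the orientation
becomes sensitive to small perturbations; none of the analyses downstream
depend on the global orientation.

**Sliding semilandmarks.** Semilandmarks slide along the chord between
their two anchor landmarks. With tangent directions held fixed, both
criteria — bending energy of the TPS anchored on the consensus
(default, the classical choice of the standard sliding tools) and plain
Procrustes distance — are quadratic in the slider displacements, so the
joint minimiser is obtained by one linear solve per specimen rather
than a coordinate-wise Gauss–Seidel sweep; this is the exact minimiser
of the same linearised objective. Sliding runs during the first
`slide_iters = 5` outer GPA iterations only: the chord-tangent
linearisation otherwise lets semilandmarks creep along the curve
indefinitely against a moving consensus (a constant ~1e-4 consensus
drift per iteration in our diagnostics), whereas a small fixed number
of passes followed by plain GPA converges cleanly — the behaviour of
the standard tools. Sliding is implemented for 2-D data (curves on
photographs); 3-D surface semilandmarks are out of scope.

**Thin-plate splines and missing landmarks.** TPS uses the kernel
`r² log r` in 2-D and `|r|` in 3-D, with the full affine part in the
polynomial term, so any affine map is reproduced exactly. Missing
landmarks are estimated within a reference group (by default the
specimen's species): the consensus of the group's *complete* specimens
(incomplete specimens never inform the reference) is TPS-warped onto
each incomplete specimen through their shared landmarks, and missing
positions are read off the warped consensus. Observed coordinates are
never altered. This is exact for specimens that are affine images of
the consensus and degrades gracefully with landmark noise. Query
specimens of unknown affinity can be estimated within a configured
reference group instead of their own (unknown or unreliable) label.

**Landmark-sampling curve.** Random landmark subsets of growing size
are GPA-aligned and their specimen ordinations (PCA scores) compared to
the full-scheme ordination by orthogonal Procrustes superimposition
with scaling; the fit is `1 − residual SS / total SS`, clamped to
[0, 1], so the full scheme scores exactly 1. The published description
of this diagnostic names the tool rather than the statistic; our
definition is pinned by the fit-at-k = 1 invariant and the redundant-
landmark saturation property, both tested.

## Shape statistics

**Procrustes ANOVA.** Sequential (type-I) decomposition of the summed
squared Procrustes deviations over ordered model terms built from
covariates, factors (dummy-coded) and `:`-interactions; `F` uses the
full-model residual mean square. Significance comes from permutation,
by default randomisation of reduced-model residuals (RRPP) — each
term's null permutes the residuals of the model containing all earlier
terms — with raw-response permutation available. The default count is
999 permutations, common practice where the original analyses leave the
count unstated. P counts the observed statistic in both numerator and
denominator, so `P ≥ 1/(permutations+1)`. The effect size Z is the
standardised position of log F within the permuted log-F distribution
(the convention of the RRPP lineage); Z values are therefore comparable
only approximately across software. A single-column response runs the
identical engine for size models (e.g. CS ~ sex, deliberately on CS
rather than log CS for the size-dimorphism panel).

**PCA and allometry-free shapes.** Shape PCA is the SVD of centred
Procrustes coordinates, truncated to numerical rank; dropping landmarks
re-runs GPA before the decomposition, since removing landmarks changes
the optimal superimposition. Allometry-free shapes are residuals of
shape on log CS (common slope, or per-group slopes), re-centred on the
grand mean so they remain valid coordinates for ordination.

## Classification

**UPGMA** uses average linkage; cophenetic distances live on the input
distance scale (the merge distance of the lowest common node), while
drawn dendrogram heights are half that. The cophenetic correlation is
Pearson's r between condensed input and cophenetic distances, reported
as NaN with a warning when all input distances are equal. Bootstrap
supports resample variable columns with replacement and score each
original internal node by the percentage of replicate trees containing
the identical specimen set.

**Stepwise LDA.** Forward selection with removal on Wilks' lambda:
the candidate with the largest partial F enters while `F ≥ f_in`,
retained predictors with partial `F < f_out` leave. Defaults
`f_in = 3.84, f_out = 2.71` (the classical defaults of the statistical
packages this procedure originates from); both configurable, and
`f_out < f_in` is enforced to prevent cycling. The two-group
discriminant direction is `pooled_cov⁻¹ (m₁ − m₂)`; Wilks' lambda is
tested with the Bartlett chi-square `−(n − 1 − (p+g)/2) ln Λ` on
`p(g−1)` degrees of freedom. Cross-validation is leave-one-out with the
predictor set held fixed (the convention behind published stepwise-DFA
cross-validation rates); this flatters the error rate when selection is
data-driven, so treat the CV rate as an upper bound unless selection is
re-run per fold.

**k-means (k = 2)** is Lloyd's algorithm, best of 25 seeded restarts by
within-group sum of squares; a run that empties a cluster is redrawn.
Assignment ties go to the lower cluster index and the cluster containing
the first specimen is labelled 0, making results deterministic for a
given seed. It agrees with scikit-learn's objective on test problems and
with exhaustive 2-partition enumeration on small ones.

## Integration

Two-block PLS takes the SVD of the between-block covariance matrix of
centred shape-variable blocks; a 2-D block analysed against a 3-D block
is zero-padded with a third coordinate per landmark, which leaves
covariances unchanged. The permutation test re-randomises specimen
correspondence between blocks with the first singular value as the
statistic (the dominant-axis focus), observed included in the null set.

Angles between singular-axis vectors are folded into [0°, 90°] because
shape-axis signs are arbitrary. The null distribution of the folded
angle between two independent uniform directions in dimension p follows
from `cos²θ ~ Beta(1/2, (p−1)/2)`, giving a closed-form P. The
effective dimension matters and is genuinely ambiguous for Procrustes
data, which are rank-deficient after superimposition (rank
`kd − d(d+1)/2 − 1` at most, less with few specimens): we default to
the rank of the group-centred data actually entering the analysis, and
always report the dimension used, with a user override. Published angle
P-values computed by other tools may therefore differ even at an
identical angle.

## Synthetic data generator

The generator emulates exactly the structure the analyses assume: two
species with template shapes separated along a localised
rostrum-elongation direction; species-specific allometric shape vectors
over log CS; log-normal size with sexual size dimorphism in the
narwhal-like species only (males larger); isotropic Gaussian landmark
noise added in shape space before random rigid placement and
centroid-size scaling; F1 hybrids built per skull part (default:
cranium at the species midpoint shifted 25 % of the inter-parent
distance toward the beluga template, mandible purely narwhal-like, size
at the larger parent's upper quartile — the mosaic phenotype of
documented narwhal-beluga hybrids, encoded as a reusable illustrative
scenario); and random missing-landmark masks that spare the first
`d + 1` anchor landmarks and always leave at least two complete
specimens per species so a reference consensus exists.

Default effect sizes (species offset magnitude 0.20, allometric slopes
0.63/0.46, noise sd 0.0085 per coordinate at k = 16) were calibrated
once by simulation so that, at about 150 specimens, the species term
explains roughly 0.45 and common allometry roughly 0.26 of shape
variance — the regime of strongly diverged sister species with shared
allometry — and are fixed.

What the generator does **not** emulate: digitising error structure
(anisotropic, landmark-specific), articulated or fragmented specimens,
asymmetry, ontogenetic series, curve semilandmarks with genuinely
arbitrary spacing, or any biomechanical covariation between skull parts
beyond what species and size structure induce. Passing tests on
synthetic data therefore validate the statistical machinery and its
calibration, not the biological fidelity of any particular empirical
dataset.

## Problem sizes and numerics

The test suite exercises the pipeline at modest sizes chosen to keep a
full run in well under a minute per module: parameter recovery uses 200
replicates of 120 specimens × 16 landmarks; null calibration of the
permutation ANOVA uses 200 datasets at 199 permutations; the acceptance
script simulates the full study structure (157 crania, 85 mandibles) at
999 permutations and 500 bootstrap replicates and completes in seconds.
Numerical tolerances: GPA consensus tolerance 1e-8; rank thresholds at
1e-10 of the leading singular value; permutation-tie comparisons use a
1e-12 slack so exact ties count as exceedances. Every stochastic
operation takes an explicit seed and all seeds are recorded in run logs.

## Known limitations

- Two-group machinery: stepwise selection and LDA keep the group count
  general in the formulas but are tested and supported for g = 2.
- No phylogenetic comparative methods, no modularity statistics
  (CR/RV), no >2-block PLS.
- Sliding semilandmarks are 2-D only; no surface semilandmarks or
  bilateral-symmetry decomposition.
- The fixed-selection cross-validation convention (see above) inherits
  the optimism of the tools it mirrors; use the nested route for honest
  error estimates.
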