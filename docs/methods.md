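# Methods

## Problem and model

Given a matrix of per-gene log2 fold changes (rows = genes, columns =
treatment–control contrasts from one or more expression experiments) and a
two-class gene labeling (e.g. membership in the ethylene vs. jasmonic-acid
signaling pathway), `gsiscan` ranks every low-dimensional feature subset by
how well the two gene groups separate when the data are projected onto it.
The intended use is exploratory: the top-ranked subsets are the scatterplot
axes on which the two pathways look most distinct.

Separation is quantified through a classifier. Each class *j* is modeled as
a finite Gaussian mixture

    f_j(y) = Σ_{k=1..G_j} τ_jk · N(y | μ_jk, Σ_jk),

fitted per class by maximum likelihood via EM, and a point is assigned to
the class maximizing the Bayes posterior τ_j f_j(y) / Σ_k τ_k f_k(y), with
class priors τ_j equal to the training class proportions. This
mixture-discriminant formulation generalizes LDA/QDA: a near-origin
component absorbs the bulk of non-differentially-expressed genes while
additional components capture displaced, biologically active subpopulations
— structure a single-Gaussian-per-class model cannot represent.

The Group Separation Index of a feature subset is

    GSI = 1 − ε̂_rcv,

where ε̂_rcv is the repeated stratified K-fold cross-validated
misclassification error rate (MER) of that classifier on the subsetted
data. MER = (n_{1|2} + n_{2|1}) / (N_1 + N_2) is the maximum-likelihood
estimate of the total probability of misclassification
TPM = p_1 P(2|1) + p_2 P(1|2) with priors taken as the observed class
proportions; an optional cost pair (c(1|2), c(2|1)) generalizes it to
asymmetric losses (unit costs by default).

## Covariance parameterizations and model selection

Six covariance structures are supported — spherical, diagonal and full,
each either shared ("equal") across components or component-specific
("varying"); these are mclust's EII, VII, EEI, VVI, EEE and VVV models.
Within each class, every (G, parameterization) pair with 1 ≤ G ≤ G_max is
fitted and the model with the highest BIC (larger-is-better convention,
2ℓ − k·log n, as in mclust) is kept; ties break toward smaller G and then
toward the earlier family entry. The default cap G_max = 2 keeps the
parameter count manageable on class sizes of a few dozen genes; larger caps
routinely produce degenerate fits at these sample sizes.

Free-parameter counts follow mclust's convention (G−1 weights, G·d means,
plus 1, G, d, G·d, d(d+1)/2 or G·d(d+1)/2 covariance terms) and are
verified against `mclust::Mclust`'s `df` in the test suite, along with
log-likelihood and BIC agreement on a reference dataset.

One semantic corner is resolved deliberately: the "-equal" constraint ties
the covariance across the components *of a class* in general, but in the
single-component, all-equal configuration (`G_max=1` with an equal-only
family) it ties the covariance across the two classes as well. The model
`family={"full-equal"}, G_max=1` is then estimated by pooling the
within-class scatter across classes and is exactly Fisher LDA (mclust's
EDDA/"EEE"); the diagonal and spherical analogues are diagonal/spherical
LDA. Without this cross-class pooling, separately fitted single components
would always yield class-specific covariances, i.e. QDA, and the documented
LDA equivalence would be unattainable.

## EM details

* Initialization: hard k-means assignment (scikit-learn `KMeans`,
  `n_init=1`) with a seed derived deterministically from the master seed,
  class index, G and parameterization index, so identical inputs and seeds
  give bit-identical fits regardless of evaluation order or worker count.
* Convergence: relative log-likelihood change below `tol` (default 1e-8) or
  500 iterations. The observed-data log-likelihood trace is retained and is
  non-decreasing by construction of the constrained M-steps.
* Degeneracy handling: whenever a covariance update is not positive
  definite, a ridge of 1e-6 × (mean diagonal variance of the data) is
  added; if the matrix is still singular, or a component's responsibility
  mass collapses to zero, the fit aborts with a degenerate-fit error. During
  cross-validation such per-fold failures trigger a logged structural
  fallback to a single component for the offending class.

## Cross-validation protocol

Stratified K-fold partitions (per class, fold sizes differ by at most one;
`StratifiedKFold` with a fixed seed) are repeated with a list of seeds:
one K-fold CV per seed, seed batches of C averaged into "runs", and the
mean of the run GSIs reported. The defaults K = 10, C = 10 with seed list
1..50 give five 10 × 10-CV runs; the seed values themselves are arbitrary
but fixed for reproducibility.

"Use the same fitted model for every fold" is read structurally: the
per-class component count and parameterization are selected once by BIC on
the full subsetted data, and each training fold refits only the mixture
*parameters* under that fixed structure (warm-started from the full-data
estimates). Reusing the fitted parameters themselves would evaluate each
validation fold with a model trained on it, defeating cross-validation;
`CvSpec(refit_structure_per_fold=True)` offers the stricter alternative
that re-selects structure within every training fold. Fold MERs are
averaged unweighted — stratified fold sizes differ by at most one object,
so size-weighting is immaterial.

## Scan, ranking, ties

For subset size M ∈ {2, 3, 4} all C(p, M) subsets are enumerated in
lexicographic order of sorted feature ids (23 features: 253, 1,771 and
8,855 subsets), each is scored by the repeated-CV GSI, and ranks are
assigned in descending order with the min-rank ("1224") convention. Tie
detection operates at 3 decimal places by default — the precision at which
GSI tables are printed — with exact-float comparison available
(`tie_decimals=None`). Subsets whose classifier fails are reported with a
failure flag and excluded from ranking, never silently dropped. M > 4 is
not offered: scatterplot matrices beyond four panels per side stop being
readable, which is the point of the tool.

## Permutation significance

For a chosen subset, class labels are randomly reassigned across genes
(class counts preserved), the GSI recomputed with the same CV machinery,
and the p-value estimated with the add-one (Phipson–Smyth style) rule
p = (1 + #{null ≥ observed}) / (1 + M), which cannot be zero and is exact
under exchangeability. Because only the shape of the null matters, the null
(and then also the observed) GSI may be computed with a reduced
configuration — e.g. a single 10-fold CV per permutation — via
`null_spec`; observed and null values are always computed identically so
they remain exchangeable under the null.

## Synthetic data generator and Bayes oracle

The generator emulates the geometry of a multi-experiment log2-fold-change
matrix: a chosen pair (or set) of informative features carries class-
specific Gaussian mixture structure, and every other feature is
class-independent N(0, noise_sd²) noise, so planted-subset recovery has
exact ground truth. The default fixture mirrors the two-pathway setting:
23 contrast ids laid out as five experiments (1-1, 2-1..2-3, 3-1..3-2,
4-1..4-8, 5-1..5-9), informative pair ("4-7", "4-8"), class JA (n = 48) a
0.6/0.4 mixture of N((0,0), 0.25·I) and N((2.276, 1.663), 0.5·I), class ET
(n = 86) a single N((0.537, 0.406), 0.5·I). The component centers and class
sizes are reported values from the real-data analysis this fixture
emulates; the mixture weights, covariances and the 0.5 noise sd are
declared fixture constants chosen to match the published scatterplot
geometry and are not reported numbers.

`bayes_error_mc` estimates the optimal-rule TPM by Monte Carlo from the
true densities and priors (binomial standard error reported; minimum
mc_n = 10⁴). It is the independent oracle against which the CV estimator is
judged. What the generator does **not** emulate: correlated noise across
contrasts, batch structure between experiments, heavy tails, or the
count-level sampling noise of the upstream fold-change estimation — so a
passing suite certifies the estimator machinery, not robustness to those
real-data features.

`sample_size_study` regenerates data at a grid of per-class sizes and
reports the mean repeated-CV GSI, its bias against the oracle, and its SD
across regenerations — the variability of the GSI estimate shrinks and its
bias contracts as n grows, which is the practical justification for
trusting single-run GSIs at large n.

## Visualization

`scatterplot` renders a 2-feature projection: class-colored points, one
ellipse per fitted mixture component tracing the Mahalanobis contour at a
χ²₂ probability level (default 0.95, configurable — the level is a display
choice, not part of the model), a dashed square at ±1 log2 unit (the
2-fold-change boundary), and caller-supplied outlier genes labeled by name.
`scatterplot_matrix` tiles all pairwise panels for 3- and 4-feature
subsets with per-feature class densities on the diagonal.

## Problem sizes used by the test suite and acceptance script

Statistical checks run at sizes chosen to make their assertions sharp while
keeping the default suite quick: Bayes-error recovery averages full
10 × 10-CV estimates over 10 generated datasets of 500 genes per class
(the average's sampling SD ≈ 0.004 is small against the oracle band);
planted-subset recovery uses 20 replicates of 8 features × 60 genes per
class with a (3, 3) shift and single-run 10 × 10 CV; permutation
calibration uses 200 replicates of a 30-per-class null with 19 permutations
and a single 10-fold CV per GSI; the sample-size study uses 8 replicates at
n = 50 and 500. Reduced-tolerance EM (tol = 1e-6) is used in these bulk
runs; spot checks confirm it does not change selected structures or GSIs at
the precision asserted.

## Known limitations

* Two classes only; multi-class GSI is out of scope.
* Exhaustive enumeration scales as C(p, M); for p much beyond a few dozen
  features at M = 4 the scan is expensive by design (no heuristic search).
* The EM fits full/diagonal/spherical structures only — no
  volume/shape/orientation decompositions beyond the six models, and which
  parameterizations the original real-data analysis had available is not
  documented, so the six-model family is a declared choice.
* Missing values are rejected rather than imputed; the EM has no
  missing-data mechanism.
* The permutation test covers one subset at a time; no family-wise
  correction across the C(p, M) scanned subsets is attempted.
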