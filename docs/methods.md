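# Methods

This note documents the statistical procedures implemented in `pananet`,
the design decisions taken where the procedure left genuine freedom, and
what the synthetic benchmark does and does not demonstrate.

## Overview

The pipeline turns a gene expression matrix **X** (N genes × M samples)
and a pathway annotation F (gene sets) into a network of *pathway
profiles*:

1. **Compression** — each pathway's expression submatrix is reduced by
   PCA to the few score vectors ("profiles") that carry statistically
   significant coordinated variation.
2. **Rule inference** — profile pairs are connected by *direct* or
   *opposite* association rules found on an entropy-optimal binary
   discretization of the profile matrix.
3. **Driving genes** — for each profile, the genes that dominate its
   loadings are identified by a density-valley cutoff.
4. **Validation** — an inferred network can be scored against an external
   gene-pair association table.

## Phase 1: pathway compression

For pathway *f* with N_f measured genes, the submatrix X_f is transposed
and column-mean-centred (each gene centred across samples), giving
X_f^c = T_f P_f^t + E with scores T_f (M × h_f) and unit-norm loadings
P_f (N_f × h_f). PCA is computed by SVD of the centred M × N_f matrix;
eigenvalues are squared singular values divided by (M − 1), so the
eigenvalue spectrum of a pathway lives on the same scale as per-gene
sample variances (ddof = 1 throughout).

**Significance by bootstrap.** The number of retained components h_f is
decided against the genome-wide gene-variance distribution rather than
any within-pathway criterion. In each of R bootstrap repetitions:

* M sample columns are drawn with replacement (one index vector per
  repetition, shared by all pathways and by the cutoff computation — the
  reading that keeps the cutoff and the eigenvalues on the same
  resample);
* a gamma distribution is fitted to the N per-gene variances of the
  resampled full matrix and its (1 − α) quantile becomes the eigenvalue
  cutoff for that repetition;
* for each pathway, the number k(r) of eigenvalues of the resampled
  submatrix above the cutoff is recorded.

Because eigenvalues are ordered, the selected index set in each
repetition is the prefix 1..k(r); the selection frequency of rank i is
therefore the fraction of repetitions with k(r) ≥ i, and h_f is the
largest i whose frequency strictly exceeds Q. Defaults: α = 0.05,
R = 100, Q = 0.95. R is not prescribed by the procedure itself; 100
makes a 0.95 frequency threshold meaningful at modest cost. Final scores
and loadings always come from a single PCA of the original
(un-resampled) submatrix.

The gamma fit is maximum likelihood with the location fixed at zero
(`gamma_method="mle"`); a method-of-moments variant is exposed for
sensitivity analysis. Zero variances are excluded from the fit; an
all-constant matrix is a degenerate-fit error. Pathways with fewer than
two measured genes, or h_f = 0, are excluded from the Pathway Level
Matrix (PLM), the row-wise concatenation of all retained score vectors.

**Sign convention.** PCA signs are arbitrary; each component is flipped
so its largest-magnitude loading is positive, which makes exported
profiles and direct/opposite labels reproducible. Driving genes use
absolute loadings and are invariant to this choice.

## Phase 2: association rules

For a target profile j, the PLM is discretized into ±1 activity states:
row j at its own mean, and every other row l at the threshold t_lj that
minimises the *partition entropy* — the size-weighted binary Shannon
entropy (base 2, 0·log 0 ≡ 0) of j's states within the two sample sets
{PLM_l ≤ t} and {PLM_l > t}. Candidate thresholds are exactly the M
observed values of row l (the search is exhaustive by construction);
ties resolve to the smallest threshold. Samples equal to the threshold
go to the low partition. Constant rows, and rows whose optimal threshold
leaves one state empty, are excluded.

Each ordered pair (l → j) from *different* pathways is then scored from
the 2×2 contingency of (states_l, states_j). The direct class predicts
the target state equal to the source state, the opposite class predicts
the inverse; accuracy is sensitivity × specificity of the prediction and
the better class is kept (ties, which have measure zero on continuous
scores, go to direct). Rules with accuracy ≥ the threshold (default
0.9) survive. Intra-pathway pairs are excluded because profiles of one
pathway are orthogonal by construction, so any rule between them is an
artefact of discretization. Both orientations are evaluated
independently; `build_network(dedupe=True)` merges mutual same-class
pairs into one undirected edge keeping the higher accuracy.

## Driving genes

The distribution of a profile's absolute loadings is typically at least
bimodal: a tall mode of near-zero loadings (genes that do not contribute)
and one or more modes of substantial ones. The cutoff is the abscissa of
the first local minimum — scanning upward from zero — of a Gaussian KDE
(Silverman bandwidth) evaluated on a 512-point grid over
[0, 1.05·max]. A local minimum necessarily follows the first mode, so
this is the valley separating negligible from important loadings; exact
plateaus resolve to their leftmost point. When the density is unimodal
on the grid (e.g. a fully coordinated pathway where all loadings are
comparable), no cutoff exists and the report falls back to the single
top-loading gene, flagged `no bimodality`. Fewer than five loadings also
triggers the fallback. The cutoff is scale-equivariant because both the
bandwidth and the grid scale with the data.

## Network validation

Given a symmetric nonnegative gene-pair score table, the association
strength of a pathway pair, ASp, is the sum of scores over all distinct
unordered gene pairs with one member in each pathway; a gene shared by
both pathways is never paired with itself, and a shared pair is counted
once. ASn is the arithmetic mean of edge ASp values. Enrichment is
reported two ways:

* a percentile table (linear-interpolation empirical quantiles, default
  the twelve percentiles 10–100%) comparing edge ASp against the
  *universal set* — all pathway pairs with ASp > 0;
* a per-edge percentile against a cardinality-matched null: n random
  pathway pairs drawn uniformly without replacement from the score
  table's gene universe, preserving (|i|, |j|, |i∩j|). The percentile is
  mid-rank ((#less + ½·#equal)/n), so an edge exchangeable with the null
  sits near 0.5.

The report also includes the pathway-size vs ASp Pearson correlation
(ASp is a sum, so independence of size is a diagnostic, not an
assumption) and a Welch two-sample t-test of edge ASp against one
cardinality-matched null draw per edge.

## Synthetic benchmark

The generator plants a known pathway structure on a full factorial grid:
pathway size × simulated expression profile (SEP) × inner-correlation
fraction ρ, one pathway (a disjoint gene block) per cell. In a block of
size g, the first round-half-up(ρ·g) genes take the SEP as their mean
profile and the rest have mean zero; every gene receives independent
N(0, s) noise per sample (multivariate normal with covariance s·I — the
simplest covariance consistent with a single scalar noise level).
Defaults reproduce the benchmark conditions: sizes 10/60/100/140/200,
SEPs 1–7, ρ ∈ {0, .2, .4, .5, .6, .7, .8}, M = 36 samples, s = 0.01 —
245 pathways and 24,990 genes. Samples are treated as arbitrary ordered
observations; no specific time design is assumed.

**SEP library.** The seven temporal patterns — linear up-ramp, convex
exponential down-ramp, single peak, single trough, one-cycle sinusoid
(cosine phase), two-cycle sinusoid, and a midpoint step — are evaluated
at t = (m + ½)/M and standardized to zero mean, unit variance. Their
free geometry was fixed once by two non-redundancy criteria: (a) no two
patterns are collinear (max pairwise |r| ≈ 0.90 at M = 36; literal
mirror-image up/down ramps or peak/trough would be perfectly
anticorrelated, hence the convex down-ramp and the offset trough), and
(b) no pattern's mean-split discretization is reproducible by
thresholding another pattern — the property that actually governs
cross-profile rules under the adaptive discretization — except for the
up-ramp/step pair, where the coincidence is geometrically forced: a
monotone ramp splits at the midpoint exactly like the step. That forced
coincidence is why, at the default operating point (α = 0.05, accuracy
0.9, s = 0.01), roughly three quarters of direct links join pathways
with the same SEP and the rest are ramp–step links, with a mean linked
profile correlation near 0.97.

**What the benchmark does not emulate**: shared genes between pathways,
batch or array effects, non-Gaussian or gene-correlated noise,
heteroscedasticity, or realistic pathway-size distributions. Passing the
benchmark shows that the estimator recovers planted low-rank structure
and its couplings under isotropic noise; it does not certify behaviour
on real microarray data, where profile selection depends on the shape of
the genome-wide variance distribution.

## Numerical notes and edge cases

* Variances, eigenvalues: ddof = 1; gamma fit excludes zeros.
* round(ρ·g) is round-half-up (documented because banker's rounding
  would change planted gene counts at ρ·g = .5 boundaries).
* Discretization comparison is "≤ threshold → low state".
* An empty PLM (no pathway retains a profile) raises an explicit error
  suggesting a larger α rather than returning an empty object.
* Duplicate expression rows keep the first occurrence; rows with missing
  values are dropped (PCA assumes complete data — no imputation).
  Annotation genes absent from the matrix are ignored per pathway;
  N_f counts measured genes only.
* Duplicate score-table pairs keep the maximum; self-pairs are invalid.
* Problem sizes in the test suite: the full factorial design is used for
  the operating-point and noise-robustness checks (five seeds and three
  noise levels respectively, R = 100); unit and property tests run on
  reduced designs (e.g. 2 sizes × 7 SEPs × 3 fractions) chosen to keep
  the planted-signal geometry while making the suite quick to run.

## Known limitations

* Component selection compares pathway eigenvalues to a genome-wide
  variance quantile; in datasets where most genes carry signal the
  cutoff is conservative, and in nearly all-noise datasets small noise
  blocks can clear it (eigenvalue concentration exceeds the variance
  quantile). This is a property of the procedure, not of the
  implementation.
* The rule search is pairwise; multi-antecedent and time-lagged rules
  are out of scope.
* The minAS fallback reports a single driving gene for unimodal loading
  densities; "many equally contributing genes" and "one dominant gene"
  are not distinguished beyond the flag.
* GraphML exports stringify provenance parameters; round-tripping
  preserves values as strings.
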