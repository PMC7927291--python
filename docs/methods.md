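# Methods

## The prediction pipeline

The library implements a multimodal brain–behaviour prediction pipeline in
which all adaptive steps are nested inside cross-validation folds. For each
fold and each modality, the training rows alone determine the per-voxel
z-normalisation statistics (sample SD, ddof = 1), the mass-univariate
Pearson screening, and the feature selection; the held-out rows are
transformed with the training statistics and only then predicted. Fused
(multimodality) predictions are arithmetic means of the mono-modality
predictions — fusion happens strictly after per-modality training, so it can
reduce prediction variance without touching selection or fitting.

Feature selection is Bonferroni by default: keep voxels with
`p < α / p_modality`, where `p_modality` is the modality's full feature
count and p-values are two-sided, from `t = r√((n−2)/(1−r²))` at df = n − 2.
Two-sided screening is used because predictive voxels of both signs are
expected and reported. The relaxed mode keeps `p < 0.001` and, when fewer
than `min_features` (default 10) pass, falls back to the `min_features`
smallest p-values (ties broken by ascending voxel index). Zero-variance
columns receive r = 0, p = 1 and can never be selected. An empty Bonferroni
selection is a signal, not an error; the pipeline's fallback is to predict
the training mean for that modality-fold and log a warning.

If a fold's predictions are constant, the out-of-fold Pearson r is reported
as NaN with a warning; MAE is always defined.

## Relevance vector regression

RVR is Bayesian linear regression with an independent Gaussian prior
`w_i ~ N(0, 1/α_i)` per basis function and type-II maximum likelihood over
`α` and the noise variance `σ²`. The default basis is the linear kernel on
training samples, `Φ = K = X Xᵀ`, the convention of kernel machines used for
voxel-wise neuroimaging data where features vastly outnumber subjects; a
primal-features basis (`Φ = X`) is available and is what the pipeline's
spec-level behaviour reduces to algebraically, via the identity `w = Xᵀμ`.
The kernel is not centred: pipeline inputs are z-scored per voxel, which
makes centring nearly moot; the intercept is handled outside the Bayesian
machinery by centring `y` on the training mean and adding it back at
prediction. A consequence worth knowing: exact representability of a planted
linear rule by a single basis assumes (approximately) centred features, which
the pipeline's z-scoring guarantees.

The default optimizer is the original batch re-estimation:
`γ_i = 1 − α_i Σ_ii`, `α_i ← γ_i/μ_i²`, `σ² ← ‖y − Φμ‖²/(n − Σγ)`, pruning
bases with `α > 10⁹`, stopping when `max |Δ log α| < 10⁻⁶` or after 1000
iterations (all configurable). Two numerical guards matter in practice.
First, the `σ²` update is skipped whenever `Σγ > 0.95 n`: in that regime the
model absorbs nearly all degrees of freedom, the denominator `n − Σγ`
vanishes, and the update would drive `σ²` to zero (the interpolation
collapse that occurs when the basis count is comparable to `n` and all bases
start active). Second, posterior evaluations reuse a precomputed Gram matrix
and solve only the active submatrix.

A fast sequential optimizer (`optimizer="fast"`) is also provided: it starts
from the single best-aligned basis and repeatedly applies the one action —
add a basis, delete one, or re-estimate its precision — that most increases
the marginal likelihood, using the closed-form sparsity and quality factors.
It reaches markedly sparser solutions than the batch fixed point when many
bases are redundant, at the cost of a more conservative noise estimate
(`σ²` is re-estimated only every tenth action, and only while the model
leaves at least 5% of the degrees of freedom to the residual). The batch
fixed point on heavily redundant bases is known to retain low-weight
stragglers; this is a property of the batch updates, not a defect of the
sparse solution, and the sequential variant is the right tool when the
active-set size itself is of interest.

With hyperparameter updates frozen, the posterior mean is exactly the
generalised ridge solution `(σ⁻²ΦᵀΦ + A)⁻¹σ⁻²Φᵀy`; the test suite holds the
implementation to this identity at 10⁻⁸ relative error.

The linear-regression baseline is the minimum-norm least-squares solution
via pseudo-inverse on centred data (exact on training data whenever the
system is consistent). SVR enters only through an adapter around any
scikit-learn-style estimator; its internals are out of scope.

## Model comparison and significance

Two models evaluated on the same subjects yield dependent accuracy
correlations. The comparison statistic is Williams' modification of the
dependent-correlation t test, df = n − 3 (see README for the formula). The
statistic is signed; the implementation exposes the upper tail at `t₂`, the
lower tail, and the upper tail at `|t₂|`, because a one-sided test's
direction is the analyst's choice. Degenerate input (identical prediction
vectors with equal accuracies) returns t₂ = 0, p = 0.5 with a warning; a
correlation triple that is not positive semi-definite is rejected.

Permutation significance re-runs the entire pipeline — including in-fold
selection — on score vectors shuffled once per permutation. The p-value is
the strict proportion of null correlations exceeding the observed one
(matching the usual verbal definition); the smoothed `(k+1)/(N+1)` estimator
is co-reported and is the one with guaranteed sub-uniform behaviour under
the null.

## Preprocessing conventions

* **Exclusions**: a subject is excluded iff it carries at least one flag;
  the union is counted once, and per-reason counts plus the multi-flag
  overlap are reported.
* **Friston-24**: column blocks `[R, R², R_{t−1}, R_{t−1}²]`, lag row 0
  zero-padded.
* **Framewise displacement**: sum of absolute backward differences of the
  six parameters, rotations (radians) scaled by a 50 mm head radius. This is
  the Power-style form, not Jenkinson's RMS form — the cited quantity is
  fully specified and testable while preserving the 0.5 mm threshold
  semantics; the divergence is deliberate and documented here.
* **Scrubbing**: frames with FD > 0.5 mm receive one-hot spike regressors in
  the nuisance design (frames are modelled, not deleted). The design
  (intercept, linear trend, Friston-24, CSF, WM, optional global signal,
  spikes) must be full rank after dropping exact duplicates.
* **ALFF**: amplitude spectrum `2|DFT|/T` at non-DC bins, averaged over bins
  with `f_low ≤ f ≤ f_high` (default 0.01–0.1 Hz, both edges inclusive).
  "Averaged" (not summed) is implemented; published toolboxes vary in the
  normalisation constant, so the convention is fixed here and every test
  uses it. At least two in-band bins are required; the error names the
  minimal series length.
* **Mask threshold**: strictly greater than (default 0.2); the boundary
  voxel is excluded.

## The synthetic generator

The generator emulates the statistical skeleton of multimodal voxel-wise
studies, not MRI physics. Features come first; scores are computed from them
by a forward linear model, so the planted weight map is the true regression
function and recovery is well-posed.

Each modality receives contiguous index clusters of predictive voxels
(1-D adjacency — sufficient for atlas aggregation without image synthesis).
Each cluster has a latent factor `v = √f · s·g + √(1−f) · h`, where `g` is a
global latent shared by all clusters and modalities, `h` is cluster-specific,
`s ∈ {±1}` is the cluster's weight sign, and `f` is the shared-signal
fraction. Voxels in the cluster measure `v + noise_sd · e`; all other voxels
are i.i.d. N(0,1). The shared latent enters sign-aligned with the cluster
weight so that cross-modality shared variance is score-aligned — with
unaligned signs the cross-modality covariance terms cancel in the score and
whole modalities lose their marginal correlations. The raw score is
`Σ_m X_m w_m + ε` with `ε` sized so the planted predictor explains a target
fraction of variance (default R² = 0.5, the interesting middle ground
between trivial and undetectable); the observed score is an exact min–max
affine map onto the 0–4 scale, recorded in the returned truth so linear
identities survive rescaling. Clipping is deliberately avoided: it would
break the noise-free identity between features and scores.

Defaults (chosen once, with the reasoning below): 300 subjects; 2,000
voxels per modality of which 10 are predictive, in two clusters of five;
`noise_sd = 1.0`, i.e. within-cluster voxel correlation 0.5, the order of
what spatially smoothed maps exhibit; `f = 0.3` cross-modality sharing. Two
opposing failure modes pin down the cluster geometry: fully collinear
clusters make individual voxel weights unidentifiable (any regression can
only see the cluster aggregate, and sparse-Bayesian back-projection turns
the indeterminacy into sign noise), while fully independent predictive
voxels at R² = 0.5 spread the signal so thin that no voxel survives a
family-wise threshold. Two moderately coherent clusters per modality sit
between the extremes: cluster-level correlations are detectable by
Bonferroni screening at n = 300, and each voxel retains enough idiosyncratic
score-relevant variance for its weight sign to be identifiable.

What passing tests on this generator do **not** show about real data: real
voxel dependence is 3-D, long-range and non-stationary; real effects are not
piecewise-constant clusters; real score noise is not Gaussian homoscedastic;
and real studies face registration, motion and scanner confounds that the
generator does not model. The generator supports verification of the
*machinery* (leakage-free nesting, calibration, recovery under a known
truth), not claims about any particular dataset.

Time-series fixtures are sums of per-voxel random-phase sinusoids plus white
noise (frequencies validated against Nyquist); motion traces are Gaussian
random walks whose rotation steps are 50× smaller than translation steps so
both contribute comparably to FD. Exclusion rosters realise exact per-flag
counts and pairwise overlaps. Toy atlases partition the voxel index range
into contiguous nodes and nodes into networks, every node non-empty.

## Interpretation outputs

Per-fold voxel weights are obtained by back-projection (`w = Xᵀμ` over the
active samples), re-embedded with zeros at unselected voxels, and averaged
across folds with the zero-fill convention (a voxel unselected in a fold
contributes 0 for that fold), which keeps weights comparable across folds; a
selected-folds-only mean is available behind a flag. Node weights are means
over member voxels; network contributions sum positive and negative node
weights separately; ranked tables break ties by ascending index. Raw
averaged weights are ranked, without normalisation.

## Problem sizes used in verification

The verification suite runs the pipeline at sizes chosen to make each
property measurable with comfortable margins on a single CPU: parameter
recovery uses 50 seeds of the default 300 × (3 × 2,000) configuration under
5-fold cross-validation (fold-averaged weights from five diverse training
sets behave like the many-fold average at a fraction of the cost); fusion
benefit uses 25 replicates of a three-modality configuration with
independent signals; permutation calibration uses 100 replicates × 200
permutations of a 60-subject global-null dataset with relaxed selection
(under a global null the Bonferroni rule selects nothing in nearly every
fold, which would leave the correlation undefined) and a capped RVR
iteration budget — permutation p-values are calibrated for any deterministic
pipeline by exchangeability, so the cap does not weaken the check. The
dependent-correlation type-I study uses 10,000 trivariate-normal replicates
at n = 100.

## Known limitations

* The batch RVR optimizer can converge to fixed points that are less sparse
  than the sequential variant's solutions, and on interpolation-capable
  bases its `σ²` estimate relies on the degrees-of-freedom guard described
  above.
* The fast optimizer's noise re-estimation is conservative; for precise `σ²`
  at fixed sparsity, refit the batch optimizer on the selected basis.
* Permutation re-runs are embarrassingly parallel but executed serially.
* NIfTI support covers matrices stacked on the 4th axis and masked 3-D maps;
  there is no BIDS or DICOM ingestion.
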