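# Methods

This note records the modelling assumptions, numerical choices and known
limitations behind `fruitspec`, in the order the pipeline runs.

## Spectra model and I/O contracts

Spectra live on a strictly increasing wavelength grid; the canonical
acquisition grid is 302–1148 nm at 2 nm (424 bands). Reflectance factors are
unitless, finite and non-negative; values above 1.5 trigger a warning rather
than an error because specular glints can legitimately exceed the white
panel. Calibration is the element-wise ratio to white-reference counts times
the panel's certified reflectance. Repeated scans of one fruit (typically
three spots × ten scans) are pooled into a single arithmetic mean; with
equal scan counts per spot this equals the mean of per-spot means, and with
unequal counts it weights spots by scan count — a deliberate choice, since
the pooled mean is the maximum-likelihood spectrum under i.i.d. noise.

Off-grid wavelengths used by published indices (e.g. 677 nm in GI, odd on an
even grid) are obtained by piecewise-linear interpolation between flanking
bands — smooth, deterministic, and exact on grid points. Extrapolation
outside the measured span is refused.

Files are wide delimited text: first column `sample_id`, remaining columns
numeric nm headers. Chosen for transparency and diff-ability; round-trips
preserve values to better than 1e-12 (17 significant digits are written).

## Index registry and custom formulas

The registry holds 16 indices: GI, PSRMI, NAI, NDVI and twelve two-band
ratios (666/636, 660/620, 670/610, 618/602, 640/590, 970/590, 764/766,
768/770, 772/762, 766/764, 760/858, 970/1000). NAI is implemented verbatim
as the normalized difference of 760 and 720 nm despite its "anthocyanin"
name — the formula, not the name, is the contract. `PRMI` is accepted as an
alias for PSRMI since both spellings circulate.

Custom index expressions are parsed through a restricted AST grammar
(arithmetic, parentheses, numbers, `R<nm>` symbols only), so formulas loaded
from configuration cannot execute code. All registry formulas are ratios of
linear band combinations and therefore invariant under per-sample
multiplicative rescaling — the property that makes SRIs robust to
illumination level, asserted numerically in the tests.

## Correlogram band search

For a trait y the engine computes, for every ordered pair (λ₁, λ₂), the
squared Pearson correlation between RSI(λ₁,λ₂) and y. This equals the R² of
the simple linear regression y ~ index and is invariant to affine
transformations of the trait. The matrix is computed one denominator column
at a time (vectorized over numerators), bounding memory at one n×424 block;
a full 424×424 search over 75 samples takes well under a second.

The diagonal (zero-variance index) and any pair with zero index variance are
flagged NaN, not 0, so they cannot create spurious minima in contour maps.
Both triangles are computed: the reciprocal transform is nonlinear, so
R²(λ₁,λ₂) ≠ R²(λ₂,λ₁) in general. The ratio family is searched by default
(the twelve new registry indices are all ratios); normalized-difference
search is available via `family="normalized_difference"`.

Peak selection is a deliberate artifact decision (published work reports the
chosen pairs but not a rule): cells are visited in decreasing R² with ties
broken by smaller λ₁ then smaller λ₂, and a cell is kept iff its Chebyshev
distance in the (λ₁, λ₂) plane to every kept pair is at least
`min_separation` (default 10 nm). This keeps exactly one representative per
correlation ridge and is fully deterministic.

## Stage statistics

One-way ANOVA uses the classical sums-of-squares decomposition; the SS
identity (total = between + within) holds to 1e-9 and degenerate inputs are
reported rather than hidden (all-equal data → F undefined; zero within-group
variance with separated means → F = ∞, p = 0).

Duncan's multiple range test sorts group means descending; for a span of p
consecutive means the protection level is α_p = 1−(1−α)^(p−1) and the
critical range is q(1−α_p, p, df_error)·√(MS_within/n_h), with n_h the
harmonic mean of the span's group sizes (Kramer adjustment — the standard
choice for unbalanced groups). A span contained in a non-significant larger
span is itself non-significant (the classical protection rule). Letters come
from maximal non-significant spans, largest mean lettered "a", matching the
agronomy table convention. The implementation is cross-checked in the tests
against an independent recursive span-enumeration oracle; α defaults to
0.05, two-sided.

## Prediction models

* **Split**: train fraction 0.7 of n, with train size = `round(0.7·n)`
  (banker's rounding; 75 → 52/23, 45 → 32/13), shuffled by a seeded
  generator. The rule is stated because neither 75 nor 45 divides evenly.
* **Input selection**: indices whose univariate r² with the trait reaches a
  threshold (default 0.5) are retained, ordered by descending r² with
  alphabetical tie-break. Selection runs on the training split by default
  (leakage-safe); `selection_on="all"` reproduces protocols that select on
  the full dataset.
* **Grid search**: exhaustive evaluation by 5-fold CV mean MSE on the
  training split, folds shuffled under the run seed; lowest mean CV MSE
  wins with ties broken by grid order; the winner is refit on the full
  training set. Grids: ANN — neurons 2–10 per layer × 1–3 layers ×
  {tanh, logistic, relu, identity} × max_iter {500…1000}, SGD with learning
  rate 0.001; RF — 1–20 trees × depth 1–10 × {squared_error, absolute_error};
  DT — depth 1–10 × the same two criteria. ANN inputs are standardized on
  training statistics inside the pipeline (SGD needs comparable scales);
  tree models are scale-free and unscaled. SGD networks routinely hit the
  iteration cap — that cap is part of the protocol, so convergence warnings
  are suppressed during the search.
* **Metrics**: MSE, MAE, and R² = 1 − SS_res/SS_tot about the actual-value
  mean. R² is undefined (NaN) for zero-variance targets.

The full ANN grid (648 combinations × 5 folds of SGD networks) is expensive;
the test suite and the acceptance script exercise the ANN family on a
reduced grid (4 neuron counts × 2 depths × 4 activations × 2 iteration caps)
and run the RF/DT families on their full grids. This is a problem-size
choice of the package's own verification setup; the full ANN grid remains
the library default.

## Synthetic data generator

The generator defines the study conditions the pipeline is verified under:
75 mango samples (25 per stage: unripe, ripe, overripe) with SPAD, TSS and
firmness, and 45 strawberry samples (15 per stage) with L\*, b\*, TSS and
firmness.

**Traits** are drawn per stage from truncated normals parameterized by
published per-stage (min, max, mean, SD) summaries. Because several cells
are strongly skewed (e.g. mango overripe SPAD: mean 0.06, SD 0.07 on
[0, 0.2]), a truncated normal centred at the table mean would be biased by
up to ~2 standard errors; the sampler therefore solves for the location that
makes the *truncated* distribution's mean equal the table mean. Stage
ordering of the resulting means mirrors ripening physiology: TSS rises;
SPAD, firmness, L\* and b\* fall.

**Spectra** come from a simple parametric forward model, not a
radiative-transfer code — sufficient to create the correlation structure
the analysis exploits, and fully invertible:

    R(λ) = vis + (plateau − vis)·σ((λ − λ_re)/14)      logistic red edge
         + a_green·G(λ; 554, 28) + a_red·G(λ; 640, 26) reflection peaks
         − a_chl·G(λ; 672, 24) − a_water·G(λ; 970, 40) absorption features
         all × (1 + s·(λ−860)/240·σ((λ−742)/3))        NIR tilt

with G a Gaussian and σ the logistic function; vis = 0.10, plateau = 0.55.
Each amplitude is linear in one [0, 1]-normalized trait: for mango, SPAD
drives a_chl, a_green and the red-edge position λ_re (686–710 nm), TSS
drives the tilt slope s (the RSI 764/766 family), and firmness drives
a_water (970/1000); for strawberry, L\* drives a_green, b\* drives a_red
(the 666/636 red block), TSS the tilt, and firmness a_chl and λ_re. Noise
is one multiplicative illumination factor per sample (SD 0.05 — exactly the
disturbance ratio indices cancel) plus independent additive noise per band
(SD 0.005); reflectance is clipped at 0.

The stored ground truth inverts the exact forward model at a few probe
bands (mango: 672, 780, 970 nm; strawberry: 554, 640, 672, 800 nm) by
root-finding, recovering the generating traits from noiseless spectra to
machine precision — this is how the designed couplings are verified rather
than assumed.

**What the generator does not emulate**: real trait–spectrum joint
distributions (only published marginals are available), spectrally
correlated instrument noise, specular geometry, cultivar differences, or
water-band physics. Passing tests therefore demonstrate that the *pipeline*
recovers structure it is designed to detect, not that the specific band
pairs are optimal for real fruit.

## Verification conditions and problem sizes

The acceptance-style checks run at these sizes, chosen once as the study
conditions: oracle equivalence on a 10-band × 30-sample set; band-pair
recovery on n = 100 with trait noise at 5 % of the trait range over 20
seeds; Duncan oracle agreement over 40 random ≤5-group instances; the
end-to-end sweep over 10 seeds of the default 75-sample mango dataset,
requiring RF test R² ≥ 0.8 for TSS in ≥ 8/10 seeds and per-stage generated
means within 2 standard errors of the configured means in ≥ 8/10 seeds
(a 95 % event per seed, so the 8-of-10 majority keeps the check sharp
without being brittle).

## Known limitations

* The correlogram R² is a marginal, linear-association screen; it will not
  find multi-band or strongly nonlinear couplings (the ML stage can, but
  only over the 16 registry indices).
* Duncan's MRT is liberal among post-hoc tests; it is provided because it is
  the convention in the fruit-quality literature, not because it is the most
  conservative choice.
* With n = 75/45, grid-searched models can overfit the CV folds; the
  held-out 30 % split is the honest number to quote, and it is what the
  acceptance script reports.
* Mango firmness is the hardest trait under default noise (large unripe
  within-stage SD against a single water-band driver), and its held-out R²
  is correspondingly lower than SPAD's or TSS's.
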