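# Methods

## The model

`larvaldelta` analyses zero-heavy counts of parasitized fish larvae from
plankton surveys with a two-part ("delta" or hurdle) generalized linear
model. The response is the frequency of parasitized larvae per
area × season × survey × species cell. Because most cells contain no
parasitized larvae, the distribution carries a probability mass at zero that
neither a normal nor a single count model handles well; the delta approach
splits it into

1. a **presence sub-model**: a binomial GLM with logit link on the 0/1
   indicator *d* > 0, fitted to all cells, giving p̂ = Pr(presence); and
2. a **positive sub-model**: a GLM with log link on the strictly positive
   frequencies only, giving the positive-part mean d̂_p. Three error
   families are supported for this part — gamma, negative binomial, and
   Poisson — compared by AIC; the gamma is the usual choice for its
   flexibility on skewed positive data.

The two likelihoods factorize, so the sub-models share no parameters and are
fitted independently. A cell-level corrected density follows the
Aitchison–Pennington product rule

    d̂_c = p̂ · d̂_p,        v(d̂_c) = p̂² · v(d̂_p) + v(p̂) · d̂_p²,

which is exact for the point estimate and a first-order (delta-method)
approximation for the variance of a product of independent estimates; it is
accurate when both coefficients of variation are small and ignores the
v(p̂)·v(d̂_p) cross term (the test suite checks it against a Monte-Carlo
variance of the product in the small-CV regime, within 10%).

### Estimation

Coefficients are maximum likelihood via IRLS (delegated to
`statsmodels.GLM`), with convergence at a relative deviance change of 1e−8
within 100 iterations. Log-likelihoods are evaluated from the written
density/mass functions so that AIC = 2k − 2ℓ is on a single, explicit
convention: k counts regression coefficients **plus one** for an estimated
gamma shape or NB dispersion. The gamma shape is the profile MLE given the
mean fit (solving log α − ψ(α) = mean(log(μ/y) + y/μ − 1) by Brent
bracketing); the NB θ is profiled by a bounded one-dimensional search on
log θ over [1e−3, 1e6] with boundary hits flagged. Coefficient covariances
are inverse expected information with the ML nuisance plugged in (this
differs from the Pearson-dispersion covariance R's `summary.glm` prints for
gamma fits; the difference is a scalar factor that shrinks as the model
fits well). Joint delta-model AIC is the sum of the two sub-model AICs —
the unique choice consistent with the factorized likelihood; because the
parameter-counting convention for the gamma shape is explicit here and
unknowable for published tables, absolute AICs are comparable only within
one convention.

### Design matrices

Treatment coding with the alphabetically first level as reference,
interactions as products of parent columns. Columns that are identically
zero (a factor level absent from the data subset — routine for the positive
part, which sees only positive cells) are dropped and logged; exactly
collinear columns are dropped the way R's `glm` aliases them, which is what
gives a species:area interaction 3 rather than 4 degrees of freedom when one
species occurs in only one area. Every design records enough provenance that
prediction cells loading on a dropped column, or referencing a level the fit
never saw, are flagged **not estimable** instead of being extrapolated.

### Inference layer

*Analysis of deviance* is Type II by likelihood ratio: each main effect is
dropped from the model of all main effects, each interaction from the full
model; nuisance parameters are re-estimated in every sub-fit, so LR ≥ 0 is
guaranteed for nested mean structures; p-values are χ² with the difference
in coefficient counts.

*Forward selection* mirrors the two-part structure, where no single F-test
spans both sub-models. Step (i): candidate terms are added one at a time (in
the model-formula order abundance, season, species, area, species:area by
default) and retained iff at least one coefficient has a two-sided Wald
p < α (t with residual df for gamma, z otherwise) in at least one sub-model.
This union-of-two-tests rule has a type-I retention rate between α and 2α by
construction, which the tests verify empirically; no cross-part adjustment
is applied because the rule is reproduced as stated. Step (ii): declared
groups of competing explanatory variables (default: the categorical season
vs the continuous larval abundance, which carry overlapping seasonal
information) are resolved by joint AIC; every decision lands in a
machine-readable trace.

*Pairwise contrasts* on the positive sub-model compare factor levels on the
link scale: estimate c′β̂, SE √(c′Σc), z reference. The default
multiple-comparison adjustment is single-step max-|z| over the joint normal
distribution of all estimable contrasts, computed by seeded Monte-Carlo
(10⁵ draws by default, so adjusted p-values carry MC error of order 1e−3);
Bonferroni and no adjustment are available. Pairs touching a level absent
from the positive data are emitted flagged, not silently dropped.

*Prediction* (the observed-vs-predicted cell figure): one cell per
species × area × season with the continuous abundance covariate fixed at the
within-stratum mean of log1p(larvae collected); p̂ by inverse logit, d̂_p by
exponentiation, each variance by the delta method from the coefficient
covariance (v(p̂) = [p̂(1−p̂)]²·v(η)), combined as above. For intercept-only
presence models the classical binomial p̂(1−p̂)/n variance is available
behind a flag.

## Descriptive layer

Prevalence (100 · parasitized/collected per cell) and mean intensity
(parasites per parasitized larva, defined only when there are parasitized
larvae, hence always ≥ 1) are always recomputed from integer counts, never
read from printed metadata. Host-length comparisons use all parasitized
larvae against a seeded uniform subsample of unparasitized ones — balanced
by default, since the original subset size is unstated and balance maximizes
power — with the pooled-variance Student form by default (the named test)
and Welch behind a flag. Spearman correlations use average ranks for ties
and an exhaustive permutation p-value for n ≤ 9 (per-area sample sizes in
the length table go as low as 3, where the t approximation is unreliable),
the t approximation above.

## Packaged table fixtures

The per-survey prevalence/intensity table and the body-length table are
hand-digitized into package data. The printed layout of the survey table is
internally inconsistent: several rows carry fewer entries than the five
species columns, one row repeats the same sample size (642) in two cells,
and one cell prints an intensity with no prevalence on n = 1. The fixture
therefore stores printed values verbatim, assigns short-row entries
positionally to the alphabetically first species, and flags every such cell
`ambiguous`; reconstruction gives integer counts via
n_parasitized = round(prevalence·n/100) and
n_parasites = round(intensity·n_parasitized) (half away from zero), with a
`discrepant` flag wherever the integers cannot reproduce the printed values
(e.g. intensity 1.22 on 11 hosts). Stratum totals and prevalence extremes do
not depend on species assignment and are computed over all cells; the Punta
Coloso autumn–winter stratum is the one whose printed sample sizes sum
consistently (872). Known unresolved discrepancies, documented rather than
repaired: the text's Isla Santa María spring–summer range "0 to 16.7%"
versus a printed 31.79% cell (and a reconstructed 100% cell from the
"– (1) [1]" entry) in the same stratum, and text totals 359/142/18 170
versus column sums 267/119/18 284. Length-range units are stored verbatim as
"paper units" (fish lengths were measured to 0.1 cm, parasite lengths in µm,
but the printed ranges are unit-ambiguous).

## Synthetic surveys

The generator emulates the study design: 2 areas × 2 seasons × 5 surveys per
stratum × 5 species (100 cells) in the preset, species-skewed log-normal
abundances spanning roughly 1–6000 larvae per cell, presence logits linear
in species, season, area and log1p(abundance), gamma positives (shape 2) and
per-larva parasite loads 1 + Poisson(0.07) giving mean intensities near 1.07
— matching the magnitudes of the digitized table. Gamma positive draws are
continuous and are rounded **up** to ≥ 1 then capped at the cell's abundance:
the generator must emit integer counts while the gamma analysis model treats
them as continuous, which deliberately reproduces the mismatch inherent in
fitting gamma GLMs to count frequencies. One seeded stream is consumed in
fixed field order per cell, so identical seeds give bitwise-identical
datasets and edits to later fields leave earlier draws unchanged.

What the generator does **not** emulate: spatial/oceanographic mechanisms
(retention, upwelling), within-survey overdispersion beyond the family
variance, tow-volume variation, species mis-identification, or any
correlation between abundance and season. Passing recovery tests therefore
show the estimation machinery is correct under the model's own assumptions,
not that the model is adequate for any particular field dataset.

### Simulation study sizes (package defaults in the test suite)

- Parameter recovery: 200 replicates at 50 surveys per stratum (1000 cells),
  abundances in the hundreds-to-thousands so the cap on positive draws
  essentially never binds and the ceil bias on log-scale coefficients stays
  below ~0.03; measured |bias| < 0.1 with 95% Wald coverage in [90%, 98%].
- Family selection: 100 replicates with ~200 positive observations each.
- Selection-rule calibration: 500 replicates for the null-retention rate,
  200 for the season-vs-abundance AIC competition.

## Known limitations

- **Count families on two-part data.** Positives in a hurdle model are ≥ 1
  by construction, i.e. zero-truncated. The positive sub-models are fitted
  *untruncated* (as the analysis framework prescribes; zero-truncated
  variants are out of scope), so Poisson/NB positives at small means are
  underdispersed relative to the fitted family, while the gamma — with a
  free shape and a continuous density evaluated at integer points — can
  absorb that. The AIC family comparison is therefore structurally biased
  toward gamma in the low-count regime: in our simulations delta-gamma wins
  essentially always on Poisson-generated counts of mean 3, and the
  untruncated Poisson recovers its own data's AIC ranking only at means
  around 8 and above, never at more than ~90%. Family AICs at low counts
  should be read with this in mind.
- Absolute AIC values depend on the nuisance-parameter counting convention
  (documented above) and, for gamma vs count families, on comparing a
  density with a mass function; within-family comparisons are unaffected.
- The presence sub-model is fixed-effects only; no random survey effects,
  offsets, weights, or quasi-likelihood.
- Wald-based forward selection inherits the order sensitivity of any
  forward procedure; the default order is the model-formula order, and the
  trace records every decision so alternatives can be audited.
- Complete separation in the binomial part (a factor level with no zeros or
  no positives) surfaces as a convergence error rather than being penalized
  away.
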