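# Methods

## Problem setting

The package audits ecological association studies in which a per-county
language variable (a dictionary relative frequency or topic score derived
from social-media word counts) is correlated with a per-county,
age-adjusted, cause-specific mortality rate, optionally adjusting for
socioeconomic covariates.  Every stage consumes or produces plain-text
tables keyed by 5-digit FIPS codes; joins are inner, and every stage logs
the number of counties a join drops, because the effective sample of such
studies is defined exactly by these losses (data-release rules, missing
covariates, zero-token counties).

Missing values are explicit absences (NaN), never imputed to zero: a
county that produced no tokens has no score, and a county below the
release threshold has no rate.  A zero count, by contrast, is data.

## The synthetic study generator

The generator produces complete studies with known latent truth so that
every downstream procedure can be checked for calibration and recovery.

* **Counties.** Populations are log-uniform over `pop_log10_range`
  (default 10²–10⁷, matching the several orders of magnitude real US
  county populations span); centroids are uniform over a continental-US
  bounding box (25–49° N, 67–125° W).  Each county carries a latent
  standard-normal "language valence" factor λ.
* **Covariates.** Each covariate is `loading·λ` plus independent Gaussian
  noise with unit total latent variance, mapped onto a natural scale
  (income: 52,000 ± 12,000 USD; fraction-valued covariates through a
  logistic squash).  Income and education default to loading −0.3 — the
  socioeconomic confounding the covariate-adjusted analyses exist to
  remove; set loadings to zero for unconfounded designs.
* **Mortality.** Log expected rate: `log μ_f = log(baseline_rate) +
  rate_dispersion · η_f`, with `η = ρλ + √(1−ρ²)ε` a unit-variance
  Gaussian mixture, so corr(λ, log μ) = ρ in population.  Under this
  linear-Gaussian structure the mixing weight that hits a target log-scale
  correlation is the target itself; no numerical solve is needed, and the
  sample correlation keeps its natural ~1/√n variability (an exact
  in-sample calibration was deliberately rejected: it would freeze the
  null statistic and destroy p-value uniformity at ρ = 0).  Deaths are
  `Poisson(μ_f · pop_f/100,000 · years)`; the reported rate is the crude
  rate per 100,000/year.  Age adjustment is modeled as the identity —
  synthetic populations have no age structure, and real pipelines consume
  age-adjusted rates rather than computing them.
* **Word counts.** County token totals are `Poisson(tokens_per_capita ·
  pop)` (default 1 token/inhabitant, which at real-world county sizes
  reproduces the regime where a fifth of counties contribute under 100k
  words).  A county emits a dictionary word with probability
  `sigmoid(logit(dict_word_fraction) + 0.3·λ)`; the slope 0.3 keeps the
  logistic near-linear over λ ∈ [−3, 3] so the dictionary score is a
  nearly linear, strictly monotone function of λ.  Within the dictionary
  and within the background vocabulary, probability mass follows a
  Zipf law with exponent 1.0 (documented constant, not a knob).
* **Map pairs.** Given per-class region counts, each classed region draws
  an interval difference uniformly from its class range and a base
  interval uniformly among the positions that accommodate it; remaining
  regions are no-data.  The construction makes the requested class counts
  exactly recoverable, which the end-to-end oracle tests exploit.

**What the generator does not emulate:** real text (words are abstract
tokens), spatial autocorrelation between neighboring counties, within-
county heterogeneity, age structure, and reporting/coding variability in
cause-of-death assignment.  Passing recovery tests therefore shows the
*pipeline* is faithful, not that real county data satisfy the model.

## Statistical conventions

* Two-sided p-values throughout.
* Simple Pearson: p from `t = r√((n−2)/(1−r²))` on n−2 df; CI from
  Fisher's z with SE 1/√(n−3).
* Partial correlation: residualize x and y on [1, C] by least squares and
  correlate the residuals; inference reuses the simple-case machinery
  with effective n′ = n − k (t on n′−2 df, Fisher SE 1/√(n′−3)), so zero
  covariates reduce bit-identically to the simple case.  Raw (unlogged)
  covariate scales are used.
* Pairwise-complete deletion per variable, never listwise across a batch;
  per-variable n is reported.
* Batch screening flags a variable significant only when *both* the
  simple and the covariate-adjusted p beat α/m.  With complete data the
  screen runs a vectorized path (columnwise correlations, one projection
  for all residualizations); a unit test pins the two paths to each other.
* Welch's t uses Satterthwaite df; Cohen's d uses the pooled SD even
  alongside Welch's t (the conventional pairing).
* Dominance shares pool counts across counties before dividing; tokens
  match by exact lowercase string equality, with no stemming (source
  dictionaries enumerate variants explicitly).
* Scores are plain relative frequencies by default; an arcsinh(√·)
  variance-stabilizing transform is available behind a flag and never
  applied implicitly.  Topic weights are used as given, un-normalized.

## Split and filter conventions

* Suppression keeps a county iff mean annual deaths ≥ threshold
  (inclusive "at least"; default 10/year).
* Median-latitude split: strictly above the median goes north; at-median
  counties go south.  Median-population split: "below the median" is read
  verbatim, so at-median counties join the larger-population group.  The
  at-median conventions are explicit choices; with distinct values both
  splits differ in size by at most one.
* Range factors are computed over the included (post-suppression) county
  set.  All ratios are returned unrounded; display rounding is the
  caller's concern.
* A zero numerator in a per-inhabitant rate ratio yields `inf`, not an
  exception — tiny denominators legitimately produce unbounded ratios.

## Map discrepancy

Pixels are snapped to the nearest scale-or-background color in Euclidean
RGB (tolerance 30 units for directly supplied colors; scale colors are
well separated, so a perceptual color space would add complexity without
changing any assignment).  A region's color is the modal snapped pixel
color; ties go to the lower interval and are logged.  Interval differences
classify as green (0–2), yellow (3–5), red (≥ 6).

The summary's mean discrepancy among δ ≥ 3 regions is a deliberate lower
bound: every yellow region is scored as exactly 3 intervals and every red
as exactly 6.  In the default paper-compatibility mode the class values
are the 1-dp rounded constants with red = 2 × yellow (21.4 and 42.8 on a
14-color scale); exact widths (δ·100/m) are available behind a flag, and
the mode in use is logged.  The scale itself is always a required input —
published legends can misstate the true number of colors, so the package
never infers a scale from a map.

## Prediction comparison

Both models (language-omnibus and traditional-covariates) run ridge
regression on identical outer folds (default k = 10, seeded shuffle), so
the comparison is paired.  Within each outer fold the penalty is selected
by inner 5-fold CV over a logarithmic grid spanning six decades
(10⁻⁴–10²), and the standardize+ridge pipeline is refit on the full
training fold; scalers are fit on training folds only.  The grid's top is
capped below the intercept-only regime deliberately: under the
CV-correlation metric a near-constant predictor is degenerate rather than
merely weak, with a systematically negative held-out correlation of about
−√(k/(n(k−1))) under the null, because each fold's intercept is the mean
of exactly the counties the fold excludes.

Model skill is the Pearson correlation of the assembled out-of-fold
predictions with the outcome, computed once.  Skills are compared with
Steiger's (1980) z for dependent correlations sharing one variable, using
the pooled-mean-correlation covariance term; identical prediction vectors
return z = 0, p = 1 by definition.  The choice of Steiger's form is an
assumption recorded in output metadata — equivalence with any particular
published analysis's test is not established.  `power_note` evaluates the
same statistic analytically at stated (n, r_a, r_b, r_ab), which is the
calculation behind "a barely significant p at enormous n is evidence for
the null" power arguments.

## Problem sizes in the validation suites

The stochastic suites run at sizes chosen to keep sampling bands tight
while staying desk-scale: family-wise error under the null at m = 2,000
variables × n = 300 counties × 200 replicates; effect recovery at
n = 1,000 counties with ρ ∈ {0, 0.2, 0.5} over 40–100 replicates; ridge
null calibration over 50 seeds at n = 500.  Recovery suites use
populations of 10⁴·⁵–10⁷ so that Poisson noise in the log rate stays
small relative to the latent dispersion — the check isolates pipeline
fidelity, while the small-denominator noise regime is studied separately
(and deliberately) by the suppression/selection suites.

## Known limitations

* The generator's independence assumptions (no spatial structure, no
  shared reporting artifacts) make its null cleaner than any real null.
* Dictionary scoring has no wildcard/stem expansion; patterns must be
  enumerated.
* The map pipeline requires region masks; segmenting arbitrary published
  maps is out of scope.
* The selection-bias t-test inherits Welch-test assumptions
  (approximately normal group means); heavy-tailed rate distributions at
  very small n are not specially handled.
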