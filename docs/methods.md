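# Methods

## The problem

Raw laboratory values extracted from an electronic health record are
sparse, irregular, outlier-ridden, and shaped as much by the health-care
process (when and why a test was ordered) as by physiology.  Downstream
phenotyping and cohort-selection algorithms need a fixed-length, per-patient
summary of each laboratory variable.  The common choice — empirical mean and
standard deviation — is not robust: a single mis-keyed unit (a value entered
a thousand-fold too high) moves both statistics arbitrarily far.

This package implements a population-guided alternative.  For each
laboratory variable it:

1. pools all patients' values and estimates their density non-parametrically
   (Gaussian-kernel KDE, density *p*);
2. fits a set of candidate parametric families to the pooled values by
   maximum likelihood (each fitted family is a candidate *q*);
3. scores every candidate by the Kullback–Leibler divergence
   `KL(p, q) = ∫ p log(p/q) dμ` — the information lost when the
   non-parametric estimate is approximated by the parametric summary;
4. selects the divergence-minimizing family (retaining the *near-minimum
   set* of families that are almost as good);
5. refits the selected family to each individual patient's values; the
   fitted parameter vector is the patient's continuous summary;
6. optionally discretizes each parameter into population quantile bins
   (deciles by default), giving an ordinal tuple per patient for consumers
   that need categorical input (topic models and the like).

The direction of the divergence is `KL(KDE ‖ parametric)`: the KDE plays
the role of the data-faithful reference and the parametric family the role
of the approximation.

## Model assumptions

The population-to-individual transfer assumes the cohort is approximately
"one family, patient-level parameter variation": every patient's values are
drawn from the *same* parametric family, with parameters that differ by
patient.  When the population is instead a wild mixture of per-patient
families (or of per-patient mixtures), the population-level winner need not
describe any individual well — mixing exponentials with random rates, for
instance, pools into something gamma-like even though no patient is
gamma-distributed.  The simulation module generates all four regimes
(`case1`–`case4`) so this failure mode can be studied directly; the
summarization pipeline itself always applies the single selected family to
every patient.

Timestamps are deliberately ignored: the summary is a time-agnostic
distributional sketch, not a trajectory model.

## Candidate families

Nine families are registered: normal, log-normal, gamma, Weibull, logistic,
uniform, Student-t (location–scale–df), Rayleigh (scale only), and the
generalized extreme value (GEV).  The registry is extensible — a new
`DistributionFamily` (density, support, MLE, sampler, parameter roles) is
picked up by the selection code without modification.

GEV sign convention: the shape parameter ξ follows the extreme-value
literature — **negative shape implies a finite upper endpoint** at
`loc − scale/shape`; positive shape gives a heavy right tail.  SciPy's
`genextreme` uses `c = −ξ`; the conversion is internal to the registry.
A patient summarized with ξ < 0 therefore carries a hard ceiling on their
values, which is clinically meaningful (it caps the plausibility of high
outliers while preserving a high location/scale).

Fitting is maximum likelihood with moment-based initialization: closed
forms where they exist (normal, log-normal, uniform `(min, max)`,
Rayleigh), numerical optimization started from method-of-moments or
quantile heuristics otherwise.  A fit is *converged* only if the optimizer
succeeded, the log-likelihood is finite, and the parameters are valid; the
optimizer is never allowed to return a point worse than its own starting
guess.  Three failure modes are recognized and reported rather than raised:
`support_violation` (a datum outside the family's maximal support, detected
before optimization — e.g. a negative value under a positive-support
family), `degenerate_data` (all values identical), and `optimizer_failure`.

## Numerical choices

* **KDE**: Gaussian kernel; Silverman's rule
  `h = 0.9·min(sd, IQR/1.34)·n^(−1/5)` by default (Scott's rule and fixed
  bandwidths available); 512 evaluation points spanning
  `[min − 3h, max + 3h]`; density renormalized to unit trapezoid integral.
  The Lebesgue integral in the divergence is realized as trapezoid
  quadrature on this grid.  No boundary correction is applied: for
  positive-support variables with appreciable density near zero, kernel
  mass leaks below the support and mildly penalizes positive-support
  families (see Limitations).
* **Divergence**: `0·log 0 = 0`; the parametric density is floored at
  `1e−12` so support mismatches are penalized heavily but finitely; if the
  floored integral still exceeds a cap (default `1e3`) the divergence is
  reported as `+∞`.  Families that fail to fit, or whose support excludes
  observed data, score `+∞`.
* **Tie rule**: the near-minimum set contains every family whose divergence
  is within a factor of `tie_ratio` (default 10) of the minimum — a family
  is ruled out only when it loses an order of magnitude more information
  than the best one.  A relative-difference rule (e.g. within 1 %) was
  considered and rejected: on realistic data the divergences of nested
  families (Student-t over normal, GEV over most shapes) differ by amounts
  far below any meaningful signal, so a 1 % band almost never contains more
  than one family, while multi-family ties are the norm in practice.  The
  selected family is the argmin, with exact ties broken by fewest
  parameters, then name, so runs are exactly reproducible.
* **Binning**: interior empirical quantiles, bins 1-indexed, half-open on
  the right with the top bin closed; duplicate quantile boundaries collapse
  with a warning.  Boundaries are computed from included patients only and
  are frozen/serializable so new patients can be binned against an existing
  scheme.
* **Exclusions**: patients with fewer than `min_obs` observations
  (default 5; an ICU-style analysis of densely measured patients may
  reasonably raise this to 25) or with non-convergent fits are emitted with
  an explicit status, never dropped silently.

## The synthetic cohort generator

No real patient data ship with (or are needed by) this package; every
evaluation runs on simulated cohorts with known ground truth.  The
generator emulates the statistical texture of EHR laboratory extracts:

* **Sparse sampling** — per-patient observation counts are a shifted
  negative binomial with floor 5 and median below 10 (outpatient regime);
  ICU-context patients have floor 25.
* **Patient-level latents** — each patient's parameters are drawn around
  population hyper-parameters.  Defaults are glucose-like in magnitude
  (location ≈ 100 mg/dL) with tight jitter, except the Weibull default,
  which is bell-shaped (shape ≈ 3.5, hemoglobin-like) because that is the
  kind of variable a Weibull wins in practice and because low-shape
  Weibulls sit against the zero boundary where the uncorrected KDE leaks.
* **Mixing regimes** — `case3` (shared family, tight latent variation) is
  the regime the algorithm assumes; `case1` (per-patient families),
  `case2`/`case4` (per-patient / shared two-component mixtures) exercise
  its failure modes.
* **Unit-error outliers** — each value is independently multiplied by
  100–1000 with small probability, the signature of a mis-keyed unit; an
  additive mode exists.  Flags are recorded in the truth.
* **Physiologic coupling** — for glucose-like variables the patient's
  latent SD is linear in their latent mean (`sd = slope·mean + intercept +
  noise`).  The canonical coupled cohort (`glucose_coupled_spec`) uses 800
  ICU-regime patients, patient means ~N(150, 40) mg/dL and coupling
  `sd = 0.3·mean + 10 + N(0, 5)`, chosen to match the published physiology
  of glycemic variability and the scale of an ICU glucose cohort.

All randomness derives from one seed through named substreams
(latents / counts / values / outliers / context), so cohorts are exactly
reproducible.

What the generator does **not** emulate: visit-timing processes,
informative-observation (sicker → measured more) hazards, multi-analyte
correlation, assay drift, or value discreteness.  Passing tests therefore
demonstrate correctness of the algorithms under the stated generative
assumptions, not performance on real EHR extracts.

## Evaluation procedures

**Maximum-entropy reference.**  Knowing only a mean, the maximum-entropy
model is uniform; mean and SD give the Gaussian; mean and SD with a linear
mean–SD constraint give the gamma.  Glucose physiology supplies exactly
that third constraint, so on physiology-dominated glucose data the selected
family should concord with the gamma prediction — an independent check the
package exposes as a lookup (`maxent_model`).

**Physiologic-relation preservation.**  For coupled cohorts the per-patient
model mean and model SD (the `mean_like` / `sd_like` columns) should
reproduce the generating linear relation.  The empirical-baseline
comparison includes the "by-hand" truncation (drop summaries with
SD > 2000) that raw mean/SD summaries need before their relation appears.
The truncation exists for evaluation parity only; it is never part of the
pipeline.

**Extreme-group purity.**  Patients whose binned parameters are all in the
bottom (or all in the top) decile form candidate low/high cohorts; for the
GEV each group may additionally be split by the sign of the fitted shape.
Review-sized subgroups (default 15, seeded) are scored by cluster purity
against binary labels.  Two conventions are emitted: `purity` (majority
class over group size, always ≥ 0.5) and `target_class_fraction` (the
fraction carrying the label of interest, which is what clinical tables
print and what drops below 0.5 for contaminated groups).  Synthetic labels
come from thresholding the true latent location at a population quantile —
a stand-in for chart review, which is out of scope.

### Two structural findings from the synthetic evaluations

Both are computed by the test suite and the acceptance script; they are
honest properties of the stated conditions, not defects of the
implementation.

1. *An exactly-gamma population does not tie with the log-normal.*  On real
   glucose data, gamma and log-normal often land in the same near-minimum
   set because both approximate messy reality about equally well.  On a
   synthetic cohort whose values are exactly gamma, the log-normal's
   divergence is bounded below by the true gamma-to-lognormal divergence
   (~0.03–0.04 at glucose-like shapes) while the best family's divergence
   shrinks toward zero with pooled n, so the ratio grows without bound and
   the tie disappears.  Multi-family ties are a signature of model error
   against real data, and a clean simulation removes it.

2. *Raw mean/SD Pearson correlation is inflated, not destroyed, by
   unit-error outliers.*  A positive multiplicative error raises a
   patient's mean by ≈ `m·(mult−1)·k/n` and their SD by
   ≈ `m·(mult−1)·√k/n` — the two co-inflate, so across patients the
   contaminated points lie along a steep error-process line and raw
   Pearson r comes out near 1 (with a slope ~two orders of magnitude above
   the physiologic one).  The physiologic relation is obliterated — the
   surviving correlation belongs to the error process — but a plain
   `r < 0.5` check cannot detect this.  The robustness advantage of model
   summaries is real and measurable on the location axis: under 2 % ×1000
   contamination, the Spearman correlation between the fitted log-normal
   location and the true latent location stays ≈ 0.82 while the empirical
   mean's drops to ≈ 0.37, and top-decile groups built from model summaries
   remain enriched for high-latent patients.  The relation evaluation
   therefore reports both Pearson and Spearman plus the fitted slope, and
   the end-to-end robustness checks compare rank fidelity.

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| `bandwidth_rule` / `bandwidth` | `silverman` | KDE bandwidth (data units when fixed) |
| `grid_size` | 512 | KDE evaluation points |
| `tie_ratio` | 10 | near-minimum inclusion factor on the KL scale |
| `kl_cap` | 1e3 | divergence above which a family scores `+∞` |
| `min_obs` | 5 | minimum observations per fitted patient |
| `n_bins` | 10 | ordinal categories per parameter (deciles) |
| `outlier_rate` / `outlier_multiplier` | 0 / 1000 | simulated unit-error contamination |

Every report echoes the effective configuration, package version and seed.

## Known limitations

* Gaussian-kernel KDE without boundary correction leaks mass outside hard
  supports; families with substantial density at a support boundary
  (uniform always; Rayleigh/Weibull/gamma at low shape) carry a divergence
  handicap of roughly `0.25·(h/σ)²·log(1/ε)` per boundary.  The ratio tie
  rule absorbs this in practice; a boundary-corrected KDE is deliberately
  out of scope.
* Maximum-likelihood fits are not robust estimators; per-patient summaries
  of heavily contaminated patients are themselves contaminated (log-scale
  families compress the damage but do not remove it).  Robust/m-estimation
  machinery is out of scope.
* No uncertainty quantification or model averaging — the near-minimum set
  is reported precisely so that downstream users can treat the top models
  as interchangeable perturbations, but no posterior weights are computed.
* Mixture families, censored likelihoods, and per-patient model selection
  are out of scope by design.

## Problem sizes used in the checks

Self-selection runs 500-patient cohorts (pooled n ≈ 10⁴) over 10 seeds per
family in the test suite and 3 seeds per family in the acceptance script;
coupled-cohort evaluations use 800 ICU-regime patients (pooled n ≈ 2.5·10⁴);
parameter recovery uses 10⁴ draws per fit and 200 patients × 25
observations for the per-patient RMSE; the purity oracle enumerates all
2¹⁵ label patterns of a 15-member group.
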