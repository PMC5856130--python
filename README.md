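# popkld

Parametric summarization of electronic-health-record laboratory values by
KL-divergence model selection, for people building phenotyping and
cohort-selection pipelines on raw EHR extracts.

EHR laboratory data are sparse, irregular, and contaminated by unit-error
outliers and health-care-process bias, yet most pipelines still summarize
each patient's values with an empirical mean and standard deviation — two
statistics a single mis-keyed value can move arbitrarily far.  This package
instead selects, per laboratory variable, the parametric family that loses
the least information relative to the pooled population distribution, and
summarizes each patient by that family's maximum-likelihood parameters.

Concretely, with *p* the Gaussian-kernel KDE of the pooled population
values and *q* a candidate family fitted to them by maximum likelihood, the
selection criterion is the Kullback–Leibler divergence

    KL(p, q) = ∫ p log(p / q) dμ ,

the information lost when *p* is approximated by *q*.  The divergence-
minimizing family (together with the *near-minimum set* of families within
an order of magnitude of the minimum) is selected; each patient is then
refitted under it, so a patient becomes e.g. a `(location, scale, shape)`
triple under the generalized extreme value family — with negative shape
implying a hard upper bound on their values.  An optional discretization
step maps each parameter to its population decile, turning the summary into
an ordinal tuple such as `(1, 8)` (location in the 1st decile, spread in
the 8th) for consumers that need categorical input.

Nine candidate families ship in an extensible registry (normal, log-normal,
gamma, Weibull, logistic, uniform, Student-t, Rayleigh, GEV).  A synthetic
cohort generator with known ground truth — sparse per-patient sampling,
per-patient latent parameters, unit-error outliers, mixed collection
contexts, and a glucose-like linear mean–SD coupling — makes the whole
pipeline testable without any real patient data, and the evaluation module
implements physiologic-relation preservation, maximum-entropy reference
predictions, and decile-extreme-group cluster purity.

See `docs/methods.md` for the model, its assumptions, and known
limitations.

## Worked example

Simulate an ICU-style glucose cohort (800 patients, ≥25 values each,
per-patient SD linear in the mean, gamma-distributed values) and run the
pipeline:

```bash
popkld simulate --n-patients 800 --family gamma --lab-name glucose \
    --icu --coupling 0.3 10 5 --mean-hyper 150 40 \
    --label-quantile 0.9 --seed 1 --out-dir demo
popkld select    --input demo/measurements.csv --out-dir demo
popkld summarize --input demo/measurements.csv \
    --report demo/selection_glucose.json --empirical --out-dir demo
popkld categorize --summaries demo/summaries_glucose.csv --out-dir demo
popkld evaluate  --summaries demo/summaries_glucose.csv \
    --categories demo/categories_glucose.csv --labels demo/labels.csv \
    --shape-param shape --out demo/evaluation.json
```

which prints

```
INFO popkld: wrote 25594 measurements for 800 patients to demo
INFO popkld: lab glucose: n=25594 selected=gev near-minimum=['gev', 'gamma']
INFO popkld: lab glucose: 800 patients, exclusion rate 0.000
INFO popkld: lab glucose: categorized 800 included patients into 10-bin tuples
INFO popkld: relation sd_like~mean_like: pearson=0.744 spearman=0.761
INFO popkld: purity: {'bottom_shape_pos': None, 'bottom_shape_neg': 1.0,
                      'top_shape_pos': 1.0, 'top_shape_neg': None}
```

Reading the output: the flexible GEV attains the minimum divergence on this
pooled mixture, with gamma — the family the values were actually drawn
from, and the one maximum entropy predicts for a variable whose SD is
linear in its mean — tied in the near-minimum set.  Per-patient fits
converge for every patient (exclusion rate 0), and the fitted model
mean/SD reproduce the generating physiologic relation (the least-squares
slope comes out 0.28 against a generating slope of 0.3).  In the purity
block, the patients whose parameters all sit in the top decile carry the
synthetic disease label (2 of 2, fraction 1.0) while the all-bottom-decile
group carries none (0 of 3) — high/low summary extremes align with the
latent disease state.  The first summary rows look like:

```
patient_id,lab_name,family,n_obs,status,loc,scale,shape,mean_like,sd_like
p000,glucose,gev,42,included,109.128,45.378,-0.128,130.163,50.580
p001,glucose,gev,34,included,106.654,42.390,-0.106,127.050,48.216
```

The same pipeline is available as a library of scikit-learn-style
estimators:

```python
from popkld import PopKLDSummarizer, PopKLDCat

summarizer = PopKLDSummarizer(lab_name="glucose", min_obs=5)
summaries = summarizer.fit(table).transform(table)   # one row per patient
print(summarizer.selected_family_)
tuples = PopKLDCat(n_bins=10).fit_transform(summaries)
```

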