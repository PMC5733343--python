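# Methods

## The experiment being modelled

The package analyses (and simulates) an in-vitro fermentation study:
willow bark extract (WBE) is incubated anaerobically with a human fecal
suspension (HFS, 0.1 g feces/ml buffer) at two extract concentrations
(2 and 10 mg/ml), alongside a vehicle control and a plain-buffer control
(fecal suspension without extract, concentration 0) and an extract
control (extract in buffer without microbes, at the high concentration).
Samples are drawn at 0.5 h (t0), 4 h (t4) and 24 h (t24) in triplicate
and measured by untargeted LC-MS in negative electrospray mode. The unit
of data is a *feature*: an (m/z, retention time) pair with a peak area
per sample; a full design therefore has 5 series x 3 times x 3
replicates = 45 samples.

## Fate classification (triage)

For each feature and each extract concentration, group ratios are formed
on replicate mean areas and assessed with an unpaired, two-tailed
Student's t-test (pooled variance, df = n1 + n2 - 2; Welch's form is
available behind a switch but is not the default, because the classical
test is what the original processing applied):

| label | rule |
|---|---|
| INCREASING | t24/t0 > 2 and p < 0.05 |
| DECREASING | t24/t0 < 0.5 and p < 0.05 |
| INTERMEDIATE | t4/t0 > 2 (p < 0.05) and t4/t24 > 1.25 |
| UNCHANGED | none of the above |

Operational choices the published rules do not pin down, made here once
and applied everywhere:

* **Precedence.** INTERMEDIATE is evaluated before the monotone rules: a
  rise-and-fall feature can also satisfy the increasing rule between t0
  and t24, and the transient interpretation is the informative one.
  Overall label precedence is MATRIX > FAST_METABOLIZED >
  INSUFFICIENT_DATA > INTERMEDIATE > INCREASING > DECREASING > UNCHANGED.
* **Not-detected handling.** Areas below the limit of detection enter
  group means as zero (they are real near-zero signals, and this
  preserves decay-to-zero dynamics), but a feature counts as *present*
  in a design cell only when at least 2 of 3 replicates were detected.
  Presence gates the direction claims: an increase requires presence at
  t24, a decrease at t0, an intermediate at t4. A feature present in no
  cell of a concentration series is INSUFFICIENT_DATA there.
* **Ratios on group means**, not per-replicate pairs; a zero-mean
  denominator with a non-zero numerator gives an infinite ratio (newly
  formed compound), two zero means give an undefined ratio that
  satisfies no rule.
* **Zero-variance groups** (which arise in noiseless simulations): p is
  defined as 0 when the means differ and 1 when they are equal — the
  limit of the t-test — so the noiseless oracle tests are total.
* **No multiple-testing correction.** The procedure deliberately uses
  raw p < alpha per feature, as in the original triage. Expect ~5% false
  positives among truly unchanged features per ratio test; downstream
  interpretation must treat single-feature calls accordingly.

Two control rules complete the triage. A feature present in a fecal
channel *without* extract (vehicle or plain buffer) at any time point is
MATRIX — fecal background, not extract-derived. A feature present in the
extract control at t0 but never detected in any fecal+extract cell is
FAST_METABOLIZED (turned over before the first sampling, 30 min into the
incubation). Finally, every fate is crosschecked against the extract
control: a same-direction significant change there (increasing/increasing
or decreasing/decreasing) sets the abiotic flag, meaning the trend does
not require microbes and the feature is excluded from microbial
substrate/metabolite reports.

## Mass annotation

Negative-mode features are [M-H]- ions, so a feature's neutral mass is
its m/z plus the proton mass (1.00727647 Da — the proton, not the
hydrogen atom, because the electron stays on the ion). Neutral masses
are matched against the theoretical monoisotopic masses of a bundled
58-compound willow-bark library within a 5 ppm window (every printed
deviation in the source table is <= 5.3 ppm); retention-time gating
(default window 0.3 min) is off unless the data share the library's
chromatographic method, since retention times are method-specific. Ties
are broken by |delta ppm|, then |delta RT|, then peak id, so isobaric
pairs (e.g. the two acetylsalicins) are separable only by RT.

Matching always uses formula-derived masses. Five library rows print a
mass that is inconsistent with their printed formula (at >= 10 carbons
and > 5 ppm); these are shipped verbatim with a `curation_note` rather
than silently corrected, and they are exempt from the library-consistency
test. Several small early-eluting acids also deviate by ~10-15 ppm from
their formula mass; their printed bookkeeping cannot be reconstructed and
is not reproduced.

## Synthetic experiments

The generator emulates the full design above with one kinetic archetype
per feature (closed forms in `synthetic_data.trajectory`):

| archetype | active-channel trajectory | extract control |
|---|---|---|
| SUBSTRATE | A exp(-k1 t) | flat at A |
| PRODUCT | A (1 - exp(-k1 t)) | absent (never forms) |
| INTERMEDIATE | A k1/(k2-k1) (exp(-k1 t) - exp(-k2 t)) | absent |
| STABLE | A | flat at A |
| ABIOTIC_UNSTABLE | A exp(-k1 t) in *every* channel | decays |
| MATRIX | A in all fecal channels, extract or not | absent |

Noise is multiplicative lognormal (default sigma = 0.2) because peak
areas are positive and heteroscedastic; areas below the limit of
detection (default 100 area units, amplitudes 2e5-2e6, so stable
features are never censored) are recorded as not-detected, distinct from
zero. Microbial rates are divided by an inhibition factor (default 1.25)
at 10 mg/ml — a minimal mechanism for the slower turnover observed at
the high extract concentration. Default rates (decays and formations
0.15-0.4 /h; intermediates k1 in 0.155-0.17 /h, k2 = k1 + 0.04) are
chosen so the noise-free ratio of every archetype clears its threshold
with at least a two-fold margin at both concentrations; fast-metabolized
substrates decay at 40 /h, which keeps them censored everywhere in fecal
channels even at the inhibited rate. `SyntheticTruth` stores every
archetype and parameter and derives the expected label of any feature
from the closed forms, which is the oracle for the recovery tests.

What the simulation does **not** emulate: chromatographic peak shapes,
retention-time drift, correlated noise across features, ion suppression,
isotope patterns, or realistic compound-to-compound rate differences —
the rate constants are free simulation parameters, not estimates of the
study's compounds. Passing recovery tests therefore demonstrate that the
triage rules invert the generator's kinetics under its noise model, not
that real incubation data would be classified with the same accuracy.

## Pathway overlays

Three degradation routes are bundled as DAG fixtures (naringenin
glycosides, catechin/flavan-3-ols, salicylic alcohol), encoding only
transformations named in the source study's text and figure legends.
Fates project onto node roles — DECREASING/FAST_METABOLIZED -> PRECURSOR,
INTERMEDIATE -> INTERMEDIATE, INCREASING -> TERMINAL_METABOLITE,
everything else UNKNOWN — and each edge u -> v gets a verdict:

* CONSISTENT if u is consumed or transient (PRECURSOR/INTERMEDIATE) and
  v is transient or accumulating (INTERMEDIATE/TERMINAL_METABOLITE);
* CONSISTENT also for TERMINAL -> TERMINAL: chained accumulating
  metabolites are expected in these routes (the ring-fission acids all
  rise together while feeding one another), so two increasing neighbours
  are evidence for, not against, the edge;
* INCONSISTENT only for TERMINAL -> INTERMEDIATE: a compound that only
  accumulates cannot plausibly feed one that demonstrably rises and
  falls;
* UNDETERMINED whenever either role is UNKNOWN.

Nodes expected to be invisible for instrument reasons (phloroglucinol is
fermented onward to short-chain acids; 3-(4-hydroxyphenyl)propionic acid
ionizes weakly in negative mode) carry `expected_undetectable`, so their
absence reads as UNDETERMINED coverage, not as pathway failure.

## OTU-table utilities

Three rules from the accompanying 16S processing: drop OTUs represented
by five or fewer reads *in total across all samples* (the source text
does not say per-sample vs total; total is implemented and documented),
total-sum scaling so each sample's abundances sum to 1 (idempotent;
zero-total samples are an error naming the sample), and selection of
OTUs strictly exceeding a relative-abundance threshold (default 1%) in
at least one sample. Upstream OTU picking, taxonomy assignment and
ordination are published tools and out of scope.

## Numerical and testing choices

* Isotope masses are bundled to >= 6 decimals (C = 12 exactly); the mass
  of a formula is an exact sum, additive to floating precision.
* The neutral/m-z conversion round-trips exactly; m/z at or below the
  proton mass is a domain error.
* Simulations are seeded through `numpy.random.default_rng`; the same
  seed reproduces tables bit-identically.
* Test problem sizes: label recovery uses the default study population
  (200 biotic + 50 abiotic + 30 context features, sigma = 0.1);
  rule-equivalence checks run 100 random 8-feature tables against a
  deliberately naive reimplementation of the rules; the t-test is checked
  against scipy's independent implementation on 1000 random group pairs
  and calibrated under a lognormal null (sigma = 0.2, n = 3, 10,000
  replicates).
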