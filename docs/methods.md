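# Methods notes

This note records the modeling and numerical choices behind `amygdecode`,
in the spirit of a methods appendix: what each stage assumes, which knobs
matter, and what the synthetic studies do and do not establish.

## Conventions

Times are floating-point milliseconds relative to stimulus onset at 0;
prestimulus times are negative; valid spike times lie in [−500, 1000).
Every analysis window is half-open, `[c − w/2, c + w/2)` for center `c` and
width `w` (default 50 ms), so adjacent non-overlapping windows partition
time and a spike is never counted twice. The "early window" (30–80 ms) is
the window centered at 55 ms under this convention. Trials with aborted
fixation are assumed already removed upstream; the file format carries no
abort flag.

## Nonparametric tests

**Wilcoxon signed-rank** (screening, latency): zero differences are
discarded (Wilcoxon's original treatment, not Pratt's), tied magnitudes get
mid-ranks. For n ≤ 25 remaining pairs the two-sided p is exact: the
distribution of the positive-rank sum over all 2^n sign assignments is
built by dynamic-programming convolution over doubled (hence integer)
ranks, and the smaller tail is doubled. Larger samples use the normal
approximation with tie and continuity corrections. All-zero differences
return p = 1 with a warning.

**Friedman test** (expression sensitivity): within-block mid-ranks,
chi-square statistic with the standard tie correction, df = k − 1 = 2
(3 expressions), upper-tail p. A table whose blocks are all completely tied
is defined as chi-square 0, p = 1 (scipy's formula divides by zero there).
A batched implementation evaluates many tables at once (all window centers
× all shuffles) using O(k²) pairwise-comparison ranking, which is what
makes the 1,000-repetition shuffle null affordable; the batch and scalar
paths are cross-checked against each other and against scipy in the tests.
`friedman_permutation_p` provides a within-block permutation p (sampling
with the add-one rule) for small-sample inference; the asymptotic
chi-square tail is anticonservative relative to the exact permutation null
at few blocks (e.g. 4 concordant blocks: chi² = 8, asymptotic p = 0.018,
exact p = 6/1296 ≈ 0.005), which is why the permutation variant exists.

**Block construction.** The Friedman table has one block per trial
repetition and cell values equal to the spike count averaged over the 3
identities at that repetition (giving n = trial count, df = 2). The
alternative — one block per identity × repetition — is available as
`mode="identity_blocks"`. Unequal repetition counts across images are
truncated to the per-image minimum in presentation order to preserve block
pairing; below 6 repetitions the neuron is excluded.

**Shuffle null.** Image labels are permuted across trials within each
neuron (preserving each neuron's count marginal), the per-window count of
significant neurons is recomputed per shuffle, and the 95th/99th
percentiles are averaged across windows (the per-window percentiles show no
temporal structure under the null, so averaging is justified and stabilizes
the threshold).

## Population decoding

Spike counts are normalized within each neuron by its maximum over the
*training* folds (applied to both train and test; the all-data variant is
available via `normalization_reference="all"` but leaks the test maximum).
A zero reference maximum maps the neuron to zeros. Three binary soft-margin
linear SVMs are trained one-vs-rest (libsvm C-SVC through scikit-learn,
linear kernel, cost 0.125, tolerance 1e-6, fixed sample order); prediction
is argmax of the decision values with ties broken in the fixed order
(open_mouth, neutral, pout_lips). Overall accuracy is the correct fraction
over the 18 test vectors; with balanced test classes this equals the mean
of per-class recalls.

The 80/20 split is a repeated random stratified split (per image, 8 of 10
trials to train), not a rotating exact 5-fold; at the paper-scale settings
of 100 repetitions the two readings coincide in expectation. Pseudo-trials
pair randomly chosen same-image trials across neurons per repetition, which
is the correct null for non-simultaneously recorded data and deliberately
destroys (unmeasurable) noise correlations. Chance is estimated by the same
machinery with training labels shuffled per repetition.

At the paper's small cost (0.125) every training sample is typically a
bounded support vector, so the hyperplane scales when the training set is
duplicated while all predictions are invariant; tests assert the invariance
that actually holds (predictions at cost 0.125, hyperplane in the
hard-margin regime).

## Peak and trough detection

The global peak of an accuracy time course is the argmax (later center on
an exact tie). The early peak is the highest local maximum preceding the
global peak and separated from it by a local minimum (the trough = lowest
point between them; the earlier of equal candidates wins); a unimodal or
flat curve has no early peak. Local maxima are screened by topographic
prominence (`scipy.signal.find_peaks`); the default floor of 0.02 ignores
repetition noise, and the analysis scripts use 0.05 for 10-trial datasets,
whose window-to-window accuracy fluctuations (shared across repetitions,
correlation length about one window width) are larger.

## Weight analysis and latency

Weights are the per-neuron mean of the open-mouth classifier weight across
repetitions at the early-peak reference window (repetitions that did not
subsample the neuron are excluded from the mean; an exactly zero mean
excludes the neuron). Weighted-sum time courses apply these *fixed*
early-peak weights at every window — the transient-mechanism reading — with
per-window retraining available by re-running the decoder; since the
weighted sum is linear in the weights, using mean weights equals averaging
per-repetition weighted sums.

Group latency is the first window center whose across-neuron firing-rate
distribution differs from the −50–0 ms baseline (two-sided signed-rank,
p < 0.05). The single-first-crossing definition is the default; a
sustained-significance variant (`sustained_ms`) requires the crossing to
persist over consecutive windows spanning the given duration. The analysis
scripts use `sustained_ms = 51` (just over one window width): because
adjacent windows share most of their data, null excursions persist for
about one window width of centers, so only a persistence requirement
*longer* than the window suppresses them. Latency scans start at center
25 ms — windows centered earlier span stimulus onset.

One caveat the synthetic studies made explicit: weight-sign groups are
selected on the same trials used for the latency test, and conditioning on
the weight sign biases each selected neuron's early open-mouth rate toward
that sign (regression to the mean), pulling both groups' crossings early.
When the question is whether the generator's excited group truly leads the
suppressed group, latencies should be computed on independently defined
groups; the analysis scripts therefore use the generator membership for the
latency table and keep the weight-sign grouping for the weight analyses.

## SF shift index

The preferred image-based SF at each stimulus size is the peak of a
Gaussian in log2(SF) fitted by least squares to the 7-point tuning curve
(3 parameters: height, center, width; initial center at the grid argmax;
argmax fallback if the fit fails), clamped to the tested 2–16 cycles/image
span (a flag reports when clamping was active). The shift index is the
least-squares slope of log2(preferred image-based SF) on log2(size) over
sizes with a defined preference (≥ 3 of 5 required). By construction:
slope 1 ⇔ preferred image-based SF proportional to size (constant
cycles/degree, retina-based frame), 0 ⇔ constant cycles/image (image-based
frame), negative ⇔ opposite shift, > 1 ⇔ super-proportional shift. This is
a re-specification of the index as a regression slope satisfying those
semantics, not a port of any particular prior formula. It is invariant to
multiplicative scaling of the surface and uses the fixed 500-ms response
window (rates enter as a 7 × 5 surface; no spike times).

## Synthetic data generator

Trials are inhomogeneous Poisson processes discretized at 1 ms (Poisson
count per bin from the piecewise-constant rate profile, uniform placement
within the bin — exact for piecewise-constant rates, no thinning needed).
No refractoriness, no spike-sorting noise, no noise correlations (the
decoder ignores them by design). A per-neuron log-normal gain per identity
(σ = 0.05) modulates rates without carrying expression information.

The default population preset (100 neurons, 10 trials per image,
baseline 10 sp/s):

| group | n | early component | late components |
|---|---|---|---|
| positive-like | 20 | +14 sp/s for open-mouth, 40–80 ms | +6 sp/s all expressions from 90 ms; +12/+5 sp/s neutral/pout-lips, 130–210 ms |
| negative-like | 20 | −10 sp/s for open-mouth, 60–90 ms | +12 sp/s all expressions from 90 ms; +40/+12 sp/s neutral/pout-lips, 130–210 ms |
| nonselective | 60 | — | — |

Rationale: the early epoch carries open-mouth information in two forms
(excitation in one group, suppression in the other, the suppression
starting later and weaker); the rebound at 90 ms restores rates without
carrying expression information; expression-discriminating late activity —
strongest for neutral faces and shared, more weakly, by the positive group
— develops from 130 ms. The separation between the early components and the
late discriminative component is what produces a genuine trough in decoding
accuracy despite the 50-ms window smearing adjacent epochs; a late
discriminative signal starting directly at the 90-ms rebound is visible in
every window past ~65 ms and fills the trough. Amplitudes are package
choices on the order of reported amygdala rates; no quantitative rates are
available to copy.

What passing the synthetic studies shows: each stage recovers the structure
it is designed to detect at realistic trial counts, and the tests are
correctly calibrated under the null. What it does not show: robustness to
non-Poisson variability, rate drift, correlated noise, or eye-movement
artifacts present in real recordings.

## Default problem sizes

The library defaults mirror the full analysis settings (1-ms window step,
100 decoding repetitions, 1,000 shuffles). The analysis scripts and test
suite run the same code at coarser settings chosen as their own defaults —
5–10 ms window steps, 48 decoding repetitions, 400–1,000 shuffles, 104 or
100 neurons, 10 trials per image — which leave every qualitative recovery
comfortably resolved (peak separations ≈ 100 ms versus a 50-ms window).
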