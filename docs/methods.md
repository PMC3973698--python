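# Methods

## The scoring model

A free-recall response is reduced to its **token set**: the text is folded
to lowercase, apostrophes are deleted (`man's` → `mans`), the string is
split on any run of non-alphanumeric characters, stop words are removed,
and duplicates are dropped. No stemming or lemmatization is applied:
`read`/`reading` and `book`/`books` are distinct words, and unmatched
synonyms (`river`/`stream`) do not score. Pure-digit tokens are kept.
These rules are deterministic and language-tooling-free, so identical
input yields identical tokens on every platform.

The **mean shared-word score** of a target response against a normative
set of N reference responses to the same stimulus is

    score(t) = (1/N) · Σ_i |T_t ∩ T_i|

where T are token sets. An equivalent form — the *frequency-weighting
identity* — is

    score(t) = Σ_{w ∈ T_t} f(w)

where f(w) is the fraction of normative responses containing w. Words
mentioned by most of the crowd are thus implicitly weighted more heavily,
and rare-but-valid details still contribute whenever at least one
reference viewer mentioned them. The identity is used both as a test
oracle and as the mental model for the measure: the score is the amount
of *crowd-validated* content in the response.

Empty token sets (possible under severe degradation) are retained with
score contributions of zero and logged, never dropped: dropping them
would bias dose-response contrasts toward null.

## Semantic-space comparators

For benchmarking, responses can also be compared in a co-occurrence
embedding: a count matrix is built either term-by-document (LSA-style) or
word-by-word within a symmetric ±2 or ±20 token window (vector-space
models), optionally reweighted (raw counts by default; log-entropy and
positive PMI available), and factored by truncated SVD. A passage is
embedded as the sum of its in-vocabulary word vectors (a mean is offered
too; cosine is invariant to the choice) and passages are compared by
cosine similarity, the standard distance-to-similarity reading for such
spaces. Default retained dimensionality is 50, appropriate for the small
bundled-corpus scale this package targets; out-of-vocabulary words
contribute nothing, and a passage with no in-vocabulary words is
"unrepresentable" — an error when scoring a single pair, a warned zero in
batch scoring. A dependency-parse-based comparator is deliberately not
offered: it requires a grammatically parsed corpus, which is outside this
package's input contract.

## Classification and its evaluation

**Take-one-out classification** scores each reference response against
every stimulus' normative set — excluding the response from its own
stimulus' set only — and assigns it to the stimulus with the highest mean
similarity. Note the denominators are consequently unequal: N−1
comparisons for the response's own clip, N for every other clip. A tied
top score counts as *incorrect* unless the true clip is the unique
maximum; ties are logged. This is conservative and makes accuracies
independent of traversal order. With C stimuli, uniform guessing succeeds
at rate 1/C.

The shared-word score matrix is computed as a sparse binary
response-by-vocabulary matrix times a vocabulary-by-clip occurrence-count
matrix, with a per-row correction for the excluded self; this is
algebraically identical to the scalar definition (asserted against a
brute-force double loop in the tests) and fast enough to re-run hundreds
of times inside resampling loops.

**Cross-dataset classification** scores one population's responses
against another's normative sets; any target whose response id occurs in
the reference pool (the pooled-dataset case) is automatically scored
take-one-out.

**Normative-set-size resampling** draws, for each replicate, an
independent per-clip subsample of n responses without replacement and
re-runs take-one-out classification on the subsampled dataset. Accuracy
as a function of n is summarized by a two-parameter saturating
exponential

    y(n) = A · (1 − exp(−n/τ)),

fitted by bounded nonlinear least squares (initialized at A₀ = max y,
τ₀ = half the n-range; both parameters positive). The size at which the
curve reaches 99% of its asymptote is the closed form n99 = τ·ln 100.
The through-origin form is adopted because the quantity of interest is
"99% of asymptote", which it supports directly; an additive offset would
make A alone the asymptote anyway while adding an unidentifiable
degree of freedom on saturating data. A flat curve (or fewer than three
points) is a signalled error, not a silent fit.

**Subset-score error** re-uses the same per-clip subsampling scheme: for
each replicate, every response of a clip is scored against the size-n
subsample — excluding itself whenever it was drawn, so take-one-out is
preserved at every n — and the error is the difference from its
full-dataset take-one-out score. At n equal to the full clip size the
subsample is the whole set and every error is exactly zero. Per-n means,
SDs and interquartile ranges are reported; replicate means are the
independent units for bias checks.

## The synthetic generator

Each synthetic stimulus ("clip") is a vocabulary of abstract tokens with
independent per-word mention probabilities:

| parameter | default | meaning |
|---|---|---|
| `n_clips` | 200 | stimuli |
| `responses_per_clip` | 12 | normative crowd size per stimulus |
| `n_core`, `p_core` | 5, 0.8 | salient details, mentioned by most viewers |
| `n_peripheral`, `p_peripheral` | 20, 0.15 | minor details, mentioned by a minority |
| `distractor_pool_size`, `p_distractor` | 150, 0.02 | generic vocabulary shared by *all* clips |
| `overlap_fraction` | 0.2 | fraction of core/peripheral slots shared across clips |
| `n_subjects` | 60 | normative roster, assigned round-robin |
| `verbosity_sd` | 0 | lognormal SD of a per-subject probability multiplier |
| `idiosyncrasy` | 0 | probability a mentioned word is replaced by a private synonym |

Tokens are purely alphanumeric (`clip017core03`, `distr114`,
`sharedcore00`) so they survive text normalization unchanged; responses
are serialized with shuffled word order and interleaved filler stop words
so that preprocessing is genuinely exercised. A ground-truth sidecar
(response id → emitted model words) is available for assertions.
Generation is bit-reproducible from (config, seed).

Because mentions are independent across words and responses, the expected
mean shared-word score between a target at retention r_t and normative
responses at retention r_n is closed-form:

    E[score] = Σ_w (p_w·r_t)(p_w·r_n),

independent of the normative-set size. This oracle (`expected_mean_score`)
assumes unit verbosity and zero idiosyncrasy and is the calibration
standard for the generator (empirical means at 10,000 independent pairs
agree within three standard errors).

An idiosyncratic subject's private synonym is a deterministic function of
(subject, word), so such subjects are *consistently* idiosyncratic — their
private tokens can match across their own responses but never another
subject's, which is the behaviour that degrades crowd scoring in real
data. Degradation multiplies every mention probability by a retention
r ∈ [0, 1] (r = 1 reproduces the normative generator byte-for-byte at the
same seed); it models loss of acquired detail, not loss of verbosity. The
five default levels are labelled with the Snellen acuities of a defocus
design (20/20 … 20/800) at retentions (1.0, 0.9, 0.8, 0.65, 0.5): mild
blur spares most salient content, severe blur removes about half of the
reportable detail. The retention values are a synthetic knob chosen once
for plausibility — no quantitative blur-to-information mapping is claimed.

What the generator does **not** emulate: correlated mentions (real
viewers report details in semantically coherent clusters), genre and
demographic effects on vocabulary, transcription/spelling errors, and
natural-language word-frequency structure. Passing tests therefore
demonstrate the *machinery* — scoring arithmetic, evaluation protocol,
statistics — under the stated statistical structure, not performance
levels on any real crowd.

Two named study conditions are used throughout the tests and the
acceptance script: the **default** configuration above (a homogeneous
crowd; classification is near-ceiling), and a **heterogeneous** variant
(`idiosyncrasy = 0.35`, `verbosity_sd = 0.4`) modeling crowds with
distinctive individual vocabularies. The heterogeneous regime is where
normative-set size genuinely limits reliability, so it is the condition
under which the size-resampling curve and the dose-response study are
demonstrated.

## Dose-response statistics

A scored-trial table (subject, clip, condition label, user-supplied dose
rank, score) supports two tests:

* **Spearman trend**: the rank correlation (midranks for ties) between
  dose rank and score, pooled over all trials, with a two-sided
  permutation p-value obtained by permuting scores across trials. This is
  the uncorrected companion analysis — it ignores subject and clip
  structure by design.
* **Stratified contrast**: the difference in mean score between two
  conditions, with a null distribution built by permuting condition
  labels *within each subject's own trials* (each subject's clip set is
  fixed by the crossed design, so the subject is the stratum). This
  permutation scheme is exact by construction for the crossed
  subject × clip design and replaces a parametric crossed-random-effects
  model fit, which would add distributional assumptions without adding
  validity at these sample sizes.

Permutation p-values use the add-one estimator (b+1)/(m+1): never zero,
and valid (stochastically no smaller than uniform) under the null. The
default permutation count is 10,000. Condition ranks are supplied by the
caller; the package does not parse acuity notation. Constant scores make
rho undefined and raise an explicit error, as do contrasts with no
stratum containing both conditions.

## Numerical and design choices

* All randomness flows through `numpy.random.default_rng` seeds; every
  stochastic API takes an explicit seed and reproduces bit-identically.
  The CLI records inputs (SHA-256), config, seed and package version in a
  JSON manifest per run.
* Argmax ties in classification: exact floating-point equality is the tie
  criterion; shared-word scores are small rationals, so this is reliable.
* Permutation tests compare `|statistic| >= |observed| − 1e-12` to avoid
  losing exact ties to rounding.
* SVD rank: requesting more dimensions than the count matrix supports
  raises an error carrying the achievable rank.
* Problem sizes in the test-suite and acceptance script (100 clips for
  the resampling curve, 50 for error distributions, 25 for dose-response
  studies; 100 replicates per n; 200 simulated trend experiments; 10,000
  calibration pairs) were chosen as the smallest sizes at which the
  Monte-Carlo assertions have comfortable margins.

## Limitations

* The shared-word rule has no synonym or morphology handling; its
  robustness in practice comes from large normative crowds, which the
  synthetic generator only partially emulates.
* `expected_mean_score` is exact only for unit verbosity and zero
  idiosyncrasy; under heterogeneity it is an upper bound on the
  crowd-matching component.
* The stratified contrast tests a mean difference; it does not estimate
  variance components, which a mixed model would.
* Classification accuracies on synthetic data are not predictions of
  accuracy on any real response corpus.
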