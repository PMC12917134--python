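# Methods

`speechcog` implements an end-to-end analysis of spontaneous speech as a
proxy for cognitive assessment: feature extraction from transcripts and
audio, confirmatory-factor composite cognitive scores, a leakage-safe
prediction harness, normative screening for cognitive low performers, and
transfer of frozen models to an external (clinical-style) cohort.  Because
the human cohort such an analysis targets cannot be redistributed, the
package ships a synthetic-cohort generator that plants the statistical
structure the analysis assumes; every stage is validated against that
ground truth.

## The synthetic cohort

Each participant carries four latent cognitive domain scores — language,
executive function, memory, speed — drawn from a multivariate normal with
unit variances and a configurable correlation matrix (default off-diagonals
0.3–0.5; cognitive domains are empirically correlated).  Linear demographic
shifts are added: per-year age effects of −0.02 to −0.04, +0.1 to +0.3 for
high education, small gender and country effects.  Demographic marginals
follow the cohort the harness expects: age ~ N(65.5, 4.8) truncated at 60,
60/40 female/male, 50/50 UK/USA, 60/40 high/low education, subjective
socioeconomic status ~ N(5.7, 1.6) clipped to 1–10.

Fourteen test outcome measures (verbal fluencies, naming, trail making A/B,
RAVLT learning/recall, reaction time, tower-of-London extra moves, Corsi,
pegboard, digit span, clicking and mouse-dragging speed; all
sign-harmonised so higher = better) are generated as `loadings @ latents +
N(0, noise_sd)` under a sparse pattern: each test loads 0.8 on one domain,
and Trail Making Test A cross-loads on executive function (0.4) and speed
(0.5).  With `noise_sd = 0.6` the observed variance is exactly 1 and the
test-latent correlation has the closed form `0.8 / sqrt(0.64 + 0.36)`,
which the recovery tests exploit.

Speech observables are driven by
`driver = sqrt(e) * latent + sqrt(1 − e) * independent noise`, so the
effect-size parameters `speech_effect_size` and `audio_effect_size`
(default 0.5 each — a deliberately strong but not deterministic link,
chosen once so that planted-signal recovery is testable at desk-scale n)
are exactly the fraction of latent variance reaching the observable.
Setting them to 0 decouples speech from cognition, which the null-control
tests use.

*Transcripts* are bags of template sentences over a bundled POS-tagged
lexicon — POS-taggable and fully controllable, not natural language.  Two
monotone mappings carry the signal: content words are Zipf-sampled with
exponent `max(0.4, 1.3 − 0.3·driver)` (a higher driver flattens the
distribution and raises lexical diversity), and hesitation interjections
are inserted with probability `clip(0.06 − 0.02·driver, 0.005, 0.25)`.
Token counts are uniform on (150, 520), matching a ~337-word mean.

*Waveforms* are rendered lazily from voiced/pause interval plans:
three-harmonic tones (f0 uniform in 100–220 Hz) amplitude-modulated at a
syllable rate `clip(4 + 0.4·driver, 2, 7)` Hz over a 1e-3 noise floor,
16 kHz mono.  The planted pause fraction is
`clip(0.30 − 0.06·driver, 0.05, 0.60)`.  Plans default to ~157 s
recordings; the bundled analysis drivers synthesize 30 s (and test
fixtures 5–12 s) recordings to keep runtimes in seconds — a problem-size
choice, stated here once, that does not alter any generative parameter.

What the generator does **not** emulate: natural-language syntax and
discourse, articulatory acoustics (formant dynamics come from additive
tones, not a vocal tract), ASR errors, microphone/channel variation, and
non-Gaussian tails in test scores.  Passing tests therefore demonstrate
that the pipeline recovers structure it is specified to recover — not that
the features are clinically valid on real speech.

## Linguistic features

The extractor computes the transcript feature set in a fixed order: 27
lexical features (word count, 13 POS-ratio features, average word length,
dictionary coverage, Brunet's index `W = N^(V^−0.165)`, Honore's statistic
`R = 100·ln N / (1 − V1/V)`, moving-average type-token ratio with window
20, mean unique words per 50-word window, propositional and content
density, and five psycholinguistic noun norms), 10 syntactic features (six
production-rule counts, NP/VP constituent ratios, mean NP length,
Flesch-Kincaid grade `0.39·w/s + 11.8·syll/w − 15.59`), and 2 semantic
features (mean TF-IDF cosine distance between sentence pairs and the
proportion of pairs at distance ≤ 0.5).

Numerical and design choices:

* Tokens are alphabetic runs (optional internal apostrophe); punctuation
  is never a token; interjections count as words.  Tags come from a
  bundled Penn-Treebank lexicon with documented suffix fallbacks
  (`-ly`→RB, `-ing`→VBG, `-ed`→VBD, `-s`→NNS/VBZ, default NN; unknown
  capitalised non-initial words → NNP).  Feature values are therefore
  tagger-dependent by construction; the tagger is frozen with the package.
* Texts shorter than a window are scored as a single whole-text window,
  which makes MATTR and `n_unique_in_50` defined everywhere and continuous
  at the boundary.
* Honore's statistic diverges when every type is a hapax (V1 = V); the
  feature is then flagged invalid rather than returned as ∞, so
  downstream standardization is never poisoned.  Natural log is used.
* Constituency counts come from a deterministic shallow chunk grammar over
  the tag sequence (NP = (DT|PRP$)? JJ* N+, or a lone PRP; PP = IN + NP;
  VP = verb group + optional NP/PP complement; INTJ = UH; a sentence with
  no verb group counts as a fragment).  Windowed and chunk statistics are
  verified against brute-force enumeration in the tests.
* Syllables: exception dictionary first, then vowel-group counting with a
  silent-e correction, floor 1.
* TF-IDF uses raw counts × smoothed idf `ln((1+n)/(1+df)) + 1` with
  L2-normalised sentence vectors; with fewer than two sentences both
  semantic features are flagged invalid.
* Every degenerate case (no nouns, no coordinating conjunctions, no
  lexicon coverage) yields an invalid flag, never a silent NaN or 0.

## Acoustic features

A 27-value vector: audio length, three pause statistics, two rate
features, and a 21-descriptor subset of the extended Geneva minimalistic
acoustic parameter set (eGeMAPS), each a documented approximation of the
published descriptor computed with numpy/scipy (frame RMS as the loudness
proxy, FFT spectral flux, 26-filter mel cepstra, autocorrelation F0 on a
semitone scale from 27.5 Hz, LPC formant-1 frequency/bandwidth,
50–1000 Hz vs 1–5 kHz alpha ratio, `stddevNorm = std/|mean|`).  The
contract is the named vector, not bit-compatibility with any external
toolkit.

Voice activity detection uses 30 ms frames at a 10 ms hop, an adaptive
energy threshold (5th-percentile noise floor + 10 dB), a 3-frame hangover,
and merging of gaps under 150 ms.  Homogeneous signals (dynamic range
below the threshold) are decided globally against a −50 dBFS silence
floor, so an unbroken tone is one voiced segment and pure noise is none.
On synthesized plans the detector recovers planted pause fractions within
±0.05 and burst boundaries within two frames.

Pause features exclude leading and trailing silence: pauses are gaps
between voiced segments inside the trimmed span, and the pause-fraction
denominator is that span (the spec of "fraction of pause over audio
length" is ambiguous when edges are trimmed; the trimmed-span convention
is the self-consistent one and is configurable by computing from the
segment object directly).  The standard deviation over a single pause is
0 (population form).

Speech rate and articulation rate divide the transcript's phoneme count by
total and voiced duration respectively.  Phonemes are counted from the
transcript via a small grapheme-to-phoneme lexicon with a letter-based
fallback (vowel groups + deduplicated consonants), with the fallback
fraction reported — counting from text rather than audio matches a
pipeline in which transcripts are first-class inputs.

Descriptor selection ranks candidates by the maximum absolute Pearson
correlation to any of the four composite scores over development-set
participants only, keeps the top 30, then greedily drops the lower-ranked
member of any pair correlated above 0.85.  Ties break by input column
order; constant candidates are excluded with a warning.

## Composite cognitive scores

1. **Outlier flagging**: per test, OLS on age/gender/education/country;
   observations with |residual z| > 4 are set missing.  Columns with under
   10 observed values are skipped; zero-residual-variance columns produce
   no flags (z is undefined there).
2. **Imputation**: round-robin (column-by-column) Bayesian-ridge
   regression over the remaining test scores, left-to-right visiting
   order, mean initialisation, deterministic given the seed.  Observed
   cells are never altered.
3. **CFA**: maximum-likelihood fit of `Sigma = L Phi L' + Psi` under the
   fixed sparse pattern (unit factor variances, free correlations bounded
   at ±0.95, diagonal residuals bounded below at 1e−6) by L-BFGS-B on the
   ML discrepancy; residual variances at the bound are reported as Heywood
   cases.  CFI/TLI/RMSEA are the standard ML indices from the model and
   independence chi-squares (robust corrections are out of scope; values
   will differ slightly from a robust-estimator fit).  Factor scores use
   the regression method `f = Phi L' Sigma^{-1} (x − mu)`.  The
   modification-index model refinement that produced the cross-loading is
   treated as configuration, not re-run.
4. **Standardization** to mean 0, SD 1 (ddof = 1) per domain.

Loadings recover to ±0.05 and factor scores correlate > 0.8 with the
generating latents at n = 5000 in the test suite.

## Prediction harness

The cohort is split 80/20 into development and holdout sets, stratified on
age (tertiles), gender, country, education and the tertile-binned mean
composite score; participants missing any stratification variable are
excluded and listed.  Strata smaller than 5 are pooled.  Within-stratum
largest-remainder apportionment makes the development count exactly
`round(0.8·n)` — 985 retained participants split 788/197.  Ten-fold CV on
the development set deals the stratum-sorted, seeded-shuffled list
round-robin, so fold sizes differ by at most one; metrics are pooled over
the union of fold test sets, not averaged per fold.

Inside every fold, feature preprocessing is fitted on training rows only:
train-statistics z-capping at |z| > 4 (no demographic regression here —
features, unlike test scores, have no normative demographic model),
round-robin imputation fitted on the masked training matrix, then
standardization by the imputed-train mean/SD.  Constant training features
are dropped with a warning.  A metamorphic audit (perturbing the apply-set
arbitrarily) verifies bit-identical fitted transforms.

Models: epsilon-SVR with RBF kernel and C = 0.5 (the only tuned values the
design fixes; epsilon stays at its 0.1 default), random-forest regression
as the cross-check, and two dummy baselines — the train-mean predictor and
a seeded random predictor sampling train targets uniformly *with*
replacement per test row.  Under the squared-residual coefficient of
determination these baselines have expected R² of 0 and −1, which the
calibration tests verify by simulation.

Metrics: R² = 1 − Σ(c_i − ĉ_i)² / Σ(c_i − c̄)², Spearman's rho with
average-rank ties, MAE.  Uncertainty: two-sided percentile bootstrap over
participants (1000 resamples by default; degenerate constant-truth
resamples are redrawn with a cap).  Superiority of feature set A over B is
declared when ≥ 95% of paired-bootstrap metric differences are strictly
positive; the type-I error of this procedure measures ≤ ~7% at nominal 5%
in the null simulations.

Shapley attributions use the interventional value function (features in
the coalition from the instance, the rest marginalised over a background
sample).  Up to 12 features the subset enumeration is exact, so local
accuracy `base + Σφ = prediction` holds to numerical precision; above
that, a seeded permutation-sampling estimator is used.  Global importance
is the mean absolute attribution.

## Normative screening

Linear norms for each composite are fitted by OLS on age, gender,
education and country over the *full* cohort (an intentional
label-construction step, matching the design this package mirrors; a
dev-only variant is available by passing the restricted frame).
Participants with standardized residual z < −1.96 are labelled low
performers; under well-specified Gaussian norms the prevalence converges
to Φ(−1.96) ≈ 2.5%.  An RBF SVM (same C discipline) produces decision
scores under the same fold structure; ROC (trapezoidal AUC) and PR
(step-wise average precision — conservative, no interpolation) curves are
bootstrapped like the regression metrics.  Decision margins, not
calibrated probabilities, feed the curves: both AUCs are invariant to
monotone transforms.

## Clinical transfer

A frozen pipeline bundles the fitted preprocessor and per-domain
regressors with their feature schema.  Applying it to an external cohort
never refits anything; missing schema columns raise, extra columns are
dropped with a warning.  Synthetic clinical cohorts shift all four latent
domains down by δ before generating speech, with patients at −δ and
matched controls at 0.  Group separation uses the pooled-variance
two-sample t-test with pooled-SD Cohen's d, sign convention control −
patient (positive d = patients lower).  The equal-variance form matches
the pooled-SD d; the monotonicity suite checks d ≈ 0 at δ = 0 and strictly
increasing d over δ ∈ {0.5, 1, 2}.

## Task scoring

Semantic fluency counts distinct animal-dictionary entries
(case-insensitive, crude lemmatisation, greedy longest-first multiword
matching); phonemic fluency counts distinct F-initial words excluding
number words and capitalised tokens (proper-noun rule), deduplicated at
the lemma level; the 20-item naming task accepts any response in the
item's acceptable set after lowercasing and article stripping.  Word error
rate is (S + I + D) / |reference| by token-level edit distance.  Agreement
between automated and reference scores reports MAE and ICC(2,1) — two-way
random effects, absolute agreement, single rater (the form is a package
choice; it is the standard one for auto-vs-human agreement) — verified
against an independent implementation to 1e−10.

## Known limitations

* The eGeMAPS-style descriptors are approximations; absolute values are
  not comparable with openSMILE output, only the named contract holds.
* The CFA reports standard, not robust, fit indices.
* The chunk grammar under-parses genuinely complex syntax; on template
  transcripts it is exact, on natural text it is a shallow approximation.
* Screening at 2.5% prevalence needs cohorts of ≥ ~1000 for stable
  cross-validated curves; smaller runs skip domains and say so.
* The one-shot modification-index CFA refinement and ASR itself are out of
  scope; transcripts are inputs and WER is only a quality metric.
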