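# Methods

This note documents the models and procedures implemented in
`cdsbattery`, the choices made where the design was open, and what the
synthetic-data experiments do and do not demonstrate.

## The measurement battery

### Transcript cleaning

Tokens tagged as onomatopoeia, exclamations, or proper names are removed
from every measure. Contractions are kept in the token/type/TTR/MATTR
counts but excluded from the phono-lexical lookups, because pronouncing
dictionaries on the IPhOD model do not list them. Every exclusion is
counted in a per-session ledger that conserves tokens (kept + excluded =
input), and the ledger is logged per session.

### Lexical diversity

TTR is types/tokens over the cleaned stream. MATTR is the mean TTR over
every contiguous window of *w* tokens (default *w* = 10), advancing one
token at a time across the whole session stream; windows are not reset at
utterance boundaries, matching the convention of the CLAN implementation
of the statistic. Sessions shorter than the window fall back to plain TTR
and flag the row.

### Phono-lexical statistics

All lexical statistics are computed over word **types**, against a
user-supplied pronouncing lexicon (TSV with pronunciation variants, log10
frequencies, and function-word flags).

* **Word length** — segments in the selected pronunciation variant,
  stress digits ignored.
* **Word frequency** — the lexicon's log10 frequency, passed through
  unchanged (already log-scaled).
* **Phonological neighborhood density** — the number of distinct
  orthographies (excluding the word itself) with a variant exactly one
  segmental edit away (substitution, deletion, or addition), the
  Vitevitch-and-Luce neighbor definition. Homophones count once per
  orthography.
* **Phonotactic probability** — the mean over positions *i* of
  count(*i*, pair)/total(*i*), where the positional tables count, for each
  position, how many lexicon pronunciations contain that ordered biphone
  starting at *i*, and the denominator is the number of pronunciations
  long enough to host a biphone there. Counting is type-based and
  unweighted by default (a frequency-weighted switch exists); this keeps
  each position a proper probability distribution. Raw probabilities are
  z-scored within word-length strata (the reference distribution is all
  lexicon pronunciations of the same length) to remove the length
  confound: longer words contain more, individually rarer, biphones.
  Strata with fewer than two members or no spread yield nulls.
* **Variant selection** — for words with several pronunciations the
  variant with the highest phonotactic probability is used; ties keep the
  first listed variant and are logged.

Session summaries use the median for frequency and density and the mean
for word length and the z-scored probability.

### Unnested median-split counts

To compare a nested per-type statistic with per-session counts on equal
footing, the nested variable is condensed to a count of outlier
observations: the **number of long words** is the count of a caregiver's
types at or above the pooled median word length (inclusive boundary), and
the **number of low-frequency words** is the count strictly below the
pooled median log frequency. The pooled median is taken over the union of
all caregivers' types at a timepoint, one observation per caregiver-type
(shared types are not deduplicated across caregivers — each caregiver's
use of a word is an observation about that caregiver's speech).

### Acoustic measures

Formants are consumed as inputs (midpoint F1/F2 of /i, a, u/ tokens); no
formant tracking is performed.

* **Lobanov normalization** — per speaker-session z-scoring of F1 and F2
  over all measured vowel tokens. Statistics are computed per session, not
  pooled across timepoints, so sessions are independently processable.
* **Vowel space area** — shoelace area of the triangle through the
  per-category mean (F2, F1) of /i, a, u/, in both normalized and raw Hz
  space. A missing category yields a null, never a zero.
* **Vowel dispersion** — Euclidean distance of each token from the
  speaker-session median (F1_z, F2_z), then averaged within word type so
  each type contributes once; per-token values are retained in the output
  for users who prefer the token-level reading.
* **Phone duration** — durations in ms of all phones passing the
  whispered/yelled/overlap filter, summarized by the median.
* **Coarticulation** — Mel log-magnitude spectra (25 ms Hann window,
  10 ms hop, 40 bands over 0–8 kHz at 16 kHz, log floor 1e-10) are
  averaged over each phone's frames; the measure is the Euclidean distance
  between the averaged spectra of adjacent phones. Larger distance = less
  coarticulation. The frame parameters are standard speech-analysis
  defaults and are configurable; distances are only comparable within one
  configuration, so no absolute distance value in this package should be
  compared against numbers produced by other front-ends.

Coarticulation eligibility: adjacent CV or VC pairs in content words, with
a stressed vowel. Excluded: prevocalic stops (utterance-initial closures
cannot be delimited), prevocalic /h/ (weak spectral signature), and pairs
touching flagged speech. The stop and /h/ exclusions apply only to the
consonant-before-vowel order; vowel-before-stop pairs remain eligible,
since the motivating segmentation problem concerns prevocalic closures.
This directional reading is an interpretive choice. Whispered, yelled, and
overlapping speech is encoded as `@w`/`@y`/`@o` suffixes on phone-tier
labels — an annotation convention of this package, since no standard
exists.

## Nonword-repetition scoring

Each nonword target phoneme is compared with the equivalent phoneme in a
design-matched real word. Wrong in both conditions → the error is
attributed to articulatory limitation and the target is not marked
incorrect; wrong only in the nonword → incorrect; right → correct. Items
refused after the two allowed experimenter prompts are marked entirely
incorrect (the articulatory control does not apply to refusals).

"Not marked incorrect" is read as "scored correct", keeping the full
33-target denominator; this is consistent with observed accuracies
reaching 1.0. Because the wording also admits dropping such targets from
the denominator, an `exclude` mode is provided. Phoneme comparison is
exact segmental match after stress stripping — binary scoring, no
feature-distance partial credit. The bundled 11-item stimulus inventory
(4/4/3 syllable split, 33 targets) is **synthetic**: it reproduces the
task design, not any published item list.

## Statistical models

* `fit_ols` and `fit_random_intercept` wrap statsmodels OLS and MixedLM
  (REML). AIC is computed as 2k − 2ℓ with k counting coefficients plus
  variance parameters (the R convention, so ΔAIC comparisons match an
  lme4/lm workflow). Mixed-model fixed-effect t tests use a residual-df
  approximation (n − k − groups + 1) rather than Satterthwaite; pairwise
  timepoint contrasts built from the fixed-effect covariance are
  therefore approximate, and are Holm-adjusted by default (an exact,
  distribution-free adjustment; "none" is available).
* Models that mix nested per-word-type rows with broadcast session-level
  covariates set an `inflated_alpha` flag and suppress the SE/p of the
  broadcast terms, which repeating a per-session value across rows
  renders meaningless.
* **Residualization / disentangle** — for collinear predictors x1, x2 of
  outcome y: regress x1 on x2, fit `y ~ resid(x1|x2) + x2 + covariates`,
  mirror for x2, and classify (x1_direct / x2_direct / both / neither) by
  which residual terms reach α = 0.05. The Frisch–Waugh–Lovell theorem
  guarantees the residual coefficient equals the joint-model coefficient
  (asserted to 1e-8 in the tests); what residualization buys is a clean
  per-variable significance test that the collinear joint fit cannot
  give.

## The synthetic corpus generator

The generator produces, per dyad and timepoint: a session transcript
(tokens sampled i.i.d. from a Zipfian lexicon, geometric utterance
lengths averaging 5 tokens), phone alignments (lognormal durations,
shape σ = 0.55, contiguous within utterances, 200 ms pauses between),
per-phone Mel spectra, peripheral-vowel formants, and child outcomes.

Per-timepoint targets default to the descriptive statistics of the
longitudinal corpus this battery is designed around: types
246.63/237.76/261.28/292.68, tokens 873.38/864.88/1,012.91/1,247.22,
MATTR 0.88/0.87/0.89/0.91 at 7/10–11/18/24 months, phone duration
90.21/90.02/–/83.45 ms and spectral distance 6.89/6.91/–/7.37 (acoustics
absent at 18 months). Duration and distance targets are matched at the
median — the natural center for the right-skewed lognormal duration model
and for the battery's own median summaries. Outcome scales mirror the
reported distributions (NWR accuracy 0.65 ± 0.16 clipped to [0, 1];
expressive vocabulary 355.94 ± 150.32).

Two calibrations keep emergent statistics on target:

* **MATTR** — a temperature θ on the Zipf sampling weights is solved by
  bisection on the closed form E[MATTR] = Σᵢ(1 − (1 − qᵢ)ʷ)/w for i.i.d.
  draws, which is exact in expectation.
* **Spectral distance** — the prototype scale is solved by bisection
  against 150 pilot sessions whose chain and noise components are stored
  separately, targeting the mean per-session median distance (the same
  statistic the battery reports, which absorbs the small-sample skew of a
  median over a few hundred pairs). The residual calibration standard
  error is exposed in `CorpusGenerator.calibration_info` and enters the
  recovery test's tolerance.

**Coarticulation model.** The realized spectrum of phone *i* is the
first-order recursive carryover

    realizedᵢ = (1 − κ) · prototypeᵢ + κ · realizedᵢ₋₁,   realized₀ = prototype₀,

plus isotropic Gaussian noise (sd 0.3 per Mel band). Under this model the
expected squared adjacent distance is proportional to
(1 − κ)² · 2/(1 + κ), strictly decreasing in κ, and at κ = 1 every
distance collapses to the noise floor. The recursive form is preferred
over a single-step blend of the previous prototype alone: a one-step blend
makes the expected squared distance proportional to 1 − 3κ + 3κ², which
is *not* monotone in κ (it rises again beyond κ = 0.5), contradicting the
intended semantics of κ as a coarticulation dial. Carryover runs through
utterance boundaries, a simplification without consequence for the
measure because cross-utterance pairs fail the adjacency tolerance anyway.
Prototypes are drawn from a fixed internal seed so that distances are
comparable across master seeds; all corpus randomness proper derives from
the configured seed via per-(replicate, dyad, timepoint) `SeedSequence`
spawn keys, making corpora byte-reproducible and any session regenerable
in isolation.

Default κ values (0.50 / 0.52 / – / 0.45) encode the observed direction of
change — older children hear less coarticulated speech — and the 24-month
vowel means are expanded radially by 8% to produce the observed vowel-space
growth.

**Outcome models.** Continuous battery features are z-scored across dyads
before the declared coefficients apply (so coefficients are per-SD
effects); binary gender is a direct offset. The default planted
coarticulation→NWR effect is −0.05 accuracy per SD of spectral distance,
i.e. |t| ≈ 3 at 84 dyads, mirroring the magnitude of the reported
nested-model effect; phone duration, maternal education, and earlier
vocabulary carry smaller defaults. NWR accuracy is clipped to [0, 1] and
the clipping rate is reported, with a warning above 10%.

**What the generator does not emulate.** Real English phonotactics: the
random pronunciations make the synthetic lexicon far sparser than
English, so neighborhood densities are small (median near 0, versus ~20
in real lexicons) — density logic is therefore validated against
brute-force oracles on constructed lexicons, not against the generator.
Word-type counts are emergent rather than calibrated (one temperature
cannot pin MATTR and type counts simultaneously); they land in a
plausible range but are not matched to the type targets. There is no
conversational structure, no child speech, and no audio: spectra are
generated directly. An audio path exists (WAV → STFT → Mel) and is
exercised on tones and silence, but synthetic evaluation bypasses it.
Passing recovery tests therefore demonstrate that the pipeline measures
what the generator encodes — not that the measures are valid for real
recordings.

## Experiment sizes

Simulation experiments use sizes chosen to estimate each rate with
adequate precision: 1,000 replicates for the type-I error of the residual
test (binomial SE ≈ 0.007 at the nominal 0.05), 500 for REML variance
recovery, 200 for disentangle classification and for the end-to-end
coarticulation sign recovery. End-to-end replicates run 84 dyads with
200-token sessions and a 600-word lexicon — session length shortens the
per-dyad median-distance estimate's input, not the planted effect, so
recovery rates are insensitive to it while each replicate stays cheap.
The acceptance script uses 84-dyad full-length corpora for the battery
summaries and 100–500 replicates for the calibration quantities.

## Known limitations

* Absolute spectral-distance values depend on the Mel configuration and
  are not comparable across front-ends.
* The residual-df approximation for mixed-model inference is slightly
  anticonservative relative to Satterthwaite at small group counts.
* The disentangle classification inherits the usual caveats of sequential
  significance testing; its error rates are characterized by simulation
  (type-I within [0.03, 0.07]; planted-structure recovery ≥ 90%) under
  the generator's conditions only.
* TextGrid support is limited to the long format; short-format files are
  rejected with a pointer to convert in Praat.
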