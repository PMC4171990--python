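# Methods

This note documents the models, measures, and design choices behind
`melent`: what is computed, under which assumptions, and where the open
design decisions were resolved.

## Representation

Melodies are monophonic sequences of note events with integer chromatic
pitch (middle C = 60), onset and duration in abstract beat units (quarter
note = 1.0), and a phrase-start flag.  Tempo is presentation-only and not
represented.  Phrase boundaries, when a source format does not carry them,
are inferred from silent gaps: the default threshold is one beat of silence
between a note's offset and the next onset, a stand-in rule chosen because
hymn-style encodings typically separate phrases with rests; it is a
parameter, not a claim about any particular corpus.

The expectation model does not predict raw pitch.  Each note is re-described
as a linked viewpoint symbol: *pitch interval* (signed semitones from the
previous note; undefined for the first note), *scale degree* (semitones
above the tonic, modulo 12 — octave-equivalent, the standard probe-tone
treatment), and, for the rhythmic "complex" style only, *IOI contour*
(sign of the change between consecutive inter-onset intervals, ties coded
0, undefined for the first two notes).  For a fixed previous pitch and key
the map from candidate pitch to symbol is injective, so a distribution over
symbols converts losslessly to a distribution over candidate pitches.
Melody-initial events carry a scale-degree-only symbol and are counted and
predicted through the same machinery; candidates an octave apart then share
a symbol and split its mass evenly.

## The expectation model

The model is a variable-order Markov model with PPM-style smoothing and two
sub-models:

* **Counting.**  An n-gram store holds context → next-symbol counts for all
  context lengths up to a bound; contexts never span melody boundaries.
  *Update exclusion* (on by default): when a symbol is observed, counts are
  updated from the longest available context down until the first context
  that had already seen the symbol — shorter contexts are left alone, since
  the longer context already predicts the symbol.  Under the variable-order
  strategy, stored context length is capped at 10; melodic contexts longer
  than that essentially never recur at the corpus sizes used here, so the
  cap bounds memory without changing predictions.

* **Smoothing.**  Interpolated blending with escape method C (Witten–Bell):
  at a context with total count n and t distinct continuations, a symbol
  with count c contributes c/(n+t) and the escape weight t/(n+t) multiplies
  the next-shorter context's estimate, grounded in a uniform 1/|alphabet|
  floor.  Escape methods A and D and a backoff (non-interpolated) mode are
  selectable.  Lower-order symbol exclusion — a further PPM refinement — is
  not implemented.  All probabilities are strictly positive by construction
  and the emitted distribution is normalized over the queried alphabet (the
  alphabet need not exhaust the continuations seen in training).  The test
  suite checks the smoother against an exact rational-arithmetic
  implementation of the same recursion to 10⁻¹².

* **Order bound.**  Fixed bounds 0–4, or *variable*: the recursion starts
  at the longest context suffix with any support (PPM*-like).  On data whose
  true structure is low-order, deep spurious matches make the variable
  strategy slightly overconfident on held-out material; where long contexts
  are genuinely predictive (repeated motifs) it clearly wins.  Both
  behaviors are covered by tests.

* **LTM, STM, and combination.**  The long-term sub-model is trained on a
  corpus beforehand (schematic, enculturated expectation); the short-term
  sub-model starts empty for each melody and learns online, always
  predicting before observing (causal).  When both are active their
  distributions combine by a weighted geometric mean with weights
  w_i = H_norm(d_i)^(−b): the more confident sub-model dominates, more so
  as the bias exponent b grows (default b = 1; b = 0 gives the plain
  geometric mean).  H_norm is floored at 10⁻⁶ in the weight computation to
  keep weights finite for near-deterministic distributions.

* **Alphabet policy.**  `corpus` (pitches observed in training plus the
  stimulus) or `chromatic_span` (chromatic fill of the corpus range).  The
  pipeline uses the span policy on a training corpus spanning B2–B5, giving
  the 37-pitch chromatic alphabet over which "37-tone entropy" is defined.

## Information measures

All logarithms are base 2.  IC(x) = −log₂ p(x); H = −Σ p log₂ p
(0 ≤ H ≤ log₂ n); H_max = log₂ n; H_norm = H/H_max ∈ [0, 1].  A
distribution can be renormalized over a pitch subset (the 9-tone entropy of
stimulus selection).  The Schmuckler difference score — mean minus minimum
of IC, or of probability, over the distribution — is implemented in both
variants because the source descriptions of this competitor disagree
between an IC and a probability formulation; the IC variant is the default
and neither is presented as canonical.

## Key finding

The induced key of a melodic segment is the (tonic, mode) pair among 24
candidates maximizing the Pearson correlation between the segment's
duration-weighted pitch-class distribution and the correspondingly rotated
key profile.  Two profile sets ship as a versioned data file with
provenance strings: the Krumhansl–Kessler probe-tone profiles and
Temperley's modified values; Temperley is the default for the final
selection stage (perceptually induced key), and a count-weighted option
exists.  Ties break deterministically: lowest tonic, major before minor.
Candidate extraction in stimulus selection uses the melody's stored
("notated") key; the final selection stage re-estimates the key from the
context itself.

## Stimulus selection

Stage 1: every note of each stimulus corpus is scored with the entropy of
the model's full-alphabet predictive distribution at that position; the 18
highest- and 18 lowest-entropy *eligible* notes per corpus become candidate
targets.  Eligibility requires a note index of at least 8, since the context
constraints below are otherwise unsatisfiable (very early notes also score
artifactually high, having almost no context).  Each candidate's context is
the shortest phrase-initial prefix ending just before the target that
contains at least one complete phrase, at least eight notes and at least
four distinct pitches; candidates with no qualifying prefix are rejected
with a recorded reason.

Stage 2: each surviving candidate receives nine chromatically consecutive
probe tones centred on the context's median pitch (even-length medians
round half down), shifted by the minimal number of semitones needed to
include the true continuation — and, additionally, to stay inside the
model's pitch alphabet.  Candidates are re-scored by the entropy of the
predictive distribution renormalized over their probes, under the
re-estimated key; per style × entropy cell the 6 most extreme candidates
are kept (highest 9-tone entropy for high cells, lowest for low), skipping
candidates whose note span overlaps an already selected context of the same
melody.  The overlap-exclusion-plus-extremeness rule is this package's
determinization of a reduction step whose exact procedure is not otherwise
specified.  The whole selection is deterministic given corpus, model and
configuration.

## Synthetic data

**Corpora** are sampled from first-order Markov grammars.  The default
grammars are *graded*: per-state Dirichlet rows whose concentration rises
log-linearly across the alphabet, so one end of the pitch range behaves
near-deterministically (low conditional entropy) and the other near-uniform,
giving the entropy-extreme selection something real to find.  Phrase
lengths are uniform on 6–10 notes with a one-beat rest at each boundary;
the isochronous style has unit IOIs, the rhythmic style draws durations
from {0.5, 1, 2} beats.  Default sizes are scaled-down analogues of the
study corpora, chosen so a full desk run takes seconds: training 60
melodies × 40 notes spanning B2–B5 (so the span policy yields the 37-pitch
alphabet), and 40 × 40 per stimulus corpus with the study's style ranges
(simple C4–F5, complex A3–A5).  The analytic stationary-averaged
conditional entropy Σ_s π(s) H(row_s) of any grammar is available as an
oracle for recovery tests.

Because the two styles use different viewpoint systems (the complex style
adds IOI contour), the shared training corpus yields one trained store per
style, mirroring a design in which a single training collection serves both
stimulus sets.

**Listeners** map model quantities to the 9-point scale affinely —
calibrated so the 5th/95th percentiles of the stimulus set's IC (or
entropy) land on 1 and 9, mirroring the instruction to use the full range
of the scale — add Gaussian noise, round and clip, and lapse to a uniform
random rating with probability 0.02.  Expertise is operationalized purely
as rating noise: musicians σ = 1.0, non-musicians σ = 2.0 on the 9-point
scale, reflecting the hypothesis that training sharpens the internal
predictive model.  The design mirrors the study: 24 contexts × 9 probes,
17 participants per group, all overridable.  Gold-MSI-like training scores
are drawn per group around the study's printed summaries (used only for
profile realism and the demographics checks).

What the generator deliberately does *not* emulate: veridical familiarity
(familiarity flags default to false), memory for specific melodies,
response times, serial-position or drift effects within the session, and
any dependence of listener behavior on tonal structure beyond what the
generating model's IC carries.  Passing tests on this world therefore show
that the pipeline recovers the structure it assumes — not that human
listeners behave this way.

## Behavioral statistics

*Inferred uncertainty* is the normalized entropy of a listener's probe
rating distribution.  Two orientations exist: `raw` (unexpectedness ratings
as weights — the default, following the procedure-level wording) and
`reversed` (expectedness weights, 10 − rating — following the
summary-level wording).  They genuinely disagree on synthetic data: under
the raw orientation a spiky-expectation context still has near-uniform
*unexpectedness* weights (one rating of 1, eight of 9 give
H_norm ≈ 0.97), so the measure is compressed near 1 and its high-vs-low
contrast is small and can invert under rating noise; the reversed
orientation separates the conditions robustly.  The pipeline analyzes and
reports both; headline entropy-effect numbers use the reversed
(expectedness-entropy) orientation.

The 2×2×2 mixed ANOVA (two 2-level within factors, one 2-level between
factor) is computed by the within-participant contrast reduction: the four
cell means per participant are transformed by an orthonormal contrast
basis; each within effect and its interaction with group are OLS tests on
one contrast column with the group effect-coded (a Type III test —
intercept = unweighted mean of group means — valid for unequal group
sizes); the between effect is the test on the subject-mean column.  For
2-level factors this is exactly the classical univariate mixed-model
analysis (sphericity is trivial), verified against a brute-force cell-means
decomposition in the tests and against pingouin on the one-within-factor
marginal.  Reported sums of squares come from the weighted orthonormal
decomposition, which is exactly additive (SS_total equals the sum of all
effect and stratum-error SS); in balanced designs F = SS_effect/MS_error
holds as usual.  The Conover–Iman variant assigns midranks over the pooled
dataset and reruns the same ANOVA.

Other choices: outlier exclusion is participant-level per dependent
variable using 1.5×IQR Tukey fences per condition, boundary values
retained; Cronbach's α treats participants as items and contexts as cases
(inter-individual consistency), switchable; Fisher's z = atanh r is capped
at atanh(1 − 10⁻¹²) so perfect correlations stay finite; the Welch and
pooled t tests work from group summaries (mean, SD, n); the 2×2 χ² is
Pearson's without continuity correction by default (required to match the
printed worked example); the Williams/Steiger statistic for comparing two
dependent correlations sharing a variable uses the T2 form
t = (r12 − r13) √[(n−1)(1+r23) / (2·((n−1)/(n−3))·|R| + r̄²(1−r23)³)] with
df = n − 3, oracle-tested against an independent symbolic evaluation;
p-values are two-tailed and no multiple-testing correction is applied.
Familiarity-flagged (participant, context) cells are dropped before every
analysis (cell-wise, not participant-wise, removal).  Shapiro–Wilk and
Levene checks are available as diagnostics through scipy but are not
automatic gates.

The model-comparison grid evaluates order bounds {0–4, variable} ×
configurations {STM, LTM, BOTH}: Spearman correlations of per-stimulus
model entropy with mean inferred and explicit uncertainty (overall and per
group) and of per-probe IC with mean unexpectedness, plus competitor rows —
both Schmuckler variants under the standard configuration, and the
three-predictor IR regression (multiple R) for the unexpectedness column.
Per-configuration trace tables allow every correlation to be recomputed.

## The Implication-Realization baseline

Three per-probe predictors combined by OLS on participant-averaged ratings:
proximity 12 − min(|probe − last|, 12); pitch reversal as a two-component
code — direction {+1 reversal, −1 continuation, 0 unison} gated on the
implicative interval exceeding 6 semitones, plus a +1.5 returning-proximity
bonus when the realized pitch lands within 2 semitones of the pitch that
launched the implicative interval; and tonal hierarchy, the
Krumhansl–Kessler profile value of the probe's scale degree in the
context's key.  The numeric codings follow the published simplification of
the theory; because the primary sources parameterize proximity in more than
one way, the constants live in one documented, overridable table
(`IR_CONSTANTS`), and the predictor is undefined (dropped) for contexts too
short to define an implicative interval.

## Numerical and degenerate-input conventions

Distributions validate Σp = 1 ± 10⁻⁹ and p > 0.  Flat pitch-class
distributions make all key correlations equal; the tie-break decides.
Zero-variance series raise an explicit undefined-statistic error rather
than returning NaN.  The Schmuckler score is clamped at 0 against float
round-off.  Selection tie-breaks are lexicographic on (melody id, note
index).  A single top-level seed is expanded into independent per-stage
streams (numpy SeedSequence), making a pipeline run byte-identical for a
fixed config.

## Problem sizes

The default run — 2400 training events, 2 × 1600 stimulus-corpus events,
24 stimuli, 34 simulated listeners, an 18-configuration comparison grid —
completes in a few seconds; the model-recovery study trains on 10⁴ events;
the replicate-recovery test re-simulates 100 listener cohorts on a fixed
stimulus set.  These sizes were chosen as the smallest at which the
qualitative effects are stable, and are all configurable upward.

## Known limitations

The synthetic grammar ties conditional entropy to pitch region, which is a
convenience, not a musicological claim; 37-tone entropy and 9-tone entropy
correlate less tightly here than they presumably do in tonal corpora, so
grid columns involving full-alphabet entropy against probe-derived measures
are noisier than their IC counterparts.  The variable-order strategy is
mildly overconfident on strictly low-order data (see above).  The IR
constants are one defensible transcription of the cited coding, not the
only one.  Human-data magnitudes (correlation coefficients, F values,
α levels from real listeners) are outside what this synthetic world can or
should reproduce; only directions and design counts are claimed.
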