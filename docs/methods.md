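# Methods

## Data model

A corpus is a flat table of vowel tokens: speaker, twin pair, speaking
style (`dialogue` | `interview`), vowel label, duration (s), and F1–F4
(Hz) measured at the vowel midpoint. The seven Brazilian Portuguese oral
monophthongs are stored as ASCII codes `i e E a O o u` (`E` = /ɛ/, `O` =
/ɔ/). Token invariants are enforced on construction: 0 < F1 < F2 < F3 <
F4 < 5000 Hz (the LPC extraction ceiling) and positive duration. Files are
UTF-8 TSV with `.` as decimal separator; thousands marks are rejected so a
number can never parse ambiguously.

## Synthetic corpus generator

Every token's formant vector is

    vowel mean + speaker offset + style offset + token noise,

all Gaussian. Key design points:

* **Speaker offsets** are drawn once per speaker per formant and shared
  across vowels — they model vocal-tract anatomy (e.g. tract length), which
  shifts all vowels coherently. Twin siblings' offsets are correlated with
  coefficient `twin_similarity` (default 0.8); twins are never compared,
  but the correlation makes twin-exclusion in grouping consequential.
* **Style offsets** are drawn per speaker *and* style, so the style effect
  is speaker-dependent rather than a global shift: some speakers move one
  way between styles, others the opposite way, which is exactly what makes
  mismatched comparisons hard.
* **Defaults** (all Hz). Vowel means are calibrated so per-vowel F1 means
  span 331–586 and F2 means 1074–2027, with F3 (2368–2655) and F4
  (3387–3570) compressed — large linguistic structure in the lower
  formants, little in the upper. Vowel probabilities follow the observed
  token distribution a:i:u:ɛ:e:o:ɔ = 5995:2910:1838:1684:1479:1063:973.
  Between-speaker sd (20, 30, 55, 60) vs within-speaker token sd
  (45, 110, 110, 120) puts proportionally more speaker information in
  F3/F4 than F1, and least in F2; the absolute level is chosen so a
  multi-token comparison system lands in the realistic EER regime of
  roughly 0.05–0.2 rather than at ceiling — same-dialect male speakers
  overlap heavily on any single vowel. Style-shift sd (8, 14, 16, 18) is
  well under the between-speaker sd: the two styles' population vowel
  spaces overlap almost completely, yet cross-style comparisons degrade
  measurably.
* **Token counts** per speaker and style are uniform on per-style ranges
  (defaults: dialogue 382–560, interview 202–450); one designated speaker
  is pinned to the range minimum in each style so the downsampling stage
  has a unique minority class with known counts (minima 382/202 give
  per-iteration totals 7,640 dialogue, 4,040 interview, 8,080 mismatched).
* **Rejection sampling**: tokens violating F1 < F2 < F3 < F4 (or the 5 kHz
  ceiling) are redrawn, a slight truncation of the Gaussian model; with the
  default means the affected mass is negligible.
* What the generator does **not** model: durations correlated with vowel
  quality or style, prosody, channel effects, per-vowel differences in
  speaker variance, session drift within a style, and phonotactics.
  Passing tests therefore demonstrate that the pipeline recovers structure
  of this idealised kind; they do not certify performance on real speech.

`recover_variance_components` closes the loop: one-way ANOVA
(method-of-moments) per vowel × style cell, pooling the within component
by degrees of freedom and the between component by cell token counts (so
precise high-frequency-vowel cells dominate noisy rare-vowel cells).
With 20 speakers the between-speaker sd estimate is limited by the
realised draw of 20 offsets (relative sd ≈ 1/√(2·19) ≈ 11%), so recovery
checks average estimates over several independently generated corpora.

## Preprocessing

Outlier screening uses per speaker × style × vowel cells: for each formant
independently, tokens outside `[Q1 − 2.5·IQR, Q3 + 2.5·IQR]` are flagged
(quartiles by linear interpolation), and a token is removed when **any**
formant flags it, because the multivariate scorer needs complete vectors.
The rule is applied once, not iterated. The 2.5 multiplier is deliberately
less conservative than the textbook 1.5 so genuine biometric extremes
survive.

Downsampling equalises per-speaker token counts to the minority speaker's
count within a style (the minority speaker's tokens pass through
unsampled); the natural vowel distribution is deliberately preserved. For
mismatched runs, counts are equalised to the global per-speaker-per-style
minimum so each speaker contributes equally in both styles. Because
sampling is random, the whole analysis is repeated over iterations and the
per-iteration metrics aggregated.

## Groups and cross-validation protocol

Speakers are organised into random groups of 10 in which no two members
are twins; with 20 speakers in 10 pairs this forces exactly one member per
pair, drawn by a fair coin (general configurations use rejection
sampling). Groups are sampled with replacement. Within a group every one
of the 45 unordered pairs is tested in turn; the remaining 8 members are
that fold's background population. Per vowel, an MVKD model is fitted on
background tokens only; development scores for calibration/fusion are all
comparisons computable among background members alone (28 Hd + 8 Hs).
The tested pair's speakers never enter background fitting or development
scoring. The fold emits the fused LR for the tested pair and for each
tested member's own same-speaker comparison, so a group cell yields 45 Hd
and 90 Hs trials.

Conditions: in matched runs each speaker's downsampled tokens are split
50/50 at random into reference and questioned halves (per iteration);
same-speaker trials compare the two halves. In mismatched runs interview
tokens are the reference material and dialogue tokens the questioned
material, for different- and same-speaker trials alike. Mismatched
background models are fitted on background speakers' pooled
interview+dialogue tokens, so the style shift inflates the within-speaker
covariance — the model "knows" styles vary without knowing how a specific
speaker shifts.

## MVKD scoring

For a questioned mean `yq` over `nq` tokens and reference mean `yr` over
`nr` tokens, with background speaker means `μⱼ`, pooled within-speaker
covariance `W`, between-speaker covariance `B` and kernel covariance
`C = h²B`:

    numerator  = N(yq − yr; 0, W/nq + W/nr)
                 · (1/m) Σⱼ N(w; μⱼ, C + W/(nq+nr)),   w = (nq·yq + nr·yr)/(nq+nr)
    denominator = [(1/m) Σⱼ N(yq; μⱼ, C + W/nq)] · [(1/m) Σⱼ N(yr; μⱼ, C + W/nr)]

a similarity term times a typicality term over the marginal typicalities.
Scores are log₁₀ and clamped to ±10 (bounded penalties; standard practice
against density underflow). Implementation notes: all Gaussian evaluations
go through batched Cholesky whitening grouped by the scalar in `C + W/s`,
and formant-subset models are sliced from the full 4-formant fit (all
fitted quantities are moments, so sub-blocks are exact) with only the
bandwidth recomputed for the new dimensionality. A singular pooled `W`
raises an error advising more tokens or fewer formants; the minimum is 3
background speakers with 2 tokens each, and comparison samples need ≥ 3
tokens per vowel.

The scorer was validated against direct numerical integration of the
two-level model (1-D adaptive quadrature and 2-D Simpson grids, ≤ 1e−6
relative) and against the closed-form normal two-level LR in the
single-Gaussian limit.

## Calibration and fusion

A single binary logistic regression maps the per-vowel log₁₀-LR vector to
one calibrated log₁₀ LR: `(w·x + b − log(Nss/Nds)) / ln 10`, the posterior
log-odds with the development-set prior log-odds subtracted (equal-prior
convention). Numerical design, in order of application:

1. **Nonnegative weights.** Each input is itself a log LR for the
   same-speaker proposition, so a fused model in which more same-speaker
   support in one vowel lowers the overall LR is unphysical; weights are
   constrained ≥ 0 (L-BFGS-B with bound constraints; the intercept is
   free). This also removes most of the freedom a small development set
   offers for fitting noise.
2. **Separation fallback.** Development sets of fold size (36 comparisons)
   are frequently perfectly separable, leaving the MLE unbounded; such
   folds are refitted with an L2 penalty of λ = 1e−3 on the mean-log-loss
   scale.
3. **Evidential-value gate.** Unless the fitted model beats the
   intercept-only model in a likelihood-ratio test at α = 0.05, the fold's
   calibrated system collapses to LR = 1 for every comparison — no
   discrimination claim without development evidence. Because the weights
   live in the nonnegative cone, the null distribution of the deviance
   improvement is the chi-bar-square mixture Σⱼ C(d, j) 2⁻ᵈ χ²(j) rather
   than χ²(d); the mixture's upper-α point is solved by bisection.
4. **Missing dimensions.** A vowel absent from one sample contributes its
   development-set column mean (a documented bias that keeps the fold
   usable); a vowel with no development scores at all is dropped from that
   fold's fusion. Constant columns are excluded from fitting.

Known limitation: with 36 development comparisons per fold, calibration
is the variance bottleneck of the whole pipeline. In the uninformative
limit (no speaker information at all) the folds that pass any in-sample
evidence test are precisely the ones whose noise alignment looks strongest,
so the aggregate Cllr of a truly uninformative corpus settles measurably
above the ideal value of 1 even though its EER is at chance; the in-sample
deviance improvement is bounded by twice the label entropy, a ceiling that
both separable noise and genuinely perfect systems attain, so no in-sample
statistic can fully close this gap. At full study scale the effect
shrinks with the number of aggregated cells but does not vanish.

## Metrics and aggregation

Cllr is computed directly from the defining penalty means; it is exactly 1
for an all-LR=1 system regardless of trial counts. EER sweeps thresholds
over the pooled empirical scores with FRR(t) = P(ss < t), FAR(t) = P(ds ≥
t) (ties count as false accepts), locates the crossing of the two step
functions and linearly interpolates between the adjacent empirical points;
an `as-printed` variant returning half the crossing value is exposed for
comparability with the halved-average formulation, whose chance level is
0.25 rather than 0.5 — the crossing convention is the default for exactly
that reason. Values above 0.5 (anti-ordered systems) are returned as
computed, with a warning.

Per-cell results (one Cllr and EER per condition × subset × group ×
iteration) are aggregated per condition × subset after removing, per
metric independently, cells outside `[Q1 − 2.5·IQR, Q3 + 2.5·IQR]` —
the same screening rule applied to tokens, here absorbing pathological
resampling iterations.

## Scale presets

The full design (150 groups × 100 downsampling iterations × 8 formant
subsets × 3 conditions) is hours of compute. The desk preset (5 groups ×
3 iterations, group size 10 over the 20-speaker corpus) is the routine
test scale; all directional claims (matched better than mismatched, upper
formants beating lower formants, all-formant fusion best) are checked at
desk scale with ≥ 10 cells per condition × subset. Group and iteration
counts are configurable and crossed (every group scored in every
iteration); seeds derive from a single `SeedSequence` per run, so runs are
bit-reproducible.

The desk preset keeps the full 20-speaker/10-pair group structure rather
than shrinking the speaker set: a smaller group would shrink each fold's
background (8 speakers) and development set (36 comparisons), changing the
statistical character of calibration, which is the component most
sensitive to scale.

## Vowel-space descriptives

Per speaker × style, the vowel space polygon is the convex hull of the
per-vowel mean (F1, F2) points; its area (Hz², shoelace via the hull) is
reported alongside per-formant min/max/range of the cross-speaker
per-vowel means. Fewer than three vowel categories leave the area
undefined (reported missing); degenerate (collinear) configurations have
area 0. The percent spread uses the symmetric convention
`(max − min) / mean(min, max) · 100`, stated explicitly because range
percentages are ambiguous without a base.
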