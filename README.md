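# formantlr

Likelihood-ratio evaluation of the speaker-discriminatory power of vowel
formant frequencies (F1–F4) under matched and mismatched speaking styles.

## The problem

Forensic speaker comparison asks how strongly a pair of speech samples
supports the hypothesis that they come from the same speaker (Hs) versus
different speakers (Hd). For vowel acoustics the evidence is the formant
frequencies — vocal-tract resonance peaks — measured per vowel token. This
package implements, end to end, a likelihood-ratio evaluation of that
evidence for corpora structured like a twin-study corpus of 20 male
Brazilian Portuguese speakers (10 identical twin pairs, only non-twin
comparisons tested) recorded in two styles: spontaneous telephone
*dialogue* and an *interview* with an unfamiliar interviewer. Comparing a
speaker's interview material (reference) against another speaker's dialogue
material (questioned) is the forensically realistic *mismatched* condition.

The score for one vowel and one formant subset is the multivariate
kernel-density (MVKD) likelihood ratio

```
LR = p(E | Hs) / p(E | Hd)
```

from a two-level model: token-level (within-speaker) variation is normal
with pooled covariance `W`; the between-speaker distribution of speaker
mean vectors is a kernel-density mixture over the `m` background speakers'
means with kernel covariance `h²B`, where `B` is the between-speaker
covariance and `h = (4 / ((2d+1) m))^(1/(d+4))` the normal-reference
bandwidth for `d` formants. Per-vowel scores are fused and calibrated by
logistic regression into a single log₁₀ LR per comparison, under
leave-pair-out cross-validation inside random 10-speaker groups that never
contain both members of a twin pair (the remaining 8 members are the
background population and supply the calibration development scores).

System validity is summarised by the log-LR cost

```
Cllr = ½ ( mean_ss log₂(1 + 1/LR) + mean_ds log₂(1 + LR) )
```

(0 = perfect, 1 = an uninformative system that always answers LR = 1) and
the equal error rate (EER; 0 = perfect, 0.5 = chance), aggregated over many
random downsampling iterations with a 2.5·IQR screen on the per-cell
metrics.

Because the study's recordings are not redistributable, the package ships a
synthetic corpus generator with the same statistical skeleton (vowel means,
imbalanced vowel and speaker token counts, between-speaker offsets,
speaker-specific style shifts, correlated twin siblings) and known ground
truth, so every stage is testable.

## Worked example

```python
import warnings
import pandas as pd
import formantlr as flr
from formantlr.metrics import aggregate

corpus, truth = flr.generate_corpus(flr.SynthConfig(seed=7))
screened, report = flr.remove_outliers(corpus, k=2.5)

cfg = flr.ExperimentConfig.desk(
    seed=0, n_groups=3, n_reps=2,
    formant_subsets=("F1+F2", "F3+F4", "F1+F2+F3+F4"),
)
with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    matched = flr.run_matched(screened, cfg.replace(conditions=("matched-dialogue",)))
    mismatched = flr.run_mismatched(screened, cfg.replace(conditions=("mismatched",)))

summary = aggregate(pd.concat([matched, mismatched], ignore_index=True))
print(summary[["condition", "subset", "cllr_mean", "eer_mean"]].round(3).to_string(index=False))
```

prints (15,248 generated tokens, 48 removed by the outlier screen):

```
       condition      subset  cllr_mean  eer_mean
matched-dialogue       F1+F2      1.187     0.185
matched-dialogue F1+F2+F3+F4      0.490     0.063
matched-dialogue       F3+F4      1.021     0.137
      mismatched       F1+F2      1.675     0.237
      mismatched F1+F2+F3+F4      0.708     0.087
      mismatched       F3+F4      0.993     0.154
```

Reading the table: fusing all four formants is clearly the best system in
both conditions (lowest Cllr and EER), the upper-formant pair F3+F4 beats
the linguistically constrained lower pair F1+F2, and every subset degrades
when reference and questioned material come from different speaking styles
(the F3+F4 matched/mismatched gap is within Monte-Carlo noise at this
deliberately reduced desk scale of 3 groups × 2 downsampling iterations;
the full design uses 150 groups × 100 iterations —
`ExperimentConfig.full_scale()`).

A command-line interface mirrors the library:

```bash
formantlr synth --out corpus.tsv
formantlr preprocess --corpus corpus.tsv --out screened.tsv --report-out outliers.tsv
formantlr run-mismatched --corpus screened.tsv --preset desk --out metrics.tsv --summary-out summary.tsv
formantlr per-vowel --corpus screened.tsv --preset desk --out by_vowel.tsv
formantlr describe --corpus screened.tsv --out-prefix desc
```

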