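"""Outlier screening and minority-class downsampling.

Two preparation steps precede likelihood-ratio scoring:

* **Outlier screening** — within every speaker x style x vowel cell, and for
  each formant independently, tokens whose value falls outside
  ``[Q1 - k*IQR, Q3 + k*IQR]`` (default k = 2.5, deliberately less
  conservative than the textbook 1.5 so genuine biometric extremes survive)
  are removed. A token is dropped when *any* formant flags it, because the
  multivariate scorer needs complete F1-F4 vectors. Quartiles use linear
  interpolation on the sorted cell values; the rule is applied once, not
  iterated.

* **Downsampling** — spontaneous speech yields wildly different token counts
  per speaker, so every speaker is randomly thinned (uniformly, without
  replacement) to the minority speaker's count within a style. The natural
  vowel distribution is deliberately preserved: no per-vowel balancing. For
  cross-style comparisons, counts are equalised to the global
  per-speaker-per-style minimum so each speaker contributes the same number
  of tokens in each style.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .corpus import Corpus, FORMANT_COLUMNS, STYLES

__all__ = ["remove_outliers", "downsample", "downsample_mismatched"]

REPORT_COLUMNS = (
    "row",
    "speaker",
    "style",
    "vowel",
    "formant",
    "value",
    "lower_bound",
    "upper_bound",
)


def remove_outliers(corpus: Corpus, k: float = 2.5) -> tuple[Corpus, pd.DataFrame]:
    """Drop tokens with any formant outside the per-cell k*IQR fences.

    Returns the screened corpus and a report with one row per (token,
    triggering formant): original row index, cell labels, offending value
    and the fence that flagged it.
    """
    if not k > 0:
        raise ValueError("k must be positive")
    df = corpus.tokens
    drop = np.zeros(len(df), dtype=bool)
    report_rows: list[dict] = []
    for (speaker, style, vowel), cell in df.groupby(["speaker", "style", "vowel"], sort=True):
        for col in FORMANT_COLUMNS:
            vals = cell[col].to_numpy(dtype=float)
            q1, q3 = np.percentile(vals, [25, 75])  # linear interpolation
            iqr = q3 - q1
            lo, hi = q1 - k * iqr, q3 + k * iqr
            bad = (vals < lo) | (vals > hi)
            if bad.any():
                for idx, val in zip(cell.index[bad], vals[bad]):
                    report_rows.append(
                        {
                            "row": int(idx),
                            "speaker": speaker,
                            "style": style,
                            "vowel": vowel,
                            "formant": col,
                            "value": float(val),
                            "lower_bound": float(lo),
                            "upper_bound": float(hi),
                        }
                    )
                drop[df.index.get_indexer(cell.index[bad])] = True
    report = pd.DataFrame(report_rows, columns=list(REPORT_COLUMNS)).sort_values(
        ["row", "formant"], ignore_index=True
    )
    return corpus.with_tokens(df.loc[~drop]), report


def _as_rng(seed=None, rng=None) -> np.random.Generator:
    if rng is not None:
        return rng
    return np.random.default_rng(seed)


def _sample_group(idx: np.ndarray, m: int, rng: np.random.Generator) -> np.ndarray:
    if len(idx) == m:  # minority class passes through unsampled
        return idx
    chosen = rng.choice(len(idx), size=m, replace=False)
    return idx[np.sort(chosen)]  # keep original row order


def downsample(
    corpus: Corpus, style: str, seed: int | None = None, rng: np.random.Generator | None = None
) -> Corpus:
    """Balance per-speaker token counts within one style to the minority count."""
    if style not in STYLES:
        raise ValueError(f"unknown style {style!r}")
    rng = _as_rng(seed, rng)
    df = corpus.tokens[corpus.tokens["style"] == style]
    counts = df.groupby("speaker").size()
    missing = sorted(set(corpus.speakers) - set(counts.index))
    if missing:
        raise ValueError(f"speaker(s) without tokens in style {style!r}: {missing}")
    m = int(counts.min())
    keep: list[np.ndarray] = []
    for speaker in sorted(counts.index):
        idx = df.index[df["speaker"] == speaker].to_numpy()
        keep.append(_sample_group(idx, m, rng))
    kept = np.sort(np.concatenate(keep))
    return corpus.with_tokens(corpus.tokens.loc[kept])


def downsample_mismatched(
    corpus: Corpus, seed: int | None = None, rng: np.random.Generator | None = None
) -> Corpus:
    """Balance counts to the global per-speaker-per-style minimum in *both* styles.

    Every speaker retains exactly ``m*`` tokens in each style, where ``m*`` is
    the smallest per-speaker count observed in either style, so cross-style
    comparisons see the same amount of material per speaker and style.
    """
    rng = _as_rng(seed, rng)
    df = corpus.tokens
    counts = df.groupby(["speaker", "style"]).size()
    for speaker in corpus.speakers:
        for style in STYLES:
            if (speaker, style) not in counts.index:
                raise ValueError(f"speaker {speaker!r} has no tokens in style {style!r}")
    m = int(counts.min())
    keep: list[np.ndarray] = []
    for speaker in sorted(corpus.speakers):
        for style in STYLES:
            idx = df.index[(df["speaker"] == speaker) & (df["style"] == style)].to_numpy()
            keep.append(_sample_group(idx, m, rng))
    kept = np.sort(np.concatenate(keep))
    return corpus.with_tokens(corpus.tokens.loc[kept])
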