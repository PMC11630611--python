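"""Vowel-formant token tables: the data model every other stage consumes.

A corpus is a flat table of measured vowel tokens, one row per token, as a
Praat formant-extraction script would emit it: speaker identity, twin-pair
membership, speaking style, vowel label, vowel duration in seconds and the
first four formant frequencies in Hertz, measured at the vowel midpoint.

Vowel labels are the seven Brazilian Portuguese oral monophthongs, stored as
ASCII codes with the obvious IPA mapping: ``i e E a O o u`` for
/i e ɛ a ɔ o u/ (``E`` = open-mid front /ɛ/, ``O`` = open-mid back /ɔ/).

The on-disk format is a UTF-8 tab-separated table with header columns
``speaker  twin_pair  style  vowel  duration_s  f1_hz  f2_hz  f3_hz  f4_hz``,
``.`` as the decimal separator and no thousands marks. ``twin_pair`` is empty
for speakers without a twin in the corpus.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

VOWELS: tuple[str, ...] = ("i", "e", "E", "a", "O", "o", "u")
VOWEL_TO_IPA: dict[str, str] = {
    "i": "i",
    "e": "e",
    "E": "ɛ",
    "a": "a",
    "O": "ɔ",
    "o": "o",
    "u": "u",
}
STYLES: tuple[str, ...] = ("dialogue", "interview")
FORMANT_COLUMNS: tuple[str, ...] = ("f1_hz", "f2_hz", "f3_hz", "f4_hz")
COLUMNS: tuple[str, ...] = (
    "speaker",
    "twin_pair",
    "style",
    "vowel",
    "duration_s",
) + FORMANT_COLUMNS

#: LPC extraction ceiling: no formant above this frequency is a valid measurement.
MAX_FORMANT_HZ: float = 5000.0


class CorpusFormatError(ValueError):
    """The file does not follow the token-table schema (missing/unparsable columns)."""


class CorpusValidationError(ValueError):
    """Rows violate the token invariants (formant ordering, labels, ranges)."""


@dataclass(frozen=True)
class FormantToken:
    """One measured vowel token."""

    speaker: str
    twin_pair: str | None
    style: str
    vowel: str
    duration_s: float
    f1_hz: float
    f2_hz: float
    f3_hz: float
    f4_hz: float


def _fmt_rows(idx: np.ndarray, limit: int = 10) -> str:
    shown = ", ".join(str(i) for i in idx[:limit])
    more = f" (+{len(idx) - limit} more)" if len(idx) > limit else ""
    return shown + more


@dataclass
class Corpus:
    """A collection of vowel tokens with speaker/twin metadata.

    Parameters
    ----------
    tokens
        One row per token with the columns in :data:`COLUMNS`. Row order is
        meaningful and preserved by I/O round-trips.
    twin_map
        ``speaker -> twin_pair`` (``None`` for unpaired speakers). Filled in
        from the token table when omitted.
    """

    tokens: pd.DataFrame
    twin_map: dict[str, str | None] = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [c for c in COLUMNS if c not in self.tokens.columns]
        if missing:
            raise CorpusFormatError(f"missing required column(s): {', '.join(missing)}")
        self.tokens = self.tokens.loc[:, list(COLUMNS)].reset_index(drop=True)
        if not self.twin_map:
            pairs = self.tokens.drop_duplicates("speaker").set_index("speaker")["twin_pair"]
            self.twin_map = {
                s: (None if pd.isna(p) or p == "" else str(p)) for s, p in pairs.items()
            }
        self.validate()

    # -- basic views -------------------------------------------------------
    @property
    def speakers(self) -> tuple[str, ...]:
        return tuple(sorted(self.twin_map))

    @property
    def n_tokens(self) -> int:
        return len(self.tokens)

    def __len__(self) -> int:
        return len(self.tokens)

    def with_tokens(self, tokens: pd.DataFrame) -> "Corpus":
        """A corpus with the same speaker/twin metadata but a new token table."""
        return Corpus(tokens.reset_index(drop=True), dict(self.twin_map))

    # -- validation --------------------------------------------------------
    def validate(self) -> None:
        df = self.tokens
        unknown_speakers = set(df["speaker"]) - set(self.twin_map)
        if unknown_speakers:
            raise CorpusValidationError(
                f"token speakers absent from twin_map: {sorted(unknown_speakers)}"
            )
        bad_style = ~df["style"].isin(STYLES)
        if bad_style.any():
            raise CorpusValidationError(
                f"invalid style labels at rows {_fmt_rows(df.index[bad_style].values)}"
            )
        bad_vowel = ~df["vowel"].isin(VOWELS)
        if bad_vowel.any():
            raise CorpusValidationError(
                f"invalid vowel labels at rows {_fmt_rows(df.index[bad_vowel].values)}"
            )
        num = df[["duration_s", *FORMANT_COLUMNS]].to_numpy(dtype=float)
        if not np.isfinite(num).all():
            bad = df.index[~np.isfinite(num).all(axis=1)].values
            raise CorpusValidationError(f"non-finite numeric fields at rows {_fmt_rows(bad)}")
        if (num[:, 0] <= 0).any():
            bad = df.index[num[:, 0] <= 0].values
            raise CorpusValidationError(f"non-positive durations at rows {_fmt_rows(bad)}")
        f = num[:, 1:]
        ordered = (f[:, 0] > 0) & (np.diff(f, axis=1) > 0).all(axis=1)
        if not ordered.all():
            bad = df.index[~ordered].values
            raise CorpusValidationError(
                f"formant ordering 0 < F1 < F2 < F3 < F4 violated at rows {_fmt_rows(bad)}"
            )
        too_high = f[:, 3] >= MAX_FORMANT_HZ
        if too_high.any():
            bad = df.index[too_high].values
            raise CorpusValidationError(
                f"F4 at/above the {MAX_FORMANT_HZ:.0f} Hz extraction ceiling "
                f"at rows {_fmt_rows(bad)}"
            )
        # each twin pair has exactly 0 or 2 members
        counts: dict[str, int] = {}
        for pair in self.twin_map.values():
            if pair is not None:
                counts[pair] = counts.get(pair, 0) + 1
        odd = {p: c for p, c in counts.items() if c != 2}
        if odd:
            raise CorpusValidationError(f"twin pairs without exactly 2 members: {odd}")


def read_corpus(path, sep: str = "\t") -> Corpus:
    """Read a token table written by :func:`write_corpus` (or the extraction script).

    Numbers must use ``.`` as the decimal separator; thousands separators are
    rejected (a comma fails numeric parsing outright, and a spurious ``.``
    thousands mark produces an out-of-range formant that fails validation).
    """
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    missing = [c for c in COLUMNS if c not in df.columns]
    if missing:
        raise CorpusFormatError(f"missing required column(s): {', '.join(missing)}")
    for col in ("duration_s", *FORMANT_COLUMNS):
        parsed = pd.to_numeric(df[col], errors="coerce")
        bad = parsed.isna().to_numpy()
        if bad.any():
            rows = df.index[bad].values
            raise CorpusFormatError(
                f"non-numeric value in column '{col}' at rows {_fmt_rows(rows)}"
            )
        df[col] = parsed.astype(float)
    df["twin_pair"] = df["twin_pair"].replace("", np.nan)
    return Corpus(df)


def write_corpus(corpus: Corpus, path) -> None:
    """Write the token table as UTF-8 TSV; formants/durations at 6 decimals."""
    df = corpus.tokens.copy()
    df["twin_pair"] = df["twin_pair"].fillna("")
    df.to_csv(path, sep="\t", index=False, float_format="%.6f")


def corpus_to_string(corpus: Corpus) -> str:
    buf = io.StringIO()
    write_corpus(corpus, buf)
    return buf.getvalue()


@dataclass
class CorpusSummary:
    """Token counts per speaker x style x vowel cell, plus the marginals."""

    cells: pd.DataFrame  # columns speaker, style, vowel, n
    by_speaker: pd.Series
    by_style: pd.Series
    by_vowel: pd.Series
    total: int


def summarize_corpus(corpus: Corpus) -> CorpusSummary:
    """Tabulate token counts in every speaker x style x vowel cell.

    The marginal sums are consistent by construction: summing the cells over
    any pair of factors recovers the single-factor marginals, and all
    marginals sum to the corpus size.
    """
    df = corpus.tokens
    cells = (
        df.groupby(["speaker", "style", "vowel"], sort=True)
        .size()
        .rename("n")
        .reset_index()
    )
    return CorpusSummary(
        cells=cells,
        by_speaker=df.groupby("speaker").size(),
        by_style=df.groupby("style").size(),
        by_vowel=df.groupby("vowel").size(),
        total=len(df),
    )
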