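"""Synthetic vowel-formant corpora with known ground truth.

The generator emulates the statistical skeleton of a twin-study corpus of
male Brazilian Portuguese speakers: 20 speakers organised as 10 identical
twin pairs, two speaking styles (spontaneous telephone *dialogue* and an
*interview* with an unfamiliar experimenter), the seven oral monophthongs
with their naturally imbalanced frequencies, and imbalanced per-speaker
token counts.

Each token's formant vector (F1..F4, Hz) is

    vowel mean + speaker offset + speaker-specific style offset + token noise

with every component Gaussian. Speaker offsets are shared across vowels
(they stand in for vocal-tract anatomy, e.g. tract length); twin siblings'
offsets are correlated with coefficient ``twin_similarity``. Style offsets
are drawn per speaker *and* style, so the style effect is speaker-dependent
rather than a global shift — mirroring the observation that different
speakers move their vowel spaces in different directions between styles.
Tokens violating the physical ordering F1 < F2 < F3 < F4 (or the 5 kHz
extraction ceiling) are redrawn, a slight truncation of the Gaussian model.

Default vowel means are calibrated so that, in the dialogue style, per-vowel
F1 means span ~331-586 Hz, F2 means ~1074-2027 Hz, F3 ~2368-2655 Hz and F4
~3387-3570 Hz, i.e. large linguistic structure in the lower formants and
compressed, speaker-dominated structure in the upper ones. Default vowel
probabilities follow the observed token distribution
a:i:u:E:e:o:O = 5995:2910:1838:1684:1479:1063:973.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import yaml

from .corpus import Corpus, FORMANT_COLUMNS, MAX_FORMANT_HZ, STYLES, VOWELS

__all__ = [
    "SynthConfig",
    "GroundTruth",
    "generate_corpus",
    "recover_variance_components",
    "EstimationError",
]


class EstimationError(ValueError):
    """Not enough data to estimate variance components."""


DEFAULT_VOWEL_MEANS: dict[str, tuple[float, float, float, float]] = {
    "i": (331.0, 2027.0, 2655.0, 3570.0),
    "e": (412.0, 1905.0, 2604.0, 3532.0),
    "E": (520.0, 1762.0, 2541.0, 3491.0),
    "a": (586.0, 1382.0, 2368.0, 3387.0),
    "O": (547.0, 1098.0, 2412.0, 3428.0),
    "o": (446.0, 1074.0, 2463.0, 3478.0),
    "u": (356.0, 1121.0, 2521.0, 3526.0),
}

_VOWEL_COUNTS = {"a": 5995, "i": 2910, "u": 1838, "E": 1684, "e": 1479, "o": 1063, "O": 973}
DEFAULT_VOWEL_PROBS: dict[str, float] = {
    v: _VOWEL_COUNTS[v] / sum(_VOWEL_COUNTS.values()) for v in VOWELS
}

#: Per-style [min, max] per-speaker token counts; the minima are the corpus'
#: post-screening per-speaker minima (382 dialogue, 202 interview).
DEFAULT_TOKEN_RANGES: dict[str, tuple[int, int]] = {
    "dialogue": (382, 560),
    "interview": (202, 450),
}

# Between-/within-speaker token sd (Hz) per formant. The between/within
# ratios put proportionally more speaker information in the upper formants
# than the lower ones and the least in F2, while vowel-category structure
# still dwarfs speaker structure in F1/F2. Absolute magnitudes are kept
# moderate — same-dialect male speakers overlap heavily per vowel, and a
# system comparing multi-token sample means should land in the realistic
# EER regime of roughly 0.05-0.2, not at ceiling.
DEFAULT_BETWEEN_SD = (20.0, 30.0, 55.0, 60.0)
DEFAULT_WITHIN_SD = (45.0, 110.0, 110.0, 120.0)
# Style offsets are well under the between-speaker sd: the two styles' vowel
# spaces overlap almost completely at the population level, yet the shift is
# large enough to degrade cross-style comparisons measurably.
DEFAULT_STYLE_SD = (8.0, 14.0, 16.0, 18.0)


@dataclass
class SynthConfig:
    """Parameters of the synthetic corpus generator.

    ``tokens_per_speaker_style`` is either a single ``(min, max)`` range used
    for both styles or a ``{style: (min, max)}`` mapping. One designated
    speaker (the first) is pinned to the range minimum in every style so the
    downsampling stage has a unique minority class.
    """

    n_speakers: int = 20
    n_twin_pairs: int = 10
    vowel_means: dict[str, tuple[float, float, float, float]] = field(
        default_factory=lambda: dict(DEFAULT_VOWEL_MEANS)
    )
    between_speaker_sd: tuple[float, ...] = DEFAULT_BETWEEN_SD
    within_speaker_sd: tuple[float, ...] = DEFAULT_WITHIN_SD
    within_speaker_cov: np.ndarray | None = None  # full 4x4 override of the diagonal model
    twin_similarity: float = 0.8
    style_shift_sd: tuple[float, ...] = DEFAULT_STYLE_SD
    vowel_probs: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_VOWEL_PROBS))
    tokens_per_speaker_style: dict[str, tuple[int, int]] | tuple[int, int] = field(
        default_factory=lambda: dict(DEFAULT_TOKEN_RANGES)
    )
    seed: int = 0

    # -- helpers -----------------------------------------------------------
    def token_range(self, style: str) -> tuple[int, int]:
        r = self.tokens_per_speaker_style
        if isinstance(r, dict):
            return tuple(r[style])
        return tuple(r)

    def validate(self) -> None:
        if self.n_speakers < 1 or self.n_twin_pairs < 0:
            raise ValueError("n_speakers must be >= 1 and n_twin_pairs >= 0")
        if 2 * self.n_twin_pairs > self.n_speakers:
            raise ValueError("need 2 * n_twin_pairs <= n_speakers")
        if not 0.0 <= self.twin_similarity <= 1.0:
            raise ValueError("twin_similarity must lie in [0, 1]")
        for name in ("between_speaker_sd", "within_speaker_sd", "style_shift_sd"):
            sd = np.asarray(getattr(self, name), dtype=float)
            if sd.shape != (4,) or (sd < 0).any():
                raise ValueError(f"{name} must be 4 nonnegative values")
        if set(self.vowel_means) != set(VOWELS):
            raise ValueError("vowel_means must cover exactly the seven vowels")
        probs = np.array([self.vowel_probs.get(v, 0.0) for v in VOWELS], dtype=float)
        if (probs < 0).any() or not np.isclose(probs.sum(), 1.0):
            raise ValueError("vowel_probs must be a probability vector over the 7 vowels")
        for style in STYLES:
            lo, hi = self.token_range(style)
            if not (0 < lo <= hi):
                raise ValueError(f"token range for {style} must satisfy 0 < min <= max")
        if self.within_speaker_cov is not None:
            c = np.asarray(self.within_speaker_cov, dtype=float)
            if c.shape != (4, 4) or not np.allclose(c, c.T):
                raise ValueError("within_speaker_cov must be a symmetric 4x4 matrix")

    @classmethod
    def from_yaml(cls, path) -> "SynthConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls(**raw)
        cfg.vowel_means = {v: tuple(m) for v, m in cfg.vowel_means.items()}
        cfg.validate()
        return cfg

    def replace(self, **kw) -> "SynthConfig":
        return replace(self, **kw)


@dataclass
class GroundTruth:
    """The latent offsets the generator drew, for parameter-recovery checks."""

    speaker_offsets: pd.DataFrame  # index: speaker, columns: f1_hz..f4_hz
    style_offsets: pd.DataFrame  # index: (speaker, style), columns: f1_hz..f4_hz


def _speaker_ids(config: SynthConfig) -> tuple[list[str], dict[str, str | None]]:
    speakers: list[str] = []
    twin_map: dict[str, str | None] = {}
    for k in range(config.n_twin_pairs):
        pair = chr(ord("A") + k) if config.n_twin_pairs <= 26 else f"P{k + 1:02d}"
        for sib in ("1", "2"):
            sid = f"{pair}{sib}"
            speakers.append(sid)
            twin_map[sid] = pair
    for j in range(config.n_speakers - 2 * config.n_twin_pairs):
        sid = f"S{j + 1:02d}"
        speakers.append(sid)
        twin_map[sid] = None
    return speakers, twin_map


def generate_corpus(
    config: SynthConfig | None = None, seed: int | None = None
) -> tuple[Corpus, GroundTruth]:
    """Draw one synthetic corpus; identical seeds give bit-identical output.

    Returns the corpus together with the latent per-speaker and per-style
    offsets actually drawn (the ground truth).
    """
    config = config or SynthConfig()
    config.validate()
    rng = np.random.default_rng(config.seed if seed is None else seed)

    speakers, twin_map = _speaker_ids(config)
    sigma_b = np.asarray(config.between_speaker_sd, dtype=float)
    sigma_w = np.asarray(config.within_speaker_sd, dtype=float)
    sigma_s = np.asarray(config.style_shift_sd, dtype=float)
    rho = config.twin_similarity

    # speaker offsets: one draw per twin pair with correlated siblings
    offsets: dict[str, np.ndarray] = {}
    for k in range(config.n_twin_pairs):
        z1 = rng.standard_normal(4)
        z2 = rho * z1 + np.sqrt(1.0 - rho**2) * rng.standard_normal(4)
        offsets[speakers[2 * k]] = sigma_b * z1
        offsets[speakers[2 * k + 1]] = sigma_b * z2
    for sid in speakers[2 * config.n_twin_pairs :]:
        offsets[sid] = sigma_b * rng.standard_normal(4)

    style_off = {
        (sid, style): sigma_s * rng.standard_normal(4)
        for sid in speakers
        for style in STYLES
    }

    mean_matrix = np.array([config.vowel_means[v] for v in VOWELS], dtype=float)
    probs = np.array([config.vowel_probs.get(v, 0.0) for v in VOWELS], dtype=float)
    probs = probs / probs.sum()

    if config.within_speaker_cov is not None:
        chol_w = np.linalg.cholesky(np.asarray(config.within_speaker_cov, dtype=float))
    else:
        chol_w = None

    frames: list[pd.DataFrame] = []
    for sid in speakers:
        for style in STYLES:
            lo, hi = config.token_range(style)
            if sid == speakers[0]:
                n = lo  # pinned minority speaker
            elif hi > lo:
                n = int(rng.integers(lo + 1, hi + 1))
            else:
                n = lo
            vowel_idx = rng.choice(len(VOWELS), size=n, p=probs)
            base = mean_matrix[vowel_idx] + offsets[sid] + style_off[(sid, style)]

            def draw_noise(size: int) -> np.ndarray:
                if chol_w is not None:
                    return rng.standard_normal((size, 4)) @ chol_w.T
                return sigma_w * rng.standard_normal((size, 4))

            values = base + draw_noise(n)
            for _ in range(1000):
                ok = (
                    (values[:, 0] > 0)
                    & (np.diff(values, axis=1) > 0).all(axis=1)
                    & (values[:, 3] < MAX_FORMANT_HZ)
                )
                if ok.all():
                    break
                bad = ~ok
                values[bad] = base[bad] + draw_noise(int(bad.sum()))
            else:  # pragma: no cover - would need absurd configs
                raise RuntimeError("rejection sampling failed to order formants")

            frames.append(
                pd.DataFrame(
                    {
                        "speaker": sid,
                        "twin_pair": twin_map[sid] if twin_map[sid] is not None else np.nan,
                        "style": style,
                        "vowel": [VOWELS[i] for i in vowel_idx],
                        "duration_s": rng.lognormal(mean=np.log(0.08), sigma=0.4, size=n),
                        **{c: values[:, j] for j, c in enumerate(FORMANT_COLUMNS)},
                    }
                )
            )

    tokens = pd.concat(frames, ignore_index=True)
    truth = GroundTruth(
        speaker_offsets=pd.DataFrame(
            {c: [offsets[s][j] for s in speakers] for j, c in enumerate(FORMANT_COLUMNS)},
            index=pd.Index(speakers, name="speaker"),
        ),
        style_offsets=pd.DataFrame(
            {
                c: [style_off[(s, st)][j] for s in speakers for st in STYLES]
                for j, c in enumerate(FORMANT_COLUMNS)
            },
            index=pd.MultiIndex.from_tuples(
                [(s, st) for s in speakers for st in STYLES], names=["speaker", "style"]
            ),
        ),
    )
    return Corpus(tokens, twin_map), truth


def recover_variance_components(corpus: Corpus) -> pd.DataFrame:
    """Method-of-moments between/within speaker sd estimates per formant.

    Within each vowel x style cell, a one-way ANOVA decomposition over
    speakers gives MS_within and MS_between; the between-speaker variance is
    ``(MSB - MSW) / n0`` with ``n0`` the usual unbalanced-design effective
    group size. The within component pools cell sums of squares over their
    degrees of freedom; the between component pools per-cell moments
    weighted by cell token counts, so precise high-frequency-vowel cells
    dominate noisy rare-vowel cells (with one cell both reduce to the plain
    per-cell estimates). Negative between-variance moments are clamped at
    zero.
    """
    df = corpus.tokens
    if df["speaker"].nunique() < 5:
        raise EstimationError("need at least 5 speakers")
    if df.groupby("speaker").size().min() < 10:
        raise EstimationError("need at least 10 tokens per speaker")

    rows = []
    for col in FORMANT_COLUMNS:
        ssw = 0.0
        dfw = 0.0
        sb_num = 0.0
        sb_den = 0.0
        for _, cell in df.groupby(["vowel", "style"], sort=True):
            sizes = cell.groupby("speaker").size()
            sizes = sizes[sizes >= 2]
            if len(sizes) < 2:
                continue
            sub = cell[cell["speaker"].isin(sizes.index)]
            x = sub[col].to_numpy(dtype=float)
            g = sub["speaker"].to_numpy()
            means = sub.groupby("speaker")[col].mean()
            n_tot = len(x)
            m = len(sizes)
            centered = x - means[g].to_numpy()
            cell_ssw = float(centered @ centered)
            grand = x.mean()
            msb = float((sizes * (means - grand) ** 2).sum()) / (m - 1)
            msw_cell = cell_ssw / (n_tot - m)
            n0 = (n_tot - float((sizes**2).sum()) / n_tot) / (m - 1)
            ssw += cell_ssw
            dfw += n_tot - m
            sb_num += max((msb - msw_cell) / n0, 0.0) * n_tot
            sb_den += n_tot
        if dfw == 0 or sb_den == 0:
            raise EstimationError("no cell with enough speakers and tokens")
        rows.append(
            {
                "formant": col,
                "sd_between": float(np.sqrt(sb_num / sb_den)),
                "sd_within": float(np.sqrt(ssw / dfw)),
            }
        )
    return pd.DataFrame(rows).set_index("formant")
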