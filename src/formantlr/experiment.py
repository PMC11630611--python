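"""Full experimental designs: matched-style, mismatched-style and per-vowel runs.

One *cell* of the design is a (condition, formant subset, speaker group,
downsampling iteration) combination. Within a cell the protocol is
leave-pair-out cross-validation:

1. every unordered pair (a, b) of the group is tested in turn;
2. the remaining group members form the fold's background population; MVKD
   models (one per vowel) are fitted on background tokens only;
3. development scores for calibration/fusion are all same-speaker and
   different-speaker comparisons computable among background members alone
   (C(8, 2) = 28 Hd + 8 Hs at group size 10);
4. the fused/calibrated LR is emitted for the tested pair and for each
   tested member's own same-speaker comparison under the same fold's model —
   test speakers' tokens never enter background fitting or development
   scoring.

Cell scores then yield one Cllr and one EER per cell, aggregated across
cells by :func:`formantlr.metrics.aggregate`.

Conditions
----------
* ``matched-dialogue`` / ``matched-interview``: tokens of one style are
  downsampled to the minority count and each speaker's tokens are split 50/50
  at random into reference and questioned halves; same-speaker trials
  compare a speaker's two halves.
* ``mismatched``: counts are equalised per speaker and style; interview
  tokens are the reference material and dialogue tokens the questioned
  material, for different- and same-speaker trials alike (no within-style
  split).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull, QhullError

from .corpus import Corpus, FORMANT_COLUMNS, VOWELS
from .fusion import ScoreFusion
from .grouping import SpeakerGroup, enumerate_pairs, make_groups
from .metrics import cllr as _cllr
from .metrics import eer as _eer
from .mvkd import MVKDScorer, SingularCovarianceError
from .preprocess import downsample, downsample_mismatched

__all__ = [
    "ExperimentConfig",
    "run_matched",
    "run_mismatched",
    "run_per_vowel",
    "vowel_space_summary",
    "parse_subset",
    "SUBSET_CHOICES",
]

CONDITIONS = ("matched-dialogue", "matched-interview", "mismatched")
_COND_CODE = {c: i + 1 for i, c in enumerate(CONDITIONS)}

SUBSET_CHOICES = ("F1", "F2", "F3", "F4", "F1+F2", "F3+F4", "F1+F3+F4", "F1+F2+F3+F4")

METRIC_COLUMNS = (
    "condition",
    "subset",
    "group_id",
    "iteration",
    "n_ss",
    "n_ds",
    "cllr",
    "eer",
)


def parse_subset(name: str) -> tuple[int, ...]:
    """Map a subset label like ``"F3+F4"`` to formant column indices (0-based)."""
    idx = []
    for part in name.split("+"):
        part = part.strip().upper()
        if part not in ("F1", "F2", "F3", "F4"):
            raise ValueError(f"unknown formant {part!r} in subset {name!r}")
        idx.append(int(part[1]) - 1)
    if len(set(idx)) != len(idx):
        raise ValueError(f"repeated formant in subset {name!r}")
    return tuple(idx)


@dataclass
class ExperimentConfig:
    """Scale and scope of a run.

    ``desk()`` builds the reduced preset used for routine testing (5 groups,
    3 downsampling repetitions); ``full_scale()`` the complete design (150
    groups, 100 repetitions), which is hours of compute.
    """

    formant_subsets: tuple[str, ...] = SUBSET_CHOICES
    conditions: tuple[str, ...] = CONDITIONS
    n_groups: int = 150
    n_reps: int = 100
    group_size: int = 10
    min_tokens: int = 3
    clamp: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.formant_subsets or not self.conditions:
            raise ValueError("formant_subsets and conditions must be nonempty")
        for s in self.formant_subsets:
            parse_subset(s)
        for c in self.conditions:
            if c not in CONDITIONS:
                raise ValueError(f"unknown condition {c!r}")

    @classmethod
    def desk(cls, **overrides) -> "ExperimentConfig":
        overrides.setdefault("n_groups", 5)
        overrides.setdefault("n_reps", 3)
        cfg = cls(**overrides)
        if cfg.n_groups > 10 or cfg.n_reps > 5:
            raise ValueError("desk preset caps n_groups at 10 and n_reps at 5")
        return cfg

    @classmethod
    def full_scale(cls, **overrides) -> "ExperimentConfig":
        return cls(**overrides)

    def replace(self, **kw) -> "ExperimentConfig":
        return replace(self, **kw)


# ---------------------------------------------------------------------------
# per-speaker prepared data


@dataclass
class _SpeakerData:
    """Downsampled material for one speaker in one condition/iteration."""

    tokens_by_vowel: dict[str, np.ndarray] = field(default_factory=dict)  # background fitting
    ref: dict[str, tuple[np.ndarray, int]] = field(default_factory=dict)  # vowel -> (mean4, n)
    quest: dict[str, tuple[np.ndarray, int]] = field(default_factory=dict)


def _vowel_matrices(df: pd.DataFrame) -> dict[str, np.ndarray]:
    return {
        v: g[list(FORMANT_COLUMNS)].to_numpy(dtype=float)
        for v, g in df.groupby("vowel", sort=True)
    }


def _mean_table(df: pd.DataFrame) -> dict[str, tuple[np.ndarray, int]]:
    return {v: (m.mean(axis=0), m.shape[0]) for v, m in _vowel_matrices(df).items()}


def _prepare_matched(ds: Corpus, rng: np.random.Generator) -> dict[str, _SpeakerData]:
    """Random 50/50 reference/questioned split of each speaker's tokens."""
    data: dict[str, _SpeakerData] = {}
    for speaker, g in ds.tokens.groupby("speaker", sort=True):
        perm = rng.permutation(len(g))
        half = len(g) // 2
        ref_df = g.iloc[np.sort(perm[:half])]
        quest_df = g.iloc[np.sort(perm[half:])]
        data[speaker] = _SpeakerData(
            tokens_by_vowel=_vowel_matrices(g),
            ref=_mean_table(ref_df),
            quest=_mean_table(quest_df),
        )
    return data


def _prepare_mismatched(ds: Corpus) -> dict[str, _SpeakerData]:
    """Interview as reference material, dialogue as questioned material."""
    data: dict[str, _SpeakerData] = {}
    for speaker, g in ds.tokens.groupby("speaker", sort=True):
        data[speaker] = _SpeakerData(
            tokens_by_vowel=_vowel_matrices(g),  # both styles pool into W
            ref=_mean_table(g[g["style"] == "interview"]),
            quest=_mean_table(g[g["style"] == "dialogue"]),
        )
    return data


# ---------------------------------------------------------------------------
# leave-pair-out cross-validation inside a group


def iter_folds(members):
    """Yield (tested pair, background members, background dev pairs) per fold."""
    members = sorted(members)
    for a, b in itertools.combinations(members, 2):
        bg = [s for s in members if s not in (a, b)]
        yield (a, b), bg, list(itertools.combinations(bg, 2))


def _crossval_cell(
    members,
    data: dict[str, _SpeakerData],
    subsets: dict[str, tuple[int, ...]],
    vowels,
    min_tokens: int,
    clamp: float,
) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Calibrated log10 LRs and labels for one group cell, per formant subset."""
    collected: dict[str, tuple[list, list]] = {name: ([], []) for name in subsets}
    for (a, b), bg, dev_pairs in iter_folds(members):
        if len(bg) < 3:
            raise ValueError("background smaller than 3 speakers; enlarge the group")
        # full 4-formant background model per vowel; subsets are sliced from it
        full_models: dict[str, MVKDScorer] = {}
        for v in vowels:
            arrays = [
                data[s].tokens_by_vowel[v]
                for s in bg
                if v in data[s].tokens_by_vowel and data[s].tokens_by_vowel[v].shape[0] >= 2
            ]
            if len(arrays) < 3:
                continue
            try:
                full_models[v] = MVKDScorer(clamp=clamp).fit(arrays)
            except SingularCovarianceError:
                continue
        if not full_models:
            continue
        vlist = sorted(full_models)

        rows = (
            [(c, d, 0) for c, d in dev_pairs]
            + [(c, c, 1) for c in bg]
            + [(a, b, 0), (a, a, 1), (b, b, 1)]
        )
        n_dev = len(dev_pairs) + len(bg)
        labels = np.array([lab for _, _, lab in rows])

        # gather the scoreable rows once per vowel (subset-independent)
        gathered: dict[str, tuple[np.ndarray, ...]] = {}
        for v in vlist:
            sel, yq, yr, nq, nr = [], [], [], [], []
            for i, (q, r, _) in enumerate(rows):
                qs = data[q].quest.get(v)
                rs = data[r].ref.get(v)
                if qs is None or rs is None or qs[1] < min_tokens or rs[1] < min_tokens:
                    continue
                sel.append(i)
                yq.append(qs[0])
                yr.append(rs[0])
                nq.append(qs[1])
                nr.append(rs[1])
            if sel:
                gathered[v] = (
                    np.array(sel),
                    np.vstack(yq),
                    np.vstack(yr),
                    np.array(nq),
                    np.array(nr),
                )

        for name, idx in subsets.items():
            X = np.full((len(rows), len(vlist)), np.nan)
            cols = list(idx)
            for j, v in enumerate(vlist):
                if v not in gathered:
                    continue
                sel, yq, yr, nq, nr = gathered[v]
                sub = full_models[v].subset_model(cols)
                X[sel, j] = sub.score_means(yq[:, cols], yr[:, cols], nq, nr)
            # vowels without any scoreable development comparison cannot be
            # fused in this fold
            cols_ok = ~np.isnan(X[:n_dev]).all(axis=0)
            if not cols_ok.any():
                continue
            Xc = X[:, cols_ok]
            dev_X, dev_y = Xc[:n_dev], labels[:n_dev]
            usable = ~np.isnan(dev_X).all(axis=1)
            if (dev_y[usable] == 1).sum() < 2 or (dev_y[usable] == 0).sum() < 2:
                warnings.warn("fold skipped: too few scoreable development comparisons")
                continue
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore", RuntimeWarning)
                    fusion = ScoreFusion().fit(dev_X[usable], dev_y[usable])
                llrs = fusion.transform(Xc[n_dev:])
            except ValueError:
                continue
            llrs = np.clip(llrs, -clamp, clamp)
            collected[name][0].extend(llrs)
            collected[name][1].extend(labels[n_dev:])
    return {
        name: (np.asarray(llr), np.asarray(lab)) for name, (llr, lab) in collected.items()
    }


# ---------------------------------------------------------------------------
# run drivers


def _experiment_groups(corpus: Corpus, config: ExperimentConfig) -> list[SpeakerGroup]:
    rng = np.random.default_rng(np.random.SeedSequence((config.seed, 0)))
    return make_groups(
        corpus.speakers, corpus.twin_map, config.n_groups, config.group_size, rng=rng
    )


def _run_conditions(
    corpus: Corpus,
    config: ExperimentConfig,
    conditions,
    vowels=VOWELS,
    vowel_label: str | None = None,
) -> pd.DataFrame:
    subsets = {name: parse_subset(name) for name in config.formant_subsets}
    groups = _experiment_groups(corpus, config)
    rows: list[dict] = []
    for condition in conditions:
        for it in range(config.n_reps):
            rng = np.random.default_rng(
                np.random.SeedSequence((config.seed, _COND_CODE[condition], it))
            )
            if condition == "mismatched":
                ds = downsample_mismatched(corpus, rng=rng)
                data = _prepare_mismatched(ds)
            else:
                style = condition.split("-", 1)[1]
                ds = downsample(corpus, style, rng=rng)
                data = _prepare_matched(ds, rng)
            for group in groups:
                cell = _crossval_cell(
                    group.members, data, subsets, vowels, config.min_tokens, config.clamp
                )
                for name, (llrs, labels) in cell.items():
                    ss = llrs[labels == 1]
                    dsc = llrs[labels == 0]
                    if len(ss) == 0 or len(dsc) == 0:
                        warnings.warn(
                            f"cell (group {group.group_id}, iter {it}, {condition}, {name}) "
                            "produced no scoreable comparisons"
                        )
                        continue
                    row = {
                        "condition": condition,
                        "subset": name,
                        "group_id": group.group_id,
                        "iteration": it,
                        "n_ss": len(ss),
                        "n_ds": len(dsc),
                        "cllr": _cllr(10.0**ss, 10.0**dsc),
                        "eer": _eer(ss, dsc),
                    }
                    if vowel_label is not None:
                        row["vowel"] = vowel_label
                    rows.append(row)
    cols = list(METRIC_COLUMNS) + (["vowel"] if vowel_label is not None else [])
    return pd.DataFrame(rows, columns=cols)


def run_matched(corpus: Corpus, config: ExperimentConfig) -> pd.DataFrame:
    """Style-matched designs (dialogue and/or interview, per ``config.conditions``)."""
    conds = [c for c in config.conditions if c.startswith("matched")]
    if not conds:
        raise ValueError("config.conditions contains no matched condition")
    return _run_conditions(corpus, config, conds)


def run_mismatched(corpus: Corpus, config: ExperimentConfig) -> pd.DataFrame:
    """Mismatched design: interview reference vs dialogue questioned material."""
    if "mismatched" not in config.conditions:
        raise ValueError("config.conditions does not include 'mismatched'")
    return _run_conditions(corpus, config, ["mismatched"])


def run_per_vowel(corpus: Corpus, config: ExperimentConfig) -> pd.DataFrame:
    """Per-vowel discriminatory power on F1+F2, without cross-vowel fusion.

    The pipeline runs separately for each vowel (fusion degenerates to plain
    calibration of that vowel's scores) in the style-matched conditions.
    """
    cfg = config.replace(formant_subsets=("F1+F2",))
    conds = [c for c in config.conditions if c.startswith("matched")]
    if not conds:
        raise ValueError("per-vowel analysis is defined for the matched conditions")
    frames = []
    present = [v for v in VOWELS if v in set(corpus.tokens["vowel"])]
    for v in present:
        res = _run_conditions(corpus, cfg, conds, vowels=(v,), vowel_label=v)
        if res.empty:
            warnings.warn(f"vowel {v!r}: insufficient tokens, omitted")
            continue
        frames.append(res)
    return pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()


# ---------------------------------------------------------------------------
# descriptive vowel-space summaries


def polygon_area(points: np.ndarray) -> float:
    """Convex-hull area (shoelace, via the hull) of 2-D points; 0 if degenerate."""
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if len(np.unique(pts, axis=0)) < 3:
        return 0.0
    try:
        return float(ConvexHull(pts).volume)  # 2-D "volume" is the area
    except QhullError:
        return 0.0  # collinear


def vowel_space_summary(corpus: Corpus):
    """Per speaker x style vowel-space polygon areas and formant-range table.

    Returns ``(areas, means, ranges)``:

    * ``areas`` — per speaker x style: number of vowel categories, convex-hull
      area (Hz^2) of the per-vowel mean (F1, F2) points (NaN when fewer than
      3 vowel categories are present);
    * ``means`` — per speaker x style x vowel mean F1..F4;
    * ``ranges`` — per style x formant: min/max/range of the cross-speaker
      per-vowel grand means, plus the percent spread
      ``(max - min) / mean(min, max) * 100``.
    """
    df = corpus.tokens
    means = (
        df.groupby(["speaker", "style", "vowel"], sort=True)[list(FORMANT_COLUMNS)]
        .mean()
        .reset_index()
    )
    area_rows = []
    for (speaker, style), g in means.groupby(["speaker", "style"], sort=True):
        pts = g[["f1_hz", "f2_hz"]].to_numpy(dtype=float)
        area = polygon_area(pts) if len(g) >= 3 else np.nan
        area_rows.append(
            {"speaker": speaker, "style": style, "n_vowels": len(g), "area_hz2": area}
        )
    areas = pd.DataFrame(area_rows)

    grand = df.groupby(["style", "vowel"], sort=True)[list(FORMANT_COLUMNS)].mean()
    range_rows = []
    for style, g in grand.groupby("style", sort=True):
        for col in FORMANT_COLUMNS:
            lo, hi = float(g[col].min()), float(g[col].max())
            range_rows.append(
                {
                    "style": style,
                    "formant": col,
                    "min_hz": lo,
                    "max_hz": hi,
                    "range_hz": hi - lo,
                    "percent_spread": 100.0 * (hi - lo) / ((hi + lo) / 2.0),
                }
            )
    ranges = pd.DataFrame(range_rows)
    return areas, means, ranges
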