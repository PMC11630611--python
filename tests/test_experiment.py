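"""Experiment orchestration: folds, accounting, determinism, descriptives."""

import warnings

import numpy as np
import pandas as pd
import pytest

import formantlr as flr
from formantlr.experiment import (
    ExperimentConfig,
    iter_folds,
    parse_subset,
    polygon_area,
    run_matched,
    run_mismatched,
    run_per_vowel,
    vowel_space_summary,
)
from formantlr.synth import SynthConfig, generate_corpus

from conftest import make_tokens


@pytest.fixture(scope="module")
def quick_corpus():
    """10 speakers / 5 twin pairs with enough tokens per vowel to score."""
    cfg = SynthConfig(
        seed=21,
        n_speakers=10,
        n_twin_pairs=5,
        tokens_per_speaker_style={"dialogue": (80, 120), "interview": (70, 110)},
    )
    corpus, _ = generate_corpus(cfg)
    return corpus


def quick_config(**overrides):
    overrides.setdefault("group_size", 5)
    overrides.setdefault("formant_subsets", ("F1+F2+F3+F4",))
    return ExperimentConfig.desk(**overrides)


def run_quiet(fn, *args):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return fn(*args)


class TestConfig:
    @pytest.mark.parametrize(
        "name,expected",
        [("F1", (0,)), ("F3+F4", (2, 3)), ("F1+F2+F3+F4", (0, 1, 2, 3))],
    )
    def test_parse_subset(self, name, expected):
        assert parse_subset(name) == expected

    def test_parse_subset_rejects_unknown_or_repeated(self):
        with pytest.raises(ValueError):
            parse_subset("F5")
        with pytest.raises(ValueError):
            parse_subset("F1+F1")

    def test_desk_preset_caps(self):
        with pytest.raises(ValueError):
            ExperimentConfig.desk(n_groups=11)
        with pytest.raises(ValueError):
            ExperimentConfig.desk(n_reps=6)
        assert ExperimentConfig.desk().n_groups == 5

    def test_full_scale_preset_defaults(self):
        cfg = ExperimentConfig.full_scale()
        assert cfg.n_groups == 150 and cfg.n_reps == 100 and cfg.group_size == 10


class TestFolds:
    def test_fold_structure_at_group_size_ten(self):
        members = [f"S{i}" for i in range(10)]
        folds = list(iter_folds(members))
        assert len(folds) == 45
        for (a, b), bg, dev_pairs in folds:
            assert len(bg) == 8 and len(dev_pairs) == 28
            assert a not in bg and b not in bg

    def test_no_test_speaker_leaks_into_development(self):
        members = [f"S{i}" for i in range(10)]
        for (a, b), bg, dev_pairs in iter_folds(members):
            dev_speakers = {s for pair in dev_pairs for s in pair}
            assert a not in dev_speakers and b not in dev_speakers
            assert dev_speakers <= set(bg)


class TestRunAccounting:
    def test_single_cell_per_style_with_unit_config(self, quick_corpus):
        cfg = quick_config(
            seed=0, n_groups=1, n_reps=1,
            conditions=("matched-dialogue", "matched-interview"),
        )
        res = run_quiet(run_matched, quick_corpus, cfg)
        assert len(res) == 2
        assert set(res["condition"]) == {"matched-dialogue", "matched-interview"}
        # 10 folds at group size 5: one Hd + two Hs trials per fold
        assert (res["n_ds"] == 10).all() and (res["n_ss"] == 20).all()

    def test_full_run_determinism(self, quick_corpus):
        cfg = quick_config(seed=4, n_groups=2, n_reps=1, conditions=("matched-dialogue",))
        a = run_quiet(run_matched, quick_corpus, cfg)
        b = run_quiet(run_matched, quick_corpus, cfg)
        pd.testing.assert_frame_equal(a, b)

    def test_provenance_columns_complete(self, quick_corpus):
        cfg = quick_config(seed=1, n_groups=2, n_reps=2, conditions=("mismatched",))
        res = run_quiet(run_mismatched, quick_corpus, cfg)
        assert set(res["group_id"]) == {0, 1} and set(res["iteration"]) == {0, 1}
        assert res["cllr"].ge(0).all()
        assert res["eer"].between(0, 1).all()

    def test_mismatched_requires_condition(self, quick_corpus):
        with pytest.raises(ValueError):
            run_mismatched(quick_corpus, quick_config(conditions=("matched-dialogue",)))

    def test_matched_requires_condition(self, quick_corpus):
        with pytest.raises(ValueError):
            run_matched(quick_corpus, quick_config(conditions=("mismatched",)))


class TestPerVowel:
    def test_cells_bounded_by_vowels_times_styles(self, quick_corpus):
        cfg = quick_config(
            seed=2, n_groups=1, n_reps=1,
            conditions=("matched-dialogue", "matched-interview"),
        )
        res = run_quiet(run_per_vowel, quick_corpus, cfg)
        cells = res.groupby(["vowel", "condition"]).size()
        assert len(cells) <= 14
        assert set(res["subset"]) == {"F1+F2"}

    def test_single_vowel_corpus_yields_single_vowel_cells(self):
        cfg_corpus = SynthConfig(
            seed=3,
            n_speakers=10,
            n_twin_pairs=5,
            vowel_probs={v: (1.0 if v == "a" else 0.0) for v in flr.corpus.VOWELS},
            tokens_per_speaker_style=(60, 80),
        )
        corpus, _ = generate_corpus(cfg_corpus)
        cfg = quick_config(seed=2, n_groups=1, n_reps=1, conditions=("matched-dialogue",))
        res = run_quiet(run_per_vowel, corpus, cfg)
        assert set(res["vowel"]) == {"a"}

    def test_fused_system_dominates_best_single_vowel(self, quick_corpus):
        # all-vowel fusion should beat (or match within epsilon) every
        # single-vowel calibration in mean Cllr
        cfg = quick_config(
            seed=2, n_groups=5, n_reps=4, formant_subsets=("F1+F2",),
            conditions=("matched-dialogue",),
        )
        fused = run_quiet(run_matched, quick_corpus, cfg)
        pervow = run_quiet(run_per_vowel, quick_corpus, cfg)
        best_single = pervow.groupby("vowel")["cllr"].mean().min()
        assert fused["cllr"].mean() <= best_single + 0.05


class TestVowelSpace:
    def test_right_triangle_area(self):
        assert polygon_area(np.array([[0, 0], [0, 1], [1, 0]])) == pytest.approx(0.5)

    def test_identical_points_area_zero(self):
        assert polygon_area(np.array([[1.0, 2.0]] * 5)) == 0.0

    def test_collinear_points_area_zero(self):
        pts = np.array([[0.0, 0.0], [1.0, 1.0], [2.0, 2.0], [3.0, 3.0]])
        assert polygon_area(pts) == 0.0

    def test_hull_area_matches_monotone_chain_shoelace_oracle(self, rng):
        def cross(o, a, b):
            return (a[0] - o[0]) * (b[1] - o[1]) - (a[1] - o[1]) * (b[0] - o[0])

        def hull_shoelace(points):
            pts = sorted(map(tuple, points))
            lower, upper = [], []
            for p in pts:
                while len(lower) >= 2 and cross(lower[-2], lower[-1], p) <= 0:
                    lower.pop()
                lower.append(p)
            for p in reversed(pts):
                while len(upper) >= 2 and cross(upper[-2], upper[-1], p) <= 0:
                    upper.pop()
                upper.append(p)
            poly = lower[:-1] + upper[:-1]
            area = 0.0
            for (x1, y1), (x2, y2) in zip(poly, poly[1:] + poly[:1]):
                area += x1 * y2 - x2 * y1
            return abs(area) / 2.0

        for _ in range(20):
            pts = rng.normal(size=(7, 2)) * [120.0, 300.0] + [450.0, 1500.0]
            assert polygon_area(pts) == pytest.approx(hull_shoelace(pts), rel=1e-9)

    def test_summary_areas_and_ranges(self, quick_corpus):
        areas, means, ranges = vowel_space_summary(quick_corpus)
        assert set(areas.columns) == {"speaker", "style", "n_vowels", "area_hz2"}
        assert (areas["area_hz2"] > 0).all()
        assert len(means) == len(
            quick_corpus.tokens.groupby(["speaker", "style", "vowel"])
        )
        dial = ranges[(ranges["style"] == "dialogue") & (ranges["formant"] == "f1_hz")]
        assert dial["range_hz"].iloc[0] == pytest.approx(
            dial["max_hz"].iloc[0] - dial["min_hz"].iloc[0]
        )

    def test_fewer_than_three_vowels_reports_missing_area(self):
        rows = []
        for vowel, f1, f2 in [("a", 600.0, 1400.0), ("i", 330.0, 2000.0)]:
            rows += [("P1", None, "dialogue", vowel, 0.08, f1, f2, 2500.0, 3400.0)] * 3
        areas, _, _ = vowel_space_summary(flr.Corpus(make_tokens(rows)))
        assert np.isnan(areas["area_hz2"].iloc[0])
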