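import io

import numpy as np
import pandas as pd
import pytest

from weightregain.errors import IntegrityError, SchemaError
from weightregain.study_corpus import (
    CSV_COLUMNS,
    build_difference_series,
    corpus_from_frame,
    filter_by_rob,
    filter_regain_eligible,
    load_corpus,
    write_corpus,
)
from weightregain.synthetic_data import CorpusParams, generate_corpus

from conftest import linear_series, make_rows


class TestLoadCorpus:
    def test_empty_file_with_header_gives_empty_corpus(self):
        buf = io.StringIO(",".join(CSV_COLUMNS) + "\n")
        corpus = load_corpus(buf)
        assert corpus.n_studies == 0 and corpus.n_arms == 0

    def test_two_study_synthetic_fixture_counts(self, tmp_path):
        df = generate_corpus(CorpusParams(n_studies=2, seed=1))
        path = tmp_path / "studies.csv"
        df.to_csv(path, index=False)
        corpus = load_corpus(path)
        assert corpus.n_studies == 2
        assert corpus.n_arms == 4  # one control + one intervention arm each

    def test_zero_n_analyzed_is_integrity_error(self):
        df = make_rows(("s1", "c", "control", 6, 6, -2.0, 3.0, 0))
        with pytest.raises(IntegrityError):
            corpus_from_frame(df)

    def test_missing_column_is_schema_error(self):
        df = make_rows(("s1", "c", "control", 6, 6, -2.0, 3.0, 50)).drop(
            columns=["mean_change_kg"]
        )
        with pytest.raises(SchemaError):
            corpus_from_frame(df)

    def test_duplicate_study_arm_time_is_integrity_error(self):
        df = make_rows(
            ("s1", "c", "control", 6, 6, -2.0, 3.0, 50),
            ("s1", "c", "control", 6, 6, -2.1, 3.0, 50),
        )
        with pytest.raises(IntegrityError):
            corpus_from_frame(df)

    def test_unparseable_numeric_row_rejected_with_warning(self):
        df = make_rows(
            ("s1", "c", "control", 6, 6, -2.0, 3.0, 50),
            ("s1", "i", "intervention", 6, 6, "oops", 3.0, 50),
        )
        with pytest.warns(UserWarning, match="unparseable"):
            corpus = corpus_from_frame(df)
        assert len(corpus.arms) == 1

    def test_round_trip_preserves_fields(self, tmp_path):
        df = generate_corpus(CorpusParams(n_studies=5, seed=11))
        path = tmp_path / "c.csv"
        df.to_csv(path, index=False)
        corpus = load_corpus(path)
        out = tmp_path / "rt.csv"
        write_corpus(corpus, out)
        back = pd.read_csv(out, dtype={"study_id": str, "arm_id": str})
        orig = pd.read_csv(path, dtype={"study_id": str, "arm_id": str})
        key = ["study_id", "arm_id", "t_months"]
        back = back.sort_values(key).reset_index(drop=True)
        orig = orig.sort_values(key).reset_index(drop=True)
        pd.testing.assert_frame_equal(back[CSV_COLUMNS], orig[CSV_COLUMNS], check_like=True)


class TestDifferenceSeries:
    def test_programme_end_difference_from_arm_means(self):
        df = make_rows(
            ("s1", "c", "control", 6, 6, -2.1, 3.3, 100),
            ("s1", "c", "control", 6, 18, -1.0, 3.3, 100),
            ("s1", "i", "intervention", 6, 6, -4.9, 3.8, 100),
            ("s1", "i", "intervention", 6, 18, -3.0, 3.8, 100),
        )
        (series,) = build_difference_series(corpus_from_frame(df))
        assert series.at_programme_end() == pytest.approx(-2.8)
        t, d, v, n = series.points[0]
        assert t == 0.0
        assert v == pytest.approx(3.8**2 / 100 + 3.3**2 / 100)
        assert n == 200

    def test_identical_arms_give_zero_difference_and_pooled_variance(self):
        df = make_rows(
            ("s1", "c", "control", 6, 6, -2.0, 3.0, 50),
            ("s1", "c", "control", 6, 18, -1.5, 3.0, 50),
            ("s1", "i", "intervention", 6, 6, -2.0, 3.0, 50),
            ("s1", "i", "intervention", 6, 18, -1.5, 3.0, 50),
        )
        (series,) = build_difference_series(corpus_from_frame(df))
        assert all(p[1] == 0.0 for p in series.points)
        assert series.points[0][2] == pytest.approx(2 * 3.0**2 / 50)

    def test_multi_arm_n_weighted_combination(self):
        df = make_rows(
            ("s1", "c", "control", 6, 6, -2.0, 3.0, 100),
            ("s1", "c", "control", 6, 18, -1.0, 3.0, 100),
            ("s1", "i1", "intervention", 6, 6, -5.0, 3.0, 100),
            ("s1", "i1", "intervention", 6, 18, -4.0, 3.0, 100),
            ("s1", "i2", "intervention", 6, 6, -3.0, 3.0, 50),
            ("s1", "i2", "intervention", 6, 18, -2.5, 3.0, 50),
        )
        (series,) = build_difference_series(corpus_from_frame(df))
        # n-weighted mean of (-5, n=100) and (-3, n=50) is -13/3
        assert series.at_programme_end() == pytest.approx(-13.0 / 3 + 2.0)

    def test_most_intensive_arm_option_keeps_largest_loss(self):
        df = make_rows(
            ("s1", "c", "control", 6, 6, -2.0, 3.0, 100),
            ("s1", "c", "control", 6, 18, -1.0, 3.0, 100),
            ("s1", "i1", "intervention", 6, 6, -5.0, 3.0, 100),
            ("s1", "i1", "intervention", 6, 18, -4.0, 3.0, 100),
            ("s1", "i2", "intervention", 6, 6, -3.0, 3.0, 50),
            ("s1", "i2", "intervention", 6, 18, -2.5, 3.0, 50),
        )
        (series,) = build_difference_series(
            corpus_from_frame(df), multi_arm="most_intensive"
        )
        assert series.at_programme_end() == pytest.approx(-3.0)

    def test_swapping_arm_roles_negates_differences(self):
        df = generate_corpus(CorpusParams(n_studies=8, seed=2))
        fwd = build_difference_series(corpus_from_frame(df))
        swapped = df.copy()
        swapped["arm_role"] = swapped["arm_role"].map(
            {"control": "intervention", "intervention": "control"}
        )
        rev = build_difference_series(corpus_from_frame(swapped))
        fmap = {s.study_id: s for s in fwd}
        for s in rev:
            np.testing.assert_allclose(s.diff, -fmap[s.study_id].diff, atol=1e-12)

    def test_no_visit_at_programme_end_excludes_study_with_warning(self):
        df = make_rows(
            ("s1", "c", "control", 6, 12, -2.0, 3.0, 50),
            ("s1", "i", "intervention", 6, 12, -4.0, 3.0, 50),
        )
        with pytest.warns(UserWarning, match="programme end"):
            assert build_difference_series(corpus_from_frame(df)) == []


class TestEligibilityFilters:
    def test_direction_and_followup_rules(self):
        losing = linear_series("keep", -0.5, 0.01, [0, 6])
        gaining = linear_series("drop_gain", +0.3, 0.01, [0, 6])
        short = linear_series("drop_short", -0.5, 0.01, [0], max_fu=11.5)
        kept = filter_regain_eligible([losing, gaining, short])
        assert [s.study_id for s in kept] == ["keep"]

    def test_idempotent(self):
        series = [linear_series(f"s{i}", -2.0 - i, 0.02, [0, 6, 12]) for i in range(4)]
        once = filter_regain_eligible(series)
        assert filter_regain_eligible(once) == once

    def test_rob_filter_counts_and_edge_cases(self):
        df = generate_corpus(CorpusParams(n_studies=40, seed=3))
        corpus = corpus_from_frame(df)
        counts = {
            lvl: sum(m.rob_overall == lvl for m in corpus.studies.values())
            for lvl in ("low", "unclear", "high")
        }
        kept = filter_by_rob(corpus, exclude={"high"})
        assert kept.n_studies == counts["low"] + counts["unclear"]
        assert filter_by_rob(kept, exclude={"high"}).n_studies == kept.n_studies
        assert filter_by_rob(corpus, exclude={"low", "unclear", "high"}).n_studies == 0
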