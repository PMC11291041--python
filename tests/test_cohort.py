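import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from survpipe.cohort import (
    ColumnSchema,
    SurvivalDataset,
    encode,
    fit_encoding,
    read_cohort,
    schema_from_dicts,
    shuffle_covariates,
    validate_schema,
    write_cohort,
)

from conftest import make_dataset, make_schema


def _write_csv(tmp_path, text):
    p = tmp_path / "cohort.csv"
    p.write_text(text)
    return str(p)


class TestSchema:
    def test_exactly_one_duration_and_event(self):
        with pytest.raises(ValueError, match="duration"):
            validate_schema([ColumnSchema("event", "event")])
        with pytest.raises(ValueError, match="event"):
            validate_schema([ColumnSchema("t", "duration", units="m")])

    def test_categorical_requires_levels(self):
        with pytest.raises(ValueError, match="levels"):
            ColumnSchema("g", "categorical")

    def test_duplicate_levels_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            ColumnSchema("g", "categorical", levels=("a", "a"))

    def test_from_dicts(self):
        schema = schema_from_dicts([
            {"name": "duration", "kind": "duration", "units": "months"},
            {"name": "event", "kind": "event"},
            {"name": "g", "kind": "categorical", "levels": ["a", "b"]},
        ])
        assert schema[2].levels == ("a", "b")


class TestReadCohort:
    def test_missing_outcome_rows_dropped(self, tmp_path, simple_schema, caplog):
        path = _write_csv(tmp_path,
            "duration,event,age,sex\n"
            "10,1,50,F\n,1,60,M\n5,1,70,F\n12,0,55,M\n8,1,65,F\n")
        with caplog.at_level("INFO"):
            ds = read_cohort(path, simple_schema)
        assert ds.n == 4
        assert "dropped 1 rows" in caplog.text

    def test_complete_file_has_empty_mask(self, tmp_path, simple_schema):
        path = _write_csv(tmp_path,
            "duration,event,age,sex\n10,1,50,F\n5,0,60,M\n")
        ds = read_cohort(path, simple_schema)
        assert not ds.missing_mask.to_numpy().any()

    def test_mask_marks_exactly_the_empty_cells(self, tmp_path):
        # "slope" empty in rows 2 and 5 of 6
        schema = make_schema(ColumnSchema("slope", "continuous"))
        path = _write_csv(tmp_path,
            "duration,event,slope\n"
            "10,1,0.5\n11,1,\n12,1,0.7\n13,0,0.8\n14,1,NA\n15,1,1.0\n")
        ds = read_cohort(path, schema)
        assert ds.n == 6
        assert list(ds.missing_mask["slope"]) == [False, True, False, False, True, False]

    def test_nonpositive_duration_rejected_rowwise(self, tmp_path, simple_schema):
        path = _write_csv(tmp_path,
            "duration,event,age,sex\n10,1,50,F\n-3,1,60,M\n0,1,70,F\n")
        ds = read_cohort(path, simple_schema)
        assert ds.n == 1

    def test_unknown_level_rejected_rowwise(self, tmp_path, simple_schema):
        path = _write_csv(tmp_path,
            "duration,event,age,sex\n10,1,50,F\n5,1,60,X\n")
        ds = read_cohort(path, simple_schema)
        assert ds.n == 1

    def test_missing_header_column_raises(self, tmp_path, simple_schema):
        path = _write_csv(tmp_path, "duration,event,age\n10,1,50\n")
        with pytest.raises(ValueError, match="sex"):
            read_cohort(path, simple_schema)

    def test_round_trip_identity(self, tmp_path, simple_dataset):
        path = str(tmp_path / "out.csv")
        write_cohort(simple_dataset, path)
        back = read_cohort(path, simple_dataset.schema)
        pd.testing.assert_frame_equal(back.values, simple_dataset.values)
        np.testing.assert_allclose(back.durations, simple_dataset.durations)
        np.testing.assert_allclose(back.events, simple_dataset.events)


class TestEncode:
    def test_population_sd_standardization(self):
        ds = make_dataset(
            pd.DataFrame({"x": [1.0, 2.0, 3.0]}),
            durations=[1, 2, 3], events=[1, 1, 1],
            covariates=[ColumnSchema("x", "continuous")],
        )
        dm = encode(ds)
        np.testing.assert_allclose(dm.matrix[:, 0], [-1.224744871, 0.0, 1.224744871])

    def test_one_hot_sums_to_one(self, simple_dataset):
        dm = encode(simple_dataset)
        sex_cols = [i for i, p in enumerate(dm.provenance) if p.source == "sex"]
        assert len(sex_cols) == 2
        np.testing.assert_allclose(dm.matrix[:, sex_cols].sum(axis=1), 1.0)

    def test_training_stats_reused_for_validation(self):
        cov = [ColumnSchema("x", "continuous")]
        train = make_dataset(pd.DataFrame({"x": [1.0, 2.0, 3.0]}),
                             [1, 2, 3], [1, 1, 1], cov)
        stats = encode(train).provenance
        mu, sigma = stats[0].mu, stats[0].sigma
        val = make_dataset(pd.DataFrame({"x": [5.0]}), [4], [1], cov)
        dm = encode(val, fit_stats=stats)
        np.testing.assert_allclose(dm.matrix[0, 0], (5.0 - mu) / sigma)
        # frozen stats unchanged by the validation transform
        assert (stats[0].mu, stats[0].sigma) == (mu, sigma)

    def test_known_training_stats_example(self):
        # value 5 with mu=2, sigma=1 -> 3.0
        from survpipe.cohort import ColumnProvenance
        cov = [ColumnSchema("x", "continuous")]
        val = make_dataset(pd.DataFrame({"x": [5.0]}), [4], [1], cov)
        dm = encode(val, fit_stats=[ColumnProvenance("x", "continuous", mu=2.0, sigma=1.0)])
        assert dm.matrix[0, 0] == 3.0

    def test_zero_variance_column_raises(self):
        ds = make_dataset(pd.DataFrame({"x": [2.0, 2.0]}), [1, 2], [1, 1],
                          [ColumnSchema("x", "continuous")])
        with pytest.raises(ValueError, match="x"):
            encode(ds)

    def test_missing_values_rejected(self):
        ds = make_dataset(pd.DataFrame({"x": [1.0, np.nan]}), [1, 2], [1, 1],
                          [ColumnSchema("x", "continuous")])
        with pytest.raises(ValueError, match="impute"):
            encode(ds)


class TestShuffle:
    def test_preserves_column_multisets(self, simple_dataset):
        out = shuffle_covariates(simple_dataset, seed=0)
        for col in out.values.columns:
            assert sorted(out.values[col]) == sorted(simple_dataset.values[col])

    def test_outcome_untouched(self, simple_dataset):
        out = shuffle_covariates(simple_dataset, seed=3)
        np.testing.assert_array_equal(out.durations, simple_dataset.durations)
        np.testing.assert_array_equal(out.events, simple_dataset.events)

    @given(seed=st.integers(0, 2**31 - 1))
    def test_deterministic(self, seed):
        rng = np.random.default_rng(0)
        ds = make_dataset(
            pd.DataFrame({"x": rng.standard_normal(8)}),
            durations=rng.exponential(5, 8) + 0.1, events=np.ones(8),
            covariates=[ColumnSchema("x", "continuous")],
        )
        a = shuffle_covariates(ds, seed)
        b = shuffle_covariates(ds, seed)
        pd.testing.assert_frame_equal(a.values, b.values)

    def test_single_row_unchanged(self):
        ds = make_dataset(pd.DataFrame({"x": [1.0]}), [2], [1],
                          [ColumnSchema("x", "continuous")])
        out = shuffle_covariates(ds, seed=9)
        pd.testing.assert_frame_equal(out.values, ds.values)
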