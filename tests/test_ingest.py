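import numpy as np
import pandas as pd
import pytest

from ntfcv.ingest import (
    FilterRule,
    LayoutSpec,
    default_day_labels,
    filter_subjects,
    load_tensor,
    read_workbook,
    reshape_sheets,
    reshape_tidy,
    reshape_wide,
    save_tensor,
)
from ntfcv.tensor_model import WeightedTensor


SPEC = LayoutSpec(symptom_names=["fatigue", "fever"], day_labels=["1_1", "1_2"])


def toy_wide(missing_cell: bool = False) -> pd.DataFrame:
    """2 subjects x 2 symptoms x 2 days, values 1..8 column-major by
    (day, symptom)."""
    df = pd.DataFrame({
        "ID": ["s1", "s2"],
        "1_1fatigue": [1.0, 2.0],
        "1_1fever": [3.0, 4.0],
        "1_2fatigue": [5.0, 6.0],
        "1_2fever": [7.0, 8.0],
    })
    if missing_cell:
        df.loc[0, "1_1fever"] = np.nan
    return df


def toy_tidy() -> pd.DataFrame:
    rows = []
    wide = toy_wide()
    for i, sid in enumerate(["s1", "s2"]):
        for day in SPEC.day_labels:
            for sym in SPEC.symptom_names:
                rows.append({"ID": sid, "days": day, "symptoms": sym,
                             "value": wide.loc[i, day + sym]})
    return pd.DataFrame(rows)


def toy_sheets() -> list[pd.DataFrame]:
    wide = toy_wide()
    return [
        wide[["ID", f"{day}fatigue", f"{day}fever"]].rename(
            columns={f"{day}fatigue": "fatigue", f"{day}fever": "fever"})
        for day in SPEC.day_labels
    ]


EXPECTED = np.array([  # (subject, symptom, day)
    [[1.0, 5.0], [3.0, 7.0]],
    [[2.0, 6.0], [4.0, 8.0]],
])


class TestReshapeWide:
    def test_hand_mapped_toy_table(self):
        x = reshape_wide(toy_wide(), SPEC)
        np.testing.assert_array_equal(x.values, EXPECTED)
        assert x.weights.sum() == 8

    def test_empty_cell_becomes_weight_zero(self):
        x = reshape_wide(toy_wide(missing_cell=True), SPEC)
        assert x.weights[0, 1, 0] == 0
        assert np.isnan(x.values[0, 1, 0])
        assert x.weights.sum() == 7

    def test_singleton(self):
        spec = LayoutSpec(symptom_names=["pain"], day_labels=["1_1"])
        x = reshape_wide(pd.DataFrame({"1_1pain": [5.0]}), spec)
        assert x.shape == (1, 1, 1)
        assert x.values[0, 0, 0] == 5.0

    def test_missing_column_names_the_pair(self):
        with pytest.raises(ValueError, match="1_2.*fever"):
            reshape_wide(toy_wide().drop(columns=["1_2fever"]), SPEC)


class TestReshapeTidy:
    def test_full_table_maps_every_triple(self):
        x = reshape_tidy(toy_tidy(), SPEC)
        np.testing.assert_array_equal(x.values, EXPECTED)

    def test_deleted_row_becomes_missing_cell(self):
        table = toy_tidy()
        table = table[~((table["ID"] == "s1") & (table["days"] == "1_2")
                        & (table["symptoms"] == "fever"))]
        x = reshape_tidy(table, SPEC)
        assert x.weights[0, 1, 1] == 0
        assert x.weights.sum() == 7

    def test_empty_table_gives_all_missing(self):
        empty = toy_tidy().iloc[0:0]
        x = reshape_tidy(empty, SPEC)
        assert x.weights.sum() == 0

    def test_duplicate_triple_rejected(self):
        table = pd.concat([toy_tidy(), toy_tidy().iloc[[0]]])
        with pytest.raises(ValueError, match="duplicate"):
            reshape_tidy(table, SPEC)

    def test_unknown_day_label_rejected(self):
        table = toy_tidy()
        table.loc[0, "days"] = "9_9"
        with pytest.raises(ValueError, match="unknown day"):
            reshape_tidy(table, SPEC)


class TestReshapeSheets:
    def test_matches_wide_layout(self):
        x = reshape_sheets(toy_sheets(), SPEC)
        np.testing.assert_array_equal(x.values, EXPECTED)

    def test_single_sheet_is_one_slice(self):
        spec = LayoutSpec(symptom_names=["fatigue", "fever"], day_labels=["1_1"])
        x = reshape_sheets(toy_sheets()[:1], spec)
        assert x.shape == (2, 2, 1)
        np.testing.assert_array_equal(x.values[:, :, 0], EXPECTED[:, :, 0])

    def test_one_na_per_sheet_counts(self):
        sheets = toy_sheets()
        sheets[0] = sheets[0].copy(); sheets[0].loc[0, "fatigue"] = np.nan
        sheets[1] = sheets[1].copy(); sheets[1].loc[1, "fever"] = np.nan
        x = reshape_sheets(sheets, SPEC)
        assert (x.weights == 0).sum() == 2

    def test_sheet_count_mismatch_rejected(self):
        with pytest.raises(ValueError, match="day labels"):
            reshape_sheets(toy_sheets()[:1], SPEC)


def test_layout_equivalence_across_all_three_formats():
    """One toy dataset in wide, tidy and multi-sheet form yields
    identical tensors."""
    xs = [reshape_wide(toy_wide(), SPEC), reshape_tidy(toy_tidy(), SPEC),
          reshape_sheets(toy_sheets(), SPEC)]
    for x in xs[1:]:
        np.testing.assert_array_equal(x.values, xs[0].values)
        np.testing.assert_array_equal(x.weights, xs[0].weights)


class TestFilterSubjects:
    def make(self, missing_counts):
        """(len(missing_counts), 2, 2) tensor with given per-subject
        missing-cell counts."""
        n = len(missing_counts)
        vals = np.ones((n, 2, 2))
        w = np.ones((n, 2, 2))
        for i, m in enumerate(missing_counts):
            w[i].flat[:m] = 0
            vals[i].flat[:m] = np.nan
        return WeightedTensor(values=vals, weights=w)

    def test_strict_threshold_on_hand_counts(self):
        # thr = 0.3 * 4 = 1.2; keep iff missing < 1.2 -> counts 0 and 1
        x = self.make([0, 1, 2])
        sub, kept = filter_subjects(x, FilterRule(0.3))
        assert kept == [0, 1]
        assert sub.shape == (2, 2, 2)

    def test_fully_observed_keeps_everyone(self):
        x = self.make([0, 0, 0])
        _, kept = filter_subjects(x)
        assert kept == [0, 1, 2]

    def test_all_missing_keeps_nobody(self):
        x = WeightedTensor(values=np.full((2, 2, 2), np.nan),
                           weights=np.zeros((2, 2, 2)))
        sub, kept = filter_subjects(x, FilterRule(0.3))
        assert kept == []
        assert sub.shape == (0, 2, 2)

    def test_idempotent(self):
        x = self.make([0, 1, 2, 3])
        once, kept1 = filter_subjects(x)
        twice, kept2 = filter_subjects(once)
        np.testing.assert_array_equal(once.weights, twice.weights)
        assert kept2 == list(range(len(kept1)))


class TestNpyRoundTrip:
    def test_exact_round_trip_with_missing_cells(self, tmp_path):
        vals = np.arange(12, dtype=float).reshape(3, 2, 2)
        w = np.ones((3, 2, 2))
        for cell in [(0, 0, 0), (2, 1, 1)]:
            w[cell] = 0; vals[cell] = np.nan
        x = WeightedTensor(values=vals, weights=w)
        path = tmp_path / "t.npy"
        save_tensor(x, path)
        y = load_tensor(path)
        np.testing.assert_array_equal(x.weights, y.weights)
        np.testing.assert_array_equal(x.values[x.weights == 1],
                                      y.values[y.weights == 1])

    def test_matrix_file_rejected(self, tmp_path):
        path = tmp_path / "m.npy"
        np.save(path, np.ones((2, 2)))
        with pytest.raises(ValueError, match="3-dimensional"):
            load_tensor(path)

    def test_negative_entries_rejected(self, tmp_path):
        arr = np.ones((2, 2, 2)); arr[0, 0, 0] = -1.0
        path = tmp_path / "neg.npy"
        np.save(path, arr)
        with pytest.raises(ValueError,
                           match="The data tensor contains negative elements"):
            load_tensor(path)


class TestWorkbookReaders:
    def test_xlsx_round_trip_all_layouts(self, tmp_path):
        wide_path = tmp_path / "wide.xlsx"
        toy_wide().to_excel(wide_path, index=False)
        tidy_path = tmp_path / "tidy.xlsx"
        toy_tidy().to_excel(tidy_path, index=False)
        sheets_path = tmp_path / "sheets.xlsx"
        with pd.ExcelWriter(sheets_path) as xw:
            for day, sheet in zip(SPEC.day_labels, toy_sheets()):
                sheet.to_excel(xw, sheet_name=day, index=False)
        for layout, path in [("wide", wide_path), ("tidy", tidy_path),
                             ("sheets", sheets_path)]:
            x = read_workbook(path, layout, SPEC)
            np.testing.assert_array_equal(x.values, EXPECTED)


def test_default_day_labels_are_dose_day_pairs():
    labels = default_day_labels()
    assert labels[:2] == ["1_1", "1_2"]
    assert labels[7] == "2_1"
    assert len(labels) == 14
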