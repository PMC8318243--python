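"""Cohort I/O, marker encoding, filtering rules and min-max normalization."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings as hyp_settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

import multlearn as ml
from multlearn.core import FormatError, SchemaError


# ---------------------------------------------------------------------------
# Normalizer
# ---------------------------------------------------------------------------

class TestNormalizer:
    def test_endpoints_and_midpoint(self):
        train = pd.DataFrame({"m": [2.0, 4.0, 6.0]})
        norm = ml.fit_normalizer(train)
        out = ml.apply_normalizer(norm, train, clip=False)
        assert out["m"].tolist() == [0.0, 0.5, 1.0]

    def test_constant_marker_maps_to_zero(self):
        train = pd.DataFrame({"m": [3.0, 3.0, 3.0]})
        norm = ml.fit_normalizer(train)
        out = ml.apply_normalizer(norm, train, clip=False)
        assert (out["m"] == 0.0).all()
        # even out-of-range values of a constant marker stay 0 under clipping
        probe = pd.DataFrame({"m": [99.0]})
        assert ml.apply_normalizer(norm, probe, clip=True)["m"].iloc[0] == 0.0

    def test_validation_clipping(self):
        norm = ml.fit_normalizer(pd.DataFrame({"m": [0.0, 10.0]}))
        val = pd.DataFrame({"m": [-5.0, 15.0, 5.0]})
        out = ml.apply_normalizer(norm, val, clip=True)
        assert out["m"].tolist() == [0.0, 1.0, 0.5]

    def test_train_reapplication_spans_unit_interval(self, rng):
        train = pd.DataFrame(rng.normal(size=(30, 4)), columns=list("abcd"))
        norm = ml.fit_normalizer(train)
        out = ml.apply_normalizer(norm, train, clip=False)
        assert np.allclose(out.min(), 0.0) and np.allclose(out.max(), 1.0)

    def test_matches_direct_formula_on_random_matrices(self, rng):
        for _ in range(100):
            X = pd.DataFrame(rng.normal(size=(8, 3)), columns=list("xyz"))
            norm = ml.fit_normalizer(X)
            out = ml.apply_normalizer(norm, X, clip=False)
            expected = (X - X.min()) / (X.max() - X.min())
            pd.testing.assert_frame_equal(out, expected)

    def test_unseen_marker_rejected(self):
        norm = ml.fit_normalizer(pd.DataFrame({"m": [1.0, 2.0]}))
        with pytest.raises(ml.ContractError):
            ml.apply_normalizer(norm, pd.DataFrame({"other": [1.0]}), clip=True)

    @hyp_settings(max_examples=50, deadline=None, derandomize=True)
    @given(train=arrays(float, (5, 2), elements=st.floats(-100, 100)),
           val=arrays(float, (4, 2), elements=st.floats(-1000, 1000)))
    def test_clipped_output_always_in_unit_interval(self, train, val):
        cols = ["a", "b"]
        norm = ml.fit_normalizer(pd.DataFrame(train, columns=cols))
        out = ml.apply_normalizer(norm, pd.DataFrame(val, columns=cols), clip=True)
        assert ((out >= 0.0) & (out <= 1.0)).all().all()


# ---------------------------------------------------------------------------
# Encoding
# ---------------------------------------------------------------------------

class TestEncodeMarkers:
    schema = {
        "race": {"type": "nominal", "levels": ["A", "B"]},
        "stage": {"type": "ordinal", "levels": ["I", "II", "III"]},
        "age": {"type": "numeric"},
    }

    def test_nominal_one_hot(self):
        raw = pd.DataFrame({"race": ["A", "B"]})
        out = ml.encode_markers(raw, {"race": self.schema["race"]})
        assert out.loc[0].tolist() == [1.0, 0.0]
        assert out.loc[1].tolist() == [0.0, 1.0]
        assert list(out.columns) == ["race=A", "race=B"]

    def test_ordinal_sequential_from_one(self):
        raw = pd.DataFrame({"stage": ["I", "II", "III"]})
        out = ml.encode_markers(raw, {"stage": self.schema["stage"]})
        assert out["stage"].tolist() == [1.0, 2.0, 3.0]

    def test_missing_values_become_zero(self):
        raw = pd.DataFrame({"age": [50.0, np.nan], "race": ["A", None],
                            "stage": ["II", None]})
        out = ml.encode_markers(raw, self.schema)
        assert out.loc[1].tolist() == [0.0] * len(out.columns)

    def test_impute_false_preserves_missingness(self):
        raw = pd.DataFrame({"age": [50.0, np.nan]})
        out = ml.encode_markers(raw, {"age": {"type": "numeric"}}, impute=False)
        assert np.isnan(out["age"].iloc[1])

    def test_undeclared_ordinal_level_rejected(self):
        raw = pd.DataFrame({"stage": ["IV"]})
        with pytest.raises(SchemaError):
            ml.encode_markers(raw, {"stage": self.schema["stage"]})


# ---------------------------------------------------------------------------
# Filtering
# ---------------------------------------------------------------------------

def _toy_cohort(n=30, treatments=("T1",), missing_col=None, missing_n=0,
                drop_response=0):
    ids = [f"P{i:03d}" for i in range(n)]
    rng = np.random.default_rng(0)
    clinical = pd.DataFrame({"c1": rng.normal(size=n), "c2": rng.normal(size=n)},
                            index=ids)
    if missing_col:
        clinical.loc[ids[:missing_n], missing_col] = np.nan
    expr = pd.DataFrame({"g1": rng.random(n), "g2": rng.random(n)}, index=ids)
    treat = pd.Series([treatments[i % len(treatments)] for i in range(n)], index=ids)
    resp = pd.Series(["CR"] * n, index=ids, dtype=object)
    if drop_response:
        resp.iloc[:drop_response] = np.nan
    return ml.Cohort(clinical=clinical, expression=expr, treatment=treat,
                     response=resp)


class TestFilterCohort:
    def test_small_treatment_removed(self):
        # 21 patients on T1, 9 on T2 -> T2 patients dropped
        ids = [f"P{i:03d}" for i in range(30)]
        cohort = _toy_cohort(30)
        cohort.treatment.iloc[:9] = "T2"
        out, log = ml.filter_cohort(cohort, min_treatment_n=10)
        assert out.n_patients == 21
        assert set(out.treatment) == {"T1"}
        assert (log["entity"] == "treatment:T2").any()

    def test_marker_above_missing_threshold_removed(self):
        cohort = _toy_cohort(100, missing_col="c1", missing_n=11)
        out, log = ml.filter_cohort(cohort, max_missing_frac=0.10)
        assert "c1" not in out.clinical.columns
        assert "c2" in out.clinical.columns

    def test_marker_at_threshold_kept_and_imputed(self):
        cohort = _toy_cohort(100, missing_col="c1", missing_n=10)
        out, _ = ml.filter_cohort(cohort, max_missing_frac=0.10)
        assert "c1" in out.clinical.columns
        assert not out.clinical.isna().any().any()

    def test_missing_response_dropped(self):
        cohort = _toy_cohort(30, drop_response=5)
        out, log = ml.filter_cohort(cohort)
        assert out.n_patients == 25

    def test_clean_cohort_unchanged(self):
        cohort = _toy_cohort(30)
        out, log = ml.filter_cohort(cohort)
        assert out.n_patients == 30
        assert len(log) == 0
        pd.testing.assert_frame_equal(out.clinical, cohort.clinical)

    def test_idempotent(self, small_cohort):
        cohort, _ = small_cohort
        once, _ = ml.filter_cohort(cohort)
        twice, log2 = ml.filter_cohort(once)
        assert len(log2) == 0
        pd.testing.assert_frame_equal(once.clinical, twice.clinical)
        pd.testing.assert_frame_equal(once.expression, twice.expression)

    def test_empty_cohort_error(self):
        cohort = _toy_cohort(9)  # single treatment below the minimum
        with pytest.raises(ml.DataError):
            ml.filter_cohort(cohort, min_treatment_n=10)


# ---------------------------------------------------------------------------
# Loading
# ---------------------------------------------------------------------------

class TestLoadCohort:
    def _write(self, tmp_path, name, df):
        path = tmp_path / name
        df.to_csv(path, sep="\t", index=False)
        return path

    def test_inner_join_on_shared_ids(self, tmp_path):
        c = self._write(tmp_path, "clinical.tsv", pd.DataFrame(
            {"patient_id": [f"A{i}" for i in range(5)], "c1": range(5)}))
        e = self._write(tmp_path, "expr.tsv", pd.DataFrame(
            {"patient_id": ["A0"] + [f"B{i}" for i in range(4)], "g1": range(5)}))
        t = self._write(tmp_path, "treat.tsv", pd.DataFrame(
            {"patient_id": ["A0"] + [f"C{i}" for i in range(4)],
             "treatment": ["T"] * 5}))
        r = self._write(tmp_path, "resp.tsv", pd.DataFrame(
            {"patient_id": ["A0"] + [f"D{i}" for i in range(4)],
             "response": ["CR"] * 5}))
        cohort = ml.load_cohort(c, e, t, r)
        assert cohort.patient_ids == ["A0"]

    def test_round_trip(self, tmp_path, small_cohort):
        cohort, _ = small_cohort
        cohort.write(tmp_path / "cohort")
        back = ml.load_cohort(tmp_path / "cohort" / "clinical.tsv",
                              tmp_path / "cohort" / "expression.tsv",
                              tmp_path / "cohort" / "treatment.tsv",
                              tmp_path / "cohort" / "response.tsv",
                              tmp_path / "cohort" / "survival.tsv")
        assert back.patient_ids == cohort.patient_ids
        np.testing.assert_allclose(back.expression.to_numpy(),
                                   cohort.expression.to_numpy())
        np.testing.assert_allclose(back.clinical.to_numpy(),
                                   cohort.clinical.to_numpy())
        assert (back.treatment == cohort.treatment).all()
        assert (back.response == cohort.response.astype(str)).all()

    def test_non_numeric_cell_named_in_error(self, tmp_path):
        c = self._write(tmp_path, "c.tsv", pd.DataFrame(
            {"patient_id": ["A"], "c1": [1.0]}))
        e = self._write(tmp_path, "e.tsv", pd.DataFrame(
            {"patient_id": ["A"], "g1": ["oops"]}))
        t = self._write(tmp_path, "t.tsv", pd.DataFrame(
            {"patient_id": ["A"], "treatment": ["T"]}))
        r = self._write(tmp_path, "r.tsv", pd.DataFrame(
            {"patient_id": ["A"], "response": ["CR"]}))
        with pytest.raises(FormatError, match="oops.*'A'.*'g1'"):
            ml.load_cohort(c, e, t, r)

    def test_missing_id_column(self, tmp_path):
        bad = self._write(tmp_path, "c.tsv", pd.DataFrame({"c1": [1.0]}))
        with pytest.raises(FormatError, match="patient_id"):
            ml.load_cohort(bad, bad, bad, bad)

    def test_zero_overlap_is_empty_join_error(self, tmp_path):
        c = self._write(tmp_path, "c.tsv", pd.DataFrame(
            {"patient_id": ["A"], "c1": [1.0]}))
        e = self._write(tmp_path, "e.tsv", pd.DataFrame(
            {"patient_id": ["B"], "g1": [1.0]}))
        t = self._write(tmp_path, "t.tsv", pd.DataFrame(
            {"patient_id": ["A"], "treatment": ["T"]}))
        r = self._write(tmp_path, "r.tsv", pd.DataFrame(
            {"patient_id": ["A"], "response": ["CR"]}))
        with pytest.raises(ml.DataError, match="empty join"):
            ml.load_cohort(c, e, t, r)
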