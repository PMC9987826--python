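import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from trophocc.data_model import (
    SNAG_CATEGORY_VALUES,
    BeetleSurvey,
    DetectionRecord,
    Fire,
    StudyDesign,
    SurveyDataset,
    ValidationError,
    build_model_inputs,
    read_dataset,
    snag_index,
    standardize_columns,
    write_dataset,
)
from trophocc.synthetic_data import GeneratorConfig, make_table1_design, simulate_dataset

CATS = list(SNAG_CATEGORY_VALUES)  # ordered low -> high


class TestSnagIndex:
    @pytest.mark.parametrize(
        "cats, expected",
        [
            (("<=5", "<=5", "<=5"), 3.0),
            ((">100", ">100", ">100"), 303.0),
            (("6-15", "16-30", "31-50"), 53.0),
        ],
    )
    def test_category_mapping(self, cats, expected):
        assert snag_index(cats) == expected

    def test_unknown_category_rejected(self):
        with pytest.raises(ValidationError, match="unknown snag count category"):
            snag_index(("<=5", "5-10", ">100"))

    @settings(max_examples=100, deadline=None)
    @given(
        idx=st.tuples(*(st.integers(0, 5),) * 3),
        pos=st.integers(0, 2),
        bump=st.integers(1, 5),
    )
    def test_monotone_in_each_size_class(self, idx, pos, bump):
        """Raising any size-class category never decreases the index."""
        hi = list(idx)
        hi[pos] = min(5, hi[pos] + bump)
        low_val = snag_index([CATS[i] for i in idx])
        hi_val = snag_index([CATS[i] for i in hi])
        assert hi_val >= low_val


class TestRoundTrip:
    def test_simulated_dataset_round_trips(self, tmp_path):
        config = GeneratorConfig(design=make_table1_design(), seed=2)
        dataset, _ = simulate_dataset(config)
        write_dataset(dataset, tmp_path)
        back = read_dataset(
            tmp_path / "detections.csv", tmp_path / "beetle.csv",
            tmp_path / "covariates.csv", tmp_path / "design.csv",
        )
        assert back.checksum() == dataset.checksum()
        assert back.design == dataset.design
        assert back.detections == dataset.detections
        assert back.beetle == dataset.beetle
        assert set(back.covariates) == set(dataset.covariates)

    def test_minimal_three_row_fixture(self, tmp_path):
        (tmp_path / "design.csv").write_text(
            "fire_id,year_burned,n_points,survey_years,reference_year\n"
            "solo,2017,1,2018,2018\n"
        )
        (tmp_path / "detections.csv").write_text(
            "fire_id,point_id,year,interval,type,detected,censored\n"
            "solo,solo-p00,2018,1,1,0,0\n"
            "solo,solo-p00,2018,2,1,1,0\n"
            "solo,solo-p00,2018,3,1,,1\n"
        )
        (tmp_path / "beetle.csv").write_text(
            "point_id,num_trees,activity\nsolo-p00,6,17\n"
        )
        (tmp_path / "covariates.csv").write_text(
            "point_id,fire_id,elevation_m,latitude,pine_prop,"
            "snag_dbh_10_30_2018,snag_dbh_30_60_2018,snag_dbh_gt60_2018\n"
            "solo-p00,solo,1800,39.5,0.6,6-15,<=5,<=5\n"
        )
        ds = read_dataset(
            tmp_path / "detections.csv", tmp_path / "beetle.csv",
            tmp_path / "covariates.csv", tmp_path / "design.csv",
        )
        assert len(ds.design.fires) == 1
        assert len(ds.covariates) == 1
        assert len(ds.detections) == 3
        assert ds.detections[2].censored and ds.detections[2].detected is None


class TestValidation:
    def test_activity_bound_is_trees_times_eight(self):
        BeetleSurvey("ok", 6, 48)  # boundary allowed
        with pytest.raises(ValidationError, match=r"activity 49 outside \[0, 48\]"):
            BeetleSurvey("bad", 6, 49)

    def test_detection_at_unknown_point_reported(self, tiny_dataset):
        tiny_dataset.detections.append(
            DetectionRecord("east", "ghost", 2018, 1, 1, 0)
        )
        with pytest.raises(ValidationError, match="ghost"):
            tiny_dataset.validate()

    def test_uncensored_interval_after_detection_rejected(self, tiny_dataset):
        tiny_dataset.detections = [
            DetectionRecord("west", "west-p00", 2018, 1, 1, 1),
            DetectionRecord("west", "west-p00", 2018, 2, 1, 0),
        ] + [r for r in tiny_dataset.detections if r.point_id != "west-p00"]
        with pytest.raises(ValidationError, match="removal design"):
            tiny_dataset.validate()

    def test_design_requires_reference_year_everywhere(self):
        with pytest.raises(ValidationError, match="reference year"):
            StudyDesign(
                fires=(Fire("f", 2015, 4, (2016, 2017)),), reference_year=2018
            )


class TestStandardize:
    def test_two_point_column_gives_plus_minus_0707(self):
        df = pd.DataFrame({"elev": [1000.0, 2000.0], "pine": [0.0, 1.0]})
        out, scaling = standardize_columns(df, ["elev"])
        np.testing.assert_allclose(out["elev"], [-0.7071067, 0.7071067], atol=1e-6)
        assert out["pine"].tolist() == [0.0, 1.0]  # natural scale preserved
        mean, sd = scaling["elev"]
        np.testing.assert_allclose(out["elev"] * sd + mean, df["elev"])  # invertible

    def test_idempotent_on_standardized_input(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame({"x": rng.normal(size=50)})
        once, _ = standardize_columns(df, ["x"])
        twice, _ = standardize_columns(once, ["x"])
        np.testing.assert_allclose(twice["x"], once["x"], atol=1e-12)

    def test_zero_variance_column_named_in_error(self):
        df = pd.DataFrame({"snag": [5.0, 5.0, 5.0]})
        with pytest.raises(ValidationError, match="snag"):
            standardize_columns(df, ["snag"])


class TestModelInputs:
    def test_age_is_years_since_fire_at_reference(self, tiny_dataset):
        inputs = build_model_inputs(tiny_dataset, standardize=False)
        T = inputs.T
        assert T == 2
        by_id = dict(zip(inputs.point_ids, inputs.age[:, T - 1]))
        assert by_id["east-p00"] == 2  # burned 2016
        assert by_id["west-p00"] == 1  # burned 2017

    def test_snag_carried_from_nearest_surveyed_year(self, tiny_dataset):
        inputs = build_model_inputs(tiny_dataset, standardize=False)
        j = inputs.point_ids.index("east-p01")
        # east-p01 has categories for 2017 and 2018; both model years observed
        assert inputs.snag[j, 0] == snag_index(("16-30", "6-15", "<=5"))
        # west-p00 starts at the reference year only
        j = inputs.point_ids.index("west-p00")
        assert not inputs.valid[j, 0] and inputs.valid[j, 1]

    def test_censored_intervals_carry_no_counts(self, tiny_dataset):
        inputs = build_model_inputs(tiny_dataset, standardize=False)
        j = inputs.point_ids.index("east-p00")
        t2017 = 0
        # 3 passive non-detections + 1 broadcast detection; 2 censored dropped
        assert inputs.nd_p[j, t2017] == 3
        assert inputs.det_b[j, t2017] == 1
        assert inputs.nd_b[j, t2017] == 0

    def test_standardized_covariates_have_mean_zero(self, tiny_dataset):
        inputs = build_model_inputs(tiny_dataset)
        assert abs(inputs.elev.mean()) < 1e-12
        assert abs(inputs.age_s[inputs.valid].mean()) < 1e-12
        assert {"elevation", "latitude", "snag", "age"} <= set(inputs.scaling)
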