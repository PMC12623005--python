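"""Survey layout bookkeeping, detection-array assembly, and covariates."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from msom import (
    DetectionArray,
    StudyLayout,
    assemble_detection_array,
    augment_detection_array,
    correlation_screen,
    reference_layout,
    standardize_covariate,
)
from msom.data import (
    DataIntegrityError,
    SiteCovariates,
    SurveyCovariates,
    read_detections_csv,
    write_detections_csv,
)
from msom.layout import LS, PM


class TestLayout:
    def test_reference_design_arithmetic(self, ref_layout):
        """50 sites x 10 slots; 350 surveyed cells, 150 missing per slice."""
        mask = ref_layout.observed_mask()
        assert ref_layout.n_sites == 50
        assert ref_layout.n_slots == 10
        assert ref_layout.n_observed_slots == 350
        assert mask.sum() == 350
        assert (~mask).sum() == 150

    def test_plant_slot_balance(self, ref_layout):
        """200 P. muticum and 150 L. spicata surveyed slots."""
        mask = ref_layout.observed_mask()
        plant = ref_layout.plant_indicator()
        assert ((plant == PM) & mask).sum() == 200
        assert ((plant == LS) & mask).sum() == 150

    def test_single_plant_sites_use_leading_slots(self):
        lay = StudyLayout(site_classes=("pm_only", "ls_only"), replicates_per_plant=5)
        mask = lay.observed_mask()
        assert mask[:, :5].all() and not mask[:, 5:].any()
        assert lay.plant_indicator()[1, 0] == LS
        assert lay.slot_of(0, PM, 2) == 2
        assert lay.slot_of(1, LS, 2) == 2
        with pytest.raises(ValueError):
            lay.slot_of(0, LS, 0)

    def test_unsurveyed_sites_have_no_cells(self):
        lay = StudyLayout(site_classes=("unsurveyed",) * 4, replicates_per_plant=5)
        assert lay.n_observed_slots == 0
        assert not lay.observed_mask().any()

    def test_unknown_class_rejected(self):
        with pytest.raises(ValueError, match="unknown site classes"):
            StudyLayout(site_classes=("both", "neither"))


class TestStandardize:
    @pytest.mark.parametrize(
        "value, mean, sd, expected",
        [
            (32.4, 32.4, 5.0, 0.0),
            (202.0, 193.2, 8.8, 1.0),
            (-4.2, 0.0, 1.0, -4.2),
        ],
    )
    def test_examples(self, value, mean, sd, expected):
        assert standardize_covariate([value], mean, sd)[0] == pytest.approx(expected)

    def test_nonpositive_sd_rejected(self):
        with pytest.raises(ValueError, match="SD must be > 0"):
            standardize_covariate([1.0], 0.0, 0.0)
        with pytest.raises(ValueError):
            standardize_covariate([1.0], 0.0, -2.0)

    def test_missing_passes_through(self):
        out = standardize_covariate([1.0, np.nan], 1.0, 2.0)
        assert out[0] == 0.0 and np.isnan(out[1])

    @settings(deadline=None, max_examples=50)
    @given(
        st.lists(st.floats(-1e6, 1e6), min_size=1, max_size=20),
        st.floats(-100, 100),
        st.floats(0.01, 100),
    )
    def test_round_trip(self, values, mean, sd):
        z = standardize_covariate(values, mean, sd)
        back = z * sd + mean
        assert np.allclose(back, values, rtol=1e-9, atol=1e-6)


class TestAssemble:
    def test_single_detection(self):
        lay = StudyLayout(site_classes=("both",), replicates_per_plant=1)
        arr = assemble_detection_array(
            [{"site": 0, "slot": 0, "taxon": "a", "detected": 1}], lay, ["a"]
        )
        assert arr.y.tolist() == [[[1, 0]]]

    def test_empty_records_reference_layout(self, ref_layout):
        """14 observed taxa, no detections: 350 surveyed zero cells each."""
        taxa = [f"t{i}" for i in range(14)]
        arr = assemble_detection_array([], ref_layout, taxa)
        assert arr.n_taxa == 14
        assert arr.y.sum() == 0
        assert arr.mask.sum() == 350

    def test_record_at_unsurveyed_cell_rejected(self):
        lay = StudyLayout(site_classes=("pm_only",), replicates_per_plant=5)
        with pytest.raises(DataIntegrityError, match="unsurveyed cell"):
            assemble_detection_array(
                [{"site": 0, "slot": 7, "taxon": "a", "detected": 1}], lay, ["a"]
            )

    def test_duplicates_collapse_with_warning(self):
        lay = StudyLayout(site_classes=("both",), replicates_per_plant=1)
        rec = {"site": 0, "slot": 0, "taxon": "a", "detected": 1}
        with pytest.warns(UserWarning, match="duplicate"):
            arr = assemble_detection_array([rec, rec], lay, ["a"])
        assert arr.y.sum() == 1

    def test_round_trip_csv(self, detection_array, tmp_path):
        path = tmp_path / "det.csv"
        write_detections_csv(detection_array, path)
        back = read_detections_csv(path, detection_array.layout)
        assert np.array_equal(back.y, detection_array.y)
        assert back.taxa == detection_array.taxa
        assert np.array_equal(back.mask, detection_array.mask)


class TestAugment:
    def test_reference_augmentation_counts(self, ref_layout):
        arr = assemble_detection_array([], ref_layout, [f"t{i}" for i in range(14)])
        aug = augment_detection_array(arr, 35)
        assert aug.n_taxa == 49
        assert aug.n_observed_taxa == 14
        assert aug.n_augmented == 35

    def test_zero_augmentation_is_identity(self, detection_array):
        assert augment_detection_array(detection_array, 0) is detection_array

    def test_missing_pattern_propagates(self, ref_layout):
        """Augmented slices inherit the raw missing cells (e.g. 5 missing
        L. spicata slots at a P. muticum-only site)."""
        arr = assemble_detection_array([], ref_layout, ["t0"])
        aug = augment_detection_array(arr, 2)
        mask = aug.mask
        pm_only_site = 20  # sites 20-39 are pm_only in the reference layout
        assert (~mask[pm_only_site, 5:]).all()
        per_slice = [mask.sum()] * aug.n_taxa
        assert per_slice == [350, 350, 350]

    def test_augmented_slices_must_be_all_zero(self, tiny_layout):
        y = np.zeros((2, 3, 2), dtype=np.int8)
        y[1, 0, 0] = 1  # a "detection" in an augmented slice
        with pytest.raises(ValueError, match="augmented"):
            DetectionArray(y=y, layout=tiny_layout, taxa=("a", "z1"),
                           n_observed_taxa=1)


class TestCorrelationScreen:
    @staticmethod
    def _pair_with_r(rho, n=40, seed=0):
        rng = np.random.default_rng(seed)
        a = rng.standard_normal(n)
        b = rng.standard_normal(n)
        a = (a - a.mean()) / a.std()
        b = b - b.mean()
        b -= a * (a @ b) / (a @ a)  # exactly orthogonal to a
        b /= b.std()
        return a, rho * a + np.sqrt(1 - rho**2) * b

    def test_perfectly_collinear_pair_excluded(self):
        x = np.arange(10.0)
        out = correlation_screen(pd.DataFrame({"x": x, "y": 2 * x}))
        assert [(a, b) for a, b, _ in out] == [("x", "y")]
        assert out[0][2] == pytest.approx(1.0)

    def test_r_054_not_excluded(self):
        a, b = self._pair_with_r(0.54)
        out = correlation_screen(pd.DataFrame({"a": a, "b": b}))
        assert out == []

    def test_boundary_r_06_excluded(self):
        a, b = self._pair_with_r(0.6)
        out = correlation_screen(pd.DataFrame({"a": a, "b": b}))
        assert len(out) == 1 and out[0][2] == pytest.approx(0.6)

    def test_negative_correlation_uses_absolute_value(self):
        a, b = self._pair_with_r(-0.75)
        out = correlation_screen(pd.DataFrame({"a": a, "b": b}))
        assert len(out) == 1

    def test_constant_covariate_warns_not_excluded(self):
        df = pd.DataFrame({"a": np.arange(10.0), "c": np.ones(10)})
        with pytest.warns(UserWarning, match="undefined"):
            out = correlation_screen(df)
        assert out == []


class TestCovariateContainers:
    def test_site_covariates_standardized_moments(self):
        df = pd.DataFrame({"urban_dist": [100.0, 200.0, 300.0, 400.0]})
        cov = SiteCovariates.from_frame(df)
        z = cov.standardized("urban_dist")
        assert z.mean() == pytest.approx(0.0, abs=1e-12)
        assert z.std(ddof=1) == pytest.approx(1.0)

    def test_site_covariates_injected_moments(self):
        df = pd.DataFrame({"temperature": [32.4, 37.4]})
        cov = SiteCovariates.from_frame(df, moments={"temperature": (32.4, 5.0)})
        assert cov.standardized("temperature") == pytest.approx([0.0, 1.0])

    def test_survey_missing_cells_filled_with_zero(self, tiny_layout):
        lay = StudyLayout(site_classes=("pm_only",), replicates_per_plant=2)
        raw = np.array([[10.0, 14.0, np.nan, np.nan]])
        cov = SurveyCovariates.from_arrays({"start_time": raw}, lay)
        z = cov.standardized("start_time")
        assert z[0, 2] == 0.0 and z[0, 3] == 0.0
        assert np.isnan(cov.raw["start_time"][0, 2])

    def test_survey_missing_at_surveyed_cell_rejected(self):
        lay = StudyLayout(site_classes=("pm_only",), replicates_per_plant=2)
        raw = np.array([[10.0, np.nan, np.nan, np.nan]])
        with pytest.raises(DataIntegrityError, match="missing at surveyed"):
            SurveyCovariates.from_arrays({"start_time": raw}, lay)
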