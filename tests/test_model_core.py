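"""Link functions, linear predictors, and the joint density."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from msom import (
    CommunityOccupancyModel,
    DetectionArray,
    ModelSpec,
    PriorSpec,
    StudyLayout,
    inv_logit,
    logit,
)
from msom.formula import ConfigurationError, Term
from msom.model import (
    build_design,
    detection_probability,
    latent_data_log_density,
    occupancy_probability,
)


class TestInvLogit:
    @pytest.mark.parametrize(
        "x, expected",
        [(-1.37, 0.20), (0.0, 0.50), (1.84, 0.86), (-3.12, 0.04), (-3.08, 0.04)],
    )
    def test_probability_scale_pairs(self, x, expected):
        assert round(float(inv_logit(x)), 2) == expected

    @settings(deadline=None, max_examples=100)
    @given(st.floats(-30, 30), st.floats(-30, 30))
    def test_monotone_and_symmetric(self, a, b):
        lo, hi = sorted([a, b])
        assert inv_logit(lo) <= inv_logit(hi)
        assert inv_logit(-a) == pytest.approx(1.0 - inv_logit(a), abs=1e-12)

    @settings(deadline=None, max_examples=100)
    @given(st.floats(1e-6, 1 - 1e-6))
    def test_inverse_of_logit(self, p):
        assert float(inv_logit(logit(p))) == pytest.approx(p, rel=1e-9)


class TestLinearPredictors:
    def test_intercept_only_occupancy(self):
        X = np.ones((4, 1))
        psi = occupancy_probability(np.array([-3.08]), X)
        assert np.allclose(psi, inv_logit(-3.08))
        assert round(float(psi[0]), 2) == 0.04

    def test_single_covariate(self):
        X = np.column_stack([np.ones(1), np.ones(1)])
        psi = occupancy_probability(np.array([0.0, 1.0]), X)
        assert float(psi[0]) == pytest.approx(0.7311, abs=1e-4)

    def test_all_zero_params_give_half(self):
        X = np.column_stack([np.ones(5), np.linspace(-2, 2, 5)])
        psi = occupancy_probability(np.zeros(2), X)
        assert np.allclose(psi, 0.5)

    def test_plant_shift(self):
        """Detection on the second host plant adds the plant coefficient."""
        X = np.array([[1.0, 1.0]])  # intercept, plant = L. spicata
        p = detection_probability(np.array([-1.0, 2.94]), X)
        assert float(p[0]) == pytest.approx(inv_logit(1.94), abs=1e-9)
        assert float(p[0]) == pytest.approx(0.8744, abs=1e-4)

    def test_interaction_vanishes_at_covariate_mean(self):
        # columns: intercept, plant, time, plant x time
        lp, f, bt, bi = -0.7, 0.9, 0.4, -0.3
        coefs = np.array([lp, f, bt, bi])
        at_zero = detection_probability(coefs, np.array([[1.0, 1.0, 0.0, 0.0]]))
        assert float(at_zero[0]) == pytest.approx(float(inv_logit(lp + f)))
        t = 1.7
        at_t = detection_probability(coefs, np.array([[1.0, 1.0, t, t]]))
        assert float(at_t[0]) == pytest.approx(float(inv_logit(lp + f + (bt + bi) * t)))

    def test_no_coefficients_means_constant_detection(self):
        X = np.column_stack([np.ones(6), np.r_[np.zeros(3), np.ones(3)],
                             np.linspace(-1, 1, 6)])
        p = detection_probability(np.array([0.3, 0.0, 0.0]), X)
        assert np.allclose(p, p[0])

    def test_missing_covariate_raises_configuration_error(self, detection_array):
        with pytest.raises(ConfigurationError, match="not supplied"):
            build_design(
                detection_array,
                ModelSpec(detection=(Term(("plant",)), Term(("light",)))),
            )


class TestJointDensity:
    def test_hand_summed_single_cell(self):
        """One taxon/site/slot, Omega = psi = p = 0.5, all indicators 1."""
        y = np.array([[1]], dtype=np.int8)
        ld = latent_data_log_density(
            y_cells=y,
            cell_site=np.array([0]),
            w=np.array([1]),
            z=np.array([[1]]),
            omega=0.5,
            psi=np.array([[0.5]]),
            p_cells=np.array([[0.5]]),
        )
        assert ld == pytest.approx(3 * np.log(0.5))
        assert ld == pytest.approx(-2.0794, abs=1e-4)

    def test_detection_without_occupancy_impossible(self):
        ld = latent_data_log_density(
            y_cells=np.array([[1]], dtype=np.int8),
            cell_site=np.array([0]),
            w=np.array([1]),
            z=np.array([[0]]),
            omega=0.5,
            psi=np.array([[0.5]]),
            p_cells=np.array([[0.5]]),
        )
        assert ld == -np.inf

    def test_occupancy_without_membership_impossible(self):
        ld = latent_data_log_density(
            y_cells=np.array([[0]], dtype=np.int8),
            cell_site=np.array([0]),
            w=np.array([0]),
            z=np.array([[1]]),
            omega=0.5,
            psi=np.array([[0.5]]),
            p_cells=np.array([[0.5]]),
        )
        assert ld == -np.inf

    def test_one_more_detection_changes_density_by_log_odds(self):
        """Flipping y 0 -> 1 at an occupied cell adds log p - log(1 - p)."""
        rng = np.random.default_rng(1)
        M, J, C = 2, 3, 6
        cell_site = np.repeat(np.arange(J), 2)
        y0 = np.zeros((M, C), dtype=np.int8)
        z = np.ones((M, J), dtype=np.int8)
        w = np.ones(M, dtype=np.int8)
        psi = rng.uniform(0.2, 0.8, (M, J))
        p = rng.uniform(0.2, 0.8, (M, C))
        y1 = y0.copy()
        y1[1, 4] = 1
        base = latent_data_log_density(y0, cell_site, w, z, 0.4, psi, p)
        bumped = latent_data_log_density(y1, cell_site, w, z, 0.4, psi, p)
        assert bumped - base == pytest.approx(
            np.log(p[1, 4]) - np.log(1 - p[1, 4])
        )

    def test_missing_cells_contribute_nothing(self, tiny_layout):
        """The joint density only sums over observed cells, so two arrays
        differing only in masked-cell fill values have equal density."""
        lay = StudyLayout(site_classes=("pm_only",), replicates_per_plant=1)
        y = np.zeros((1, 1, 2), dtype=np.int8)
        det = DetectionArray(y=y, layout=lay, taxa=("a",), n_observed_taxa=1)
        model = CommunityOccupancyModel(det, spec=ModelSpec(detection=()))
        assert model.design.n_cells == 1  # the masked slot never enters

    def test_full_joint_with_priors_is_finite_and_reproducible(self, detection_array):
        model = CommunityOccupancyModel(
            detection_array, spec=ModelSpec(detection=()), priors=PriorSpec()
        )
        hyper = {
            "mu_occ": np.array([0.2]),
            "sd_occ": np.array([1.0]),
            "mu_det": np.array([-0.5]),
            "sd_det": np.array([1.5]),
        }
        args = dict(
            w=np.array([1, 1]),
            z=np.array([[1, 0, 1], [0, 1, 0]]),
            occ_coefs=np.array([[0.3], [-0.2]]),
            det_coefs=np.array([[-0.1], [0.4]]),
            omega=0.6,
            hyper=hyper,
        )
        ld = model.joint_log_density(**args)
        assert np.isfinite(ld)
        assert ld == model.joint_log_density(**args)
        with pytest.raises(ValueError, match="non-finite"):
            model.joint_log_density(
                **{**args, "det_coefs": np.array([[np.nan], [0.4]])}
            )
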