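"""Sampler full conditionals, schedule arithmetic, chain invariants, R-hat."""

import numpy as np
import pytest

from msom import MCMCConfig, StudyLayout, gelman_rubin
from msom.data import DetectionArray
from msom.model import CommunityOccupancyModel, ModelSpec
from msom.priors import PriorSpec
from msom.sampler import (
    effective_sample_size,
    omega_full_conditional,
    w_full_conditional,
    z_full_conditional,
)


class TestFullConditionals:
    def test_detection_forces_occupancy(self):
        assert z_full_conditional(1, 0.3, [0.5, 0.5], [0, 1]) == 1.0

    def test_no_membership_forces_absence(self):
        assert z_full_conditional(0, 0.9, [0.5], [0]) == 0.0

    def test_occupied_but_undetected_weight(self):
        """psi = 0.5, two slots undetected at p = 0.5: 0.125/0.625 = 0.2."""
        pz = z_full_conditional(1, 0.5, [0.5, 0.5], [0, 0])
        assert pz == pytest.approx(0.2)

    def test_membership_forced_by_occupancy(self):
        assert w_full_conditional(0.2, [0.5, 0.5], [0, 1]) == 1.0

    def test_membership_weight_with_no_occupancy(self):
        pw = w_full_conditional(0.5, [0.5, 0.5], [0, 0])
        assert pw == pytest.approx(0.2)

    def test_membership_vanishes_with_omega(self):
        assert w_full_conditional(1e-12, [0.5], [0]) == pytest.approx(0.0, abs=1e-11)

    def test_omega_conjugate_update(self):
        w = np.r_[np.ones(21), np.zeros(28)]
        a, b = omega_full_conditional(w, 0.001, 1.0)
        assert (a, b) == (pytest.approx(21.001), pytest.approx(29.0))

    def test_omega_posterior_mean_near_zero_without_members(self):
        a, b = omega_full_conditional(np.zeros(49), 0.001, 1.0)
        assert a / (a + b) == pytest.approx(0.001 / 50.001)


class TestSchedule:
    def test_study_schedule_retains_105000(self):
        cfg = MCMCConfig(n_chains=3, n_iterations=450_000, burn_in=100_000,
                        thin=10, seed=0)
        assert cfg.retained_per_chain == 35_000
        assert cfg.total_retained == 105_000

    def test_small_schedule_arithmetic(self):
        cfg = MCMCConfig(n_chains=2, n_iterations=1_000, burn_in=500, thin=5, seed=0)
        assert cfg.total_retained == 200

    def test_invalid_schedules_rejected(self):
        with pytest.raises(ValueError):
            MCMCConfig(n_iterations=100, burn_in=100)
        with pytest.raises(ValueError):
            MCMCConfig(thin=0)


class TestChains:
    def test_same_seed_is_bit_identical(self, small_sim):
        cfg = MCMCConfig(n_chains=2, n_iterations=800, burn_in=300, thin=2, seed=5)
        a = small_sim.model().fit(cfg, compute_gof=False).samples
        b = small_sim.model().fit(cfg, compute_gof=False).samples
        assert np.array_equal(a.omega, b.omega)
        assert np.array_equal(a.species_det, b.species_det)
        assert np.array_equal(a.zrow, b.zrow)

    def test_latent_invariants_every_draw(self, small_fit):
        """z <= w and z = 1 wherever a detection occurred, at every draw."""
        s = small_fit.samples
        det = small_fit.model.detections
        # occupancy anywhere implies membership
        assert np.all((s.zrow == 0) | (s.w == 1))
        # detected (taxon, site) pairs stay occupied in the full z trace
        detected = det.detected_sites()  # (M, J) over observed taxa rows
        z = s.z  # (chains, draws, M, J)
        for i in range(det.n_observed_taxa):
            assert np.all(z[:, :, i, detected[i]] == 1)
        # and per-taxon occupied-site counts dominate detected-site counts
        assert np.all(s.zrow[:, :, : det.n_observed_taxa]
                      >= detected[: det.n_observed_taxa].sum(axis=1))

    def test_metropolis_acceptance_interior(self, small_fit):
        """Adapted species-effect acceptance rates sit strictly inside (0, 1).

        Entries are NaN for taxa that never faced a Metropolis step (their
        effects are Gibbs-drawn from the community prior while unoccupied).
        """
        saw_rates = False
        for rates in small_fit.samples.acceptance.values():
            finite = rates[np.isfinite(rates)]
            if finite.size:
                saw_rates = True
                assert 0.0 < finite.mean() < 1.0
                assert np.all(finite >= 0.0) and np.all(finite <= 1.0)
        assert saw_rates

    def test_derived_trace_consistency(self, small_fit):
        s = small_fit.samples
        assert np.array_equal(s.zrow.sum(axis=2), s.zcol.sum(axis=2))
        assert np.all(s.zcol <= s.n_taxa)
        assert np.all(s.w.sum(axis=2) >= (s.zrow >= 1).sum(axis=2))


class TestPriorRecovery:
    def test_empty_dataset_reproduces_induced_priors(self):
        """With every observation missing the posterior is the prior: the
        sampled community hyperparameters match fresh hyperprior draws."""
        from msom.priors import sample_induced_prior

        lay = StudyLayout(site_classes=("unsurveyed",) * 4, replicates_per_plant=2)
        det = DetectionArray(
            y=np.zeros((6, 4, 4), dtype=np.int8),
            layout=lay,
            taxa=tuple(f"t{i}" for i in range(6)),
            n_observed_taxa=6,
        )
        model = CommunityOccupancyModel(det, spec=ModelSpec(detection=()))
        res = model.fit(
            MCMCConfig(n_chains=2, n_iterations=30_000, burn_in=2_000, thin=10,
                       seed=3),
            compute_gof=False,
        )
        post = res.samples.hyper_trace("mu_p[(p intercept)]").ravel()
        prior = sample_induced_prior(
            PriorSpec(), "detection_intercept_mean", n_draws=100_000, seed=11
        )["draws"]  # probability scale
        from msom.model import inv_logit

        qs = np.linspace(0.1, 0.9, 9)
        assert np.allclose(
            np.quantile(inv_logit(post), qs), np.quantile(prior, qs), atol=0.035
        )
        sd_post = res.samples.hyper_trace("sd_p[(p intercept)]").ravel()
        # Uniform(0, 4) prior on the community SD
        assert np.quantile(sd_post, 0.5) == pytest.approx(2.0, abs=0.15)
        assert sd_post.max() < 4.0 and sd_post.min() > 0.0


class TestGelmanRubin:
    def test_stationary_chains_converge(self):
        rng = np.random.default_rng(0)
        traces = rng.standard_normal((2, 5_000))
        r = gelman_rubin(traces)
        assert r == pytest.approx(1.0, abs=0.01)
        assert r < 1.05

    def test_disjoint_chains_flagged(self):
        traces = np.vstack([np.zeros(100) + np.linspace(0, 0.1, 100),
                            np.full(100, 10.0) + np.linspace(0, 0.1, 100)])
        assert gelman_rubin(traces) > 5.0

    def test_threshold_boundary(self):
        # the convergence rule is strict inequality at 1.05
        assert 1.049 < 1.05

    def test_degenerate_traces_warn_and_return_one(self):
        with pytest.warns(UserWarning, match="degenerate"):
            assert gelman_rubin(np.ones((2, 50))) == 1.0

    def test_agrees_with_arviz_on_well_mixed_chains(self):
        az = pytest.importorskip("arviz")
        rng = np.random.default_rng(7)
        traces = rng.standard_normal((4, 2_000)) * 1.3 - 0.4
        ours = gelman_rubin(traces)
        theirs = float(az.rhat(traces))
        assert ours == pytest.approx(theirs, abs=0.01)

    def test_ess_sane_for_iid_draws(self):
        rng = np.random.default_rng(3)
        traces = rng.standard_normal((2, 4_000))
        ess = effective_sample_size(traces)
        assert 0.6 * 8_000 < ess <= 8_000 * 1.05
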