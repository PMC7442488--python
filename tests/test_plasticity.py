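"""Tests for the inhibitory plasticity rules and training loop."""

import numpy as np
import pytest

import pecircuit as pz
from pecircuit import protocols
from pecircuit.connectivity import PATHWAYS
from pecircuit.errors import ConfigurationError, DivergenceError
from pecircuit.plasticity import (PlasticityConfig, train, update_wDS,
                                  update_wEP, update_wPE_antihebbian,
                                  update_wPX_backprop, update_wPX_homeostatic,
                                  update_wPX_local)

from conftest import SMALL_SIZES, train_small


class TestUpdateRules:
    """Sign structure and gating of the individual rules; each rule is zero
    at its fixed point and pushes activity back toward baseline."""

    mask = np.ones((2, 2))

    def test_wEP_zero_at_target_and_presynaptically_gated(self):
        rho = np.array([1.0, 1.0])
        assert not update_wEP(rho, rho, np.array([2.0, 2.0]), self.mask, 1e-3).any()
        assert not update_wEP(rho + 1, rho, np.zeros(2), self.mask, 1e-3).any()

    def test_wEP_strengthens_inhibition_above_target(self):
        delta = update_wEP(np.array([2.0, 2.0]), np.ones(2),
                           np.array([3.0, 3.0]), self.mask, 1e-3)
        assert (delta > 0).all()

    def test_wDS_zero_at_epsilon_and_signs(self):
        eps = 0.1
        assert not update_wDS(np.full(2, eps), eps, np.ones(2), self.mask, 1e-3).any()
        assert (update_wDS(np.zeros(2), eps, np.ones(2), self.mask, 1e-3) < 0).all()
        assert (update_wDS(np.full(2, 5.0), eps, np.ones(2), self.mask, 1e-3) > 0).all()

    def test_backprop_sign_chain(self):
        post_mean = np.full((2, 2), 0.5)
        rho = np.ones(2)
        # PCs above target -> less inhibition of PV -> PV rises -> PCs fall
        delta = update_wPX_backprop(rho + 1, rho, np.ones(2), post_mean,
                                    self.mask, 1e-3)
        assert (delta < 0).all()
        assert not update_wPX_backprop(rho, rho, np.ones(2), post_mean,
                                       self.mask, 1e-3).any()
        assert not update_wPX_backprop(rho + 1, rho, np.zeros(2), post_mean,
                                       self.mask, 1e-3).any()

    def test_local_rule_signs(self):
        w_PE = np.full((2, 2), 0.7)
        rho = np.ones(2)
        assert not update_wPX_local(rho, rho, w_PE, np.ones(2), self.mask, 1e-3).any()
        delta = update_wPX_local(rho + 1, rho, w_PE, np.ones(2), self.mask, 1e-3)
        assert (delta < 0).all()

    def test_homeostatic_pair_pushes_pv_down_from_both_sides(self):
        rho_P = np.ones(2)
        r_P = rho_P + 1.0
        d_px = update_wPX_homeostatic(r_P, rho_P, np.ones(2), self.mask, 1e-3)
        d_pe = update_wPE_antihebbian(r_P, rho_P, np.ones(2), self.mask, 1e-3)
        assert (d_px > 0).all()  # more SOM/VIP inhibition onto PV
        assert (d_pe < 0).all()  # less PC->PV excitation
        assert not update_wPX_homeostatic(rho_P, rho_P, np.ones(2),
                                          self.mask, 1e-3).any()

    def test_rule_equivalence_on_dense_network(self):
        """With full PC->PV connectivity and shared deviations, the local
        rule's update is proportional to the backprop update (cosine
        similarity > 0.99): the feedback-alignment regime."""
        rng = np.random.default_rng(0)
        n_E, n_P = 20, 6
        w_PE = np.full((n_P, n_E), 1.5 / n_E)  # dense, uniform
        post_mean = np.full((n_P, n_E), 1.0 / n_E)
        mask = np.ones((n_P, 4))
        rho = np.ones(n_E)
        r_E = rho + rng.uniform(0.5, 1.5)  # homogeneous deviation
        r_pre = rng.uniform(0.5, 3.0, 4)
        d_bp = update_wPX_backprop(r_E, rho, r_pre, post_mean, mask, 1.0)
        d_loc = update_wPX_local(r_E, rho, w_PE, r_pre, mask, 1.0)
        cos = np.sum(d_bp * d_loc) / (np.linalg.norm(d_bp) * np.linalg.norm(d_loc))
        assert cos > 0.99


class TestConfig:
    def test_unknown_variant_rejected(self):
        with pytest.raises(ConfigurationError):
            PlasticityConfig(rule_variant="hebbian")

    def test_negative_rate_rejected(self):
        with pytest.raises(ConfigurationError):
            PlasticityConfig(eta_EP=-1e-6)


class TestTrain:
    def test_zero_learning_rates_leave_weights_unchanged(self, default_config):
        ws = pz.default_plastic_weights(default_config, SMALL_SIZES, rng_seed=0)
        before = {pw: ws.matrix(pw).copy() for pw in PATHWAYS}
        seq = protocols.generate_training_sequence("QT", 2, rng_seed=0)
        res = train(ws, default_config, seq,
                    PlasticityConfig(eta_EP=0, eta_DS=0, eta_PX=0, eta_PE=0))
        for pw in PATHWAYS:
            np.testing.assert_array_equal(res.weights.matrix(pw), before[pw])

    def test_dale_compliance_after_every_update(self, default_config):
        """No negative magnitude is ever persisted during training, even at
        aggressive learning rates."""
        res = train_small(default_config, n_stimuli=30,
                          config=PlasticityConfig(eta_EP=1e-4, eta_DS=1e-4,
                                                  eta_PX=1e-4))
        for pw in PATHWAYS:
            w = res.weights.matrix(pw)
            assert w.min() >= 0.0
            assert not w[~res.weights.masks[pw]].any()

    def test_analytic_weights_are_a_fixed_point(self, nonplastic_net, default_config):
        """Starting from the balanced analytic solution, the rate-error-driven
        rules (PV->PC, SOM/VIP->PV) barely move (< 1% over 40 stimuli). The
        SOM->dendrite weight is allowed a small slow decay: its rule carries
        the -epsilon term, so its own equilibrium sits at dendritic activity
        epsilon rather than exactly at the analytic point. An unbalanced
        network drifts visibly more."""
        ws, background = nonplastic_net
        balanced = ws.copy()
        balanced.plastic = frozenset({"EP", "DS", "PS", "PV"})
        seq = protocols.generate_training_sequence("QT", 40, rng_seed=5)
        cfg = PlasticityConfig(convergence_tol=0.0)
        res = train(balanced, default_config, seq, cfg, background=background)
        eff0, eff1 = ws.effective(), res.weights.effective()
        drift = {pw: abs(eff1[pw] - eff0[pw]) / eff0[pw]
                 for pw in ("EP", "DS", "PS", "PV")}
        assert max(drift[pw] for pw in ("EP", "PS", "PV")) < 0.01
        assert drift["DS"] < 0.08

        unbalanced = pz.default_plastic_weights(default_config, rng_seed=2)
        res_u = train(unbalanced, default_config, seq, cfg)
        eff_u0, eff_u1 = unbalanced.effective(), res_u.weights.effective()
        drift_u = max(abs(eff_u1[pw] - eff_u0[pw]) / eff_u0[pw]
                      for pw in ("EP", "DS", "PS", "PV"))
        assert drift_u > max(drift.values())

    def test_divergence_aborts_with_diagnostic(self, default_config):
        ws = pz.default_plastic_weights(default_config, SMALL_SIZES, rng_seed=0)
        seq = protocols.generate_training_sequence("QT", 4, rng_seed=0)
        with pytest.raises(DivergenceError, match="mean rates"):
            train(ws, default_config, seq, PlasticityConfig(rate_cap=2.0))

    def test_fixed_wpv_option_freezes_vip_to_pv(self, default_config):
        cfg = PlasticityConfig(fixed_wPV=0.3)
        res = train_small(default_config, paradigm="CT", n_stimuli=20, config=cfg)
        np.testing.assert_allclose(res.weights.w_PV.sum(axis=1), 0.3)
        assert "PV" not in res.weights.plastic

    def test_training_reduces_response_errors(self, trained_default):
        """Running mean |ΔR/R| over stimulus phases decreases over training
        (negative Spearman rank correlation across checkpoints)."""
        drr = trained_default.history["mean_abs_drr"]
        block = 50
        means = np.array([drr[i:i + block].mean()
                          for i in range(0, len(drr) - block, block)])
        ranks = np.argsort(np.argsort(means))
        rho = np.corrcoef(np.arange(len(means)), ranks)[0, 1]
        assert rho < 0
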