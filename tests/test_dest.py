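"""CPMG/R2 fitting and McConnell-equation DEST simulation and fitting."""

import numpy as np
import pandas as pd
import pytest

from synbind.dest import (
    CPMG_ELEMENT_DURATION,
    CPMGSeries,
    DESTExperimentConfig,
    TwoStateFit,
    _evolution_matrices,
    _propagate,
    _simulate_one,
    build_cpmg_schedule,
    delta_r2_pseudo,
    delta_r2_two_state,
    fit_r2_decay,
    fit_two_state,
    pseudo_first_order_check,
    residue_kinetics,
    simulate_dest,
    simulate_dest_stepwise,
)
from synbind.simulate import DestGenConfig, gen_dest_dataset

# compact acquisition grid for fast fitting tests (same +/-30 kHz span)
SMALL = DESTExperimentConfig(
    offsets_hz=np.array([-30, -18, -9, -4, -1.5, -0.5, 0.5, 1.5, 4, 9, 18, 30]) * 1e3)


class TestCPMGSchedule:
    def test_zero_elements_is_single_zero_delay(self):
        assert list(build_cpmg_schedule(0)) == [0.0]

    def test_maximum_delay_is_294_ms(self):
        delays = build_cpmg_schedule(18)
        assert delays.max() == pytest.approx(18 * CPMG_ELEMENT_DURATION)
        assert delays.max() == pytest.approx(0.29376)

    def test_scrambling_is_a_permutation(self):
        delays = build_cpmg_schedule(18, seed=7)
        assert sorted(delays) == pytest.approx(
            list(np.arange(19) * CPMG_ELEMENT_DURATION))

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            build_cpmg_schedule(19)


class TestR2Decay:
    delays = np.sort(build_cpmg_schedule(18, seed=0))

    def test_noiseless_rate_recovered(self):
        h = 1000.0 * np.exp(-5.0 * self.delays)
        r2, err = fit_r2_decay(CPMGSeries(1, self.delays, h))
        assert r2 == pytest.approx(5.0, rel=1e-6)

    def test_constant_heights_give_zero_rate(self):
        r2, _ = fit_r2_decay(CPMGSeries(1, self.delays, np.full_like(self.delays, 9.0)))
        assert r2 == pytest.approx(0.0, abs=1e-8)

    def test_monte_carlo_median_within_two_percent(self, rng):
        truth = 8.0
        base = 1000.0 * np.exp(-truth * self.delays)
        rates = []
        for _ in range(200):
            h = np.clip(base * (1 + rng.normal(0, 0.01, base.shape)), 1e-3, None)
            reps = base[9] * (1 + rng.normal(0, 0.01, 3))
            r2, _ = fit_r2_decay(CPMGSeries(1, self.delays, h,
                                            replicate_heights=reps,
                                            replicate_delay=self.delays[9]))
            rates.append(r2)
        assert np.median(rates) == pytest.approx(truth, rel=0.02)

    def test_invalid_series_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            fit_r2_decay(CPMGSeries(1, self.delays, -np.ones_like(self.delays)))
        with pytest.raises(ValueError, match="4 distinct"):
            fit_r2_decay(CPMGSeries(1, self.delays[:3], np.ones(3)))


TWO_STATE = TwoStateFit(kon_app=5.0, koff=20.0, R2_bound=2000.0)


class TestDestSimulation:
    def test_no_exchange_far_off_resonance_unattenuated(self):
        cfg = DESTExperimentConfig(reference="unsaturated")
        prof = _simulate_one(cfg, TwoStateFit(0.0, 20.0, 2000.0), 10.0, 400.0)
        assert prof[0] >= 0.98 and prof[-1] >= 0.98

    def test_on_resonance_fully_saturated(self):
        prof = _simulate_one(DESTExperimentConfig(), TWO_STATE, 10.0, 400.0)
        i0 = np.argmin(np.abs(DESTExperimentConfig().offsets_hz))
        assert abs(prof[i0]) < 0.05

    def test_matrix_exponential_matches_fixed_step_integration(self):
        # 10 us steps suffice for the two-state (7x7) system; the 3-state
        # system needs 2 us to resolve the 30 kHz off-resonance oscillation
        cfg = DESTExperimentConfig(
            offsets_hz=np.array([-30, -9, -1.5, 0, 1.5, 9, 30]) * 1e3)
        exact = _simulate_one(cfg, TWO_STATE, 5.0, 400.0)
        stepped = simulate_dest_stepwise(cfg, TWO_STATE, 5.0, 400.0, step=1e-5)
        assert np.max(np.abs(exact - stepped)) < 1e-6
        kin = residue_kinetics(2.0, 3.0, 20.0, 300.0, 5000.0)
        exact = _simulate_one(cfg, kin, 5.0, 400.0)
        stepped = simulate_dest_stepwise(cfg, kin, 5.0, 400.0, step=2e-6)
        assert np.max(np.abs(exact - stepped)) < 1e-6

    def test_profiles_symmetric_in_offset_sign(self):
        prof = _simulate_one(DESTExperimentConfig(), TWO_STATE, 5.0, 400.0)
        assert np.max(np.abs(prof - prof[::-1])) < 1e-8

    def test_total_z_conserved_without_relaxation_or_field(self):
        pops = np.array([0.8, 0.2])
        kex = np.array([[0.0, 20.0], [5.0, 0.0]])
        L = _evolution_matrices(np.array([0.0]), 0.0, 0.0,
                                np.array([0.0, 0.0]), kex, pops)
        v0 = np.zeros(7)
        v0[0] = 1.0
        v0[3], v0[6] = 0.5, 0.5  # arbitrary non-equilibrium z split
        out = _propagate(L, 0.9, v0)
        assert out[0, 3] + out[0, 6] == pytest.approx(1.0, abs=1e-10)

    def test_stationary_free_fraction_matches_rates(self):
        kon, koff = 5.0, 20.0
        pops = np.array([koff, kon]) / (kon + koff)
        kex = np.array([[0.0, koff], [kon, 0.0]])
        L = _evolution_matrices(np.array([0.0]), 0.0, 0.0,
                                np.array([0.0, 0.0]), kex, pops)
        v0 = np.zeros(7)
        v0[0], v0[3], v0[6] = 1.0, 1.0, 0.0   # start fully free
        out = _propagate(L, 50.0, v0)
        assert out[0, 3] == pytest.approx(koff / (kon + koff), abs=1e-6)

    def test_pseudo_two_state_nests_two_state_limits(self):
        cfg = DESTExperimentConfig()
        two = _simulate_one(cfg, TWO_STATE, 5.0, 400.0)
        # K3 -> infinity: all binding in the direct mode
        direct = residue_kinetics(0.0, 5.0, 20.0, 300.0, 2000.0)
        assert np.max(np.abs(two - _simulate_one(cfg, direct, 5.0, 400.0))) < 1e-9
        # K3 -> 0: all binding tethered, R2_tethered playing R2_bound
        teth = residue_kinetics(5.0, 0.0, 20.0, 2000.0, 9e4)
        assert np.max(np.abs(two - _simulate_one(cfg, teth, 5.0, 400.0))) < 1e-9

    def test_higher_saturation_power_broader_dips(self):
        cfg = DESTExperimentConfig()
        hi = _simulate_one(cfg, TWO_STATE, 5.0, 400.0)
        lo = _simulate_one(cfg, TWO_STATE, 5.0, 175.0)
        # tolerance covers coherent on-resonance nutation ringing (~1e-3)
        assert np.all(hi <= lo + 2e-3)

    def test_simulate_dest_returns_profiles_and_delta_r2(self):
        profs, dr2 = simulate_dest(DESTExperimentConfig(), TWO_STATE, 5.0, residue=3)
        assert set(profs) == {400.0, 175.0}
        assert list(profs[400.0].residues) == [3]
        assert dr2 == pytest.approx(delta_r2_two_state(5.0, 20.0, 5.0, 2000.0))

    def test_asymmetric_offsets_rejected(self):
        with pytest.raises(ValueError, match="symmetric"):
            DESTExperimentConfig(offsets_hz=np.array([-1e4, 0.0, 2e4]))


class TestDeltaR2:
    def test_slow_exchange_limit(self):
        # R2_bound >> koff: nearly every excursion is lost, delta R2 ~ kon
        assert delta_r2_two_state(5.0, 20.0, 5.0, 2e5) == pytest.approx(5.0, rel=0.01)

    def test_pseudo_reduces_to_two_state_in_single_mode_limit(self):
        a = delta_r2_two_state(5.0, 20.0, 5.0, 2000.0)
        assert delta_r2_pseudo(0.0, 5.0, 20.0, 5.0, 300.0, 2000.0) == pytest.approx(a)
        assert delta_r2_pseudo(5.0, 0.0, 20.0, 5.0, 2000.0, 9e4) == pytest.approx(a)


def small_dataset(**kw):
    kw.setdefault("experiment", SMALL)
    kw.setdefault("n_residues", 6)
    cfg = DestGenConfig(**kw)
    pair, r2, truth = gen_dest_dataset(cfg)
    free = r2["free"].values
    dr2 = r2["with_vesicles"].values - free
    return cfg, pair, free, dr2, truth


class TestTwoStateFit:
    def test_noiseless_global_recovery(self):
        cfg, pair, free, dr2, _ = small_dataset(
            seed=1, model="two_state", noise_sd=0.0,
            kon_total=5.0, koff=20.0, R2_bound=2000.0)
        fit = fit_two_state(pair, dr2, free, cfg.experiment, seed=0, n_starts=3)
        assert fit.kon_app == pytest.approx(5.0, rel=0.10)
        assert fit.koff == pytest.approx(20.0, rel=0.10)
        assert fit.R2_bound == pytest.approx(2000.0, rel=0.10)
        assert fit.p_bound == pytest.approx(0.2, rel=0.10)

    def test_zero_exchange_data_give_negligible_on_rate(self):
        cfg, pair, free, dr2, _ = small_dataset(
            seed=2, model="two_state", noise_sd=0.0, kon_total=5.0,
            n_residues=0, n_tail_residues=6)
        fit = fit_two_state(pair, dr2, free, cfg.experiment, seed=0, n_starts=2,
                            max_residue=140)
        assert fit.kon_app < 0.1

    def test_flat_profiles_rejected(self):
        cfg, pair, free, dr2, _ = small_dataset(seed=3, model="two_state")
        flat = [type(p)(ratios=p.ratios * 0 + 1.0, bandwidth_hz=p.bandwidth_hz)
                for p in pair]
        with pytest.raises(ValueError, match="flat"):
            fit_two_state(flat, dr2, free, cfg.experiment)


class TestPseudoTwoStateFit:
    def test_noiseless_round_trip_recovers_truth(self):
        from synbind.dest import fit_pseudo_two_state

        cfg, pair, free, dr2, truth = small_dataset(
            seed=4, model="pseudo_two_state", noise_sd=0.0)
        fit = fit_pseudo_two_state(pair, dr2, free, cfg.experiment, seed=0)
        assert fit.koff == pytest.approx(20.0, rel=0.01)
        assert fit.R2_direct == pytest.approx(5000.0, rel=0.01)
        assert np.allclose(fit.K3, truth["K3"], rtol=0.01)
        assert not fit.non_identifiable.any()

    def test_interconversion_refinement_declines_on_interconversion_free_data(self):
        from synbind.dest import fit_pseudo_two_state

        cfg, pair, free, dr2, _ = small_dataset(
            seed=5, model="pseudo_two_state", noise_sd=0.0, n_residues=4)
        base = fit_pseudo_two_state(pair, dr2, free, cfg.experiment, seed=0)
        ref = fit_pseudo_two_state(pair, dr2, free, cfg.experiment, seed=0,
                                   refine_interconversion=True)
        if ref.k3 > 0:  # only reported when it lowered the objective
            assert ref.k3 < ref.koff and ref.k_m3 < ref.koff
        assert ref.objective <= base.objective * 1.01 + 1e-9


class TestPseudoFirstOrder:
    residues = pd.Index(range(1, 21))

    def make_sets(self, lipid_coeff=1.0, protein_coeff=0.0, rng=None):
        base = pd.Series(np.linspace(3.0, 1.0, 20), index=self.residues)
        sets = []
        for L in (0.5e-3, 1e-3, 2e-3):
            d = base * (L / 1e-3) ** lipid_coeff
            if rng is not None:
                d = d + rng.normal(0, 0.05, 20)
            sets.append((L, 1e-4, d))
        for P in (0.5e-4, 2e-4):
            d = base * (P / 1e-4) ** protein_coeff
            if rng is not None:
                d = d + rng.normal(0, 0.05, 20)
            sets.append((1e-3, P, d))
        return sets

    def test_lipid_proportional_protein_flat_is_consistent(self, rng):
        rep = pseudo_first_order_check(self.make_sets(rng=rng), seed=0)
        assert rep.verdict == "pseudo-first-order consistent"

    def test_protein_dependence_flags_violation(self):
        rep = pseudo_first_order_check(
            self.make_sets(lipid_coeff=0.0, protein_coeff=1.0), seed=0)
        assert "violation" in rep.verdict

    def test_doubling_lipid_doubles_mean_delta_r2_within_ci(self, rng):
        sets = self.make_sets(rng=rng)
        rep = pseudo_first_order_check(sets, seed=0)
        means = {L: d.mean() for L, P, d in sets if P == 1e-4}
        assert means[2e-3] / means[1e-3] == pytest.approx(2.0, rel=0.05)
        # slope CI consistent with strict proportionality (slope = mean/conc)
        implied = means[1e-3] / 1e-3
        assert rep.lipid_ci[0] <= implied <= rep.lipid_ci[1]

    def test_insufficient_conditions_rejected(self):
        base = pd.Series(2.0, index=self.residues)
        with pytest.raises(ValueError, match="levels"):
            pseudo_first_order_check([(1e-3, 1e-4, base), (2e-3, 1e-4, base)])
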