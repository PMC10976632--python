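"""Replica ladder, bias potential, Monte Carlo propagation and exchanges."""

import numpy as np
import pytest
from scipy import stats as sstats

from wbpremd import (ModelPotential, ReplicaLadder, eval_bias_potential,
                     exchange_probability, mc_propagate,
                     quadrature_state_probabilities, run_wbp_remd)
from wbpremd.model import KB
from wbpremd.remd import OmegaSeries, replica_hamiltonian

KT_300 = KB * 300.0


class TestLadder:
    def test_default_ladder(self):
        ladder = ReplicaLadder()
        fc = ladder.force_constants
        assert len(fc) == 12
        assert fc[0] == 2.5 and fc[-1] == 0.0
        assert np.allclose(np.diff(fc), fc[1] - fc[0])  # equidistant
        assert np.all(np.diff(fc) < 0)

    def test_invalid_parameters(self):
        with pytest.raises(ValueError):
            ReplicaLadder(n_replicas=0)
        with pytest.raises(ValueError):
            ReplicaLadder(max_force_constant=-1.0)


class TestBiasPotential:
    @pytest.mark.parametrize("omegas, v, expected", [
        ((0.0, 0.0, 0.0), 1.0, 0.0),        # cis untouched
        ((180.0, 180.0, 180.0), 1.0, 6.0),  # 2V per trans residue
        ((180.0, 0.0, 0.0), 1.0, 2.0),
    ])
    def test_values(self, omegas, v, expected):
        assert eval_bias_potential(omegas, v) == pytest.approx(expected, abs=1e-12)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            eval_bias_potential((0, 0, 0), -1.0)


class TestExchangeProbability:
    def test_identical_hamiltonians(self):
        ham = lambda x: float(np.sum(np.square(x)))
        assert exchange_probability([10, 20, 30], [40, 50, 60], ham, ham) == 1.0

    def test_kt_cross_difference(self):
        # H_a(x) = 0, H_b picks up kT exactly for configuration b
        ham_a = lambda x: 0.0
        ham_b = lambda x: KT_300 if x[0] > 0 else 0.0
        p = exchange_probability([-1, 0, 0], [1, 0, 0], ham_b, ham_a)
        assert p == pytest.approx(np.exp(-1.0), abs=1e-12)

    def test_downhill_always_accepted(self):
        ham_a = lambda x: 5.0 if x[0] > 0 else 0.0
        ham_b = lambda x: 0.0
        assert exchange_probability([1, 0, 0], [-1, 0, 0], ham_a, ham_b) == 1.0


class TestMCPropagate:
    def test_deterministic_given_seed(self):
        ham = lambda x: 0.0
        a = mc_propagate([0, 0, 0], ham, 200, seed=7)
        b = mc_propagate([0, 0, 0], ham, 200, seed=7)
        np.testing.assert_array_equal(a.frames, b.frames)

    def test_flat_potential_uniform(self):
        series = mc_propagate([0, 0, 0], lambda x: 0.0, 20_000, step_sigma=60.0, seed=3)
        for axis in range(3):
            u = (series.frames[::10, axis] + 180.0) / 360.0
            assert sstats.kstest(u, "uniform").pvalue > 0.01

    def test_double_well_matches_quadrature(self):
        """Long single-chain run reproduces the Boltzmann octant weights."""
        offsets = [0.0] * 8
        offsets[1] = 0.8  # TTC offset; low barrier so the chain can cross
        model = ModelPotential.physical(0.25, offsets)
        series = mc_propagate([180, 180, 180], model.energy, 40_000,
                              step_sigma=40.0, seed=11)
        frames = series.frames[2_000:]
        probs = quadrature_state_probabilities(model, grid_points=120)
        trans = np.abs(frames) > 90.0
        idx = trans[:, 0] * 4 + trans[:, 1] * 2 + trans[:, 2]
        p_ttt_hat = np.mean(idx == 7)
        n_eff = len(frames) / 40.0  # generous autocorrelation allowance
        se = np.sqrt(probs[0] * (1 - probs[0]) / n_eff)
        assert abs(p_ttt_hat - probs[0]) < 3 * se

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            mc_propagate([0, 0, 0], lambda x: 0.0, 0)
        with pytest.raises(ValueError):
            mc_propagate([0, 0, 0], lambda x: 0.0, 10, step_sigma=0.0)


class TestRunWbpRemd:
    def test_requires_two_replicas_for_exchange(self, calibrated_model):
        with pytest.raises(ValueError):
            run_wbp_remd(calibrated_model, ReplicaLadder(n_replicas=1), 100)

    def test_deterministic_given_seed(self, calibrated_model):
        ladder = ReplicaLadder(n_replicas=4)
        s1, _ = run_wbp_remd(calibrated_model, ladder, 2_000, seed=5)
        s2, _ = run_wbp_remd(calibrated_model, ladder, 2_000, seed=5)
        np.testing.assert_array_equal(s1[0].frames, s2[0].frames)

    def test_equal_levels_accept_all_exchanges(self, calibrated_model):
        ladder = ReplicaLadder(n_replicas=3, max_force_constant=0.0)
        _, stats = run_wbp_remd(calibrated_model, ladder, 5_000, seed=2)
        assert np.all(stats.attempts > 0)
        assert np.all(stats.accepted == stats.attempts)

    def test_top_replica_crosses_freely(self, calibrated_model):
        """At zero torsion force constant cis/trans transitions are unhindered."""
        series, _ = run_wbp_remd(calibrated_model, ReplicaLadder(), 10_000,
                                 save_stride=1, seed=4)
        top = series[-1].frames
        assert series[-1].level_force_constant == 0.0
        trans = np.abs(top[:, 0]) > 90.0
        assert np.count_nonzero(trans[1:] != trans[:-1]) > 0

    def test_no_exchange_traps_replica1(self, calibrated_model):
        """The 20 kcal/mol barrier freezes replica 1 without exchanges."""
        series, _ = run_wbp_remd(calibrated_model, ReplicaLadder(), 10_000,
                                 exchange_every=0, save_stride=1, seed=4)
        r1 = series[0].frames
        trans = np.abs(r1) > 90.0
        transitions = np.count_nonzero(trans[1:] != trans[:-1])
        assert transitions == 0

    def test_replica1_biased_occupancies_match_quadrature(self, calibrated_model):
        """Replica-1 octant frequencies converge to the biased Boltzmann weights."""
        series, stats = run_wbp_remd(calibrated_model, ReplicaLadder(), 400_000,
                                     save_stride=10, seed=9)
        frames = series[0].frames[2_000:]
        probs = quadrature_state_probabilities(calibrated_model, grid_points=120,
                                               bias_force_constant=1.0)
        trans = np.abs(frames) > 90.0
        idx = trans[:, 0] * 4 + trans[:, 1] * 2 + trans[:, 2]
        order_idx = {"TTT": 7, "TTC": 6, "CTC": 2}
        n_eff = len(frames) / 400.0  # exchange-limited decorrelation
        from wbpremd.model import STATE_ORDER
        for state, bits in order_idx.items():
            p = probs[STATE_ORDER.index(state)]
            se = max(np.sqrt(p * (1 - p) / n_eff), 1e-3)
            assert abs(np.mean(idx == bits) - p) < 3 * se, state

    def test_exchange_acceptance_within_bounds(self, calibrated_model):
        _, stats = run_wbp_remd(calibrated_model, ReplicaLadder(), 20_000, seed=6)
        acc = stats.acceptance
        assert np.all((acc >= 0) & (acc <= 1))
        assert np.all(stats.attempts > 0)


class TestOmegaSeriesIO:
    def test_table_round_trip(self, tmp_path):
        frames = np.array([[0.0, 10.0, -170.0], [45.5, -90.0, 179.9]])
        series = OmegaSeries(frames=frames, replica_index=1, save_stride=10, seed=3)
        path = tmp_path / "replica1.tsv"
        series.to_table(path)
        loaded = OmegaSeries.from_table(path)
        np.testing.assert_allclose(loaded.frames, frames, atol=1e-4)
        assert loaded.save_stride == 10


def test_replica_hamiltonian_combines_terms(calibrated_model):
    ladder = ReplicaLadder()
    ham1 = replica_hamiltonian(calibrated_model, ladder, 1)
    ham12 = replica_hamiltonian(calibrated_model, ladder, 12)
    # replica 12 has no torsion barrier: at +-90 only bias+coupling remain
    at_barrier = [90.0, 90.0, 90.0]
    assert ham1(at_barrier) - ham12(at_barrier) == pytest.approx(60.0, abs=1e-9)
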