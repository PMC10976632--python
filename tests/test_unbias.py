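"""Histogramming, bias reweighting, state integration and free energies."""

import numpy as np
import pytest

from wbpremd import (Density3D, block_sem, conditional_dG, conditional_dG_table,
                     cycle_closure, free_energy_table, histogram3d, isomerization_dG,
                     pmf_1d, project_density, quadrature_density, sample_iid_density,
                     state_probabilities, state_probability, unbias_density)
from wbpremd.model import KB, STATE_ORDER, ModelPotential
from wbpremd.unbias import Marginal

KT_300 = KB * 300.0


def uniform_density(n=50):
    return Density3D(np.full((n, n, n), 1.0 / 360.0 ** 3))


# strict-interior bins of each half for 50 bins (centers at exactly +-90
# are shared boundary ordinates and left empty)
TRANS_BINS = np.r_[0:12, 38:50]
CIS_BINS = np.r_[13:37]


def two_state_density(p_ttt=0.88, p_ttc=0.12):
    """Density filling the TTT and TTC octants uniformly with given masses."""
    vals = np.zeros((50, 50, 50))
    vals[np.ix_(TRANS_BINS, TRANS_BINS, TRANS_BINS)] = p_ttt
    vals[np.ix_(TRANS_BINS, TRANS_BINS, CIS_BINS)] = p_ttc
    return Density3D(vals)


class TestHistogram3D:
    def test_single_frame_single_bin(self):
        d = histogram3d(np.array([[0.0, 0.0, 0.0]]))
        assert np.count_nonzero(d.values) == 1
        assert d.integral == pytest.approx(1.0)

    def test_uniform_samples(self, rng):
        frames = rng.uniform(-180, 180, size=(1_000_000, 3))
        d = histogram3d(frames, n_bins=10)
        expected = 1.0 / 360.0 ** 3
        counts_per_bin = 1_000_000 / 1000
        se = expected / np.sqrt(counts_per_bin)
        assert np.abs(d.values - expected).max() < 5 * se

    def test_empty_series_rejected(self):
        with pytest.raises(ValueError):
            histogram3d(np.empty((0, 3)))

    def test_iid_samples_match_quadrature(self, calibrated_model):
        series = sample_iid_density(calibrated_model, with_bias=False, n=300_000, seed=8)
        d = histogram3d(series, n_bins=50)
        ref = quadrature_density(calibrated_model, n_bins=50)
        # compare well bins (where mass concentrates) in units of sampling SE
        mask = ref > ref.max() * 1e-3
        n_expected = ref[mask] * d.bin_width ** 3 * len(series)
        se = np.sqrt(n_expected) / (d.bin_width ** 3 * len(series))
        z = (d.values[mask] - ref[mask]) / se
        assert np.abs(z).max() < 6.0


class TestUnbiasDensity:
    def test_zero_bias_identity(self, rng):
        vals = rng.random((50, 50, 50))
        d = Density3D(vals / (vals.sum() * 7.2 ** 3), biased=True)
        out = unbias_density(d, 0.0)
        np.testing.assert_array_equal(out.values, d.values)
        assert not out.biased

    def test_quadrature_round_trip(self, calibrated_model):
        """unbias(bias(density)) equals the unbiased quadrature density."""
        biased = Density3D(quadrature_density(calibrated_model, n_bins=50,
                                              bias_force_constant=1.0), biased=True)
        unbiased = unbias_density(biased, 1.0, 300.0)
        ref = quadrature_density(calibrated_model, n_bins=50)
        rel = np.abs(unbiased.values - ref) / ref.max()
        assert rel.max() < 0.01

    def test_sampled_round_trip(self, calibrated_model):
        """i.i.d. draws from the biased density unbias to the model density."""
        series = sample_iid_density(calibrated_model, with_bias=True, n=1_000_000, seed=5)
        unbiased = unbias_density(histogram3d(series), 1.0, 300.0)
        ref = quadrature_density(calibrated_model, n_bins=50)
        rel = np.abs(unbiased.values - ref) / ref.max()
        assert rel.max() < 0.05

    def test_uniform_biased_gives_boltzmann_of_bias(self):
        out = unbias_density(uniform_density(), 1.0, 300.0)
        centers = out.bin_centers
        b = 1.0 - np.cos(np.radians(centers))
        expected = np.exp((b[:, None, None] + b[None, :, None] + b[None, None, :]) / KT_300)
        expected /= expected.sum() * out.bin_width ** 3
        np.testing.assert_allclose(out.values, expected, rtol=1e-9)
        # peak at all-trans
        peak = np.unravel_index(np.argmax(out.values), out.values.shape)
        assert abs(abs(centers[peak[0]]) - 176.4) < 1e-9


class TestStateProbability:
    def test_uniform_octants(self):
        probs = state_probabilities(uniform_density())
        assert all(abs(p - 0.125) < 1e-10 for p in probs.values())

    def test_concentrated_octant(self):
        vals = np.zeros((50, 50, 50))
        vals[25, 25, 25] = 1.0  # near (0,0,0): CCC octant
        d = Density3D(vals / 7.2 ** 3)
        probs = state_probabilities(d)
        assert probs["CCC"] == pytest.approx(1.0, abs=1e-12)
        assert probs["TTT"] == pytest.approx(0.0, abs=1e-12)

    def test_unknown_label_rejected(self):
        with pytest.raises(ValueError):
            state_probability(uniform_density(), "TTX")

    def test_matches_quadrature_oracle(self, calibrated_model, calibrated_probs):
        d = Density3D(quadrature_density(calibrated_model, n_bins=50))
        probs = state_probabilities(d)
        for s in STATE_ORDER:
            assert probs[s] == pytest.approx(calibrated_probs[s], abs=5e-4)


class TestFreeEnergyTable:
    def test_two_state_closed_form(self):
        report = free_energy_table(two_state_density(0.88, 0.12), 300.0)
        assert report.free_energies["TTC"] == pytest.approx(1.188, abs=2e-3)

    def test_equal_probabilities_zero(self):
        report = free_energy_table(uniform_density(), 300.0)
        assert all(abs(g) < 1e-9 for g in report.free_energies.values())

    def test_empty_octant_warns_infinite(self):
        vals = np.zeros((50, 50, 50))
        vals[40, 40, 40] = 1.0
        with pytest.warns(RuntimeWarning):
            report = free_energy_table(Density3D(vals), 300.0)
        assert np.isinf(report.free_energies["CCC"])

    def test_recovers_reference_ttc(self, calibrated_model):
        d = Density3D(quadrature_density(calibrated_model, n_bins=50))
        report = free_energy_table(d, 300.0)
        assert report.free_energies["TTC"] == pytest.approx(1.62, abs=0.02)


class TestProjection:
    def test_projection_normalized(self, calibrated_model):
        d = Density3D(quadrature_density(calibrated_model, n_bins=50))
        for keep in ([2], [7], [2, 3], [3, 7]):
            assert project_density(d, keep).integral == pytest.approx(1.0, abs=1e-10)

    def test_product_density_factorizes(self, rng):
        a, b, c = (rng.random(50) for _ in range(3))
        prod = a[:, None, None] * b[None, :, None] * c[None, None, :]
        d = Density3D(prod / (prod.sum() * 7.2 ** 3))
        joint = project_density(d, [2, 3]).values
        m2 = project_density(d, [2]).values
        m3 = project_density(d, [3]).values
        np.testing.assert_allclose(joint, np.outer(m2, m3) * 1.0, atol=1e-10)

    def test_invalid_axes(self):
        d = uniform_density()
        with pytest.raises(ValueError):
            project_density(d, [])
        with pytest.raises(ValueError):
            project_density(d, [4])


class TestPmf1D:
    def test_flat_marginal(self):
        m = Marginal(np.full(50, 1 / 360.0), residues=(2,))
        assert np.allclose(pmf_1d(m, 300.0), 0.0)

    def test_recovers_torsion_shape(self):
        """Boltzmann marginal of the physical torsion inverts to the potential."""
        model = ModelPotential.physical(0.5)
        d = Density3D(quadrature_density(model, n_bins=50))
        m = project_density(d, [2])
        g = pmf_1d(m, 300.0)
        expected = 4 * 0.5 * (1 + np.cos(np.radians(2 * m.bin_centers - 180.0)))
        # bin averaging flattens the barrier top slightly
        assert np.abs(g - expected).max() < 0.05

    def test_scale_invariance(self):
        vals = np.linspace(1, 2, 50)
        g1 = pmf_1d(Marginal(vals, (2,)), 300.0)
        g2 = pmf_1d(Marginal(10 * vals, (2,)), 300.0)
        np.testing.assert_allclose(g1, g2, atol=1e-12)


class TestIsomerizationDG:
    def test_symmetric_marginal_zero(self):
        assert isomerization_dG(Marginal(np.full(50, 1 / 360.0), (2,)), 300.0) == pytest.approx(0.0)

    def test_two_state_closed_form(self):
        vals = np.zeros(50)
        vals[TRANS_BINS] = 0.88 / len(TRANS_BINS)
        vals[CIS_BINS] = 0.12 / len(CIS_BINS)
        dg = isomerization_dG(Marginal(vals, (2,)), 300.0)
        assert dg == pytest.approx(-1.188, abs=2e-3)

    def test_mixture_identity(self, calibrated_model, calibrated_probs):
        """The marginal dG is the Boltzmann mixture of the conditional dGs."""
        d = Density3D(quadrature_density(calibrated_model, n_bins=50))
        dg_marg = isomerization_dG(project_density(d, [2]), 300.0)
        probs = state_probabilities(d)
        p_cis = sum(p for s, p in probs.items() if s[0] == "C")
        mix = 0.0
        for s_j in "TC":
            for s_k in "TC":
                entry = conditional_dG(d, 2, s_j, s_k, 300.0)
                weight = probs["C" + s_j + s_k] / p_cis
                mix += weight * np.exp(-entry.dg_cis_to_trans / KT_300)
        assert dg_marg == pytest.approx(-KT_300 * np.log(mix), abs=1e-9)


class TestConditionalDG:
    def test_reference_pro7_cis_favoring(self, calibrated_model):
        d = Density3D(quadrature_density(calibrated_model, n_bins=50))
        entry = conditional_dG(d, 7, "C", "T", 300.0)
        assert entry.labels == ("CTT", "CTC")
        assert entry.dg_cis_to_trans == pytest.approx(0.89, abs=0.02)

    def test_independent_residues_constant_conditionals(self):
        """With additive per-residue offsets all four conditions agree."""
        per_res = {"T": 0.0, "C": 0.7}
        offsets = [sum(per_res[ch] for ch in s) for s in STATE_ORDER]
        model = ModelPotential.physical(2.5, offsets)
        d = Density3D(quadrature_density(model, n_bins=50))
        values = [conditional_dG(d, 3, s_j, s_k, 300.0).dg_cis_to_trans
                  for s_j in "TC" for s_k in "TC"]
        assert np.ptp(values) < 1e-6

    def test_reference_ddg_magnitude(self, calibrated_model):
        """Pro2 coupling to Pro7 (at Pro3 trans) spans 2.51 kcal/mol."""
        d = Density3D(quadrature_density(calibrated_model, n_bins=50))
        dg_7t = conditional_dG(d, 2, "T", "T", 300.0).dg_cis_to_trans
        dg_7c = conditional_dG(d, 2, "T", "C", 300.0).dg_cis_to_trans
        assert abs(dg_7c - dg_7t) == pytest.approx(2.51, abs=0.03)

    def test_cycle_closure_exact_on_quadrature(self, calibrated_model):
        d = Density3D(quadrature_density(calibrated_model, n_bins=50))
        assert cycle_closure(state_probabilities(d), 300.0) < 1e-8

    def test_consistency_with_state_table(self, calibrated_model):
        """Octant free-energy differences reproduce every conditional dG."""
        d = Density3D(quadrature_density(calibrated_model, n_bins=50))
        report = free_energy_table(d, 300.0)
        for entry in conditional_dG_table(d, 300.0):
            t_label, c_label = entry.labels
            expected = report.free_energies[t_label] - report.free_energies[c_label]
            assert entry.dg_cis_to_trans == pytest.approx(expected, abs=1e-9)


class TestBlockSEM:
    def test_constant_stream(self):
        assert block_sem(np.ones(1000), np.mean) == 0.0

    def test_iid_normal_scaling(self, rng):
        sems = [block_sem(rng.normal(size=5000), np.mean) for _ in range(20)]
        expected = 1.0 / np.sqrt(1000) / np.sqrt(5)
        assert expected / 2 < np.median(sems) < expected * 2

    def test_insufficient_frames_rejected(self):
        with pytest.raises(ValueError):
            block_sem(np.ones(3), np.mean, n_blocks=5)

    def test_statistic_on_contiguous_blocks(self):
        stream = np.repeat(np.arange(5), 10)  # each block constant
        assert block_sem(stream, np.std) == 0.0
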