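"""Frame weights, weighted histograms, and PMF construction."""

import numpy as np
import pytest

import amdmem as am
from amdmem.reweighting import (
    frame_weights,
    maclaurin_weights,
    pmf_2d,
    pmf_from_histogram,
    weighted_histogram,
    weighted_histogram_2d,
)


def series_from_x(x_over_kT, kT):
    dv = np.asarray(x_over_kT) * kT
    n = len(dv)
    return am.BoostRecordSeries(
        step=np.arange(1, n + 1), v_total=np.zeros(n), v_dih=np.zeros(n),
        dv_total=dv, dv_dih=np.zeros(n),
    )


class TestFrameWeights:
    def test_exponential_closed_form(self, thermo300):
        s = series_from_x([0.0, 1.0, 2.0], thermo300.kT)
        w = frame_weights(s, thermo300, method="exponential")
        np.testing.assert_allclose(
            w.weights, [1.0, 2.718281828459045, 7.38905609893065], rtol=1e-12)

    def test_maclaurin2_by_hand(self, thermo300):
        # 1 + x + x^2/2 at x = 0, 1, 2
        s = series_from_x([0.0, 1.0, 2.0], thermo300.kT)
        w = frame_weights(s, thermo300, method="maclaurin", order=2)
        np.testing.assert_allclose(w.weights, [1.0, 2.5, 5.0], rtol=1e-12)

    def test_maclaurin0_is_unweighted(self, thermo300):
        s = series_from_x(np.linspace(0, 3, 7), thermo300.kT)
        w = frame_weights(s, thermo300, method="maclaurin", order=0)
        np.testing.assert_array_equal(w.weights, np.ones(7))

    def test_weights_at_least_one(self, thermo300, rng):
        s = series_from_x(rng.uniform(0, 5, 100), thermo300.kT)
        for method, order in (("exponential", 0), ("maclaurin", 3)):
            w = frame_weights(s, thermo300, method=method, order=order)
            assert np.all(w.weights >= 1.0)
            assert len(w) == 100

    def test_component_selection(self, thermo300):
        s = am.BoostRecordSeries(step=[1], v_total=[0], v_dih=[0],
                                 dv_total=[thermo300.kT], dv_dih=[thermo300.kT])
        w_tot = frame_weights(s, thermo300, component="total")
        w_dih = frame_weights(s, thermo300, component="dihedral")
        assert w_tot.weights[0] == pytest.approx(np.e**2)
        assert w_dih.weights[0] == pytest.approx(np.e)

    def test_maclaurin_convergence_monotone(self):
        # agreement with the exponential improves monotonically in order
        x = np.linspace(0, 3, 1001)
        exact = np.exp(x)
        prev = np.inf
        for k in range(1, 11):
            err = np.max(np.abs(maclaurin_weights(x, k) - exact) / exact)
            assert err <= prev + 1e-15
            prev = err
        assert prev < 5e-4  # 0.05% at order 10 on [0, 3]


class TestWeightedHistogram:
    def test_unit_weights_reduce_to_counts(self, rng):
        v = rng.uniform(0, 10, 500)
        edges = np.linspace(0, 10, 11)
        h = weighted_histogram(v, np.ones(500), edges)
        np.testing.assert_array_equal(h.sums, h.counts)

    def test_hand_tally(self):
        h = weighted_histogram([0.5, 1.5, 1.5], [1.0, 2.0, 3.0], [0, 1, 2])
        np.testing.assert_array_equal(h.sums, [1.0, 5.0])
        np.testing.assert_array_equal(h.counts, [1, 2])
        assert h.n_excluded == 0

    def test_out_of_range_excluded(self):
        h = weighted_histogram([5.0, -1.0, 2.0], np.ones(3), [0, 1])
        assert h.counts.sum() == 0
        assert h.n_excluded == 3

    def test_non_monotone_edges_rejected(self):
        with pytest.raises(ValueError):
            weighted_histogram([0.5], [1.0], [0, 2, 1])

    def test_zero_boost_changes_nothing(self, thermo300, rng):
        # reweighting a zero-boost series leaves bin sums bitwise equal
        v = rng.uniform(0, 1, 1000)
        edges = np.linspace(0, 1, 21)
        s = series_from_x(np.zeros(1000), thermo300.kT)
        w = frame_weights(s, thermo300, method="exponential")
        h_w = weighted_histogram(v, w, edges)
        h_u = weighted_histogram(v, np.ones(1000), edges)
        assert np.array_equal(h_w.sums, h_u.sums)


class TestPmf:
    def test_hand_probabilities(self, thermo300):
        h = weighted_histogram([0.25, 0.25, 1.25, 2.25], [2.0, 2.0, 2.0, 2.0],
                               [0, 1, 2, 3])
        fes = pmf_from_histogram(h, thermo300)
        np.testing.assert_allclose(fes.probability, [0.5, 0.25, 0.25])
        expected = thermo300.kT * np.log(2.0)  # 0.41323 kcal/mol
        np.testing.assert_allclose(fes.pmf, [0.0, expected, expected], rtol=1e-12)
        assert expected == pytest.approx(0.41323, abs=1e-4)

    def test_flat_distribution_flat_pmf(self, thermo300):
        h = weighted_histogram([0.5, 1.5, 2.5, 3.5], np.ones(4), [0, 1, 2, 3, 4])
        fes = pmf_from_histogram(h, thermo300)
        np.testing.assert_array_equal(fes.pmf, np.zeros(4))

    def test_empty_bin_masked_not_zero(self, thermo300):
        h = weighted_histogram([0.5, 0.5, 2.5], np.ones(3), [0, 1, 2, 3])
        fes = pmf_from_histogram(h, thermo300)
        assert fes.mask[1]
        assert np.isnan(fes.pmf[1]) and np.isnan(fes.probability[1])
        assert np.nanmin(fes.pmf) == 0.0
        assert np.nansum(fes.probability) == pytest.approx(1.0, abs=1e-9)

    def test_all_bins_empty_rejected(self, thermo300):
        h = weighted_histogram([], [], [0, 1])
        with pytest.raises(ValueError):
            pmf_from_histogram(h, thermo300)


class TestPmf2d:
    def test_single_occupied_bin(self, thermo300):
        fes = pmf_2d([0.5], [0.5], [1.0], [0, 1, 2], [0, 1, 2], thermo300)
        assert fes.pmf[0, 0] == 0.0
        assert fes.mask.sum() == 3

    def test_separable_product_additivity(self, thermo300, rng):
        # independent coordinates: 2D PMF == sum of the 1D PMFs (exactly,
        # when the joint histogram is the outer product of the marginals)
        px = np.array([0.5, 0.3, 0.2])
        py = np.array([0.6, 0.4])
        joint = np.outer(px, py)
        xs, ys, ws = [], [], []
        for i in range(3):
            for j in range(2):
                xs.append(i + 0.5)
                ys.append(j + 0.5)
                ws.append(joint[i, j])
        ex, ey = [0, 1, 2, 3], [0, 1, 2]
        fes2 = pmf_2d(xs, ys, ws, ex, ey, thermo300)
        fes_x = pmf_from_histogram(weighted_histogram(xs, ws, ex), thermo300)
        fes_y = pmf_from_histogram(weighted_histogram(ys, ws, ey), thermo300)
        expected = fes_x.pmf[:, None] + fes_y.pmf[None, :]
        np.testing.assert_allclose(fes2.pmf, expected, atol=1e-9)

    def test_swapping_inputs_transposes(self, thermo300, rng):
        x = rng.uniform(0, 3, 400)
        y = rng.uniform(0, 2, 400)
        w = rng.uniform(1, 2, 400)
        ex = np.linspace(0, 3, 7)
        ey = np.linspace(0, 2, 5)
        a = pmf_2d(x, y, w, ex, ey, thermo300)
        b = pmf_2d(y, x, w, ey, ex, thermo300)
        np.testing.assert_allclose(a.pmf, b.pmf.T, equal_nan=True)


def test_recovery_double_well_small_scale(thermo300):
    """Boosted sampling + exponential reweighting recovers the analytic
    profile of a tilted double well (reduced-n version of the full check)."""
    pot = am.ToyPotentialSpec(
        "double_well_1d", {"barrier": 3.0, "half_sep": 1.0, "tilt": -0.5},
        bounds=(-2.0, 2.0),
    )
    amd = am.AmdParams(mode=1, e_total=pot.min_energy() + 4.0, alpha_total=2.0)
    xs, boost = am.sample_boosted(
        pot, am.SamplerSpec(n_samples=40000, seed=5, kT=thermo300.kT, amd=amd))
    assert boost.total_boost.mean() > 0
    assert boost.total_boost.max() < amd.e_total - pot.min_energy()
    edges = np.linspace(-2.0, 2.0, 41)
    w = frame_weights(boost, thermo300, method="exponential")
    fes = pmf_from_histogram(weighted_histogram(xs, w, edges), thermo300)
    p_true = pot.boltzmann_bin_probabilities(edges, thermo300.kT)
    pmf_true = -thermo300.kT * np.log(p_true / p_true.max())
    ok = fes.counts >= 200
    assert np.nanmax(np.abs(fes.pmf - pmf_true)[ok]) < 0.3
    assert np.nanargmin(np.where(fes.mask, np.nan, fes.pmf)) == np.argmin(pmf_true)
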