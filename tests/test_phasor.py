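"""Phasor transform, chord decomposition and redox-ratio identities."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mobflim import phasor as ph
from mobflim import synthetic as syn

OMEGA = ph.omega_from_period(12.5)  # 80 MHz, first harmonic


def ideal_decay_image(tau, n_bins=1024, period=12.5, shape=(1, 1), rate=1.0):
    pdf = syn.decay_histogram([tau], [1.0], n_bins, period)
    counts = np.broadcast_to(pdf[:, None, None] * rate,
                             (n_bins, *shape)).copy()
    return ph.DecayImage(counts, laser_period_ns=period)


class TestPhasorTransform:
    def test_monoexponential_semicircle_and_inversion(self):
        """An ideal 2.5 ns decay sits on the universal semicircle at the
        closed-form coordinates and inverts back to its lifetime."""
        pm = ph.phasor_transform(ideal_decay_image(2.5))
        g, s = pm.g[0, 0], pm.s[0, 0]
        assert g == pytest.approx(0.3877, abs=2e-4)
        assert s == pytest.approx(0.4872, abs=2e-4)
        assert (g - 0.5) ** 2 + s**2 == pytest.approx(0.25, abs=1e-4)
        assert ph.phasor_to_lifetime(g, s, pm.omega) == pytest.approx(
            2.5, rel=1e-3)

    def test_zero_lifetime_corner(self):
        # the limit is (1, 0); the residual offset is the first bin center
        pm = ph.phasor_transform(ideal_decay_image(1e-4, n_bins=4096))
        assert pm.g[0, 0] == pytest.approx(1.0, abs=1e-5)
        assert pm.s[0, 0] == pytest.approx(0.0, abs=2e-3)

    def test_mixture_phasor_is_midpoint(self):
        """The transform is linear in intensity: a 50/50 mixture lands on
        the midpoint of the two pure-species phasors."""
        taus = (0.45, 3.4)
        pure = [ph.phasor_transform(ideal_decay_image(t, n_bins=4096))
                for t in taus]
        pdf = syn.decay_histogram(taus, [0.5, 0.5], 4096, 12.5)
        mixed = ph.phasor_transform(
            ph.DecayImage(pdf[:, None, None], laser_period_ns=12.5))
        assert mixed.g[0, 0] == pytest.approx(
            (pure[0].g[0, 0] + pure[1].g[0, 0]) / 2, abs=1e-9)
        assert mixed.s[0, 0] == pytest.approx(
            (pure[0].s[0, 0] + pure[1].s[0, 0]) / 2, abs=1e-9)

    def test_zero_photon_pixels_invalid(self):
        counts = np.zeros((8, 2, 2))
        counts[:, 0, 0] = 1.0
        pm = ph.phasor_transform(ph.DecayImage(counts))
        assert pm.valid[0, 0] and not pm.valid[1, 1]
        assert np.isnan(pm.g[1, 1])

    def test_all_zero_image_warns(self):
        with pytest.warns(UserWarning):
            pm = ph.phasor_transform(ph.DecayImage(np.zeros((8, 2, 2))))
        assert not pm.valid.any()

    @settings(max_examples=30, deadline=None)
    @given(st.lists(st.tuples(st.floats(0.01, 1.0), st.floats(0.05, 10.0)),
                    min_size=1, max_size=5))
    def test_exponential_mixtures_inside_semicircle(self, species):
        """Any mixture of decaying exponentials maps inside or on the
        universal semicircle (up to discretization tolerance)."""
        fracs = [f for f, _ in species]
        taus = [t for _, t in species]
        pdf = syn.decay_histogram(taus, fracs, 512, 12.5)
        pm = ph.phasor_transform(ph.DecayImage(pdf[:, None, None]))
        g, s = pm.g[0, 0], pm.s[0, 0]
        assert (g - 0.5) ** 2 + s**2 <= 0.25 + 1e-3
        assert s >= -1e-9


class TestMedianFilter:
    def test_constant_map_unchanged(self):
        pm = ph.PhasorMap(g=np.full((5, 5), 0.4), s=np.full((5, 5), 0.3),
                          omega=OMEGA, total_photons=np.ones((5, 5)))
        out = ph.median_filter_phasor(pm)
        np.testing.assert_allclose(out.g, 0.4)
        np.testing.assert_allclose(out.s, 0.3)

    def test_outlier_replaced(self):
        g = np.full((3, 3), 0.4)
        g[1, 1] = 0.99
        pm = ph.PhasorMap(g=g, s=g.copy(), omega=OMEGA,
                          total_photons=np.ones((3, 3)))
        out = ph.median_filter_phasor(pm)
        assert out.g[1, 1] == pytest.approx(0.4)

    def test_checkerboard_matches_bruteforce(self):
        """Every pixel equals the brute-force median of its in-bounds
        neighborhood."""
        rng = np.random.default_rng(0)
        g = np.where((np.indices((6, 7)).sum(axis=0)) % 2 == 0, 0.2, 0.7)
        s = rng.random((6, 7))
        pm = ph.PhasorMap(g=g, s=s, omega=OMEGA,
                          total_photons=np.ones((6, 7)))
        out = ph.median_filter_phasor(pm)
        for arr, res in ((g, out.g), (s, out.s)):
            for i in range(6):
                for j in range(7):
                    nb = arr[max(0, i - 1):i + 2, max(0, j - 1):j + 2]
                    assert res[i, j] == pytest.approx(np.median(nb))

    def test_invalid_excluded_from_neighborhoods(self):
        g = np.full((3, 3), 0.4)
        g[0, 0] = np.nan
        valid = np.isfinite(g)
        pm = ph.PhasorMap(g=g, s=g.copy(), omega=OMEGA,
                          total_photons=valid.astype(float), valid=valid)
        out = ph.median_filter_phasor(pm)
        assert out.g[1, 1] == pytest.approx(0.4)
        assert np.isnan(out.g[0, 0])

    def test_bad_window_rejected(self):
        pm = ph.PhasorMap(g=np.zeros((2, 2)), s=np.zeros((2, 2)),
                          omega=OMEGA, total_photons=np.ones((2, 2)))
        with pytest.raises(ValueError):
            ph.median_filter_phasor(pm, window=0)
        with pytest.raises(ValueError):
            ph.median_filter_phasor(pm, window=4)


def _map_of(points):
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    g = pts[:, 0].reshape(1, -1)
    s = pts[:, 1].reshape(1, -1)
    return ph.PhasorMap(g=g, s=s, omega=OMEGA,
                        total_photons=np.ones_like(g))


class TestResolveBoundFraction:
    def test_free_anchor_coordinates(self):
        gf, sf = ph.monoexp_phasor(0.45, OMEGA)
        assert gf == pytest.approx(0.9513, abs=1e-4)
        assert sf == pytest.approx(0.2152, abs=1e-4)

    def test_pixel_at_free_anchor(self):
        lt = ph.resolve_bound_fraction(_map_of([ph.monoexp_phasor(0.45, OMEGA)]))
        assert lt.alpha_bound[0, 0] == 0.0

    def test_pure_bound_species(self):
        lt = ph.resolve_bound_fraction(_map_of([ph.monoexp_phasor(3.4, OMEGA)]))
        assert lt.alpha_bound[0, 0] == pytest.approx(1.0, abs=1e-9)
        assert lt.tau_bound[0, 0] == pytest.approx(3.4, rel=1e-9)
        assert lt.qc_flag[0, 0] == ph.QC_OK

    def test_chord_midpoint_is_half_bound(self):
        """Forward-construct the 50/50 free/bound mixture phasor and invert:
        the chord midpoint decodes to alpha = 0.5 at the bound lifetime."""
        p = ph.mixture_phasor([0.5, 0.5], [0.45, 3.4], OMEGA)
        assert p == (pytest.approx(0.6032, abs=1e-4),
                     pytest.approx(0.3255, abs=1e-4))
        lt = ph.resolve_bound_fraction(_map_of([p]))
        assert lt.alpha_bound[0, 0] == pytest.approx(0.5, rel=1e-9)
        assert lt.tau_bound[0, 0] == pytest.approx(3.4, rel=1e-9)

    def test_alpha_monotone_in_bound_fraction(self):
        """alpha_bound recovered from closed-form mixtures increases with
        the bound intensity fraction at fixed tau_bound."""
        fracs = np.linspace(0, 1, 21)
        pts = [ph.mixture_phasor([1 - f, f], [0.45, 3.4], OMEGA)
               for f in fracs]
        lt = ph.resolve_bound_fraction(_map_of(pts))
        np.testing.assert_allclose(lt.alpha_bound[0], fracs, atol=1e-9)
        assert np.all(np.diff(lt.alpha_bound[0]) > 0)

    def test_outside_circle_clamped(self):
        lt = ph.resolve_bound_fraction(_map_of([(0.1, 0.6)]))
        assert lt.alpha_bound[0, 0] == 1.0
        assert lt.qc_flag[0, 0] == ph.QC_CLAMPED

    def test_wrong_side_invalid(self):
        # below the g-axis: the second intersection has s <= 0
        lt = ph.resolve_bound_fraction(_map_of([(0.97, 0.05)]))
        assert lt.qc_flag[0, 0] == ph.QC_INVALID

    def test_invalid_photons_propagate(self):
        pm = _map_of([(0.6, 0.3)])
        pm.valid[:] = False
        lt = ph.resolve_bound_fraction(pm)
        assert lt.qc_flag[0, 0] == ph.QC_INVALID


class TestORR:
    def _masks(self):
        mito = np.zeros((4, 4), dtype=bool)
        mito[:2] = True
        return mito, ~mito

    def test_bleed_correction_identity(self):
        """A constant NAD(P)H bleed fraction into the FAD channel cancels
        exactly: the corrected ratio equals the true mitochondrial ratio."""
        mito, cyto = self._masks()
        nadph = np.full((4, 4), 10.0)
        fad_true = np.where(mito, 8.0, 0.0)
        fad_obs = fad_true + 0.3 * nadph
        orr, baseline = ph.compute_orr(fad_obs, nadph, mito, cyto)
        assert orr == pytest.approx(0.8, abs=1e-12)
        assert baseline == pytest.approx(0.3, abs=1e-12)

    def test_zero_fad_gives_zero(self):
        mito, cyto = self._masks()
        orr, _ = ph.compute_orr(np.zeros((4, 4)), np.ones((4, 4)), mito, cyto)
        assert orr == 0.0

    def test_printed_formula(self):
        mito, cyto = self._masks()
        nadph = np.ones((4, 4))
        fad = np.where(mito, 0.8, 0.3)
        orr, _ = ph.compute_orr(fad, nadph, mito, cyto)
        assert orr == pytest.approx(0.5)

    def test_empty_region_undefined(self):
        mito, cyto = self._masks()
        orr, _ = ph.compute_orr(np.ones((4, 4)), np.ones((4, 4)),
                                np.zeros((4, 4), dtype=bool), cyto)
        assert np.isnan(orr)

    def test_overlapping_masks_rejected(self):
        mito, _ = self._masks()
        with pytest.raises(ValueError):
            ph.compute_orr(np.ones((4, 4)), np.ones((4, 4)), mito, mito)


class TestRoundTrip:
    def test_noisefree_pipeline_recovers_truth(self, noisefree_scene):
        """Noise-free scene -> phasor -> median filter -> decomposition
        recovers the per-cell alpha_bound and tau_bound maps to < 1e-3
        relative error (256 bins)."""
        spec, (nadph, _, truth) = noisefree_scene
        pm = ph.median_filter_phasor(ph.phasor_transform(nadph))
        lt = ph.resolve_bound_fraction(pm)
        cell = truth.label_map == 1
        assert np.nanmean(lt.alpha_bound[cell]) == pytest.approx(0.5, rel=1e-3)
        assert np.nanmean(lt.tau_bound[cell]) == pytest.approx(3.4, rel=1e-3)
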