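"""Dosimetric reductions on constructed grids with known answers."""

import numpy as np
import pytest

from ssadose import dosimetry as D
from ssadose import materials as M
from ssadose.beam_model import ProtonBundle
from ssadose.transport import DoseGrid


def _grid(shape=(21, 21, 30)):
    return DoseGrid.zeros(shape, 1.0)


def _bundle_with_energies(energies):
    n = len(energies)
    return ProtonBundle(np.zeros((n, 3)), np.tile([0, 0, 1.0], (n, 1)),
                        np.asarray(energies, float), np.ones(n), np.ones(n, bool))


class TestIdd:
    def test_normalized_entrance_is_one_and_conserves_total(self):
        g = _grid()
        g.dose[10, 10, :] = np.linspace(1.0, 4.0, 30)
        raw = D.idd(g)
        assert raw.value.sum() == pytest.approx(g.dose.sum())
        norm = D.idd(g, normalize=True)
        assert norm.value[0] == pytest.approx(1.0)
        assert norm.normalization == "entrance=1"

    def test_zero_entrance_with_normalize_raises(self):
        g = _grid()
        g.dose[10, 10, 5:] = 1.0
        with pytest.raises(ValueError, match="entrance"):
            D.idd(g, normalize=True)


class TestBraggPeakDepth:
    def test_exact_peak_at_a_bin(self):
        z = np.arange(30) + 0.5
        v = np.zeros(30)
        v[17] = 5.0
        v[16] = v[18] = 2.5
        assert D.bragg_peak_depth(D.DepthCurve(z, v)) == pytest.approx(z[17])

    def test_parabola_vertex_recovered(self):
        z = np.arange(0.5, 30.0, 1.0)
        vertex = 13.37
        v = 400.0 - (z - vertex) ** 2
        assert D.bragg_peak_depth(D.DepthCurve(z, v)) == pytest.approx(vertex, abs=0.01)

    def test_flat_curve_raises(self):
        z = np.arange(5) + 0.5
        with pytest.raises(ValueError, match="flat"):
            D.bragg_peak_depth(D.DepthCurve(z, np.ones(5)))


class TestSpotSigma:
    def test_recovers_known_gaussian_width(self):
        g = _grid((41, 41, 10))
        x = g.x_centers
        prof = np.exp(-0.5 * (x / 4.0) ** 2)
        g.dose[:, 20, 5] = prof
        assert D.spot_sigma(g, 5.5) == pytest.approx(4.0, abs=0.05)
        assert D.spot_sigma(g, 5.5, method="rms") == pytest.approx(4.0, abs=0.2)

    def test_symmetric_profile_centers_on_axis(self):
        g = _grid((41, 41, 10))
        x = g.x_centers
        g.dose[:, 20, 5] = np.exp(-0.5 * (x / 2.5) ** 2)  # queried at bin center
        from scipy.optimize import curve_fit

        popt, _ = curve_fit(D._gauss, x, g.dose[:, 19:22, 5].sum(axis=1),
                            p0=[1.0, 0.5, 2.0])
        assert abs(popt[1]) < 0.1

    def test_all_zero_profile_raises(self):
        with pytest.raises(ValueError, match="zero"):
            D.spot_sigma(_grid(), 5.0)


class TestPeakToEntrance:
    def test_equals_maximum_of_normalized_curve(self):
        z = np.arange(10) + 0.5
        v = np.array([1.0, 1.1, 1.3, 1.6, 2.2, 3.5, 4.0, 2.0, 0.3, 0.05])
        curve = D.DepthCurve(z, v, "entrance=1")
        assert D.peak_to_entrance(curve) == pytest.approx(4.0)

    def test_zero_entrance_raises(self):
        z = np.arange(5) + 0.5
        with pytest.raises(ValueError):
            D.peak_to_entrance(D.DepthCurve(z, np.array([0.0, 1, 2, 1, 0.5])))


class TestTransmission:
    def test_identical_grids_give_unity(self):
        g = _grid()
        g.dose[10, 10, :] = 1.0
        assert D.transmission(g, g) == pytest.approx(1.0)

    def test_fully_blocked_gives_zero(self):
        g0 = _grid()
        g1 = _grid()
        g1.dose[10, 10, :] = 2.0
        assert D.transmission(g0, g1) == 0.0

    def test_mismatched_shapes_raise(self):
        with pytest.raises(ValueError, match="shape"):
            D.transmission(_grid((10, 10, 5)), _grid((11, 11, 5)))

    def test_excess_dose_raises(self):
        g0, g1 = _grid(), _grid()
        g0.dose[10, 10, :] = 2.0
        g1.dose[10, 10, :] = 1.0
        with pytest.raises(ValueError, match="matched pair"):
            D.transmission(g0, g1)

    def test_zero_denominator_raises(self):
        with pytest.raises(ValueError, match="zero total dose"):
            D.transmission(_grid(), _grid())


class TestIld:
    def test_degenerate_average_returns_stopping_power(self):
        g = _grid()
        water = M.get_material("water")
        let = M.linear_stopping_power(water, 80.0)
        g.let_den[10, 10, :] = 2.0
        g.let_num[10, 10, :] = 2.0 * let
        curve = D.ild(g)
        np.testing.assert_allclose(curve.value, let)

    def test_empty_accumulators_raise(self):
        with pytest.raises(ValueError, match="empty"):
            D.ild(_grid())

    def test_let_rises_towards_bragg_peak(self, ssa_pair):
        with_ap, _ = ssa_pair
        curve = D.ild(with_ap.dose_grid)
        bp = D.bragg_peak_depth(D.idd(with_ap.dose_grid))
        at_bp = curve.value[np.argmin(np.abs(curve.z - bp))]
        assert at_bp > curve.value[0]


class TestExports:
    def test_profiles_csv_round_trips_idd(self, tmp_path):
        import pandas as pd

        g = _grid()
        g.dose[10, 10, :] = np.linspace(1.0, 4.0, 30)
        g.let_den[10, 10, :] = 1.0
        g.let_num[10, 10, :] = 5.0
        path = tmp_path / "profiles.csv"
        D.export_profiles_csv(g, path)
        df = pd.read_csv(path)
        np.testing.assert_allclose(df.idd, D.idd(g).value, rtol=1e-6)
        np.testing.assert_allclose(df.dose_averaged_let_kev_um, 5.0)

    def test_mhd_export_preserves_volume(self, tmp_path):
        sitk = pytest.importorskip("SimpleITK")
        g = _grid()
        g.dose[10, 10, 3] = 7.0
        path = tmp_path / "dose.mhd"
        D.export_mhd(g, path)
        back = sitk.GetArrayFromImage(sitk.ReadImage(str(path)))
        assert back.sum() == pytest.approx(7.0)


class TestExitSpectrum:
    def test_fractions_normalized(self):
        b = _bundle_with_energies([50.0, 51.0, 52.0, 80.0])
        _, frac = D.exit_spectrum(b)
        assert frac.sum() == pytest.approx(1.0)

    def test_empty_collection_raises(self):
        with pytest.raises(ValueError):
            D.exit_spectrum(ProtonBundle.empty())
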