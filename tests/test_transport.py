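"""Transport kernel physics: stopping, scattering, geometry, conservation."""

import numpy as np
import pytest

from ssadose import materials as M
from ssadose import dosimetry as D
from ssadose.beam_model import sample_beamlet, energy_for_bp_depth
from ssadose.transport import (
    Aperture,
    GeometryStack,
    in_bore,
    simulate_configuration,
    step_protons,
    transport_beamlet,
)
from ssadose.workflow import ssa_geometry, _paired_transmission, SweepSpec


def _uniform_bundle(n, energy):
    from ssadose.beam_model import ProtonBundle

    pos = np.zeros((n, 3))
    dirs = np.tile([0.0, 0.0, 1.0], (n, 1))
    return ProtonBundle(pos, dirs, np.full(n, float(energy)), np.ones(n),
                        np.ones(n, dtype=bool))


class TestInBore:
    def test_axis_point_inside_centered_bore(self):
        ap = Aperture(M.get_material("tungsten"), 11.1, 3.0)
        assert in_bore((0.0, 0.0), ap)

    def test_point_exactly_at_radius_is_outside(self):
        ap = Aperture(M.get_material("tungsten"), 11.1, 3.0)
        assert not in_bore((3.0, 0.0), ap)

    def test_misaligned_bore_excludes_axis(self):
        ap = Aperture(M.get_material("tungsten"), 11.1, 1.0, lateral_offset=(1.5, 0.0))
        assert not in_bore((0.0, 0.0), ap)

    def test_vectorized_matches_scalar(self):
        ap = Aperture(M.get_material("nickel"), 18.5, 2.0, lateral_offset=(0.5, -0.5))
        pts = np.array([[0.0, 0.0], [2.4, -0.5], [0.5, 1.4]])
        got = in_bore(pts, ap)
        assert list(got) == [in_bore(p, ap) for p in pts]


class TestStepKernel:
    def test_mean_energy_loss_matches_stopping_table(self):
        water = M.get_material("water")
        b = _uniform_bundle(100_000, 150.0)
        rng = np.random.default_rng(0)
        out = step_protons(b, water, 1.0, rng)
        mean_loss = (b.energy - out.energy).mean()
        expected = M.linear_stopping_power(water, 150.0) * 1.0
        assert mean_loss == pytest.approx(expected, rel=0.01)

    def test_rms_scattering_angle_matches_highland(self):
        water = M.get_material("water")
        b = _uniform_bundle(100_000, 150.0)
        rng = np.random.default_rng(1)
        out = step_protons(b, water, 1.0, rng)
        slopes = out.direction[:, 0] / out.direction[:, 2]
        theta0 = M.highland_sigma(water, 150.0, 1.0)
        assert slopes.std() == pytest.approx(theta0, rel=0.03)

    def test_air_step_loses_almost_nothing(self):
        air = M.get_material("air")
        b = _uniform_bundle(1000, 150.0)
        out = step_protons(b, air, 1.0, np.random.default_rng(2))
        assert (b.energy - out.energy).mean() < 1e-3

    def test_vacuum_is_pure_drift(self):
        b = _uniform_bundle(10, 150.0)
        out = step_protons(b, None, 5.0, np.random.default_rng(3))
        np.testing.assert_allclose(out.position[:, 2], 5.0)
        np.testing.assert_array_equal(out.energy, b.energy)


class TestTransportBeamlet:
    def test_bragg_peak_near_csda_range(self, pristine_result):
        curve = D.idd(pristine_result.dose_grid)
        bp = D.bragg_peak_depth(curve)
        csda = M.csda_range(M.get_material("water"), 160.0)
        assert bp == pytest.approx(csda, abs=2.0)

    def test_energy_bookkeeping_closes(self, pristine_result, ssa_pair):
        for res in (pristine_result, *ssa_pair):
            assert res.energy_accounted / res.initial_energy == pytest.approx(1.0, abs=0.01)

    def test_aperture_removes_dose(self, ssa_pair):
        with_ap, without_ap = ssa_pair
        assert with_ap.dose_grid.dose.sum() < without_ap.dose_grid.dose.sum()
        assert with_ap.n_primaries == without_ap.n_primaries

    def test_seed_determinism_is_bitwise(self, beam_model):
        src = sample_beamlet(beam_model, 100.0, 2000, seed=5)
        geom = ssa_geometry("tungsten", 2.0, 50.0)
        a = transport_beamlet(src, geom, seed=6)
        b = transport_beamlet(src, geom, seed=6)
        np.testing.assert_array_equal(a.dose_grid.dose, b.dose_grid.dose)
        np.testing.assert_array_equal(a.dose_grid.let_num, b.dose_grid.let_num)

    def test_geometry_overlap_rejected(self):
        poly = M.get_material("polycarbonate")
        ap = Aperture(M.get_material("tungsten"), 11.1, 3.0, z_downstream=-50.0)
        geom = GeometryStack(range_shifter=(poly, 40.0, -55.0), aperture=ap)
        src = _uniform_bundle(10, 100.0)
        with pytest.raises(ValueError, match="overlap"):
            transport_beamlet(src, geom, seed=1)

    def test_empty_source_rejected(self):
        from ssadose.beam_model import ProtonBundle

        with pytest.raises(ValueError):
            transport_beamlet(ProtonBundle.empty(), GeometryStack(), seed=1)


class TestLateralSpread:
    def test_sigma_growth_matches_fermi_eyges(self, pristine_result):
        """MC lateral sigma vs moment integration of the same scattering power."""
        water = M.get_material("water")
        grid = pristine_result.dose_grid
        r0 = M.csda_range(water, 160.0)
        ds = 1.0
        u_edges = np.arange(0.0, 172.0, ds)
        resid = np.maximum(r0 - u_edges, M.csda_range(water, M.E_TABLE_MIN))
        e_local = np.array([M.energy_from_range(water, r) for r in resid])
        t_x0 = ds / 10.0 * water.density / water.radiation_length
        for z_probe in (100.0, 150.0, 170.0):
            var = 0.0
            cum = 0.0
            for u, e in zip(u_edges, e_local):
                if u + ds > z_probe:
                    break
                th = M.highland_sigma(water, e, ds, cum_t_x0=cum)
                lever = z_probe - (u + ds)
                var += th**2 * (ds**2 / 12.0 + (ds / 2.0 + lever) ** 2)
                cum += t_x0
            sigma_fe = np.sqrt(var)
            rms = D.spot_sigma(grid, z_probe, method="rms")
            sigma_mc = np.sqrt(max(rms**2 - grid.voxel_size**2 / 12.0, 0.0))
            assert sigma_mc == pytest.approx(sigma_fe, rel=0.05)


class TestAperturePhysics:
    def test_slit_scattering_produces_low_energy_tail(self, ssa_pair):
        with_ap, without_ap = ssa_pair
        centers, frac = D.exit_spectrum(with_ap.exit_states)
        mode = centers[np.argmax(frac)]
        assert frac[centers < mode - 10.0].sum() > 0.0
        # the uncollimated exit spectrum is a single quasi-Gaussian peak
        c0, f0 = D.exit_spectrum(without_ap.exit_states)
        m0 = c0[np.argmax(f0)]
        assert f0[np.abs(c0 - m0) <= 3.0].sum() > 0.9

    def test_low_energy_fraction_grows_as_bore_shrinks(self, beam_model):
        energy = energy_for_bp_depth(50.0, 45.0)
        fracs = []
        for radius in (4.0, 1.5):
            src = sample_beamlet(beam_model, energy, 30_000, seed=21)
            res = transport_beamlet(src, ssa_geometry("tungsten", radius, 50.0), seed=22)
            centers, frac = D.exit_spectrum(res.exit_states)
            mode = centers[np.argmax(frac)]
            fracs.append(frac[centers < mode - 10.0].sum())
        assert fracs[1] > fracs[0]

    def test_huge_bore_approaches_unit_transmission(self, beam_model):
        energy = energy_for_bp_depth(50.0, 45.0)
        src = sample_beamlet(beam_model, energy, 30_000, seed=23)
        geom = ssa_geometry("tungsten", 20.0, 50.0)
        with_ap, without_ap = simulate_configuration(src, geom, seed=24)
        assert D.transmission(with_ap.dose_grid, without_ap.dose_grid) > 0.97

    def test_misalignment_barely_changes_transmission(self):
        spec = SweepSpec(n_histories=50_000, seed=31)
        cache = {}
        _, _, t0 = _paired_transmission("tungsten", 2.0, 50.0, 0.0, 50.0, spec,
                                        without_cache=cache)
        _, _, t1 = _paired_transmission("tungsten", 2.0, 50.0, 0.0, 50.0, spec,
                                        offset_mm=(1.0, 0.0), without_cache=cache)
        assert abs(t1 - t0) < 0.02

    def test_infinitesimal_sigma_is_a_lower_bound(self, beam_model, ssa_pair):
        # same Bragg-peak depth reached by a bare infinitesimal beamlet vs a
        # finite beamlet through a range shifter at the aperture position
        energy = M.energy_from_range(M.get_material("water"), 50.0)
        src = sample_beamlet(beam_model, energy, 20_000, seed=25, infinitesimal=True)
        res = transport_beamlet(src, GeometryStack(), seed=26)
        bp_inf = D.bragg_peak_depth(D.idd(res.dose_grid))
        sig_inf = D.spot_sigma(res.dose_grid, bp_inf)
        _, without_ap = ssa_pair
        bp_rs = D.bragg_peak_depth(D.idd(without_ap.dose_grid))
        sig_rs = D.spot_sigma(without_ap.dose_grid, bp_rs)
        assert abs(bp_inf - bp_rs) < 3.0
        assert sig_inf < sig_rs
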