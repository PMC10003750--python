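"""The three striatal release models: SUR ODE and STUR/STDR radial PDEs."""

import numpy as np
import pytest

from fscvmodels import (
    GeometryParams,
    PlasticityParams,
    ReleaseUptakeParams,
    dead_space_mask,
    make_single_burst,
    mm_uptake,
    simulate_stdr,
    simulate_stur,
    simulate_sur,
)
from fscvmodels.release import default_site_positions


class TestMMUptake:
    def test_half_maximal_at_km(self):
        assert mm_uptake(0.2, v_m=4.8, km=0.2) == pytest.approx(2.4)

    def test_zero_at_zero(self):
        assert mm_uptake(0.0, v_m=4.8, km=0.2) == 0.0

    def test_saturates_to_vm(self):
        assert mm_uptake(100 * 0.2, v_m=4.8, km=0.2) == pytest.approx(4.8, rel=0.01)

    def test_linear_limit_at_low_concentration(self):
        c = 1e-4
        assert mm_uptake(c, v_m=4.8, km=0.2) == pytest.approx(4.8 * c / 0.2, rel=1e-3)

    def test_rejects_negative_concentration(self):
        with pytest.raises(ValueError):
            mm_uptake(-0.1, v_m=4.8, km=0.2)


class TestDeadSpaceMask:
    def test_center_is_active(self, geometry):
        assert dead_space_mask(0.0, geometry) == 1.0

    def test_boundary_is_dead(self, geometry):
        assert dead_space_mask(geometry.r_l, geometry) == 0.0

    def test_switch_at_active_radius(self, geometry):
        # r_l = 50, r_d = 3: the mask flips at R = 47 um
        assert dead_space_mask(46.999, geometry) == 1.0
        assert dead_space_mask(47.0, geometry) == 0.0

    def test_no_dead_space_limit_is_all_active(self):
        geom = GeometryParams(r_d=0.0)
        assert dead_space_mask(geom.r_l, geom) == 1.0


class TestSUR:
    def test_no_release_gives_zero(self, wt_kinetics, single_burst, fine_grid_12s):
        da = simulate_sur(
            single_burst, wt_kinetics, ReleaseUptakeParams(da_p=0.0, v_m=4.8),
            fine_grid_12s,
        )
        assert np.all(da == 0.0)

    def test_no_uptake_integrates_release_per_pulse(
        self, flat_kinetics, single_burst, fine_grid_12s
    ):
        """With V_m = 0 and A = 1 the end concentration is DA_P * I * NP.

        Tolerance reflects the O(dt) quadrature error of sampling the
        discontinuous burst indicator at the two burst edges.
        """
        params = ReleaseUptakeParams(da_p=0.420, v_m=0.0)
        da = simulate_sur(single_burst, flat_kinetics, params, fine_grid_12s)
        assert da[-1] == pytest.approx(0.420 * single_burst.current * 30, rel=2e-3)

    def test_wt_transient_peaks_near_burst_offset(
        self, wt_kinetics, single_burst, wt_release, fine_grid_12s
    ):
        da = simulate_sur(single_burst, wt_kinetics, wt_release, fine_grid_12s)
        t_peak = fine_grid_12s[np.argmax(da)]
        assert 2.0 < t_peak <= 2.8  # burst spans [2.0, 2.6]
        assert da[-1] < 0.05 * da.max()  # decays back toward zero
        assert np.all(da >= 0.0)

    def test_output_matches_plasticity_free_model_when_factors_zero(
        self, single_burst, wt_release, fine_grid_12s
    ):
        """p_j = 0 for all j must reproduce the A = 1 model exactly."""
        a = simulate_sur(
            single_burst,
            PlasticityParams(p=(0, 0, 0), tau=(7.5, 15.0, 900.0)),
            wt_release, fine_grid_12s,
        )
        b = simulate_sur(
            single_burst,
            PlasticityParams(p=(0, 0, 0), tau=(1.0, 2.0, 3.0)),
            wt_release, fine_grid_12s,
        )
        assert np.array_equal(a, b)


class TestSTUR:
    def test_no_release_gives_zero_field(self, wt_kinetics, single_burst, geometry):
        t = np.arange(0.0, 4.0001, 1e-3)
        fld, tr = simulate_stur(
            single_burst, wt_kinetics, ReleaseUptakeParams(da_p=0.0, v_m=4.8),
            geometry, t,
        )
        assert np.all(fld.values == 0.0) and np.all(tr == 0.0)

    def test_reduces_to_sur_without_dead_space(
        self, wt_kinetics, single_burst, fine_grid_12s
    ):
        """Uniform source + no-flux walls + r_d = 0 keeps the field uniform."""
        params = ReleaseUptakeParams(da_p=0.422, v_m=4.8)
        _, tr = simulate_stur(
            single_burst, wt_kinetics, params, GeometryParams(r_d=0.0), fine_grid_12s
        )
        da = simulate_sur(single_burst, wt_kinetics, params, fine_grid_12s)
        assert np.max(np.abs(tr - da)) / da.max() < 0.01

    def test_mass_conserved_with_sources_off(self, flat_kinetics, geometry):
        """Diffusion-only: the discrete cylindrical mass integral is constant."""
        proto = make_single_burst(100.0)
        t = np.arange(0.0, 5.0001, 1e-3)
        radii = geometry.radii()
        c0 = np.exp(-(((radii - 20.0) / 5.0) ** 2))
        fld, _ = simulate_stur(
            proto, flat_kinetics, ReleaseUptakeParams(da_p=0.0, v_m=0.0),
            geometry, t, initial_field=c0,
        )
        mass = fld.mass()
        assert (mass.max() - mass.min()) / mass[0] < 1e-3

    def test_grid_halving_self_consistency(self, wt_kinetics, single_burst):
        """Halving both dr and dt changes the boundary trace by < 1%."""
        params = ReleaseUptakeParams(da_p=0.422, v_m=4.8)
        t1 = np.arange(0.0, 8.0001, 1e-3)
        t2 = np.arange(0.0, 8.00005, 5e-4)
        _, a = simulate_stur(single_burst, wt_kinetics, params, GeometryParams(dr=0.5), t1)
        _, b = simulate_stur(single_burst, wt_kinetics, params, GeometryParams(dr=0.25), t2)
        assert np.max(np.abs(a - b[::2])) / a.max() < 0.01

    def test_explicit_scheme_agrees_with_implicit(self, wt_kinetics, single_burst):
        params = ReleaseUptakeParams(da_p=0.422, v_m=4.8)
        geom = GeometryParams(dr=1.0)  # D*dt/dr^2 = 0.24, inside the guard
        t = np.arange(0.0, 6.0001, 1e-3)
        _, a = simulate_stur(single_burst, wt_kinetics, params, geom, t, scheme="cn")
        _, b = simulate_stur(single_burst, wt_kinetics, params, geom, t, scheme="euler")
        assert np.max(np.abs(a - b)) / a.max() < 0.01

    def test_explicit_scheme_stability_guard(self, wt_kinetics, single_burst, geometry):
        t = np.arange(0.0, 2.0001, 1e-3)  # D*dt/dr^2 = 0.96 > 0.5
        with pytest.raises(ValueError, match="unstable"):
            simulate_stur(
                single_burst, wt_kinetics, ReleaseUptakeParams(da_p=0.4, v_m=4.8),
                geometry, t, scheme="euler",
            )


class TestSTDR:
    def test_no_sites_gives_zero_field(self, wt_kinetics, single_burst):
        geom = GeometryParams(site_positions=())
        t = np.arange(0.0, 3.0001, 1e-3)
        fld, tr = simulate_stdr(
            single_burst, wt_kinetics, ReleaseUptakeParams(da_p=2.43, v_m=4.8),
            geom, t,
        )
        assert np.all(fld.values == 0.0) and np.all(tr == 0.0)

    def test_default_sites_spaced_six_microns(self, geometry):
        sites = default_site_positions(geometry)
        assert np.allclose(np.diff(sites), 6.0)
        assert all(0 < s < geometry.active_radius for s in sites)

    def test_site_in_dead_space_rejected(self):
        with pytest.raises(ValueError):
            GeometryParams(site_positions=(48.0,))

    @pytest.mark.parametrize("dr", [0.5, 0.25])
    def test_injected_mass_matches_shell_sources(self, flat_kinetics, single_burst, dr):
        """With V_m = 0, mass per burst is DA_P*I*NP * sum_i 2*pi*R_i, any dr."""
        geom = GeometryParams(dr=dr)
        params = ReleaseUptakeParams(da_p=2.43, v_m=0.0)
        t = np.arange(0.0, 4.0001, 1e-3)
        fld, _ = simulate_stdr(single_burst, flat_kinetics, params, geom, t)
        expected = 2.43 * single_burst.current * 30 * sum(
            2 * np.pi * r for r in default_site_positions(geom)
        )
        assert fld.mass()[-1] == pytest.approx(expected, rel=5e-3)

    def test_transient_shape_matches_stur(self, wt_kinetics, single_burst, geometry):
        """Discrete and uniform release produce the same transient shape.

        Amplitudes differ (the default site grid ends 5 um short of the
        active-region edge, so less release reaches the electrode), but
        the rise/decay shape and timing must agree closely.
        """
        t = np.arange(0.0, 10.0001, 1e-3)
        _, a = simulate_stur(
            single_burst, wt_kinetics, ReleaseUptakeParams(da_p=0.422, v_m=4.8),
            geometry, t,
        )
        _, b = simulate_stdr(
            single_burst, wt_kinetics, ReleaseUptakeParams(da_p=2.43, v_m=4.8),
            geometry, t,
        )
        assert np.corrcoef(a, b)[0, 1] > 0.98
        assert abs(t[np.argmax(a)] - t[np.argmax(b)]) < 0.1
        assert 0.4 < b.max() / a.max() < 1.0


class TestGeometryValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"r_d": 60.0},            # dead space larger than cylinder
            {"r_d": -1.0},
            {"d": 0.0},
            {"dr": 5.0, "r_d": 3.0},  # grid cannot resolve the dead space
            {"dr": 0.0},
        ],
    )
    def test_invalid_geometry_rejected(self, kwargs):
        with pytest.raises(ValueError):
            GeometryParams(**kwargs)

    def test_dr_must_divide_radius(self):
        with pytest.raises(ValueError, match="evenly"):
            GeometryParams(dr=0.7).radii()
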