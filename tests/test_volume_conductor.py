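"""Volume-conductor solver: analytic oracles and field invariants."""

import math

import numpy as np
import pytest

from retistim.geometry import (
    ElectrodeShape,
    ElectrodeSpec,
    Layer,
    LayerStack,
    build_layer_stack,
)
from retistim.volume_conductor import (
    AxisymmetricGrid,
    build_grid,
    convergence_study,
    field_strength_profile,
    interface_charge_density_profile,
    max_field_in_layer,
    max_field_ratio,
    sample_potential,
    solve_potential,
)

SIGMA = 1.2821


def uniform_halfspace_stack(erd=50.0, height=5000.0, radius=5000.0):
    layers = (Layer("vitreous", SIGMA, -erd, 0.0),
              Layer("medium", SIGMA, 0.0, height))
    return LayerStack(layers, erd=erd, domain_radius=radius)


@pytest.fixture(scope="module")
def newman_solution():
    """50 μm disk flush in an insulating plane under a uniform half-space."""
    stack = uniform_halfspace_stack()
    spec = ElectrodeSpec(ElectrodeShape.DISK, 50.0, erd=50.0)
    return solve_potential(stack, spec, current_ua=-20.0)


class TestAnalyticOracles:
    def test_equipotential_disk_on_axis(self, newman_solution):
        """On-axis potential of a flush disk matches the equipotential-disk
        closed form φ(z) = (2V0/π)·arctan(a/z), V0 = I/(4σa), within 2%."""
        a = 25e-6
        v0 = -20e-6 / (4 * SIGMA * a)
        for zeta_um in (5.0, 10.0, 25.0, 50.0, 100.0):
            ana_mv = v0 * (2 / math.pi) * math.atan(a / (zeta_um * 1e-6)) * 1e3
            num_mv = float(sample_potential(newman_solution,
                                            [[0.0, 0.0, zeta_um - 50.0]])[0])
            assert num_mv == pytest.approx(ana_mv, rel=0.02)

    def test_far_field_matches_half_space_point_source(self, newman_solution):
        """Far from the disk the potential approaches I/(2πσd) (half-space
        point source; the substrate plane is insulating) within 2%."""
        for d_um in (300.0, 500.0):
            ana_mv = -20e-6 / (2 * math.pi * SIGMA * d_um * 1e-6) * 1e3
            num_mv = float(sample_potential(newman_solution,
                                            [[0.0, 0.0, d_um - 50.0]])[0])
            assert num_mv == pytest.approx(ana_mv, rel=0.02 + d_um / 5000.0)

    def test_uniform_slab_one_dimensional_limit(self):
        """An electrode nearly as wide as the domain drives an almost
        uniform vertical field under its centre (1-D slab limit)."""
        stack = LayerStack((Layer("vitreous", SIGMA, -20.0, 0.0),
                            Layer("medium", SIGMA, 0.0, 150.0)),
                           erd=20.0, domain_radius=450.0)
        spec = ElectrodeSpec(ElectrodeShape.DISK, 800.0, erd=20.0)
        sol = solve_potential(stack, spec, current_ua=-20.0)
        prof = field_strength_profile(sol, 60.0)
        r = prof["r_um"]
        central = prof["e_v_per_m"][r < 100.0]
        assert np.ptp(central) / np.mean(central) < 0.05


class TestSolutionInvariants:
    def test_current_balance(self, disk100_erd20):
        assert disk100_erd20.current_balance_error < 0.005

    def test_linearity_of_scaling(self, disk100_erd20):
        doubled = disk100_erd20.scaled_to(-40.0)
        ratio = doubled.phi / disk100_erd20.phi
        assert np.nanmax(np.abs(ratio - 2.0)) < 1e-12
        q1 = interface_charge_density_profile(disk100_erd20)
        q2 = interface_charge_density_profile(doubled)
        assert np.allclose(q2["q_uc_per_cm2"], 2.0 * q1["q_uc_per_cm2"])

    def test_maximum_principle(self, disk100_erd20):
        phi = disk100_erd20.phi
        assert np.nanmax(np.abs(phi)) <= abs(disk100_erd20.electrode_potential) + 1e-9

    def test_electrode_surface_is_equipotential(self, disk100_erd20):
        v = sample_potential(disk100_erd20, [[0.0, 0.0, -20.4],
                                             [30.0, 0.0, -20.4]])
        assert v == pytest.approx(disk100_erd20.electrode_potential, rel=0.02)

    def test_axisymmetry_of_sampling(self, disk100_erd20):
        pts = [[60.0, 0.0, 10.0], [0.0, 60.0, 10.0],
               [60.0 / math.sqrt(2), 60.0 / math.sqrt(2), 10.0]]
        v = sample_potential(disk100_erd20, pts)
        assert np.ptp(v) < 1e-9

    def test_sampling_outside_domain_rejected(self, disk100_erd20):
        with pytest.raises(ValueError):
            sample_potential(disk100_erd20, [[0.0, 0.0, 5000.0]])

    def test_identical_specs_have_unit_field_ratio(self, disk100_erd20):
        assert max_field_ratio(disk100_erd20, disk100_erd20) == pytest.approx(1.0)


class TestFieldStructure:
    def test_large_disk_develops_rim_peaks(self, field_cache):
        """A 200 μm disk at ERD 20 concentrates field over its perimeter."""
        sol = field_cache(ElectrodeShape.DISK, 200.0, 20.0)
        prof = field_strength_profile(sol, 24.5)
        assert 70.0 <= prof["r_max_um"] <= 130.0

    def test_max_field_decreases_with_erd(self, field_cache):
        values = [max_field_in_layer(field_cache(ElectrodeShape.DISK, 50.0, erd),
                                     24.0, 73.0)
                  for erd in (20.0, 40.0, 60.0, 80.0)]
        assert np.all(np.diff(values) < 0)

    def test_edge_peaks_grow_for_smaller_disks_and_gaps(self, field_cache):
        """At matched drive current the interface charge-density peak is
        higher for smaller disks and shorter gaps (stronger edge effect)."""

        def peak(diameter, erd):
            sol = field_cache(ElectrodeShape.DISK, diameter, erd)
            return interface_charge_density_profile(sol)["peak_uc_per_cm2"]

        assert peak(50.0, 20.0) > peak(200.0, 20.0)
        assert peak(50.0, 20.0) > peak(50.0, 80.0)


class TestGridAndConvergence:
    def test_grid_is_graded_and_aligned(self):
        stack = build_layer_stack(40.0)
        spec = ElectrodeSpec(ElectrodeShape.CONVEX_CONE, 100.0, 40.0)
        grid = build_grid(stack, spec)
        assert grid.max_refinement_ratio() <= 1.3 + 1e-9
        assert 0.0 in np.round(grid.z_edges, 6)
        assert -40.0 in np.round(grid.z_edges, 6)
        fine = np.diff(grid.r_edges)[grid.r_centers < 50.0]
        assert np.max(fine) <= 0.5 + 1e-9

    def test_convergence_study_approaches_limit(self):
        stack = build_layer_stack(20.0)
        spec = ElectrodeSpec(ElectrodeShape.DISK, 100.0, 20.0)
        out = convergence_study(stack, spec, resolutions=(2.8, 2.0, 1.4, 1.0))
        changes = out["relative_changes"]
        assert changes[-1] < 0.01
        assert out["converged"]

    def test_unresolved_electrode_warns(self):
        stack = build_layer_stack(20.0)
        spec = ElectrodeSpec(ElectrodeShape.DISK, 50.0, 20.0)
        r_edges = np.linspace(0.0, 1400.0, 40)
        z_edges = np.unique(np.concatenate([
            np.linspace(-21.0, 332.0, 60), [-20.0, 0.0]]))
        grid = AxisymmetricGrid(r_edges, z_edges)
        with pytest.warns(UserWarning, match="refine"):
            solve_potential(stack, spec, grid=grid)
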