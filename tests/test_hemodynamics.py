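"""Hemodynamic maps: kinetic energy, flow decomposition, maximum velocity,
viscous energy loss, luminal summaries."""

import dataclasses

import numpy as np
import pytest

from dissectflow.core import FluidConstants, LumenMasks, VelocityField4D, VoxelGrid
from dissectflow.geometry import (
    CenterlinePlanes,
    VoxelPlaneAssignment,
    assign_voxels_to_planes,
    extract_centerline,
)
from dissectflow.hemodynamics import (
    compute_energy_loss,
    compute_flow_decomposition,
    compute_kinetic_energy,
    compute_max_velocity,
    summarize_lumen,
)

from conftest import (
    make_poiseuille_field,
    make_random_field,
    make_uniform_field,
    poiseuille_analytic_dissipation_w,
)


def straight_assignment(masks: LumenMasks) -> VoxelPlaneAssignment:
    """Trivial plane assignment with forward direction +z for every voxel."""
    idx = np.nonzero(masks.whole)
    n = len(idx[0])
    return VoxelPlaneAssignment(
        plane_index=np.zeros(n, dtype=int),
        forward_direction=np.tile([0.0, 0.0, 1.0], (n, 1)),
        voxel_indices=idx,
    )


class TestKineticEnergy:
    def test_single_voxel_unit_case(self):
        """One 1 mm^3 voxel moving at 1 m/s for one retained frame carries
        0.5 * 1060 * 1e-9 * 1 = 5.3e-7 J."""
        grid = VoxelGrid((1, 1, 1), (1.0, 1.0, 1.0))
        v = np.full((1, 1, 1, 2), 100.0)  # 1 m/s
        field = VelocityField4D(
            vx=np.zeros_like(v), vy=np.zeros_like(v), vz=v, grid=grid,
            venc=160.0, temporal_resolution=500.0, rr_interval=1000.0,
        )
        mask = np.ones((1, 1, 1), dtype=bool)
        ke_map, total = compute_kinetic_energy(field, mask)
        # two frames retained -> twice the single-frame value
        assert total == pytest.approx(2 * 5.3e-7, rel=1e-12)

    def test_zero_field(self):
        field = make_uniform_field(value=(0.0, 0.0, 0.0))
        _, total = compute_kinetic_energy(
            field, np.ones(field.grid.shape, dtype=bool)
        )
        assert total == 0.0

    def test_quadratic_velocity_scaling(self):
        field = make_random_field(np.random.default_rng(0))
        mask = np.ones(field.grid.shape, dtype=bool)
        _, ke1 = compute_kinetic_energy(field, mask)
        scaled = dataclasses.replace(
            field, vx=3.0 * field.vx, vy=3.0 * field.vy, vz=3.0 * field.vz
        )
        _, ke9 = compute_kinetic_energy(scaled, mask)
        assert ke9 == pytest.approx(9.0 * ke1, rel=1e-12)

    def test_matches_bruteforce_triple_loop(self):
        rng = np.random.default_rng(1)
        field = make_random_field(rng, shape=(3, 3, 2), n_t=3, spacing=2.0)
        mask = rng.random((3, 3, 2)) < 0.7
        mask[0, 0, 0] = True
        _, total = compute_kinetic_energy(field, mask)
        rho, dv = 1060.0, 8.0 * 1e-9
        expected = 0.0
        for idx in np.ndindex(3, 3, 2):
            if not mask[idx]:
                continue
            for t in range(3):
                v2 = sum((getattr(field, c)[idx][t] * 1e-2) ** 2
                         for c in ("vx", "vy", "vz"))
                expected += 0.5 * rho * dv * v2
        assert total == pytest.approx(expected, rel=1e-12)

    def test_empty_mask_rejected(self):
        field = make_uniform_field()
        with pytest.raises(ValueError, match="empty"):
            compute_kinetic_energy(field, np.zeros(field.grid.shape, dtype=bool))


class TestFlowDecomposition:
    def _tube(self, rng=None, negate=False):
        field = make_uniform_field(shape=(3, 3, 8), value=(0.0, 0.0, 20.0), n_t=4)
        if rng is not None:
            field = dataclasses.replace(
                field,
                vz=field.vz + rng.normal(0, 30.0, field.vz.shape),
            )
        whole = np.ones((3, 3, 8), dtype=bool)
        tl = whole.copy()
        tl[:, :, 4:] = False
        masks = LumenMasks(whole=whole, tl=tl, fl=whole & ~tl)
        return field, masks

    def test_pure_forward_flow_has_zero_reverse(self):
        field, masks = self._tube()
        ff, rf, means = compute_flow_decomposition(
            field, straight_assignment(masks), masks
        )
        assert np.all(rf == 0.0)
        assert np.all(ff[masks.whole] > 0.0)
        assert means["tl_rf"] == 0.0

    def test_velocity_negation_swaps_maps_exactly(self):
        field, masks = self._tube(rng=np.random.default_rng(2))
        asg = straight_assignment(masks)
        ff1, rf1, _ = compute_flow_decomposition(field, asg, masks)
        neg = dataclasses.replace(
            field, vx=-field.vx, vy=-field.vy, vz=-field.vz
        )
        ff2, rf2, _ = compute_flow_decomposition(neg, asg, masks)
        assert np.array_equal(ff1, rf2)
        assert np.array_equal(rf1, ff2)

    def test_single_voxel_unit_arithmetic(self):
        """10 cm/s through 1 mm^2 for a 1 s cycle is 0.1 mL."""
        grid = VoxelGrid((1, 1, 1), (1.0, 1.0, 1.0))
        v = np.full((1, 1, 1, 4), 10.0)
        field = VelocityField4D(
            vx=np.zeros_like(v), vy=np.zeros_like(v), vz=v, grid=grid,
            venc=160.0, temporal_resolution=250.0, rr_interval=1000.0,
        )
        whole = np.ones((1, 1, 1), dtype=bool)
        masks = LumenMasks(whole=whole, tl=whole, fl=np.zeros_like(whole))
        _, _, means = compute_flow_decomposition(
            field, straight_assignment(masks), masks
        )
        assert means["tl_ff"] == pytest.approx(0.1, rel=1e-12)

    def test_forward_plus_reverse_equals_total_absolute_flow(self):
        field, masks = self._tube(rng=np.random.default_rng(3))
        asg = straight_assignment(masks)
        ff, rf, _ = compute_flow_decomposition(field, asg, masks)
        area = 1e-6
        dt = field.temporal_resolution * 1e-3
        expected = np.abs(field.vz * 1e-2).sum(axis=3) * area * dt * 1e6
        assert np.allclose((ff + rf)[masks.whole], expected[masks.whole], rtol=1e-12)

    def test_linear_velocity_scaling(self):
        field, masks = self._tube(rng=np.random.default_rng(4))
        asg = straight_assignment(masks)
        _, _, m1 = compute_flow_decomposition(field, asg, masks)
        scaled = dataclasses.replace(field, vz=2.5 * field.vz)
        _, _, m2 = compute_flow_decomposition(scaled, asg, masks)
        assert m2["tl_ff"] == pytest.approx(2.5 * m1["tl_ff"], rel=1e-12)
        assert m2["fl_rf"] == pytest.approx(2.5 * m1["fl_rf"], rel=1e-12)


class TestMaxVelocity:
    def test_uniform_speed(self):
        field = make_uniform_field(shape=(5, 5, 5), value=(0.0, 0.0, 30.0))
        mask = np.ones((5, 5, 5), dtype=bool)
        mv, t_star, mv_map = compute_max_velocity(field, mask)
        assert mv == pytest.approx(0.30)
        assert t_star == 0  # earliest timepoint on ties
        assert np.allclose(mv_map[mask], 0.30)

    def test_scaling_homogeneity(self):
        field = make_random_field(np.random.default_rng(5), shape=(6, 6, 6))
        mask = np.ones((6, 6, 6), dtype=bool)
        mv1, t1, _ = compute_max_velocity(field, mask)
        scaled = dataclasses.replace(
            field, vx=2.0 * field.vx, vy=2.0 * field.vy, vz=2.0 * field.vz
        )
        mv2, t2, _ = compute_max_velocity(scaled, mask)
        assert mv2 == pytest.approx(2.0 * mv1, rel=1e-12)
        assert t1 == t2

    def test_matches_full_sort_oracle(self):
        """Timepoint selection by max 95th percentile, then mean of speeds at
        or above it, against a brute-force sort."""
        rng = np.random.default_rng(6)
        for _ in range(10):
            field = make_random_field(rng, shape=(5, 5, 4), n_t=5)
            mask = rng.random((5, 5, 4)) < 0.8
            if mask.sum() < 20:
                continue
            mv, t_star, _ = compute_max_velocity(field, mask)
            speeds = field.speed()[mask] * 1e-2
            p95 = np.percentile(speeds, 95.0, axis=0)
            t_exp = int(np.argmax(p95))
            at_t = np.sort(speeds[:, t_exp])
            expected = at_t[at_t >= p95[t_exp]].mean()
            assert t_star == t_exp
            assert mv == pytest.approx(expected, rel=1e-12)

    def test_small_mask_warns_and_uses_maximum(self):
        field = make_random_field(np.random.default_rng(7), shape=(3, 2, 2))
        mask = np.zeros((3, 2, 2), dtype=bool)
        mask[0, 0, 0] = mask[1, 1, 1] = True
        with pytest.warns(UserWarning, match="top-5%"):
            mv, _, _ = compute_max_velocity(field, mask)
        assert mv == pytest.approx(field.speed()[mask].max() * 1e-2)


class TestEnergyLoss:
    def test_uniform_translation_zero_dissipation(self):
        field = make_uniform_field(shape=(6, 6, 6), value=(10.0, -5.0, 20.0))
        mask = np.ones((6, 6, 6), dtype=bool)
        el_total, el_mean, _ = compute_energy_loss(field, mask)
        assert np.all(el_total == 0.0)
        assert np.all(el_mean == 0.0)

    def test_solid_body_rotation_zero_dissipation(self):
        """The antisymmetric velocity gradient of rigid rotation cancels in
        the symmetrized dissipation function."""
        grid = VoxelGrid((8, 8, 8), (1.0, 1.0, 1.0), (-3.5, -3.5, -3.5))
        xyz = grid.world_coordinates()
        omega = 2.0  # rad/s about z
        vx = (-omega * xyz[..., 1])[..., None].repeat(2, axis=3)
        vy = (omega * xyz[..., 0])[..., None].repeat(2, axis=3)
        field = VelocityField4D(
            vx=vx, vy=vy, vz=np.zeros_like(vx), grid=grid, venc=1e4,
            temporal_resolution=500.0, rr_interval=1000.0,
        )
        mask = np.ones((8, 8, 8), dtype=bool)
        el_total, _, _ = compute_energy_loss(field, mask)
        assert np.allclose(el_total, 0.0, atol=1e-18)

    def test_galilean_shift_invariance(self):
        """Adding a uniform velocity leaves the dissipation unchanged: all
        stencils stay inside the lumen, so the constant cancels exactly."""
        field, mask = make_poiseuille_field(spacing_mm=1.0, length_mm=20.0)
        el1, _, _ = compute_energy_loss(field, mask)
        shifted = dataclasses.replace(
            field, vx=field.vx + 15.0, vy=field.vy - 10.0, vz=field.vz + 30.0
        )
        el2, _, _ = compute_energy_loss(shifted, mask)
        assert np.allclose(el1, el2, rtol=1e-9, atol=1e-18)

    def test_poiseuille_against_hagen_poiseuille_dissipation(self):
        """Lumen-summed dissipation rate of a steady parabolic pipe flow
        approximates 8 mu L Q^2 / (pi R^4)."""
        field, mask = make_poiseuille_field(spacing_mm=1.0)
        _, el_mean, _ = compute_energy_loss(field, mask)
        analytic = poiseuille_analytic_dissipation_w(8.0, 60.0, 80.0)
        assert el_mean[mask].sum() == pytest.approx(analytic, rel=0.10)

    def test_anisotropic_grid_rejected(self):
        grid = VoxelGrid((4, 4, 4), (1.0, 1.0, 2.0))
        v = np.zeros((4, 4, 4, 2))
        field = VelocityField4D(
            vx=v.copy(), vy=v.copy(), vz=v.copy(), grid=grid, venc=160.0,
            temporal_resolution=500.0, rr_interval=1000.0,
        )
        with pytest.raises(ValueError, match="isotropic"):
            compute_energy_loss(field, np.ones((4, 4, 4), dtype=bool))


class TestSummarize:
    @pytest.fixture(scope="class")
    def analytic_phantom(self):
        """Uncorrupted straight phantom (no tear jet) with closed-form
        luminal summaries."""
        from dissectflow.phantom import PhantomConfig, generate_phantom

        cfg = PhantomConfig(
            tl_radius=8.0, fl_radius=10.0, length=40.0, grid_spacing=1.0,
            n_timepoints=16, fl_retrograde_fraction=0.3,
            tear_jet_velocity=0.0, seed=1,
        )
        field, _, masks, truth = generate_phantom(cfg)
        cl = extract_centerline(masks.tl, field.grid)
        asg = assign_voxels_to_planes(masks, cl, field.grid)
        return cfg, field, masks, asg, truth

    def test_six_scalars_match_analytic_integration(self, analytic_phantom):
        """TL/FL KE, MV and mean FF/RF against closed-form integrals of the
        parabolic-profile field: KE = 0.5 rho sum_t w(t)^2 pi R^2 L / 3,
        MV = 0.975 max_t w(t) (the top-5% band of a parabolic profile),
        mean FF/RF = A dt sum_t w(t)^{+/-} / 2."""
        from dissectflow.phantom import fl_waveform, tl_waveform

        cfg, field, masks, asg, _ = analytic_phantom
        summary = summarize_lumen(field, masks, asg)
        phase = np.arange(cfg.n_timepoints) / cfg.n_timepoints
        w_tl = tl_waveform(phase, cfg.peak_tl_velocity) * 1e-2  # m/s
        w_fl = fl_waveform(
            phase, cfg.peak_fl_velocity, cfg.fl_retrograde_fraction
        ) * 1e-2
        rho = 1060.0
        # the voxelized tube holds one slice of material per voxel center in
        # [0, length], i.e. n_z * h of tube
        L = field.grid.shape[2] * cfg.grid_spacing * 1e-3

        def ke_analytic(w, r_mm):
            r = r_mm * 1e-3
            return 0.5 * rho * (w**2).sum() * np.pi * r**2 * L / 3.0

        assert summary.tl_ke == pytest.approx(
            ke_analytic(w_tl, cfg.tl_radius), rel=0.02
        )
        assert summary.fl_ke == pytest.approx(
            ke_analytic(w_fl, cfg.fl_radius), rel=0.02
        )
        assert summary.tl_mv == pytest.approx(0.975 * w_tl.max(), rel=0.02)
        assert summary.fl_mv == pytest.approx(0.975 * w_fl.max(), rel=0.02)

        area = (cfg.grid_spacing * 1e-3) ** 2
        dt = field.temporal_resolution * 1e-3
        n_z = field.grid.shape[2]
        h2 = cfg.grid_spacing**2
        # mean parabolic profile over the lattice disk: cross-section integral
        # pi R^2 / 2 divided by the actual voxel count per slice
        mean_prof_tl = (np.pi * cfg.tl_radius**2 / 2.0 * n_z) / (
            masks.tl.sum() * h2
        )
        mean_prof_fl = (np.pi * cfg.fl_radius**2 / 2.0 * n_z) / (
            masks.fl.sum() * h2
        )
        ff_tl = area * dt * np.maximum(w_tl, 0.0).sum() * mean_prof_tl * 1e6  # mL
        rf_fl = area * dt * np.maximum(-w_fl, 0.0).sum() * mean_prof_fl * 1e6
        assert summary.tl_ff == pytest.approx(ff_tl, rel=0.02)
        assert summary.fl_rf == pytest.approx(rf_fl, rel=0.02)

    def test_doubling_velocity_quadruples_ke(self, analytic_phantom):
        cfg, field, masks, asg, _ = analytic_phantom
        s1 = summarize_lumen(field, masks, asg)
        doubled = dataclasses.replace(
            field, vx=2 * field.vx, vy=2 * field.vy, vz=2 * field.vz
        )
        s2 = summarize_lumen(doubled, masks, asg)
        assert s2.tl_ke == pytest.approx(4 * s1.tl_ke, rel=1e-12)
        assert s2.fl_ke == pytest.approx(4 * s1.fl_ke, rel=1e-12)
        assert s2.tl_mv == pytest.approx(2 * s1.tl_mv, rel=1e-12)
        assert s2.fl_rf == pytest.approx(2 * s1.fl_rf, rel=1e-12)

    def test_single_voxel_lumen_summary(self):
        grid = VoxelGrid((3, 3, 3), (1.0, 1.0, 1.0))
        v = np.zeros((3, 3, 3, 2))
        v[1, 1, 1] = [50.0, 60.0]
        field = VelocityField4D(
            vx=np.zeros_like(v), vy=np.zeros_like(v), vz=v, grid=grid,
            venc=160.0, temporal_resolution=500.0, rr_interval=1000.0,
        )
        whole = np.zeros((3, 3, 3), dtype=bool)
        whole[1, 1, 1] = True
        masks = LumenMasks(whole=whole, tl=whole, fl=np.zeros_like(whole))
        with pytest.warns(UserWarning):
            summary = summarize_lumen(field, masks, straight_assignment(masks))
        ke = 0.5 * 1060 * 1e-9 * (0.5**2 + 0.6**2)
        assert summary.tl_ke == pytest.approx(ke, rel=1e-12)
        assert summary.tl_mv == pytest.approx(0.6, rel=1e-12)
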