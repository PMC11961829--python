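"""MPM frame loop: kernel, transfers, boundary handling, frame invariants."""

import numpy as np
import pytest

from softmpm import (
    GridState,
    MaterialParams,
    OutOfDomainError,
    ParticleState,
    ParticleStatus,
    SimConfig,
    advance_frame,
    finalize_frame,
    g2p,
    grid_update,
    kernel_weights,
    make_slab,
    p2g,
)
from softmpm.mpm_core import _stencil, _all_offset_terms


def _single_particle(cfg, x, v=(0.0, 0.0), m=1e-3):
    p = ParticleState.zeros(1, cfg.d)
    p.x[0] = x
    p.v[0] = v
    p.m[:] = m
    p.V0[:] = cfg.dx**cfg.d
    return p


class TestKernel:
    def test_on_node_weights(self, small_cfg):
        base, w = kernel_weights([10 * small_cfg.dx, 7 * small_cfg.dx], small_cfg.dx)
        axis = np.array([0.125, 0.75, 0.125])
        assert np.allclose(w, np.outer(axis, axis), atol=1e-14)
        assert tuple(base) == (9, 6)

    def test_partition_of_unity_and_first_moment(self, small_cfg, rng):
        dx = small_cfg.dx
        for _ in range(20):
            x = rng.uniform(5 * dx, 20 * dx, size=2)
            base, w = kernel_weights(x, dx)
            assert w.sum() == pytest.approx(1.0, abs=1e-12)
            # first moment about the particle vanishes
            moment = np.zeros(2)
            for i in range(3):
                for j in range(3):
                    node = (base + [i, j]) * dx
                    moment += w[i, j] * (node - x)
            assert np.abs(moment).max() < 1e-12

    def test_mirror_symmetry(self, small_cfg):
        dx = small_cfg.dx
        node = 12 * dx
        for off in (0.3 * dx, 0.11 * dx):
            _, w_plus = kernel_weights([node + off, node], dx)
            _, w_minus = kernel_weights([node - off, node], dx)
            assert np.allclose(w_plus, w_minus[::-1, :], atol=1e-12)


class TestP2G:
    def test_resting_particle_scatters_mass_only(self, small_cfg, params):
        p = _single_particle(small_cfg, [10.2 * small_cfg.dx, 8.7 * small_cfg.dx])
        grid = GridState.zeros(small_cfg)
        p2g(p, grid, params, small_cfg)
        assert np.abs(grid.momentum).max() == 0.0
        assert grid.mass.sum() == pytest.approx(p.m.sum(), rel=1e-14)

    def test_mass_and_momentum_conservation(self, small_cfg, small_spec, params, rng):
        p = make_slab(small_spec, small_cfg, seed=3)
        p.v = rng.normal(0.0, 0.1, p.v.shape)
        p.C = rng.normal(0.0, 1.0, p.C.shape)
        grid = GridState.zeros(small_cfg)
        p2g(p, grid, params, small_cfg)
        assert grid.mass.sum() == pytest.approx(p.m.sum(), rel=1e-13)
        target = (p.m[:, None] * p.v).sum(axis=0)
        got = grid.momentum.reshape(-1, 2).sum(axis=0)
        assert np.allclose(got, target, rtol=1e-10, atol=1e-14)

    def test_f_update_reduces_to_apic_form_when_dv_zero(
        self, small_cfg, small_spec, params, rng
    ):
        p = make_slab(small_spec, small_cfg, seed=3)
        p.C = rng.normal(0.0, 0.5, p.C.shape)
        expected_F = (np.eye(2) + small_cfg.dt * p.C) @ p.F
        grid = GridState.zeros(small_cfg)
        p2g(p, grid, params, small_cfg)
        assert np.allclose(p.F, expected_F, rtol=1e-14)

    def test_out_of_domain_particle_reported(self, small_cfg, params):
        p = _single_particle(small_cfg, [0.0, 8.0 * small_cfg.dx])
        grid = GridState.zeros(small_cfg)
        with pytest.raises(OutOfDomainError, match="particle 0"):
            p2g(p, grid, params, small_cfg, frame=7)


class TestGridUpdate:
    def test_interior_velocity_is_momentum_over_mass(self, small_cfg):
        grid = GridState.zeros(small_cfg)
        grid.mass[10, 10] = 2.0
        grid.momentum[10, 10] = [4.0, -2.0]
        grid.mean_particle_mass = 1.0
        grid_update(grid, small_cfg)
        assert np.allclose(grid.velocity[10, 10], [2.0, -1.0])

    def test_slip_boundary_zeroes_only_inward_component(self, small_cfg):
        grid = GridState.zeros(small_cfg)
        grid.mean_particle_mass = 1.0
        grid.mass[1, 10] = 1.0
        grid.momentum[1, 10] = [-0.5, 0.25]   # moving toward low-x face
        grid.mass[1, 12] = 1.0
        grid.momentum[1, 12] = [0.5, 0.25]    # moving away: untouched
        grid_update(grid, small_cfg)
        assert np.allclose(grid.velocity[1, 10], [0.0, 0.25])
        assert np.allclose(grid.velocity[1, 12], [0.5, 0.25])

    def test_sticky_boundary_zeroes_everything(self, small_cfg):
        from dataclasses import replace

        cfg = replace(small_cfg, boundary="sticky")
        grid = GridState.zeros(cfg)
        grid.mean_particle_mass = 1.0
        grid.mass[1, 10] = 1.0
        grid.momentum[1, 10] = [0.5, 0.25]
        grid_update(grid, cfg)
        assert np.allclose(grid.velocity[1, 10], 0.0)

    def test_inactive_nodes_stay_silent(self, small_cfg):
        grid = GridState.zeros(small_cfg)
        grid.mean_particle_mass = 1.0
        grid.mass[5, 5] = 1e-20   # below threshold
        grid.momentum[5, 5] = [1.0, 1.0]
        grid_update(grid, small_cfg)
        assert np.allclose(grid.velocity[5, 5], 0.0)


class TestG2P:
    def _grid_with_velocity(self, cfg, field):
        grid = GridState.zeros(cfg)
        idx = np.indices(cfg.domain_extent).transpose(1, 2, 0) * cfg.dx
        grid.velocity = field(idx)
        return grid

    def test_uniform_field_recovered_with_zero_affine(self, small_cfg, small_spec):
        u = np.array([0.3, -0.1])
        grid = self._grid_with_velocity(small_cfg, lambda x: np.broadcast_to(
            u, x.shape).copy())
        p = make_slab(small_spec, small_cfg, seed=0)
        p.status[:] = ParticleStatus.FREE
        v_tilde, x_tilde = g2p(grid, p, small_cfg)
        assert np.allclose(v_tilde, u, atol=1e-13)
        assert np.abs(p.C).max() < 1e-9
        assert np.allclose(x_tilde, p.x + small_cfg.dt * v_tilde)

    def test_linear_field_reproduces_gradient(self, small_cfg, small_spec):
        A = np.array([[0.8, -0.3], [0.5, 0.2]])
        grid = self._grid_with_velocity(small_cfg, lambda x: x @ A.T)
        p = make_slab(small_spec, small_cfg, seed=0)
        p.status[:] = ParticleStatus.FREE
        v_tilde, _ = g2p(grid, p, small_cfg)
        assert np.allclose(v_tilde, p.x @ A.T, rtol=1e-10, atol=1e-12)
        assert np.allclose(p.C, A[None], rtol=1e-6, atol=1e-9)

    def test_fixed_particles_are_dirichlet(self, small_cfg, small_spec):
        grid = self._grid_with_velocity(small_cfg, lambda x: np.ones_like(x))
        p = make_slab(small_spec, small_cfg, seed=0)
        fixed = p.status == ParticleStatus.FIXED
        assert np.any(fixed)
        v_tilde, x_tilde = g2p(grid, p, small_cfg)
        assert np.all(v_tilde[fixed] == 0.0)
        assert np.array_equal(x_tilde[fixed], p.x[fixed])


class TestFinalize:
    def test_no_collision_means_zero_increments(self, small_cfg, small_spec, params):
        p = make_slab(small_spec, small_cfg, seed=0)
        p.v[:] = [0.05, 0.0]
        p.status[:] = ParticleStatus.FREE
        grid = GridState.zeros(small_cfg)
        p2g(p, grid, params, small_cfg)
        grid_update(grid, small_cfg)
        v_tilde, x_tilde = g2p(grid, p, small_cfg)
        finalize_frame(p, grid, p.x.copy(), x_tilde, v_tilde, small_cfg)
        assert np.abs(p.dv).max() < 1e-12
        assert np.abs(grid.dv).max() < 1e-9

    def test_displaced_particle_velocity(self, small_cfg, params):
        p = _single_particle(small_cfg, [10.0 * small_cfg.dx, 8.0 * small_cfg.dx])
        grid = GridState.zeros(small_cfg)
        p2g(p, grid, params, small_cfg)
        grid_update(grid, small_cfg)
        v_tilde, x_tilde = g2p(grid, p, small_cfg)
        delta = np.array([1e-4, 0.0])
        finalize_frame(p, grid, p.x.copy(), x_tilde + delta, v_tilde, small_cfg)
        assert np.allclose(p.v[0], delta / small_cfg.dt)

    def test_grid_dv_matches_bruteforce_scatter(self, small_cfg, params, rng):
        n = 20
        p = ParticleState.zeros(n, 2)
        p.x = rng.uniform(8 * small_cfg.dx, 20 * small_cfg.dx, (n, 2))
        p.m = rng.uniform(0.5e-3, 2e-3, n)
        p.V0[:] = small_cfg.dx**2
        grid = GridState.zeros(small_cfg)
        p2g(p, grid, params, small_cfg)
        grid_update(grid, small_cfg)
        v_tilde, x_tilde = g2p(grid, p, small_cfg)
        x_old = p.x.copy()
        x_new = x_tilde + rng.normal(0, 1e-5, x_tilde.shape)
        finalize_frame(p, grid, x_old, x_new, v_tilde, small_cfg)
        # brute-force double loop oracle
        num = np.zeros(small_cfg.domain_extent + (2,))
        for q in range(n):
            base, w = kernel_weights(x_old[q], small_cfg.dx)
            for i in range(3):
                for j in range(3):
                    num[base[0] + i, base[1] + j] += (
                        w[i, j] * p.m[q] * p.dv[q]
                    )
        expected = np.zeros_like(num)
        active = grid.mass > 0
        expected[active] = num[active] / grid.mass[active, None]
        assert np.allclose(grid.dv, expected, rtol=1e-10, atol=1e-18)


class TestAdvanceFrame:
    def test_resting_slab_stays_at_rest(self, small_cfg, small_spec, params):
        p = make_slab(small_spec, small_cfg, seed=0)
        x0 = p.x.copy()
        grid = GridState.zeros(small_cfg)
        for k in range(100):
            force = advance_frame(p, grid, params, small_cfg, frame=k)
        assert np.abs(p.x - x0).max() < 1e-8
        assert np.abs(force).max() < 1e-10
        assert np.abs(p.F - np.eye(2)).max() < 1e-10

    def test_rigid_translation_is_stress_free(self, small_cfg, small_spec, params):
        p = make_slab(small_spec, small_cfg, seed=0)
        p.status[:] = ParticleStatus.FREE
        u = np.array([0.05, 0.02])
        p.v[:] = u
        x0 = p.x.copy()
        grid = GridState.zeros(small_cfg)
        fmax = 0.0
        for k in range(100):
            force = advance_frame(p, grid, params, small_cfg, frame=k)
            fmax = max(fmax, np.abs(force).max())
        assert np.abs(p.F - np.eye(2)).max() < 1e-8
        assert fmax < 1e-8
        assert np.allclose(p.x - x0, u * small_cfg.dt * 100, atol=1e-12)

    def test_determinism_bit_identical(self, small_cfg, small_spec, params):
        def run():
            p = make_slab(small_spec, small_cfg, seed=5)
            p.v[:, 0] = 0.01
            grid = GridState.zeros(small_cfg)
            for k in range(20):
                advance_frame(p, grid, params, small_cfg, frame=k)
            return p

        a, b = run(), run()
        assert np.array_equal(a.x, b.x)
        assert np.array_equal(a.v, b.v)
        assert np.array_equal(a.F, b.F)

    def test_cfl_warning(self, small_cfg, params):
        p = _single_particle(small_cfg, [10.0 * small_cfg.dx, 8.0 * small_cfg.dx])
        p.v[0] = [100.0, 0.0]   # dt*v well beyond half a cell
        grid = GridState.zeros(small_cfg)
        with pytest.warns(RuntimeWarning, match="unstable"):
            advance_frame(p, grid, params, small_cfg, frame=0)


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(d=4),
            dict(dx=0.0),
            dict(dt=-1.0),
            dict(bc_margin=1),
            dict(domain_extent=(64,)),
            dict(boundary="free"),
            dict(damping=1.5),
        ],
    )
    def test_invalid_config_rejected(self, kwargs):
        base = dict(domain_extent=(64, 32))
        base.update(kwargs)
        with pytest.raises(ValueError):
            SimConfig(**base)
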