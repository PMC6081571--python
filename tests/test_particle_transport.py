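"""Lagrangian transport: seeding, drag integration, deposition, hand-off."""

import math
import warnings
from dataclasses import replace

import numpy as np
import pytest
from scipy.stats import kstest

from aerotree.airway_model import AirwayTree, Branch, CrossSection
from aerotree.boundary_conditions import (
    DEFAULT_FLUID,
    cunningham,
    propagate_flows,
    relaxation_time,
)
from aerotree.flow_field import build_frames
from aerotree.particle_transport import (
    FATE_DEPOSITED,
    ParticleState,
    ReleaseSpec,
    TransportConfig,
    advance,
    advance_velocity,
    detect_deposition,
    run_ensemble,
    seed_particles,
)

G = 9.81


def _circle(r):
    return (
        CrossSection(area=math.pi * r**2, perimeter=2 * math.pi * r, station=0.0),
        CrossSection(area=math.pi * r**2, perimeter=2 * math.pi * r, station=1.0),
    )


def _y_tree(theta_deg=35.0, r_parent=6e-3, r_child=4.5e-3):
    """Parent along +z with two symmetric daughters: hand-off testbed."""
    th = math.radians(theta_deg)
    d1 = np.array([math.sin(th), 0.0, math.cos(th)])
    d2 = np.array([-math.sin(th), 0.0, math.cos(th)])
    L = 0.04
    return AirwayTree(
        [
            Branch(id="t", parent_id=None, length=L, origin=np.zeros(3),
                   direction=np.array([0.0, 0.0, 1.0]),
                   cross_sections=_circle(r_parent), generation=0),
            Branch(id="a", parent_id="t", length=L, origin=np.array([0, 0, L]),
                   direction=d1, cross_sections=_circle(r_child),
                   lobe="RUL", generation=1),
            Branch(id="b", parent_id="t", length=L, origin=np.array([0, 0, L]),
                   direction=d2, cross_sections=_circle(r_child),
                   lobe="RLL", generation=1),
        ]
    )


class TestSeeding:
    def test_count_and_extent(self, healthy_frames):
        rs = ReleaseSpec(n_particles=10000, seed_radius=5e-3, rng_seed=1)
        frame = healthy_frames["Trachea"]
        pos, vel = seed_particles(rs, 0, frame, 10e-6)
        assert pos.shape == (10000, 3) and vel.shape == (10000, 3)
        s, x, y = frame.local_coords(pos)
        k = math.sqrt(math.pi * 5e-3**2 / (math.pi * frame.a0 * frame.b0))
        r2 = (x / frame.b0) ** 2 + (y / frame.a0) ** 2
        assert np.all(r2 <= k**2 * (1 + 1e-9))
        assert np.all((s >= 0) & (s <= rs.seed_depth + 1e-12))

    def test_area_uniform_radial_distribution(self, healthy_frames):
        """KS: squared normalized radius is uniform (area-uniform sampling)."""
        rs = ReleaseSpec(n_particles=10000, seed_radius=5e-3, rng_seed=2)
        frame = healthy_frames["Trachea"]
        pos, _ = seed_particles(rs, 0, frame, 10e-6)
        _, x, y = frame.local_coords(pos)
        k2 = (math.pi * 5e-3**2) / (math.pi * frame.a0 * frame.b0)
        r2 = ((x / frame.b0) ** 2 + (y / frame.a0) ** 2) / k2
        assert kstest(r2, "uniform").pvalue > 0.01

    def test_deterministic_per_release_substream(self, healthy_frames):
        rs = ReleaseSpec(n_particles=500, seed_radius=5e-3, rng_seed=3)
        frame = healthy_frames["Trachea"]
        p1, _ = seed_particles(rs, 4, frame, 10e-6)
        p2, _ = seed_particles(rs, 4, frame, 2.5e-6)  # size-independent
        p3, _ = seed_particles(rs, 5, frame, 10e-6)
        np.testing.assert_array_equal(p1, p2)
        assert not np.array_equal(p1, p3)

    def test_velocity_matches_local_fluid(self, healthy_frames):
        from aerotree.flow_field import velocity_field

        rs = ReleaseSpec(n_particles=200, seed_radius=5e-3, rng_seed=4)
        frame = healthy_frames["Trachea"]
        pos, vel = seed_particles(rs, 0, frame, 10e-6)
        ref, _ = velocity_field(frame, pos)
        np.testing.assert_allclose(vel, ref, rtol=1e-12)


class TestDragIntegration:
    def test_settling_terminal_velocity_closed_form(self):
        """10 um particle in still air reaches tau_p g (rho_p-rho_f)/rho_p."""
        d, rho_p = 10e-6, 1000.0
        tau = relaxation_time(d, rho_p, DEFAULT_FLUID.mu_f)
        p = ParticleState(
            position=np.zeros(3), velocity=np.zeros(3), diameter=d, rho_p=rho_p
        )
        dt = tau / 10.0
        for _ in range(200):  # 20 relaxation times
            p = advance(p, np.zeros(3), dt)
        v_expected = tau * G * (rho_p - DEFAULT_FLUID.rho_f) / rho_p
        assert np.linalg.norm(p.velocity) == pytest.approx(v_expected, rel=1e-3)
        assert v_expected == pytest.approx(3.0e-3, abs=0.1e-3)  # ~3 mm/s
        assert p.velocity[1] < 0  # settles along -y (supine gravity)

    def test_equilibrium_velocity_is_fixed_point(self):
        tau = relaxation_time(5e-6, 1000.0, DEFAULT_FLUID.mu_f)
        u = np.array([1.0, 0.2, -0.4])
        g_eff = np.array([0.0, -G, 0.0]) * (1000.0 - DEFAULT_FLUID.rho_f) / 1000.0
        v_eq = u + tau * g_eff
        v_next = advance_velocity(v_eq.copy(), u, tau, g_eff, dt=7 * tau)
        np.testing.assert_allclose(v_next, v_eq, rtol=1e-12)

    def test_tracer_limit_tracks_fluid_in_one_step(self):
        p = ParticleState(
            position=np.zeros(3), velocity=np.array([5.0, 0.0, 0.0]), diameter=0.0
        )
        u = np.array([0.0, 0.0, 1.3])
        p = advance(p, u, 1e-3)
        np.testing.assert_allclose(p.velocity, u, rtol=1e-12)
        np.testing.assert_allclose(p.position, u * 1e-3, rtol=1e-12)

    def test_nonpositive_dt_rejected(self):
        p = ParticleState(np.zeros(3), np.zeros(3), 1e-6)
        with pytest.raises(ValueError):
            advance(p, np.zeros(3), 0.0)


class TestDepositionDetection:
    def test_point_outside_lumen_deposits(self, healthy_frames):
        f = healthy_frames["Trachea"]
        p = ParticleState(
            position=f.origin + 0.5 * f.length * f.axis + 2 * f.a0 * f.normal_v,
            velocity=np.zeros(3), diameter=10e-6,
        )
        p = detect_deposition(p, f)
        assert p.fate == FATE_DEPOSITED
        assert p.branch_id == "Trachea"

    def test_point_inside_lumen_unchanged(self, healthy_frames):
        f = healthy_frames["Trachea"]
        p = ParticleState(
            position=f.origin + 0.5 * f.length * f.axis,
            velocity=np.zeros(3), diameter=10e-6,
        )
        assert detect_deposition(p, f).fate == "in_domain"


def _run_y_tree(fractions, n=10000, diameters=(0.0,), seed=11):
    tree = _y_tree()
    flow = propagate_flows(tree, fractions, 3.27e-4)
    rs = ReleaseSpec(
        n_particles=n, n_releases=1, diameters=diameters, rng_seed=seed
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return run_ensemble(
            tree, flow, rs, TransportConfig(turbulence=None, gravity=(0, 0, 0))
        ), tree


class TestBifurcationHandoff:
    def test_symmetric_split_within_binomial_error(self):
        s, tree = _run_y_tree({"a": 0.5, "b": 0.5})
        tal = s.tallies[0.0][0]
        n = tal.entering["a"] + tal.entering["b"]
        sigma = math.sqrt(n * 0.25)
        assert abs(tal.entering["a"] - 0.5 * n) <= 3 * sigma

    def test_seventy_thirty_split_follows_flow(self):
        s, tree = _run_y_tree({"a": 0.7, "b": 0.3}, seed=12)
        tal = s.tallies[0.0][0]
        n = tal.entering["a"] + tal.entering["b"]
        sigma = math.sqrt(n * 0.7 * 0.3)
        assert abs(tal.entering["a"] - 0.7 * n) <= 3 * sigma

    def test_tracers_never_deposit_in_straight_branches(self):
        s, _ = _run_y_tree({"a": 0.6, "b": 0.4}, n=4000, seed=13)
        assert s.tallies[0.0][0].deposited_total == 0

    def test_terminal_exit_records_lobe_advection(self):
        s, _ = _run_y_tree({"a": 0.5, "b": 0.5}, n=2000, seed=14)
        tal = s.tallies[0.0][0]
        assert tal.lobe_advection["RUL"] > 0
        assert tal.lobe_advection["RLL"] > 0
        assert tal.lobe_advection["RUL"] + tal.lobe_advection["RLL"] == (
            tal.advected_total
        )


class TestBookkeeping:
    def test_release_conservation(self, tracer_summary, inertial_summary):
        for summary in (tracer_summary, inertial_summary):
            for tallies in summary.tallies.values():
                for t in tallies:
                    assert (
                        t.deposited_total + t.advected_total + t.stranded_total
                        == t.released
                    )

    def test_lobe_taxonomy_identity(self, healthy_tree, inertial_summary):
        """distribution = lobar deposition + advection + stranded in lobe."""
        for tallies in inertial_summary.tallies.values():
            for t in tallies:
                for lobe in ("RUL", "RML", "RLL", "LUL", "LLL"):
                    stranded_in_lobe = sum(
                        t.stranded[bid]
                        for bid, b in healthy_tree.branches.items()
                        if b.lobe == lobe
                    )
                    assert t.lobe_distribution[lobe] == (
                        t.lobe_deposition[lobe]
                        + t.lobe_advection[lobe]
                        + stranded_in_lobe
                    )

    def test_deposition_increases_with_size(self, inertial_summary):
        dep5 = sum(t.deposited_total for t in inertial_summary.tallies[5e-6])
        dep10 = sum(t.deposited_total for t in inertial_summary.tallies[10e-6])
        assert dep10 > dep5

    def test_ensemble_mean_converges_with_releases(self, healthy_tree, healthy_flow):
        """Cumulative-mean error against the known tracer truth shrinks."""
        rs = ReleaseSpec(
            n_particles=2000, n_releases=6, diameters=(0.0,), rng_seed=17
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            s = run_ensemble(
                healthy_tree, healthy_flow, rs, TransportConfig(turbulence=None)
            )
        truth = sum(
            v for t, v in healthy_flow.f_terminal.items()
            if healthy_tree.branches[t].lobe == "RLL"
        )
        fracs = np.array(
            [
                t.lobe_distribution["RLL"] / sum(t.lobe_distribution.values())
                for t in s.tallies[0.0]
            ]
        )
        cum = np.cumsum(fracs) / np.arange(1, 7)
        early = np.abs(cum[:2] - truth).max()
        late = np.abs(cum[4:] - truth).min()
        assert late <= early + 1e-12

    def test_releases_are_distinct_but_reproducible(
        self, healthy_tree, healthy_flow, healthy_frames
    ):
        from aerotree.particle_transport import run_release

        rs = ReleaseSpec(n_particles=500, n_releases=3, diameters=(0.0,), rng_seed=19)
        cfg = TransportConfig(turbulence=None)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            a = run_release(healthy_tree, healthy_flow, healthy_frames, rs, 0.0, 0, cfg)
            b = run_release(healthy_tree, healthy_flow, healthy_frames, rs, 0.0, 0, cfg)
            c = run_release(healthy_tree, healthy_flow, healthy_frames, rs, 0.0, 1, cfg)
        assert a.entering == b.entering and a.deposited == b.deposited
        assert a.entering != c.entering
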