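"""Unit tests for the Langevin integrator, system setup and trajectory I/O."""

import numpy as np
import pytest

from prkap.cg_builder import CGModel, _backbone_bonds, build_polypr
from prkap.constants import KB, RESIDUE_MASS
from prkap.forcefield import ForceFieldParams, TotalForceField
from prkap.simulator import (
    ChainSpec,
    SimulationConfig,
    SystemState,
    Trajectory,
    _chunk,
    initialize_system,
    kabsch_rmsd,
    langevin_step,
    read_trajectory,
    run_simulation,
    write_trajectory,
)


def single_bead(aa="R"):
    return CGModel(sequence=aa, positions=np.zeros((1, 3)),
                   charges=[1.0 if aa == "R" else 0.0], aromatic=[False],
                   structured_mask=[False], backbone_bonds=_backbone_bonds(1),
                   elastic_pairs=np.zeros((0, 2), int), elastic_rest=np.zeros(0))


class TestSimulationConfig:
    def test_validation(self):
        with pytest.raises(ValueError):
            SimulationConfig(timestep=0.0)
        with pytest.raises(ValueError):
            SimulationConfig(equilibration_fraction=1.0)
        with pytest.raises(ValueError):
            SimulationConfig(save_interval=0)


class TestInitializeSystem:
    def test_single_chain_centered_no_overlap(self, toy_receptor, params):
        model, _, _ = toy_receptor
        cfg = SimulationConfig(chains=[ChainSpec(model, "receptor")],
                               box=20.0, seed=1, n_steps=0)
        state = initialize_system(cfg, params)
        center = state.positions.mean(axis=0)
        np.testing.assert_allclose(center, 10.0, atol=1.5)

    def test_same_seed_identical_state(self, toy_receptor, params, pr7):
        model, _, _ = toy_receptor
        cfg = SimulationConfig(chains=[ChainSpec(model, "receptor"),
                                       ChainSpec(pr7, "pr")],
                               box=14.0, seed=42, n_steps=0)
        s1 = initialize_system(cfg, params)
        s2 = initialize_system(cfg, params)
        np.testing.assert_array_equal(s1.positions, s2.positions)
        np.testing.assert_array_equal(s1.velocities, s2.velocities)

    def test_interchain_separation(self, toy_receptor, params, pr7):
        model, _, _ = toy_receptor
        cfg = SimulationConfig(chains=[ChainSpec(model, "receptor"),
                                       ChainSpec(pr7, "pr", 3)],
                               box=16.0, seed=5, n_steps=0)
        state = initialize_system(cfg, params)
        n_rec = model.n_beads
        rec = state.positions[:n_rec]
        box = cfg.box
        for c in range(3):
            chain = state.positions[n_rec + 14 * c: n_rec + 14 * (c + 1)]
            d = rec[:, None, :] - chain[None, :, :]
            d -= box * np.rint(d / box)
            # minimisation may pull bound pairs closer, but never into overlap
            assert np.linalg.norm(d, axis=-1).min() > 0.3

    def test_placement_failure_suggests_larger_box(self, params):
        big = build_polypr(120, seed=0)
        cfg = SimulationConfig(chains=[ChainSpec(big, "pr", 40)],
                               box=6.0, seed=0, n_steps=0)
        with pytest.raises(ValueError, match="box"):
            initialize_system(cfg, params, max_retries=5)

    def test_maxwell_boltzmann_kinetic_energy(self, params, pr7):
        """Initial KE per DOF ~ kT/2 averaged over many seeds."""
        kes = []
        for seed in range(40):
            cfg = SimulationConfig(chains=[ChainSpec(pr7, "pr")], box=14.0,
                                   seed=seed, n_steps=0)
            state = initialize_system(cfg, params)
            kes.append(state.kinetic_energy() / (3 * pr7.n_beads))
        assert np.mean(kes) == pytest.approx(KB * 300.0 / 2.0, rel=0.05)


class TestLangevinStep:
    def test_free_flight_drift(self):
        """Zero T, zero friction, zero force: pure drift x += v*dt."""
        params = ForceFieldParams(salt_mM=200.0)
        model = single_bead("S")  # neutral, no bonds
        ff = TotalForceField([model], ["pr"], 20.0, params)
        pos = np.array([[10.0, 10.0, 10.0]])
        vel = np.array([[1.0, -2.0, 0.5]])
        state = SystemState(ff=ff, positions=pos.copy(), velocities=vel.copy(),
                            forces=np.zeros((1, 3)),
                            rng=np.random.default_rng(0))
        cfg = SimulationConfig(chains=[], temperature=0.0, friction=0.0,
                               timestep=0.02, box=20.0, n_steps=0)
        for _ in range(10):
            langevin_step(state, params, cfg)
        np.testing.assert_allclose(state.positions, pos + vel * 0.2, rtol=1e-12)
        np.testing.assert_allclose(state.velocities, vel, rtol=1e-12)

    def test_harmonic_variance_equipartition(self):
        """Tethered bead: positional variance per coordinate == kT/k."""
        params = ForceFieldParams(salt_mM=200.0)
        model = single_bead("R")
        k = 100.0
        center = np.array([[10.0, 10.0, 10.0]])
        ff = TotalForceField([model], ["pr"], 20.0, params,
                             restraints=([0], k, center))
        rng = np.random.default_rng(7)
        state = SystemState(ff=ff, positions=center.copy(),
                            velocities=rng.standard_normal((1, 3))
                            * np.sqrt(KB * 300 / ff.mass[0]),
                            forces=np.zeros((1, 3)), rng=rng)
        cfg = SimulationConfig(chains=[], friction=2.0, timestep=0.02,
                               box=20.0, n_steps=0)
        samples = []
        for _ in range(1500):
            _chunk(state, cfg, params, 250)
            samples.append(state.positions[0] - center[0])
        var = np.array(samples).var(axis=0).mean()
        assert var == pytest.approx(KB * 300.0 / k, rel=0.05)

    def test_energy_conservation_deterministic_limit(self):
        """gamma=0, T=0 on a bonded dimer: energy conserved to O(dt^2)."""
        params = ForceFieldParams(salt_mM=200.0)
        model = build_polypr(1, seed=0)  # two bonded beads
        ff = TotalForceField([model], ["pr"], 20.0, params)
        pos = np.array([[10.0, 10, 10], [10.42, 10, 10]])  # stretched bond
        vel = np.zeros((2, 3))
        f0, rep0 = ff.compute(pos)
        state = SystemState(ff=ff, positions=pos.copy(), velocities=vel,
                            forces=f0, rng=np.random.default_rng(0))
        cfg = SimulationConfig(chains=[], temperature=0.0, friction=0.0,
                               timestep=0.002, box=20.0, n_steps=0)
        e0 = rep0.total
        drift = 0.0
        for _ in range(100):
            _chunk(state, cfg, params, 1000)
            e = (ff.energy(state.positions).total + state.kinetic_energy())
            drift = max(drift, abs(e - e0))
        assert drift < 0.02 * abs(e0) + 1e-3


class TestRunSimulation:
    def test_zero_steps_single_frame(self, params, pr7):
        cfg = SimulationConfig(chains=[ChainSpec(pr7, "pr")], box=14.0,
                               seed=2, n_steps=0)
        traj = run_simulation(cfg, params)
        assert traj.n_frames == 1
        assert traj.times[0] == 0.0

    def test_determinism(self, params, pr7, toy_receptor):
        model, _, _ = toy_receptor
        cfg = SimulationConfig(chains=[ChainSpec(model, "receptor"),
                                       ChainSpec(pr7, "pr")],
                               box=12.0, seed=9, n_steps=2000, save_interval=500)
        t1 = run_simulation(cfg, params)
        t2 = run_simulation(cfg, params)
        np.testing.assert_array_equal(t1.positions, t2.positions)
        np.testing.assert_array_equal(t1.times, t2.times)

    def test_frame_count_and_times(self, params, pr7):
        cfg = SimulationConfig(chains=[ChainSpec(pr7, "pr")], box=14.0,
                               seed=2, n_steps=2200, save_interval=500)
        traj = run_simulation(cfg, params)
        assert traj.n_frames == 1 + 5  # 4 full chunks + remainder
        assert np.all(np.diff(traj.times) > 0)
        assert traj.times[-1] == pytest.approx(2200 * 0.02)

    def test_elastic_network_holds_structure(self, params, toy_receptor):
        model, _, _ = toy_receptor
        pr = build_polypr(10, seed=4)
        cfg = SimulationConfig(chains=[ChainSpec(model, "receptor"),
                                       ChainSpec(pr, "pr")],
                               box=12.0, seed=3, n_steps=20000, save_interval=2000)
        traj = run_simulation(cfg, params)
        ridx = traj.beads_with_role("receptor")
        ref = traj.positions[0][ridx]
        for frame in traj.positions[1:]:
            assert kabsch_rmsd(ref, frame[ridx]) < 0.5


class TestTrajectoryIO:
    def _traj(self, rng, frames=20, beads=17):
        pos = rng.normal(0, 3, (frames, beads, 3))
        return Trajectory(times=np.arange(frames, dtype=float) * 10.0,
                          positions=pos, box=25.0,
                          chain_map=[{"chain_id": "R", "role": "receptor",
                                      "start": 0, "stop": 10},
                                     {"chain_id": "P", "role": "pr",
                                      "start": 10, "stop": beads}],
                          kinetic=rng.random(frames),
                          energies=rng.normal(0, 1, (frames, 6)))

    def test_roundtrip_exact(self, tmp_path, rng):
        traj = self._traj(rng)
        path = tmp_path / "t.traj"
        write_trajectory(traj, path)
        clone = read_trajectory(path)
        np.testing.assert_array_equal(clone.positions, traj.positions)
        np.testing.assert_array_equal(clone.times, traj.times)
        np.testing.assert_array_equal(clone.kinetic, traj.kinetic)
        np.testing.assert_array_equal(clone.energies, traj.energies)
        assert clone.chain_map == traj.chain_map
        assert clone.box == traj.box

    def test_same_seed_identical_bytes(self, tmp_path, params, pr7):
        cfg = SimulationConfig(chains=[ChainSpec(pr7, "pr")], box=14.0,
                               seed=6, n_steps=1000, save_interval=250)
        p1, p2 = tmp_path / "a.traj", tmp_path / "b.traj"
        write_trajectory(run_simulation(cfg, params), p1)
        write_trajectory(run_simulation(cfg, params), p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_bad_magic_is_error(self, tmp_path):
        path = tmp_path / "bad.traj"
        path.write_bytes(b"NOTATRAJ" + b"\x00" * 64)
        with pytest.raises(ValueError, match="not a prkap"):
            read_trajectory(path)

    def test_truncated_file_is_error(self, tmp_path, rng):
        traj = self._traj(rng)
        path = tmp_path / "t.traj"
        write_trajectory(traj, path)
        data = path.read_bytes()
        path.write_bytes(data[: len(data) // 2])
        with pytest.raises(ValueError, match="truncated"):
            read_trajectory(path)

    def test_nondecreasing_times_rejected(self, rng):
        with pytest.raises(ValueError, match="increasing"):
            Trajectory(times=[0.0, 0.0], positions=np.zeros((2, 3, 3)),
                       box=10.0, chain_map=[])


class TestGeometryHelpers:
    def test_kabsch_rmsd_invariant_to_rigid_motion(self, rng):
        P = rng.normal(0, 1, (30, 3))
        theta = 0.7
        R = np.array([[np.cos(theta), -np.sin(theta), 0],
                      [np.sin(theta), np.cos(theta), 0], [0, 0, 1.0]])
        Q = P @ R.T + np.array([3.0, -1.0, 2.0])
        assert kabsch_rmsd(P, Q) < 1e-10

    def test_kabsch_rmsd_detects_distortion(self, rng):
        P = rng.normal(0, 1, (30, 3))
        Q = P.copy()
        Q[0] += 2.0
        assert kabsch_rmsd(P, Q) > 0.1

    def test_min_image_consistency(self, params, pr7, toy_receptor):
        """Contact statistics are invariant to shifting coordinates by
        whole box lengths (wrapping convention)."""
        from prkap.contact_analysis import compute_contact_results
        model, _, _ = toy_receptor
        cfg = SimulationConfig(chains=[ChainSpec(model, "receptor"),
                                       ChainSpec(pr7, "pr")],
                               box=12.0, seed=8, n_steps=5000, save_interval=500)
        traj = run_simulation(cfg, params)
        res1 = compute_contact_results(traj)
        shifted = Trajectory(times=traj.times,
                             positions=traj.positions + traj.box * 3.0,
                             box=traj.box, chain_map=traj.chain_map)
        res2 = compute_contact_results(shifted)
        assert res1.ct == res2.ct
        assert res1.pb == res2.pb
        np.testing.assert_array_equal(res1.residue_profile, res2.residue_profile)


class TestExports:
    def test_pdb_topology_roundtrip(self, tmp_path, pr7):
        from prkap.simulator import export_pdb_topology
        from prkap.cg_builder import parse_calpha_trace
        path = tmp_path / "top.pdb"
        export_pdb_topology([pr7], ["pr"], path)
        trace = parse_calpha_trace(path.read_text(), "A")
        assert trace.sequence == pr7.sequence
        np.testing.assert_allclose(trace.positions, pr7.positions, atol=1e-4)

    def test_dcd_export_readable(self, tmp_path, rng):
        import MDAnalysis as mda
        from prkap.simulator import export_dcd
        pos = rng.normal(5, 1, (4, 9, 3))
        traj = Trajectory(times=np.arange(4.0), positions=pos, box=20.0,
                          chain_map=[{"chain_id": "P", "role": "pr",
                                      "start": 0, "stop": 9}])
        path = tmp_path / "t.dcd"
        export_dcd(traj, path)
        u = mda.Universe.empty(9, trajectory=True)
        u.load_new(str(path))
        assert len(u.trajectory) == 4
        u.trajectory[2]
        np.testing.assert_allclose(u.atoms.positions, pos[2] * 10.0, atol=1e-3)
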