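"""NVT Langevin dynamics in a cubic periodic box.

The integrator is a BAOAB splitting of Langevin dynamics with protocol
defaults of 300 K, a 0.02 ps timestep and a 0.02 ps^-1 friction
coefficient; run lengths default to desk scale.  Trajectories are fully
deterministic given (seed, config, params).
"""

from __future__ import annotations

import json
import math
import struct
from dataclasses import dataclass, field

import numpy as np

from . import _kernels
from .cg_builder import CGModel
from .constants import KB
from .forcefield import EnergyReport, ForceFieldParams, TotalForceField

__all__ = [
    "ChainSpec",
    "SimulationConfig",
    "Trajectory",
    "SystemState",
    "initialize_system",
    "langevin_step",
    "run_simulation",
    "write_trajectory",
    "read_trajectory",
    "kabsch_rmsd",
]

_MAGIC = b"PRKPTRJ1"


@dataclass
class ChainSpec:
    model: CGModel
    role: str  # "receptor" | "pr"
    copies: int = 1


@dataclass
class SimulationConfig:
    chains: list = field(default_factory=list)  # list of ChainSpec
    temperature: float = 300.0
    timestep: float = 0.02  # ps
    friction: float = 0.02  # ps^-1
    box: float = 15.0  # nm
    n_steps: int = 100000
    save_interval: int = 500
    seed: int = 0
    equilibration_fraction: float = 0.2

    def __post_init__(self) -> None:
        if self.timestep <= 0:
            raise ValueError("timestep must be positive")
        if not 0 <= self.equilibration_fraction < 1:
            raise ValueError("equilibration_fraction must lie in [0, 1)")
        if self.save_interval < 1:
            raise ValueError("save_interval must be >= 1")
        if self.n_steps < 0:
            raise ValueError("n_steps must be >= 0")
        if self.box <= 0:
            raise ValueError("box edge must be positive")


@dataclass
class SystemState:
    ff: TotalForceField
    positions: np.ndarray
    velocities: np.ndarray
    forces: np.ndarray
    rng: np.random.Generator
    time: float = 0.0
    step: int = 0

    def kinetic_energy(self) -> float:
        return float(0.5 * np.sum(self.ff.mass[:, None] * self.velocities**2))


@dataclass
class Trajectory:
    """Time-stamped frames of all bead positions in a periodic cubic box."""

    times: np.ndarray  # (F,) ps
    positions: np.ndarray  # (F, N, 3) nm
    box: float
    chain_map: list  # [{"chain_id", "role", "start", "stop"}, ...]
    kinetic: np.ndarray | None = None  # (F,) kJ/mol
    energies: np.ndarray | None = None  # (F, 6) per-term potential energies

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 3:
            raise ValueError("positions must be (frames, beads, 3)")
        if len(self.times) != len(self.positions):
            raise ValueError("frame count mismatch between times and positions")
        if len(self.times) > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("frame times must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return len(self.times)

    @property
    def n_beads(self) -> int:
        return self.positions.shape[1]

    def beads_with_role(self, role: str) -> np.ndarray:
        idx = []
        for entry in self.chain_map:
            if entry["role"] == role:
                idx.extend(range(entry["start"], entry["stop"]))
        return np.array(idx, dtype=np.int64)

    def chains_with_role(self, role: str) -> list:
        return [e for e in self.chain_map if e["role"] == role]

    def production_slice(self, equilibration_fraction: float = 0.2) -> slice:
        skip = int(math.floor(self.n_frames * equilibration_fraction))
        if skip >= self.n_frames:
            raise ValueError("no production frames after equilibration discard")
        return slice(skip, self.n_frames)


# ---------------------------------------------------------------------------


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotation matrix (QR of a Gaussian matrix)."""
    m = rng.standard_normal((3, 3))
    q, r = np.linalg.qr(m)
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q


def initialize_system(config: SimulationConfig, params: ForceFieldParams,
                      max_retries: int = 500) -> SystemState:
    """Place chains at seeded random positions/orientations and draw
    Maxwell-Boltzmann velocities.

    The first receptor chain is centred in the box; every other chain is
    placed with a minimum inter-chain bead distance of one excluded-volume
    diameter.
    """
    if not config.chains:
        raise ValueError("no chains configured")
    models = []
    roles = []
    for spec in config.chains:
        for _c in range(spec.copies):
            models.append(spec.model)
            roles.append(spec.role)
    ff = TotalForceField(models, roles, config.box, params)

    rng = np.random.default_rng(config.seed)
    box = config.box
    placed: list[np.ndarray] = []
    order = sorted(range(len(models)),
                   key=lambda i: 0 if roles[i] == "receptor" else 1)
    coords = [None] * len(models)
    first_receptor_done = False
    for i in order:
        pos = models[i].positions - models[i].positions.mean(axis=0)
        if roles[i] == "receptor" and not first_receptor_done:
            cand = pos + box / 2.0
            if placed and _min_interchain_distance(cand, placed, box) < params.ev_diameter:
                raise ValueError("receptor placement overlaps; increase the box")
            coords[i] = cand
            placed.append(cand)
            first_receptor_done = True
            continue
        ok = False
        for _try in range(max_retries):
            rot = _random_rotation(rng)
            center = rng.uniform(0.0, box, size=3)
            cand = pos @ rot.T + center
            if not placed or _min_interchain_distance(cand, placed, box) >= params.ev_diameter:
                ok = True
                break
        if not ok:
            raise ValueError("chain placement failed after bounded retries; "
                             "increase the box edge")
        coords[i] = cand
        placed.append(cand)

    positions = np.concatenate(coords, axis=0)
    positions = _minimize(ff, positions)
    kT = KB * config.temperature
    sigma = np.sqrt(kT / ff.mass)[:, None]
    velocities = rng.standard_normal((ff.n_beads, 3)) * sigma
    forces, _report = ff.compute(positions)
    return SystemState(ff=ff, positions=positions, velocities=velocities,
                       forces=forces, rng=rng)


def _minimize(ff: TotalForceField, positions: np.ndarray,
              max_steps: int = 300, max_move: float = 0.02,
              ftol: float = 50.0) -> np.ndarray:
    """Capped steepest descent to relax build-geometry strain before dynamics."""
    pos = positions.copy()
    for _ in range(max_steps):
        forces, _rep = ff.compute(pos)
        fmax = float(np.abs(forces).max())
        if fmax < ftol:
            break
        pos = pos + forces * (max_move / fmax)
    return pos


def _min_interchain_distance(cand: np.ndarray, placed: list, box: float) -> float:
    best = np.inf
    for other in placed:
        d = cand[:, None, :] - other[None, :, :]
        d -= box * np.rint(d / box)
        r = np.sqrt((d**2).sum(axis=-1)).min()
        best = min(best, float(r))
    return best


def _chunk(state: SystemState, config: SimulationConfig,
           params: ForceFieldParams, n: int):
    """Advance ``n`` BAOAB steps using the compiled kernel."""
    ff = state.ff
    noise = state.rng.standard_normal((n, ff.n_beads, 3))
    kT = KB * config.temperature
    energies, r_min = _kernels._integrate_chunk(
        state.positions, state.velocities, 1.0 / ff.mass, noise,
        config.timestep, config.friction, kT, config.box,
        ff.charge, ff.cationic, ff.aromatic, ff.hydro, ff.chain_index, ff.role,
        ff.bond_i, ff.bond_j, ff.bond_r0, params.backbone_k,
        ff.el_i, ff.el_j, ff.el_r0, params.elastic_k,
        ff.ang_i, ff.ang_j, ff.ang_k, ff.ang_kf, ff.ang_t0,
        ff.tor_i, ff.tor_j, ff.tor_k, ff.tor_l, ff.tor_kf, ff.tor_p0,
        ff.tet_idx, ff.tet_k, ff.tet_c,
        ff._p, params.skin, state.forces)
    state.step += n
    state.time += n * config.timestep
    if not np.isfinite(state.positions).all() or not np.isfinite(state.forces).all():
        raise RuntimeError(f"non-finite coordinates or forces at step {state.step}")
    if r_min <= 1.0e-6:
        raise RuntimeError(f"overlapping beads at step {state.step}")
    return energies


def langevin_step(state: SystemState, params: ForceFieldParams,
                  config: SimulationConfig) -> SystemState:
    """One BAOAB Langevin update, in place (returns the state)."""
    _chunk(state, config, params, 1)
    return state


def run_simulation(config: SimulationConfig,
                   params: ForceFieldParams) -> Trajectory:
    """Integrate the configured system and collect frames.

    The initial configuration is always stored as frame 0; afterwards one
    frame is stored every ``save_interval`` steps.  ``n_steps == 0``
    yields a single-frame trajectory.
    """
    state = initialize_system(config, params)
    ff = state.ff

    chain_map = []
    offset = 0
    counter: dict = {}
    for model, role in zip(ff.models, ff.roles):
        k = counter.get(model.chain_id, 0)
        counter[model.chain_id] = k + 1
        cid = model.chain_id if k == 0 else f"{model.chain_id}.{k}"
        chain_map.append({"chain_id": cid, "role": role,
                          "start": offset, "stop": offset + model.n_beads})
        offset += model.n_beads

    times = [0.0]
    frames = [state.positions.copy()]
    kinetic = [state.kinetic_energy()]
    _f, report0 = ff.compute(state.positions)
    energies = [[getattr(report0, t) for t in EnergyReport.TERMS]]

    remaining = config.n_steps
    while remaining > 0:
        n = min(config.save_interval, remaining)
        e = _chunk(state, config, params, n)
        remaining -= n
        times.append(state.time)
        frames.append(state.positions.copy())
        kinetic.append(state.kinetic_energy())
        energies.append(list(e))

    return Trajectory(times=np.array(times), positions=np.array(frames),
                      box=config.box, chain_map=chain_map,
                      kinetic=np.array(kinetic), energies=np.array(energies))


# ---------------------------------------------------------------------------
# trajectory I/O (binary: JSON header + raw little-endian float64 payload)
# ---------------------------------------------------------------------------


def write_trajectory(traj: Trajectory, path) -> None:
    header = {
        "version": 1,
        "n_frames": int(traj.n_frames),
        "n_beads": int(traj.n_beads),
        "box": float(traj.box),
        "chain_map": traj.chain_map,
        "has_kinetic": traj.kinetic is not None,
        "has_energies": traj.energies is not None,
    }
    blob = json.dumps(header, sort_keys=True).encode()
    with open(path, "wb") as fh:
        fh.write(_MAGIC)
        fh.write(struct.pack("<Q", len(blob)))
        fh.write(blob)
        fh.write(np.ascontiguousarray(traj.times, dtype="<f8").tobytes())
        fh.write(np.ascontiguousarray(traj.positions, dtype="<f8").tobytes())
        if traj.kinetic is not None:
            fh.write(np.ascontiguousarray(traj.kinetic, dtype="<f8").tobytes())
        if traj.energies is not None:
            fh.write(np.ascontiguousarray(traj.energies, dtype="<f8").tobytes())


def read_trajectory(path) -> Trajectory:
    with open(path, "rb") as fh:
        magic = fh.read(len(_MAGIC))
        if magic != _MAGIC:
            raise ValueError("not a prkap trajectory file")
        (hlen,) = struct.unpack("<Q", fh.read(8))
        header = json.loads(fh.read(hlen).decode())
        if header.get("version") != 1:
            raise ValueError(f"unsupported trajectory version {header.get('version')}")
        nf, nb = header["n_frames"], header["n_beads"]
        if nf < 1:
            raise ValueError("trajectory file contains no frames")

        def _read(count):
            raw = fh.read(count * 8)
            if len(raw) != count * 8:
                raise ValueError("truncated trajectory file")
            return np.frombuffer(raw, dtype="<f8")

        times = _read(nf)
        positions = _read(nf * nb * 3).reshape(nf, nb, 3)
        kinetic = _read(nf) if header["has_kinetic"] else None
        energies = _read(nf * 6).reshape(nf, 6) if header["has_energies"] else None
    return Trajectory(times=times, positions=positions, box=header["box"],
                      chain_map=header["chain_map"], kinetic=kinetic,
                      energies=energies)


def export_pdb_topology(models, roles, path) -> None:
    """Write a minimal PDB snapshot of the build geometry for viewers."""
    from .constants import THREE_TO_ONE

    one_to_three = {v: k for k, v in THREE_TO_ONE.items() if len(k) == 3}
    lines = []
    serial = 1
    for ci, model in enumerate(models):
        chain = chr(ord("A") + (ci % 26))
        for i, aa in enumerate(model.sequence):
            x, y, z = model.positions[i] * 10.0
            res3 = one_to_three.get(aa, "GLY")
            lines.append(
                f"ATOM  {serial:5d}  CA  {res3} {chain}{i + 1:4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00           C"
            )
            serial += 1
        lines.append("TER")
    lines.append("END")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def export_dcd(traj: Trajectory, path) -> None:
    """Optional export to DCD (Angstrom) for external viewers.

    Pair with :func:`export_pdb_topology` for a loadable topology.
    """
    import MDAnalysis as mda

    u = mda.Universe.empty(traj.n_beads, trajectory=True)
    with mda.Writer(str(path), n_atoms=traj.n_beads) as writer:
        for frame in traj.positions:
            u.atoms.positions = frame * 10.0
            u.dimensions = [traj.box * 10.0] * 3 + [90.0, 90.0, 90.0]
            writer.write(u.atoms)


def kabsch_rmsd(reference: np.ndarray, coords: np.ndarray) -> float:
    """RMSD (nm) after optimal rigid superposition of coords onto reference."""
    P = np.asarray(reference, dtype=float)
    Q = np.asarray(coords, dtype=float)
    Pc = P - P.mean(axis=0)
    Qc = Q - Q.mean(axis=0)
    H = Qc.T @ Pc
    U, _S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    diff = Qc @ R.T - Pc
    return float(np.sqrt((diff**2).sum() / len(P)))
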