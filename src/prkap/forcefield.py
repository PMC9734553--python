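"""Implicit-solvent force field for the one-bead-per-residue models.

Interaction classes
-------------------
* receptor intra-chain: backbone + elastic-network harmonics, excluded volume
* chain (poly-PR) intra/inter: screened electrostatics, hydrophobic
  attraction, excluded volume, plus residue-class (G/P/other) bending and
  torsion terms on disordered stretches
* chain-receptor: screened electrostatics, cation-pi (R/K against F/Y/W),
  excluded volume

All well depths, ranges and bonded-class parameters are configuration
defaults shipped with the package (the published parameterisation is not
reproduced here); functional forms are fixed.  Every pair potential is
energy-shifted to zero at its cutoff.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import yaml

from . import _kernels
from .cg_builder import CGModel
from .constants import (
    CATIONIC_RESIDUES,
    COULOMB_PREFACTOR,
    HYDROPHOBICITY,
    KB,
    RESIDUE_MASS,
)

__all__ = [
    "ForceFieldParams",
    "EnergyReport",
    "TotalForceField",
    "debye_screening_length",
    "electrostatic_pair_energy",
    "cation_pi_pair_energy",
    "excluded_volume_pair_energy",
    "hydrophobic_pair_energy",
    "bonded_energy",
]

from scipy import constants as _sc

#: residue bonded-pattern classes
_CLASS_OF = lambda aa: "G" if aa == "G" else ("P" if aa == "P" else "other")


def debye_screening_length(salt_mM: float, temperature: float = 300.0,
                           epsilon_r: float = 80.0) -> float:
    """Debye length in nm for a monovalent salt solution.

    kappa^-1 = sqrt(eps0 eps_r kB T / (2 NA e^2 I)) with ionic strength
    I = salt concentration (1 mM == 1 mol/m^3 for a 1:1 salt).
    """
    if salt_mM <= 0:
        raise ValueError("salt_mM must be positive (unscreened Coulomb must be "
                         "requested explicitly via debye_length=inf)")
    ionic = salt_mM  # mol/m^3
    num = _sc.epsilon_0 * epsilon_r * _sc.k * temperature
    den = 2.0 * _sc.N_A * _sc.e**2 * ionic
    return math.sqrt(num / den) * 1e9


@dataclass
class ForceFieldParams:
    """Force-field parameter set (all values are shipped defaults)."""

    temperature: float = 300.0
    salt_mM: float = 200.0
    dielectric_mode: str = "constant"  # "constant" | "distance"
    epsilon_r: float = 80.0
    epsilon_min: float = 2.0  # distance mode: permittivity at contact
    epsilon_xi: float = 0.25  # distance mode: saturation length, nm
    cation_pi_depth: float = 3.0  # kJ/mol
    cation_pi_sigma: float = 0.60  # nm, well-minimum distance
    ev_strength: float = 2.5  # kJ/mol
    ev_diameter: float = 0.60  # nm
    backbone_k: float = 8000.0  # kJ mol^-1 nm^-2
    backbone_r0: float = 0.38  # nm
    elastic_k: float = 8000.0  # kJ mol^-1 nm^-2
    cutoff: float = 2.5  # nm, nonbonded
    skin: float = 0.3  # nm, Verlet-list skin
    hydrophobic_depth: float = 2.0  # kJ/mol at h_i = h_j = 1
    hydrophobic_sigma: float = 0.65  # nm
    # bending: class of the central bead -> (k [kJ/mol/rad^2], theta0 [rad])
    angle_params: dict = field(default_factory=lambda: {
        "G": (2.0, 1.85), "P": (8.0, 2.20), "other": (5.0, 2.00),
    })
    # torsion: classes of the two central beads -> (k [kJ/mol], phase [rad])
    torsion_params: dict = field(default_factory=lambda: {
        ("G", "G"): (0.2, 0.0), ("G", "P"): (0.4, 0.0), ("G", "other"): (0.3, 0.0),
        ("P", "P"): (1.0, 0.0), ("P", "other"): (0.6, 0.0),
        ("other", "other"): (0.5, 0.0),
    })
    hydrophobicity: dict = field(default_factory=lambda: dict(HYDROPHOBICITY))

    def __post_init__(self) -> None:
        if self.cutoff < max(self.ev_diameter, self.cation_pi_sigma,
                             self.hydrophobic_sigma):
            raise ValueError("nonbonded cutoff smaller than an interaction range")
        for name in ("cation_pi_depth", "cation_pi_sigma", "ev_strength",
                     "ev_diameter", "backbone_k", "elastic_k", "cutoff",
                     "hydrophobic_sigma"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.dielectric_mode not in ("constant", "distance"):
            raise ValueError("dielectric_mode must be 'constant' or 'distance'")

    @property
    def debye_length(self) -> float:
        return debye_screening_length(self.salt_mM, self.temperature, self.epsilon_r)

    @property
    def kT(self) -> float:
        return KB * self.temperature

    def epsilon_at(self, r):
        """Relative permittivity at separation r (vectorised)."""
        if self.dielectric_mode == "constant":
            return np.full_like(np.asarray(r, dtype=float), self.epsilon_r)
        r = np.asarray(r, dtype=float)
        return self.epsilon_min + (self.epsilon_r - self.epsilon_min) * (
            1.0 - np.exp(-r / self.epsilon_xi))

    # -- serialization ------------------------------------------------------

    def to_yaml(self, path=None) -> str:
        d = asdict(self)
        d["torsion_params"] = {f"{a}:{b}": list(v)
                               for (a, b), v in self.torsion_params.items()}
        d["angle_params"] = {k: list(v) for k, v in self.angle_params.items()}
        d["format"] = "prkap-ff-1"
        text = yaml.safe_dump(d, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_yaml(cls, source) -> "ForceFieldParams":
        text = source.read() if hasattr(source, "read") else open(source).read()
        d = yaml.safe_load(text)
        if d.pop("format", None) != "prkap-ff-1":
            raise ValueError("unrecognised force-field file format")
        d["torsion_params"] = {tuple(k.split(":")): tuple(v)
                               for k, v in d["torsion_params"].items()}
        d["angle_params"] = {k: tuple(v) for k, v in d["angle_params"].items()}
        return cls(**d)


@dataclass
class EnergyReport:
    """Per-term potential-energy totals, kJ/mol."""

    bonded: float = 0.0
    elastic: float = 0.0
    electrostatic: float = 0.0
    cation_pi: float = 0.0
    excluded_volume: float = 0.0
    hydrophobic: float = 0.0

    TERMS = ("bonded", "elastic", "electrostatic", "cation_pi",
             "excluded_volume", "hydrophobic")

    @property
    def total(self) -> float:
        return sum(getattr(self, t) for t in self.TERMS)

    def to_tsv(self) -> str:
        lines = ["term\tenergy_kJ_mol"]
        for t in self.TERMS:
            lines.append(f"{t}\t{getattr(self, t):.8g}")
        lines.append(f"total\t{self.total:.8g}")
        return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# scalar pair potentials (reference implementations; also used by tests)
# ---------------------------------------------------------------------------


def _check_r(r) -> np.ndarray:
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0):
        raise ValueError("pair distance must be positive")
    return r


def electrostatic_pair_energy(q_i: float, q_j: float, r, params: ForceFieldParams,
                              shifted: bool = True):
    """Debye-screened Coulomb energy, truncated and shifted at the cutoff."""
    r = _check_r(r)
    lam = params.debye_length
    eps = params.epsilon_at(r)
    u = COULOMB_PREFACTOR * q_i * q_j * np.exp(-r / lam) / (eps * r)
    if shifted:
        rc = params.cutoff
        eps_c = params.epsilon_at(rc)
        u = np.where(
            r < rc,
            u - COULOMB_PREFACTOR * q_i * q_j * math.exp(-rc / lam) / (eps_c * rc),
            0.0,
        )
    return u if u.shape else float(u)


def _well(r, sigma, depth, rc):
    """12-6 well with minimum exactly -depth at r = sigma, shifted to 0 at rc."""
    s6 = (sigma / r) ** 6
    g = s6 * s6 - 2.0 * s6
    s6c = (sigma / rc) ** 6
    gc = s6c * s6c - 2.0 * s6c
    k = depth / (1.0 + gc)
    return np.where(r < rc, k * (g - gc), 0.0)


def cation_pi_pair_energy(r, params: ForceFieldParams):
    """Cation-pi attraction for {R,K} x {F,Y,W} bead pairs."""
    r = _check_r(r)
    u = _well(r, params.cation_pi_sigma, params.cation_pi_depth, params.cutoff)
    return u if u.shape else float(u)


def hydrophobic_pair_energy(r, h_i: float, h_j: float, params: ForceFieldParams):
    """Hydrophobicity-scaled attraction between disordered-chain beads."""
    r = _check_r(r)
    depth = params.hydrophobic_depth * math.sqrt(max(h_i, 0.0) * max(h_j, 0.0))
    u = _well(r, params.hydrophobic_sigma, depth, params.cutoff)
    return u if u.shape else float(u)


def excluded_volume_pair_energy(r, params: ForceFieldParams):
    """Purely repulsive soft core, zero at and beyond the bead diameter."""
    r = _check_r(r)
    s6 = (params.ev_diameter / r) ** 6
    u = np.where(r < params.ev_diameter,
                 params.ev_strength * (s6 * s6 - 2.0 * s6 + 1.0), 0.0)
    return u if u.shape else float(u)


def pack_params(params: ForceFieldParams) -> np.ndarray:
    """Pack scalar parameters into the kernel vector (see _kernels docstring)."""
    p = np.zeros(_kernels.NP)
    lam = params.debye_length
    rc = params.cutoff
    if params.dielectric_mode == "constant":
        p[0] = COULOMB_PREFACTOR / params.epsilon_r
        p[11] = COULOMB_PREFACTOR * math.exp(-rc / lam) / (params.epsilon_r * rc)
        p[12] = 0.0
    else:
        p[0] = COULOMB_PREFACTOR
        eps_c = float(params.epsilon_at(rc))
        p[11] = COULOMB_PREFACTOR * math.exp(-rc / lam) / (eps_c * rc)
        p[12] = 1.0
    p[1] = lam
    p[2] = rc
    s6c = (params.cation_pi_sigma / rc) ** 6
    gc = s6c * s6c - 2.0 * s6c
    p[3] = params.cation_pi_depth / (1.0 + gc)
    p[4] = params.cation_pi_sigma
    p[5] = gc
    p[6] = params.ev_strength
    p[7] = params.ev_diameter
    s6h = (params.hydrophobic_sigma / rc) ** 6
    ghc = s6h * s6h - 2.0 * s6h
    p[8] = params.hydrophobic_sigma
    p[9] = ghc
    p[10] = params.hydrophobic_depth
    p[13] = params.epsilon_r
    p[14] = params.epsilon_min
    p[15] = params.epsilon_xi
    return p


# ---------------------------------------------------------------------------
# assembled system
# ---------------------------------------------------------------------------


class TotalForceField:
    """Force/energy evaluator for an assembled multi-chain system.

    Parameters
    ----------
    models : list of CGModel
        The chains, concatenated in order.
    roles : list of str
        One of ``"receptor"`` or ``"pr"`` per chain.
    box : float
        Cubic box edge, nm.
    params : ForceFieldParams
    restraints : optional ``(indices, k, centers)``
        Harmonic position tethers (used by sampling validation tests).
    """

    def __init__(self, models, roles, box: float, params: ForceFieldParams,
                 restraints=None):
        if len(models) != len(roles):
            raise ValueError("one role required per chain")
        for role in roles:
            if role not in ("receptor", "pr"):
                raise ValueError(f"unknown chain role {role!r}")
        self.models = list(models)
        self.roles = list(roles)
        self.box = float(box)
        self.params = params
        self._p = pack_params(params)

        seqs = []
        charge = []
        arom = []
        cat = []
        hyd = []
        mass = []
        chain_index = []
        role_arr = []
        bond_i, bond_j = [], []
        el_i, el_j, el_r0 = [], [], []
        ang = []  # (i, j, k, kf, t0)
        tor = []  # (i, j, k, l, kf, p0)
        offset = 0
        for ci, (model, role) in enumerate(zip(models, roles)):
            n = model.n_beads
            seqs.append(model.sequence)
            charge.extend(model.charges.tolist())
            arom.extend(model.aromatic.tolist())
            cat.extend([aa in CATIONIC_RESIDUES for aa in model.sequence])
            hyd.extend([params.hydrophobicity.get(aa, 0.0) for aa in model.sequence])
            mass.extend([RESIDUE_MASS[aa] for aa in model.sequence])
            chain_index.extend([ci] * n)
            role_arr.extend([0 if role == "receptor" else 1] * n)
            for a, b in model.backbone_bonds:
                bond_i.append(offset + int(a))
                bond_j.append(offset + int(b))
            for (a, b), r0 in zip(model.elastic_pairs, model.elastic_rest):
                el_i.append(offset + int(a))
                el_j.append(offset + int(b))
                el_r0.append(float(r0))
            sm = model.structured_mask
            for j in range(1, n - 1):
                if sm[j]:
                    continue
                cls = _CLASS_OF(model.sequence[j])
                kf, t0 = params.angle_params[cls]
                ang.append((offset + j - 1, offset + j, offset + j + 1, kf, t0))
            for j in range(1, n - 2):
                if sm[j] or sm[j + 1]:
                    continue
                c1 = _CLASS_OF(model.sequence[j])
                c2 = _CLASS_OF(model.sequence[j + 1])
                key = (c1, c2) if (c1, c2) in params.torsion_params else (c2, c1)
                kf, p0 = params.torsion_params[key]
                tor.append((offset + j - 1, offset + j, offset + j + 1,
                            offset + j + 2, kf, p0))
            offset += n

        self.n_beads = offset
        self.sequence = "".join(seqs)
        self.charge = np.array(charge)
        self.aromatic = np.array(arom, dtype=np.bool_)
        self.cationic = np.array(cat, dtype=np.bool_)
        self.hydro = np.array(hyd)
        self.mass = np.array(mass)
        self.chain_index = np.array(chain_index, dtype=np.int64)
        self.role = np.array(role_arr, dtype=np.int64)
        self.bond_i = np.array(bond_i, dtype=np.int64)
        self.bond_j = np.array(bond_j, dtype=np.int64)
        self.bond_r0 = np.full(len(bond_i), params.backbone_r0)
        self.el_i = np.array(el_i, dtype=np.int64)
        self.el_j = np.array(el_j, dtype=np.int64)
        self.el_r0 = np.array(el_r0)
        ang_arr = np.array(ang, dtype=float).reshape(-1, 5)
        self.ang_i = ang_arr[:, 0].astype(np.int64)
        self.ang_j = ang_arr[:, 1].astype(np.int64)
        self.ang_k = ang_arr[:, 2].astype(np.int64)
        self.ang_kf = ang_arr[:, 3].copy()
        self.ang_t0 = ang_arr[:, 4].copy()
        tor_arr = np.array(tor, dtype=float).reshape(-1, 6)
        self.tor_i = tor_arr[:, 0].astype(np.int64)
        self.tor_j = tor_arr[:, 1].astype(np.int64)
        self.tor_k = tor_arr[:, 2].astype(np.int64)
        self.tor_l = tor_arr[:, 3].astype(np.int64)
        self.tor_kf = tor_arr[:, 4].copy()
        self.tor_p0 = tor_arr[:, 5].copy()
        if restraints is not None:
            idx, k, centers = restraints
            self.tet_idx = np.asarray(idx, dtype=np.int64)
            k = np.asarray(k, dtype=float)
            self.tet_k = (np.full(len(self.tet_idx), float(k))
                          if k.ndim == 0 else k)
            self.tet_c = np.asarray(centers, dtype=float).reshape(-1, 3)
        else:
            self.tet_idx = np.zeros(0, dtype=np.int64)
            self.tet_k = np.zeros(0)
            self.tet_c = np.zeros((0, 3))

        min_extent = 2.0 * (params.cutoff + params.skin)
        if self.box < min_extent:
            raise ValueError(f"box edge must be at least {min_extent:.2f} nm")

    def initial_positions(self) -> np.ndarray:
        return np.concatenate([m.positions for m in self.models], axis=0)

    def neighbor_pairs(self, positions: np.ndarray):
        p = self._p
        return _kernels._build_pairs(
            np.ascontiguousarray(positions, dtype=float), self.box,
            self.chain_index, self.role, p[7] + self.params.skin,
            p[2] + self.params.skin)

    def compute(self, positions: np.ndarray):
        """Forces (N, 3) and an EnergyReport for one configuration."""
        pos = np.ascontiguousarray(positions, dtype=float)
        if pos.shape != (self.n_beads, 3):
            raise ValueError("positions shape mismatch")
        if not np.isfinite(pos).all():
            raise ValueError("non-finite coordinates")
        f = np.zeros_like(pos)
        e_bond, e_elastic = _kernels._bonded_forces(
            pos, self.box, self.bond_i, self.bond_j, self.bond_r0,
            self.params.backbone_k, self.el_i, self.el_j, self.el_r0,
            self.params.elastic_k, self.ang_i, self.ang_j, self.ang_k,
            self.ang_kf, self.ang_t0, self.tor_i, self.tor_j, self.tor_k,
            self.tor_l, self.tor_kf, self.tor_p0,
            self.tet_idx, self.tet_k, self.tet_c, f)
        pi, pj, pt = self.neighbor_pairs(pos)
        e_el, e_cp, e_ev, e_hp, r_min = _kernels._pair_forces(
            pos, self.box, self.charge, self.cationic, self.aromatic,
            self.hydro, pi, pj, pt, self._p, f)
        if r_min <= 1.0e-6:
            raise ValueError("overlapping beads (pair distance below numerical floor)")
        report = EnergyReport(bonded=e_bond, elastic=e_elastic,
                              electrostatic=e_el, cation_pi=e_cp,
                              excluded_volume=e_ev, hydrophobic=e_hp)
        return f, report

    def energy(self, positions: np.ndarray) -> EnergyReport:
        return self.compute(positions)[1]


def bonded_energy(model: CGModel, positions: np.ndarray,
                  params: ForceFieldParams, box: float = 1000.0) -> float:
    """Backbone + class-patterned bending/torsion + elastic-network energy
    of a single chain at the given coordinates."""
    positions = np.asarray(positions, dtype=float)
    if positions.shape != (model.n_beads, 3):
        raise ValueError("positions do not match model")
    if not np.isfinite(positions).all():
        raise ValueError("missing (non-finite) positions")
    role = "receptor" if model.structured_mask.any() else "pr"
    ff = TotalForceField([model], [role], box, params)
    f = np.zeros_like(positions)
    e_bond, e_elastic = _kernels._bonded_forces(
        np.ascontiguousarray(positions), box, ff.bond_i, ff.bond_j, ff.bond_r0,
        params.backbone_k, ff.el_i, ff.el_j, ff.el_r0, params.elastic_k,
        ff.ang_i, ff.ang_j, ff.ang_k, ff.ang_kf, ff.ang_t0,
        ff.tor_i, ff.tor_j, ff.tor_k, ff.tor_l, ff.tor_kf, ff.tor_p0,
        ff.tet_idx, ff.tet_k, ff.tet_c, f)
    return float(e_bond + e_elastic)
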