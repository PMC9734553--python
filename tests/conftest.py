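"""Shared fixtures and independent test oracles."""

from __future__ import annotations

import numpy as np
import pytest

from prkap.cg_builder import build_polypr
from prkap.forcefield import ForceFieldParams
from prkap.synthetic_data import SolenoidSpec, generate_toy_solenoid

AA3 = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS",
    "E": "GLU", "Q": "GLN", "G": "GLY", "H": "HIS", "I": "ILE",
    "L": "LEU", "K": "LYS", "M": "MET", "F": "PHE", "P": "PRO",
    "S": "SER", "T": "THR", "W": "TRP", "Y": "TYR", "V": "VAL",
}


def make_pdb(sequence, coords, chain="A", missing=(), seqres=True,
             altloc_dup=None, first_resseq=1):
    """Render a minimal PDB text: SEQRES plus CA ATOM records.

    ``coords`` are in Angstrom.  Residue positions listed in ``missing``
    (0-based) get no ATOM record.  ``altloc_dup`` optionally duplicates
    one residue's CA with altlocs A/B at different occupancies.
    """
    lines = []
    if seqres:
        res3 = [AA3[aa] for aa in sequence]
        for i in range(0, len(res3), 13):
            lines.append(
                f"SEQRES {i // 13 + 1:3d} {chain} {len(res3):4d}  "
                + " ".join(res3[i:i + 13]))
    serial = 1
    for i, aa in enumerate(sequence):
        if i in missing:
            continue
        x, y, z = coords[i]
        resseq = first_resseq + i
        if altloc_dup == i:
            for alt, occ, dx in (("A", 0.65, 0.0), ("B", 0.35, 0.9)):
                lines.append(
                    f"ATOM  {serial:5d}  CA {alt}{AA3[aa]:>3s} {chain}"
                    f"{resseq:4d}    {x + dx:8.3f}{y:8.3f}{z:8.3f}"
                    f"{occ:6.2f}  0.00")
                serial += 1
        else:
            lines.append(
                f"ATOM  {serial:5d}  CA  {AA3[aa]:>3s} {chain}{resseq:4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}  0.00")
            serial += 1
    lines.append("END")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# independent energy oracle (pure numpy, no kernel code shared)
# ---------------------------------------------------------------------------


def oracle_chain_bonded_energy(sequence, positions, params: ForceFieldParams):
    """Reference bonded energy of one fully disordered chain."""
    pos = np.asarray(positions, dtype=float)
    n = len(sequence)
    e = 0.0
    for i in range(n - 1):
        r = np.linalg.norm(pos[i + 1] - pos[i])
        e += 0.5 * params.backbone_k * (r - params.backbone_r0) ** 2
    cls = ["G" if a == "G" else ("P" if a == "P" else "other") for a in sequence]
    for j in range(1, n - 1):
        u = pos[j - 1] - pos[j]
        v = pos[j + 1] - pos[j]
        ct = np.clip(u @ v / (np.linalg.norm(u) * np.linalg.norm(v)), -1, 1)
        k, t0 = params.angle_params[cls[j]]
        e += 0.5 * k * (np.arccos(ct) - t0) ** 2
    for j in range(1, n - 2):
        b1, b2, b3 = pos[j] - pos[j - 1], pos[j + 1] - pos[j], pos[j + 2] - pos[j + 1]
        n1, n2 = np.cross(b1, b2), np.cross(b2, b3)
        if n1 @ n1 < 1e-9 or n2 @ n2 < 1e-9:
            continue
        # collinearity switch s(x) = x/(x + xc) on each sin^2(angle)
        xc = 0.02
        x1 = (n1 @ n1) / ((b1 @ b1) * (b2 @ b2))
        x2 = (n2 @ n2) / ((b2 @ b2) * (b3 @ b3))
        sw = (x1 / (x1 + xc)) * (x2 / (x2 + xc))
        m = np.cross(n1, b2 / np.linalg.norm(b2))
        phi = np.arctan2(m @ n2, n1 @ n2)
        key = (cls[j], cls[j + 1])
        if key not in params.torsion_params:
            key = (cls[j + 1], cls[j])
        k, p0 = params.torsion_params[key]
        e += sw * k * (1.0 + np.cos(phi - p0))
    return e


def brute_force_contacts(frame, box, probe_idx, receptor_idx, cutoff=1.0):
    """O(N*M) double-loop contact count with minimum image."""
    count = 0
    pflags = np.zeros(len(probe_idx), dtype=bool)
    rflags = np.zeros(len(receptor_idx), dtype=bool)
    for a, p in enumerate(probe_idx):
        for b, r in enumerate(receptor_idx):
            d = frame[p] - frame[r]
            d -= box * np.rint(d / box)
            if np.sqrt((d**2).sum()) <= cutoff:
                count += 1
                pflags[a] = True
                rflags[b] = True
    return count, pflags, rflags


# ---------------------------------------------------------------------------
# fixtures
# ---------------------------------------------------------------------------


@pytest.fixture(scope="session")
def params():
    return ForceFieldParams(salt_mM=200.0)


@pytest.fixture(scope="session")
def toy_receptor():
    """Default toy solenoid (model, annotation, sites); build once."""
    return generate_toy_solenoid(SolenoidSpec())


@pytest.fixture(scope="session")
def pr7():
    return build_polypr(7, seed=11)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
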