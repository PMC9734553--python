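"""Synthetic test systems: toy HEAT-repeat solenoids, (PR)n sequences and
scripted fixture trajectories.

The toy solenoid emulates the architecture of a transport receptor:
tandem two-helix repeats laid on a superhelical scaffold, with the
B-helices forming the inner concave surface and the A-helices the outer
convex surface.  Negative charges are sprinkled on the two surfaces at
configurable densities (concentrated on the inner surface by default)
and one designated inter-helix linker can carry a contiguous acidic run.
Everything is deterministic given the spec seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .cg_builder import (
    BindingSiteSet,
    CGModel,
    RegionAnnotation,
    _backbone_bonds,
    assign_bead_chemistry,
    build_elastic_network,
)
from .simulator import Trajectory

__all__ = [
    "SolenoidSpec",
    "generate_toy_solenoid",
    "generate_polypr_sequence",
    "generate_fixture_trajectory",
]


@dataclass
class SolenoidSpec:
    n_heat_repeats: int = 8
    helix_len: int = 8  # residues per A/B helix
    linker_len: int = 3  # residues per linker
    radius: float = 2.2  # superhelical radius, nm
    pitch: float = 0.9  # axial rise per repeat, nm
    repeats_per_turn: float = 10.0
    helix_gap: float = 1.0  # radial A/B separation, nm
    inner_negative_density: float = 0.4  # B-helix (inner surface)
    outer_negative_density: float = 0.05  # A-helix (outer surface)
    acidic_linker: bool = True
    acidic_linker_len: int = 5
    aromatic_density: float = 0.05
    site_sizes: dict = field(default_factory=lambda: {
        "cargo": 10, "ibb": 8, "rangtp": 10, "fg_nup": 10})
    elastic_cutoff: float = 1.4
    bond_length: float = 0.38
    min_separation: float = 0.48  # self-avoidance floor, nm
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("inner_negative_density", "outer_negative_density",
                     "aromatic_density"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.n_heat_repeats < 2:
            raise ValueError("need at least two HEAT repeats")
        if self.helix_len < 2 or self.linker_len < 1:
            raise ValueError("helix_len >= 2 and linker_len >= 1 required")


def _cyl(radius: float, phi: float, z: float) -> np.ndarray:
    return np.array([radius * math.cos(phi), radius * math.sin(phi), z])


def _interp_line(a: np.ndarray, b: np.ndarray, n: int) -> list:
    """n interior points evenly spaced strictly between a and b."""
    return [a + (b - a) * (k / (n + 1)) for k in range(1, n + 1)]


def _arc_points(a: np.ndarray, b: np.ndarray, n: int, bond: float,
                bulge: np.ndarray) -> list:
    """n interior points on a circular arc from a to b.

    The arc length is (n+1)*bond so consecutive spacing stays close to the
    backbone bond length; the arc bulges towards ``bulge`` (unit-ish
    direction orthogonalised against the chord).  Falls back to a straight
    line when the chord already requires stretched bonds.
    """
    from scipy.optimize import brentq

    chord = b - a
    c = float(np.linalg.norm(chord))
    L = (n + 1) * bond
    if c >= L * 0.999:
        return _interp_line(a, b, n)
    t = chord / c
    u = bulge - (bulge @ t) * t
    nu = np.linalg.norm(u)
    if nu < 1e-9:  # bulge parallel to chord; pick any perpendicular
        u = np.cross(t, np.array([0.0, 0.0, 1.0]))
        if np.linalg.norm(u) < 1e-9:
            u = np.cross(t, np.array([1.0, 0.0, 0.0]))
        nu = np.linalg.norm(u)
    u = u / nu

    theta = brentq(lambda th: math.sin(th / 2.0) / (th / 2.0) - c / L,
                   1e-6, 2.0 * math.pi - 1e-6)
    R = L / theta
    mid = (a + b) / 2.0
    center = mid - R * math.cos(theta / 2.0) * u
    pts = []
    for k in range(1, n + 1):
        psi = -theta / 2.0 + theta * k / (n + 1)
        pts.append(center + R * (math.cos(psi) * u + math.sin(psi) * t))
    return pts


def generate_toy_solenoid(spec: SolenoidSpec):
    """Build (CGModel, RegionAnnotation, BindingSiteSet) for a toy solenoid.

    Returns a fully structured receptor model whose realised NCPR equals
    minus the number of decorated acidic beads over the length.
    """
    rng = np.random.default_rng(spec.seed)
    dphi = 2.0 * math.pi / spec.repeats_per_turn
    r_out = spec.radius + spec.helix_gap / 2.0
    r_in = spec.radius - spec.helix_gap / 2.0
    if r_in <= 0:
        raise ValueError("helix_gap too large for the superhelical radius")
    rise = spec.bond_length
    h_top = (spec.helix_len - 1) * rise

    acidic_repeat = spec.n_heat_repeats // 2  # designated H8-like linker

    positions = []
    labels = []  # per-bead (heat_index, label, surface) surface in {inner, outer, linker}
    for k in range(spec.n_heat_repeats):
        phi_a = k * dphi
        phi_b = phi_a + dphi / 2.0
        z0 = k * spec.pitch
        # A-helix: up the outer surface
        for i in range(spec.helix_len):
            positions.append(_cyl(r_out, phi_a, z0 + i * rise))
            labels.append((k, "A", "outer"))
        # top linker: outer A-top -> inner B-top
        a_top = _cyl(r_out, phi_a, z0 + h_top)
        b_top = _cyl(r_in, phi_b, z0 + h_top)
        n_top = (spec.acidic_linker_len
                 if (spec.acidic_linker and k == acidic_repeat)
                 else spec.linker_len)
        for pt in _arc_points(a_top, b_top, n_top, spec.bond_length,
                              np.array([0.0, 0.0, 1.0])):
            positions.append(pt)
            labels.append((k, "linker", "linker"))
        # B-helix: down the inner surface
        for i in range(spec.helix_len):
            positions.append(_cyl(r_in, phi_b, z0 + h_top - i * rise))
            labels.append((k, "B", "inner"))
        # bottom linker to the next repeat
        if k < spec.n_heat_repeats - 1:
            b_bot = _cyl(r_in, phi_b, z0)
            a_next = _cyl(r_out, (k + 1) * dphi, (k + 1) * spec.pitch)
            for pt in _arc_points(b_bot, a_next, spec.linker_len,
                                  spec.bond_length, np.array([0.0, 0.0, -1.0])):
                positions.append(pt)
                labels.append((k, "linker", "linker"))

    positions = np.array(positions)
    n = len(positions)

    # self-avoidance check (backbone-local corner contacts are fine; flag
    # genuine overlap of distant segments)
    from scipy.spatial import cKDTree
    tree = cKDTree(positions)
    for a, b in tree.query_pairs(spec.min_separation):
        if abs(a - b) >= 4:
            raise ValueError(
                f"geometric self-collision between beads {a} and {b}; "
                "adjust radius/pitch/repeats_per_turn")

    # charge / aromatic decoration
    seq = []
    n_neg = 0
    for idx, (k, label, surface) in enumerate(labels):
        if spec.acidic_linker and k == acidic_repeat and label == "linker" and (
                idx < n and surface == "linker" and _is_top_linker(labels, idx)):
            seq.append("D")
            n_neg += 1
            continue
        if surface == "inner":
            p_neg = spec.inner_negative_density
        elif surface == "outer":
            p_neg = spec.outer_negative_density
        else:
            p_neg = 0.0
        if p_neg > 0 and rng.random() < p_neg:
            seq.append("D")
            n_neg += 1
        elif spec.aromatic_density > 0 and rng.random() < spec.aromatic_density:
            seq.append("F")
        else:
            seq.append("A")
    sequence = "".join(seq)

    charges, aromatic = assign_bead_chemistry(sequence)
    assert int(round(-charges.sum())) == n_neg
    pairs, rests = build_elastic_network(positions, np.ones(n, dtype=bool),
                                         spec.elastic_cutoff, spec.bond_length)
    model = CGModel(
        sequence=sequence, positions=positions, charges=charges,
        aromatic=aromatic, structured_mask=np.ones(n, dtype=bool),
        backbone_bonds=_backbone_bonds(n), elastic_pairs=pairs,
        elastic_rest=rests, chain_id="TOY", bond_length=spec.bond_length)

    annotation = _spans_from_labels(labels)

    inner_idx = [i for i, (_k, _l, s) in enumerate(labels) if s == "inner"]
    outer_idx = [i for i, (_k, _l, s) in enumerate(labels) if s == "outer"]
    linker_idx = [i for i, (_k, _l, s) in enumerate(labels) if s == "linker"]
    acidic_idx = [i for i, (k, l, _s) in enumerate(labels)
                  if spec.acidic_linker and k == acidic_repeat and l == "linker"
                  and _is_top_linker(labels, i)]

    def _sample(pool, size):
        if size is None:
            return None
        pool = list(pool)
        if size >= len(pool):
            return frozenset(pool)
        return frozenset(int(i) for i in rng.choice(pool, size=size, replace=False))

    sizes = spec.site_sizes
    rangtp_pool = acidic_idx + [i for i in linker_idx if i not in acidic_idx]
    rangtp_size = sizes.get("rangtp")
    if rangtp_size is None:
        rangtp = None
    else:
        base = list(acidic_idx)[:rangtp_size]
        extra = max(0, rangtp_size - len(base))
        others = [i for i in rangtp_pool if i not in base]
        rangtp = frozenset(base) | (_sample(others, extra) or frozenset())
    sites = BindingSiteSet(
        cargo=_sample(inner_idx, sizes.get("cargo")),
        ibb=_sample(inner_idx, sizes.get("ibb")),
        rangtp=rangtp,
        fg_nup=_sample(outer_idx, sizes.get("fg_nup")),
    )
    sites.validate_for(n)
    return model, annotation, sites


def _is_top_linker(labels, idx: int) -> bool:
    """True when the linker bead at idx sits between an A- and a B-helix
    (as opposed to the inter-repeat bottom linker)."""
    k = labels[idx][0]
    j = idx
    while j >= 0 and labels[j][1] == "linker" and labels[j][0] == k:
        j -= 1
    return j >= 0 and labels[j][1] == "A" and labels[j][0] == k


def _spans_from_labels(labels) -> RegionAnnotation:
    spans = []
    start = 0
    for i in range(1, len(labels) + 1):
        if i == len(labels) or labels[i][:2] != labels[start][:2]:
            heat, label = labels[start][0], labels[start][1]
            spans.append((start, i - 1, heat, label))
            start = i
    return RegionAnnotation(spans=spans)


def generate_polypr_sequence(n: int) -> str:
    """'PR' repeated n times."""
    if n < 1:
        raise ValueError("n must be >= 1")
    return "PR" * n


def generate_fixture_trajectory(script, n_probe: int, n_receptor: int,
                                spacing: float = 4.0,
                                contact_distance: float = 0.5) -> Trajectory:
    """Trajectory whose frames realise exactly a scripted contact pattern.

    ``script`` is a sequence of frames; each frame maps probe bead index
    -> receptor bead index (a dict, or an iterable of (probe, receptor)
    pairs).  Every scripted pair sits at ``contact_distance`` (one pair
    contact); all other probe beads are parked far from everything.
    A probe bead mapped to more than one receptor bead is unrealisable.
    """
    frames = []
    box = max(200.0, spacing * (max(n_probe, n_receptor) + 2) + 100.0)
    receptor = np.zeros((n_receptor, 3))
    receptor[:, 0] = spacing * np.arange(n_receptor)
    receptor += 10.0  # keep everything strictly inside the box
    parked = np.zeros((n_probe, 3))
    parked[:, 0] = spacing * np.arange(n_probe) + 10.0
    parked[:, 1] = 60.0

    for f, frame_script in enumerate(script):
        if isinstance(frame_script, dict):
            items = list(frame_script.items())
        else:
            items = list(frame_script)
        seen = set()
        probe = parked.copy()
        for p, r in items:
            p, r = int(p), int(r)
            if not 0 <= p < n_probe:
                raise ValueError(f"frame {f}: probe index {p} out of range")
            if not 0 <= r < n_receptor:
                raise ValueError(f"frame {f}: receptor index {r} out of range")
            if p in seen:
                raise ValueError(
                    f"frame {f}: probe bead {p} scripted against multiple "
                    "receptor beads (unrealisable)")
            seen.add(p)
            probe[p] = receptor[r] + np.array([0.0, contact_distance, 0.0])
        frames.append(np.concatenate([receptor, probe], axis=0))

    if not frames:
        raise ValueError("script must contain at least one frame")
    chain_map = [
        {"chain_id": "REC", "role": "receptor", "start": 0, "stop": n_receptor},
        {"chain_id": "PR", "role": "pr", "start": n_receptor,
         "stop": n_receptor + n_probe},
    ]
    return Trajectory(times=np.arange(len(frames), dtype=float),
                      positions=np.array(frames), box=box, chain_map=chain_map)
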