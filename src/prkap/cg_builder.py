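"""Construction of one-bead-per-residue chain models.

Receptors are built from C-alpha traces of crystal structures: resolved
beads keep their crystal coordinates and are cross-linked by a stiff
elastic network; crystallographically missing stretches are grown as
disordered regions.  Disordered chains such as (PR)n are built directly
from sequence.
"""

from __future__ import annotations

import io
import json
import warnings
from dataclasses import dataclass, field

import numpy as np

from .constants import (
    AMINO_ACIDS,
    AROMATIC_RESIDUES,
    RESIDUE_CHARGE,
    THREE_TO_ONE,
)

#: Default virtual C-alpha/C-alpha backbone bond length, nm.
DEFAULT_BOND_LENGTH = 0.38
#: Default elastic-network distance cutoff, nm.
DEFAULT_ELASTIC_CUTOFF = 1.4

__all__ = [
    "CGModel",
    "CalphaTrace",
    "RegionAnnotation",
    "BindingSiteSet",
    "parse_calpha_trace",
    "assign_bead_chemistry",
    "build_elastic_network",
    "model_missing_regions",
    "build_polypr",
    "compute_ncpr",
]


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class CGModel:
    """A single coarse-grained chain.

    Attributes
    ----------
    sequence : str
        One-letter amino-acid string, one bead per residue.
    positions : (N, 3) float array
        Bead coordinates in nm.
    charges : (N,) float array
        Elementary charge per bead, drawn from {-1, 0, +1}.
    aromatic : (N,) bool array
        True for F/Y/W beads.
    structured_mask : (N,) bool array
        True for beads resolved in the source structure (restrained by
        the elastic network), False for modelled disordered beads.
    backbone_bonds : (N-1, 2) int array
        Consecutive-bead bonds, shared rest length ``bond_length``.
    elastic_pairs : (M, 2) int array and ``elastic_rest`` (M,) float
        Elastic-network pairs between structured beads with per-pair
        rest lengths equal to the build-time distances.
    chain_id : str
        Chain label.
    """

    sequence: str
    positions: np.ndarray
    charges: np.ndarray
    aromatic: np.ndarray
    structured_mask: np.ndarray
    backbone_bonds: np.ndarray
    elastic_pairs: np.ndarray
    elastic_rest: np.ndarray
    chain_id: str = "A"
    bond_length: float = DEFAULT_BOND_LENGTH

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float).reshape(-1, 3)
        self.charges = np.asarray(self.charges, dtype=float)
        self.aromatic = np.asarray(self.aromatic, dtype=bool)
        self.structured_mask = np.asarray(self.structured_mask, dtype=bool)
        self.backbone_bonds = np.asarray(self.backbone_bonds, dtype=np.int64).reshape(-1, 2)
        self.elastic_pairs = np.asarray(self.elastic_pairs, dtype=np.int64).reshape(-1, 2)
        self.elastic_rest = np.asarray(self.elastic_rest, dtype=float)
        self.validate()

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def n_beads(self) -> int:
        return len(self.sequence)

    def validate(self) -> None:
        n = len(self.sequence)
        if not (len(self.positions) == len(self.charges) == len(self.aromatic)
                == len(self.structured_mask) == n):
            raise ValueError("per-bead array lengths disagree with sequence length")
        if n > 1:
            expected = np.column_stack([np.arange(n - 1), np.arange(1, n)])
            if not np.array_equal(self.backbone_bonds, expected):
                raise ValueError("backbone bonds must link consecutive beads in order")
        if not np.all(np.isin(self.charges, (-1.0, 0.0, 1.0))):
            raise ValueError("charges must be drawn from {-1, 0, +1}")
        if len(self.elastic_pairs) != len(self.elastic_rest):
            raise ValueError("elastic pair/rest-length count mismatch")
        if len(self.elastic_pairs):
            if not self.structured_mask[self.elastic_pairs].all():
                raise ValueError("elastic pairs must connect structured beads")

    def net_charge(self) -> float:
        return float(self.charges.sum())

    def ncpr(self) -> float:
        return compute_ncpr(self.charges)

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "format": "prkap-cgmodel-1",
            "chain_id": self.chain_id,
            "sequence": self.sequence,
            "bond_length": self.bond_length,
            "positions": self.positions.tolist(),
            "charges": self.charges.tolist(),
            "aromatic": self.aromatic.astype(int).tolist(),
            "structured_mask": self.structured_mask.astype(int).tolist(),
            "elastic_pairs": self.elastic_pairs.tolist(),
            "elastic_rest": self.elastic_rest.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CGModel":
        if d.get("format") != "prkap-cgmodel-1":
            raise ValueError(f"unrecognised model format: {d.get('format')!r}")
        n = len(d["sequence"])
        return cls(
            sequence=d["sequence"],
            positions=np.array(d["positions"], dtype=float),
            charges=np.array(d["charges"], dtype=float),
            aromatic=np.array(d["aromatic"], dtype=bool),
            structured_mask=np.array(d["structured_mask"], dtype=bool),
            backbone_bonds=_backbone_bonds(n),
            elastic_pairs=np.array(d["elastic_pairs"], dtype=np.int64).reshape(-1, 2),
            elastic_rest=np.array(d["elastic_rest"], dtype=float),
            chain_id=d["chain_id"],
            bond_length=float(d["bond_length"]),
        )

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict())
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, source) -> "CGModel":
        if hasattr(source, "read"):
            text = source.read()
        else:
            text = str(source)
            if "\n" not in text and text.strip().endswith(".json") or (
                not text.lstrip().startswith("{")
            ):
                with open(text) as fh:
                    text = fh.read()
        return cls.from_dict(json.loads(text))


@dataclass
class CalphaTrace:
    """Per-residue C-alpha record of a chain: identity, coordinate, resolved flag.

    Unresolved residues carry NaN positions.
    """

    sequence: str
    positions: np.ndarray  # (N, 3) nm, NaN rows where unresolved
    resolved: np.ndarray  # (N,) bool
    chain_id: str = "A"

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float).reshape(-1, 3)
        self.resolved = np.asarray(self.resolved, dtype=bool)
        if not (len(self.sequence) == len(self.positions) == len(self.resolved)):
            raise ValueError("trace array lengths disagree")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class RegionAnnotation:
    """Labelled spans over receptor residues (0-based inclusive internally).

    Each span is ``(start, end, heat_index, label)`` with
    ``label in {"A", "B", "linker"}``.
    """

    spans: list = field(default_factory=list)

    VALID_LABELS = ("A", "B", "linker")

    def __post_init__(self) -> None:
        self.spans = [(int(s), int(e), int(h), str(l)) for s, e, h, l in self.spans]
        self.validate()

    def validate(self) -> None:
        covered = set()
        for start, end, _heat, label in self.spans:
            if label not in self.VALID_LABELS:
                raise ValueError(f"invalid region label {label!r}")
            if end < start:
                raise ValueError(f"span ({start}, {end}) has end < start")
            idx = set(range(start, end + 1))
            if covered & idx:
                raise ValueError("overlapping region spans")
            covered |= idx

    def annotated_indices(self) -> set:
        out = set()
        for start, end, _h, _l in self.spans:
            out.update(range(start, end + 1))
        return out

    def label_of(self, index: int):
        for start, end, _h, label in self.spans:
            if start <= index <= end:
                return label
        return None

    def to_tsv(self, path=None) -> str:
        """Write 1-based inclusive TSV (columns: start, end, heat_index, label)."""
        buf = io.StringIO()
        buf.write("start\tend\theat_index\tlabel\n")
        for start, end, heat, label in self.spans:
            buf.write(f"{start + 1}\t{end + 1}\t{heat}\t{label}\n")
        text = buf.getvalue()
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_tsv(cls, source) -> "RegionAnnotation":
        text = source.read() if hasattr(source, "read") else open(source).read()
        spans = []
        for line in text.splitlines()[1:]:
            if not line.strip():
                continue
            start, end, heat, label = line.split("\t")
            spans.append((int(start) - 1, int(end) - 1, int(heat), label))
        return cls(spans=spans)


#: Binding-partner classes recognised in annotation files.
SITE_CLASSES = ("cargo", "ibb", "rangtp", "fg_nup")


@dataclass
class BindingSiteSet:
    """Receptor residue indices (0-based internally) per binding-partner class.

    ``None`` for a class means "no known sites" and is distinct from an
    empty set.
    """

    cargo: frozenset | None = None
    ibb: frozenset | None = None
    rangtp: frozenset | None = None
    fg_nup: frozenset | None = None

    def __post_init__(self) -> None:
        for cls_name in SITE_CLASSES:
            val = getattr(self, cls_name)
            if val is not None:
                setattr(self, cls_name, frozenset(int(i) for i in val))

    def as_dict(self) -> dict:
        return {c: getattr(self, c) for c in SITE_CLASSES}

    def validate_for(self, n_residues: int) -> None:
        for cls_name, sites in self.as_dict().items():
            if sites is None:
                continue
            bad = [i for i in sites if not 0 <= i < n_residues]
            if bad:
                raise ValueError(f"{cls_name} site index out of range: {bad}")

    def to_tsv(self, path=None) -> str:
        """Write 1-based TSV (columns: class, residue_index)."""
        buf = io.StringIO()
        buf.write("class\tresidue_index\n")
        for cls_name in SITE_CLASSES:
            sites = getattr(self, cls_name)
            if sites is None:
                continue
            for i in sorted(sites):
                buf.write(f"{cls_name}\t{i + 1}\n")
        text = buf.getvalue()
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_tsv(cls, source) -> "BindingSiteSet":
        text = source.read() if hasattr(source, "read") else open(source).read()
        sets: dict = {}
        for line in text.splitlines()[1:]:
            if not line.strip():
                continue
            cls_name, idx = line.split("\t")
            if cls_name not in SITE_CLASSES:
                raise ValueError(f"unknown binding-site class {cls_name!r}")
            sets.setdefault(cls_name, set()).add(int(idx) - 1)
        return cls(**{c: frozenset(v) for c, v in sets.items()})


def _backbone_bonds(n: int) -> np.ndarray:
    if n < 2:
        return np.zeros((0, 2), dtype=np.int64)
    return np.column_stack([np.arange(n - 1), np.arange(1, n)])


# ---------------------------------------------------------------------------
# PDB parsing
# ---------------------------------------------------------------------------


def parse_calpha_trace(structure_text: str, chain: str) -> CalphaTrace:
    """Extract the C-alpha trace of one chain from PDB-format text.

    Returns one entry per residue of the chain's full sequence; residues
    present in SEQRES (or implied by gaps in author numbering) but
    lacking coordinates come back with ``resolved=False``.  Coordinates
    are converted from Angstrom to nm.  Duplicate-altloc C-alphas keep
    the highest-occupancy copy (with a warning).
    """
    seqres = _parse_seqres(structure_text, chain)
    observed = _parse_ca_atoms(structure_text, chain)
    if not observed:
        raise ValueError(f"no C-alpha atoms found for chain {chain!r}")

    resseqs = [r for r, _aa, _pos in observed]
    if any(b <= a for a, b in zip(resseqs, resseqs[1:])):
        raise ValueError("residue numbering is not strictly increasing within chain")

    first, last = resseqs[0], resseqs[-1]
    n = last - first + 1
    by_resseq = {r: (aa, pos) for r, aa, pos in observed}

    # Align observed residues to SEQRES to recover identities of unresolved
    # residues (and any unresolved termini).
    offset = _seqres_offset(seqres, observed) if seqres else None
    if seqres and offset is not None:
        full_len = len(seqres)
        seq_chars = []
        positions = np.full((full_len, 3), np.nan)
        resolved = np.zeros(full_len, dtype=bool)
        for k in range(full_len):
            resseq = first - offset + k
            if resseq in by_resseq:
                aa, pos = by_resseq[resseq]
                positions[k] = pos
                resolved[k] = True
                seq_chars.append(aa)
            else:
                seq_chars.append(seqres[k])
        return CalphaTrace("".join(seq_chars), positions * 0.1, resolved, chain)

    # No usable SEQRES: residues implied by numbering gaps get identity 'G'.
    seq_chars = []
    positions = np.full((n, 3), np.nan)
    resolved = np.zeros(n, dtype=bool)
    for k in range(n):
        resseq = first + k
        if resseq in by_resseq:
            aa, pos = by_resseq[resseq]
            positions[k] = pos
            resolved[k] = True
            seq_chars.append(aa)
        else:
            seq_chars.append("G")
    return CalphaTrace("".join(seq_chars), positions * 0.1, resolved, chain)


def _parse_ca_atoms(text: str, chain: str):
    """Fixed-column ATOM record scan for C-alphas of one chain."""
    records: dict = {}  # resseq -> list of (occupancy, aa, xyz)
    seen_chain = False
    for line in text.splitlines():
        if not line.startswith(("ATOM", "HETATM")):
            continue
        if len(line) < 54:
            continue
        if line[21].strip() != chain:
            continue
        seen_chain = True
        name = line[12:16].strip()
        if name != "CA":
            continue
        resname = line[17:20].strip()
        aa = THREE_TO_ONE.get(resname)
        if aa is None:
            continue
        resseq = int(line[22:26])
        try:
            occ = float(line[54:60])
        except (ValueError, IndexError):
            occ = 1.0
        xyz = np.array([float(line[30:38]), float(line[38:46]), float(line[46:54])])
        records.setdefault(resseq, []).append((occ, aa, xyz))
    if not seen_chain:
        raise ValueError(f"chain {chain!r} not present in structure")
    out = []
    for resseq in sorted(records):
        alts = records[resseq]
        if len(alts) > 1:
            warnings.warn(
                f"residue {resseq}: {len(alts)} altloc C-alphas, keeping highest occupancy",
                stacklevel=3,
            )
            alts = sorted(alts, key=lambda t: -t[0])
        occ, aa, xyz = alts[0]
        out.append((resseq, aa, xyz))
    return out


def _parse_seqres(text: str, chain: str) -> str:
    chars = []
    for line in text.splitlines():
        if not line.startswith("SEQRES"):
            continue
        if line[11].strip() != chain:
            continue
        for resname in line[19:].split():
            chars.append(THREE_TO_ONE.get(resname, "X"))
    return "".join(chars)


def _seqres_offset(seqres: str, observed) -> int | None:
    """Find the SEQRES index of the first observed residue, or None."""
    first = observed[0][0]
    obs = {r - first: aa for r, aa, _ in observed}
    for offset in range(len(seqres)):
        ok = True
        for rel, aa in obs.items():
            k = offset + rel
            if k >= len(seqres) or seqres[k] != aa:
                ok = False
                break
        if ok:
            return offset
    return None


# ---------------------------------------------------------------------------
# Bead chemistry / elastic network / disordered completion
# ---------------------------------------------------------------------------


def assign_bead_chemistry(sequence: str):
    """Charges (-1 for D/E, +1 for R/K, else 0) and aromatic flags (F/Y/W)."""
    charges = np.zeros(len(sequence))
    aromatic = np.zeros(len(sequence), dtype=bool)
    for i, aa in enumerate(sequence):
        if aa not in AMINO_ACIDS:
            raise ValueError(f"unknown residue {aa!r} at position {i}")
        charges[i] = RESIDUE_CHARGE.get(aa, 0.0)
        aromatic[i] = aa in AROMATIC_RESIDUES
    return charges, aromatic


def build_elastic_network(
    positions: np.ndarray,
    structured_mask: np.ndarray,
    cutoff: float = DEFAULT_ELASTIC_CUTOFF,
    bond_length: float = DEFAULT_BOND_LENGTH,
):
    """All structured-bead pairs (|i-j| >= 2) within ``cutoff``.

    Returns ``(pairs, rest_lengths)`` with rest lengths set to the
    build-time distances.
    """
    from scipy.spatial import cKDTree

    if cutoff <= bond_length:
        raise ValueError("elastic cutoff must exceed the backbone bond length")
    positions = np.asarray(positions, dtype=float)
    structured_mask = np.asarray(structured_mask, dtype=bool)
    idx = np.flatnonzero(structured_mask)
    if len(idx) < 3:
        return np.zeros((0, 2), dtype=np.int64), np.zeros(0)
    pts = positions[idx]
    if not np.isfinite(pts).all():
        raise ValueError("positions undefined for some structured beads")
    tree = cKDTree(pts)
    raw = tree.query_pairs(cutoff, output_type="ndarray")
    pairs = []
    rests = []
    for a, b in raw:
        i, j = int(idx[a]), int(idx[b])
        if abs(i - j) < 2:
            continue
        if i > j:
            i, j = j, i
        pairs.append((i, j))
        rests.append(float(np.linalg.norm(positions[i] - positions[j])))
    if not pairs:
        return np.zeros((0, 2), dtype=np.int64), np.zeros(0)
    order = np.lexsort((np.array(pairs)[:, 1], np.array(pairs)[:, 0]))
    pairs = np.array(pairs, dtype=np.int64)[order]
    rests = np.array(rests)[order]
    return pairs, rests


def _grow_bridge(anchor_a, anchor_b, n_new, bond, existing, rng, clash=0.50):
    """Self-avoiding growth of n_new beads between two fixed anchors.

    The clash distance is progressively relaxed if placement keeps
    failing (tight pockets between anchors)."""
    gap = np.linalg.norm(anchor_b - anchor_a)
    if gap > (n_new + 1) * bond * (1.0 + 1e-9):
        raise ValueError(
            f"unresolved stretch of {n_new} residues cannot bridge a {gap:.2f} nm gap"
        )
    clash0 = clash
    for _attempt in range(200):
        clash = max(0.30, clash0 * 0.85 ** (_attempt // 40))
        placed = []
        cur = anchor_a.copy()
        ok = True
        for k in range(n_new):
            remaining = n_new - k  # segments left after placing this bead
            for _try in range(60):
                step = rng.standard_normal(3)
                step *= bond / np.linalg.norm(step)
                # bias toward target when the leash tightens
                to_b = anchor_b - cur
                dist_b = np.linalg.norm(to_b)
                slack = remaining * bond - (dist_b - bond)
                bias = max(0.0, 1.0 - slack / (2.0 * bond))
                if dist_b > 1e-12 and bias > 0:
                    step = (1 - bias) * step + bias * bond * to_b / dist_b
                    step *= bond / np.linalg.norm(step)
                cand = cur + step
                d_to_b = np.linalg.norm(anchor_b - cand)
                if d_to_b > remaining * bond:
                    continue
                if remaining == 1 and abs(d_to_b - bond) > 0.25 * bond:
                    continue
                pts = placed + existing
                if pts and min(np.linalg.norm(cand - p) for p in pts) < clash:
                    continue
                break
            else:
                ok = False
                break
            placed.append(cand)
            cur = cand
        if ok:
            return np.array(placed).reshape(n_new, 3)
    raise ValueError("self-avoiding growth failed for unresolved region")


def _grow_tail(anchor, n_new, bond, existing, rng, direction, clash=0.50):
    placed = []
    cur = anchor.copy()
    heading = direction / np.linalg.norm(direction)
    for _k in range(n_new):
        for _try in range(200):
            clash_eff = clash if _try < 120 else 0.30
            step = heading * bond + 0.7 * bond * rng.standard_normal(3)
            step *= bond / np.linalg.norm(step)
            cand = cur + step
            pts = placed + existing
            if pts and min(np.linalg.norm(cand - p) for p in pts) < clash_eff:
                continue
            break
        else:
            raise ValueError("self-avoiding growth failed for terminal tail")
        placed.append(cand)
        heading = (cand - cur) / bond
        cur = cand
    return np.array(placed).reshape(n_new, 3)


def model_missing_regions(
    trace: CalphaTrace,
    *,
    elastic_cutoff: float = DEFAULT_ELASTIC_CUTOFF,
    bond_length: float = DEFAULT_BOND_LENGTH,
    seed: int = 0,
    chain_id: str | None = None,
) -> CGModel:
    """Complete a C-alpha trace into a CGModel.

    Resolved beads keep crystal coordinates and are never moved;
    unresolved stretches are grown self-avoidingly at the backbone bond
    length from their resolved anchors and are excluded from the elastic
    network.
    """
    n = len(trace)
    positions = trace.positions.copy()
    resolved = trace.resolved.copy()
    rng = np.random.default_rng(seed)
    existing = [positions[i].copy() for i in np.flatnonzero(resolved)]

    # locate maximal unresolved runs
    i = 0
    while i < n:
        if resolved[i]:
            i += 1
            continue
        j = i
        while j < n and not resolved[j]:
            j += 1
        run = slice(i, j)
        m = j - i
        if i > 0 and j < n:  # internal gap
            new = _grow_bridge(positions[i - 1], positions[j], m, bond_length, existing, rng)
        elif j < n:  # N-terminal tail, grow backwards from first anchor
            centroid = np.nanmean(trace.positions[resolved], axis=0)
            outward = positions[j] - centroid
            if np.linalg.norm(outward) < 1e-9:
                outward = np.array([1.0, 0.0, 0.0])
            new = _grow_tail(positions[j], m, bond_length, existing, rng, outward)[::-1]
        elif i > 0:  # C-terminal tail
            centroid = np.nanmean(trace.positions[resolved], axis=0)
            outward = positions[i - 1] - centroid
            if np.linalg.norm(outward) < 1e-9:
                outward = np.array([1.0, 0.0, 0.0])
            new = _grow_tail(positions[i - 1], m, bond_length, existing, rng, outward)
        else:
            raise ValueError("trace has no resolved residues")
        positions[run] = new
        existing.extend(p.copy() for p in new)
        i = j

    charges, aromatic = assign_bead_chemistry(trace.sequence)
    pairs, rests = build_elastic_network(positions, resolved, elastic_cutoff, bond_length)
    return CGModel(
        sequence=trace.sequence,
        positions=positions,
        charges=charges,
        aromatic=aromatic,
        structured_mask=resolved,
        backbone_bonds=_backbone_bonds(n),
        elastic_pairs=pairs,
        elastic_rest=rests,
        chain_id=chain_id if chain_id is not None else trace.chain_id,
        bond_length=bond_length,
    )


def build_polypr(
    n_repeats: int,
    *,
    bond_length: float = DEFAULT_BOND_LENGTH,
    seed: int = 0,
    chain_id: str = "PR",
) -> CGModel:
    """Fully disordered (PR)^n chain: 2n beads, net charge +n.

    Initial coordinates are a seeded self-avoiding walk.
    """
    if n_repeats < 1:
        raise ValueError("n_repeats must be >= 1")
    sequence = "PR" * n_repeats
    n = len(sequence)
    rng = np.random.default_rng(seed)
    positions = np.zeros((n, 3))
    if n > 1:
        tail = _grow_tail(positions[0], n - 1, bond_length, [positions[0]], rng,
                          np.array([1.0, 0.0, 0.0]))
        positions[1:] = tail
    charges, aromatic = assign_bead_chemistry(sequence)
    return CGModel(
        sequence=sequence,
        positions=positions,
        charges=charges,
        aromatic=aromatic,
        structured_mask=np.zeros(n, dtype=bool),
        backbone_bonds=_backbone_bonds(n),
        elastic_pairs=np.zeros((0, 2), dtype=np.int64),
        elastic_rest=np.zeros(0),
        chain_id=chain_id,
        bond_length=bond_length,
    )


def compute_ncpr(charges) -> float:
    """Net charge per residue: integer charge sum divided by chain length."""
    charges = np.asarray(charges, dtype=float)
    if charges.size == 0:
        raise ValueError("empty charge list")
    total = int(round(charges.sum()))
    return total / charges.size
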