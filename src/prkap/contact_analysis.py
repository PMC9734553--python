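"""Contact statistics between disordered probe chains and a receptor.

Definitions (all with minimum-image distances and a 1 nm cutoff unless
stated otherwise):

* a *pair contact* is a (probe bead, receptor bead) pair within the cutoff;
* ``Ct`` is the time-averaged pair-contact count over production frames,
  with a normalised variant Ct / (N_receptor * N_probe);
* ``Pb`` is the fraction of production frames in which strictly more than
  10% of the probe residues are in contact;
* a receptor residue is a *contact site* when its per-frame contact
  probability is strictly greater than 0.10;
* ``Ncontact`` resolves contact sites by A-helix / B-helix / linker region;
* ``Nshared`` intersects contact sites with native binding-site classes.

Scalar uncertainties are half the standard deviation over contiguous
production blocks.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.spatial import cKDTree

from .cg_builder import SITE_CLASSES, BindingSiteSet, RegionAnnotation
from .simulator import Trajectory

__all__ = [
    "ContactResults",
    "frame_contacts",
    "time_averaged_contacts",
    "binding_probability",
    "residue_contact_probability",
    "contact_sites",
    "region_contact_counts",
    "shared_binding_sites",
    "scalar_uncertainty",
    "ncpr_contact_regression",
    "compute_contact_results",
]

DEFAULT_CONTACT_CUTOFF = 1.0  # nm
DEFAULT_BINDING_FRACTION = 0.10
DEFAULT_SITE_THRESHOLD = 0.10
DEFAULT_N_BLOCKS = 5


@dataclass
class ContactResults:
    """Bundle of contact statistics for one trajectory."""

    ct: float
    ct_normalized: float
    pb: float
    residue_profile: np.ndarray  # per receptor residue
    contact_site_set: frozenset
    ncontact_by_region: dict | None = None  # {"A", "B", "linker"} (+"unannotated")
    nshared_by_class: dict | None = None  # class -> int or None (no known sites)
    pb_per_copy: list | None = None
    uncertainty: dict = field(default_factory=dict)

    def validate(self) -> None:
        if not 0.0 <= self.pb <= 1.0:
            raise ValueError("Pb outside [0, 1]")
        if np.any(self.residue_profile < 0) or np.any(self.residue_profile > 1):
            raise ValueError("profile values outside [0, 1]")

    def to_tsv_dir(self, outdir) -> None:
        """One TSV per statistic: scalars, residue profile, contact sites,
        region counts and shared-site counts (1-based residue indices)."""
        from pathlib import Path
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        with open(out / "scalars.tsv", "w") as fh:
            fh.write("statistic\tvalue\tuncertainty\n")
            for name, value in (("ct", self.ct),
                                ("ct_normalized", self.ct_normalized),
                                ("pb", self.pb)):
                err = self.uncertainty.get(name, "")
                fh.write(f"{name}\t{value:.8g}\t{err}\n")
        with open(out / "residue_profile.tsv", "w") as fh:
            fh.write("residue_index\tcontact_probability\n")
            for i, p in enumerate(self.residue_profile):
                fh.write(f"{i + 1}\t{p:.8g}\n")
        with open(out / "contact_sites.tsv", "w") as fh:
            fh.write("residue_index\n")
            for i in sorted(self.contact_site_set):
                fh.write(f"{i + 1}\n")
        if self.ncontact_by_region is not None:
            with open(out / "ncontact_by_region.tsv", "w") as fh:
                fh.write("region\tn_contact\n")
                for k, v in self.ncontact_by_region.items():
                    fh.write(f"{k}\t{v}\n")
        if self.nshared_by_class is not None:
            with open(out / "nshared_by_class.tsv", "w") as fh:
                fh.write("class\tn_shared\n")
                for k, v in self.nshared_by_class.items():
                    fh.write(f"{k}\t{'-' if v is None else v}\n")

    def to_json(self, path=None) -> str:
        d = {
            "ct": self.ct,
            "ct_normalized": self.ct_normalized,
            "pb": self.pb,
            "residue_profile": list(map(float, self.residue_profile)),
            "contact_sites": sorted(self.contact_site_set),
            "ncontact_by_region": self.ncontact_by_region,
            "nshared_by_class": self.nshared_by_class,
            "pb_per_copy": self.pb_per_copy,
            "uncertainty": self.uncertainty,
        }
        text = json.dumps(d, indent=1)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


# ---------------------------------------------------------------------------
# per-frame kernel
# ---------------------------------------------------------------------------


def frame_contacts(frame: np.ndarray, box: float, probe_idx: np.ndarray,
                   receptor_idx: np.ndarray,
                   cutoff: float = DEFAULT_CONTACT_CUTOFF):
    """Pair contacts in one frame.

    Returns ``(pair_count, probe_flags, receptor_flags)`` where the flag
    arrays mark residues participating in at least one pair contact.
    Uses a periodic k-d tree; distances follow the minimum-image
    convention.
    """
    probe_idx = np.asarray(probe_idx, dtype=np.int64)
    receptor_idx = np.asarray(receptor_idx, dtype=np.int64)
    if probe_idx.size == 0 or receptor_idx.size == 0:
        raise ValueError("chain map must provide both probe and receptor beads")
    p = np.mod(frame[probe_idx], box)
    r = np.mod(frame[receptor_idx], box)
    # guard against coordinates landing exactly on the box edge after mod
    p[p >= box] = 0.0
    r[r >= box] = 0.0
    tree_r = cKDTree(r, boxsize=box)
    tree_p = cKDTree(p, boxsize=box)
    pairs = tree_p.query_ball_tree(tree_r, cutoff)
    count = 0
    probe_flags = np.zeros(probe_idx.size, dtype=bool)
    receptor_flags = np.zeros(receptor_idx.size, dtype=bool)
    for a, hits in enumerate(pairs):
        if hits:
            count += len(hits)
            probe_flags[a] = True
            receptor_flags[hits] = True
    return count, probe_flags, receptor_flags


def _trajectory_contact_tables(traj: Trajectory, equilibration_fraction: float,
                               cutoff: float):
    """Per-production-frame contact count and residue flags."""
    sl = traj.production_slice(equilibration_fraction)
    probe_idx = traj.beads_with_role("pr")
    receptor_idx = traj.beads_with_role("receptor")
    frames = traj.positions[sl]
    counts = np.zeros(len(frames), dtype=np.int64)
    probe_flags = np.zeros((len(frames), probe_idx.size), dtype=bool)
    rec_flags = np.zeros((len(frames), receptor_idx.size), dtype=bool)
    for f, frame in enumerate(frames):
        c, pf, rf = frame_contacts(frame, traj.box, probe_idx, receptor_idx, cutoff)
        counts[f] = c
        probe_flags[f] = pf
        rec_flags[f] = rf
    return counts, probe_flags, rec_flags


# ---------------------------------------------------------------------------
# statistics
# ---------------------------------------------------------------------------


def time_averaged_contacts(traj: Trajectory,
                           equilibration_fraction: float = 0.2,
                           cutoff: float = DEFAULT_CONTACT_CUTOFF):
    """(Ct, Ct_normalized): production-mean pair-contact count and its
    value divided by N_receptor * N_probe."""
    counts, _pf, _rf = _trajectory_contact_tables(traj, equilibration_fraction, cutoff)
    if counts.size == 0:
        raise ValueError("zero production frames")
    ct = float(counts.mean())
    n_rec = traj.beads_with_role("receptor").size
    n_probe = traj.beads_with_role("pr").size
    return ct, ct / (n_rec * n_probe)


def binding_probability(traj: Trajectory,
                        fraction: float = DEFAULT_BINDING_FRACTION,
                        cutoff: float = DEFAULT_CONTACT_CUTOFF,
                        equilibration_fraction: float = 0.2) -> float:
    """Fraction of production frames with strictly more than
    ``fraction`` of the probe residues in contact with the receptor."""
    _c, probe_flags, _rf = _trajectory_contact_tables(traj, equilibration_fraction,
                                                      cutoff)
    if probe_flags.shape[0] == 0:
        raise ValueError("zero production frames")
    n_probe = probe_flags.shape[1]
    bound = probe_flags.sum(axis=1) > fraction * n_probe
    return float(bound.mean())


def residue_contact_probability(traj: Trajectory,
                                cutoff: float = DEFAULT_CONTACT_CUTOFF,
                                equilibration_fraction: float = 0.2) -> np.ndarray:
    """Per receptor residue: fraction of production frames in contact
    with any probe bead (any probe copy)."""
    _c, _pf, rec_flags = _trajectory_contact_tables(traj, equilibration_fraction,
                                                    cutoff)
    if rec_flags.shape[0] == 0:
        raise ValueError("zero production frames")
    return rec_flags.mean(axis=0)


def contact_sites(profile: np.ndarray,
                  threshold: float = DEFAULT_SITE_THRESHOLD) -> frozenset:
    """Receptor residues with contact probability strictly above threshold."""
    profile = np.asarray(profile, dtype=float)
    return frozenset(int(i) for i in np.flatnonzero(profile > threshold))


def region_contact_counts(sites, annotation: RegionAnnotation) -> dict:
    """Contact sites per region label; unannotated sites counted separately."""
    annotation.validate()
    counts = {"A": 0, "B": 0, "linker": 0, "unannotated": 0}
    for idx in sites:
        label = annotation.label_of(idx)
        if label is None:
            counts["unannotated"] += 1
        else:
            counts[label] += 1
    return counts


def shared_binding_sites(sites, binding_sites: BindingSiteSet) -> dict:
    """|contact sites intersect class sites| per class; ``None`` where no
    sites are known for the class (the "(-)" marker)."""
    sites = frozenset(sites)
    out = {}
    for cls_name in SITE_CLASSES:
        known = getattr(binding_sites, cls_name)
        out[cls_name] = None if known is None else len(sites & known)
    return out


def scalar_uncertainty(block_values) -> float:
    """Half the sample standard deviation of per-block values."""
    vals = np.asarray(block_values, dtype=float)
    if vals.size < 2:
        raise ValueError("need at least two blocks")
    return 0.5 * float(np.std(vals, ddof=1))


def _block_slices(n: int, n_blocks: int):
    edges = np.linspace(0, n, n_blocks + 1).astype(int)
    return [slice(a, b) for a, b in zip(edges[:-1], edges[1:]) if b > a]


def ncpr_contact_regression(points):
    """OLS fit of normalized Ct against receptor NCPR.

    ``points`` is an iterable of (ncpr, normalized_ct).  Returns
    ``(slope, intercept, pearson_r)``.
    """
    pts = np.asarray(list(points), dtype=float)
    if pts.shape[0] < 3:
        raise ValueError("need at least three points")
    x, y = pts[:, 0], pts[:, 1]
    if np.ptp(x) == 0 or np.allclose(np.var(x), 0):
        raise ValueError("degenerate x-variance")
    res = stats.linregress(x, y)
    return float(res.slope), float(res.intercept), float(res.rvalue)


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------


def compute_contact_results(traj: Trajectory,
                            annotation: RegionAnnotation | None = None,
                            binding_sites: BindingSiteSet | None = None,
                            *,
                            cutoff: float = DEFAULT_CONTACT_CUTOFF,
                            binding_fraction: float = DEFAULT_BINDING_FRACTION,
                            site_threshold: float = DEFAULT_SITE_THRESHOLD,
                            equilibration_fraction: float = 0.2,
                            n_blocks: int = DEFAULT_N_BLOCKS) -> ContactResults:
    """All contact statistics for one trajectory in a single pass."""
    counts, probe_flags, rec_flags = _trajectory_contact_tables(
        traj, equilibration_fraction, cutoff)
    if counts.size == 0:
        raise ValueError("zero production frames")
    n_rec = rec_flags.shape[1]
    n_probe_total = probe_flags.shape[1]

    ct = float(counts.mean())
    ct_norm = ct / (n_rec * n_probe_total)
    bound = probe_flags.sum(axis=1) > binding_fraction * n_probe_total
    pb = float(bound.mean())
    profile = rec_flags.mean(axis=0)
    sites = contact_sites(profile, site_threshold)

    pb_per_copy = []
    probe_chains = traj.chains_with_role("pr")
    if len(probe_chains) > 1:
        probe_global = traj.beads_with_role("pr")
        col_of = {int(g): c for c, g in enumerate(probe_global)}
        for entry in probe_chains:
            cols = [col_of[i] for i in range(entry["start"], entry["stop"])]
            flags = probe_flags[:, cols]
            n_copy = len(cols)
            pb_per_copy.append(
                float((flags.sum(axis=1) > binding_fraction * n_copy).mean()))
    else:
        pb_per_copy = [pb]

    uncertainty = {}
    if counts.size >= n_blocks and n_blocks >= 2:
        blocks = _block_slices(counts.size, n_blocks)
        ct_blocks = [counts[s].mean() for s in blocks]
        pb_blocks = [(probe_flags[s].sum(axis=1)
                      > binding_fraction * n_probe_total).mean() for s in blocks]
        uncertainty["ct"] = scalar_uncertainty(ct_blocks)
        uncertainty["ct_normalized"] = uncertainty["ct"] / (n_rec * n_probe_total)
        uncertainty["pb"] = scalar_uncertainty(pb_blocks)

    ncontact = region_contact_counts(sites, annotation) if annotation else None
    nshared = shared_binding_sites(sites, binding_sites) if binding_sites else None

    results = ContactResults(
        ct=ct, ct_normalized=ct_norm, pb=pb, residue_profile=profile,
        contact_site_set=sites, ncontact_by_region=ncontact,
        nshared_by_class=nshared, pb_per_copy=pb_per_copy,
        uncertainty=uncertainty)
    results.validate()
    return results
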