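"""Geometric hydrogen-bond and ionic-contact detection with occupancies.

A hydrogen bond is declared from geometry alone.  With hydrogens present,
the criterion is the common visualization-tool convention: donor–acceptor
heavy-atom distance at most 3.0 Å and the donor–H–acceptor angle within
20° of linear.  Without hydrogens (coarse or heavy-atom-only models), a
single heavy-atom distance cutoff of 3.5 Å is used instead; the mode is
explicit and never falls back silently.

The trajectory-level statistic is *occupancy*: the fraction of snapshots in
which any donor–acceptor pair between two residue groups satisfies the
criterion, expressed as a percent.  The group-level series is a per-frame
OR over constituent pairs — one snapshot either has the interaction or it
does not, regardless of how many atom pairs realise it.

Cation coordination (e.g. the pocket Na+ against its carboxylate/hydroxyl
oxygens) is counted per frame as the number of partner oxygens within an
ionic-contact cutoff, default 3.0 Å.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from . import chemistry
from .structure_io import Frame, Trajectory, select_atoms

__all__ = [
    "HBCriterion",
    "ContactSeries",
    "CoordinationSeries",
    "detect_hbond",
    "hbond_series",
    "occupancy_percent",
    "ionic_coordination",
]


@dataclass(frozen=True)
class HBCriterion:
    """Geometric hydrogen-bond criterion.

    ``mode`` is ``"with_hydrogens"`` (distance + angle) or ``"heavy_only"``
    (distance only, with its own looser cutoff).
    """

    da_cutoff_A: float = 3.0
    dha_angle_cutoff_deg: float = 20.0
    heavy_only_cutoff_A: float = 3.5
    mode: str = "with_hydrogens"

    def __post_init__(self):
        if self.da_cutoff_A <= 0 or self.heavy_only_cutoff_A <= 0:
            raise ValueError("distance cutoffs must be positive")
        if not 0 < self.dha_angle_cutoff_deg <= 90:
            raise ValueError("angle cutoff must lie in (0, 90] degrees")
        if self.mode not in ("with_hydrogens", "heavy_only"):
            raise ValueError(f"unknown mode {self.mode!r}")


@dataclass
class ContactSeries:
    """Per-frame boolean occupancy of one defined interaction."""

    pair_label: str
    occupancy: np.ndarray

    def __post_init__(self):
        self.occupancy = np.asarray(self.occupancy, dtype=bool)
        if self.occupancy.ndim != 1:
            raise ValueError("occupancy must be one-dimensional")

    def __len__(self) -> int:
        return self.occupancy.size


@dataclass
class CoordinationSeries:
    """Per-frame count of coordinating partners around one cation."""

    cation_label: str
    partner_labels: tuple[str, ...]
    counts: np.ndarray

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=int)
        if np.any(self.counts < 0) or np.any(self.counts > len(self.partner_labels)):
            raise ValueError("counts must lie in [0, n_partners]")


# ---------------------------------------------------------------------------
# Single-frame predicate
# ---------------------------------------------------------------------------

def detect_hbond(
    frame: Frame,
    donor: int,
    hydrogen: int | None,
    acceptor: int,
    criterion: HBCriterion = HBCriterion(),
) -> bool:
    """Evaluate the geometric criterion for one donor/(H)/acceptor triple."""
    xyz = frame.coordinates
    d, a = xyz[donor], xyz[acceptor]
    dist = float(np.linalg.norm(d - a))
    if criterion.mode == "heavy_only":
        return bool(dist <= criterion.heavy_only_cutoff_A)
    if hydrogen is None:
        raise ValueError("criterion requires hydrogens but none was given")
    if dist > criterion.da_cutoff_A:
        return False
    h = xyz[hydrogen]
    v1, v2 = d - h, a - h
    n1, n2 = np.linalg.norm(v1), np.linalg.norm(v2)
    if n1 == 0 or n2 == 0:
        raise ValueError("degenerate donor-hydrogen-acceptor geometry")
    cosang = float(np.clip(np.dot(v1, v2) / (n1 * n2), -1.0, 1.0))
    angle = np.degrees(np.arccos(cosang))
    return bool((180.0 - angle) <= criterion.dha_angle_cutoff_deg)


# ---------------------------------------------------------------------------
# Trajectory-level series
# ---------------------------------------------------------------------------

def _atom_index(traj: Trajectory, chain: str | None, residue_id: int, atom_name: str) -> int | None:
    sel = select_atoms(traj, chain=chain, residue_id=residue_id, atom_name=atom_name)
    return sel.indices[0] if len(sel) == 1 else None


def _enumerate_donors(traj, chain, residue_ids, need_hydrogens):
    """(donor_idx, hydrogen_idx or None, residue_id) triples present in topology."""
    out = []
    for rid in residue_ids:
        names = {a.residue_name for a in traj.topology if a.residue_id == rid
                 and (chain is None or a.chain_id == chain)}
        for resname in sorted(names):
            for heavy, hydrogens in chemistry.donors_for(resname):
                di = _atom_index(traj, chain, rid, heavy)
                if di is None:
                    continue
                if need_hydrogens:
                    for hname in hydrogens:
                        hi = _atom_index(traj, chain, rid, hname)
                        if hi is not None:
                            out.append((di, hi, rid))
                else:
                    out.append((di, None, rid))
    return out


def _enumerate_acceptors(traj, chain, residue_ids):
    out = []
    for rid in residue_ids:
        names = {a.residue_name for a in traj.topology if a.residue_id == rid
                 and (chain is None or a.chain_id == chain)}
        for resname in sorted(names):
            for heavy in chemistry.acceptors_for(resname):
                ai = _atom_index(traj, chain, rid, heavy)
                if ai is not None:
                    out.append((ai, rid))
    return out


def hbond_series(
    traj: Trajectory,
    group_a: Iterable[int],
    group_b: Iterable[int],
    criterion: HBCriterion = HBCriterion(),
    chain_a: str | None = None,
    chain_b: str | None = None,
    pair_label: str | None = None,
) -> ContactSeries:
    """Per-frame occupancy of any hydrogen bond between two residue groups.

    ``group_a`` and ``group_b`` are residue-id collections; donors and
    acceptors are enumerated from the bundled standard-residue chemistry
    against the atoms actually present in the topology.  Occupancy at frame
    ``t`` is True iff ANY enumerated donor–acceptor pair across the groups
    satisfies the criterion ("the snapshot has the bond").
    """
    group_a = sorted(set(int(r) for r in group_a))
    group_b = sorted(set(int(r) for r in group_b))
    if not group_a or not group_b:
        raise ValueError("residue groups must be non-empty")
    need_h = criterion.mode == "with_hydrogens"

    don_a = _enumerate_donors(traj, chain_a, group_a, need_h)
    acc_a = _enumerate_acceptors(traj, chain_a, group_a)
    don_b = _enumerate_donors(traj, chain_b, group_b, need_h)
    acc_b = _enumerate_acceptors(traj, chain_b, group_b)

    pairs = []  # (donor_idx, hydrogen_idx or None, acceptor_idx)
    for di, hi, drid in don_a:
        for ai, arid in acc_b:
            if drid == arid and chain_a == chain_b:
                continue  # no intra-residue bonds
            pairs.append((di, hi, ai))
    for di, hi, drid in don_b:
        for ai, arid in acc_a:
            if drid == arid and chain_a == chain_b:
                continue
            pairs.append((di, hi, ai))
    if not pairs:
        raise ValueError(
            f"no donor/acceptor pairs between groups {group_a} and {group_b}"
        )

    occ = np.zeros(traj.n_frames, dtype=bool)
    xyz = traj.coords
    cut = criterion.heavy_only_cutoff_A if not need_h else criterion.da_cutoff_A
    for di, hi, ai in pairs:
        dist = np.linalg.norm(xyz[:, di, :] - xyz[:, ai, :], axis=1)
        hit = dist <= cut
        if need_h:
            v1 = xyz[:, di, :] - xyz[:, hi, :]
            v2 = xyz[:, ai, :] - xyz[:, hi, :]
            n1 = np.linalg.norm(v1, axis=1)
            n2 = np.linalg.norm(v2, axis=1)
            cosang = np.clip(np.einsum("ij,ij->i", v1, v2) / (n1 * n2), -1.0, 1.0)
            dev = 180.0 - np.degrees(np.arccos(cosang))
            hit &= dev <= criterion.dha_angle_cutoff_deg
        occ |= hit

    label = pair_label or (
        "+".join(map(str, group_a)) + "–" + "+".join(map(str, group_b))
    )
    return ContactSeries(pair_label=label, occupancy=occ)


def occupancy_percent(series: ContactSeries) -> float:
    """100 × (snapshots with the interaction) / (total snapshots)."""
    if len(series) == 0:
        raise ValueError("empty contact series")
    return 100.0 * float(np.mean(series.occupancy))


def ionic_coordination(
    traj: Trajectory,
    cation: int,
    partners: Sequence[int],
    cutoff_A: float = 3.0,
    cation_label: str = "NA",
    partner_labels: Sequence[str] | None = None,
) -> CoordinationSeries:
    """Per-frame number of partner atoms within ``cutoff_A`` of the cation."""
    if cutoff_A <= 0:
        raise ValueError("cutoff must be positive")
    partners = list(partners)
    if not partners:
        raise ValueError("need at least one partner atom")
    n_atoms = traj.n_atoms
    for idx in [cation, *partners]:
        if not 0 <= idx < n_atoms:
            raise ValueError(f"atom index {idx} outside topology")
    dist = np.linalg.norm(
        traj.coords[:, partners, :] - traj.coords[:, [cation], :], axis=2
    )
    counts = (dist <= cutoff_A).sum(axis=1)
    labels = tuple(
        partner_labels
        if partner_labels is not None
        else [str(traj.topology[p].residue_id) for p in partners]
    )
    return CoordinationSeries(
        cation_label=cation_label, partner_labels=labels, counts=counts
    )
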