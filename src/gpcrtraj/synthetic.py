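"""Seeded synthetic helix-bundle trajectories with planted ground truth.

This module emulates the *statistical* structure of microsecond receptor MD
ensembles so that every analysis stage of the package can be exercised and
validated without any simulation download:

* a two-state (locked / unlocked) Markov chain drives the intracellular
  TM6–TM7 gap, reproducing the unimodal-vs-multimodal distance contrast
  between a wild-type-like and a lock-broken mutant-like receptor;
* the extracellular TM2–TM6 gap is emitted per state, which plants the
  intracellular/extracellular coupling that conditional histograms must
  recover;
* an independent wide/narrow pocket state drives the pocket-width distance
  and a per-frame Poisson count of water oxygens in the uppermost pocket
  zone, emulating the reduced hydration of the Y2.53F-like receptor;
* side-chain pseudo-atoms realise (or break) the TM6–H8 ionic-lock
  hydrogen-bond geometry in lockstep with the chain state, and a Na+ ion
  sits coordinated by the D2.50/S7.46/T3.39 oxygens.

The emission model is kinematic — rigid helix-segment displacements plus
isotropic Gaussian jitter — not physics: the package's claims are about
analysis correctness, not force fields.  A single seeded generator drives
every draw in a fixed order, so identical seeds give byte-identical
output.  Canonical run structure: three independent runs of 1 μs saved
every 1 ns, pooled to 3,000 snapshots per system.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .bw import BWTable, MOUSE_ETAR_BW, resolve_bw
from .structure_io import AtomRecord, Frame, Trajectory, concat_trajectories

__all__ = [
    "SyntheticSpec",
    "GroundTruth",
    "RunPlan",
    "make_bundle_topology",
    "simulate_trajectory",
    "simulate_runs",
    "preset",
    "PRESET_NAMES",
    "planted_motion_trajectory",
    "stationary_distribution",
    "markov_mean_se",
    "write_ground_truth",
]

LOCKED, UNLOCKED = 0, 1
WIDE, NARROW = 0, 1


@dataclass(frozen=True)
class SyntheticSpec:
    """Generator parameters.

    Distances in Å; ``lock_transition_probs`` is the row-stochastic matrix
    of the locked/unlocked chain (row = from-state).  State-conditional
    emissions are (mean, sd) pairs indexed (locked, unlocked) for the
    TM6–TM7 and TM2–TM6 gaps, and (wide, narrow) for the pocket width,
    area-3 water Poisson mean and the ligand–receptor distance.
    """

    n_frames: int = 3000
    frame_interval_ns: float = 1.0
    seed: int = 0
    lock_transition_probs: tuple[tuple[float, float], tuple[float, float]] = (
        (0.97, 0.03),
        (0.07, 0.93),
    )
    tmin_params: tuple[tuple[float, float], tuple[float, float]] = (
        (6.0, 0.4),
        (8.5, 0.6),
    )
    tmex_params: tuple[tuple[float, float], tuple[float, float]] = (
        (23.5, 0.7),
        (21.0, 0.7),
    )
    tmpkt_params: tuple[tuple[float, float], tuple[float, float]] = (
        (9.5, 0.3),
        (8.0, 0.3),
    )
    water_lambda: tuple[float, float] = (10.0, 5.0)
    bulk_water_lambda: float = 8.0
    pocket_narrow_prob: float = 0.0
    ligand_dist_params: tuple[tuple[float, float], tuple[float, float]] = (
        (9.5, 0.4),
        (8.0, 0.4),
    )
    hbond_when_locked: bool = True
    include_sodium: bool = True
    include_ligand: bool = False
    noise_sd_A: float = 0.15
    n_water_pool: int = 60

    def validate(self) -> None:
        P = np.asarray(self.lock_transition_probs, dtype=float)
        if P.shape != (2, 2) or np.any(P < 0) or np.any(P > 1):
            raise ValueError("transition matrix entries must lie in [0, 1]")
        if not np.allclose(P.sum(axis=1), 1.0, atol=1e-12):
            raise ValueError("transition matrix rows must sum to 1")
        if self.n_frames < 2:
            raise ValueError("n_frames must be at least 2")
        if self.frame_interval_ns <= 0:
            raise ValueError("frame_interval_ns must be positive")
        for pair in (self.tmin_params, self.tmex_params, self.tmpkt_params,
                     self.ligand_dist_params):
            for mean, sd in pair:
                if sd <= 0 or mean <= 0:
                    raise ValueError("emission means and sds must be positive")
        if any(lam <= 0 for lam in self.water_lambda) or self.bulk_water_lambda <= 0:
            raise ValueError("Poisson means must be positive")
        if not 0 <= self.pocket_narrow_prob <= 1:
            raise ValueError("pocket_narrow_prob must lie in [0, 1]")
        if self.noise_sd_A < 0:
            raise ValueError("noise_sd_A must be non-negative")
        if self.n_water_pool < 1:
            raise ValueError("n_water_pool must be positive")

    @property
    def transition_matrix(self) -> np.ndarray:
        return np.asarray(self.lock_transition_probs, dtype=float)


@dataclass
class GroundTruth:
    """Planted per-frame state labels and emission values (pre-jitter),
    plus post-jitter geometric truths evaluated by direct predicates
    independent of the analysis modules."""

    states: np.ndarray  # 0 locked / 1 unlocked
    pocket_states: np.ndarray  # 0 wide / 1 narrow
    tmin: np.ndarray
    tmex: np.ndarray
    tmpkt: np.ndarray
    water_counts: np.ndarray  # (n_frames, 3), zones area1..area3
    hbond_planted: np.ndarray  # bool: lock geometry was set bonded
    hbond_geometric: np.ndarray  # bool: post-jitter heavy-atom predicate
    na_coordination: np.ndarray | None
    ligand_dist: np.ndarray | None
    stationary: np.ndarray  # chain stationary distribution (locked, unlocked)

    @property
    def n_frames(self) -> int:
        return self.states.size


@dataclass(frozen=True)
class RunPlan:
    """Production-run bookkeeping: independent runs pooled for analysis."""

    n_runs: int = 3
    run_length_ns: float = 1000.0
    save_interval_ns: float = 1.0

    @property
    def snapshots_per_run(self) -> int:
        return int(round(self.run_length_ns / self.save_interval_ns))

    @property
    def total_snapshots(self) -> int:
        return self.n_runs * self.snapshots_per_run


# ---------------------------------------------------------------------------
# Markov-chain utilities
# ---------------------------------------------------------------------------

def stationary_distribution(P: np.ndarray) -> np.ndarray:
    """Stationary distribution of a 2-state row-stochastic matrix."""
    P = np.asarray(P, dtype=float)
    p01, p10 = P[0, 1], P[1, 0]
    if p01 + p10 == 0:  # two absorbing states: convention (1, 0)
        return np.array([1.0, 0.0])
    return np.array([p10, p01]) / (p01 + p10)


def markov_mean_se(P: np.ndarray, n: int) -> float:
    """Standard error of the empirical state-0 frequency over ``n`` steps.

    Uses the autocorrelation correction for a 2-state chain: the indicator
    autocorrelation decays as rho**k with rho = 1 - p01 - p10, inflating
    the i.i.d. binomial variance by (1 + rho) / (1 - rho).
    """
    P = np.asarray(P, dtype=float)
    pi = stationary_distribution(P)
    rho = float(np.clip(1.0 - P[0, 1] - P[1, 0], -1.0, 1.0 - 1e-12))
    factor = (1.0 + rho) / (1.0 - rho)
    return float(np.sqrt(pi[0] * pi[1] * factor / n))


# ---------------------------------------------------------------------------
# Geometry layout
# ---------------------------------------------------------------------------

_RING_RADIUS = 12.0
_RISE_PER_RES = 1.5
_POCKET_CENTER = np.array([2.0, 2.0, 7.0])
_H8_ANGLE_DEG = 247.5
_H8_BASE_RADIUS = 10.0
_H8_Z = -20.0
_WATER_MARGIN = 0.9  # keeps jittered waters inside their planted zone
_HB_BONDED_OO = 2.6
_HEAVY_CUTOFF = 3.5  # ground-truth heavy-atom HB predicate
_NA_CUTOFF = 3.0

_MARKER_RESNAMES = {
    126: "ASP", 129: "TYR", 133: "ASP", 141: "LEU", 172: "THR", 182: "ASP",
    183: "ARG", 296: "GLU", 301: "ARG", 303: "GLU", 307: "THR", 318: "CYS",
    319: "TRP", 326: "ARG", 329: "LYS", 362: "SER", 372: "VAL", 373: "SER",
    374: "LYS",
}
# residue -> extra side-chain atoms (placed by the generator)
_MARKER_SIDECHAINS = {
    126: [("OD1", "O")],
    129: [("CZ", "C")],
    172: [("OG1", "O")],
    303: [("OE1", "O"), ("OE2", "O")],
    319: [("CH2", "C")],
    362: [("OG", "O")],
    373: [("OG", "O")],
    374: [("NZ", "N")],
}


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


class _Layout:
    """Base coordinates, index maps and displacement directions."""

    def __init__(self, spec: SyntheticSpec, table: BWTable):
        self.table = table
        records: list[AtomRecord] = []
        coords: list[np.ndarray] = []
        self.index: dict[tuple[str, int, str], int] = {}
        serial = 0

        def add(chain, rid, rname, aname, elem, xyz, hetero=False):
            nonlocal serial
            serial += 1
            records.append(AtomRecord(serial, aname, rname, rid, chain, elem, hetero))
            coords.append(np.asarray(xyz, dtype=float))
            self.index[(chain, rid, aname)] = len(records) - 1

        # receptor helices: straight CA traces on a ring
        for h in sorted(table.helix_ranges):
            lo, hi = table.helix_ranges[h]
            if h == 8:  # intracellular helix, horizontal and radial
                ang = np.deg2rad(_H8_ANGLE_DEG)
                direction = np.array([np.cos(ang), np.sin(ang), 0.0])
                for r in range(lo, hi + 1):
                    radius = _H8_BASE_RADIUS + _RISE_PER_RES * (r - lo)
                    xyz = np.array([*(radius * direction[:2]), _H8_Z])
                    add("A", r, _MARKER_RESNAMES.get(r, "ALA"), "CA", "C", xyz)
                continue
            ang = np.deg2rad(45.0 * (h - 1))
            xy = _RING_RADIUS * np.array([np.cos(ang), np.sin(ang)])
            mid = (lo + hi) / 2.0
            sign = 1.0 if table.extracellular_is_cterm.get(h, h % 2 == 0) else -1.0
            for r in range(lo, hi + 1):
                z = _RISE_PER_RES * (r - mid) * sign
                add("A", r, _MARKER_RESNAMES.get(r, "ALA"), "CA", "C", [*xy, z])
        # marker side-chain atoms (positions refined below / per frame)
        for rid, atoms in _MARKER_SIDECHAINS.items():
            for aname, elem in atoms:
                ca = coords[self.index[("A", rid, "CA")]]
                add("A", rid, _MARKER_RESNAMES[rid], aname, elem, ca + [0.0, 0.0, 1.0])

        if spec.include_ligand:
            for rid, rname in ((18, "ASP"), (20, "GLY"), (21, "TRP")):
                add("L", rid, rname, "CA", "C", [0.0, 0.0, 40.0])
        if spec.include_sodium:
            add("I", 390, "NA", "NA", "NA", _POCKET_CENTER, hetero=True)
        self.water_slice = slice(len(records), len(records) + spec.n_water_pool)
        for w in range(spec.n_water_pool):
            add("W", 401 + w, "HOH", "O", "O",
                [60.0 + 3.0 * w, 60.0, 0.0], hetero=True)

        self.records = records
        self.base = np.array(coords)

        ca = lambda rid: self.base[self.index[("A", rid, "CA")]]
        # displacement geometry
        self.ca307 = ca(307)
        self.ca319 = ca(319)
        self.ca329 = ca(329)
        self.ca326 = ca(326)
        self.ca133_base = ca(133)
        self.ca141_base = ca(141)
        self.ca372_base = ca(372)
        self.u_in = _unit(self.ca372_base - self.ca307)
        self.u_ex = _unit(self.ca141_base - self.ca329)
        self.u_pk = _unit(self.ca133_base - self.ca319)
        self.u_lig = _unit(np.array([0.0, 0.0, 30.0]) - self.ca326)

        def atom_block(pred):
            return np.array(
                [i for i, a in enumerate(records) if a.chain_id == "A" and pred(a)],
                dtype=int,
            )

        lo7, hi7 = table.helix_ranges[7]
        self.tm7_idx = atom_block(lambda a: lo7 <= a.residue_id <= hi7)
        self.mid2_idx = atom_block(lambda a: 129 <= a.residue_id <= 136)
        self.tip2_idx = atom_block(lambda a: 137 <= a.residue_id <= 142)

        # static pocket oxygens and lock-side atoms
        self.i_od1_126 = self.index[("A", 126, "OD1")]
        self.i_og1_172 = self.index[("A", 172, "OG1")]
        self.i_og_362 = self.index[("A", 362, "OG")]
        self.i_og_373 = self.index[("A", 373, "OG")]
        self.i_nz_374 = self.index[("A", 374, "NZ")]
        self.i_oe1 = self.index[("A", 303, "OE1")]
        self.i_oe2 = self.index[("A", 303, "OE2")]
        self.i_cz_129 = self.index[("A", 129, "CZ")]
        self.i_ch2_319 = self.index[("A", 319, "CH2")]
        self.i_ca362 = self.index[("A", 362, "CA")]
        self.i_ca129 = self.index[("A", 129, "CA")]
        self.i_ca303 = self.index[("A", 303, "CA")]
        self.i_ca126 = self.index[("A", 126, "CA")]

        c = _POCKET_CENTER
        self.base[self.i_od1_126] = c + 2.0 * _unit(ca(126) - c)
        self.base[self.i_og1_172] = c + 2.0 * _unit(ca(172) - c)
        self.base[self.i_ch2_319] = self.ca319 + 2.0 * self.u_pk
        og373 = ca(373) + 1.7 * _unit(ca(303) - ca(373))
        self.base[self.i_og_373] = og373
        self.base[self.i_nz_374] = ca(374) + 1.7 * _unit(ca(303) - ca(374))
        self.ca303_pos = ca(303)
        self.og373_pos = og373
        # zone anchor: the D2.50 CA axial coordinate
        self.anchor_z = float(ca(126)[2])

    # -- per-frame frame construction (pre-jitter) ------------------------
    def frame_coords(
        self,
        tmin: float,
        tmex: float,
        tmpkt: float,
        hb_on: bool,
        water_xyz: np.ndarray | None,
        lig_dist: float | None,
        include_sodium: bool,
    ) -> np.ndarray:
        xyz = self.base.copy()
        d7 = (self.ca307 + tmin * self.u_in) - self.ca372_base
        xyz[self.tm7_idx] += d7
        d_mid = (self.ca319 + tmpkt * self.u_pk) - self.ca133_base
        xyz[self.mid2_idx] += d_mid
        d_tip = (self.ca329 + tmex * self.u_ex) - self.ca141_base
        xyz[self.tip2_idx] += d_tip

        c = _POCKET_CENTER
        xyz[self.i_og_362] = c + 2.0 * _unit(xyz[self.i_ca362] - c)
        ch2 = xyz[self.i_ch2_319]
        ca129 = xyz[self.i_ca129]
        xyz[self.i_cz_129] = ca129 + 1.5 * _unit(ch2 - ca129)

        og = self.og373_pos
        toward_303 = _unit(self.ca303_pos - og)
        if hb_on:
            oe1 = og + _HB_BONDED_OO * toward_303
        else:
            oe1 = self.ca303_pos + 2.0 * toward_303  # points away from H8
        xyz[self.i_oe1] = oe1
        perp = _unit(np.cross(toward_303, [0.0, 0.0, 1.0]))
        xyz[self.i_oe2] = oe1 + 1.8 * perp

        if lig_dist is not None:
            d18 = self.ca326 + lig_dist * self.u_lig
            xyz[self.index[("L", 18, "CA")]] = d18
            xyz[self.index[("L", 20, "CA")]] = d18 + [0.0, 0.0, 3.0]
            xyz[self.index[("L", 21, "CA")]] = d18 + [2.0, 0.0, 4.5]
        if water_xyz is not None and water_xyz.size:
            start = self.water_slice.start
            xyz[start:start + water_xyz.shape[0]] = water_xyz
        return xyz


# ---------------------------------------------------------------------------
# Public generator operations
# ---------------------------------------------------------------------------

def make_bundle_topology(spec: SyntheticSpec) -> tuple[list[AtomRecord], Frame, BWTable]:
    """Topology, locked-state reference frame and generic-numbering table.

    The reference frame is built at the locked-state emission means with no
    jitter, so the designed TM6–TM7 gap is reproduced exactly.
    """
    spec.validate()
    table = MOUSE_ETAR_BW
    layout = _Layout(spec, table)
    ref = layout.frame_coords(
        tmin=spec.tmin_params[LOCKED][0],
        tmex=spec.tmex_params[LOCKED][0],
        tmpkt=spec.tmpkt_params[WIDE][0],
        hb_on=spec.hbond_when_locked,
        water_xyz=None,
        lig_dist=spec.ligand_dist_params[WIDE][0] if spec.include_ligand else None,
        include_sodium=spec.include_sodium,
    )
    return layout.records, Frame(coordinates=ref), table


def _sample_chain(rng: np.random.Generator, P: np.ndarray, n: int) -> np.ndarray:
    pi = stationary_distribution(P)
    states = np.empty(n, dtype=int)
    states[0] = int(rng.random() >= pi[0])
    u = rng.random(n - 1)
    for t in range(1, n):
        stay = P[states[t - 1], states[t - 1]]
        states[t] = states[t - 1] if u[t - 1] < stay else 1 - states[t - 1]
    return states


def _place_zone_waters(rng, n, zone_lo, zone_hi, radius):
    r = (radius - _WATER_MARGIN) * np.sqrt(rng.random(n))
    phi = 2.0 * np.pi * rng.random(n)
    z = rng.uniform(zone_lo + _WATER_MARGIN, zone_hi - _WATER_MARGIN, n)
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def simulate_trajectory(spec: SyntheticSpec) -> tuple[Trajectory, GroundTruth]:
    """One seeded run of the kinematic two-state generator."""
    spec.validate()
    records, _, table = make_bundle_topology(spec)
    layout = _Layout(spec, table)
    rng = np.random.default_rng(spec.seed)
    n = spec.n_frames
    P = spec.transition_matrix

    # fixed draw order guarantees bit-reproducibility for a given seed
    states = _sample_chain(rng, P, n)
    pockets = (rng.random(n) < spec.pocket_narrow_prob).astype(int)
    means = np.array([p[0] for p in spec.tmin_params])
    sds = np.array([p[1] for p in spec.tmin_params])
    tmin = rng.normal(means[states], sds[states])
    means = np.array([p[0] for p in spec.tmex_params])
    sds = np.array([p[1] for p in spec.tmex_params])
    tmex = rng.normal(means[states], sds[states])
    means = np.array([p[0] for p in spec.tmpkt_params])
    sds = np.array([p[1] for p in spec.tmpkt_params])
    tmpkt = rng.normal(means[pockets], sds[pockets])

    lam3 = np.array(spec.water_lambda)[pockets]
    counts = np.column_stack([
        rng.poisson(spec.bulk_water_lambda, n),
        rng.poisson(spec.bulk_water_lambda, n),
        rng.poisson(lam3, n),
    ])
    # clip to the fixed pool, filling zones bottom-up
    for t in range(n):
        excess = counts[t].sum() - spec.n_water_pool
        z = 2
        while excess > 0 and z >= 0:
            take = min(excess, counts[t, z])
            counts[t, z] -= take
            excess -= take
            z -= 1

    if spec.include_ligand:
        means = np.array([p[0] for p in spec.ligand_dist_params])
        sds = np.array([p[1] for p in spec.ligand_dist_params])
        lig = rng.normal(means[pockets], sds[pockets])
    else:
        lig = None

    zone_edges = layout.anchor_z + 8.0 * np.array([-1.5, -0.5, 0.5, 1.5])
    radius = 8.0
    hb_planted = (states == LOCKED) & spec.hbond_when_locked

    coords = np.empty((n, len(records), 3))
    for t in range(n):
        placed = [
            _place_zone_waters(rng, counts[t, z], zone_edges[z], zone_edges[z + 1], radius)
            for z in range(3)
        ]
        water_xyz = np.concatenate(placed) if counts[t].sum() else np.empty((0, 3))
        coords[t] = layout.frame_coords(
            tmin=tmin[t],
            tmex=tmex[t],
            tmpkt=tmpkt[t],
            hb_on=bool(hb_planted[t]),
            water_xyz=water_xyz,
            lig_dist=None if lig is None else float(lig[t]),
            include_sodium=spec.include_sodium,
        )
    if spec.noise_sd_A > 0:
        coords += rng.normal(0.0, spec.noise_sd_A, coords.shape)

    traj = Trajectory(
        records, coords,
        frame_interval_ns=spec.frame_interval_ns,
        source_label=f"synthetic(seed={spec.seed})",
    )

    # post-jitter geometric truths via direct distance predicates
    def _dist(i, j):
        return np.linalg.norm(coords[:, i, :] - coords[:, j, :], axis=1)

    hb_geo = np.zeros(n, dtype=bool)
    for di in (layout.i_og_373, layout.i_nz_374):
        for ai in (layout.i_oe1, layout.i_oe2):
            hb_geo |= _dist(di, ai) <= _HEAVY_CUTOFF
    if spec.include_sodium:
        na = layout.index[("I", 390, "NA")]
        na_coord = sum(
            (_dist(na, o) <= _NA_CUTOFF).astype(int)
            for o in (layout.i_od1_126, layout.i_og1_172, layout.i_og_362)
        )
    else:
        na_coord = None

    gt = GroundTruth(
        states=states,
        pocket_states=pockets,
        tmin=tmin,
        tmex=tmex,
        tmpkt=tmpkt,
        water_counts=counts,
        hbond_planted=hb_planted,
        hbond_geometric=hb_geo,
        na_coordination=na_coord,
        ligand_dist=lig,
        stationary=stationary_distribution(P),
    )
    return traj, gt


def simulate_runs(spec: SyntheticSpec, plan: RunPlan = RunPlan()) -> tuple[Trajectory, GroundTruth]:
    """Independent runs pooled into one analysis ensemble.

    Each run gets its own child seed derived from ``spec.seed``; frames are
    concatenated in run order, matching the convention of pooling all
    production runs of one system before histogramming.
    """
    children = np.random.SeedSequence(spec.seed).spawn(plan.n_runs)
    trajs, gts = [], []
    for child in children:
        run_seed = int(child.generate_state(1)[0] % (2**31))
        run_spec = replace(spec, seed=run_seed, n_frames=plan.snapshots_per_run,
                           frame_interval_ns=plan.save_interval_ns)
        traj, gt = simulate_trajectory(run_spec)
        trajs.append(traj)
        gts.append(gt)
    pooled = concat_trajectories(trajs, source_label=f"pooled({plan.n_runs} runs)")
    merged = GroundTruth(
        states=np.concatenate([g.states for g in gts]),
        pocket_states=np.concatenate([g.pocket_states for g in gts]),
        tmin=np.concatenate([g.tmin for g in gts]),
        tmex=np.concatenate([g.tmex for g in gts]),
        tmpkt=np.concatenate([g.tmpkt for g in gts]),
        water_counts=np.concatenate([g.water_counts for g in gts]),
        hbond_planted=np.concatenate([g.hbond_planted for g in gts]),
        hbond_geometric=np.concatenate([g.hbond_geometric for g in gts]),
        na_coordination=(
            np.concatenate([g.na_coordination for g in gts])
            if gts[0].na_coordination is not None else None
        ),
        ligand_dist=(
            np.concatenate([g.ligand_dist for g in gts])
            if gts[0].ligand_dist is not None else None
        ),
        stationary=gts[0].stationary,
    )
    return pooled, merged


PRESET_NAMES = ("WT-like", "E303K-like", "Y129F-like")


def preset(name: str, seed: int = 0, n_frames: int = 3000) -> SyntheticSpec:
    """Named study conditions emulating the three receptor variants.

    ``WT-like``: the ionic lock holds (fully locked chain, bond geometry
    on), giving a single narrow TM6–TM7 mode in 5–7 Å.  ``E303K-like``:
    the lock is broken (no bond geometry) and the chain mixes locked and
    unlocked states, giving a multimodal gap distribution with coupled
    extracellular narrowing in the unlocked state.  ``Y129F-like``: the
    lock holds but the pocket dwells in a narrow, water-poor state about
    half the time.
    """
    if name == "WT-like":
        return SyntheticSpec(
            n_frames=n_frames, seed=seed,
            lock_transition_probs=((1.0, 0.0), (1.0, 0.0)),
            tmin_params=((6.0, 0.2), (8.5, 0.6)),
            hbond_when_locked=True,
            pocket_narrow_prob=0.0,
        )
    if name == "E303K-like":
        return SyntheticSpec(
            n_frames=n_frames, seed=seed,
            lock_transition_probs=((0.97, 0.03), (0.04, 0.96)),
            hbond_when_locked=False,
            pocket_narrow_prob=0.0,
        )
    if name == "Y129F-like":
        return SyntheticSpec(
            n_frames=n_frames, seed=seed,
            lock_transition_probs=((0.995, 0.005), (0.08, 0.92)),
            tmin_params=((6.0, 0.3), (8.5, 0.6)),
            hbond_when_locked=True,
            pocket_narrow_prob=0.55,
        )
    raise ValueError(f"unknown preset {name!r}; choose from {PRESET_NAMES}")


def planted_motion_trajectory(
    n_frames: int = 3000,
    variances: tuple[float, ...] = (4.0, 1.0),
    n_atoms: int = 40,
    seed: int = 0,
    noise_sd: float = 0.0,
) -> tuple[Trajectory, np.ndarray, np.ndarray]:
    """Ensemble with k planted orthonormal collective motions.

    Frames are ``base + sum_i a_i(t) d_i`` with amplitudes
    ``a_i ~ N(0, variances[i])`` and random orthonormal 3N directions
    ``d_i``; returns (trajectory, directions (k, 3N), amplitudes (n, k)).
    Used for PCA parameter-recovery checks.
    """
    rng = np.random.default_rng(seed)
    base = rng.uniform(-10.0, 10.0, (n_atoms, 3))
    dim = 3 * n_atoms
    raw = rng.normal(size=(dim, len(variances)))
    q, _ = np.linalg.qr(raw)
    directions = q.T  # (k, 3N), orthonormal
    amps = rng.normal(0.0, np.sqrt(variances), size=(n_frames, len(variances)))
    flat = base.reshape(-1) + amps @ directions
    coords = flat.reshape(n_frames, n_atoms, 3)
    if noise_sd > 0:
        coords = coords + rng.normal(0.0, noise_sd, coords.shape)
    records = [
        AtomRecord(i + 1, "CA", "ALA", i + 1, "A", "C") for i in range(n_atoms)
    ]
    return Trajectory(records, coords, source_label="planted-motion"), directions, amps


def write_ground_truth(gt: GroundTruth, path: str | Path) -> None:
    """Dump the planted per-frame truth as a TSV."""
    data = {
        "frame": np.arange(gt.n_frames),
        "state": np.where(gt.states == LOCKED, "locked", "unlocked"),
        "pocket": np.where(gt.pocket_states == WIDE, "wide", "narrow"),
        "tmin_A": gt.tmin,
        "tmex_A": gt.tmex,
        "tmpkt_A": gt.tmpkt,
        "waters_area1": gt.water_counts[:, 0],
        "waters_area2": gt.water_counts[:, 1],
        "waters_area3": gt.water_counts[:, 2],
        "hbond_planted": gt.hbond_planted.astype(int),
        "hbond_geometric": gt.hbond_geometric.astype(int),
    }
    if gt.na_coordination is not None:
        data["na_coordination"] = gt.na_coordination
    if gt.ligand_dist is not None:
        data["ligand_dist_A"] = gt.ligand_dist
    pd.DataFrame(data).to_csv(path, sep="\t", index=False, float_format="%.4f")
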