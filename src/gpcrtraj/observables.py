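"""Named distance observables, pocket zoning, and distribution analysis.

The analyses here mirror how activation-relevant geometry is usually read
out of receptor trajectories:

* scalar Cα–Cα (or side-chain) distances between two named atoms, e.g. the
  intracellular TM6–TM7 gap, the extracellular TM2–TM6 gap, and the
  Na+/water-pocket width;
* a partition of the interhelical space below the ligand-binding site into
  three stacked 8 Å slabs along the membrane normal (intracellular
  G-protein area, the D2.50 level, and the Y2.53 level), with per-frame
  counts of water oxygens inside a bounding cylinder;
* probability histograms of any per-frame series, including conditional
  overlays ("the same histogram restricted to frames where another
  observable passes a threshold"), which is how coupling between the
  intracellular and extracellular sides is demonstrated.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .structure_io import AtomIndexSet, Trajectory, select_atoms

__all__ = [
    "NamedObservableConfig",
    "DistanceSeries",
    "ZonePartition",
    "WaterCountSeries",
    "Histogram",
    "distance_series",
    "count_waters",
    "zone_anchor_from_residue",
    "histogram",
    "conditional_histogram",
    "threshold_condition",
    "histogram_modes",
]


@dataclass(frozen=True)
class NamedObservableConfig:
    """A named scalar distance between two topology atoms."""

    name: str
    atom_a: tuple[int, str]  # (residue_id, atom_name)
    atom_b: tuple[int, str]
    chain_a: str | None = None
    chain_b: str | None = None

    def __post_init__(self):
        if self.atom_a == self.atom_b and self.chain_a == self.chain_b:
            raise ValueError(f"observable {self.name!r} uses the same atom twice")


@dataclass
class DistanceSeries:
    """Per-frame scalar distance (Å) for one named observable."""

    name: str
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("distance series must be one-dimensional")
        if self.values.size and (
            not np.all(np.isfinite(self.values)) or np.any(self.values < 0)
        ):
            raise ValueError(f"series {self.name!r} has invalid values")

    def __len__(self) -> int:
        return self.values.size


@dataclass(frozen=True)
class ZonePartition:
    """Stacked axial slabs bounded laterally by a cylinder.

    ``anchor_z`` is the axial coordinate of the centre of the middle zone
    (zone index ``n_zones // 2``); for the receptor pocket this is the mean
    axial position of the D2.50 Cα.  Zones are contiguous, each
    ``zone_width_A`` wide, ordered from intracellular (index 0, "area 1")
    to extracellular; intervals are half-open ``[lower, upper)`` with
    boundary points assigned upward, so no point is double-counted.
    """

    anchor_z: float
    zone_width_A: float = 8.0
    n_zones: int = 3
    lateral_radius_A: float = 8.0
    axis: tuple[float, float, float] = (0.0, 0.0, 1.0)  # membrane normal, +z extracellular

    def __post_init__(self):
        if self.zone_width_A <= 0 or self.lateral_radius_A <= 0 or self.n_zones < 1:
            raise ValueError("zone geometry parameters must be positive")
        ax = np.asarray(self.axis, dtype=float)
        n = np.linalg.norm(ax)
        if n == 0:
            raise ValueError("axis must be a nonzero vector")
        object.__setattr__(self, "axis", tuple(ax / n))

    @property
    def edges(self) -> np.ndarray:
        """Axial zone boundaries, ascending, length ``n_zones + 1``."""
        lower0 = self.anchor_z - (self.n_zones / 2.0) * self.zone_width_A
        return lower0 + self.zone_width_A * np.arange(self.n_zones + 1)

    @property
    def span_A(self) -> float:
        return self.n_zones * self.zone_width_A


# Zones are constructed with the membrane normal as +z toward the
# extracellular side; callers may supply any unit axis.
def _default_axis() -> tuple[float, float, float]:
    return (0.0, 0.0, 1.0)


@dataclass
class WaterCountSeries:
    """Per-frame integer water-oxygen counts per zone, shape (n_frames, n_zones)."""

    counts: np.ndarray
    zone_labels: tuple[str, ...]

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=int)
        if self.counts.ndim != 2 or self.counts.shape[1] != len(self.zone_labels):
            raise ValueError("counts must be (n_frames, n_zones)")
        if np.any(self.counts < 0):
            raise ValueError("negative water count")

    def zone(self, index: int) -> np.ndarray:
        return self.counts[:, index]


@dataclass
class Histogram:
    """Probability histogram: ``probabilities`` sum to 1 over ``n_samples``."""

    bin_edges: np.ndarray
    probabilities: np.ndarray
    n_samples: int

    def __post_init__(self):
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        self.probabilities = np.asarray(self.probabilities, dtype=float)
        if self.probabilities.size != self.bin_edges.size - 1:
            raise ValueError("need one probability per bin")
        if np.any(np.diff(self.bin_edges) <= 0):
            raise ValueError("bin edges must ascend")
        if np.any(self.probabilities < 0) or abs(self.probabilities.sum() - 1.0) > 1e-9:
            raise ValueError("probabilities must be non-negative and sum to 1")

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    def mass_in(self, lo: float, hi: float) -> float:
        """Probability mass of bins whose centre lies in [lo, hi]."""
        c = self.bin_centers
        return float(self.probabilities[(c >= lo) & (c <= hi)].sum())


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def _single_atom(traj: Trajectory, residue_id: int, atom_name: str, chain: str | None) -> int:
    sel = select_atoms(traj, chain=chain, residue_id=residue_id, atom_name=atom_name)
    if len(sel) != 1:
        raise ValueError(f"atom not found: residue {residue_id} atom {atom_name!r}")
    return sel.indices[0]


def distance_series(traj: Trajectory, cfg: NamedObservableConfig) -> DistanceSeries:
    """Per-frame Euclidean distance between the two configured atoms."""
    ia = _single_atom(traj, cfg.atom_a[0], cfg.atom_a[1], cfg.chain_a)
    ib = _single_atom(traj, cfg.atom_b[0], cfg.atom_b[1], cfg.chain_b)
    diff = traj.coords[:, ia, :] - traj.coords[:, ib, :]
    return DistanceSeries(name=cfg.name, values=np.linalg.norm(diff, axis=1))


def zone_anchor_from_residue(
    traj: Trajectory,
    residue_id: int,
    atom_name: str = "CA",
    chain: str | None = None,
    axis: tuple[float, float, float] | None = None,
) -> float:
    """Mean axial coordinate of one atom over the trajectory (zone anchor)."""
    idx = _single_atom(traj, residue_id, atom_name, chain)
    u = np.asarray(axis if axis is not None else _default_axis(), dtype=float)
    u = u / np.linalg.norm(u)
    return float(np.mean(traj.coords[:, idx, :] @ u))


def count_waters(
    traj: Trajectory,
    partition: ZonePartition,
    bundle_axis_point: tuple[float, float] | tuple[float, float, float] = (0.0, 0.0),
    zone_labels: tuple[str, ...] | None = None,
) -> WaterCountSeries:
    """Count water oxygens per frame and zone.

    A water oxygen is counted in zone ``i`` when its axial coordinate lies
    in the half-open interval ``[edges[i], edges[i+1])`` and its lateral
    distance from the bundle axis is ``<= lateral_radius_A``.
    """
    if zone_labels is None:
        zone_labels = tuple(f"area{i + 1}" for i in range(partition.n_zones))
    ox = [
        i
        for i, a in enumerate(traj.topology)
        if a.is_water and a.element.upper() == "O"
    ]
    counts = np.zeros((traj.n_frames, partition.n_zones), dtype=int)
    if not ox:
        warnings.warn("no water oxygens in topology; zone counts are all zero")
        return WaterCountSeries(counts=counts, zone_labels=zone_labels)

    u = np.asarray(partition.axis, dtype=float)
    p0 = np.asarray(bundle_axis_point, dtype=float)
    if p0.size == 2:
        p0 = np.array([p0[0], p0[1], 0.0])
    coords = traj.coords[:, ox, :]  # (n_frames, n_waters, 3)
    axial = coords @ u
    rel = coords - p0
    lateral = np.linalg.norm(rel - np.multiply.outer(rel @ u, u), axis=2)
    inside = lateral <= partition.lateral_radius_A
    edges = partition.edges
    for z in range(partition.n_zones):
        in_zone = (axial >= edges[z]) & (axial < edges[z + 1]) & inside
        counts[:, z] = in_zone.sum(axis=1)
    return WaterCountSeries(counts=counts, zone_labels=zone_labels)


def _bin_edges(values: np.ndarray, bin_width: float, integer_data: bool) -> np.ndarray:
    if integer_data:
        lo = int(np.floor(values.min()))
        hi = int(np.ceil(values.max()))
        return np.arange(lo, hi + 2) - 0.5  # unit bins centred on integers
    lo = np.floor(values.min() / bin_width) * bin_width
    hi = np.ceil(values.max() / bin_width) * bin_width
    if hi <= lo + 1e-12:  # constant series: one bin containing the value
        hi = lo + bin_width
    n = int(round((hi - lo) / bin_width))
    return lo + bin_width * np.arange(n + 1)


def _series_values(series) -> tuple[np.ndarray, bool]:
    if isinstance(series, DistanceSeries):
        return series.values, False
    if isinstance(series, WaterCountSeries):
        if series.counts.shape[1] != 1:
            raise ValueError("histogram a single zone: pass series.zone(i)")
        return series.counts[:, 0].astype(float), True
    arr = np.asarray(series)
    return arr.astype(float), np.issubdtype(arr.dtype, np.integer)


def histogram(series, bin_width: float = 0.2) -> Histogram:
    """Probability histogram of a per-frame series.

    Distances use ``bin_width`` Å bins aligned to multiples of the width;
    integer data (water counts) use unit bins centred on the integers.
    """
    values, integer_data = _series_values(series)
    if values.size == 0:
        raise ValueError("cannot histogram an empty series")
    if bin_width <= 0:
        raise ValueError("bin width must be positive")
    edges = _bin_edges(values, bin_width, integer_data)
    hist, _ = np.histogram(values, bins=edges)
    return Histogram(
        bin_edges=edges,
        probabilities=hist / values.size,
        n_samples=int(values.size),
    )


def conditional_histogram(
    series, condition: np.ndarray, bin_width: float = 0.2
) -> tuple[Histogram, np.ndarray]:
    """Histogram with a conditional overlay on the unconditional binning.

    The overlay gives, per bin, ``count(in bin AND condition) / n_samples``
    — i.e. it shares the unconditional denominator, so overlay mass never
    exceeds the unconditional mass bin-wise and its sum equals the fraction
    of frames satisfying the condition.
    """
    values, _ = _series_values(series)
    condition = np.asarray(condition, dtype=bool)
    if condition.shape != values.shape:
        raise ValueError("condition length must match series length")
    hist = histogram(series, bin_width=bin_width)
    sub, _ = np.histogram(values[condition], bins=hist.bin_edges)
    return hist, sub / values.size


def threshold_condition(series, predicate: str, value: float) -> np.ndarray:
    """Element-wise comparison of a series against a threshold."""
    values, _ = _series_values(series)
    ops = {
        ">": np.greater,
        "<": np.less,
        ">=": np.greater_equal,
        "<=": np.less_equal,
    }
    if predicate not in ops:
        raise ValueError(f"unknown predicate {predicate!r}")
    return ops[predicate](values, value)


def histogram_modes(hist: Histogram, min_prob: float = 0.002) -> list[tuple[float, float, float]]:
    """Contiguous runs of bins whose mass exceeds a noise floor.

    Returns ``(lower_edge, upper_edge, mass)`` per mode.  ``min_prob``
    suppresses isolated tail bins so that modality reflects the bulk of the
    distribution rather than single stray frames.
    """
    occupied = hist.probabilities >= min_prob
    modes = []
    start = None
    for i, occ in enumerate(occupied):
        if occ and start is None:
            start = i
        elif not occ and start is not None:
            modes.append((start, i))
            start = None
    if start is not None:
        modes.append((start, occupied.size))
    return [
        (
            float(hist.bin_edges[a]),
            float(hist.bin_edges[b]),
            float(hist.probabilities[a:b].sum()),
        )
        for a, b in modes
    ]
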