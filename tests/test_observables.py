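import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from gpcrtraj import (
    DistanceSeries,
    NamedObservableConfig,
    ZonePartition,
    conditional_histogram,
    count_waters,
    distance_series,
    histogram,
    histogram_modes,
    threshold_condition,
)
from conftest import simple_trajectory


def _water_specs(n):
    return [("W", 401 + i, "HOH", "O", "O", True) for i in range(n)]


def test_distance_series_constant_and_brute_force():
    coords = np.zeros((4, 2, 3))
    coords[:, 1, 2] = 8.0
    traj = simple_trajectory(coords)
    cfg = NamedObservableConfig("gap", (1, "CA"), (2, "CA"))
    assert np.array_equal(distance_series(traj, cfg).values, np.full(4, 8.0))

    rng = np.random.default_rng(0)
    coords = rng.uniform(-15, 15, (50, 2, 3))
    traj = simple_trajectory(coords)
    got = distance_series(traj, cfg).values
    brute = np.array([
        sum((coords[t, 0, k] - coords[t, 1, k]) ** 2 for k in range(3)) ** 0.5
        for t in range(50)
    ])
    assert np.max(np.abs(got - brute)) < 1e-9


def test_distance_series_rigid_motion_invariant():
    from scipy.spatial.transform import Rotation

    rng = np.random.default_rng(1)
    coords = rng.uniform(-10, 10, (20, 2, 3))
    traj = simple_trajectory(coords)
    cfg = NamedObservableConfig("gap", (1, "CA"), (2, "CA"))
    ref = distance_series(traj, cfg).values
    moved = np.stack([
        Rotation.random(rng=rng).apply(coords[t]) + rng.uniform(-40, 40, 3)
        for t in range(20)
    ])
    got = distance_series(simple_trajectory(moved), cfg).values
    assert np.max(np.abs(got - ref)) < 1e-9


def test_missing_atom_error_names_atom():
    traj = simple_trajectory(np.zeros((1, 1, 3)))
    with pytest.raises(ValueError, match=r"residue 2 atom 'CB'"):
        distance_series(traj, NamedObservableConfig("x", (1, "CA"), (2, "CB")))


def test_count_waters_no_waters_warns_and_zeros():
    traj = simple_trajectory(np.zeros((3, 2, 3)))
    with pytest.warns(UserWarning, match="no water oxygens"):
        wc = count_waters(traj, ZonePartition(anchor_z=0.0))
    assert not wc.counts.any()


def test_count_waters_matches_exhaustive_enumeration():
    part = ZonePartition(anchor_z=6.0)  # zones [-6,2), [2,10), [10,18)
    rng = np.random.default_rng(5)
    n_frames, n_w = 25, 20
    coords = np.empty((n_frames, n_w, 3))
    coords[:, :, 0] = rng.uniform(-12, 12, (n_frames, n_w))
    coords[:, :, 1] = rng.uniform(-12, 12, (n_frames, n_w))
    coords[:, :, 2] = rng.uniform(-10, 22, (n_frames, n_w))
    traj = simple_trajectory(coords, atom_specs=_water_specs(n_w))
    wc = count_waters(traj, part, (0.0, 0.0))
    edges = part.edges
    for t in range(n_frames):
        for z in range(3):
            expected = sum(
                1
                for w in range(n_w)
                if edges[z] <= coords[t, w, 2] < edges[z + 1]
                and (coords[t, w, 0] ** 2 + coords[t, w, 1] ** 2) ** 0.5 <= 8.0
            )
            assert wc.counts[t, z] == expected


def test_zone_boundary_is_half_open_upward():
    part = ZonePartition(anchor_z=6.0)
    # oxygen exactly on the area2/area3 boundary (z = 10) and on the
    # lateral radius; a second oxygen just outside the cylinder
    coords = np.array([[[0.0, 8.0, 10.0], [0.0, 8.0001, 10.0]]])
    traj = simple_trajectory(coords, atom_specs=_water_specs(2))
    wc = count_waters(traj, part, (0.0, 0.0))
    assert wc.counts[0].tolist() == [0, 0, 1]  # upper zone only, once
    assert wc.counts[0].sum() == 1


def test_zone_partition_geometry():
    part = ZonePartition(anchor_z=6.0)
    assert part.span_A == 24.0
    assert np.allclose(part.edges, [-6.0, 2.0, 10.0, 18.0])
    with pytest.raises(ValueError):
        ZonePartition(anchor_z=0.0, zone_width_A=-1.0)


def test_histogram_constant_series():
    hist = histogram(DistanceSeries("x", np.full(50, 6.0)), bin_width=0.2)
    assert hist.probabilities.sum() == pytest.approx(1.0)
    assert (hist.probabilities == 1.0).sum() == 1


def test_histogram_matches_hand_binned_mixture():
    rng = np.random.default_rng(9)
    values = np.concatenate([rng.normal(6, 0.3, 600), rng.normal(8.5, 0.5, 400)])
    hist = histogram(DistanceSeries("x", values), bin_width=0.2)
    for b in range(hist.probabilities.size):
        lo, hi = hist.bin_edges[b], hist.bin_edges[b + 1]
        last = b == hist.probabilities.size - 1
        manual = sum(
            1 for v in values if (lo <= v < hi) or (last and v == hi)
        )
        assert hist.probabilities[b] == pytest.approx(manual / 1000)
    assert hist.n_samples == 1000


def test_histogram_integer_data_unit_bins():
    counts = np.array([5, 5, 6, 7, 7, 7])
    hist = histogram(counts)
    assert np.allclose(np.diff(hist.bin_edges), 1.0)
    assert np.allclose(hist.bin_centers, [5, 6, 7])
    assert np.allclose(hist.probabilities, [2 / 6, 1 / 6, 3 / 6])


@settings(derandomize=True, max_examples=50)
@given(st.lists(st.floats(min_value=0.0, max_value=50.0), min_size=1, max_size=200))
def test_histogram_normalises(values):
    hist = histogram(DistanceSeries("x", np.array(values)), bin_width=0.5)
    assert abs(hist.probabilities.sum() - 1.0) < 1e-9


def test_histogram_empty_and_bad_width():
    with pytest.raises(ValueError):
        histogram(DistanceSeries("x", np.array([])))
    with pytest.raises(ValueError):
        histogram(DistanceSeries("x", np.array([1.0])), bin_width=0.0)


def test_conditional_histogram_identity_and_zero():
    rng = np.random.default_rng(2)
    series = DistanceSeries("x", rng.uniform(5, 9, 300))
    hist, overlay = conditional_histogram(series, np.ones(300, bool))
    assert np.allclose(overlay, hist.probabilities)
    _, overlay0 = conditional_histogram(series, np.zeros(300, bool))
    assert not overlay0.any()
    with pytest.raises(ValueError, match="length"):
        conditional_histogram(series, np.ones(299, bool))


def test_conditional_histogram_filter_then_bin_oracle():
    rng = np.random.default_rng(4)
    # two coupled channels: state selects both components
    state = rng.random(1000) < 0.4
    primary = np.where(state, rng.normal(8.5, 0.4, 1000), rng.normal(6.0, 0.3, 1000))
    secondary = np.where(state, rng.normal(21.0, 0.5, 1000), rng.normal(23.5, 0.5, 1000))
    cond = threshold_condition(DistanceSeries("p", primary), ">", 7.0)
    hist, overlay = conditional_histogram(DistanceSeries("s", secondary), cond)
    # oracle: filter first, then count on the same bins, same denominator
    for b in range(hist.probabilities.size):
        lo, hi = hist.bin_edges[b], hist.bin_edges[b + 1]
        last = b == hist.probabilities.size - 1
        manual = sum(
            1 for v, c in zip(secondary, cond)
            if c and ((lo <= v < hi) or (last and v == hi))
        )
        assert overlay[b] == pytest.approx(manual / 1000)
    # overlay never exceeds the unconditional mass; sums to the condition rate
    assert np.all(overlay <= hist.probabilities + 1e-12)
    assert overlay.sum() == pytest.approx(cond.mean())
    # mass concentrates in the coupled (shifted) component
    centers = hist.bin_centers
    assert overlay[centers < 22.25].sum() > 0.8 * overlay.sum()


@pytest.mark.parametrize(
    "values,pred,thr,expected",
    [
        ([6.5, 7.5], ">", 7.0, [False, True]),
        ([7, 8], "<=", 7, [True, False]),
        ([5.0, 6.0], ">", 4.0, [True, True]),
        ([5.0, 6.0], "<", 4.0, [False, False]),
        ([7.0], ">=", 7.0, [True]),
    ],
)
def test_threshold_condition(values, pred, thr, expected):
    got = threshold_condition(DistanceSeries("x", np.array(values, float)), pred, thr)
    assert got.tolist() == expected
    with pytest.raises(ValueError):
        threshold_condition(DistanceSeries("x", np.array([1.0])), "!=", 0.0)


def test_pooled_histogram_is_weighted_average_of_runs():
    rng = np.random.default_rng(8)
    run1 = rng.normal(6, 0.4, 400)
    run2 = rng.normal(8, 0.4, 200)
    pooled = np.concatenate([run1, run2])
    hist = histogram(DistanceSeries("x", pooled), bin_width=0.2)
    # oracle: per-run hand counts on the pooled binning, sample-weighted
    recombined = np.zeros_like(hist.probabilities)
    for run in (run1, run2):
        for b in range(hist.probabilities.size):
            lo, hi = hist.bin_edges[b], hist.bin_edges[b + 1]
            last = b == hist.probabilities.size - 1
            recombined[b] += sum(
                1 for v in run if (lo <= v < hi) or (last and v == hi)
            )
    recombined /= pooled.size
    assert np.allclose(hist.probabilities, recombined)


def test_histogram_modes_detects_contiguous_runs():
    values = np.concatenate([np.full(500, 6.0), np.full(300, 8.5)])
    hist = histogram(DistanceSeries("x", values), bin_width=0.2)
    modes = histogram_modes(hist)
    assert len(modes) == 2
    (lo1, hi1, m1), (lo2, hi2, m2) = modes
    assert lo1 <= 6.0 <= hi1 and lo2 <= 8.5 <= hi2
    assert m1 == pytest.approx(0.625) and m2 == pytest.approx(0.375)
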