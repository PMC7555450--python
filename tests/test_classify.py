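"""Thresholding, minimum-area filtering (vs a flood-fill oracle) and
co-localization classification."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fragquant.classify import (
    CLASS_NAMES,
    ThresholdConfig,
    classify_stack,
    classify_voxels,
    filter_min_area,
    threshold_channel,
)
from fragquant.io import ChannelStack
from fragquant.simulate import (
    STATE_DEAD,
    STATE_DYING,
    STATE_LIVE,
    simulate_fragment,
)
from fragquant.pipeline import midgap_thresholds

from conftest import noise_free


def _stack_from(green, red=None, apc=None, voxel=(1.0, 1.0, 1.0)):
    z = np.zeros_like(np.asarray(green, dtype=float))
    return ChannelStack(
        channels={
            "live_green": np.asarray(green, dtype=float),
            "til_red": z if red is None else np.asarray(red, dtype=float),
            "dead_apc": z if apc is None else np.asarray(apc, dtype=float),
        },
        voxel_size_um=voxel,
        time_h=0.0,
    )


# --------------------------------------------------------------------------
# thresholding
# --------------------------------------------------------------------------

def test_threshold_is_strict_inequality():
    vals = np.array([[[0.0, 10.0, 20.0, 50.0]]])
    stack = _stack_from(vals)
    cfg = ThresholdConfig(thresholds={"live_green": 20.0})
    mask = threshold_channel(stack, "live_green", cfg)
    np.testing.assert_array_equal(mask, [[[False, False, False, True]]])


def test_threshold_zero_is_positive_support():
    vals = np.array([[[0.0, 0.5, 3.0]]])
    stack = _stack_from(vals)
    cfg = ThresholdConfig(thresholds={"live_green": 0.0})
    np.testing.assert_array_equal(
        threshold_channel(stack, "live_green", cfg), vals > 0
    )


def test_unknown_channel_rejected():
    stack = _stack_from(np.zeros((1, 2, 2)))
    with pytest.raises(KeyError, match="nonsense"):
        threshold_channel(stack, "nonsense", ThresholdConfig(thresholds={"nonsense": 1}))
    with pytest.raises(KeyError, match="no threshold"):
        threshold_channel(stack, "live_green", ThresholdConfig())


@settings(derandomize=True, max_examples=30)
@given(
    thr_low=st.floats(0, 500),
    delta=st.floats(0, 500),
    seed=st.integers(0, 2**16),
)
def test_raising_threshold_never_gains_voxels(thr_low, delta, seed):
    rng = np.random.default_rng(seed)
    vals = rng.uniform(0, 1000, size=(2, 8, 8))
    stack = _stack_from(vals)
    lo = threshold_channel(
        stack, "live_green", ThresholdConfig(thresholds={"live_green": thr_low})
    )
    hi = threshold_channel(
        stack, "live_green",
        ThresholdConfig(thresholds={"live_green": thr_low + delta}),
    )
    assert hi.sum() <= lo.sum()
    assert np.all(lo | ~hi)  # hi is a subset of lo


def test_midgap_threshold_recovers_state_volume_within_5pct(tiny_params):
    """SNR 10 with a mid-gap green threshold: masked green volume within 5%
    of the true live+dying voxel count."""
    stacks, truth = simulate_fragment(tiny_params)
    cfg = midgap_thresholds(tiny_params, min_area_um2=0.0)
    for stack, labels in zip(stacks, truth.label_volumes):
        mask = threshold_channel(stack, "live_green", cfg)
        true_n = int(((labels == STATE_LIVE) | (labels == STATE_DYING)).sum())
        assert abs(int(mask.sum()) - true_n) <= 0.05 * true_n


# --------------------------------------------------------------------------
# minimum-area filter vs flood-fill oracle
# --------------------------------------------------------------------------

def _flood_fill_components(slice2d, connectivity):
    """Independent component enumeration: BFS flood fill on a 2D grid."""
    if connectivity == 1:
        nbrs = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    else:
        nbrs = [(dy, dx) for dy in (-1, 0, 1) for dx in (-1, 0, 1)
                if (dy, dx) != (0, 0)]
    seen = np.zeros_like(slice2d, dtype=bool)
    comps = []
    h, w = slice2d.shape
    for y in range(h):
        for x in range(w):
            if slice2d[y, x] and not seen[y, x]:
                queue = [(y, x)]
                seen[y, x] = True
                comp = []
                while queue:
                    cy, cx = queue.pop()
                    comp.append((cy, cx))
                    for dy, dx in nbrs:
                        ny, nx = cy + dy, cx + dx
                        if 0 <= ny < h and 0 <= nx < w and slice2d[ny, nx] \
                                and not seen[ny, nx]:
                            seen[ny, nx] = True
                            queue.append((ny, nx))
                comps.append(comp)
    return comps


def _oracle_filter(slice2d, min_pixels, connectivity):
    out = np.zeros_like(slice2d, dtype=bool)
    for comp in _flood_fill_components(slice2d, connectivity):
        if len(comp) >= min_pixels:
            for y, x in comp:
                out[y, x] = True
    return out


def test_small_region_below_cutoff_removed():
    mask = np.zeros((1, 6, 6), dtype=bool)
    mask[0, 2, 2:4] = True  # 2-pixel region
    cfg = ThresholdConfig(min_area_um2=3.0)  # 3 pixels' worth at 1x1 um pixels
    out = filter_min_area(mask, cfg, (1.0, 1.0, 1.0))
    assert not out.any()


def test_min_area_zero_is_identity():
    rng = np.random.default_rng(3)
    mask = rng.random((3, 10, 10)) > 0.6
    cfg = ThresholdConfig(min_area_um2=0.0)
    np.testing.assert_array_equal(filter_min_area(mask, cfg, (1, 1, 1)), mask)


def test_mixed_region_sizes_survivors():
    """Regions of pixel-areas {2, 5, 9} with a 4-pixel cutoff: 14 pixels keep."""
    mask = np.zeros((1, 12, 12), dtype=bool)
    mask[0, 0, 0:2] = True                 # area 2 -> removed
    mask[0, 4, 4:9] = True                 # area 5 -> kept
    mask[0, 8:11, 8:11] = True             # area 9 -> kept
    cfg = ThresholdConfig(min_area_um2=4.0, connectivity=2)
    out = filter_min_area(mask, cfg, (1.0, 1.0, 1.0))
    assert int(out.sum()) == 14


def test_region_exactly_at_cutoff_is_kept():
    mask = np.zeros((1, 5, 5), dtype=bool)
    mask[0, 1, 1:4] = True  # exactly 3 pixels
    cfg = ThresholdConfig(min_area_um2=3.0)
    out = filter_min_area(mask, cfg, (1.0, 1.0, 1.0))
    assert int(out.sum()) == 3


@pytest.mark.parametrize("connectivity", [1, 2])
def test_filter_matches_flood_fill_oracle(connectivity):
    rng = np.random.default_rng(42)
    for _ in range(100):
        slice2d = rng.random((16, 16)) > rng.uniform(0.4, 0.8)
        min_pixels = int(rng.integers(1, 7))
        cfg = ThresholdConfig(min_area_um2=float(min_pixels),
                              connectivity=connectivity)
        got = filter_min_area(slice2d[None], cfg, (1.0, 1.0, 1.0))[0]
        want = _oracle_filter(slice2d, min_pixels, connectivity)
        np.testing.assert_array_equal(got, want)


def test_3d_mode_joins_regions_across_slices():
    # two single-pixel regions stacked in z: removed in 2D mode, kept in 3D
    mask = np.zeros((2, 4, 4), dtype=bool)
    mask[0, 1, 1] = mask[1, 1, 1] = True
    voxel = (1.0, 1.0, 1.0)
    cfg2d = ThresholdConfig(min_area_um2=2.0, mode="2d")
    cfg3d = ThresholdConfig(min_area_um2=2.0, mode="3d")
    assert not filter_min_area(mask, cfg2d, voxel).any()
    assert filter_min_area(mask, cfg3d, voxel).sum() == 2


# --------------------------------------------------------------------------
# classification
# --------------------------------------------------------------------------

_EXPECTED_CLASS = {
    # (green, red, apc) -> class
    (False, False, False): "background",
    (True, False, False): "live",
    (False, False, True): "dead",
    (True, False, True): "dying",
    (False, True, False): "til",
    (False, True, True): "dying_til",
    (True, True, False): "til_on_live",
    (True, True, True): "dying_til",  # TIL death takes precedence
}


@pytest.mark.parametrize("combo", sorted(_EXPECTED_CLASS))
def test_classification_table(combo):
    g, r, a = combo
    masks = {
        "live_green": np.full((1, 1, 1), g),
        "til_red": np.full((1, 1, 1), r),
        "dead_apc": np.full((1, 1, 1), a),
    }
    cv = classify_voxels(masks, (1.0, 1.0, 1.0))
    assert CLASS_NAMES[cv.labels[0, 0, 0]] == _EXPECTED_CLASS[combo]


@settings(derandomize=True, max_examples=25)
@given(seed=st.integers(0, 2**16))
def test_classes_partition_grid(seed):
    rng = np.random.default_rng(seed)
    masks = {c: rng.random((3, 6, 6)) > 0.5
             for c in ("live_green", "til_red", "dead_apc")}
    cv = classify_voxels(masks, (2.0, 2.0, 10.0))
    assert sum(cv.counts.values()) == 3 * 6 * 6
    # volumes are counts x voxel volume
    assert cv.volumes_um3["live"] == cv.counts["live"] * 40.0


def test_mask_grid_mismatch_rejected():
    masks = {
        "live_green": np.zeros((1, 2, 2), bool),
        "til_red": np.zeros((1, 2, 2), bool),
        "dead_apc": np.zeros((1, 2, 3), bool),
    }
    with pytest.raises(ValueError, match="differ"):
        classify_voxels(masks, (1, 1, 1))


def test_noise_free_simulation_recovered_exactly(tiny_noise_free):
    """On noise-free simulator output with mid-gap thresholds, classification
    reproduces the truth labels exactly under the dye-rendering map."""
    stacks, truth = simulate_fragment(tiny_noise_free)
    cfg = midgap_thresholds(tiny_noise_free, min_area_um2=0.0)
    for stack, labels, til, dtil in zip(
        stacks, truth.label_volumes, truth.til_masks, truth.dying_til_masks
    ):
        cv = classify_stack(stack, cfg)
        got = np.array(CLASS_NAMES)[cv.labels]
        want = np.full(labels.shape, "background", dtype=object)
        want[labels == STATE_LIVE] = "live"
        want[labels == STATE_DYING] = "dying"
        want[labels == STATE_DEAD] = "dead"
        # overlay the TIL rendering
        til_on_green = til & ((labels == STATE_LIVE) | (labels == STATE_DYING))
        want[til] = "til"
        want[til & (labels == STATE_DEAD)] = "dying_til"
        want[til_on_green & (labels == STATE_LIVE)] = "til_on_live"
        want[til & (labels == STATE_DYING)] = "dying_til"
        want[dtil] = "dying_til"
        want[dtil & ((labels == STATE_LIVE))] = "dying_til"
        np.testing.assert_array_equal(got.astype(str), want.astype(str))
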