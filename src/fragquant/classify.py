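"""Five-class co-localization labeling of multi-channel stacks.

Raw intensities become per-channel binary masks through a low-intensity
threshold (strict ``>``), small connected regions are discarded per z-slice
as noise, and each voxel is classified by the set of channels for which it
is positive:

================  =========================  =======================
class             channels positive          interpretation
================  =========================  =======================
live              green only                 intact tumor tissue
dead              APC only                   dead cells, green lost
dying             green + APC                early-apoptotic tumor
til               red only                   TIL
dying_til         red + APC (green or not)   annexin-positive TIL
til_on_live       red + green                TIL over live tumor
background        none                       no signal
================  =========================  =======================

A voxel positive in all three channels is assigned ``dying_til`` (TIL death
takes precedence over the underlying tumor signal); the choice is recorded
in the output provenance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from skimage import measure

from .io import CHANNELS, ChannelStack

CLASS_NAMES = ("background", "live", "dead", "dying", "til", "dying_til", "til_on_live")
CLASS_CODES = {name: i for i, name in enumerate(CLASS_NAMES)}


@dataclass(frozen=True)
class ThresholdConfig:
    """Per-channel low-intensity thresholds and the minimum-region filter.

    ``min_area_um2`` is a physical area applied per 2D z-slice (the default
    ``mode="2d"``); connected regions smaller than it are discarded as
    noise, regions at least as large are kept untouched. ``connectivity``
    selects the 2D neighborhood: 1 = 4-connected, 2 = 8-connected. In
    ``mode="3d"`` components are found with the 3D analogue of the chosen
    connectivity and the cutoff becomes the volume ``min_area_um2 * dz``.
    """

    thresholds: dict[str, float] = field(default_factory=dict)
    min_area_um2: float = 0.0
    connectivity: int = 2
    mode: str = "2d"

    def __post_init__(self) -> None:
        for name, thr in self.thresholds.items():
            if thr < 0:
                raise ValueError(f"threshold for {name} must be >= 0, got {thr}")
        if self.min_area_um2 < 0:
            raise ValueError("min_area_um2 must be >= 0")
        if self.connectivity not in (1, 2):
            raise ValueError("connectivity must be 1 (4-neighbor) or 2 (8-neighbor)")
        if self.mode not in ("2d", "3d"):
            raise ValueError("mode must be '2d' or '3d'")


@dataclass
class ClassifiedVolume:
    """Per-voxel class labels plus class counts/volumes and provenance."""

    labels: np.ndarray  # uint8, codes per CLASS_CODES
    voxel_size_um: tuple[float, float, float]
    config: ThresholdConfig
    fragment_id: str = "frag"
    time_h: float = 0.0

    @property
    def counts(self) -> dict[str, int]:
        c = np.bincount(self.labels.ravel(), minlength=len(CLASS_NAMES))
        return {name: int(c[i]) for i, name in enumerate(CLASS_NAMES)}

    @property
    def volumes_um3(self) -> dict[str, float]:
        dx, dy, dz = self.voxel_size_um
        vv = dx * dy * dz
        return {name: n * vv for name, n in self.counts.items()}

    @property
    def voxel_volume_um3(self) -> float:
        dx, dy, dz = self.voxel_size_um
        return dx * dy * dz


def threshold_channel(
    stack: ChannelStack, channel: str, config: ThresholdConfig
) -> np.ndarray:
    """Binary mask of voxels whose intensity strictly exceeds the threshold."""
    if channel not in stack.channels:
        raise KeyError(
            f"unknown channel {channel!r}; stack has {list(stack.channels)}"
        )
    if channel not in config.thresholds:
        raise KeyError(f"no threshold configured for channel {channel!r}")
    return stack.channels[channel] > config.thresholds[channel]


def filter_min_area(
    mask: np.ndarray,
    config: ThresholdConfig,
    voxel_size_um: tuple[float, float, float],
) -> np.ndarray:
    """Remove connected regions smaller than the configured minimum.

    In 2D mode each z-slice is labeled independently and regions with area
    (pixels x dx x dy) strictly below ``min_area_um2`` are zeroed. In 3D
    mode a single 3D labeling is used with cutoff ``min_area_um2 * dz`` on
    component volume.
    """
    if config.min_area_um2 <= 0:
        return mask.copy()
    dx, dy, dz = voxel_size_um
    out = np.zeros_like(mask, dtype=bool)
    if config.mode == "2d":
        pixel_area = dx * dy
        for z in range(mask.shape[0]):
            sl = mask[z]
            if not sl.any():
                continue
            lab = measure.label(sl, connectivity=config.connectivity)
            sizes = np.bincount(lab.ravel())
            keep = sizes * pixel_area >= config.min_area_um2
            keep[0] = False
            out[z] = keep[lab]
    else:
        if mask.any():
            conn3d = 3 if config.connectivity == 2 else 1
            lab = measure.label(mask, connectivity=conn3d)
            sizes = np.bincount(lab.ravel())
            vv = dx * dy * dz
            keep = sizes * vv >= config.min_area_um2 * dz
            keep[0] = False
            out = keep[lab]
    return out


def classify_voxels(
    masks: Mapping[str, np.ndarray],
    voxel_size_um: tuple[float, float, float],
    config: ThresholdConfig | None = None,
    fragment_id: str = "frag",
    time_h: float = 0.0,
) -> ClassifiedVolume:
    """Combine per-channel masks into the mutually exclusive class labels.

    ``masks`` must contain ``live_green``, ``til_red`` and ``dead_apc`` on a
    shared grid. The classes partition the grid: every voxel gets exactly
    one label.
    """
    missing = [c for c in CHANNELS if c not in masks]
    if missing:
        raise KeyError(f"missing channel mask(s): {missing}")
    green = np.asarray(masks["live_green"], dtype=bool)
    red = np.asarray(masks["til_red"], dtype=bool)
    apc = np.asarray(masks["dead_apc"], dtype=bool)
    if not (green.shape == red.shape == apc.shape):
        raise ValueError(
            f"mask grids differ: green {green.shape}, red {red.shape}, apc {apc.shape}"
        )

    labels = np.zeros(green.shape, dtype=np.uint8)
    labels[green & ~red & ~apc] = CLASS_CODES["live"]
    labels[apc & ~green & ~red] = CLASS_CODES["dead"]
    labels[green & apc & ~red] = CLASS_CODES["dying"]
    labels[red & ~green & ~apc] = CLASS_CODES["til"]
    labels[red & apc] = CLASS_CODES["dying_til"]  # incl. triple-positive
    labels[red & green & ~apc] = CLASS_CODES["til_on_live"]

    return ClassifiedVolume(
        labels=labels,
        voxel_size_um=voxel_size_um,
        config=config if config is not None else ThresholdConfig(),
        fragment_id=fragment_id,
        time_h=time_h,
    )


def classify_stack(stack: ChannelStack, config: ThresholdConfig) -> ClassifiedVolume:
    """Threshold, noise-filter and classify one stack in a single call."""
    masks = {
        c: filter_min_area(
            threshold_channel(stack, c, config), config, stack.voxel_size_um
        )
        for c in CHANNELS
    }
    return classify_voxels(
        masks,
        voxel_size_um=stack.voxel_size_um,
        config=config,
        fragment_id=stack.fragment_id,
        time_h=stack.time_h,
    )


def suggest_thresholds(stacks: list[ChannelStack]) -> dict[str, float]:
    """Otsu-based per-channel threshold initializer, pooled over an experiment.

    A convenience starting point only — thresholds remain an explicit user
    input and are never applied silently.
    """
    from skimage.filters import threshold_otsu

    out: dict[str, float] = {}
    for c in CHANNELS:
        pooled = np.concatenate([s.channels[c].ravel() for s in stacks])
        out[c] = float(threshold_otsu(pooled))
    return out
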