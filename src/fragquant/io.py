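"""Image-stack and experiment-layout I/O.

On-disk model: one multi-page TIFF per fragment per timepoint (pages are
z-planes, channel-major), a JSON sidecar declaring channel order, voxel
sizes and acquisition time, and a YAML layout file mapping fragments to
treatment conditions and stack files.

Coordinate convention used throughout the package: arrays are indexed
``(z, y, x)``, 0-based, with values at voxel centers. Channel identity is
always carried by name (the sidecar), never by page order.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile
import yaml

#: Canonical channel names: CellTracker Green (live tumor tissue),
#: CellTracker Red (TILs), annexin V-APC (dead/dying cells).
CHANNELS = ("live_green", "til_red", "dead_apc")

#: Closed vocabulary of treatment conditions.
CONDITIONS = ("isotype", "anti_PD1", "anti_CTLA4")

_SIDECAR_REQUIRED = ("channels", "shape_zyx", "voxel_size_um", "time_h", "fragment_id")


@dataclass
class ChannelStack:
    """One fragment's multi-channel 3D intensity volume at one timepoint.

    Parameters
    ----------
    channels
        Mapping from channel name to a 3D ``(z, y, x)`` array of
        non-negative intensities. All channels share one grid.
    voxel_size_um
        ``(dx, dy, dz)`` voxel dimensions in micrometers.
    time_h
        Hours since the start of TIL perfusion.
    fragment_id
        Opaque fragment identifier.
    """

    channels: dict[str, np.ndarray]
    voxel_size_um: tuple[float, float, float]
    time_h: float
    fragment_id: str = "frag"

    def __post_init__(self) -> None:
        if not self.channels:
            raise ValueError("stack has no channels")
        shapes = {name: arr.shape for name, arr in self.channels.items()}
        first = next(iter(shapes.values()))
        if len(first) != 3:
            raise ValueError(f"channel arrays must be 3D (z, y, x), got shape {first}")
        for name, shp in shapes.items():
            if shp != first:
                raise ValueError(
                    f"channel dimension mismatch: {name} has {shp}, expected {first}"
                )
        dx, dy, dz = self.voxel_size_um
        if min(dx, dy, dz) <= 0:
            raise ValueError(f"voxel sizes must be positive, got {self.voxel_size_um}")
        for name, arr in self.channels.items():
            if np.any(arr < 0):
                raise ValueError(f"channel {name} contains negative intensities")

    @property
    def shape(self) -> tuple[int, int, int]:
        return next(iter(self.channels.values())).shape

    @property
    def voxel_volume_um3(self) -> float:
        dx, dy, dz = self.voxel_size_um
        return dx * dy * dz

    @property
    def channel_names(self) -> tuple[str, ...]:
        return tuple(self.channels)


def _sidecar_path(tiff_path: Path) -> Path:
    return tiff_path.with_suffix(tiff_path.suffix + ".json")


def write_stack(stack: ChannelStack, path: str | Path, sidecar: str | Path | None = None) -> Path:
    """Write a stack as a channel-major multi-page TIFF plus JSON sidecar.

    Pages are ordered channel-major: all z-planes of the first channel,
    then the next channel. Returns the sidecar path.
    """
    path = Path(path)
    sidecar = _sidecar_path(path) if sidecar is None else Path(sidecar)
    names = stack.channel_names
    data = np.stack([stack.channels[c] for c in names])  # (C, Z, Y, X)
    c, z, y, x = data.shape
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, data.reshape(c * z, y, x), photometric="minisblack")
    meta = {
        "channels": list(names),
        "shape_zyx": [z, y, x],
        "voxel_size_um": [float(v) for v in stack.voxel_size_um],
        "time_h": float(stack.time_h),
        "fragment_id": stack.fragment_id,
    }
    sidecar.write_text(json.dumps(meta, indent=1))
    return sidecar


def read_stack(path: str | Path, sidecar: str | Path | None = None) -> ChannelStack:
    """Read a multi-page TIFF + sidecar back into a :class:`ChannelStack`.

    Channels are mapped by the names declared in the sidecar, never by
    page-order assumptions. Raises ``ValueError`` on a missing sidecar
    field, a page count inconsistent with the declared shape (the error
    names the missing channels), or fewer than the declared channels.
    """
    path = Path(path)
    sidecar = _sidecar_path(path) if sidecar is None else Path(sidecar)
    if not sidecar.exists():
        raise FileNotFoundError(f"sidecar not found: {sidecar}")
    meta = json.loads(sidecar.read_text())
    missing = [k for k in _SIDECAR_REQUIRED if k not in meta]
    if missing:
        raise ValueError(f"sidecar {sidecar} missing required field(s): {missing}")
    names = list(meta["channels"])
    z, y, x = (int(v) for v in meta["shape_zyx"])
    pages = tifffile.imread(path)
    if pages.ndim == 2:
        pages = pages[None]
    n_pages = pages.shape[0]
    if pages.shape[1:] != (y, x):
        raise ValueError(
            f"page dimensions {pages.shape[1:]} do not match sidecar shape ({y}, {x})"
        )
    expected = len(names) * z
    if n_pages != expected:
        if n_pages % z == 0 and n_pages < expected:
            absent = names[n_pages // z :]
            raise ValueError(
                f"{path} has {n_pages} pages but sidecar declares {expected}; "
                f"missing channel(s): {absent}"
            )
        raise ValueError(
            f"{path} has {n_pages} pages, expected {expected} "
            f"({len(names)} channels x {z} z-planes)"
        )
    data = pages.reshape(len(names), z, y, x)
    return ChannelStack(
        channels={name: data[i] for i, name in enumerate(names)},
        voxel_size_um=tuple(float(v) for v in meta["voxel_size_um"]),
        time_h=float(meta["time_h"]),
        fragment_id=str(meta["fragment_id"]),
    )


@dataclass
class FragmentInfo:
    fragment_id: str
    condition: str
    tumor_model: str = ""


@dataclass
class ExperimentLayout:
    """Validated map of a multi-fragment, multi-condition experiment.

    ``stack_paths`` maps ``(fragment_id, time_h)`` to a stack file; it may
    be empty for fully in-memory runs.
    """

    fragments: list[FragmentInfo]
    time_points_h: list[float]
    stack_paths: dict[tuple[str, float], Path] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.fragments:
            raise ValueError("layout declares no fragments")
        seen: set[str] = set()
        for frag in self.fragments:
            if frag.fragment_id in seen:
                raise ValueError(f"duplicate fragment_id: {frag.fragment_id}")
            seen.add(frag.fragment_id)
            if frag.condition not in CONDITIONS:
                raise ValueError(
                    f"unknown condition {frag.condition!r} for fragment "
                    f"{frag.fragment_id}; allowed conditions: {list(CONDITIONS)}"
                )

    @property
    def condition_of(self) -> dict[str, str]:
        return {f.fragment_id: f.condition for f in self.fragments}

    @property
    def group_sizes(self) -> dict[str, int]:
        sizes: dict[str, int] = {}
        for f in self.fragments:
            sizes[f.condition] = sizes.get(f.condition, 0) + 1
        return sizes

    def missing_paths(self) -> list[Path]:
        return [p for p in self.stack_paths.values() if not p.exists()]


def load_layout(path: str | Path) -> ExperimentLayout:
    """Load and validate an experiment layout from YAML.

    Validation is exhaustive before any stack file is opened: unknown
    condition labels, duplicate fragment ids, an empty fragment list, and
    declared conditions with zero fragments are all rejected up front, and
    unresolved stack paths are reported as a group.
    """
    path = Path(path)
    raw = yaml.safe_load(path.read_text())
    if not isinstance(raw, dict):
        raise ValueError(f"layout file {path} is not a mapping")
    frag_entries = raw.get("fragments") or []
    fragments = [
        FragmentInfo(
            fragment_id=str(e["fragment_id"]),
            condition=str(e["condition"]),
            tumor_model=str(e.get("tumor_model", "")),
        )
        for e in frag_entries
    ]
    time_points = [float(t) for t in raw.get("time_points_h", [])]

    stack_paths: dict[tuple[str, float], Path] = {}
    for entry in frag_entries:
        for t, rel in (entry.get("stacks") or {}).items():
            stack_paths[(str(entry["fragment_id"]), float(t))] = path.parent / rel

    layout = ExperimentLayout(fragments=fragments, time_points_h=time_points,
                              stack_paths=stack_paths)

    declared = raw.get("conditions")
    if declared is not None:
        present = layout.group_sizes
        for cond in declared:
            if cond not in CONDITIONS:
                raise ValueError(
                    f"unknown condition {cond!r}; allowed conditions: {list(CONDITIONS)}"
                )
            if present.get(cond, 0) == 0:
                raise ValueError(f"declared condition {cond!r} has zero fragments")

    missing = layout.missing_paths()
    if missing:
        raise FileNotFoundError(
            f"{len(missing)} stack file(s) referenced by {path} do not exist, "
            f"e.g. {missing[0]}"
        )
    return layout


def save_layout(layout: ExperimentLayout, path: str | Path) -> Path:
    """Write a layout to YAML with stack paths relative to the YAML file."""
    path = Path(path)
    frag_entries = []
    for f in layout.fragments:
        stacks = {
            float(t): str(Path(p).resolve().relative_to(path.parent.resolve()))
            for (fid, t), p in layout.stack_paths.items()
            if fid == f.fragment_id
        }
        entry: dict = {
            "fragment_id": f.fragment_id,
            "condition": f.condition,
            "tumor_model": f.tumor_model,
        }
        if stacks:
            entry["stacks"] = stacks
        frag_entries.append(entry)
    doc = {
        "time_points_h": [float(t) for t in layout.time_points_h],
        "fragments": frag_entries,
    }
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(yaml.safe_dump(doc, sort_keys=False))
    return path
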