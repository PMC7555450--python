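"""Synthetic tumor-fragment image simulator with known ground truth.

Generates 4D (x, y, z, t) three-channel confocal-like stacks of a perfused
tumor fragment under TIL attack. The model is deliberately phenomenological:
its job is to produce image data whose true voxel states are known exactly,
so the co-localization pipeline can be validated end to end, not to be a
mechanistic model of immune killing.

Geometry and kinetics
---------------------
* The fragment is a spheroid (default equivalent diameter 150-300 um) with
  a smooth random radial perturbation capturing biopsy-fragment
  irregularity. Depth below the surface of a voxel is measured radially.
* A perimeter ring of depth ``perimeter_damage_depth_um`` is dead at t=0,
  emulating tissue damage from fragmentation and device loading.
* A killing front advances inward at ``kill_front_speed_um_h``; a voxel at
  depth d (beyond the damage ring) enters the "dying" state at
  ``t = (d - damage) / speed``, stays dying for ``dying_duration_h``, then
  becomes "dead". Transitions are monotone per voxel: live -> dying -> dead.
* TILs arrive on the fragment surface as a Poisson process (rate per um^2
  of surface per hour), burrow inward at ``til_infiltration_speed_um_h``,
  and accelerate death locally within ``til_kill_radius_um`` of their path
  (contact-killing foci). TILs older than ``til_death_age_h`` become
  annexin-positive themselves ("dying TILs").

Dye rendering
-------------
* live/dying tumor voxels carry CellTracker Green signal that photobleaches
  as ``exp(-green_bleach_rate * t)``; dead voxels have lost green.
* dying and dead voxels (and dying TILs) carry annexin V-APC signal.
* TIL voxels carry CellTracker Red signal.
* Noise: additive Gaussian background (mean ``background_level``, sd
  ``background_sd``) plus zero-mean Gaussian dispersion proportional to the
  noise-free signal (``signal_dispersion``), clipped at zero. Setting all
  three to zero yields a noise-free rendering that matches the truth labels
  exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .io import CHANNELS, ChannelStack

# Tumor voxel state codes in truth label volumes.
STATE_OUTSIDE, STATE_LIVE, STATE_DYING, STATE_DEAD = 0, 1, 2, 3
STATE_NAMES = {0: "outside", 1: "live", 2: "dying", 3: "dead"}

#: Condition presets: multipliers on (kill_front_speed, til_surface_rate).
#: These potencies are free modelling parameters chosen so that treated
#: fragments die measurably faster than isotype controls; they are not
#: measured quantities.
CONDITION_PRESETS: dict[str, tuple[float, float]] = {
    "isotype": (1.0, 1.0),
    "anti_PD1": (2.4, 2.0),
    "anti_CTLA4": (4.0, 3.0),
}


def _default_times() -> tuple[float, ...]:
    # every 4 h from the pre-TIL baseline through Day 4 of perfusion
    return tuple(float(t) for t in range(0, 97, 4))


def _default_base_intensities() -> dict[str, float]:
    return {"live_green": 1000.0, "til_red": 800.0, "dead_apc": 900.0}


@dataclass(frozen=True)
class SimulationParams:
    """Parameters of one simulated fragment time series.

    All lengths are micrometers, times hours, rates per hour. Identical
    params (including ``seed``) produce bit-identical output.
    """

    fragment_diameter_um: float = 200.0
    radial_perturbation: float = 0.10
    voxel_size_um: tuple[float, float, float] = (4.0, 4.0, 10.0)  # dx, dy, dz
    time_points_h: tuple[float, ...] = field(default_factory=_default_times)
    perimeter_damage_depth_um: float = 10.0
    kill_front_speed_um_h: float = 0.05
    dying_duration_h: float = 24.0
    til_surface_rate_per_um2_h: float = 5.0e-6
    til_infiltration_speed_um_h: float = 2.0
    til_radius_um: float = 5.0
    til_kill_radius_um: float = 6.0
    til_death_age_h: float = 48.0
    green_bleach_rate_per_h: float = 0.005
    base_intensities: dict[str, float] = field(default_factory=_default_base_intensities)
    background_level: float = 100.0
    background_sd: float = 20.0
    signal_dispersion: float = 0.05
    grid_shape: tuple[int, int, int] | None = None  # (nz, ny, nx); auto if None
    seed: int = 0

    def validate(self) -> None:
        if self.fragment_diameter_um <= 0:
            raise ValueError("fragment_diameter_um must be positive")
        if not (0 <= self.radial_perturbation < 1):
            raise ValueError("radial_perturbation must be in [0, 1)")
        if min(self.voxel_size_um) <= 0:
            raise ValueError("voxel sizes must be positive")
        if len(self.time_points_h) == 0:
            raise ValueError("time_points_h is empty")
        tp = list(self.time_points_h)
        if any(t < 0 for t in tp) or tp != sorted(tp):
            raise ValueError("time_points_h must be non-negative and sorted")
        for name in (
            "perimeter_damage_depth_um", "kill_front_speed_um_h", "dying_duration_h",
            "til_surface_rate_per_um2_h", "til_infiltration_speed_um_h",
            "green_bleach_rate_per_h", "background_level", "background_sd",
            "signal_dispersion", "til_radius_um", "til_kill_radius_um",
            "til_death_age_h",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.dying_duration_h == 0:
            raise ValueError("dying_duration_h must be positive")
        missing = [c for c in CHANNELS if c not in self.base_intensities]
        if missing:
            raise ValueError(f"base_intensities missing channel(s): {missing}")

    @property
    def max_radius_um(self) -> float:
        return 0.5 * self.fragment_diameter_um * (1.0 + self.radial_perturbation)

    def resolved_grid_shape(self) -> tuple[int, int, int]:
        """Grid shape (nz, ny, nx) holding the fragment with >= 2 voxels margin."""
        if self.grid_shape is not None:
            return self.grid_shape
        dx, dy, dz = self.voxel_size_um
        extent = 2.0 * self.max_radius_um
        return (
            int(math.ceil(extent / dz)) + 5,
            int(math.ceil(extent / dy)) + 5,
            int(math.ceil(extent / dx)) + 5,
        )


def params_for_condition(base: SimulationParams, condition: str) -> SimulationParams:
    """Scale kill-front speed and TIL arrival rate by the condition preset."""
    if condition not in CONDITION_PRESETS:
        raise ValueError(
            f"unknown condition {condition!r}; presets: {list(CONDITION_PRESETS)}"
        )
    k_mult, t_mult = CONDITION_PRESETS[condition]
    return replace(
        base,
        kill_front_speed_um_h=base.kill_front_speed_um_h * k_mult,
        til_surface_rate_per_um2_h=base.til_surface_rate_per_um2_h * t_mult,
    )


@dataclass
class SimulationTruth:
    """Ground truth of one simulated fragment time series.

    ``label_volumes[i]`` holds tumor state codes (0 outside, 1 live,
    2 dying, 3 dead) on the image grid at ``time_points_h[i]``;
    ``til_masks[i]`` marks TIL-occupied voxels and ``dying_til_masks[i]``
    the subset that is annexin-positive. ``true_fraction`` is the dying
    voxel count divided by the full initial tumor voxel count
    (live + dying + dead), which is conserved over time.
    """

    time_points_h: list[float]
    n_live: list[int]
    n_dying: list[int]
    n_dead: list[int]
    true_fraction: list[float]
    n_til_voxels: list[int]
    max_til_depth_um: list[float]
    label_volumes: list[np.ndarray]
    til_masks: list[np.ndarray]
    dying_til_masks: list[np.ndarray]
    fragment_mask: np.ndarray
    voxel_size_um: tuple[float, float, float]

    @property
    def n_fragment_voxels(self) -> int:
        return int(self.fragment_mask.sum())

    @property
    def equivalent_diameter_um(self) -> float:
        dx, dy, dz = self.voxel_size_um
        vol = self.n_fragment_voxels * dx * dy * dz
        return (6.0 * vol / math.pi) ** (1.0 / 3.0)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_h": self.time_points_h,
                "n_live": self.n_live,
                "n_dying": self.n_dying,
                "n_dead": self.n_dead,
                "true_fraction": self.true_fraction,
                "n_til_voxels": self.n_til_voxels,
                "max_til_depth_um": self.max_til_depth_um,
            }
        )


def _sphere_offsets(radius_um: float, voxel_size_um: tuple[float, float, float]) -> np.ndarray:
    """Integer (dz, dy, dx) offsets of voxels within a physical radius."""
    dx, dy, dz = voxel_size_um
    nz = int(radius_um // dz)
    ny = int(radius_um // dy)
    nx = int(radius_um // dx)
    zz, yy, xx = np.mgrid[-nz : nz + 1, -ny : ny + 1, -nx : nx + 1]
    keep = (zz * dz) ** 2 + (yy * dy) ** 2 + (xx * dx) ** 2 <= radius_um**2
    return np.stack([zz[keep], yy[keep], xx[keep]], axis=1)


class _RadialPerturbation:
    """Smooth random perturbation of the directional radius.

    A random degree-<=2 polynomial in the direction cosines, rescaled so its
    maximum absolute value over the grid directions is 1; the fragment
    radius along direction u is ``R0 * (1 + amplitude * s(u))``.
    """

    def __init__(self, rng: np.random.Generator, amplitude: float):
        self.amplitude = amplitude
        self.coef = rng.normal(size=8)
        self._scale = 1.0

    def _raw(self, ux, uy, uz):
        c = self.coef
        return (
            c[0] * ux + c[1] * uy + c[2] * uz
            + c[3] * ux * uy + c[4] * uy * uz + c[5] * uz * ux
            + c[6] * (ux**2 - uy**2) + c[7] * (2 * uz**2 - ux**2 - uy**2) / 2.0
        )

    def calibrate(self, ux, uy, uz) -> None:
        if self.amplitude == 0:
            return
        m = float(np.max(np.abs(self._raw(ux, uy, uz))))
        self._scale = 1.0 / m if m > 0 else 1.0

    def __call__(self, ux, uy, uz):
        if self.amplitude == 0:
            return np.zeros_like(np.asarray(ux, dtype=float))
        return self.amplitude * self._scale * self._raw(ux, uy, uz)


def simulate_fragment(
    params: SimulationParams, fragment_id: str = "sim"
) -> tuple[list[ChannelStack], SimulationTruth]:
    """Simulate one fragment and render its three-channel stacks over time.

    Returns one :class:`~fragquant.io.ChannelStack` per entry of
    ``params.time_points_h`` plus the :class:`SimulationTruth` describing
    the noise-free voxel states behind them.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    dx, dy, dz = params.voxel_size_um
    nz, ny, nx = params.resolved_grid_shape()
    r0 = 0.5 * params.fragment_diameter_um

    half = (nz * dz / 2.0, ny * dy / 2.0, nx * dx / 2.0)
    need = params.max_radius_um
    for h, step in zip(half, (dz, dy, dx)):
        if need + 2.0 * step > h:
            raise ValueError(
                f"fragment (max radius {need:.1f} um) does not fit in the "
                f"field of view with a 2-voxel margin (grid {nz}x{ny}x{nx}, "
                f"voxel {params.voxel_size_um} um)"
            )

    # physical voxel-center coordinates relative to the grid center
    zc = (np.arange(nz) - (nz - 1) / 2.0) * dz
    yc = (np.arange(ny) - (ny - 1) / 2.0) * dy
    xc = (np.arange(nx) - (nx - 1) / 2.0) * dx
    zz, yy, xx = np.meshgrid(zc, yc, xc, indexing="ij")
    r = np.sqrt(zz**2 + yy**2 + xx**2)

    perturb = _RadialPerturbation(rng, params.radial_perturbation)
    with np.errstate(invalid="ignore", divide="ignore"):
        ux, uy, uz = xx / r, yy / r, zz / r
    ux[r == 0] = uy[r == 0] = uz[r == 0] = 0.0
    perturb.calibrate(ux, uy, uz)
    radius_dir = r0 * (1.0 + perturb(ux, uy, uz))

    depth = radius_dir - r  # radial depth below the fragment surface, um
    fragment = depth >= 0

    # per-voxel dying-onset time from the inward killing front; the damage
    # ring enters at -dying_duration so it is already dead at t=0
    t_on = np.full((nz, ny, nx), np.inf)
    ring = fragment & (depth <= params.perimeter_damage_depth_um)
    t_on[ring] = -params.dying_duration_h
    deeper = fragment & ~ring
    if params.kill_front_speed_um_h > 0:
        t_on[deeper] = (
            depth[deeper] - params.perimeter_damage_depth_um
        ) / params.kill_front_speed_um_h

    # --- TIL arrival process ---------------------------------------------
    t_final = params.time_points_h[-1]
    surface_area = 4.0 * math.pi * r0**2
    lam = params.til_surface_rate_per_um2_h * surface_area * t_final
    n_til = int(rng.poisson(lam)) if lam > 0 else 0
    til_times = np.sort(rng.uniform(0.0, t_final, size=n_til)) if n_til else np.empty(0)
    if n_til:
        dirs = rng.normal(size=(n_til, 3))  # (z, y, x) components
        dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
        s_dir = perturb(dirs[:, 2], dirs[:, 1], dirs[:, 0])
        entry_radius = r0 * (1.0 + s_dir)
    else:
        dirs = np.empty((0, 3))
        entry_radius = np.empty(0)

    def til_positions(t: float) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(positions um, depths um, ages h) of TILs active at time t."""
        active = til_times <= t
        if not active.any():
            return np.empty((0, 3)), np.empty(0), np.empty(0)
        ages = t - til_times[active]
        depths = np.minimum(params.til_infiltration_speed_um_h * ages,
                            entry_radius[active])
        pos = dirs[active] * (entry_radius[active] - depths)[:, None]
        return pos, depths, ages

    # TIL contact-killing foci: walk each TIL's inward path on a fine time
    # grid and pull the local dying onset down to the contact time
    if n_til and params.til_kill_radius_um > 0:
        kill_offsets = _sphere_offsets(params.til_kill_radius_um, params.voxel_size_um)
        step_h = max(0.5, min(dx, dy, dz) / max(params.til_infiltration_speed_um_h, 1e-9) / 2.0)
        center_idx = np.array([(nz - 1) / 2.0, (ny - 1) / 2.0, (nx - 1) / 2.0])
        scale = np.array([dz, dy, dx])
        for j in range(n_til):
            t = til_times[j]
            while t <= t_final:
                d = min(params.til_infiltration_speed_um_h * (t - til_times[j]),
                        entry_radius[j])
                pos = dirs[j] * (entry_radius[j] - d)
                idx = np.rint(pos / scale + center_idx).astype(int)
                vox = kill_offsets + idx
                ok = (
                    (vox[:, 0] >= 0) & (vox[:, 0] < nz)
                    & (vox[:, 1] >= 0) & (vox[:, 1] < ny)
                    & (vox[:, 2] >= 0) & (vox[:, 2] < nx)
                )
                v = vox[ok]
                flat = (v[:, 0] * ny + v[:, 1]) * nx + v[:, 2]
                tf = t_on.ravel()
                np.minimum.at(tf, flat, t)
                if d >= entry_radius[j]:
                    break
                t += step_h
        t_on[~fragment] = np.inf  # foci only kill tumor tissue

    til_blob = _sphere_offsets(params.til_radius_um, params.voxel_size_um)

    # --- render each timepoint -------------------------------------------
    n_frag = int(fragment.sum())
    stacks: list[ChannelStack] = []
    truth = SimulationTruth(
        time_points_h=[], n_live=[], n_dying=[], n_dead=[], true_fraction=[],
        n_til_voxels=[], max_til_depth_um=[], label_volumes=[], til_masks=[],
        dying_til_masks=[], fragment_mask=fragment,
        voxel_size_um=params.voxel_size_um,
    )
    center_idx = np.array([(nz - 1) / 2.0, (ny - 1) / 2.0, (nx - 1) / 2.0])
    scale = np.array([dz, dy, dx])
    base = params.base_intensities

    for t in params.time_points_h:
        state = np.zeros((nz, ny, nx), dtype=np.uint8)
        live = fragment & (t < t_on)
        dying = fragment & (t >= t_on) & (t < t_on + params.dying_duration_h)
        dead = fragment & (t >= t_on + params.dying_duration_h)
        state[live] = STATE_LIVE
        state[dying] = STATE_DYING
        state[dead] = STATE_DEAD

        pos, depths, ages = til_positions(t)
        til_mask = np.zeros((nz, ny, nx), dtype=bool)
        dying_til = np.zeros((nz, ny, nx), dtype=bool)
        tm = til_mask.ravel()
        dtm = dying_til.ravel()
        for p, age in zip(pos, ages):
            idx = np.rint(p / scale + center_idx).astype(int)
            vox = til_blob + idx
            ok = (
                (vox[:, 0] >= 0) & (vox[:, 0] < nz)
                & (vox[:, 1] >= 0) & (vox[:, 1] < ny)
                & (vox[:, 2] >= 0) & (vox[:, 2] < nx)
            )
            v = vox[ok]
            flat = (v[:, 0] * ny + v[:, 1]) * nx + v[:, 2]
            tm[flat] = True
            if age >= params.til_death_age_h:
                dtm[flat] = True

        green = np.where(
            live | dying,
            base["live_green"] * math.exp(-params.green_bleach_rate_per_h * t),
            0.0,
        )
        apc = np.where(dying | dead | dying_til, float(base["dead_apc"]), 0.0)
        red = np.where(til_mask, float(base["til_red"]), 0.0)

        channels: dict[str, np.ndarray] = {}
        for name, sig in (("live_green", green), ("til_red", red), ("dead_apc", apc)):
            out = sig.astype(np.float32)
            if params.background_level > 0 or params.background_sd > 0:
                out = out + rng.normal(
                    params.background_level, max(params.background_sd, 1e-12),
                    size=sig.shape,
                ).astype(np.float32)
            if params.signal_dispersion > 0:
                out = out + (
                    rng.standard_normal(sig.shape) * (params.signal_dispersion * sig)
                ).astype(np.float32)
            channels[name] = np.clip(out, 0.0, None)

        stacks.append(
            ChannelStack(
                channels=channels,
                voxel_size_um=params.voxel_size_um,
                time_h=float(t),
                fragment_id=fragment_id,
            )
        )
        n_dying_v = int(dying.sum())
        truth.time_points_h.append(float(t))
        truth.n_live.append(int(live.sum()))
        truth.n_dying.append(n_dying_v)
        truth.n_dead.append(int(dead.sum()))
        truth.true_fraction.append(n_dying_v / n_frag if n_frag else 0.0)
        truth.n_til_voxels.append(int(til_mask.sum()))
        truth.max_til_depth_um.append(float(depths.max()) if depths.size else 0.0)
        truth.label_volumes.append(state)
        truth.til_masks.append(til_mask)
        truth.dying_til_masks.append(dying_til)

    return stacks, truth


def analytic_killed_volume_um3(
    radius_um: float,
    perimeter_damage_depth_um: float,
    kill_front_speed_um_h: float,
    t_h: float,
) -> float:
    """Closed-form dead+dying volume of a sphere consumed by an inward front.

    The killed region at time t is the shell between radius R and
    ``R - (damage_depth + speed * t)`` (clamped at the center).
    """
    d = perimeter_damage_depth_um + kill_front_speed_um_h * t_h
    inner = max(radius_um - d, 0.0)
    return 4.0 / 3.0 * math.pi * (radius_um**3 - inner**3)


def truth_table(truths: dict[str, SimulationTruth]) -> pd.DataFrame:
    """Tidy per-fragment truth table (fragment_id, time_h, counts, fraction)."""
    frames = []
    for fid, tr in truths.items():
        df = tr.to_frame()
        df.insert(0, "fragment_id", fid)
        frames.append(df)
    return pd.concat(frames, ignore_index=True)
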