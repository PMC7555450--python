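"""Normalized dying-tumor-fraction statistic and fold-increase comparisons.

The headline readout: the volume of "dying" tissue (green/APC co-positive
voxels) divided by the total tumor volume at that timepoint, giving a size-
normalized fraction comparable across fragments of different diameters.

Denominator convention: total tumor volume = live + dying + til_on_live
voxels — i.e. all tissue still carrying the green tumor stain. Fully dead
voxels have lost the green signal (dye leakage plus photobleaching), so a
green-based denominator is the one actually observable at every timepoint;
an alternative including the dead class is selectable with
``include_dead=True``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .classify import ClassifiedVolume
from .io import ExperimentLayout

#: Classes whose volumes form the default total-tumor-volume denominator.
TUMOR_DENOMINATOR_CLASSES = ("live", "dying", "til_on_live")


@dataclass
class DyingFractionRecord:
    """One fragment x timepoint dying-fraction measurement."""

    fragment_id: str
    time_h: float
    dying_volume_um3: float
    total_tumor_volume_um3: float
    dying_fraction: float  # NaN when the denominator is empty
    condition: str | None = None
    qc_flags: tuple[str, ...] = ()


def dying_fraction(
    classified: ClassifiedVolume,
    include_dead: bool = False,
    condition: str | None = None,
) -> DyingFractionRecord:
    """Dying-tumor fraction of one classified volume.

    ``include_dead=True`` adds the dead class to the denominator. When the
    denominator is zero the record is flagged ``empty_tumor_mask`` and the
    fraction is NaN — never fabricated.
    """
    vols = classified.volumes_um3
    dying = vols["dying"]
    denom_classes = TUMOR_DENOMINATOR_CLASSES + (("dead",) if include_dead else ())
    total = sum(vols[c] for c in denom_classes)
    flags: list[str] = []
    if total > 0:
        frac = dying / total
    else:
        frac = float("nan")
        flags.append("empty_tumor_mask")
    return DyingFractionRecord(
        fragment_id=classified.fragment_id,
        time_h=classified.time_h,
        dying_volume_um3=dying,
        total_tumor_volume_um3=total,
        dying_fraction=frac,
        condition=condition,
        qc_flags=tuple(flags),
    )


def records_frame(records: list[DyingFractionRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "fragment_id": [r.fragment_id for r in records],
            "condition": [r.condition for r in records],
            "time_h": [r.time_h for r in records],
            "dying_volume_um3": [r.dying_volume_um3 for r in records],
            "total_tumor_volume_um3": [r.total_tumor_volume_um3 for r in records],
            "dying_fraction": [r.dying_fraction for r in records],
            "qc_flags": [";".join(r.qc_flags) for r in records],
        }
    )


def timeseries(
    records: list[DyingFractionRecord], layout: ExperimentLayout
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Tidy per-fragment trajectory plus per-condition mean and SE.

    Returns ``(tidy, summary)``. ``tidy`` has one row per fragment per
    timepoint, with the condition resolved from the layout. ``summary``
    aggregates per condition per timepoint: mean fraction, standard error
    (sd/sqrt(n), NaN for n=1) and n. Missing (fragment, timepoint) pairs
    remain gaps; nothing is interpolated.
    """
    cond = layout.condition_of
    for r in records:
        if r.fragment_id not in cond:
            raise ValueError(
                f"record references fragment {r.fragment_id!r} absent from layout"
            )
    tidy = records_frame(records)
    tidy["condition"] = tidy["fragment_id"].map(cond)
    tidy = tidy.sort_values(["condition", "fragment_id", "time_h"]).reset_index(drop=True)

    grp = tidy.dropna(subset=["dying_fraction"]).groupby(
        ["condition", "time_h"], sort=True
    )["dying_fraction"]
    summary = grp.agg(n="size", mean_fraction="mean").reset_index()
    sd = grp.std(ddof=1).reset_index(drop=True)
    summary["se_fraction"] = sd / np.sqrt(summary["n"])
    summary.loc[summary["n"] < 2, "se_fraction"] = np.nan
    return tidy, summary


@dataclass
class FoldIncrease:
    """Treated-vs-control comparison reported in both fold conventions.

    ``relative_increase`` is (treated - control)/control; ``ratio`` is
    treated/control. Both are kept side by side because colloquial
    "x-fold increase" usage is ambiguous between the two.
    """

    treated_mean: float
    control_mean: float
    relative_increase: float
    ratio: float
    condition: str | None = None
    time_h: float | None = None
    undefined: bool = False


def fold_increase(
    treated_mean: float,
    control_mean: float,
    condition: str | None = None,
    time_h: float | None = None,
) -> FoldIncrease:
    """Fold comparison of a treated group mean against the control mean.

    A zero control mean makes both conventions undefined; the result is
    flagged with NaN values rather than raising.
    """
    if control_mean < 0 or treated_mean < 0:
        raise ValueError("group means must be non-negative")
    if control_mean == 0:
        return FoldIncrease(
            treated_mean=treated_mean, control_mean=control_mean,
            relative_increase=float("nan"), ratio=float("nan"),
            condition=condition, time_h=time_h, undefined=True,
        )
    ratio = treated_mean / control_mean
    return FoldIncrease(
        treated_mean=treated_mean, control_mean=control_mean,
        relative_increase=ratio - 1.0, ratio=ratio,
        condition=condition, time_h=time_h,
    )


def fold_table(
    summary: pd.DataFrame,
    control_condition: str = "isotype",
    time_h: float | None = None,
) -> pd.DataFrame:
    """Fold increases of every treated condition against the control.

    Computed at ``time_h`` (default: the last timepoint present for the
    control). Returns an empty table when no treated condition exists.
    """
    ctrl = summary[summary["condition"] == control_condition]
    if ctrl.empty:
        raise ValueError(f"control condition {control_condition!r} absent from summary")
    if time_h is None:
        time_h = float(ctrl["time_h"].max())
    ctrl_at = ctrl[ctrl["time_h"] == time_h]
    if ctrl_at.empty:
        raise ValueError(f"control has no record at t={time_h} h")
    control_mean = float(ctrl_at["mean_fraction"].iloc[0])

    rows = []
    for cond in sorted(set(summary["condition"]) - {control_condition}):
        sel = summary[(summary["condition"] == cond) & (summary["time_h"] == time_h)]
        if sel.empty:
            continue
        fi = fold_increase(
            float(sel["mean_fraction"].iloc[0]), control_mean,
            condition=cond, time_h=time_h,
        )
        rows.append(
            {
                "condition": cond,
                "time_h": time_h,
                "treated_mean": fi.treated_mean,
                "control_mean": fi.control_mean,
                "relative_increase": fi.relative_increase,
                "ratio": fi.ratio,
                "undefined": fi.undefined,
            }
        )
    cols = ["condition", "time_h", "treated_mean", "control_mean",
            "relative_increase", "ratio", "undefined"]
    return pd.DataFrame(rows, columns=cols)


def plot_trajectories(summary: pd.DataFrame, path, title: str = "Dying tumor over time"):
    """Percent-dying-vs-time plot with SE error bars, one line per condition."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    colors = {"isotype": "black", "anti_PD1": "green", "anti_CTLA4": "orange"}
    for cond, sub in summary.groupby("condition"):
        sub = sub.sort_values("time_h")
        ax.errorbar(
            sub["time_h"], 100 * sub["mean_fraction"],
            yerr=100 * sub["se_fraction"].fillna(0.0),
            marker="o", capsize=3, label=cond, color=colors.get(cond),
        )
    ax.set_xlabel("time (h)")
    ax.set_ylabel("dying tumor (%)")
    ax.set_title(title)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path
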