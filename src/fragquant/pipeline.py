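"""End-to-end orchestration: simulate an experiment, quantify it, compare groups.

Ties the simulator, classification, viability and statistics modules
together for both the command-line interface and scripted analyses. All
randomness flows from a single experiment seed through independently
derived per-fragment seeds, so a run is a pure function of (config, seed).
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .classify import ThresholdConfig, classify_stack
from .io import (
    CHANNELS,
    CONDITIONS,
    ChannelStack,
    ExperimentLayout,
    FragmentInfo,
    read_stack,
    save_layout,
    write_stack,
)
from .simulate import (
    SimulationParams,
    SimulationTruth,
    params_for_condition,
    simulate_fragment,
    truth_table,
)
from .stats import per_timepoint_kruskal
from .viability import dying_fraction, fold_table, timeseries


@dataclass
class ExperimentBundle:
    """In-memory result of a simulated multi-condition experiment."""

    layout: ExperimentLayout
    stacks: dict[tuple[str, float], ChannelStack]
    truths: dict[str, SimulationTruth]
    params: dict[str, SimulationParams] = field(default_factory=dict)

    def truth_frame(self) -> pd.DataFrame:
        df = truth_table(self.truths)
        df.insert(1, "condition", df["fragment_id"].map(self.layout.condition_of))
        return df


def derive_seeds(seed: int, n: int) -> list[int]:
    """n reproducible child seeds (< 2**31) from one experiment seed."""
    rng = np.random.default_rng(seed)
    return [int(s) for s in rng.integers(0, 2**31 - 1, size=n)]


def simulate_experiment(
    base_params: SimulationParams,
    n_per_condition: int = 3,
    conditions: tuple[str, ...] = CONDITIONS,
    tumor_model: str = "synthetic",
    seed: int = 0,
) -> ExperimentBundle:
    """Simulate ``n_per_condition`` fragments under each condition preset.

    Each fragment gets its own derived seed (geometry, TIL process and
    noise differ across fragments) while condition presets scale the
    killing kinetics.
    """
    for c in conditions:
        if c not in CONDITIONS:
            raise ValueError(f"unknown condition {c!r}; allowed: {list(CONDITIONS)}")
    fragments: list[FragmentInfo] = []
    stacks: dict[tuple[str, float], ChannelStack] = {}
    truths: dict[str, SimulationTruth] = {}
    all_params: dict[str, SimulationParams] = {}
    seeds = derive_seeds(seed, len(conditions) * n_per_condition)
    i = 0
    for cond in conditions:
        cparams = params_for_condition(base_params, cond)
        for k in range(n_per_condition):
            fid = f"{cond}_f{k + 1:02d}"
            fparams = dataclasses.replace(cparams, seed=seeds[i])
            i += 1
            frag_stacks, truth = simulate_fragment(fparams, fragment_id=fid)
            fragments.append(FragmentInfo(fid, cond, tumor_model))
            truths[fid] = truth
            all_params[fid] = fparams
            for st in frag_stacks:
                stacks[(fid, st.time_h)] = st
    layout = ExperimentLayout(
        fragments=fragments,
        time_points_h=[float(t) for t in base_params.time_points_h],
    )
    return ExperimentBundle(layout=layout, stacks=stacks, truths=truths,
                            params=all_params)


def save_experiment(bundle: ExperimentBundle, outdir: str | Path) -> Path:
    """Write stacks (TIFF + sidecar), truth CSV and layout YAML to a directory.

    Returns the layout path. Stack files land under ``stacks/``.
    """
    outdir = Path(outdir)
    stack_dir = outdir / "stacks"
    stack_dir.mkdir(parents=True, exist_ok=True)
    paths: dict[tuple[str, float], Path] = {}
    for (fid, t), stack in sorted(bundle.stacks.items()):
        p = stack_dir / f"{fid}_t{t:07.2f}h.tif"
        write_stack(stack, p)
        paths[(fid, t)] = p
    layout = ExperimentLayout(
        fragments=bundle.layout.fragments,
        time_points_h=bundle.layout.time_points_h,
        stack_paths=paths,
    )
    layout_path = save_layout(layout, outdir / "layout.yaml")
    bundle.truth_frame().to_csv(outdir / "truth.csv", index=False)
    return layout_path


def load_experiment_stacks(
    layout: ExperimentLayout,
) -> dict[tuple[str, float], ChannelStack]:
    missing = layout.missing_paths()
    if missing:
        raise FileNotFoundError(
            f"{len(missing)} stack file(s) missing, e.g. {missing[0]}"
        )
    return {key: read_stack(p) for key, p in sorted(layout.stack_paths.items())}


def midgap_thresholds(
    params: SimulationParams, min_area_um2: float = 50.0
) -> ThresholdConfig:
    """Thresholds midway between background and the weakest expected signal.

    The green threshold accounts for photobleaching: it sits halfway between
    the background level and the bleached live-channel signal at the final
    timepoint, so live tissue stays above threshold through the whole run.
    """
    bg = params.background_level
    t_final = max(params.time_points_h)
    green_final = params.base_intensities["live_green"] * math.exp(
        -params.green_bleach_rate_per_h * t_final
    )
    thr = {
        "live_green": 0.5 * (bg + green_final),
        "til_red": 0.5 * (bg + params.base_intensities["til_red"]),
        "dead_apc": 0.5 * (bg + params.base_intensities["dead_apc"]),
    }
    return ThresholdConfig(thresholds=thr, min_area_um2=min_area_um2)


@dataclass
class QuantifyResult:
    """Tables produced by quantifying one experiment."""

    records: pd.DataFrame          # fragment x timepoint dying fractions
    summary: pd.DataFrame          # condition x timepoint mean / SE / n
    folds: pd.DataFrame            # treated-vs-isotype fold increases (final t)
    tests: pd.DataFrame            # per-timepoint Kruskal-Wallis
    class_volumes: pd.DataFrame    # per-class volumes per fragment x timepoint


def quantify_experiment(
    stacks: dict[tuple[str, float], ChannelStack],
    layout: ExperimentLayout,
    config: ThresholdConfig,
    include_dead: bool = False,
    control_condition: str = "isotype",
) -> QuantifyResult:
    """Classify every stack and compute trajectories, folds and group tests."""
    cond = layout.condition_of
    recs = []
    vol_rows = []
    for (fid, t), stack in sorted(stacks.items()):
        classified = classify_stack(stack, config)
        recs.append(dying_fraction(classified, include_dead=include_dead,
                                   condition=cond.get(fid)))
        row = {"fragment_id": fid, "time_h": t}
        row.update({f"vol_{k}_um3": v for k, v in classified.volumes_um3.items()})
        vol_rows.append(row)
    tidy, summary = timeseries(recs, layout)

    treated_exists = any(c != control_condition for c in cond.values())
    if treated_exists and (summary["condition"] == control_condition).any():
        folds = fold_table(summary, control_condition=control_condition)
    else:
        folds = pd.DataFrame(
            columns=["condition", "time_h", "treated_mean", "control_mean",
                     "relative_increase", "ratio", "undefined"]
        )

    n_conditions = len(set(cond.values()))
    if n_conditions >= 2:
        tests = per_timepoint_kruskal(tidy, "dying_fraction", "condition", "time_h")
    else:
        tests = pd.DataFrame(columns=["time_h", "H", "df", "p", "n_total", "p_holm"])
    return QuantifyResult(
        records=tidy, summary=summary, folds=folds, tests=tests,
        class_volumes=pd.DataFrame(vol_rows),
    )


def recovery_errors(
    result: QuantifyResult, bundle: ExperimentBundle
) -> pd.DataFrame:
    """Recovered-vs-true dying fraction per fragment per timepoint.

    The truth fraction uses the conserved whole-fragment denominator
    (live + dying + dead), so the recovered fraction is recomputed on the
    matching convention: dying volume over all tumor-derived classes.
    """
    truth = bundle.truth_frame()
    rec = result.records.merge(
        truth[["fragment_id", "time_h", "true_fraction"]],
        on=["fragment_id", "time_h"], how="inner",
    )
    cls = result.class_volumes
    denom = (
        cls["vol_live_um3"] + cls["vol_dying_um3"] + cls["vol_dead_um3"]
        + cls["vol_til_on_live_um3"]
    )
    with np.errstate(invalid="ignore", divide="ignore"):
        frac_all = np.where(denom > 0, cls["vol_dying_um3"] / denom, np.nan)
    cls = cls.assign(recovered_fraction_total=frac_all)
    rec = rec.merge(
        cls[["fragment_id", "time_h", "recovered_fraction_total"]],
        on=["fragment_id", "time_h"], how="left",
    )
    rec["abs_error"] = (rec["recovered_fraction_total"] - rec["true_fraction"]).abs()
    return rec
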