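"""Treatment-group comparisons: Kruskal-Wallis and tumor-growth summaries.

The Kruskal-Wallis H test is implemented from first principles (midranks,
tie correction, chi-square upper tail) so its behaviour on the very small
groups typical of these experiments (n = 3 per condition) is fully
transparent; an exact permutation p-value is available for such sizes.

In vivo tumor-growth tables are plain DataFrames with columns
``animal_id, group, day, volume_mm3``; an animal is implicitly censored
after its last row (sacrifice at the volume endpoint), so per-day summaries
naturally shrink in n.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

GROWTH_COLUMNS = ("animal_id", "group", "day", "volume_mm3")


# --------------------------------------------------------------------------
# Kruskal-Wallis
# --------------------------------------------------------------------------

@dataclass
class KruskalWallisResult:
    H: float
    k: int
    df: int
    p: float
    n_per_group: tuple[int, ...]
    tie_correction: float
    method: str = "chi2"


def _midranks(values: np.ndarray) -> np.ndarray:
    """Ranks 1..N with ties assigned the mean of their covered ranks."""
    order = np.argsort(values, kind="mergesort")
    ranks = np.empty(len(values), dtype=float)
    i = 0
    while i < len(values):
        j = i
        while j + 1 < len(values) and values[order[j + 1]] == values[order[i]]:
            j += 1
        ranks[order[i : j + 1]] = 0.5 * (i + j) + 1.0  # mean of ranks i+1..j+1
        i = j + 1
    return ranks


def _h_statistic(pooled: np.ndarray, sizes: list[int]) -> tuple[float, float]:
    """Tie-corrected H and the tie correction C for pooled data split by sizes."""
    n = len(pooled)
    ranks = _midranks(pooled)
    h = 0.0
    start = 0
    for ni in sizes:
        ri = ranks[start : start + ni].sum()
        h += ri * ri / ni
        start += ni
    h = 12.0 / (n * (n + 1)) * h - 3.0 * (n + 1)
    _, counts = np.unique(pooled, return_counts=True)
    c = 1.0 - float(np.sum(counts.astype(float) ** 3 - counts)) / (n**3 - n)
    if c == 0.0:  # every observation identical
        return 0.0, 0.0
    return h / c, c


def kruskal_wallis(groups: list[np.ndarray | list], exact: bool = False) -> KruskalWallisResult:
    """Kruskal-Wallis rank test across two or more groups.

    H = 12/(N(N+1)) * sum(R_i^2 / n_i) - 3(N+1), divided by the tie
    correction C = 1 - sum(t^3 - t)/(N^3 - N) over tied-value groups. The
    p-value is the chi-square upper tail with k-1 degrees of freedom;
    ``exact=True`` replaces it with a full permutation p-value (all distinct
    assignments of observations to groups, feasible for small N).
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2:
        raise ValueError("kruskal_wallis needs at least 2 groups")
    if any(a.size == 0 for a in arrays):
        raise ValueError("every group needs at least one observation")
    sizes = [a.size for a in arrays]
    n = sum(sizes)
    if n < 3:
        raise ValueError("need at least 3 observations in total")
    pooled = np.concatenate(arrays)
    h, c = _h_statistic(pooled, sizes)
    k = len(arrays)
    df = k - 1
    if c == 0.0:
        return KruskalWallisResult(H=0.0, k=k, df=df, p=1.0,
                                   n_per_group=tuple(sizes), tie_correction=0.0)
    if exact:
        p = _exact_permutation_p(pooled, sizes, h)
        method = "exact-permutation"
    else:
        p = float(sps.chi2.sf(h, df))
        method = "chi2"
    return KruskalWallisResult(H=h, k=k, df=df, p=p, n_per_group=tuple(sizes),
                               tie_correction=c, method=method)


def _exact_permutation_p(pooled: np.ndarray, sizes: list[int], h_obs: float) -> float:
    n = len(pooled)
    n_assign = math.factorial(n)
    for s in sizes:
        n_assign //= math.factorial(s)
    if n_assign > 500_000:
        raise ValueError(
            f"exact permutation infeasible: {n_assign} assignments; "
            "use the chi-square approximation"
        )
    idx = list(range(n))
    count = 0
    total = 0

    def rec(remaining: list[int], gi: int, chosen: list[np.ndarray]):
        nonlocal count, total
        if gi == len(sizes) - 1:
            arrs = chosen + [pooled[remaining]]
            h, _ = _h_statistic(np.concatenate(arrs), sizes)
            total += 1
            if h >= h_obs - 1e-12:
                count += 1
            return
        for comb in itertools.combinations(range(len(remaining)), sizes[gi]):
            sel = [remaining[i] for i in comb]
            rest = [r for i, r in enumerate(remaining) if i not in set(comb)]
            rec(rest, gi + 1, chosen + [pooled[sel]])

    rec(idx, 0, [])
    return count / total


# --------------------------------------------------------------------------
# In vivo tumor-growth tables
# --------------------------------------------------------------------------

def validate_growth_table(table: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in GROWTH_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"growth table missing column(s): {missing}")
    if (table["volume_mm3"] < 0).any():
        raise ValueError("volumes must be non-negative")
    if (table["day"] < 0).any():
        raise ValueError("days must be non-negative")
    dup = table.duplicated(subset=["animal_id", "day"])
    if dup.any():
        raise ValueError("more than one row per animal per day")
    return table


@dataclass
class PercentReduction:
    percent: float
    treated_mean: float
    control_mean: float
    n_treated: int
    n_control: int
    day: float
    treated_group: str
    control_group: str


def percent_reduction(
    table: pd.DataFrame, day: float, treated_group: str, control_group: str
) -> PercentReduction:
    """Percent tumor-volume reduction of a treated group vs control at a day.

    100 * (1 - mean(treated)/mean(control)) over the animals still measured
    at that day (censored animals contribute nothing).
    """
    validate_growth_table(table)
    at_day = table[table["day"] == day]
    treated = at_day[at_day["group"] == treated_group]["volume_mm3"]
    control = at_day[at_day["group"] == control_group]["volume_mm3"]
    if treated.empty or control.empty:
        raise ValueError(
            f"day {day}: no measured animals in "
            f"{'treated' if treated.empty else 'control'} group"
        )
    cm = float(control.mean())
    if cm == 0:
        raise ValueError("control mean volume is zero; reduction undefined")
    tm = float(treated.mean())
    return PercentReduction(
        percent=100.0 * (1.0 - tm / cm),
        treated_mean=tm, control_mean=cm,
        n_treated=len(treated), n_control=len(control),
        day=day, treated_group=treated_group, control_group=control_group,
    )


def group_timeseries_summary(table: pd.DataFrame) -> pd.DataFrame:
    """Per-group per-day mean volume, standard error and surviving n."""
    validate_growth_table(table)
    grp = table.groupby(["group", "day"], sort=True)["volume_mm3"]
    out = grp.agg(n="size", mean_volume_mm3="mean").reset_index()
    sd = grp.std(ddof=1).reset_index(drop=True)
    out["se_volume_mm3"] = sd / np.sqrt(out["n"])
    out.loc[out["n"] < 2, "se_volume_mm3"] = np.nan
    return out


def per_timepoint_kruskal(
    df: pd.DataFrame,
    value_col: str,
    group_col: str,
    time_col: str,
    exact: bool = False,
) -> pd.DataFrame:
    """Kruskal-Wallis at every timepoint, with a Holm-adjusted p column.

    Mirrors per-day significance marks on trajectory plots; the unadjusted
    column reproduces that presentation, the Holm column flags the
    multiple-testing caveat.
    """
    rows = []
    for t, sub in df.dropna(subset=[value_col]).groupby(time_col, sort=True):
        groups = [g[value_col].to_numpy() for _, g in sub.groupby(group_col)]
        if len(groups) < 2 or sum(len(g) for g in groups) < 3:
            continue
        res = kruskal_wallis(groups, exact=exact)
        rows.append({time_col: t, "H": res.H, "df": res.df, "p": res.p,
                     "n_total": int(sum(res.n_per_group))})
    out = pd.DataFrame(rows, columns=[time_col, "H", "df", "p", "n_total"])
    if len(out):
        out["p_holm"] = _holm(out["p"].to_numpy())
    else:
        out["p_holm"] = pd.Series(dtype=float)
    return out


def _holm(p: np.ndarray) -> np.ndarray:
    m = len(p)
    order = np.argsort(p)
    adj = np.empty(m)
    running = 0.0
    for rank, i in enumerate(order):
        running = max(running, (m - rank) * p[i])
        adj[i] = min(1.0, running)
    return adj


def simulate_growth_table(
    n_per_group: int = 8,
    days: tuple[float, ...] = (0, 3, 5, 7, 9, 11, 14, 16, 18, 21, 23, 25, 28),
    growth_rates: dict[str, float] | None = None,
    v0_mm3: float = 100.0,
    rate_sd: float = 0.02,
    noise_cv: float = 0.10,
    endpoint_mm3: float = 1500.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Synthetic exponential-growth cohort with endpoint censoring.

    Each animal grows as ``v0 * exp(r_a * day)`` with an animal-level rate
    drawn around its group rate plus lognormal measurement noise; an animal
    is measured through the first day its volume reaches ``endpoint_mm3``
    and censored afterwards (no further rows), mimicking sacrifice at the
    volume endpoint.
    """
    if growth_rates is None:
        growth_rates = {"vehicle": 0.13, "anti_PD1": 0.10, "anti_CTLA4": 0.07}
    rng = np.random.default_rng(seed)
    rows = []
    for group, r in growth_rates.items():
        for a in range(n_per_group):
            aid = f"{group}_{a:02d}"
            ra = rng.normal(r, rate_sd)
            censored = False
            for day in days:
                if censored:
                    break
                vol = v0_mm3 * math.exp(ra * day) * math.exp(rng.normal(0, noise_cv))
                rows.append({"animal_id": aid, "group": group, "day": float(day),
                             "volume_mm3": vol})
                if vol >= endpoint_mm3:
                    censored = True
    return pd.DataFrame(rows, columns=list(GROWTH_COLUMNS))
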