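"""Immunoactivity stratification and the two-state slope-change statistic.

Samples are partitioned into low/moderate/high immunoactivity by exact 1-D
k-means: dynamic programming over the sorted composite scores minimizing the
total within-group sum of squared deviations ("sum of squared differences"
clustering). The optimum over contiguous partitions of the sorted order is
the global optimum for one-dimensional k-means, so the result is
deterministic and exactly optimal.

The change of immunoactivity between the control (healthy) and tumor state
is quantified per cell type by ordinary least squares of activity (y) on
abundance (x) within each state and the slope difference
``delta_k = k_tumor - k_control``. A percentile bootstrap confidence
interval (points resampled within each state) turns the bare sign into an
enhanced / weakened / unchanged call: enhanced when the interval lies above
zero, weakened when below.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats

from .deconvolution import CellFractions, spearman_with_p
from .scoring import ActivityScore


@dataclass
class ImmunoGroups:
    """Low/moderate/high partition of samples by composite activity score."""

    labels: pd.Series                # sample -> {"low", "moderate", "high", ...}
    boundaries: list[float]          # k-1 cut values (midpoints between groups)
    wss: float                       # minimal within-group sum of squares

    def sizes(self) -> dict[str, int]:
        return self.labels.value_counts().to_dict()


@dataclass
class StateRegression:
    """Per-state OLS fit of activity on abundance."""

    state: str
    k: float
    b: float
    r2: float
    p: float
    n: int


@dataclass
class DeltaK:
    """Slope change between tumor and control with its bootstrap interval."""

    delta_k: float
    ci: tuple[float, float]
    call: str                        # enhanced | weakened | unchanged
    celltype: str = ""
    tumor: StateRegression | None = None
    control: StateRegression | None = None


GROUP_NAMES_3 = ("low", "moderate", "high")


def _kmeans_1d_dp(x: np.ndarray, k: int) -> tuple[np.ndarray, float]:
    """Exact 1-D k-means on sorted x: returns (sizes of the k groups in
    ascending order, minimal total within-group sum of squares)."""
    n = len(x)
    pre = np.concatenate([[0.0], np.cumsum(x)])
    pre2 = np.concatenate([[0.0], np.cumsum(x ** 2)])

    def cost(i: int, j: int) -> float:
        # sum of squared deviations of x[i:j] from its mean
        s = pre[j] - pre[i]
        s2 = pre2[j] - pre2[i]
        m = j - i
        return s2 - s * s / m

    INF = float("inf")
    dp = np.full((k + 1, n + 1), INF)
    back = np.zeros((k + 1, n + 1), dtype=int)
    dp[0, 0] = 0.0
    for m in range(1, k + 1):
        for j in range(m, n + 1):
            best, arg = INF, m - 1
            for i in range(m - 1, j):
                c = dp[m - 1, i] + cost(i, j)
                if c < best - 1e-15:
                    best, arg = c, i
            dp[m, j] = best
            back[m, j] = arg
    sizes = []
    j = n
    for m in range(k, 0, -1):
        i = back[m, j]
        sizes.append(j - i)
        j = i
    return np.array(sizes[::-1], dtype=int), float(dp[k, n])


def partition_by_activity(scores: pd.Series, k_groups: int = 3) -> ImmunoGroups:
    """Partition samples into k contiguous score groups minimizing the
    within-group sum of squared deviations (exact, deterministic)."""
    scores = scores.astype(float)
    if scores.nunique() < k_groups:
        raise ValueError("fewer distinct scores than groups")
    order = np.argsort(scores.to_numpy(), kind="stable")
    x = scores.to_numpy()[order]
    sizes, wss = _kmeans_1d_dp(x, k_groups)
    if k_groups == 3:
        names = list(GROUP_NAMES_3)
    else:
        names = [f"g{i}" for i in range(k_groups)]
    labels = np.empty(len(x), dtype=object)
    boundaries = []
    pos = 0
    for gi, size in enumerate(sizes):
        labels[pos:pos + size] = names[gi]
        if gi + 1 < k_groups:
            boundaries.append(float((x[pos + size - 1] + x[pos + size]) / 2.0))
        pos += size
    out = pd.Series(index=scores.index[order], data=labels, name="group")
    return ImmunoGroups(out.reindex(scores.index), boundaries, wss)


def fit_state_regression(x: np.ndarray, y: np.ndarray, state: str = "") -> StateRegression:
    """Ordinary least squares y = k*x + b for one state, with R^2 and the
    two-sided t-test p-value of the slope (n-2 df)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 points")
    if np.ptp(x) == 0:
        raise ValueError("constant abundance (x) — slope undefined")
    xc = x - x.mean()
    k = float((xc * y).sum() / (xc ** 2).sum())
    b = float(y.mean() - k * x.mean())
    resid = y - (k * x + b)
    ss_res = float((resid ** 2).sum())
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    if ss_res <= 0:
        p = 0.0 if k != 0 else 1.0
    else:
        se = np.sqrt(ss_res / (n - 2) / (xc ** 2).sum())
        t = k / se
        p = float(2.0 * scipy.stats.t.sf(abs(t), df=n - 2))
    return StateRegression(state=state, k=k, b=b, r2=max(0.0, min(1.0, r2)),
                           p=min(max(p, np.finfo(float).tiny), 1.0), n=n)


def _boot_slopes(x: np.ndarray, y: np.ndarray, reps: int,
                 rng: np.random.Generator) -> np.ndarray:
    """Vectorized bootstrap of the OLS slope (resampling points)."""
    n = len(x)
    idx = rng.integers(0, n, size=(reps, n))
    xb = x[idx]
    yb = y[idx]
    xc = xb - xb.mean(axis=1, keepdims=True)
    denom = (xc ** 2).sum(axis=1)
    # degenerate resamples (all points identical) are redrawn as the mean slope
    with np.errstate(divide="ignore", invalid="ignore"):
        slopes = (xc * yb).sum(axis=1) / denom
    bad = ~np.isfinite(slopes)
    if bad.any():
        slopes[bad] = np.nanmean(slopes[~bad]) if (~bad).any() else 0.0
    return slopes


def delta_k(tumor_xy: tuple[np.ndarray, np.ndarray],
            control_xy: tuple[np.ndarray, np.ndarray],
            boot_reps: int = 1000, seed: int | np.random.Generator = 0,
            ci_level: float = 0.95, celltype: str = "") -> DeltaK:
    """Slope change k_tumor - k_control with a percentile bootstrap CI.

    Negative delta_k reads as weakened immunoactivity in the tumor state,
    positive as enhanced; the call is made only when the bootstrap interval
    excludes zero.
    """
    if boot_reps < 100:
        raise ValueError("boot_reps must be at least 100")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    fit_t = fit_state_regression(*tumor_xy, state="tumor")
    fit_c = fit_state_regression(*control_xy, state="control")
    dk = fit_t.k - fit_c.k
    bt = _boot_slopes(np.asarray(tumor_xy[0], float), np.asarray(tumor_xy[1], float),
                      boot_reps, rng)
    bc = _boot_slopes(np.asarray(control_xy[0], float), np.asarray(control_xy[1], float),
                      boot_reps, rng)
    deltas = bt - bc
    lo_q = (1.0 - ci_level) / 2.0
    ci = (float(np.quantile(deltas, lo_q)), float(np.quantile(deltas, 1.0 - lo_q)))
    if ci[0] > 0:
        call = "enhanced"
    elif ci[1] < 0:
        call = "weakened"
    else:
        call = "unchanged"
    return DeltaK(delta_k=float(dk), ci=ci, call=call, celltype=celltype,
                  tumor=fit_t, control=fit_c)


def delta_k_table(fractions: CellFractions, activity: ActivityScore,
                  states: pd.Series, boot_reps: int = 1000,
                  seed: int | np.random.Generator = 0) -> pd.DataFrame:
    """Per-cell-type slope change: abundance (estimated fraction) as x,
    that cell type's activity score as y, split by tumor/control state.

    Cell types without a matching activity column are skipped.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    states = states.reindex(fractions.sample_ids)
    shared_sets = [ct for ct in fractions.celltype_ids if ct in set(activity.set_names)]
    rows = []
    for ct in shared_sets:
        x = fractions.fractions[ct]
        y = activity.scores[ct].reindex(fractions.sample_ids)
        t_mask = (states == "tumor").to_numpy()
        c_mask = (states == "control").to_numpy()
        res = delta_k((x.to_numpy()[t_mask], y.to_numpy()[t_mask]),
                      (x.to_numpy()[c_mask], y.to_numpy()[c_mask]),
                      boot_reps=boot_reps, seed=rng, celltype=ct)
        rows.append({
            "celltype": ct, "delta_k": res.delta_k,
            "ci_low": res.ci[0], "ci_high": res.ci[1], "call": res.call,
            "k_tumor": res.tumor.k, "r2_tumor": res.tumor.r2, "p_tumor": res.tumor.p,
            "k_control": res.control.k, "r2_control": res.control.r2,
            "p_control": res.control.p,
        })
    return pd.DataFrame(rows)


def stagewise_abundance_pathway(fractions: CellFractions, activity: ActivityScore,
                                stages: list[tuple[str, list[str]]]) -> pd.DataFrame:
    """Per-stage median abundance and median pathway score per cell type,
    plus the Spearman correlation of the two stage-ordered trajectories.

    ``stages`` is an ordered list of (stage name, sample ids). A flat
    trajectory has undefined correlation and is reported as NaN.
    """
    if len(stages) < 2:
        raise ValueError("need at least 2 stages")
    for name, ids in stages:
        if not ids:
            raise ValueError(f"stage {name!r} has no samples")
    shared_sets = [ct for ct in fractions.celltype_ids if ct in set(activity.set_names)]
    rows = []
    for ct in shared_sets:
        med_fr, med_act = [], []
        for name, ids in stages:
            med_fr.append(float(fractions.fractions.loc[ids, ct].median()))
            med_act.append(float(activity.scores.loc[ids, ct].median()))
        rho, _ = spearman_with_p(np.array(med_fr), np.array(med_act))
        for (name, _ids), f, a in zip(stages, med_fr, med_act):
            rows.append({"celltype": ct, "stage": name,
                         "median_fraction": f, "median_pathway_score": a,
                         "trajectory_rho": rho})
    return pd.DataFrame(rows)
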