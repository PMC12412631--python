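"""Block-delta statistics, ROI selection, paired comparison and the
cluster-based permutation test.

The unit of analysis is the block delta: the mean concentration over
7-18 s after block onset minus the mean over the 2 s before onset
(windows include their start sample and exclude their end sample). Per
subject, channel (or vertex), condition and chromophore, the t-statistic
is the mean delta across blocks over its standard error. ROI comparisons
select, per subject and hemisphere, the channel with the extreme
t-statistic (max for HbO, min for HbR) and compare arrays with a paired
two-tailed Student's t-test. Group channel maps are family-wise
corrected with a sign-flip cluster-mass permutation test (adjacency =
inter-channel distance below a radius, default 33 mm).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "BlockDelta",
    "TStatResult",
    "RoiDefinition",
    "block_delta",
    "block_deltas",
    "tstat",
    "t_critical",
    "select_roi_vertices",
    "select_max_t",
    "paired_ttest",
    "cluster_permutation",
    "ClusterResult",
    "group_summary",
]

TASK_WINDOW = (7.0, 18.0)
BASELINE_WINDOW = (-2.0, 0.0)


@dataclass
class BlockDelta:
    """Per-block activation deltas for one measurement site."""

    subject: object
    id: int  # channel or vertex id
    condition: str
    chromophore: str
    deltas: np.ndarray  # uM, one per retained block

    @property
    def n_blocks(self) -> int:
        return len(self.deltas)


@dataclass
class TStatResult:
    id: object
    t: float
    mean: float
    se: float
    n: int
    p: float | None = None
    degenerate: bool = False


@dataclass
class RoiDefinition:
    """Mirror-symmetric left/right channel sets plus shared vertex ids."""

    side_channels: dict[str, dict[str, np.ndarray]]  # layout -> side -> channel idx
    vertex_ids: dict[str, np.ndarray] = field(default_factory=dict)  # side -> ids

    def channels(self, layout: str, side: str) -> np.ndarray:
        return self.side_channels[layout][side]


def _window_slice(onset: float, window: tuple[float, float], fs: float, n: int):
    a = int(np.ceil((onset + window[0]) * fs - 1e-9))
    b = int(np.ceil((onset + window[1]) * fs - 1e-9))
    if a < 0 or b > n:
        raise ValueError("trace does not cover the required window")
    return slice(a, b)


def block_delta(conc_trace: np.ndarray, onset: float, fs: float) -> float:
    """Task-window mean minus pre-onset baseline mean for one block.

    Windows are [onset+7, onset+18) and [onset-2, onset) seconds,
    start-inclusive / end-exclusive at the sample level.
    """
    conc_trace = np.asarray(conc_trace, dtype=float)
    n = len(conc_trace)
    task = _window_slice(onset, TASK_WINDOW, fs, n)
    base = _window_slice(onset, BASELINE_WINDOW, fs, n)
    return float(conc_trace[task].mean() - conc_trace[base].mean())


def block_deltas(conc_trace: np.ndarray, onsets: np.ndarray, fs: float) -> np.ndarray:
    return np.array([block_delta(conc_trace, o, fs) for o in onsets])


def tstat(deltas: np.ndarray) -> TStatResult:
    """Mean over standard error across blocks (sample SD, n-1)."""
    deltas = np.asarray(deltas, dtype=float)
    n = len(deltas)
    if n < 2:
        raise ValueError("need at least two blocks")
    mean = float(deltas.mean())
    sd = float(deltas.std(ddof=1))
    se = sd / np.sqrt(n)
    if se == 0:
        t = float(np.sign(mean) * np.inf) if mean != 0 else 0.0
        return TStatResult(id=None, t=t, mean=mean, se=0.0, n=n, degenerate=True)
    return TStatResult(id=None, t=mean / se, mean=mean, se=se, n=n)


def t_critical(n: int, alpha: float = 0.05) -> float:
    """Two-tailed Student critical value at df = n - 1."""
    if n < 2:
        raise ValueError("need n >= 2")
    return float(sps.t.ppf(1.0 - alpha / 2.0, n - 1))


def select_roi_vertices(
    S_hd, roi_channels: np.ndarray, threshold: float = 0.01,
    surface: str | None = "brain",
) -> np.ndarray:
    """Two-stage vertex selection from the HD sensitivity matrix.

    Stage 1 keeps vertices whose sensitivity summed over the ROI channels
    (normalized to a maximum of 1) strictly exceeds ``threshold``;
    stage 2 keeps those whose value strictly exceeds the stage-1 mean.
    By default candidates are restricted to the cortical (brain) surface —
    the image ROI is anatomical — and the map is normalized over that
    surface. The returned ids index the sensitivity matrix's vertex table
    and are shared by both arrays.
    """
    roi_channels = np.asarray(roi_channels, dtype=int)
    total = S_hd.values[:, roi_channels, :].sum(axis=(0, 1))
    if surface is not None:
        allowed = (S_hd.vertices["surface"] == surface).to_numpy()
    else:
        allowed = np.ones(len(total), bool)
    m = total[allowed].max() if allowed.any() else 0.0
    if m <= 0:
        raise ValueError("degenerate sensitivity over ROI channels")
    total = total / m
    stage1 = np.flatnonzero(allowed & (total > threshold))
    if stage1.size == 0:
        raise ValueError("no vertices above threshold")
    avg = total[stage1].mean()
    return stage1[total[stage1] > avg]


def select_max_t(
    subject_results: pd.DataFrame,
    chromophore: str = "hbo",
    n_top: int = 1,
) -> pd.DataFrame:
    """Extreme-t selection per subject (and any other grouping columns).

    ``subject_results`` needs columns (subject, id, t, delta) and is
    typically pre-filtered to one ROI side. HbO selects the highest t,
    HbR the lowest; ties break toward the lowest id. With ``n_top > 1``
    (image analysis) the mean delta over the ``n_top`` most extreme
    vertices is returned.
    """
    if subject_results.empty:
        raise ValueError("no unpruned candidates to select from")
    ascending = chromophore.lower() == "hbr"
    rows = []
    for subject, grp in subject_results.groupby("subject"):
        grp = grp.sort_values(["t", "id"], ascending=[ascending, True],
                              kind="mergesort")
        top = grp.head(n_top)
        rows.append(
            {
                "subject": subject,
                "id": int(top.iloc[0]["id"]),
                "t": float(top.iloc[0]["t"]),
                "delta": float(top["delta"].mean()),
                "n_top": len(top),
            }
        )
    return pd.DataFrame(rows)


def paired_ttest(a: np.ndarray, b: np.ndarray) -> TStatResult:
    """Two-tailed paired Student's t-test on a - b.

    Pairs with a missing member (NaN) are dropped.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired samples must have equal length")
    ok = np.isfinite(a) & np.isfinite(b)
    d = a[ok] - b[ok]
    n = len(d)
    if n < 2:
        raise ValueError("fewer than two complete pairs")
    res = tstat(d)
    if res.degenerate:
        p = 1.0 if res.t == 0 else 0.0
    else:
        p = float(2.0 * sps.t.sf(abs(res.t), n - 1))
    return TStatResult(id=None, t=res.t, mean=res.mean, se=res.se, n=n, p=p,
                       degenerate=res.degenerate)


def _components(active: np.ndarray, adjacency: np.ndarray) -> list[np.ndarray]:
    """Connected components of the supra-threshold channel graph."""
    idx = np.flatnonzero(active)
    unseen = set(idx.tolist())
    comps = []
    while unseen:
        stack = [unseen.pop()]
        comp = [stack[0]]
        while stack:
            u = stack.pop()
            for v in np.flatnonzero(adjacency[u]):
                if v in unseen:
                    unseen.remove(v)
                    stack.append(v)
                    comp.append(v)
        comps.append(np.array(sorted(comp)))
    return comps


@dataclass
class ClusterResult:
    mask: np.ndarray  # channels inside significant clusters
    clusters: list[np.ndarray]
    cluster_p: np.ndarray
    t_obs: np.ndarray
    t_threshold: float


def cluster_permutation(
    channel_positions: np.ndarray,
    subject_deltas: np.ndarray,
    radius: float = 33.0,
    alpha: float = 0.05,
    n_perm: int = 5000,
    seed: int | np.random.Generator = 0,
) -> ClusterResult:
    """Sign-flip cluster-mass permutation test over channels.

    Per channel, the observed group t is the subject-mean delta over its
    standard error. Channels with ``|t|`` above the two-tailed critical
    value form clusters through spatial adjacency (distance <= radius;
    an isolated supra-threshold channel is a singleton cluster); cluster
    mass is the sum of ``|t|``. The null flips each subject's sign at
    random and records the maximum cluster mass per permutation;
    ``p = (1 + #{null >= observed}) / (1 + n_perm)``. Channels outside
    clusters with p <= alpha are masked.
    """
    if n_perm < 1:
        raise ValueError("need at least one permutation")
    X = np.asarray(subject_deltas, dtype=float)  # (n_subjects, n_channels)
    n_sub, n_ch = X.shape
    if n_sub < 2:
        raise ValueError("need at least two subjects")
    pos = np.asarray(channel_positions, dtype=float)
    d = np.linalg.norm(pos[:, None, :] - pos[None, :, :], axis=-1)
    adjacency = (d <= radius) & ~np.eye(n_ch, dtype=bool)

    def group_t(mean, sumsq):
        var = (sumsq - n_sub * mean**2) / (n_sub - 1)
        var = np.maximum(var, 0.0)
        se = np.sqrt(var / n_sub)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.where(se > 0, mean / np.where(se > 0, se, 1.0), 0.0)
        return t

    sumsq = np.einsum("sc,sc->c", X, X)  # invariant under sign flips
    t_obs = group_t(X.mean(axis=0), sumsq)
    t_thr = t_critical(n_sub, alpha)

    def max_mass(t):
        active = np.abs(t) > t_thr
        if not active.any():
            return 0.0, [], np.array([])
        sub_adj = adjacency & active[:, None] & active[None, :]
        comps = _components(active, sub_adj)
        masses = np.array([np.abs(t[c]).sum() for c in comps])
        return masses.max(), comps, masses

    _, comps_obs, masses_obs = max_mass(t_obs)

    rng = np.random.default_rng(seed)
    signs = rng.choice([-1.0, 1.0], size=(n_perm, n_sub))
    null_means = signs @ X / n_sub  # (n_perm, n_channels)
    null_max = np.zeros(n_perm)
    for i in range(n_perm):
        null_max[i], _, _ = max_mass(group_t(null_means[i], sumsq))

    cluster_p = np.array(
        [(1.0 + np.sum(null_max >= m - 1e-12)) / (1.0 + n_perm) for m in masses_obs]
    )
    mask = np.zeros(n_ch, dtype=bool)
    for comp, p in zip(comps_obs, cluster_p):
        if p <= alpha:
            mask[comp] = True
    return ClusterResult(
        mask=mask,
        clusters=comps_obs,
        cluster_p=cluster_p,
        t_obs=t_obs,
        t_threshold=t_thr,
    )


def group_summary(subject_block_averages: np.ndarray) -> pd.DataFrame:
    """Group t map from per-subject block-average deltas.

    ``subject_block_averages`` is (n_subjects, n_channels) with NaN for
    subject/channel combinations lost to pruning. Channels with fewer
    than two contributing subjects are marked unavailable; identical
    contributions (SE = 0) are flagged degenerate.
    """
    X = np.asarray(subject_block_averages, dtype=float)
    rows = []
    for ch in range(X.shape[1]):
        vals = X[:, ch]
        vals = vals[np.isfinite(vals)]
        n = len(vals)
        if n < 2:
            rows.append(
                {"channel": ch, "n": n, "mean": np.nan, "se": np.nan,
                 "t": np.nan, "available": False, "degenerate": False}
            )
            continue
        res = tstat(vals)
        rows.append(
            {"channel": ch, "n": n, "mean": res.mean, "se": res.se,
             "t": res.t, "available": True, "degenerate": res.degenerate}
        )
    return pd.DataFrame(rows)
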