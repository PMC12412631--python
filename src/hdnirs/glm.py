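"""Per-channel GLM with a Gaussian temporal basis and short-separation
regression.

Each long channel is fit with ordinary least squares against a design
holding, per condition, a consecutive sequence of Gaussian functions of
1 s width (SD) and 1 s step whose centres span -2 s to 23 s around block
onset (26 per condition, both endpoints included), Legendre drift
polynomials of order 0-3, and one nuisance regressor: the 8 mm
short-separation channel most correlated with the long channel. The HRF
estimate is the basis expansion evaluated on the -2..23 s grid at the
recording's sampling rate. Chromophores are fit independently; since the
short-separation regressor differs per channel, there is one GLM per
channel.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import h5py
import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve, LinAlgError

from .synth import CONDITIONS, ParadigmSchedule, Recording

__all__ = [
    "DesignMatrix",
    "HrfEstimate",
    "select_ss_channel",
    "build_design",
    "fit_glm",
]

HRF_T_PRE = 2.0
HRF_T_POST = 23.0
BASIS_WIDTH = 1.0
BASIS_STEP = 1.0
DRIFT_ORDER = 3


@dataclass
class DesignMatrix:
    """Stimulus + drift design; the SS regressor is appended per channel."""

    matrix: np.ndarray  # (T, K)
    labels: list[str]
    fs: float
    conditions: tuple[str, ...]
    n_basis: int  # Gaussians per condition
    empty_conditions: list[str] = field(default_factory=list)

    @property
    def n_samples(self) -> int:
        return self.matrix.shape[0]

    def condition_columns(self, condition: str) -> np.ndarray:
        return np.array(
            [i for i, lab in enumerate(self.labels) if lab.startswith(f"{condition}:")]
        )

    def nuisance_columns(self) -> np.ndarray:
        return np.array(
            [
                i
                for i, lab in enumerate(self.labels)
                if lab.startswith(("drift", "rejected_", "step@"))
            ]
        )


def _basis_centres() -> np.ndarray:
    """Gaussian centres, both endpoints included: -2, -1, ..., 23 s."""
    return np.arange(-HRF_T_PRE, HRF_T_POST + 0.5 * BASIS_STEP, BASIS_STEP)


def hrf_time_grid(fs: float) -> np.ndarray:
    """-2..23 s sampling grid; length round((23+2)*fs)+1."""
    n = int(round((HRF_T_POST + HRF_T_PRE) * fs)) + 1
    return -HRF_T_PRE + np.arange(n) / fs


def basis_on_grid(fs: float) -> np.ndarray:
    """Gaussian basis evaluated on the HRF grid, shape (n_t, n_basis)."""
    t = hrf_time_grid(fs)
    centres = _basis_centres()
    return np.exp(-0.5 * ((t[:, None] - centres[None, :]) / BASIS_WIDTH) ** 2)


def build_design(
    schedule: ParadigmSchedule,
    fs: float,
    n_samples: int | None = None,
    include_blocks: np.ndarray | None = None,
    step_times: np.ndarray | None = None,
) -> DesignMatrix:
    """Condition-wise Gaussian basis columns plus Legendre drift columns.

    Each basis column is the sum over that condition's blocks of a
    Gaussian placed at onset + centre; a condition with zero blocks
    yields all-zero columns and is flagged in ``empty_conditions``.
    ``include_blocks`` (boolean mask over the schedule's blocks) excludes
    rejected blocks — e.g. motion-contaminated ones — from estimation.
    ``step_times`` adds one Heaviside nuisance column per detected motion
    event, absorbing residual baseline steps left by imperfect
    corrections (including those inside a short-separation regressor).
    """
    if fs <= 0:
        raise ValueError("sampling rate must be positive")
    if n_samples is None:
        n_samples = int(round(schedule.duration * fs))
    if include_blocks is None:
        include_blocks = np.ones(schedule.n_blocks, dtype=bool)
    include_blocks = np.asarray(include_blocks, dtype=bool)
    t = np.arange(n_samples) / fs
    centres = _basis_centres()
    cols, labels = [], []
    empty = []

    def _basis_block(onsets, prefix):
        for c in centres:
            col = np.zeros(n_samples)
            for onset in onsets:
                col += np.exp(-0.5 * ((t - onset - c) / BASIS_WIDTH) ** 2)
            cols.append(col)
            labels.append(f"{prefix}:{c:+.0f}s")

    rejected_any = False
    for cond in CONDITIONS:
        in_cond = np.array([c == cond for c in schedule.block_condition])
        onsets = schedule.block_onsets[in_cond & include_blocks]
        if len(onsets) == 0:
            empty.append(cond)
        _basis_block(onsets, cond)
        # rejected blocks are modelled too — as nuisance columns — so their
        # responses cannot leak into the retained-condition estimates
        rej = schedule.block_onsets[in_cond & ~include_blocks]
        if len(rej):
            _basis_block(rej, f"rejected_{cond}")
            rejected_any = True
    # Legendre drift polynomials on [-1, 1] for conditioning
    u = 2.0 * t / t[-1] - 1.0 if n_samples > 1 else np.zeros(1)
    for k in range(DRIFT_ORDER + 1):
        cols.append(np.polynomial.legendre.Legendre.basis(k)(u))
        labels.append(f"drift{k}")
    if step_times is not None:
        for st in np.atleast_1d(step_times):
            col = (t >= st).astype(float)
            # skip steps too close to either end to be identifiable
            if fs <= col.sum() <= n_samples - fs:
                cols.append(col)
                labels.append(f"step@{st:.0f}s")
    return DesignMatrix(
        matrix=np.column_stack(cols),
        labels=labels,
        fs=fs,
        conditions=CONDITIONS,
        n_basis=len(centres),
        empty_conditions=empty,
    )


def select_ss_channel(
    long_channel: int, ss_set: np.ndarray, conc: Recording, chromophore: int = 0
) -> int:
    """Short-separation channel whose trace best correlates with a long one.

    Correlation is Pearson's r on the chosen chromophore (HbO by
    default); ties break toward the lowest channel index.
    """
    ss_set = np.asarray(ss_set, dtype=int)
    if ss_set.size == 0:
        raise ValueError("no short channels")
    y = conc.data[long_channel, chromophore]
    best, best_r = None, -np.inf
    for ss in np.sort(ss_set):
        x = conc.data[ss, chromophore]
        sx, sy = x.std(), y.std()
        r = float(np.corrcoef(x, y)[0, 1]) if sx > 0 and sy > 0 else -np.inf
        if r > best_r + 1e-12:
            best, best_r = int(ss), r
    return int(ss_set.min()) if best is None else best


@dataclass
class HrfEstimate:
    """GLM output: HRF time courses, coefficients and residual variance."""

    hrf: np.ndarray  # (channels, n_conditions, 2 chromophores, n_t)
    time: np.ndarray  # -2..23 s grid
    coefficients: np.ndarray  # (channels, 2, K [+1 with SS])
    residual_variance: np.ndarray  # (channels, 2)
    design: DesignMatrix
    conditions: tuple[str, ...]
    ss_channel: np.ndarray | None = None  # per long channel, -1 if none
    cleaned: np.ndarray | None = None  # conc minus drift+SS fit, (C, 2, T)

    def condition_index(self, condition: str) -> int:
        return self.conditions.index(condition)

    def to_hdf5(self, path) -> None:
        with h5py.File(path, "w") as f:
            f.create_dataset("hrf", data=self.hrf)
            f.create_dataset("time", data=self.time)
            f.create_dataset("coefficients", data=self.coefficients)
            f.create_dataset("residual_variance", data=self.residual_variance)
            f.attrs["conditions"] = list(self.conditions)
            if self.ss_channel is not None:
                f.create_dataset("ss_channel", data=self.ss_channel)


def fit_glm(
    conc: Recording,
    design: DesignMatrix,
    ss_channels: np.ndarray | None = None,
    keep: np.ndarray | None = None,
) -> HrfEstimate:
    """Ordinary-least-squares fit of every channel and chromophore.

    ``ss_channels`` gives, per long channel, the index of the
    short-separation channel whose concentration trace joins the design
    as a nuisance column (-1 for none, e.g. for the SS channels
    themselves). Residuals are orthogonal to the design; adding the SS
    column can therefore never increase residual variance.
    """
    if conc.stage != "concentration":
        raise ValueError("GLM operates on concentration data")
    B = design.matrix
    T, K = B.shape
    if conc.n_samples != T:
        raise ValueError("design and data length mismatch")
    nonzero = np.abs(B).max(axis=0) > 0
    Bz = B[:, nonzero]
    G = Bz.T @ Bz
    try:
        cho = cho_factor(G)
    except LinAlgError:
        _, sv, vt = np.linalg.svd(G)
        bad = [design.labels[i] for i in np.flatnonzero(
            np.abs(vt[np.argmin(sv)]) > 0.3)]
        raise ValueError(f"rank-deficient design; collinear columns: {bad}")

    C = conc.n_channels
    basis = basis_on_grid(design.fs)
    n_t = basis.shape[0]
    n_cond = len(design.conditions)
    hrf = np.zeros((C, n_cond, 2, n_t))
    coefs = np.zeros((C, 2, K + 1))
    resvar = np.zeros((C, 2))
    cleaned = np.zeros_like(conc.data)
    if keep is None:
        keep = np.ones(C, bool)

    Y = conc.data  # (C, 2, T)
    BtY = np.einsum("tk,cwt->ckw", Bz, Y)  # (C, Kz, 2)
    nuis = design.nuisance_columns()
    nuis_z = np.array([np.flatnonzero(nonzero)[i] in nuis for i in range(Bz.shape[1])])
    # map from reduced to full coefficient positions
    full_pos = np.flatnonzero(nonzero)

    for c in range(C):
        if not keep[c]:
            continue
        s = None
        if ss_channels is not None and ss_channels[c] >= 0:
            s = Y[int(ss_channels[c])]  # (2, T)
        for w in range(2):
            y = Y[c, w]
            rhs = BtY[c, :, w]
            if s is not None and s[w].std() > 0:
                sv_ = s[w]
                Bts = Bz.T @ sv_
                ss_ = sv_ @ sv_
                sy = sv_ @ y
                # bordered-system solve: [[G, Bts],[Bts^T, ss]] beta = [rhs, sy]
                Ginv_Bts = cho_solve(cho, Bts)
                Ginv_rhs = cho_solve(cho, rhs)
                schur = ss_ - Bts @ Ginv_Bts
                if schur <= 1e-12 * ss_:
                    beta_s = 0.0
                    beta_b = Ginv_rhs
                else:
                    beta_s = (sy - Bts @ Ginv_rhs) / schur
                    beta_b = Ginv_rhs - Ginv_Bts * beta_s
                fitted_nuis = Bz[:, nuis_z] @ beta_b[nuis_z] + sv_ * beta_s
                rss = y @ y - rhs @ beta_b - sy * beta_s
                coefs[c, w, full_pos] = beta_b
                coefs[c, w, K] = beta_s
            else:
                beta_b = cho_solve(cho, rhs)
                fitted_nuis = Bz[:, nuis_z] @ beta_b[nuis_z]
                rss = y @ y - rhs @ beta_b
                coefs[c, w, full_pos] = beta_b
            resvar[c, w] = max(rss, 0.0) / max(T - Bz.shape[1] - (s is not None), 1)
            cleaned[c, w] = y - fitted_nuis
            for ci, cond in enumerate(design.conditions):
                cond_cols = design.condition_columns(cond)
                hrf[c, ci, w] = basis @ coefs[c, w, cond_cols]

    return HrfEstimate(
        hrf=hrf,
        time=hrf_time_grid(design.fs),
        coefficients=coefs,
        residual_variance=resvar,
        design=design,
        conditions=design.conditions,
        ss_channel=ss_channels,
        cleaned=cleaned,
    )
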