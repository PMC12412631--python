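"""Channel-space preprocessing: prune -> OD -> SplineSG -> low-pass -> MBLL.

The chain (in this fixed order) takes raw two-wavelength intensities to
chromophore concentration changes:

1. :func:`prune_channels` drops channels whose mean raw intensity falls
   below 0.001 units or whose raw SNR (mean/SD per wavelength) is below 5;
2. :func:`intensity_to_od` forms natural-log optical density;
3. :func:`splinesg_correct` corrects baseline-shift and spike motion
   artifacts with a smoothing-spline / Savitzky-Golay hybrid;
4. :func:`lowpass` removes cardiac and other high-frequency content with a
   zero-phase 0.5 Hz Butterworth filter;
5. :func:`od_to_conc` applies the modified Beer-Lambert law.

Re-running any step on identical input is bit-identical.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.interpolate import make_smoothing_spline
from scipy.signal import butter, savgol_filter, sosfiltfilt

from .extinction import extinction_matrix
from .synth import Recording

__all__ = [
    "PruneReport",
    "prune_channels",
    "intensity_to_od",
    "splinesg_correct",
    "lowpass",
    "motion_flags",
    "od_to_conc",
    "reject_blocks_and_subjects",
    "preprocess_recording",
]


@dataclass
class PruneReport:
    """Per-channel keep/prune decision with the triggering reason."""

    keep: np.ndarray  # bool per channel
    reason: list[str | None]  # None, "low_intensity" or "low_snr"
    intensity_min: float
    snr_min: float

    @property
    def n_kept(self) -> int:
        return int(self.keep.sum())

    @property
    def n_pruned(self) -> int:
        return int((~self.keep).sum())

    def to_table(self) -> pd.DataFrame:
        return pd.DataFrame({"keep": self.keep, "reason": self.reason})


def prune_channels(
    rec: Recording, intensity_min: float = 0.001, snr_min: float = 5.0
) -> PruneReport:
    """Flag channels with low raw signal or low raw SNR at either wavelength.

    SNR is the raw mean divided by the raw standard deviation per
    wavelength; a constant channel (SD = 0) counts as infinite SNR and is
    kept. Thresholds are strict ("less than"), so a channel exactly at a
    threshold survives.
    """
    if rec.stage != "intensity":
        raise ValueError("pruning operates on the intensity stage")
    if rec.n_samples == 0 or rec.n_channels == 0:
        raise ValueError("empty recording")
    mean = rec.data.mean(axis=2)  # (C, 2)
    sd = rec.data.std(axis=2)
    with np.errstate(divide="ignore"):
        snr = np.where(sd > 0, mean / np.where(sd > 0, sd, 1.0), np.inf)
    low_int = (mean < intensity_min).any(axis=1)
    low_snr = (snr < snr_min).any(axis=1)
    keep = ~(low_int | low_snr)
    reason = [
        None if k else ("low_intensity" if li else "low_snr")
        for k, li in zip(keep, low_int)
    ]
    return PruneReport(keep=keep, reason=reason,
                       intensity_min=intensity_min, snr_min=snr_min)


def intensity_to_od(rec: Recording) -> Recording:
    """OD(t) = -ln(I(t) / mean(I)) per channel and wavelength."""
    if rec.stage != "intensity":
        raise ValueError("input must be at the intensity stage")
    bad = np.argwhere(rec.data <= 0)
    if len(bad):
        c, w, _ = bad[0]
        raise ValueError(f"non-positive intensity in channel {c}, wavelength index {w}")
    mean = rec.data.mean(axis=2, keepdims=True)
    od = -np.log(rec.data / mean)
    return rec.copy_with(stage="od", data=od)


def _detect_artifacts(y: np.ndarray, fs: float):
    """Flag spike samples and baseline-shift segments in one OD trace.

    Spikes: residual from a short (2 s) Savitzky-Golay baseline exceeding
    6x its robust SD. Shifts: the baseline's change across a 1 s span
    exceeding 6x the robust SD of that change series, which self-
    normalizes for smooth physiological oscillation.
    """
    n = len(y)
    win = int(round(2.0 * fs)) | 1
    win = max(win, 5)
    if win >= n:
        return np.zeros(n, bool), np.zeros(n, bool)
    baseline = savgol_filter(y, win, 3)
    resid = y - baseline
    sigma = 1.4826 * np.median(np.abs(resid - np.median(resid)))
    spikes = np.abs(resid) > 6.0 * sigma if sigma > 0 else np.zeros(n, bool)

    h = max(1, int(round(0.5 * fs)))
    jump = np.zeros(n)
    jump[h:-h] = baseline[2 * h :] - baseline[: -2 * h]
    sigma_j = 1.4826 * np.median(np.abs(jump - np.median(jump)))
    shifts = np.abs(jump) > 6.0 * sigma_j if sigma_j > 0 else np.zeros(n, bool)
    # dilate shift flags by 0.5 s so segments cover the whole transition
    if shifts.any():
        kernel = np.ones(2 * h + 1)
        shifts = np.convolve(shifts.astype(float), kernel, mode="same") > 0
    return spikes, shifts


def _segments(mask: np.ndarray) -> list[tuple[int, int]]:
    idx = np.flatnonzero(np.diff(np.concatenate([[0], mask.view(np.int8), [0]])))
    return [(idx[i], idx[i + 1]) for i in range(0, len(idx), 2)]


def _correct_shifts(y: np.ndarray, fs: float, shifts: np.ndarray, p: float) -> np.ndarray:
    """Subtract a smoothing spline inside each motion segment and re-anchor.

    Within a flagged segment the spline (smoothing parameter ``p`` in the
    usual 0..1 fidelity convention) tracks the artifact trajectory; the
    segment is re-levelled to the data just before it, and everything
    after the segment is shifted to close the residual discontinuity, so
    step artifacts are removed from the rest of the run too.
    """
    out = y.copy()
    # 3 s windows on a smoothed copy for level estimation: averaging a
    # low-passed trace keeps cardiac oscillation and noise out of the
    # anchor levels, so the residual step stays small
    w = max(1, int(round(3.0 * fs)))
    lam = (1.0 - p) / p

    def _level(arr, sl):
        win = int(round(2.0 * fs)) | 1
        seg = arr[sl]
        if len(seg) >= max(win, 5):
            from scipy.signal import savgol_filter

            return savgol_filter(seg, win, 3).mean()
        return seg.mean()

    for a, b in _segments(shifts):
        seg = out[a:b].copy()
        if b - a >= 4:
            x = np.arange(b - a, dtype=float)
            trend = make_smoothing_spline(x, seg, lam=lam)(x)
        else:
            trend = seg.copy()
        anchor = _level(out, slice(max(0, a - w), a)) if a > 0 else seg[0]
        corrected = seg - trend + anchor
        out[a:b] = corrected
        if b < len(out):
            tail_level = _level(out, slice(b, min(len(out), b + w)))
            seg_end = _level(corrected, slice(max(0, len(corrected) - w), len(corrected)))
            out[b:] -= tail_level - seg_end
    return out


def splinesg_correct(rec: Recording, p: float = 0.99, frame_s: float = 10.0) -> Recording:
    """Hybrid spline / Savitzky-Golay motion correction on OD traces.

    Baseline shifts are corrected by smoothing-spline subtraction within
    detected motion segments (with level re-anchoring); remaining spike
    samples are replaced by the value of a ``frame_s``-long, order-3
    Savitzky-Golay fit. Channels without detected motion pass through
    unchanged.
    """
    if rec.stage != "od":
        raise ValueError("SplineSG operates on optical density")
    frame = int(round(frame_s * rec.fs)) | 1
    if frame < 3:
        raise ValueError("frame shorter than 3 samples")
    out = rec.data.copy()
    n = rec.n_samples
    for c in range(rec.n_channels):
        for w in range(out.shape[1]):
            y = out[c, w]
            spikes, shifts = _detect_artifacts(y, rec.fs)
            if shifts.any():
                y = _correct_shifts(y, rec.fs, shifts, p)
            if spikes.any():
                smooth = savgol_filter(y, min(frame, n - (n + 1) % 2), 3)
                y = np.where(spikes, smooth, y)
            out[c, w] = y
    return rec.copy_with(data=out)


def motion_flags(rec: Recording, keep: np.ndarray | None = None) -> np.ndarray:
    """Global motion time mask: union of detected baseline-shift segments.

    Returns a boolean vector over samples; paradigm blocks overlapping it
    should be excluded from HRF estimation, mirroring the practice of
    rejecting motion-contaminated blocks before the GLM. Spike flags are
    not included (spike samples are repaired in place)."""
    if rec.stage != "od":
        raise ValueError("motion detection operates on optical density")
    mask = np.zeros(rec.n_samples, dtype=bool)
    for c in range(rec.n_channels):
        if keep is not None and not keep[c]:
            continue
        for w in range(rec.data.shape[1]):
            _, shifts = _detect_artifacts(rec.data[c, w], rec.fs)
            mask |= shifts
    return mask


def lowpass(rec: Recording, fc: float = 0.5, order: int = 3) -> Recording:
    """Zero-phase Butterworth low-pass (applied forward and backward)."""
    if rec.stage != "od":
        raise ValueError("low-pass operates on optical density")
    if fc >= rec.fs / 2.0:
        raise ValueError("cutoff at or above Nyquist")
    sos = butter(order, fc, btype="low", fs=rec.fs, output="sos")
    data = sosfiltfilt(sos, rec.data, axis=2)
    return rec.copy_with(data=np.ascontiguousarray(data))


def od_to_conc(rec: Recording, ppf: float = 1.0) -> Recording:
    """Modified Beer-Lambert law: OD at two wavelengths -> (dHbO, dHbR) uM.

    Per channel, ``[dHbO; dHbR] = E^-1 @ (dOD / (L * ppf))`` with E the
    2x2 natural-log extinction matrix in 1/(mm*uM) and L the channel
    separation in mm. ``ppf`` is the partial-pathlength factor (default 1).
    """
    if rec.stage != "od":
        raise ValueError("Beer-Lambert conversion operates on optical density")
    E = extinction_matrix(rec.wavelengths)
    if abs(np.linalg.det(E)) < 1e-18:
        raise ValueError("singular extinction matrix")
    Einv = np.linalg.inv(E)
    sep = rec.channels["separation"].to_numpy()[:, None, None]
    scaled = rec.data / (sep * ppf)
    conc = np.einsum("kw,cwt->ckt", Einv, scaled)
    return rec.copy_with(stage="concentration", data=conc)


def reject_blocks_and_subjects(
    block_table: pd.DataFrame,
    min_blocks: int = 5,
    range_threshold: float | None = None,
) -> tuple[pd.DataFrame, list]:
    """Automated surrogate for manual block rejection.

    ``block_table`` holds one row per (subject, condition, block) with a
    ``range`` column (peak-to-peak concentration during the block, uM).
    Blocks whose range exceeds ``range_threshold`` are dropped; subjects
    left with fewer than ``min_blocks`` blocks in either condition are
    excluded entirely. Returns the filtered table and the excluded
    subjects.
    """
    table = block_table.copy()
    if range_threshold is not None and "range" in table.columns:
        table = table[table["range"] <= range_threshold]
    excluded = []
    for subject, grp in table.groupby("subject"):
        counts = grp.groupby("condition")["block"].nunique()
        conditions = block_table["condition"].unique()
        if any(counts.get(c, 0) < min_blocks for c in conditions):
            excluded.append(subject)
    table = table[~table["subject"].isin(excluded)]
    return table.reset_index(drop=True), excluded


def preprocess_recording(
    rec: Recording,
    intensity_min: float = 0.001,
    snr_min: float = 5.0,
    p: float = 0.99,
    frame_s: float = 10.0,
    fc: float = 0.5,
    ppf: float = 1.0,
) -> tuple[Recording, PruneReport]:
    """Run the full channel-space chain; pruned channels are zeroed out.

    Returns the concentration-stage recording together with the prune
    report (downstream analyses must respect ``report.keep``).
    """
    report = prune_channels(rec, intensity_min=intensity_min, snr_min=snr_min)
    od = intensity_to_od(rec)
    od.data[~report.keep] = 0.0
    motion = motion_flags(od, keep=report.keep)
    od = splinesg_correct(od, p=p, frame_s=frame_s)
    od = lowpass(od, fc=fc)
    conc = od_to_conc(od, ppf=ppf)
    conc.data[~report.keep] = 0.0
    conc.meta = dict(conc.meta, motion_mask=motion)
    return conc, report
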