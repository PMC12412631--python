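"""Synthetic block-design recordings with known ground truth.

The generator emulates the statistical structure the downstream analysis
assumes: a word-colour-Stroop-style block paradigm (18 blocks of 18 s,
nine per condition, inter-stimulus rest jittered uniformly in 10-15 s,
20 s initial rest), bilateral cortical activation patches carrying a
canonical double-gamma haemodynamic response, a shared low-frequency
superficial (scalp) signal picked up preferentially by the 8 mm channels,
and instrumental/physiological nuisance: ~1.1 Hz cardiac pulsation, slow
drift, white noise, spike and baseline-shift motion artifacts and an
optional fraction of dead (low-intensity) channels.

All randomness is seeded; identical seeds reproduce recordings bit for
bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .forward import HeadModel, SensitivityMatrix
from .probe import ProbeLayout
from .recon import MultispectralSystem, stack_multispectral

__all__ = [
    "CONDITIONS",
    "DEFAULT_FS",
    "ParadigmSchedule",
    "generate_schedule",
    "canonical_hrf",
    "block_response",
    "GroundTruth",
    "make_ground_truth",
    "SynthNoise",
    "Recording",
    "simulate_recording",
]

CONDITIONS = ("congruent", "incongruent")

#: acquisition sampling rate per array (Hz)
DEFAULT_FS = {"sparse": 24.4, "hd": 17.5}


@dataclass
class ParadigmSchedule:
    """Block onsets/conditions for one run."""

    block_onsets: np.ndarray  # seconds, strictly increasing
    block_condition: list[str]
    block_duration: float = 18.0
    initial_rest: float = 20.0
    isi_range: tuple[float, float] = (10.0, 15.0)

    def __post_init__(self):
        self.block_onsets = np.asarray(self.block_onsets, dtype=float)
        if len(self.block_onsets) != len(self.block_condition):
            raise ValueError("onsets and conditions length mismatch")
        counts = {c: self.block_condition.count(c) for c in CONDITIONS}
        # conditions that occur must be balanced (a zero-block condition is
        # tolerated so degenerate designs can be flagged downstream)
        if len({v for v in counts.values() if v > 0}) > 1:
            raise ValueError("conditions must be balanced")
        gaps = np.diff(self.block_onsets) - self.block_duration
        lo, hi = self.isi_range
        if np.any(np.diff(self.block_onsets) <= 0):
            raise ValueError("onsets must be strictly increasing")
        if len(gaps) and (gaps.min() < lo - 1e-9 or gaps.max() > hi + 1e-9):
            raise ValueError("inter-stimulus interval outside allowed range")

    @property
    def n_blocks(self) -> int:
        return len(self.block_onsets)

    @property
    def duration(self) -> float:
        """Run length: last block end plus a 20 s tail."""
        return float(self.block_onsets[-1] + self.block_duration + 20.0)

    def onsets(self, condition: str) -> np.ndarray:
        mask = [c == condition for c in self.block_condition]
        return self.block_onsets[np.asarray(mask, bool)]

    def to_events(self) -> pd.DataFrame:
        """Plain-text events table (onset, duration, condition)."""
        return pd.DataFrame(
            {
                "onset": self.block_onsets,
                "duration": self.block_duration,
                "condition": self.block_condition,
            }
        )


def generate_schedule(
    seed: int | np.random.Generator,
    n_per_condition: int = 9,
    block_duration: float = 18.0,
    initial_rest: float = 20.0,
    isi_range: tuple[float, float] = (10.0, 15.0),
) -> ParadigmSchedule:
    """Seeded random schedule: balanced random block order, jittered rest."""
    rng = np.random.default_rng(seed)
    conditions = list(CONDITIONS) * n_per_condition
    order = rng.permutation(len(conditions))
    conditions = [conditions[i] for i in order]
    isis = rng.uniform(*isi_range, size=len(conditions) - 1)
    onsets = initial_rest + np.concatenate(
        [[0.0], np.cumsum(block_duration + isis)]
    )
    return ParadigmSchedule(
        block_onsets=onsets,
        block_condition=conditions,
        block_duration=block_duration,
        initial_rest=initial_rest,
        isi_range=isi_range,
    )


def canonical_hrf(t: np.ndarray, peak: float = 6.0, undershoot: float = 16.0,
                  ratio: float = 1.0 / 6.0) -> np.ndarray:
    """Canonical double-gamma impulse response, peak-normalized to 1."""
    from scipy.stats import gamma as gamma_dist

    t = np.asarray(t, dtype=float)
    h = gamma_dist.pdf(t, peak) - ratio * gamma_dist.pdf(t, undershoot)
    m = h.max()
    return h / m if m > 0 else h


def block_response(fs: float, block_duration: float = 18.0,
                   length: float = 40.0) -> np.ndarray:
    """Double-gamma response to one block boxcar, peak-normalized to 1.

    Scaling an active vertex by an amplitude in uM therefore makes that
    amplitude the peak concentration excursion of the block.
    """
    dt = 1.0 / fs
    t = np.arange(0.0, length, dt)
    kernel = canonical_hrf(t)
    boxcar = (t < block_duration).astype(float)
    resp = np.convolve(boxcar, kernel)[: len(t)] * dt
    m = resp.max()
    return resp / m if m > 0 else resp


@dataclass
class GroundTruth:
    """Known activation/nuisance structure behind a synthetic subject.

    ``active_brain_vertices`` maps condition -> indices into the head
    model's stacked vertex array (brain surface entries). The superficial
    signal is a seeded sum of low-frequency sinusoids shared by all scalp
    vertices, evaluable at any sampling rate so both arrays see the same
    truth.
    """

    active_brain_vertices: dict[str, np.ndarray]
    hbo_amplitude: dict[str, float]
    hbr_amplitude: dict[str, float]
    superficial_components: np.ndarray  # (K, 3): freq Hz, amplitude uM, phase
    superficial_hbr_ratio: float = -0.3
    artifact_spec: dict = field(default_factory=dict)
    activation_centers: np.ndarray | None = None
    seed: int = 0

    def __post_init__(self):
        for cond in self.hbo_amplitude:
            if self.hbo_amplitude[cond] > 0 and not self.hbr_amplitude[cond] < 0:
                raise ValueError("HbR amplitude must oppose HbO for activation")

    def superficial(self, t: np.ndarray) -> np.ndarray:
        """Shared scalp HbO signal (uM) at times ``t``."""
        t = np.asarray(t, dtype=float)
        out = np.zeros_like(t)
        for f, a, ph in self.superficial_components:
            out += a * np.sin(2.0 * np.pi * f * t + ph)
        return out


def make_ground_truth(
    head: HeadModel,
    seed: int = 0,
    centers: np.ndarray | None = None,
    radius: float = 12.0,
    hbo_amplitude: dict[str, float] | None = None,
    hbr_ratio: float = -0.25,
    superficial_amp: float = 0.05,
    n_spikes: int = 6,
    n_shifts: int = 2,
    duration: float = 620.0,
) -> GroundTruth:
    """Bilateral activation patches plus seeded nuisance structure.

    Defaults: two 12 mm-radius patches centred 90 mm left/right of the
    midline on the brain surface (a dorsolateral-prefrontal analogue for
    a frontotemporal array), incongruent peak HbO 1.0 uM and congruent
    0.5 uM with HbR at -0.25 of HbO, and a ~0.05 uM RMS superficial signal
    concentrated below 0.12 Hz.
    """
    rng = np.random.default_rng(seed)
    if centers is None:
        centers = np.array([[-90.0, 0.0], [90.0, 0.0]])
    if hbo_amplitude is None:
        hbo_amplitude = {"congruent": 0.5, "incongruent": 1.0}
    brain = head.brain_vertices
    active = []
    for cx, cy in np.atleast_2d(centers):
        d = np.hypot(brain[:, 0] - cx, brain[:, 1] - cy)
        active.append(np.flatnonzero(d <= radius))
    active_idx = np.unique(np.concatenate(active))
    if len(active_idx) == 0:
        raise ValueError("no brain vertices within radius of activation centers")
    # same bilateral patches for both conditions; amplitudes differ
    active_map = {c: active_idx for c in CONDITIONS}
    freqs = rng.uniform(0.02, 0.12, size=5)
    phases = rng.uniform(0, 2 * np.pi, size=5)
    amps = rng.uniform(0.5, 1.0, size=5)
    amps *= superficial_amp / np.sqrt(0.5 * np.sum(amps**2))  # RMS ~ superficial_amp
    components = np.column_stack([freqs, amps, phases])
    artifact_spec = {
        "spike_times": np.sort(rng.uniform(30.0, duration - 30.0, size=n_spikes)),
        "spike_amps": rng.uniform(0.05, 0.15, size=n_spikes),
        "shift_times": np.sort(rng.uniform(30.0, duration - 30.0, size=n_shifts)),
        "shift_amps": rng.uniform(0.03, 0.08, size=n_shifts)
        * rng.choice([-1.0, 1.0], size=n_shifts),
    }
    return GroundTruth(
        active_brain_vertices=active_map,
        hbo_amplitude=dict(hbo_amplitude),
        hbr_amplitude={c: hbr_ratio * a for c, a in hbo_amplitude.items()},
        superficial_components=components,
        artifact_spec=artifact_spec,
        activation_centers=np.atleast_2d(centers),
        seed=int(seed),
    )


@dataclass(frozen=True)
class SynthNoise:
    """Nuisance magnitudes, all in optical-density units unless noted.

    Defaults give raw-intensity channel SNR (mean/SD) of roughly 40-60.
    """

    white_sd: float = 0.003
    cardiac_amp: float = 0.021
    cardiac_freq: float = 1.1
    drift_amp: float = 0.012
    dead_channel_fraction: float = 0.0
    artifact_channel_fraction: float = 0.15
    #: white OD noise scales as 1/sqrt(detected light); short channels are
    #: photon-rich and quiet, long ones dimmer and noisier. The factor is
    #: sqrt(G(30 mm)/G(L)) clipped to this range.
    shot_scale_bounds: tuple[float, float] = (0.1, 3.0)

    @classmethod
    def noiseless(cls) -> "SynthNoise":
        return cls(white_sd=0.0, cardiac_amp=0.0, drift_amp=0.0,
                   dead_channel_fraction=0.0, artifact_channel_fraction=0.0)


@dataclass
class Recording:
    """Multi-channel two-wavelength (or two-chromophore) time series.

    ``data`` has shape (channels, 2, time); axis 1 holds wavelengths for
    the intensity/od stages and (HbO, HbR) for the concentration stage.
    """

    layout_name: str
    fs: float
    stage: str  # intensity | od | concentration
    data: np.ndarray
    schedule: ParadigmSchedule
    channels: pd.DataFrame
    wavelengths: tuple[float, float] = (760.0, 850.0)
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.stage not in ("intensity", "od", "concentration"):
            raise ValueError(f"unknown stage {self.stage!r}")
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3 or self.data.shape[1] != 2:
            raise ValueError("data must be (channels, 2, time)")
        if self.stage == "intensity" and np.any(self.data <= 0):
            raise ValueError("intensity must be strictly positive")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    @property
    def time(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.fs

    def copy_with(self, **kw) -> "Recording":
        out = replace(self, **kw)
        return out


def simulate_recording(
    layout: ProbeLayout,
    S: SensitivityMatrix,
    truth: GroundTruth,
    schedule: ParadigmSchedule,
    noise: SynthNoise = SynthNoise(),
    seed: int = 0,
    fs: float | None = None,
    i0: float = 0.02,
) -> Recording:
    """Generate a raw-intensity recording via the linear Rytov forward model.

    Concentration time courses on active brain vertices (per condition)
    and on all scalp vertices (shared superficial signal) are pushed
    through the wavelength-stacked sensitivity to channel optical density;
    cardiac, drift, white noise and artifact events are added in OD, and
    intensity is formed as ``I = i0 * exp(-OD_total)``.
    """
    if i0 <= 0:
        raise ValueError("baseline intensity i0 must be positive")
    if fs is None:
        fs = DEFAULT_FS.get(layout.name, 20.0)
    rng = np.random.default_rng(seed)
    system: MultispectralSystem = stack_multispectral(S)
    A = system.A
    V = system.n_vertices
    n_ch = S.n_channels
    n_rows = A.shape[0]  # wavelengths * channels

    T = int(round(schedule.duration * fs))
    t = np.arange(T) / fs

    od = np.zeros((n_rows, T))

    # --- cortical activation -------------------------------------------
    resp = block_response(fs, schedule.block_duration)
    for cond in CONDITIONS:
        g = np.zeros(T)
        for onset in schedule.onsets(cond):
            i0_idx = int(round(onset * fs))
            seg = resp[: max(0, T - i0_idx)]
            g[i0_idx : i0_idx + len(seg)] += seg
        idx = truth.active_brain_vertices[cond]
        a_ch = (
            A[:, idx].sum(axis=1) * truth.hbo_amplitude[cond]
            + A[:, V + idx].sum(axis=1) * truth.hbr_amplitude[cond]
        )
        od += np.outer(a_ch, g)

    # --- shared superficial (scalp) signal -----------------------------
    scalp_idx = np.flatnonzero(S.scalp_mask)
    s_t = truth.superficial(t)
    a_sup = (
        A[:, scalp_idx].sum(axis=1)
        + truth.superficial_hbr_ratio * A[:, V + scalp_idx].sum(axis=1)
    )
    od += np.outer(a_sup, s_t)

    # --- nuisance -------------------------------------------------------
    if noise.cardiac_amp > 0:
        phase = rng.uniform(0, 2 * np.pi, size=n_ch)
        amp = noise.cardiac_amp * rng.uniform(0.8, 1.2, size=n_ch)
        cardiac = amp[:, None] * np.sin(
            2 * np.pi * noise.cardiac_freq * t[None, :] + phase[:, None]
        )
        od += np.tile(cardiac, (len(S.wavelengths), 1))
    if noise.drift_amp > 0:
        # slow instrumental wander: smooth random cubic per row, RMS =
        # drift_amp (sub-polynomial physiological fluctuation lives in the
        # shared superficial compartment instead)
        u = 2.0 * t / max(t[-1], 1.0) - 1.0
        P = np.polynomial.legendre.legvander(u, 3)[:, 1:]  # P1..P3
        coef = rng.standard_normal((n_rows, 3))
        wander = coef @ P.T
        sd = wander.std(axis=1, keepdims=True)
        od += noise.drift_amp * wander / np.where(sd > 0, sd, 1.0)
    if noise.white_sd > 0:
        # shot-noise-like scaling: OD noise ~ 1/sqrt(detected intensity),
        # which follows the DC Green's function of the separation
        from .forward import green_semi_infinite

        sep = np.array([c.separation for c in layout.channels])
        g = green_semi_infinite(
            np.zeros(3),
            np.column_stack([sep, np.zeros_like(sep), np.zeros_like(sep)]),
            0.018, 1.1,
        )
        g30 = green_semi_infinite(np.zeros(3), np.array([30.0, 0.0, 0.0]), 0.018, 1.1)
        factor = np.clip(np.sqrt(g30 / g), *noise.shot_scale_bounds)
        sd_rows = noise.white_sd * np.tile(factor, len(S.wavelengths))
        od += rng.normal(0.0, 1.0, size=od.shape) * sd_rows[:, None]

    # --- motion artifacts ----------------------------------------------
    spec = truth.artifact_spec
    if spec and noise.artifact_channel_fraction > 0:
        n_art = max(1, int(round(noise.artifact_channel_fraction * n_ch)))
        for st, sa in zip(spec.get("spike_times", []), spec.get("spike_amps", [])):
            chans = rng.choice(n_ch, size=n_art, replace=False)
            k = int(round(st * fs))
            if 0 <= k < T:
                width = max(1, int(round(0.2 * fs)))
                shape = sa * np.exp(-np.arange(width) / (0.05 * fs + 1e-9))
                for c in chans:
                    for w in range(len(S.wavelengths)):
                        seg = shape[: T - k]
                        od[w * n_ch + c, k : k + len(seg)] += seg
        for st, sa in zip(spec.get("shift_times", []), spec.get("shift_amps", [])):
            chans = rng.choice(n_ch, size=n_art, replace=False)
            k = int(round(st * fs))
            if 0 <= k < T:
                for c in chans:
                    for w in range(len(S.wavelengths)):
                        od[w * n_ch + c, k:] += sa

    intensity = i0 * np.exp(-od)

    # --- dead channels --------------------------------------------------
    if noise.dead_channel_fraction > 0:
        n_dead = int(np.floor(noise.dead_channel_fraction * n_ch))
        dead = rng.choice(n_ch, size=n_dead, replace=False)
        for c in dead:
            for w in range(len(S.wavelengths)):
                row = w * n_ch + c
                intensity[row] = 4e-4 * (1.0 + 0.3 * rng.standard_normal(T)) ** 2 + 1e-6

    data = np.stack(
        [intensity[w * n_ch : (w + 1) * n_ch] for w in range(len(S.wavelengths))],
        axis=1,
    )
    return Recording(
        layout_name=layout.name,
        fs=float(fs),
        stage="intensity",
        data=data,
        schedule=schedule,
        channels=layout.channel_table(),
        wavelengths=tuple(S.wavelengths),
        meta={"i0": i0, "seed": int(seed)},
    )
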