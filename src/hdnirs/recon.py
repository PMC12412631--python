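"""Brain + scalp image reconstruction with spatially variant regularization.

The forward statement is ``y = A x`` with y stacked channel optical
densities over the two wavelengths and x stacked (HbO, HbR) concentration
changes over all brain and scalp vertices. Because shallow (scalp)
vertices dominate raw sensitivity, A is first rescaled column-wise by a
diagonal L,

    L_vv       = sqrt( (A^T A)_vv + lambda_spatial ),
    lambda_sp  = alpha_spatial * max(diag(A^T A)),
    A_hat      = A L^{-1},

which down-weights high-sensitivity superficial vertices and tunes the
reconstruction depth. The under-determined system is then inverted with
Tikhonov regularization in channel space,

    x      = L^{-1} A_hat^T (A_hat A_hat^T + lambda I)^{-1} y,
    lambda = alpha_meas * max(diag(A_hat A_hat^T)),

where alpha_meas smooths the image. A "brain only" variant restricts A to
brain columns and skips the spatial rescaling. The channel-space system is
solved through a Cholesky factorization (never an explicit inverse).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve

from .extinction import extinction_matrix
from .forward import SensitivityMatrix

__all__ = [
    "ReconConfig",
    "BrainImage",
    "MultispectralSystem",
    "stack_multispectral",
    "rescale_sensitivity",
    "reconstruct",
    "ImageReconstructor",
    "image_timecourse",
]


@dataclass(frozen=True)
class ReconConfig:
    alpha_spatial: float = 0.001
    alpha_meas: float = 0.001
    mode: str = "brain_scalp"  # or "brain_only"

    def __post_init__(self):
        if self.alpha_spatial <= 0 or self.alpha_meas <= 0:
            raise ValueError("regularization parameters must be positive")
        if self.mode not in ("brain_scalp", "brain_only"):
            raise ValueError(f"unknown reconstruction mode {self.mode!r}")


@dataclass
class BrainImage:
    """Per-vertex HbO/HbR values (uM, or t-statistics) on brain and scalp."""

    hbo: np.ndarray
    hbr: np.ndarray
    vertices: pd.DataFrame  # x, y, z, surface

    @property
    def brain_mask(self) -> np.ndarray:
        return (self.vertices["surface"] == "brain").to_numpy()

    @property
    def scalp_mask(self) -> np.ndarray:
        return (self.vertices["surface"] == "scalp").to_numpy()

    def peak_brain_vertex(self, chromophore: str = "hbo") -> int:
        """Index (into the vertex table) of the maximal brain-surface value."""
        vals = getattr(self, chromophore).copy()
        vals[~self.brain_mask] = -np.inf
        return int(np.argmax(vals))

    def surface_energy_fraction(self, surface: str = "scalp") -> float:
        mask = self.brain_mask if surface == "brain" else self.scalp_mask
        total = float(np.sum(self.hbo**2 + self.hbr**2))
        if total == 0:
            return 0.0
        part = float(np.sum(self.hbo[mask] ** 2 + self.hbr[mask] ** 2))
        return part / total

    def to_table(self) -> pd.DataFrame:
        out = self.vertices.copy()
        out["hbo"] = self.hbo
        out["hbr"] = self.hbr
        return out


@dataclass
class MultispectralSystem:
    """Wavelength-stacked, chromophore-resolved sensitivity system."""

    A: np.ndarray  # (n_wavelengths * n_channels, 2 * n_vertices)
    sensitivity: SensitivityMatrix

    @property
    def n_vertices(self) -> int:
        return self.sensitivity.n_vertices

    @property
    def n_channels(self) -> int:
        return self.sensitivity.n_channels

    def column_mask(self, surface: str | None = None) -> np.ndarray:
        """Boolean mask over the 2V columns, optionally one surface only."""
        if surface is None:
            return np.ones(2 * self.n_vertices, bool)
        m = (self.sensitivity.vertices["surface"] == surface).to_numpy()
        return np.concatenate([m, m])

    def hbo_cols(self) -> slice:
        return slice(0, self.n_vertices)

    def hbr_cols(self) -> slice:
        return slice(self.n_vertices, 2 * self.n_vertices)


def stack_multispectral(S: SensitivityMatrix) -> MultispectralSystem:
    """Combine per-wavelength sensitivities with extinction coefficients.

    Row block w, column block c holds ``E[w, c] * S_w`` so that
    ``y = A @ [dHbO; dHbR]`` yields natural-log optical density directly
    from concentration changes in uM.
    """
    E = extinction_matrix(S.wavelengths)
    blocks = [
        [E[w, 0] * S.values[w], E[w, 1] * S.values[w]]
        for w in range(len(S.wavelengths))
    ]
    A = np.block(blocks)
    return MultispectralSystem(A=A, sensitivity=S)


def rescale_sensitivity(A: np.ndarray, alpha_spatial: float = 0.001):
    """Spatially variant rescaling ``A_hat = A L^{-1}``.

    Returns ``(A_hat, L)`` with L the diagonal (as a 1-D vector) over
    columns (vertices x chromophores). Columns with the highest raw
    sensitivity — the superficial ones — are down-weighted the most.
    """
    if alpha_spatial <= 0:
        raise ValueError("alpha_spatial must be positive")
    A = np.asarray(A, dtype=float)
    col_energy = np.einsum("ij,ij->j", A, A)  # diag(A^T A)
    if not np.any(col_energy > 0):
        raise ValueError("degenerate sensitivity matrix")
    lam_spatial = alpha_spatial * col_energy.max()
    L = np.sqrt(col_energy + lam_spatial)
    return A / L, L


class ImageReconstructor:
    """Precomputed inversion operator for repeated reconstructions.

    Factorizes the regularized channel-space Gram matrix once so that each
    subsequent measurement vector costs only a triangular solve plus one
    matrix-vector product.
    """

    def __init__(
        self,
        system: MultispectralSystem | np.ndarray,
        config: ReconConfig = ReconConfig(),
        brain_mask: np.ndarray | None = None,
    ):
        self.config = config
        if isinstance(system, MultispectralSystem):
            self.system = system
            A = system.A
            if brain_mask is None:
                brain_mask = system.column_mask("brain")
        else:
            self.system = None
            A = np.asarray(system, dtype=float)
        self.n_cols = A.shape[1]
        if config.mode == "brain_only":
            if brain_mask is None:
                raise ValueError("brain_only mode needs a brain column mask")
            self.active = np.flatnonzero(brain_mask)
            A_act = A[:, self.active]
            self.L = np.ones(len(self.active))
            A_hat = A_act
        else:
            self.active = np.arange(self.n_cols)
            A_hat, self.L = rescale_sensitivity(A, config.alpha_spatial)
        M = A_hat @ A_hat.T
        lam = config.alpha_meas * float(np.max(np.diag(M)))
        if lam <= 0:
            raise ValueError("degenerate sensitivity matrix")
        M[np.diag_indices_from(M)] += lam
        self._cho = cho_factor(M, lower=True)
        self._A_hat = A_hat

    def __call__(self, y: np.ndarray) -> np.ndarray:
        y = np.asarray(y, dtype=float)
        if y.shape[-1] != self._A_hat.shape[0]:
            raise ValueError(
                f"measurement length {y.shape[-1]} != {self._A_hat.shape[0]} channels"
            )
        if not np.all(np.isfinite(y)):
            raise ValueError("non-finite measurement vector")
        w = cho_solve(self._cho, y.T)  # (rows, ...) channel-space weights
        x_act = (self._A_hat.T @ w).T / self.L
        x = np.zeros(y.shape[:-1] + (self.n_cols,))
        x[..., self.active] = x_act
        return x

    def image(self, y: np.ndarray) -> BrainImage:
        if self.system is None:
            raise ValueError("image() requires a MultispectralSystem")
        x = self(y)
        V = self.system.n_vertices
        return BrainImage(
            hbo=x[:V], hbr=x[V:], vertices=self.system.sensitivity.vertices
        )


def reconstruct(
    y: np.ndarray,
    system: MultispectralSystem | np.ndarray,
    config: ReconConfig = ReconConfig(),
    brain_mask: np.ndarray | None = None,
):
    """One-shot reconstruction; see :class:`ImageReconstructor`.

    Returns a :class:`BrainImage` when given a :class:`MultispectralSystem`
    and a plain coefficient vector when given a bare matrix.
    """
    op = ImageReconstructor(system, config, brain_mask=brain_mask)
    if isinstance(system, MultispectralSystem):
        return op.image(np.asarray(y, dtype=float))
    return op(y)


def hrf_to_od(
    hrf_conc: np.ndarray,
    separations: np.ndarray,
    wavelengths=(760.0, 850.0),
    ppf: float = 1.0,
) -> np.ndarray:
    """Forward Beer-Lambert: (C, 2, T) uM -> stacked OD (W*C, T)."""
    E = extinction_matrix(wavelengths)
    hrf_conc = np.asarray(hrf_conc, dtype=float)
    sep = np.asarray(separations, dtype=float)[:, None]
    blocks = [
        sep * ppf * (E[w, 0] * hrf_conc[:, 0] + E[w, 1] * hrf_conc[:, 1])
        for w in range(len(wavelengths))
    ]
    return np.vstack(blocks)


def image_timecourse(
    hrf_conc: np.ndarray,
    times: np.ndarray,
    system: MultispectralSystem,
    config: ReconConfig = ReconConfig(),
    window: tuple[float, float] | None = None,
    step: float = 1.0,
    ppf: float = 1.0,
) -> tuple[np.ndarray, list[BrainImage]]:
    """Reconstruct one image per second of the channel HRF time courses.

    ``hrf_conc`` is (channels, 2 chromophores, time) in uM on the grid
    ``times`` (s). Returns the sampled times and their images; the mean
    time course of a vertex set is the element-wise average of the
    per-vertex traces of these images.
    """
    times = np.asarray(times, dtype=float)
    if window is None:
        window = (times[0], times[-1])
    t0, t1 = window
    if t1 < t0:
        raise ValueError("empty reconstruction window")
    sample_times = np.arange(t0, t1 + 1e-9, step)
    idx = np.searchsorted(times, sample_times - 1e-9)
    idx = np.clip(idx, 0, len(times) - 1)
    sep = system.sensitivity.channels["separation"].to_numpy()
    od = hrf_to_od(hrf_conc, sep, system.sensitivity.wavelengths, ppf=ppf)
    op = ImageReconstructor(system, config)
    images = [op.image(od[:, i]) for i in idx]
    return times[idx], images
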