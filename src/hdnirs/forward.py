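"""Analytic diffusion forward model and channel sensitivity matrices.

The channel-to-vertex sensitivity ("Jacobian", A) is built from the
semi-infinite-medium diffusion Green's function with an extrapolated
boundary, in the Rytov (adjoint) form

    A[ch, v]  =  G(r_s, r_v) * G(r_v, r_d) / G(r_s, r_d) * dV / D ,

so that ``delta_OD = A @ delta_mu_a`` for small absorption perturbations.
The head is collapsed to two sampled planes below the optode plane: a
shallow "scalp" surface and a deeper "brain" surface with congruent
lateral grids, which preserves the brain/scalp separability that the
two-surface image reconstruction exploits while staying deterministic and
desk-scale (a photon-transport Monte Carlo would model curved multi-layer
anatomy, which this comparison does not need).

Conventions: the optode plane is z = 0 and tissue occupies z < 0; depths
are given as positive mm below the plane.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import h5py
import numpy as np
import pandas as pd

from .probe import ProbeLayout

__all__ = [
    "OpticalProperties",
    "DEFAULT_OPTICAL_PROPERTIES",
    "HeadModel",
    "SensitivityMatrix",
    "green_semi_infinite",
    "build_sensitivity",
    "total_sensitivity_mask",
]


@dataclass(frozen=True)
class OpticalProperties:
    """Effective homogeneous absorption/reduced-scattering, 1/mm."""

    mu_a: float
    mu_s_prime: float

    def __post_init__(self):
        if self.mu_a <= 0 or self.mu_s_prime <= 0:
            raise ValueError("optical coefficients must be positive")

    @property
    def D(self) -> float:
        """Diffusion coefficient, mm."""
        return 1.0 / (3.0 * (self.mu_a + self.mu_s_prime))

    @property
    def mu_eff(self) -> float:
        """Effective attenuation coefficient, 1/mm."""
        return float(np.sqrt(self.mu_a / self.D))


#: typical adult-head effective coefficients at the two laser lines
DEFAULT_OPTICAL_PROPERTIES: dict[float, OpticalProperties] = {
    760.0: OpticalProperties(mu_a=0.018, mu_s_prime=1.1),
    850.0: OpticalProperties(mu_a=0.019, mu_s_prime=1.0),
}


def green_semi_infinite(r_src, r, mu_a: float, mu_s_prime: float) -> np.ndarray:
    """Diffusion Green's function for a pencil beam on a semi-infinite medium.

    The beam entering at ``r_src`` (on the z=0 plane) is replaced by an
    isotropic point source one transport mean free path deep, plus a
    negative image source mirrored about the extrapolated boundary at
    z = +z_b (index-matched, z_b = 2 D). Accepts ``r`` with shape (..., 3);
    returns fluence-like values of the same leading shape, strictly
    positive inside the medium.
    """
    props = OpticalProperties(mu_a, mu_s_prime)
    r_src = np.asarray(r_src, dtype=float)
    r = np.asarray(r, dtype=float)
    z0 = 1.0 / mu_s_prime
    zb = 2.0 * props.D
    true_src = r_src + np.array([0.0, 0.0, -z0])
    image_src = r_src + np.array([0.0, 0.0, z0 + 2.0 * zb])
    d1 = np.linalg.norm(r - true_src, axis=-1)
    d2 = np.linalg.norm(r - image_src, axis=-1)
    if np.any(d1 < 1e-9):
        raise ValueError("evaluation at source point")
    k = props.mu_eff
    phi = (np.exp(-k * d1) / d1 - np.exp(-k * d2) / d2) / (4.0 * np.pi * props.D)
    return phi


@dataclass
class HeadModel:
    """Two congruent lateral vertex grids at scalp and brain depth."""

    scalp_vertices: np.ndarray  # (N, 3), z < 0
    brain_vertices: np.ndarray  # (N, 3), z < scalp z
    optical_properties: dict[float, OpticalProperties] = field(
        default_factory=lambda: dict(DEFAULT_OPTICAL_PROPERTIES)
    )
    spacing: float = 5.0
    #: effective thickness (mm) of the tissue compartment each surface
    #: represents: the superficial scalp+skull compartment is much thicker
    #: than the cortical gray-matter sheet, which sets the relative column
    #: weight of the two surfaces in the sensitivity matrix
    scalp_thickness: float = 10.0
    brain_thickness: float = 4.0

    def __post_init__(self):
        self.scalp_vertices = np.atleast_2d(np.asarray(self.scalp_vertices, float))
        self.brain_vertices = np.atleast_2d(np.asarray(self.brain_vertices, float))
        if self.scalp_vertices.shape != self.brain_vertices.shape:
            raise ValueError("scalp and brain vertex grids must be congruent")
        d_scalp = -self.scalp_vertices[:, 2].mean()
        d_brain = -self.brain_vertices[:, 2].mean()
        if not (d_brain > d_scalp > 0):
            raise ValueError("need brain depth > scalp depth > 0 below z=0")

    @classmethod
    def for_layout(
        cls,
        *layouts: ProbeLayout,
        spacing: float = 5.0,
        scalp_depth: float = 3.0,
        brain_depth: float = 15.0,
        margin: float = 10.0,
        scalp_thickness: float = 10.0,
        brain_thickness: float = 4.0,
    ) -> "HeadModel":
        """Regular grid covering the union of the given layouts' footprints."""
        if not layouts:
            raise ValueError("need at least one layout")
        pts = np.vstack(
            [np.array([o.position for o in lay.optodes]) for lay in layouts]
        )
        lo = pts.min(axis=0)[:2] - margin
        hi = pts.max(axis=0)[:2] + margin
        xs = np.arange(lo[0], hi[0] + 0.5 * spacing, spacing)
        ys = np.arange(lo[1], hi[1] + 0.5 * spacing, spacing)
        gx, gy = np.meshgrid(xs, ys, indexing="ij")
        lateral = np.column_stack([gx.ravel(), gy.ravel()])
        scalp = np.column_stack([lateral, np.full(len(lateral), -scalp_depth)])
        brain = np.column_stack([lateral, np.full(len(lateral), -brain_depth)])
        return cls(scalp_vertices=scalp, brain_vertices=brain, spacing=spacing,
                   scalp_thickness=scalp_thickness, brain_thickness=brain_thickness)

    @property
    def n_per_surface(self) -> int:
        return len(self.scalp_vertices)

    @property
    def vertices(self) -> np.ndarray:
        """All vertices, brain surface first then scalp, shape (2N, 3)."""
        return np.vstack([self.brain_vertices, self.scalp_vertices])

    @property
    def surface(self) -> np.ndarray:
        n = self.n_per_surface
        return np.array(["brain"] * n + ["scalp"] * n)

    def vertex_table(self) -> pd.DataFrame:
        v = self.vertices
        return pd.DataFrame(
            {"x": v[:, 0], "y": v[:, 1], "z": v[:, 2], "surface": self.surface}
        )


@dataclass
class SensitivityMatrix:
    """Per-wavelength channel x vertex sensitivities (brain + scalp)."""

    values: np.ndarray  # (n_wavelengths, n_channels, n_vertices)
    wavelengths: tuple[float, ...]
    channels: pd.DataFrame  # source_id, detector_id, separation, class, is_short
    vertices: pd.DataFrame  # x, y, z, surface

    @property
    def n_channels(self) -> int:
        return self.values.shape[1]

    @property
    def n_vertices(self) -> int:
        return self.values.shape[2]

    @property
    def brain_mask(self) -> np.ndarray:
        return (self.vertices["surface"] == "brain").to_numpy()

    @property
    def scalp_mask(self) -> np.ndarray:
        return (self.vertices["surface"] == "scalp").to_numpy()

    def summed_map(self, normalize: bool = True) -> np.ndarray:
        """Total (channel- and wavelength-summed) sensitivity per vertex."""
        total = self.values.sum(axis=(0, 1))
        if normalize:
            m = total.max()
            if m <= 0:
                raise ValueError("degenerate sensitivity")
            total = total / m
        return total

    def brain_fraction(self, channel: int, wavelength_index: int = 0) -> float:
        row = self.values[wavelength_index, channel]
        tot = row.sum()
        return float(row[self.brain_mask].sum() / tot) if tot > 0 else 0.0

    # -- persistence -----------------------------------------------------
    def to_hdf5(self, path) -> None:
        with h5py.File(path, "w") as f:
            f.create_dataset("values", data=self.values)
            f.create_dataset("wavelengths", data=np.asarray(self.wavelengths))
            for name, df in (("channels", self.channels), ("vertices", self.vertices)):
                grp = f.create_group(name)
                for col in df.columns:
                    data = df[col].to_numpy()
                    if data.dtype == object or data.dtype.kind == "U":
                        data = data.astype("S")
                    grp.create_dataset(col, data=data)

    @classmethod
    def from_hdf5(cls, path) -> "SensitivityMatrix":
        with h5py.File(path, "r") as f:
            values = f["values"][()]
            wavelengths = tuple(float(w) for w in f["wavelengths"][()])
            frames = {}
            for name in ("channels", "vertices"):
                cols = {}
                for col, ds in f[name].items():
                    arr = ds[()]
                    if arr.dtype.kind == "S":
                        arr = arr.astype(str)
                    cols[col] = arr
                frames[name] = pd.DataFrame(cols)
        return cls(values, wavelengths, frames["channels"], frames["vertices"])


def build_sensitivity(layout: ProbeLayout, head: HeadModel) -> SensitivityMatrix:
    """Rytov sensitivity of every channel to every brain/scalp vertex.

    Reciprocity holds by construction (the kernel is symmetric in the
    source and detector positions), every entry is non-negative, and short
    channels carry a smaller brain-surface mass fraction than long ones.
    """
    if head.n_per_surface == 0:
        raise ValueError("empty head model")
    src_pos = layout.channel_source_positions()
    det_pos = layout.channel_detector_positions()
    if np.any(np.linalg.norm(src_pos - det_pos, axis=1) < 1e-9):
        raise ValueError("channel with coincident source and detector")
    verts = head.vertices
    # voxel volume per surface sample: lateral cell area times the
    # thickness of the tissue compartment the surface stands for
    n = head.n_per_surface
    thickness = np.concatenate(
        [np.full(n, head.brain_thickness), np.full(n, head.scalp_thickness)]
    )
    dV = head.spacing**2 * thickness
    values = np.empty((len(layout.wavelengths), len(src_pos), len(verts)))
    for wi, wl in enumerate(layout.wavelengths):
        props = head.optical_properties[wl]
        g_src = _green_rows(src_pos, verts, props)
        g_det = _green_rows(det_pos, verts, props)
        g_sd = np.array(
            [
                green_semi_infinite(s, d, props.mu_a, props.mu_s_prime)
                for s, d in zip(src_pos, det_pos)
            ]
        )
        values[wi] = g_src * g_det / g_sd[:, None] * (dV[None, :] / props.D)
    values = np.clip(values, 0.0, None)
    return SensitivityMatrix(
        values=values,
        wavelengths=tuple(layout.wavelengths),
        channels=layout.channel_table(),
        vertices=head.vertex_table(),
    )


def _green_rows(optode_pos: np.ndarray, verts: np.ndarray, props: OpticalProperties) -> np.ndarray:
    """Vectorised Green's function from each optode to every vertex."""
    z0 = 1.0 / props.mu_s_prime
    zb = 2.0 * props.D
    true_src = optode_pos + np.array([0.0, 0.0, -z0])
    image_src = optode_pos + np.array([0.0, 0.0, z0 + 2.0 * zb])
    d1 = np.linalg.norm(verts[None, :, :] - true_src[:, None, :], axis=-1)
    d2 = np.linalg.norm(verts[None, :, :] - image_src[:, None, :], axis=-1)
    k = props.mu_eff
    return (np.exp(-k * d1) / d1 - np.exp(-k * d2) / d2) / (4.0 * np.pi * props.D)


def total_sensitivity_mask(S: SensitivityMatrix, threshold: float = 0.01) -> np.ndarray:
    """Vertices whose normalized channel-summed sensitivity exceeds ``threshold``.

    Strict inequality: a vertex exactly at the threshold stays masked.
    """
    total = S.summed_map(normalize=True)
    return total > threshold
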