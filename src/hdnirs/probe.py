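"""Optode layouts and channel enumeration.

Two planar frontotemporal layouts are provided:

* a "sparse" grid modelled after the classic commercial 3x11 alternating
  source/detector arrangement (30 mm pitch, 17 sources / 16 detectors,
  52 long channels) with 8 additional short-separation detectors at 8 mm;
* a "hd" (high-density) hexagonal arrangement on a triangular lattice whose
  first/second/third nearest-neighbour source-detector separations are
  8 / 19 / 33 mm (25 sources, 58 long detectors plus 8 short-separation
  detectors).

Positions are millimetres in a head-surface plane with the origin at the
layout centroid; the analysis compares arrays, not anatomy, so no atlas
registration is attempted.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Optode",
    "Channel",
    "ProbeLayout",
    "enumerate_channels",
    "build_sparse_layout",
    "build_hd_layout",
    "SPARSE_BINS",
    "HD_BINS",
]

#: distance-class labels keyed by nominal separation in mm
DISTANCE_CLASS = {8.0: "SS8", 19.0: "NN19", 30.0: "NN30", 33.0: "NN33"}

#: enumeration bins (centre mm, tolerance mm) for each layout
SPARSE_BINS = [(8.0, 2.0), (30.0, 2.0)]
HD_BINS = [(8.0, 2.0), (19.0, 2.0), (33.0, 2.0)]

#: triangular-lattice pitch chosen so the second nearest neighbour is 33.0 mm
HD_PITCH = 33.0 / math.sqrt(3.0)

SPARSE_PITCH = 30.0
SS_SEPARATION = 8.0


@dataclass(frozen=True)
class Optode:
    """A single source or detector at a fixed plane position (mm)."""

    id: int
    role: str  # "source" | "detector"
    position: tuple[float, float, float]

    def __post_init__(self):
        if self.role not in ("source", "detector"):
            raise ValueError(f"unknown optode role {self.role!r}")

    @property
    def xyz(self) -> np.ndarray:
        return np.asarray(self.position, dtype=float)


@dataclass(frozen=True)
class Channel:
    """A source-detector pair with its separation and distance class."""

    source_id: int
    detector_id: int
    separation: float
    distance_class: str

    @property
    def is_short(self) -> bool:
        return self.distance_class == "SS8"


@dataclass
class ProbeLayout:
    """An optode array plus its enumerated measurement channels."""

    name: str
    optodes: list[Optode]
    channels: list[Channel] = field(default_factory=list)
    wavelengths: tuple[float, float] = (760.0, 850.0)

    def __post_init__(self):
        ids = [o.id for o in self.optodes]
        if len(ids) != len(set(ids)):
            raise ValueError("optode ids must be unique within a layout")
        self._by_id = {o.id: o for o in self.optodes}

    # -- lookups ---------------------------------------------------------
    def optode(self, optode_id: int) -> Optode:
        return self._by_id[optode_id]

    @property
    def sources(self) -> list[Optode]:
        return [o for o in self.optodes if o.role == "source"]

    @property
    def detectors(self) -> list[Optode]:
        return [o for o in self.optodes if o.role == "detector"]

    @property
    def n_channels(self) -> int:
        return len(self.channels)

    def positions(self, ids: Iterable[int]) -> np.ndarray:
        return np.array([self._by_id[i].position for i in ids], dtype=float)

    def channel_source_positions(self) -> np.ndarray:
        return self.positions(c.source_id for c in self.channels)

    def channel_detector_positions(self) -> np.ndarray:
        return self.positions(c.detector_id for c in self.channels)

    def channel_midpoints(self) -> np.ndarray:
        return 0.5 * (self.channel_source_positions() + self.channel_detector_positions())

    def channel_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "source_id": [c.source_id for c in self.channels],
                "detector_id": [c.detector_id for c in self.channels],
                "separation": [c.separation for c in self.channels],
                "distance_class": [c.distance_class for c in self.channels],
                "is_short": [c.is_short for c in self.channels],
            }
        )

    def class_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for c in self.channels:
            counts[c.distance_class] = counts.get(c.distance_class, 0) + 1
        return counts

    def bounding_box(self, include_short: bool = False) -> tuple[np.ndarray, np.ndarray]:
        """(min, max) corner of the optode positions, excluding SS detectors
        by default so the field of view of the long-channel array is compared."""
        short_dets = {c.detector_id for c in self.channels if c.is_short}
        pts = np.array(
            [
                o.position
                for o in self.optodes
                if include_short or o.id not in short_dets
            ]
        )
        return pts.min(axis=0), pts.max(axis=0)

    # -- serialization ---------------------------------------------------
    def to_json(self, path=None) -> str:
        payload = {
            "name": self.name,
            "wavelengths": list(self.wavelengths),
            "optodes": [
                {"id": o.id, "role": o.role, "x": o.position[0], "y": o.position[1], "z": o.position[2]}
                for o in self.optodes
            ],
            "channels": [
                {
                    "src": c.source_id,
                    "det": c.detector_id,
                    "class": c.distance_class,
                    "separation": c.separation,
                }
                for c in self.channels
            ],
        }
        text = json.dumps(payload, indent=1)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, source) -> "ProbeLayout":
        if isinstance(source, str) and source.lstrip().startswith("{"):
            payload = json.loads(source)
        else:
            with open(source) as fh:
                payload = json.load(fh)
        optodes = [
            Optode(o["id"], o["role"], (o["x"], o["y"], o["z"]))
            for o in payload["optodes"]
        ]
        channels = [
            Channel(c["src"], c["det"], c["separation"], c["class"])
            for c in payload["channels"]
        ]
        return cls(
            name=payload["name"],
            optodes=optodes,
            channels=channels,
            wavelengths=tuple(payload["wavelengths"]),
        )


def _classify(separation: float, bins: Sequence[tuple[float, float]]) -> str | None:
    for centre, tol in bins:
        if abs(separation - centre) <= tol:
            return DISTANCE_CLASS.get(centre, f"NN{int(round(centre))}")
    return None


def enumerate_channels(
    layout: ProbeLayout, bins: Sequence[tuple[float, float]]
) -> list[Channel]:
    """Enumerate every source-detector pair whose separation falls in a bin.

    Ordering is deterministic: ascending ``(source_id, detector_id)``.
    """
    if not bins:
        raise ValueError("no distance bins")
    sources = sorted(layout.sources, key=lambda o: o.id)
    detectors = sorted(layout.detectors, key=lambda o: o.id)
    if not sources or not detectors:
        raise ValueError("layout needs at least one source and one detector")
    channels = []
    for s in sources:
        for d in detectors:
            sep = float(np.linalg.norm(s.xyz - d.xyz))
            cls = _classify(sep, bins)
            if cls is not None:
                channels.append(Channel(s.id, d.id, sep, cls))
    return channels


def _centre(optodes: list[Optode]) -> list[Optode]:
    """Translate optodes so the centroid is at the origin."""
    pts = np.array([o.position for o in optodes])
    c = pts.mean(axis=0)
    return [
        Optode(o.id, o.role, tuple(np.asarray(o.position) - c)) for o in optodes
    ]


def build_sparse_layout() -> ProbeLayout:
    """Construct the 3x11 alternating source/detector grid at 30 mm pitch.

    Grid cells with even ``row + col`` carry sources (corners are sources),
    giving 17 sources and 16 detectors and exactly 52 channels at 30 mm.
    Eight short-separation detectors sit 8 mm outward of the sources in
    columns 2/4/6/8 of the top and bottom rows (mirror-symmetric about the
    midline; the carrying sources are a design choice).
    """
    a = SPARSE_PITCH
    optodes: list[Optode] = []
    next_id = 0
    grid_index: dict[tuple[int, int], int] = {}
    for row in range(3):
        for col in range(11):
            role = "source" if (row + col) % 2 == 0 else "detector"
            optodes.append(Optode(next_id, role, (col * a, row * a, 0.0)))
            grid_index[(row, col)] = next_id
            next_id += 1
    # short-separation detectors: rows 0 and 2 at columns 2,4,6,8, offset
    # 8 mm away from the middle row so no spurious 30 mm pair is created
    for row, dy in ((0, -SS_SEPARATION), (2, +SS_SEPARATION)):
        for col in (2, 4, 6, 8):
            src = optodes[grid_index[(row, col)]]
            assert src.role == "source"
            x, y, z = src.position
            optodes.append(Optode(next_id, "detector", (x, y + dy, z)))
            next_id += 1
    layout = ProbeLayout("sparse", _centre(optodes))
    layout.channels = enumerate_channels(layout, SPARSE_BINS)
    return layout


def build_hd_layout() -> ProbeLayout:
    """Construct the hexagonal high-density layout.

    Optodes occupy a 5-row triangular lattice with pitch 33/sqrt(3) mm so
    that first nearest neighbours are 19.05 mm and second nearest 33.0 mm
    apart. Sources sit at even columns of rows 0/4 and odd columns of
    row 2 (the centre site of row 4 is a detector), yielding 25 sources and
    58 detectors whose 19 mm / 33 mm channel counts land close to the
    reference hexagonal design. Eight short-separation detectors hang
    8 mm below the outer sources of the bottom row.
    """
    a = HD_PITCH
    dy = a * math.sqrt(3.0) / 2.0  # = 16.5 mm exactly
    optodes: list[Optode] = []
    next_id = 0
    site_index: dict[tuple[int, int], int] = {}

    def is_source(i: int, j: int) -> bool:
        if i in (0, 4):
            return j % 2 == 0 and not (i == 4 and j == 8)
        if i == 2:
            return j % 2 == 1
        return False

    for i in range(5):
        n_cols = 17 if i % 2 == 0 else 16
        x0 = 0.0 if i % 2 == 0 else 0.5 * a
        for j in range(n_cols):
            role = "source" if is_source(i, j) else "detector"
            optodes.append(Optode(next_id, role, (x0 + j * a, i * dy, 0.0)))
            site_index[(i, j)] = next_id
            next_id += 1
    # short-separation detectors under the bottom-row sources (skip centre)
    for j in (0, 2, 4, 6, 10, 12, 14, 16):
        src = optodes[site_index[(0, j)]]
        assert src.role == "source"
        x, y, z = src.position
        optodes.append(Optode(next_id, "detector", (x, y - SS_SEPARATION, z)))
        next_id += 1
    layout = ProbeLayout("hd", _centre(optodes))
    layout.channels = enumerate_channels(layout, HD_BINS)
    return layout
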