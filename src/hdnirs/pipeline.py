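"""End-to-end synthetic experiment: simulate both arrays, preprocess,
fit GLMs, reconstruct images and compare the arrays statistically.

For each synthetic subject the sparse and HD arrays record the *same*
cortical ground truth (different runs, hence different schedules and
noise draws), mirroring a within-subject array comparison. Per subject
and array the pipeline computes channel-space block deltas and
t-statistics, per-block image reconstructions, ROI extreme-t selections
in both channel and image space, and peak-localization error against the
injected activation; at the group level it forms paired array
comparisons and cluster-corrected channel maps.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .forward import HeadModel, SensitivityMatrix, build_sensitivity
from .glm import build_design, fit_glm
from .preprocess import preprocess_recording, reject_blocks_and_subjects
from .probe import ProbeLayout, build_hd_layout, build_sparse_layout
from .recon import (
    ImageReconstructor,
    MultispectralSystem,
    ReconConfig,
    hrf_to_od,
    stack_multispectral,
)
from .stats import (
    RoiDefinition,
    cluster_permutation,
    group_summary,
    paired_ttest,
    select_max_t,
    select_roi_vertices,
    tstat,
)
from .synth import (
    CONDITIONS,
    DEFAULT_FS,
    SynthNoise,
    generate_schedule,
    make_ground_truth,
    simulate_recording,
)

__all__ = ["ExperimentConfig", "ExperimentResult", "run_experiment", "lateral_roi_channels"]

SIDES = ("left", "right")
CHROMOPHORES = ("hbo", "hbr")


@dataclass
class ExperimentConfig:
    """All knobs of a simulated array-comparison study (defaults = study
    values; thresholds mirror the preprocessing contract)."""

    n_subjects: int = 17
    seed: int = 0
    layouts: tuple[str, ...] = ("sparse", "hd")
    # head model
    spacing: float = 5.0
    scalp_depth: float = 3.0
    brain_depth: float = 15.0
    # ground truth
    activation_centers: tuple = ((-90.0, 0.0), (90.0, 0.0))
    activation_radius: float = 12.0
    center_jitter: float = 12.0  # per-subject uniform shift, mm (anatomy varies)
    hbo_amplitude: dict = field(
        default_factory=lambda: {"congruent": 0.5, "incongruent": 1.0}
    )
    hbr_ratio: float = -0.25
    superficial_amp: float = 0.05
    # noise
    noise: SynthNoise = field(default_factory=SynthNoise)
    # preprocessing
    intensity_min: float = 0.001
    snr_min: float = 5.0
    spline_p: float = 0.99
    frame_s: float = 10.0
    lowpass_fc: float = 0.5
    ppf: float = 1.0
    min_blocks: int = 5
    block_range_threshold: float = 50.0  # uM, automated block rejection
    # reconstruction
    alpha_spatial: float = 0.001
    alpha_meas: float = 0.001
    recon_mode: str = "brain_scalp"
    # statistics
    alpha: float = 0.05
    cluster_radius: float = 33.0
    n_perm: int = 1000
    roi_x_band: tuple[float, float] = (55.0, 125.0)
    n_top_vertices: int = 25
    out_dir: str | None = None

    def recon_config(self) -> ReconConfig:
        return ReconConfig(self.alpha_spatial, self.alpha_meas, self.recon_mode)

    def to_dict(self) -> dict:
        d = asdict(self)
        return d

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        if "noise" in d and isinstance(d["noise"], dict):
            d["noise"] = SynthNoise(**d["noise"])
        for key in ("layouts", "activation_centers", "roi_x_band"):
            if key in d and isinstance(d[key], list):
                d[key] = tuple(tuple(v) if isinstance(v, list) else v for v in d[key])
        return cls(**d)


def lateral_roi_channels(
    layout: ProbeLayout, x_band: tuple[float, float] = (55.0, 125.0)
) -> dict[str, np.ndarray]:
    """Mirror-symmetric lateral channel sets (long channels only).

    A channel belongs to the left/right set when the magnitude of its
    midpoint x coordinate falls inside ``x_band`` — a dorsolateral analogue
    on the planar patch, excluding the medial strip and the far edges.
    """
    mids = layout.channel_midpoints()[:, 0]
    long_ch = ~np.array([c.is_short for c in layout.channels])
    lo, hi = x_band
    return {
        "left": np.flatnonzero(long_ch & (mids <= -lo) & (mids >= -hi)),
        "right": np.flatnonzero(long_ch & (mids >= lo) & (mids <= hi)),
    }


def build_roi(
    layouts: dict[str, ProbeLayout],
    S_hd: SensitivityMatrix,
    x_band: tuple[float, float],
    threshold: float = 0.01,
) -> RoiDefinition:
    side_channels = {
        name: lateral_roi_channels(lay, x_band) for name, lay in layouts.items()
    }
    vertex_ids = {
        side: select_roi_vertices(S_hd, side_channels["hd"][side], threshold)
        for side in SIDES
    }
    return RoiDefinition(side_channels=side_channels, vertex_ids=vertex_ids)


@dataclass
class ExperimentResult:
    config: ExperimentConfig
    config_hash: str
    roi: RoiDefinition
    channel_rows: pd.DataFrame  # per subject/layout/side/condition/chromophore
    image_rows: pd.DataFrame
    localization: pd.DataFrame
    paired: pd.DataFrame
    group_maps: dict
    retention: pd.DataFrame

    def save(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.config.to_yaml(out / "config.yaml")
        for name in ("channel_rows", "image_rows", "localization", "paired", "retention"):
            getattr(self, name).to_csv(out / f"{name}.csv", index=False)
        (out / "config_hash.txt").write_text(self.config_hash + "\n")


def _subject_analysis(
    subject: int,
    layout: ProbeLayout,
    system: MultispectralSystem,
    truth,
    config: ExperimentConfig,
    seeds: np.ndarray,
):
    """Full single-array chain for one subject; returns per-site tables."""
    fs = DEFAULT_FS[layout.name]
    schedule = generate_schedule(int(seeds[0]))
    rec = simulate_recording(
        layout, system.sensitivity, truth, schedule,
        noise=config.noise, seed=int(seeds[1]), fs=fs,
    )
    conc, report = preprocess_recording(
        rec,
        intensity_min=config.intensity_min,
        snr_min=config.snr_min,
        p=config.spline_p,
        frame_s=config.frame_s,
        fc=config.lowpass_fc,
        ppf=config.ppf,
    )
    keep = report.keep
    is_short = conc.channels["is_short"].to_numpy()
    ss_avail = np.flatnonzero(is_short & keep)

    # short-separation partner per long channel (vectorized correlation)
    C = conc.n_channels
    ss_sel = np.full(C, -1, dtype=int)
    if ss_avail.size:
        hbo = conc.data[:, 0, :]
        ss_traces = hbo[ss_avail]
        ss_sd = ss_traces.std(axis=1)
        ch_sd = hbo.std(axis=1)
        centred = hbo - hbo.mean(axis=1, keepdims=True)
        ss_centred = ss_traces - ss_traces.mean(axis=1, keepdims=True)
        cov = centred @ ss_centred.T / hbo.shape[1]
        with np.errstate(invalid="ignore", divide="ignore"):
            corr = cov / np.outer(ch_sd, ss_sd)
        corr[:, ss_sd <= 0] = -np.inf
        best = np.argmax(np.nan_to_num(corr, nan=-np.inf), axis=1)
        ss_sel[:] = ss_avail[best]
        ss_sel[is_short] = -1
        ss_sel[~keep] = -1
        ss_sel[np.flatnonzero(ch_sd <= 0)] = -1

    # --- block rejection before the GLM --------------------------------
    # blocks overlapping detected motion segments are excluded from both
    # HRF estimation and the delta statistics (residual artifacts in a
    # short-separation regressor would otherwise corrupt nearby blocks)
    onsets = schedule.block_onsets
    n_blocks = len(onsets)
    motion = conc.meta.get("motion_mask")
    include = np.ones(n_blocks, dtype=bool)
    step_times = None
    if motion is not None and motion.any():
        for b, onset in enumerate(onsets):
            a = max(0, int(np.ceil((onset - 2.0) * fs - 1e-9)))
            z = min(conc.n_samples, int(np.ceil((onset + 23.0) * fs - 1e-9)))
            include[b] = not motion[a:z].any()
        from .preprocess import _segments

        step_times = np.array(
            [0.5 * (a + b) / fs for a, b in _segments(motion)]
        )

    design = build_design(
        schedule, fs, conc.n_samples,
        include_blocks=include, step_times=step_times,
    )
    est = fit_glm(conc, design, ss_channels=ss_sel, keep=keep)
    cleaned = est.cleaned  # (C, 2, T), drift and SS removed

    # --- per-block deltas ----------------------------------------------
    deltas = np.zeros((C, 2, n_blocks))
    ranges = np.zeros(n_blocks)
    long_kept = np.flatnonzero(keep & ~is_short)
    for b, onset in enumerate(onsets):
        a = int(np.ceil((onset - 2.0) * fs - 1e-9))
        z = int(np.ceil((onset + 18.0) * fs - 1e-9))
        task = slice(int(np.ceil((onset + 7.0) * fs - 1e-9)), z)
        base = slice(a, int(np.ceil(onset * fs - 1e-9)))
        deltas[:, :, b] = cleaned[:, :, task].mean(axis=2) - cleaned[:, :, base].mean(axis=2)
        if long_kept.size:
            seg = cleaned[long_kept, :, a:z]
            ranges[b] = np.ptp(seg, axis=2).max()

    block_table = pd.DataFrame(
        {
            "subject": subject,
            "condition": schedule.block_condition,
            "block": np.arange(n_blocks),
            "range": np.where(include, ranges, np.inf),  # motion-rejected
        }
    )
    filtered, _ = reject_blocks_and_subjects(
        block_table, min_blocks=0, range_threshold=config.block_range_threshold
    )
    kept_blocks = {
        cond: filtered[filtered["condition"] == cond]["block"].to_numpy()
        for cond in CONDITIONS
    }

    # --- channel t-stats -----------------------------------------------
    site_rows = []
    for cond in CONDITIONS:
        bidx = kept_blocks[cond]
        for w, chrom in enumerate(CHROMOPHORES):
            for c in long_kept:
                res = tstat(deltas[c, w, bidx])
                site_rows.append(
                    {
                        "subject": subject,
                        "condition": cond,
                        "chromophore": chrom,
                        "id": int(c),
                        "t": res.t,
                        "delta": res.mean,
                        "n_blocks": res.n,
                    }
                )
    channel_stats = pd.DataFrame(site_rows)

    # --- per-block image reconstruction --------------------------------
    recon = ImageReconstructorSubset(system, config.recon_config(), keep)
    sep = conc.channels["separation"].to_numpy()
    V = system.n_vertices
    vert_deltas = {}
    for cond in CONDITIONS:
        bidx = kept_blocks[cond]
        hbo_img = np.zeros((len(bidx), V))
        hbr_img = np.zeros((len(bidx), V))
        for k, b in enumerate(bidx):
            y = hrf_to_od(deltas[:, :, b][:, :, None], sep,
                          system.sensitivity.wavelengths, ppf=config.ppf)[:, 0]
            x = recon(y)
            hbo_img[k] = x[:V]
            hbr_img[k] = x[V:]
        vert_deltas[cond] = {"hbo": hbo_img, "hbr": hbr_img}

    # --- localization error (mean incongruent HbO image) ----------------
    verts = system.sensitivity.vertices
    brain_mask = (verts["surface"] == "brain").to_numpy()
    loc_rows = []
    centers = truth.activation_centers
    for cond in CONDITIONS:
        img = vert_deltas[cond]["hbo"].mean(axis=0)
        img_b = np.where(brain_mask, img, -np.inf)
        peak = int(np.argmax(img_b))
        px, py = verts["x"].iloc[peak], verts["y"].iloc[peak]
        err = min(np.hypot(px - cx, py - cy) for cx, cy in centers)
        loc_rows.append({"subject": subject, "condition": cond, "peak_vertex": peak,
                         "loc_error_mm": float(err)})

    return {
        "schedule": schedule,
        "report": report,
        "channel_deltas": deltas,
        "kept_blocks": kept_blocks,
        "channel_stats": channel_stats,
        "vertex_deltas": vert_deltas,
        "localization": pd.DataFrame(loc_rows),
        "keep": keep,
    }


class ImageReconstructorSubset(ImageReconstructor):
    """Reconstructor restricted to the rows of retained channels."""

    def __init__(self, system: MultispectralSystem, config: ReconConfig, keep):
        keep = np.asarray(keep, bool)
        rows = np.concatenate([np.flatnonzero(keep) + w * len(keep)
                               for w in range(len(system.sensitivity.wavelengths))])
        self._rows = rows
        sub = MultispectralSystem(A=system.A[rows], sensitivity=system.sensitivity)
        super().__init__(sub, config)

    def __call__(self, y):
        return super().__call__(np.asarray(y)[..., self._rows])


def run_experiment(config: ExperimentConfig) -> ExperimentResult:
    """Simulate and analyse the full paired-array study."""
    layouts = {}
    for name in config.layouts:
        if name == "sparse":
            layouts[name] = build_sparse_layout()
        elif name == "hd":
            layouts[name] = build_hd_layout()
        else:
            raise ValueError(f"unknown layout {name!r}")
    head = HeadModel.for_layout(
        *layouts.values(),
        spacing=config.spacing,
        scalp_depth=config.scalp_depth,
        brain_depth=config.brain_depth,
    )
    systems = {
        name: stack_multispectral(build_sensitivity(lay, head))
        for name, lay in layouts.items()
    }
    roi = build_roi(layouts, systems["hd"].sensitivity, config.roi_x_band)

    master = np.random.default_rng(config.seed)
    subject_seeds = master.integers(0, 2**31 - 1, size=(config.n_subjects, 5))

    channel_rows, image_rows, loc_rows, retention_rows = [], [], [], []
    group_delta = {
        name: {cond: [] for cond in CONDITIONS} for name in layouts
    }

    jitter_rng = np.random.default_rng(int(master.integers(0, 2**31 - 1)))
    for s in range(config.n_subjects):
        centers = np.asarray(config.activation_centers, dtype=float)
        if config.center_jitter > 0:
            centers = centers + jitter_rng.uniform(
                -config.center_jitter, config.center_jitter, size=centers.shape
            )
        truth = make_ground_truth(
            head,
            seed=int(subject_seeds[s, 0]),
            centers=centers,
            radius=config.activation_radius,
            hbo_amplitude=dict(config.hbo_amplitude),
            hbr_ratio=config.hbr_ratio,
            superficial_amp=config.superficial_amp,
        )
        for li, (name, layout) in enumerate(layouts.items()):
            res = _subject_analysis(
                s, layout, systems[name], truth, config,
                subject_seeds[s, 1 + 2 * li : 3 + 2 * li],
            )
            retention_rows.append(
                {
                    "subject": s,
                    "layout": name,
                    "kept": res["report"].n_kept,
                    "pruned": res["report"].n_pruned,
                }
            )
            stats_df = res["channel_stats"]
            verts = systems[name].sensitivity.vertices
            for cond in CONDITIONS:
                # group channel map input: block-average HbO delta per channel
                row = np.full(layouts[name].n_channels, np.nan)
                sub = stats_df[(stats_df["condition"] == cond)
                               & (stats_df["chromophore"] == "hbo")]
                row[sub["id"].to_numpy()] = sub["delta"].to_numpy()
                group_delta[name][cond].append(row)
                for chrom in CHROMOPHORES:
                    w = CHROMOPHORES.index(chrom)
                    for side in SIDES:
                        chs = roi.channels(name, side)
                        cand = stats_df[
                            (stats_df["condition"] == cond)
                            & (stats_df["chromophore"] == chrom)
                            & (stats_df["id"].isin(chs))
                        ]
                        if cand.empty:
                            continue
                        sel = select_max_t(cand, chromophore=chrom)
                        channel_rows.append(
                            {
                                "subject": s, "layout": name, "condition": cond,
                                "chromophore": chrom, "side": side,
                                "id": int(sel["id"].iloc[0]),
                                "t": float(sel["t"].iloc[0]),
                                "delta": float(sel["delta"].iloc[0]),
                            }
                        )
                        # image space: per-vertex t over blocks in ROI vertices
                        vids = roi.vertex_ids[side]
                        mat = res["vertex_deltas"][cond][chrom][:, vids]
                        if mat.shape[0] < 2:
                            continue
                        mean = mat.mean(axis=0)
                        se = mat.std(axis=0, ddof=1) / np.sqrt(mat.shape[0])
                        with np.errstate(divide="ignore", invalid="ignore"):
                            tv = np.where(se > 0, mean / np.where(se > 0, se, 1), 0.0)
                        vert_df = pd.DataFrame(
                            {"subject": s, "id": vids, "t": tv, "delta": mean}
                        )
                        vsel = select_max_t(vert_df, chromophore=chrom,
                                            n_top=config.n_top_vertices)
                        image_rows.append(
                            {
                                "subject": s, "layout": name, "condition": cond,
                                "chromophore": chrom, "side": side,
                                "id": int(vsel["id"].iloc[0]),
                                "t": float(vsel["t"].iloc[0]),
                                "delta": float(vsel["delta"].iloc[0]),
                            }
                        )
            loc = res["localization"].copy()
            loc["layout"] = name
            loc_rows.append(loc)

    channel_df = pd.DataFrame(channel_rows)
    image_df = pd.DataFrame(image_rows)
    loc_df = pd.concat(loc_rows, ignore_index=True)
    retention_df = pd.DataFrame(retention_rows)

    # --- paired array comparisons --------------------------------------
    paired_rows = []
    if set(config.layouts) >= {"sparse", "hd"}:
        for space, df in (("channel", channel_df), ("image", image_df)):
            for cond in CONDITIONS:
                for chrom in CHROMOPHORES:
                    for side in SIDES:
                        sub = df[(df["condition"] == cond)
                                 & (df["chromophore"] == chrom)
                                 & (df["side"] == side)]
                        piv = sub.pivot_table(index="subject", columns="layout",
                                              values="delta")
                        if not {"hd", "sparse"} <= set(piv.columns):
                            continue
                        piv = piv.dropna()
                        if len(piv) < 2:
                            continue
                        res = paired_ttest(piv["hd"].to_numpy(),
                                           piv["sparse"].to_numpy())
                        sign = -1.0 if chrom == "hbr" else 1.0
                        frac = float(
                            np.mean(sign * piv["hd"] >= sign * piv["sparse"])
                        )
                        paired_rows.append(
                            {
                                "space": space, "condition": cond,
                                "chromophore": chrom, "side": side,
                                "n": res.n, "t": res.t, "p": res.p,
                                "mean_hd": float(piv["hd"].mean()),
                                "mean_sparse": float(piv["sparse"].mean()),
                                "frac_hd_ge_sparse": frac,
                            }
                        )
    paired_df = pd.DataFrame(paired_rows)

    # --- group channel maps with cluster correction ---------------------
    group_maps = {}
    for gi, (name, lay) in enumerate(layouts.items()):
        mids = lay.channel_midpoints()
        for ci, cond in enumerate(CONDITIONS):
            X = np.vstack(group_delta[name][cond])
            summary = group_summary(X)
            complete = np.flatnonzero(np.isfinite(X).all(axis=0))
            cluster = None
            if complete.size >= 2 and X.shape[0] >= 2:
                cluster = cluster_permutation(
                    mids[complete][:, :2],
                    X[:, complete],
                    radius=config.cluster_radius,
                    alpha=config.alpha,
                    n_perm=config.n_perm,
                    seed=int(subject_seeds[0, 4]) % (2**30) + 7 * gi + ci,
                )
            group_maps[(name, cond)] = {
                "summary": summary,
                "cluster": cluster,
                "complete_channels": complete,
            }

    result = ExperimentResult(
        config=config,
        config_hash=config.config_hash(),
        roi=roi,
        channel_rows=channel_df,
        image_rows=image_df,
        localization=loc_df,
        paired=paired_df,
        group_maps=group_maps,
        retention=retention_df,
    )
    if config.out_dir:
        result.save(config.out_dir)
    return result
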