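"""End-to-end orchestration: segment -> track -> filter -> measure ->
summarize -> heatmap, with reproducibility plumbing.

Every run writes its outputs together with a config snapshot and the seed,
and a rerun with an identical config reproduces byte-identical CSVs.
"""

from __future__ import annotations

import dataclasses
import logging
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from . import io as ndio
from .dynamics import sf_heatmap, summarize_tracks
from .movie import Movie
from .segmentation import (
    FeatureSpec,
    PixelClassifier,
    project_mask_2d,
    segment_movie,
    train_pixel_classifier,
)
from .shape import measure_shape
from .synth import GroundTruth, SynthMovieConfig, OPEN_REGIME, VESSEL_REGIME, render_movie
from .tracking import Detection, Track, filter_tracks, link_tracks

__all__ = [
    "PipelineConfig",
    "run_pipeline",
    "detections_from_labels",
    "tracks_to_dataframe",
    "scribble_annotations",
    "train_classifier_on_truth",
]

log = logging.getLogger("nucleodyn")

_REGIMES = {"open": OPEN_REGIME, "vessel": VESSEL_REGIME}


@dataclass(frozen=True)
class PipelineConfig:
    """Validated parameter set for a full pipeline run."""

    seed: int = 0
    # input: either a movie TIFF path (+ optional classifier) or a synthetic regime
    movie_path: str | None = None
    classifier_path: str | None = None
    regime: str = "vessel"
    n_nuclei: int = 3
    n_frames: int = 40
    frame_interval_s: float = 30.0
    pixel_size_um: float = 0.3
    # segmentation
    prob_threshold: float = 0.5
    min_volume_vox: int = 30
    # tracking & filtering
    max_disp_um: float = 10.0
    max_gap: int = 1
    min_timepoints: int = 4
    restrict_to_vessel: bool = True
    # measurement
    sf_threshold: float = 0.4
    sf_formula: str = "axis_diff"
    standard_window_min: float = 15.0
    heatmap_bin_px: int = 17

    def __post_init__(self) -> None:
        if self.movie_path is None and self.regime not in _REGIMES:
            raise ValueError(f"unknown regime {self.regime!r}")
        if not 0.0 < self.prob_threshold < 1.0:
            raise ValueError("prob_threshold must lie in (0, 1)")
        if not 0.0 < self.sf_threshold < 1.0:
            raise ValueError("sf_threshold must lie in (0, 1)")
        if self.min_timepoints < 1:
            raise ValueError("min_timepoints must be >= 1")
        if self.max_disp_um < 0:
            raise ValueError("max_disp_um must be non-negative")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @staticmethod
    def from_dict(d: dict) -> "PipelineConfig":
        return PipelineConfig(**d)


def detections_from_labels(labels_tzyx: np.ndarray) -> list[Detection]:
    """One Detection per (frame, label): centroid (x, y, z) px + 2D mask."""
    dets: list[Detection] = []
    for t in range(labels_tzyx.shape[0]):
        vol = labels_tzyx[t]
        for lab in np.unique(vol):
            if lab == 0:
                continue
            zz, yy, xx = np.nonzero(vol == lab)
            dets.append(
                Detection(
                    frame=t,
                    label=int(lab),
                    centroid_px=(float(xx.mean()), float(yy.mean()), float(zz.mean())),
                    mask2d=project_mask_2d(vol, int(lab)),
                )
            )
    return dets


def tracks_to_dataframe(
    tracks: list[Track],
    pixel_size_um: float,
    frame_interval_s: float,
    sf_formula: str = "axis_diff",
) -> pd.DataFrame:
    """Measure every detection's 2D shape and emit the tracks table."""
    rows = []
    for tr in tracks:
        for det, gap in zip(tr.detections, tr.gap_flags):
            m = measure_shape(det.mask2d, pixel_size_um, sf_formula=sf_formula)
            rows.append(
                dict(
                    track_id=tr.track_id,
                    frame=det.frame,
                    time_s=det.frame * frame_interval_s,
                    nucleus_label=det.label,
                    x_um=det.centroid_px[0] * pixel_size_um,
                    y_um=det.centroid_px[1] * pixel_size_um,
                    z_um=det.centroid_px[2] * pixel_size_um,
                    area_um2=m.area_um2,
                    sf=m.shape_factor,
                    circularity=m.circularity,
                    min_feret_um=m.min_feret_um,
                    max_feret_um=m.max_feret_um,
                    gap=int(gap),
                )
            )
    df = pd.DataFrame(rows, columns=ndio.TRACKS_COLUMNS)
    return df.sort_values(["track_id", "frame"]).reset_index(drop=True)


def scribble_annotations(
    movie: Movie,
    truth: GroundTruth,
    frame: int = 0,
    n_per_class: int = 200,
    seed: int = 0,
) -> np.ndarray:
    """Scribble mask (1 = foreground, 2 = background) from generation truth.

    Emulates interactive annotation on a synthetic movie: foreground pixels
    are sampled well inside each nucleus (within half the minor semi-axis),
    background pixels far from every nucleus.
    """
    vol = movie.frame(frame)
    nz, ny, nx = vol.shape
    sub = truth.table[truth.table["frame"] == frame]
    zz, yy, xx = np.mgrid[0:nz, 0:ny, 0:nx]
    fg = np.zeros(vol.shape, dtype=bool)
    safe_bg = np.ones(vol.shape, dtype=bool)
    for _, r in sub.iterrows():
        dist2 = (
            (xx - r.x_px) ** 2 + (yy - r.y_px) ** 2 + (zz - r.z_px) ** 2
        )
        fg |= dist2 <= (0.5 * r.semi_minor_px) ** 2
        safe_bg &= dist2 > (2.0 * r.semi_major_px) ** 2
    rng = np.random.default_rng(seed)
    ann = np.zeros(vol.shape, dtype=np.uint8)
    for sel, value in ((fg, 1), (safe_bg, 2)):
        idx = np.flatnonzero(sel)
        take = rng.choice(idx, size=min(n_per_class, idx.size), replace=False)
        ann.ravel()[take] = value
    return ann


def train_classifier_on_truth(
    movie: Movie,
    truth: GroundTruth,
    spec: FeatureSpec = FeatureSpec(),
    n_per_class: int = 200,
    seed: int = 0,
) -> PixelClassifier:
    ann = scribble_annotations(movie, truth, frame=0, n_per_class=n_per_class, seed=seed)
    return train_pixel_classifier([movie.frame(0)], [ann], spec=spec)


def run_pipeline(config: PipelineConfig, out_dir) -> dict:
    """Execute the full chain and write all outputs into ``out_dir``.

    Returns a dict of output paths plus in-memory results (tracks and
    summary DataFrames, heatmap grid, ground truth when synthetic).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_path = out / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    t0 = time.perf_counter()
    try:
        return _run(config, out)
    except Exception as exc:  # noqa: BLE001 - annotate the failing stage
        log.error("pipeline aborted: %s", exc)
        raise
    finally:
        log.info("total runtime %.1f s", time.perf_counter() - t0)
        log.removeHandler(handler)
        handler.close()


def _stage(name):
    log.info("stage: %s", name)


def _run(config: PipelineConfig, out: Path) -> dict:
    ndio.write_config(config.to_dict(), out / "config.yaml")
    truth = None
    if config.movie_path is not None:
        _stage("load movie")
        movie = ndio.read_movie(
            config.movie_path, config.pixel_size_um, config.frame_interval_s
        )
    else:
        _stage("simulate movie")
        synth_cfg = SynthMovieConfig(
            regime=_REGIMES[config.regime],
            n_nuclei=config.n_nuclei,
            n_frames=config.n_frames,
            frame_interval_s=config.frame_interval_s,
            pixel_size_um=config.pixel_size_um,
            seed=config.seed,
        )
        movie, truth = render_movie(synth_cfg)
        ndio.write_movie(movie, out / "movie.tif")
        ndio.write_ground_truth(truth, out / "ground_truth.csv")
        if truth.vessel_mask is not None:
            tifffile.imwrite(out / "vessel_mask.tif", truth.vessel_mask)

    _stage("train/load classifier")
    if config.classifier_path is not None:
        clf = PixelClassifier.load(config.classifier_path)
    elif truth is not None:
        clf = train_classifier_on_truth(movie, truth, seed=config.seed)
        clf.save(out / "classifier.json")
    else:
        raise ValueError("a classifier_path is required for an external movie")

    _stage("segment")
    labels = segment_movie(movie, clf, config.prob_threshold, config.min_volume_vox)
    ndio.write_labels(labels, out / "labels.tif")

    _stage("track")
    dets = detections_from_labels(labels)
    tracks = link_tracks(dets, config.max_disp_um, config.max_gap, movie.pixel_size_um)

    _stage("filter")
    region = truth.vessel_mask if (truth is not None and config.restrict_to_vessel) else None
    kept = filter_tracks(tracks, config.min_timepoints, region)

    _stage("measure")
    tracks_df = tracks_to_dataframe(
        kept, movie.pixel_size_um, movie.frame_interval_s, config.sf_formula
    )
    ndio.write_tracks_csv(tracks_df, out / "tracks.csv")

    _stage("summarize")
    summaries = summarize_tracks(
        tracks_df,
        movie.frame_interval_s,
        config.sf_threshold,
        config.standard_window_min,
    )
    summaries.to_csv(out / "summaries.csv", index=False)

    _stage("heatmap")
    ny, nx = movie.shape_yx
    grid = sf_heatmap(tracks_df, config.heatmap_bin_px, (ny, nx), movie.pixel_size_um)
    tifffile.imwrite(out / "heatmap.tif", grid.mean_sf.astype(np.float32))
    tifffile.imwrite(out / "heatmap_counts.tif", grid.counts.astype(np.int32))

    return dict(
        out_dir=out,
        movie=movie,
        truth=truth,
        labels=labels,
        tracks=kept,
        tracks_df=tracks_df,
        summaries=summaries,
        heatmap=grid,
        classifier=clf,
    )
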