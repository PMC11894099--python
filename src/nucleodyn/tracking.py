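"""Linking per-frame detections into nuclear tracks, plus track filters.

Linking is greedy nearest-neighbour with gap closing: for each frame,
candidate (track, detection) pairs within the allowed displacement (scaled
by the gap length) are matched in ascending order of distance, with ties
broken deterministically by (distance, lower track id, lower label id).
Unmatched detections open new tracks.  The output is invariant to the
input order of detections within a frame.

Tracks with fewer than a minimum number of timepoints, or whose centroids
lie mostly outside a supplied region mask (e.g. the vessel), are excluded
before analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["Detection", "Track", "link_tracks", "filter_tracks"]


@dataclass
class Detection:
    """One segmented nucleus in one frame; centroid in pixel coordinates."""

    frame: int
    label: int
    centroid_px: tuple[float, float, float]  # (x, y, z)
    mask2d: np.ndarray | None = field(default=None, repr=False)


@dataclass
class Track:
    track_id: int
    detections: list[Detection] = field(default_factory=list)
    gap_flags: list[bool] = field(default_factory=list)  # gap before detection i

    @property
    def frames(self) -> list[int]:
        return [d.frame for d in self.detections]

    @property
    def n_timepoints(self) -> int:
        return len(self.detections)

    @property
    def last(self) -> Detection:
        return self.detections[-1]


def link_tracks(
    detections: list[Detection],
    max_disp_um: float = 10.0,
    max_gap: int = 1,
    pixel_size_um: float = 0.3,
) -> list[Track]:
    """Link detections frame by frame into tracks.

    ``max_disp_um`` is the per-frame linking radius; across a gap of g
    missing frames the radius scales to ``(g + 1) * max_disp_um``.
    """
    if max_disp_um < 0:
        raise ValueError("max_disp_um must be non-negative")
    if max_gap < 0:
        raise ValueError("max_gap must be non-negative")
    if not detections:
        return []
    by_frame: dict[int, list[Detection]] = {}
    for d in detections:
        by_frame.setdefault(d.frame, []).append(d)
    frames = sorted(by_frame)

    tracks: list[Track] = []
    open_tracks: list[Track] = []
    for f in range(frames[0], frames[-1] + 1):
        dets = sorted(by_frame.get(f, []), key=lambda d: d.label)
        # candidate pairs: open tracks within reach of this frame
        pairs = []
        for tr in open_tracks:
            dt = f - tr.last.frame
            if dt < 1 or dt > max_gap + 1:
                continue
            limit = max_disp_um * dt
            lx, ly, lz = tr.last.centroid_px
            for det in dets:
                dx, dy, dz = (
                    det.centroid_px[0] - lx,
                    det.centroid_px[1] - ly,
                    det.centroid_px[2] - lz,
                )
                dist = float(np.sqrt(dx * dx + dy * dy + dz * dz)) * pixel_size_um
                if dist <= limit:
                    pairs.append((dist, tr.track_id, det.label, tr, det))
        pairs.sort(key=lambda p: (p[0], p[1], p[2]))
        used_tracks: set[int] = set()
        used_dets: set[int] = set()
        for dist, tid, lab, tr, det in pairs:
            if tid in used_tracks or id(det) in used_dets:
                continue
            gap = det.frame - tr.last.frame > 1
            tr.detections.append(det)
            tr.gap_flags.append(gap)
            used_tracks.add(tid)
            used_dets.add(id(det))
        for det in dets:
            if id(det) not in used_dets:
                tr = Track(track_id=len(tracks), detections=[det], gap_flags=[False])
                tracks.append(tr)
        # keep only tracks still eligible for extension
        open_tracks = [t for t in tracks if f - t.last.frame <= max_gap]
    return tracks


def filter_tracks(
    tracks: list[Track],
    min_timepoints: int = 4,
    region_mask: np.ndarray | None = None,
) -> list[Track]:
    """Apply the track-level exclusion rules.

    Tracks with fewer than ``min_timepoints`` detections are removed.  If a
    2D (y, x) region mask is given, a track is removed when the majority of
    its centroids fall outside the region (centroids rounded to the nearest
    pixel; out-of-bounds counts as outside).  Survivors are unmodified.
    """
    if min_timepoints < 1:
        raise ValueError("min_timepoints must be >= 1")
    out = []
    for tr in tracks:
        if tr.n_timepoints < min_timepoints:
            continue
        if region_mask is not None:
            mask = np.asarray(region_mask)
            ny, nx = mask.shape
            inside = 0
            for det in tr.detections:
                x = int(round(det.centroid_px[0]))
                y = int(round(det.centroid_px[1]))
                if 0 <= y < ny and 0 <= x < nx and mask[y, x] > 0:
                    inside += 1
            if inside * 2 < tr.n_timepoints:  # removed when majority outside
                continue
        out.append(tr)
    return out
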