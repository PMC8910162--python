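"""IoU linear-assignment tracking of filopodia detections.

Consecutive frames are linked by a one-to-one matching that maximizes the
total Intersection-over-Union of detection masks, with pairs below an IoU
floor forbidden (solved exactly by linear assignment on an augmented cost
matrix, so unmatched detections are allowed).  Chained matchings become
tracks; a track ends when its filopodium goes unmatched for more than
``max_gap`` consecutive frames (default 0: no gap closing).  Tracks alive
at the first or last movie frame carry censoring flags — their true birth
or death is unobserved, and lifetime statistics must exclude them.

The filopodium's pointed (−) extremity is the skeleton endpoint nearer
the parent cell body (Euclidean distance transform of the islet mask) and
the barbed (+) extremity the farther one; per-frame labels are stabilized
along the track by majority vote so single-frame flips cannot corrupt
end-speed estimates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Tuple

import numpy as np
from scipy import ndimage
from scipy.optimize import linear_sum_assignment

from .detection import FilopodiumDetection, IsletRecord

__all__ = [
    "FilopodiumTrack",
    "mask_iou",
    "link_frames",
    "build_tracks",
    "assign_extremities",
]

_FORBIDDEN = 1e6


@dataclass
class FilopodiumTrack:
    """A time-linked filopodium.

    ``steps`` lists (frame, detection index within that frame) in strictly
    increasing frame order.  ``minus_end``/``plus_end`` hold per-frame
    (row, col) endpoint positions once extremities are assigned.
    """

    id: int
    steps: List[Tuple[int, int]]
    censored_start: bool = False
    censored_end: bool = False
    minus_end: List[np.ndarray] = field(default_factory=list)
    plus_end: List[np.ndarray] = field(default_factory=list)
    ambiguous_polarity: bool = False

    @property
    def birth_frame(self) -> int:
        return self.steps[0][0]

    @property
    def death_frame(self) -> int:
        return self.steps[-1][0]

    @property
    def n_frames(self) -> int:
        return len(self.steps)


def _pixel_set(det: FilopodiumDetection) -> set:
    return {(int(r), int(c)) for r, c in det.pixels}


def mask_iou(mask_a: np.ndarray, mask_b: np.ndarray) -> float:
    """Intersection over Union of two same-shape boolean masks.

    Raises when both masks are empty (the overlap of nothing is
    undefined, not zero).
    """
    a = np.asarray(mask_a, dtype=bool)
    b = np.asarray(mask_b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError("masks must have the same shape")
    union = np.logical_or(a, b).sum()
    if union == 0:
        raise ValueError("IoU of two empty masks is undefined")
    return float(np.logical_and(a, b).sum() / union)


def _iou_from_sets(pa: set, pb: set) -> float:
    inter = len(pa & pb)
    if inter == 0:
        return 0.0
    return inter / len(pa | pb)


def _centroid(det: FilopodiumDetection) -> np.ndarray:
    return det.pixels.mean(axis=0)


def link_frames(
    dets_t: Sequence[FilopodiumDetection],
    dets_t1: Sequence[FilopodiumDetection],
    iou_min: float = 0.2,
) -> Tuple[List[Tuple[int, int]], List[int], List[int]]:
    """Optimal one-to-one matching between two frames' detections.

    Maximizes the summed IoU over matched pairs; pairs with IoU below
    ``iou_min`` are forbidden, and leaving a detection unmatched is always
    allowed.  Ties are broken toward smaller centroid displacement, then
    lower detection index (deterministic output).

    Returns ``(matches, deaths, births)``: index pairs (i in t, j in t+1),
    indices in t left unmatched (candidate deaths) and indices in t+1 left
    unmatched (births).
    """
    n, m = len(dets_t), len(dets_t1)
    if n == 0 or m == 0:
        return [], list(range(n)), list(range(m))
    sets_t = [_pixel_set(d) for d in dets_t]
    sets_t1 = [_pixel_set(d) for d in dets_t1]
    iou = np.zeros((n, m))
    for i in range(n):
        for j in range(m):
            iou[i, j] = _iou_from_sets(sets_t[i], sets_t1[j])
    # tie-breaking perturbations, far below the IoU quantization scale
    cent_t = np.array([_centroid(d) for d in dets_t])
    cent_t1 = np.array([_centroid(d) for d in dets_t1])
    disp = np.linalg.norm(cent_t[:, None, :] - cent_t1[None, :, :], axis=2)
    diag = disp.max() + 1.0
    jitter = 1e-9 * (disp / diag) + 1e-12 * np.arange(m)[None, :]
    cost = np.where(iou >= iou_min, -(iou - jitter), _FORBIDDEN)
    # augmented square matrix: diagonal "stay unmatched" slots at cost 0
    big = np.full((n + m, n + m), 0.0)
    big[:n, :m] = cost
    big[:n, m:] = _FORBIDDEN
    big[n:, :m] = _FORBIDDEN
    np.fill_diagonal(big[:n, m:], 0.0)
    np.fill_diagonal(big[n:, :m], 0.0)
    rows, cols = linear_sum_assignment(big)
    matches = [(int(i), int(j)) for i, j in zip(rows, cols)
               if i < n and j < m and iou[i, j] >= iou_min]
    matched_t = {i for i, _ in matches}
    matched_t1 = {j for _, j in matches}
    deaths = [i for i in range(n) if i not in matched_t]
    births = [j for j in range(m) if j not in matched_t1]
    return matches, deaths, births


def build_tracks(
    detections: Dict[int, Sequence[FilopodiumDetection]],
    iou_min: float = 0.2,
    max_gap: int = 0,
) -> List[FilopodiumTrack]:
    """Chain frame-to-frame matchings into tracks.

    ``detections`` maps frame index -> detections of that frame; frames
    must cover a contiguous range (frames with no detections may simply be
    absent).  With ``max_gap`` > 0 a track survives up to that many
    missing frames, reclaimed by IoU against its last seen mask.  Censor
    flags mark tracks alive at the movie boundaries.
    """
    if not detections:
        return []
    frames = sorted(detections)
    first, last = frames[0], frames[-1]
    tracks: List[FilopodiumTrack] = []
    # open[track_index] = (last frame seen, detection, gap run)
    open_tracks: Dict[int, Tuple[int, FilopodiumDetection]] = {}
    gap_run: Dict[int, int] = {}

    def new_track(frame: int, j: int) -> int:
        t = FilopodiumTrack(id=len(tracks), steps=[(frame, j)])
        tracks.append(t)
        return t.id

    for j, _ in enumerate(detections.get(first, [])):
        tid = new_track(first, j)
        open_tracks[tid] = (first, detections[first][j])
        gap_run[tid] = 0
    for frame in range(first + 1, last + 1):
        dets_now = list(detections.get(frame, []))
        open_ids = list(open_tracks)
        prev_dets = [open_tracks[t][1] for t in open_ids]
        matches, deaths, births = link_frames(prev_dets, dets_now, iou_min)
        matched_now = set()
        for i, j in matches:
            tid = open_ids[i]
            tracks[tid].steps.append((frame, j))
            open_tracks[tid] = (frame, dets_now[j])
            gap_run[tid] = 0
            matched_now.add(j)
        for i in deaths:
            tid = open_ids[i]
            gap_run[tid] += 1
            if gap_run[tid] > max_gap:
                del open_tracks[tid]
                del gap_run[tid]
        for j in births:
            tid = new_track(frame, j)
            open_tracks[tid] = (frame, dets_now[j])
            gap_run[tid] = 0
    for t in tracks:
        t.censored_start = t.birth_frame <= first
        t.censored_end = t.death_frame >= last
    return tracks


def assign_extremities(
    track: FilopodiumTrack,
    detections: Dict[int, Sequence[FilopodiumDetection]],
    islet_masks: Dict[int, np.ndarray] | np.ndarray,
    ambiguity_px: float = 0.5,
    dt_by_frame: Dict[int, np.ndarray] | None = None,
) -> FilopodiumTrack:
    """Label each frame's endpoints as (−) (body-proximal) / (+) (distal).

    ``islet_masks`` is either one static boolean body mask or a mapping
    frame -> mask.  Per frame the endpoint with the smaller distance to
    the body is (−); a majority vote along the track then fixes the
    polarity of frames whose two endpoints are nearly equidistant
    (within ``ambiguity_px``).  If more than half the frames are
    ambiguous the track is flagged ``ambiguous_polarity``.
    """

    def mask_for(frame: int, islet_label: int) -> np.ndarray:
        src = islet_masks[frame] if isinstance(islet_masks, dict) else islet_masks
        if isinstance(src, dict):
            # per-islet masks: distance is to the PARENT body only, so a
            # filopodium reaching toward a neighbouring islet cannot have
            # its polarity flipped by that neighbour
            return src.get(islet_label, next(iter(src.values())))
        return src

    dt_cache: Dict[tuple, np.ndarray] = {}

    def dt_for(frame: int, islet_label: int) -> np.ndarray:
        if dt_by_frame is not None and frame in dt_by_frame:
            src = dt_by_frame[frame]
            if isinstance(src, dict):
                return src.get(islet_label, next(iter(src.values())))
            return src
        key = (frame if isinstance(islet_masks, dict) else -1, islet_label)
        if key not in dt_cache:
            dt_cache[key] = ndimage.distance_transform_edt(
                ~mask_for(frame, islet_label).astype(bool))
        return dt_cache[key]

    votes = 0
    n_ambiguous = 0
    per_frame = []
    for frame, j in track.steps:
        det = detections[frame][j]
        p0 = det.base.astype(float)
        p1 = det.tip.astype(float)
        dt = dt_for(frame, det.islet)
        shape = dt.shape
        i0 = (int(np.clip(round(p0[0]), 0, shape[0] - 1)),
              int(np.clip(round(p0[1]), 0, shape[1] - 1)))
        i1 = (int(np.clip(round(p1[0]), 0, shape[0] - 1)),
              int(np.clip(round(p1[1]), 0, shape[1] - 1)))
        d0 = float(dt[i0])
        d1 = float(dt[i1])
        ambiguous = abs(d0 - d1) < ambiguity_px
        votes += 0 if ambiguous else (1 if d0 <= d1 else -1)
        per_frame.append((p0, p1, d0, d1, ambiguous))
        n_ambiguous += ambiguous
    majority_first_is_minus = votes >= 0
    track.minus_end = []
    track.plus_end = []
    for p0, p1, d0, d1, ambiguous in per_frame:
        if ambiguous:
            first_is_minus = majority_first_is_minus
        else:
            first_is_minus = d0 <= d1
        # stabilization: follow the majority when the per-frame call
        # disagrees only weakly with it
        if (d0 <= d1) != majority_first_is_minus and abs(d0 - d1) < 2.0 * ambiguity_px:
            first_is_minus = majority_first_is_minus
        if first_is_minus:
            track.minus_end.append(p0)
            track.plus_end.append(p1)
        else:
            track.minus_end.append(p1)
            track.plus_end.append(p0)
    track.ambiguous_polarity = n_ambiguous > 0.5 * len(per_frame)
    return track
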