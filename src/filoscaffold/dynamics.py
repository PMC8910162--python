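"""Dynamic quantities of tracked filopodia and treatment statistics.

Per movie this module turns tracks into the reference dynamic readouts:

* mean/median length over all detections (um);
* mean lifetime over uncensored tracks only — a track alive at the first
  or last frame has an unknown true lifetime and is discarded;
* per-extremity elongation and retraction speeds (nm/s), from endpoint
  displacements projected on the filopodium axis, with a noise floor
  (default 1 px) separating real steps from localization jitter;
* filopodia number normalized by the total cell-islet perimeter (um^-1);
* the fraction of filopodia elongating per frame.

Kinetic time courses are smoothed with a Savitzky-Golay filter (window 21
intervals = 7 min at 20 s frames, cubic), and pre/post-drug comparisons
use fixed-duration window means (10.3 min; the drug window starts 21.3 min
after addition, or 40 min for slow-acting compounds; control lifetime
windows end 5 min before addition) followed by a paired t-test gated by a
Shapiro-Wilk normality check on the paired differences.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, List, Sequence, Tuple

import numpy as np
from scipy.signal import savgol_filter
from scipy.stats import shapiro, ttest_rel

from .detection import FilopodiumDetection, IsletRecord
from .io import ImageMeta
from .tracking import FilopodiumTrack

__all__ = [
    "DynamicsSummary",
    "KineticCurve",
    "track_lifetimes",
    "end_speeds",
    "normalized_count",
    "fraction_elongating",
    "smooth_kinetic_curve",
    "interval_means",
    "paired_significance_test",
    "summarize_movie",
]


@dataclass
class DynamicsSummary:
    """Per-movie aggregate of filopodia dynamics."""

    movie: str
    mean_length_um: float
    median_length_um: float
    mean_lifetime_s: float
    elong_speed_plus_nms: float
    elong_speed_minus_nms: float
    retract_speed_plus_nms: float
    retract_speed_minus_nms: float
    normalized_number_per_um: float
    fraction_elongating: float
    n_filopodia: int
    n_frames: int
    births_per_min: float = float("nan")
    deaths_per_min: float = float("nan")


@dataclass
class KineticCurve:
    """A per-frame time series with its smoothed version."""

    time_s: np.ndarray
    raw: np.ndarray
    smoothed: np.ndarray
    quantity: str


def track_lifetimes(
    tracks: Sequence[FilopodiumTrack],
    frame_interval: float,
) -> np.ndarray:
    """Lifetimes (s) of fully observed tracks.

    ``(death - birth + 1) * frame_interval`` for tracks with both censor
    flags false; censored tracks never contribute.  All tracks censored
    returns an empty array with a warning.
    """
    out = [
        (t.death_frame - t.birth_frame + 1) * frame_interval
        for t in tracks
        if not (t.censored_start or t.censored_end)
    ]
    if not out and len(tracks):
        warnings.warn("all tracks touch the movie boundaries; no lifetimes",
                      stacklevel=2)
    return np.asarray(out, dtype=float)


def end_speeds(
    track: FilopodiumTrack,
    frame_interval: float,
    pixel_size: float,
    min_step_um: float | None = None,
) -> Dict[str, float]:
    """Per-extremity elongation/retraction speeds of one track (nm/s).

    For each consecutive frame pair, each endpoint's displacement is
    projected on the filopodium axis (minus -> plus direction); outward
    projections above the noise floor count as elongation, inward as
    retraction.  Speeds are the mean |displacement| / frame_interval per
    category.  Categories without any step are NaN.

    Single-frame tracks are undefined (raises ValueError).
    """
    if track.n_frames < 2:
        raise ValueError("end speeds of a single-frame track are undefined")
    if not track.minus_end:
        raise ValueError("track endpoints not assigned; run assign_extremities")
    if min_step_um is None:
        min_step_um = pixel_size
    pools: Dict[str, List[float]] = {
        "elong_plus": [], "retract_plus": [], "elong_minus": [], "retract_minus": []
    }
    # track-level axis: filopodia are straight, so the mean minus->plus
    # chord over all frames beats any single-frame chord, whose direction
    # is dominated by endpoint noise while the filopodium is short
    chords = np.asarray(track.plus_end) - np.asarray(track.minus_end)
    track_axis = chords.mean(axis=0)
    track_norm = np.linalg.norm(track_axis)
    for i in range(len(track.steps) - 1):
        f0, f1 = track.steps[i][0], track.steps[i + 1][0]
        dt = (f1 - f0) * frame_interval
        if track_norm > 0:
            axis = track_axis / track_norm
        else:
            axis = track.plus_end[i] - track.minus_end[i]
            norm = np.linalg.norm(axis)
            if norm == 0:
                continue
            axis = axis / norm
        if dt <= 0:
            continue
        d_plus = float(np.dot(track.plus_end[i + 1] - track.plus_end[i], axis)) * pixel_size
        d_minus = float(np.dot(track.minus_end[i + 1] - track.minus_end[i], axis)) * pixel_size
        if abs(d_plus) >= min_step_um:
            (pools["elong_plus"] if d_plus > 0 else pools["retract_plus"]).append(
                abs(d_plus) / dt)
        # the minus end grows outward when it moves against the axis
        if abs(d_minus) >= min_step_um:
            (pools["retract_minus"] if d_minus > 0 else pools["elong_minus"]).append(
                abs(d_minus) / dt)
    return {k: (float(np.mean(v)) * 1000.0 if v else float("nan"))
            for k, v in pools.items()}


def normalized_count(
    detections: Sequence[FilopodiumDetection],
    islets: Sequence[IsletRecord],
) -> float:
    """Filopodia per um of islet perimeter in one frame."""
    if not islets:
        raise ValueError("no islets in frame")
    perim = sum(i.perimeter_um for i in islets)
    if perim <= 0:
        raise ValueError("zero total islet perimeter")
    return len(detections) / perim


def fraction_elongating(
    tracks: Sequence[FilopodiumTrack],
    lengths: Dict[Tuple[int, int], float],
    min_step_um: float,
) -> float:
    """Fraction of live filopodia whose length grows frame-over-frame.

    ``lengths`` maps (frame, detection index) -> length in um.  Per frame
    pair the filopodium counts as elongating when its length increased by
    more than ``min_step_um``; the fractions are averaged over frames.
    """
    per_frame: Dict[int, List[bool]] = {}
    for t in tracks:
        for i in range(1, len(t.steps)):
            f0, j0 = t.steps[i - 1]
            f1, j1 = t.steps[i]
            grew = lengths[(f1, j1)] - lengths[(f0, j0)] > min_step_um
            per_frame.setdefault(f1, []).append(grew)
    if not per_frame:
        return float("nan")
    fracs = [np.mean(v) for v in per_frame.values()]
    return float(np.mean(fracs))


def smooth_kinetic_curve(
    time_s: np.ndarray,
    values: np.ndarray,
    window: int = 21,
    degree: int = 3,
    quantity: str = "",
) -> KineticCurve:
    """Savitzky-Golay smoothing of a kinetic curve.

    The window must be odd, larger than the polynomial degree and no
    longer than the series; endpoints are handled by polynomial fits on
    truncated windows (``mode='interp'``), so any polynomial up to the
    fitting degree is reproduced exactly.
    """
    time_s = np.asarray(time_s, dtype=float)
    values = np.asarray(values, dtype=float)
    if window % 2 == 0:
        raise ValueError("window must be odd")
    if window <= degree:
        raise ValueError("window must exceed the polynomial degree")
    if len(values) < window:
        raise ValueError("series shorter than the smoothing window")
    smoothed = savgol_filter(values, window_length=window, polyorder=degree,
                             mode="interp")
    return KineticCurve(time_s=time_s, raw=values, smoothed=smoothed,
                        quantity=quantity)


def interval_means(
    curve: KineticCurve,
    drug_time: float,
    slow_onset: bool = False,
    window_s: float = 10.3 * 60.0,
    onset_s: float = 21.3 * 60.0,
    slow_onset_s: float = 40.0 * 60.0,
    lifetime_margin_s: float = 5.0 * 60.0,
) -> Tuple[float, float]:
    """Pre/post-treatment means over fixed-duration windows.

    The control window spans ``window_s`` (10.3 min) ending at drug
    addition — except for lifetime curves, whose control window ends 5 min
    earlier because lifetimes near the interruption cannot be assessed.
    The treated window spans the same duration starting 21.3 min (40 min
    for slow-acting drugs) after addition.
    """
    t = curve.time_s
    onset = slow_onset_s if slow_onset else onset_s
    ctr_end = drug_time - (lifetime_margin_s if curve.quantity == "lifetime" else 0.0)
    # windows are right-open: the instant of drug addition belongs to
    # neither the control nor the treated interval
    ctr_sel = (t >= ctr_end - window_s) & (t < ctr_end)
    drug_sel = (t >= drug_time + onset) & (t < drug_time + onset + window_s)
    if not ctr_sel.any() or not drug_sel.any():
        raise ValueError("sampling window outside the curve span")
    vals = curve.smoothed
    return float(np.nanmean(vals[ctr_sel])), float(np.nanmean(vals[drug_sel]))


def paired_significance_test(
    ctr: Sequence[float], drug: Sequence[float]
) -> Tuple[float, float, float]:
    """Shapiro-Wilk-gated paired t-test.

    Returns ``(shapiro_p, t, p)``.  The Shapiro-Wilk test runs on the
    paired differences; a low ``shapiro_p`` flags non-normality but does
    not switch tests.  Zero-variance differences are degenerate.
    """
    ctr = np.asarray(ctr, dtype=float)
    drug = np.asarray(drug, dtype=float)
    if ctr.shape != drug.shape or ctr.ndim != 1 or len(ctr) < 3:
        raise ValueError("need equal-length paired samples with n >= 3")
    diff = drug - ctr
    if np.allclose(diff, diff[0]):
        raise ValueError("degenerate paired test: differences have zero variance")
    shapiro_p = float(shapiro(diff).pvalue)
    res = ttest_rel(drug, ctr)
    return shapiro_p, float(res.statistic), float(res.pvalue)


def summarize_movie(
    tracks: Sequence[FilopodiumTrack],
    detections: Dict[int, Sequence[FilopodiumDetection]],
    islets_by_frame: Dict[int, Sequence[IsletRecord]],
    meta: ImageMeta,
    movie: str = "",
    min_step_um: float | None = None,
    min_track_frames: int = 3,
) -> DynamicsSummary:
    """All per-movie dynamics in one record.

    Lengths and normalized numbers pool every detection; lifetimes use
    uncensored tracks only (NaN if there are none); speeds are per-track
    means averaged over tracks.  Track-based statistics ignore tracks
    shorter than ``min_track_frames`` (default 3): real filopodia persist
    for many frames, so one- or two-frame tracks are almost always
    transient detection noise.  Birth/death rates per minute (a
    convenience readout, not a standard one) count uncensored track starts
    and ends.
    """
    if min_step_um is None:
        min_step_um = meta.pixel_size
    tracks = [t for t in tracks if t.n_frames >= min_track_frames]
    frames = sorted(detections)
    n_frames = len(frames)
    all_lengths = [d.length_um for f in frames for d in detections[f]]
    lengths_map = {(f, j): d.length_um
                   for f in frames for j, d in enumerate(detections[f])}
    lifetimes = track_lifetimes(tracks, meta.frame_interval) if tracks else np.array([])
    speed_keys = ("elong_plus", "elong_minus", "retract_plus", "retract_minus")
    speed_pools: Dict[str, List[float]] = {k: [] for k in speed_keys}
    for t in tracks:
        if t.n_frames < 2 or not t.minus_end:
            continue
        sp = end_speeds(t, meta.frame_interval, meta.pixel_size, min_step_um)
        for k in speed_keys:
            if np.isfinite(sp[k]):
                speed_pools[k].append(sp[k])
    norm_counts = []
    for f in frames:
        isl = islets_by_frame.get(f, [])
        if isl:
            norm_counts.append(normalized_count(detections[f], isl))
    n_unc = sum(1 for t in tracks if not (t.censored_start or t.censored_end))
    duration_min = n_frames * meta.frame_interval / 60.0
    return DynamicsSummary(
        movie=movie,
        mean_length_um=float(np.mean(all_lengths)) if all_lengths else float("nan"),
        median_length_um=float(np.median(all_lengths)) if all_lengths else float("nan"),
        mean_lifetime_s=float(np.mean(lifetimes)) if len(lifetimes) else float("nan"),
        elong_speed_plus_nms=float(np.mean(speed_pools["elong_plus"]))
        if speed_pools["elong_plus"] else float("nan"),
        elong_speed_minus_nms=float(np.mean(speed_pools["elong_minus"]))
        if speed_pools["elong_minus"] else float("nan"),
        retract_speed_plus_nms=float(np.mean(speed_pools["retract_plus"]))
        if speed_pools["retract_plus"] else float("nan"),
        retract_speed_minus_nms=float(np.mean(speed_pools["retract_minus"]))
        if speed_pools["retract_minus"] else float("nan"),
        normalized_number_per_um=float(np.mean(norm_counts)) if norm_counts else float("nan"),
        fraction_elongating=fraction_elongating(tracks, lengths_map, min_step_um)
        if tracks else float("nan"),
        n_filopodia=len(tracks),
        n_frames=n_frames,
        births_per_min=n_unc / duration_min if duration_min > 0 else float("nan"),
        deaths_per_min=n_unc / duration_min if duration_min > 0 else float("nan"),
    )
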