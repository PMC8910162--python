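"""Per-frame cell-islet segmentation and filopodia detection.

Filopodia are thin (sub-um) actin protrusions emanating from the cell
islets in the bottom plane.  Detection follows a detection-map contract:
any callable turning a normalized frame into a per-pixel ridge/probability
map can serve as the detector; the map is thresholded, skeletonized,
pruned to simple paths and clipped to pixels outside the islet bodies.
The default detector is classical multiscale ridge enhancement
(Hessian-based tubeness, maximum over scales), which plays the role of a
learned detection model behind the same interface.

Each accepted detection carries its pixel mask (used as the tracking
affinity via IoU), the ordered skeleton path from base to tip, the two
endpoints, the geodesic length in um and the axial orientation against
the scaffold reference axis.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, List, Sequence, Tuple

import numpy as np
from scipy import ndimage
from skimage.filters import sato, threshold_otsu
from skimage.measure import label as cc_label, perimeter_crofton
from skimage.morphology import closing, dilation, disk, opening, skeletonize

from .io import ImageMeta
from .scaffold import fold_angle_deg

__all__ = [
    "IsletRecord",
    "FilopodiumDetection",
    "DetectionParams",
    "ridge_detection_map",
    "segment_islets",
    "detect_filopodia",
    "skeleton_length",
    "filopodium_orientation",
]


@dataclass
class IsletRecord:
    """One segmented cell islet in one frame."""

    frame: int
    label: int
    mask: np.ndarray
    perimeter_um: float
    area_um2: float


@dataclass
class FilopodiumDetection:
    """One detected filopodium in one frame.

    ``pixels`` is the (n, 2) array of (row, col) mask pixels; ``path`` the
    ordered (m, 2) skeleton from base to tip; endpoints are (row, col)
    floats.  ``length_um`` is the geodesic path length plus the sub-pixel
    extension of the mask beyond the skeleton at both ends.
    """

    frame: int
    id: int
    pixels: np.ndarray
    path: np.ndarray
    base: np.ndarray
    tip: np.ndarray
    length_um: float
    orientation_deg: float
    islet: int


@dataclass(frozen=True)
class DetectionParams:
    """Tunable thresholds of the classical detection chain.

    ``min_length``/``max_width`` are the acceptance filters (um);
    ``map_threshold`` applies to the normalized detection map;
    ``prune_px`` removes skeleton spurs shorter than this many pixels;
    ``ridge_sigmas_px`` are the tubeness scales.
    """

    min_length: float = 1.0
    max_width: float = 1.5
    map_threshold: float = 1.5
    prune_px: int = 3
    ridge_sigmas_px: Tuple[float, ...] = (1.0, 2.0, 3.0)
    psf_sigma_um: float = 0.45
    flatten_radius_um: float = 1.65
    islet_min_area_um2: float = 20.0
    islet_opening_um: float = 0.8
    exclusion_dilation_px: int = 2


def _normalize(img: np.ndarray) -> np.ndarray:
    """Noise-referenced normalization: (img - median) in robust-sigma units.

    Expressing the frame in units of its own background noise makes the
    ridge-map threshold a signal-to-noise criterion, independent of camera
    gain.
    """
    img = np.asarray(img, dtype=float)
    lo = np.median(img)
    noise = 1.4826 * np.median(np.abs(img - lo))
    # the default chain feeds Anscombe residuals, where shot noise has
    # unit sigma by construction; the floor keeps noise-free synthetic
    # images on the same scale instead of amplifying numerical residue
    noise = max(noise, 1.0)
    return np.clip((img - lo) / noise, 0, None)


def flatten_frame(img: np.ndarray, islets: List["IsletRecord"] | None = None,
                  psf_sigma_px: float = 1.4, median_radius_px: int = 5) -> np.ndarray:
    """Remove cell bodies and background, leaving noise-normalized ridges.

    The frame is variance-stabilized (Anscombe transform: Poisson shot
    noise gets unit variance at every intensity) and a local background is
    subtracted.  Two background estimates are combined pixelwise by
    maximum:

    * a running median over a disk window — exact over straight PSF-blurred
      body edges (the window median of a monotone ramp is its centre
      value) and blind to thin ridges, but too low just outside convex
      body corners where the halo is genuinely bright;
    * the islet masks blurred with the PSF and scaled to the body level —
      models corner halos correctly, but its pixel-accurate mask leaves
      dipole errors along straight edges.

    Each estimate covers the other's failure mode; filopodia sit above
    both, so they survive at full contrast.
    """
    img = np.asarray(img, dtype=float)
    ans = 2.0 * np.sqrt(np.clip(img, 0, None) + 0.375)
    bgnd = ndimage.median_filter(ans, footprint=disk(int(median_radius_px)))
    if islets is not None and (isinstance(islets, np.ndarray) or len(islets)):
        if isinstance(islets, np.ndarray):
            body = islets.astype(bool)
        else:
            body = np.zeros(img.shape, dtype=bool)
            for isl in islets:
                body |= isl.mask
        if body.any() and (~body).any():
            bg = float(np.median(img[~body]))
            level = float(np.median(img[body]))
            model = bg + (level - bg) * ndimage.gaussian_filter(
                body.astype(float), psf_sigma_px)
            bgnd = np.maximum(bgnd, 2.0 * np.sqrt(model + 0.375))
    return ans - bgnd


def ridge_detection_map(img: np.ndarray,
                        sigmas: Sequence[float] = (1.0, 2.0, 3.0)) -> np.ndarray:
    """Default detector: multiscale Hessian tubeness of the normalized frame.

    Bright thin lines score high (in the frame's noise units), uniform
    regions and blobs score low.  Any callable with this signature can
    replace it (e.g. a learned model's probability map).
    """
    norm = _normalize(img)
    return sato(norm, sigmas=sigmas, black_ridges=False, mode="reflect")


def segment_islets(
    frame_img: np.ndarray,
    meta: ImageMeta,
    params: DetectionParams = DetectionParams(),
    frame: int = 0,
) -> List[IsletRecord]:
    """Segment cell bodies: threshold, opening (removes thin protrusions),
    hole filling, small-object removal.

    Perimeter is the Crofton contour estimate in um.  A blank frame yields
    an empty list.
    """
    img = np.asarray(frame_img, dtype=float)
    if np.ptp(img) == 0:
        return []
    thr = threshold_otsu(img)
    fg = img > thr
    if not fg.any():
        return []
    r = max(1, int(round(params.islet_opening_um / meta.pixel_size)))
    body = opening(fg, disk(r))
    body = ndimage.binary_fill_holes(body)
    min_px = int(params.islet_min_area_um2 / meta.pixel_size**2)
    body = _remove_small(body, max(min_px, 1))
    labels = cc_label(body)
    out: List[IsletRecord] = []
    for lab in range(1, labels.max() + 1):
        mask = labels == lab
        perim = perimeter_crofton(mask, directions=4) * meta.pixel_size
        area = mask.sum() * meta.pixel_size**2
        out.append(IsletRecord(frame=frame, label=lab, mask=mask,
                               perimeter_um=perim, area_um2=area))
    return out


# ---------------------------------------------------------------------------
# skeleton helpers
# ---------------------------------------------------------------------------

_NEIGHBORS = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


def _remove_small(binary: np.ndarray, min_px: int) -> np.ndarray:
    labels, n = ndimage.label(binary, structure=np.ones((3, 3), dtype=int))
    if n == 0:
        return binary
    sizes = np.bincount(labels.ravel())
    keep = sizes >= min_px
    keep[0] = False
    return keep[labels]


def _neighbor_counts(skel: np.ndarray) -> np.ndarray:
    k = np.ones((3, 3), dtype=int)
    k[1, 1] = 0
    return ndimage.convolve(skel.astype(int), k, mode="constant")


def _prune_spurs(skel: np.ndarray, prune_px: int) -> np.ndarray:
    """Iteratively remove terminal branches shorter than ``prune_px``."""
    skel = skel.copy()
    for _ in range(8):
        nb = _neighbor_counts(skel)
        endpoints = np.argwhere(skel & (nb == 1))
        removed_any = False
        for ep in endpoints:
            path = [tuple(ep)]
            prev = None
            cur = tuple(ep)
            while len(path) <= prune_px:
                nxt = [
                    (cur[0] + dr, cur[1] + dc)
                    for dr, dc in _NEIGHBORS
                    if 0 <= cur[0] + dr < skel.shape[0]
                    and 0 <= cur[1] + dc < skel.shape[1]
                    and skel[cur[0] + dr, cur[1] + dc]
                    and (cur[0] + dr, cur[1] + dc) != prev
                ]
                if len(nxt) != 1:
                    break  # junction or isolated pixel
                prev, cur = cur, nxt[0]
                if _neighbor_counts(skel)[cur] >= 3:
                    # reached a junction: path so far is a spur
                    if len(path) < prune_px:
                        for p in path:
                            skel[p] = False
                        removed_any = True
                    break
                path.append(cur)
        if not removed_any:
            break
    return skel


def _order_path(pixels: np.ndarray) -> np.ndarray | None:
    """Order the pixels of a simple (branch-free) skeleton into a path."""
    pix = {tuple(p) for p in pixels}
    if len(pix) == 1:
        return np.array(list(pix))
    deg = {}
    for p in pix:
        deg[p] = sum((p[0] + dr, p[1] + dc) in pix for dr, dc in _NEIGHBORS)
    ends = [p for p, d in deg.items() if d == 1]
    if len(ends) != 2:
        return None  # loop or residual branch
    start = min(ends)
    path = [start]
    prev = None
    cur = start
    while True:
        nxt = [
            (cur[0] + dr, cur[1] + dc)
            for dr, dc in _NEIGHBORS
            if (cur[0] + dr, cur[1] + dc) in pix and (cur[0] + dr, cur[1] + dc) != prev
        ]
        # prefer 4-connected steps so diagonal shortcuts do not skip pixels
        nxt = [p for p in nxt if p not in path]
        if not nxt:
            break
        nxt.sort(key=lambda p: (abs(p[0] - cur[0]) + abs(p[1] - cur[1])))
        prev, cur = cur, nxt[0]
        path.append(cur)
    if len(path) != len(pix):
        return None
    return np.array(path)


def _end_direction(path: np.ndarray, end: int) -> np.ndarray:
    """Outward unit direction at a path end (0 = start, -1 = end)."""
    k = min(4, len(path) - 1)
    if end == 0:
        v = path[0] - path[k]
    else:
        v = path[-1] - path[-1 - k]
    n = np.linalg.norm(v.astype(float))
    return v.astype(float) / n if n else np.zeros(2)


def _rejoin_collinear(paths: List[np.ndarray], junctions: np.ndarray,
                      cos_max: float = -0.75) -> List[np.ndarray]:
    """Reconnect path ends across skeleton junctions when collinear.

    Splitting a skeleton at its junctions breaks crossing or merging
    filopodia into fragments whose free ends sit mid-filament.  Two
    fragments whose end directions at the same junction are anti-aligned
    (cosine below ``cos_max``) are continuations of one filament and get
    merged back, which resolves X crossings into two straight paths and
    V merges into a main filament plus a branch.
    """
    if not len(junctions) or len(paths) < 2:
        return paths
    jlabels = cc_label(junctions, connectivity=2)
    # candidate (path index, end, junction cluster, outward direction)
    cands = []
    for pi, p in enumerate(paths):
        for end in (0, -1):
            pt = p[end]
            r0, r1 = max(0, pt[0] - 2), min(junctions.shape[0], pt[0] + 3)
            c0, c1 = max(0, pt[1] - 2), min(junctions.shape[1], pt[1] + 3)
            local = jlabels[r0:r1, c0:c1]
            labs = np.unique(local[local > 0])
            for lab in labs:
                cands.append((pi, end, int(lab), _end_direction(p, end)))
    by_junction: dict = {}
    for pi, end, lab, u in cands:
        by_junction.setdefault(lab, []).append((pi, end, u))
    # greedy anti-parallel pairing per junction
    links = []  # ((pi, end), (pj, end2))
    used_ends = set()
    for lab, ends in by_junction.items():
        pairs = []
        for a in range(len(ends)):
            for b in range(a + 1, len(ends)):
                pi, ei, ui = ends[a]
                pj, ej, uj = ends[b]
                if pi == pj:
                    continue
                pairs.append((float(np.dot(ui, uj)), (pi, ei), (pj, ej)))
        for cos, ea, eb in sorted(pairs):
            if cos > cos_max:
                break
            if ea in used_ends or eb in used_ends:
                continue
            used_ends.add(ea)
            used_ends.add(eb)
            links.append((ea, eb))
    if not links:
        return paths
    # assemble chains through the links
    link_map: dict = {}
    for ea, eb in links:
        link_map[ea] = eb
        link_map[eb] = ea
    merged: List[np.ndarray] = []
    visited = set()
    for pi in range(len(paths)):
        if pi in visited:
            continue
        # walk to a free end of the chain containing pi
        start, senter = pi, 0
        seen = {pi}
        while (start, senter) in link_map:
            nxt, nend = link_map[(start, senter)]
            if nxt in seen:
                break  # cycle guard
            seen.add(nxt)
            start, senter = nxt, 0 if nend == -1 else -1
        chain = []
        cur, entry = start, senter
        seen = set()
        while True:
            seen.add(cur)
            p = paths[cur]
            chain.append(p if entry == 0 else p[::-1])
            visited.add(cur)
            exit_end = -1 if entry == 0 else 0
            key = (cur, exit_end)
            if key not in link_map:
                break
            nxt, nend = link_map[key]
            if nxt in seen:
                break
            cur, entry = nxt, nend
        merged.append(np.concatenate(chain, axis=0))
    return merged


def _split_at_bends(path: np.ndarray, window: int = 3,
                    max_turn_deg: float = 55.0) -> List[np.ndarray]:
    """Split a path where its direction turns sharply.

    Filopodia are straight filaments; a sharp bend in an extracted path
    marks two distinct filaments fused at the mask level (typical where
    several filopodia radiate from a small, highly curved stretch of the
    body).  Directions are measured over a few-pixel window so the
    0/45-degree quantization of single pixel steps does not trigger
    splits.
    """
    if len(path) < 2 * window + 2:
        return [path]
    dirs = path[window:] - path[:-window]
    dirs = dirs / np.maximum(np.linalg.norm(dirs, axis=1, keepdims=True), 1e-9)
    cos_lim = np.cos(np.deg2rad(max_turn_deg))
    cuts = []
    i = window
    while i < len(dirs):
        if float(np.dot(dirs[i - window], dirs[i])) < cos_lim:
            cuts.append(i)
            i += window + 1
        else:
            i += 1
    if not cuts:
        return [path]
    pieces = []
    prev = 0
    for c in cuts:
        pieces.append(path[prev:c + 1])
        prev = c + 1
    pieces.append(path[prev:])
    return [p for p in pieces if len(p) >= 2]


def _refine_tip(corrected: np.ndarray, path: np.ndarray) -> Tuple[np.ndarray, float]:
    """Sub-pixel tip from the half-maximum crossing along the ridge axis.

    The rendered/imaged ridge ends in an error-function falloff whose
    half-amplitude point is the true tip; locating it on the flattened
    frame (bilinear samples along the terminal path direction) removes
    most of the +-1 px skeleton-endpoint jitter that would otherwise
    dominate end-speed estimates.

    Returns the refined (row, col) tip and its signed offset (px) from
    the skeleton endpoint along the outward direction.
    """
    tip = path[-1].astype(float)
    ref = path[max(0, len(path) - 6)].astype(float)
    u = tip - ref
    n = np.linalg.norm(u)
    if n == 0:
        return tip, 0.0
    u = u / n
    perp = np.array([-u[1], u[0]])
    ts = np.arange(-3.0, 3.01, 0.25)
    # average over three parallel rays: the ridge is wider than the
    # sampling noise correlation length, so this cuts jitter ~sqrt(3)
    vals = np.zeros_like(ts)
    for off in (-0.8, 0.0, 0.8):
        pts = tip[None, :] + ts[:, None] * u[None, :] + off * perp[None, :]
        vals += ndimage.map_coordinates(corrected, pts.T, order=1, mode="nearest")
    vals /= 3.0
    level = float(np.median(vals[ts <= -1.0]))
    if level <= 0:
        return tip, 0.0
    half = 0.5 * level
    above = vals >= half
    if not above[0]:
        return tip, 0.0
    idx = np.argmin(above) if not above.all() else len(ts) - 1
    if idx == 0:
        return tip, 0.0
    if above.all():
        t_star = ts[-1]
    else:
        v0, v1 = vals[idx - 1], vals[idx]
        frac = (v0 - half) / (v0 - v1) if v0 != v1 else 0.0
        t_star = ts[idx - 1] + frac * (ts[idx] - ts[idx - 1])
    t_star = float(np.clip(t_star, -1.5, 2.5))
    return tip + t_star * u, t_star


def skeleton_length(path: np.ndarray, pixel_size: float) -> float:
    """Geodesic length (um) of an ordered pixel path: steps of 1 or sqrt(2)."""
    path = np.asarray(path, dtype=float)
    if len(path) < 2:
        return 0.0
    steps = np.diff(path, axis=0)
    return float(np.hypot(steps[:, 0], steps[:, 1]).sum() * pixel_size)


def filopodium_orientation(base: Sequence[float], tip: Sequence[float],
                           reference_axis: Sequence[float]) -> float:
    """Axial angle (deg, [0, 90]) of the base->tip vector vs the axis.

    Points are (row, col); the reference axis is an (x, y) unit vector in
    image coordinates (x = col, y = row).
    """
    base = np.asarray(base, dtype=float)
    tip = np.asarray(tip, dtype=float)
    d = tip - base
    if np.allclose(d, 0):
        raise ValueError("zero-length base->tip vector")
    v = np.array([d[1], d[0]])  # (x, y)
    axis = np.asarray(reference_axis, dtype=float)
    theta = np.degrees(np.arctan2(v[1], v[0]) - np.arctan2(axis[1], axis[0]))
    return fold_angle_deg(theta)


def detect_filopodia(
    frame_img: np.ndarray,
    islets: List[IsletRecord],
    meta: ImageMeta,
    detector: Callable[[np.ndarray], np.ndarray] | None = None,
    params: DetectionParams = DetectionParams(),
    reference_axis: Sequence[float] = (1.0, 0.0),
    frame: int = 0,
    exclusion_mask: np.ndarray | None = None,
) -> List[FilopodiumDetection]:
    """Detect filopodia in one frame, outside the islet bodies.

    The detection map (default: :func:`ridge_detection_map`) is
    thresholded, clipped to pixels outside the (slightly dilated) islet
    bodies and any static exclusion mask, skeletonized, spur-pruned and
    split at junctions into simple paths.  Paths shorter than
    ``min_length`` or wider than ``max_width`` are rejected; each survivor
    is assigned to the nearest islet, with the base at the islet-proximal
    endpoint.

    Without islets the result is empty: a filopodium needs a parent body.
    """
    if not islets:
        return []
    # the exclusion / body model uses the raw thresholded foreground: the
    # opening applied for islet measurement shaves convex corners, whose
    # halo would otherwise leak into the detection map
    img_f = np.asarray(frame_img, dtype=float)
    body = np.zeros(img_f.shape, dtype=bool)
    for isl in islets:
        body |= isl.mask
    if np.ptp(img_f) > 0:
        fg = ndimage.binary_fill_holes(img_f > threshold_otsu(img_f))
        if fg.any() and not fg.all():
            body |= fg
    r_med = max(3, int(round(params.flatten_radius_um / meta.pixel_size)))
    corrected = flatten_frame(frame_img, body,
                              params.psf_sigma_um / meta.pixel_size, r_med)
    det = detector or (lambda im: ridge_detection_map(im, params.ridge_sigmas_px))
    dmap = np.asarray(det(corrected), dtype=float)
    body_dil = dilation(body, disk(params.exclusion_dilation_px))
    dmap = dmap.copy()
    dmap[body_dil] = 0
    if exclusion_mask is not None:
        dmap[exclusion_mask] = 0
    # tubeness catches the ridge body; the intensity criterion on the
    # flattened frame (noise units) recovers the faint last pixels at the
    # ridge ends that the Hessian response erodes.  Hysteresis: extended
    # pixels count only in components seeded by a tubeness detection.
    core = dmap > params.map_threshold
    binary = core | (_normalize(corrected) > 2.0 * params.map_threshold)
    labs, nlab = ndimage.label(binary, structure=np.ones((3, 3), dtype=int))
    if nlab:
        seeded = np.zeros(nlab + 1, dtype=bool)
        seeded[np.unique(labs[core])] = True
        seeded[0] = False
        binary = seeded[labs]
    binary = closing(binary, disk(1))
    binary &= ~body_dil
    min_px = max(2, int(round(0.5 * params.min_length / meta.pixel_size)))
    binary = _remove_small(binary, min_px)
    if not binary.any():
        return []
    skel = skeletonize(binary)
    skel = _prune_spurs(skel, params.prune_px)
    # split at junctions into simple paths, then rejoin collinear
    # fragments so crossing/merging filopodia keep their true tips
    def paths_from(mask: np.ndarray) -> List[np.ndarray]:
        skel_m = _prune_spurs(skeletonize(mask), params.prune_px)
        nbm = _neighbor_counts(skel_m)
        junc = skel_m & (nbm >= 3)
        seg = cc_label(skel_m & ~junc, connectivity=2)
        out = []
        for lab in range(1, seg.max() + 1):
            p = _order_path(np.argwhere(seg == lab))
            if p is not None and len(p) >= 2:
                out.append(p)
        out = _rejoin_collinear(out, junc)
        return [piece for p in out for piece in _split_at_bends(p)]

    dist_islet = [ndimage.distance_transform_edt(~isl.mask) for isl in islets]
    comp_labels = cc_label(binary, connectivity=2)
    dt_binary = ndimage.distance_transform_edt(binary)
    queue = [(p, dt_binary, binary, True) for p in paths_from(binary)]
    detections: List[FilopodiumDetection] = []
    many = len(queue) > 1
    for item in queue:
        path, dt_mask, src_mask, allow_split = item
        d_end0 = [d[tuple(path[0])] for d in dist_islet]
        d_end1 = [d[tuple(path[-1])] for d in dist_islet]
        if min(d_end0) <= min(d_end1):
            islet_idx = int(np.argmin(d_end0))
            base_gap = min(d_end0)
        else:
            path = path[::-1]
            islet_idx = int(np.argmin(d_end1))
            base_gap = min(d_end1)
        base = path[0].astype(float)
        tip, tip_ext = _refine_tip(corrected, path)
        # a diffraction-rounded tip cap appears to extend ~0.75 PSF sigma
        # beyond the true filament end; pull the half-max tip back by it
        cap_px = 0.75 * params.psf_sigma_um / meta.pixel_size
        u_tip = _end_direction(path, -1)
        tip = tip - cap_px * u_tip
        tip_ext -= cap_px
        # length runs from the cell-body edge (the exclusion band hides the
        # first pixels, so bridge the base gap) to the sub-pixel tip
        length = (skeleton_length(path, meta.pixel_size)
                  + max(base_gap - 0.5, 0.0) * meta.pixel_size
                  + tip_ext * meta.pixel_size)
        if length < params.min_length:
            continue
        # intrinsic width: apparent mask width minus the PSF broadening
        width = max(2.0 * float(dt_mask[tuple(path.T)].mean()) * meta.pixel_size
                    - 2.0 * params.psf_sigma_um, 0.0)
        if width > params.max_width:
            if allow_split:
                # an over-wide blob is usually two unresolved parallel
                # filopodia: re-threshold the component locally to split
                # the crests, then process the sub-paths
                comp_id = cc_label(src_mask, connectivity=2)[
                    tuple(path[len(path) // 2])]
                comp = cc_label(src_mask, connectivity=2) == comp_id
                sub = comp & (_normalize(corrected) > 4.0 * params.map_threshold)
                sub = _remove_small(sub, 3)
                if cc_label(sub, connectivity=2).max() >= 2:
                    dt_sub = ndimage.distance_transform_edt(sub)
                    for p2 in paths_from(sub):
                        queue.append((p2, dt_sub, sub, False))
            continue
        comp_id = comp_labels[tuple(path[len(path) // 2])]
        comp_pix = np.argwhere(comp_labels == comp_id)
        if many:
            # assign component pixels to the nearest path when split
            from scipy.spatial import cKDTree

            tree = cKDTree(path)
            d, _ = tree.query(comp_pix)
            comp_pix = comp_pix[d <= max(2.0, width / meta.pixel_size)]
        detections.append(FilopodiumDetection(
            frame=frame, id=len(detections), pixels=comp_pix, path=path,
            base=base, tip=tip, length_um=length,
            orientation_deg=filopodium_orientation(base, tip, reference_axis),
            islet=islets[islet_idx].label,
        ))
    return detections
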