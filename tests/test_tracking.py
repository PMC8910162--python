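"""IoU linear-assignment linking, track building and extremity labels."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from filoscaffold.detection import FilopodiumDetection
from filoscaffold.tracking import (assign_extremities, build_tracks,
                                   link_frames, mask_iou)

from _oracles import brute_force_max_matching


def make_det(pixels, frame=0, det_id=0, islet=1):
    """Minimal detection carrying only what linking needs."""
    px = np.asarray(sorted(set(map(tuple, pixels))), dtype=int)
    order = np.lexsort((px[:, 1], px[:, 0]))
    px = px[order]
    return FilopodiumDetection(
        frame=frame, id=det_id, pixels=px, path=px,
        base=px[0].astype(float), tip=px[-1].astype(float),
        length_um=len(px) * 0.33, orientation_deg=0.0, islet=islet)


def rect(r0, c0, h, w):
    return [(r, c) for r in range(r0, r0 + h) for c in range(c0, c0 + w)]


class TestMaskIoU:
    def test_identical_is_one(self):
        m = np.zeros((10, 10), bool)
        m[2:5, 3:7] = True
        assert mask_iou(m, m) == 1.0

    def test_disjoint_is_zero(self):
        a = np.zeros((10, 10), bool)
        b = np.zeros((10, 10), bool)
        a[0, 0] = True
        b[5, 5] = True
        assert mask_iou(a, b) == 0.0

    def test_rectangles_overlap(self):
        """2x4 rectangles overlapping on 2x2: IoU = 4/12 by pixel counting."""
        a = np.zeros((10, 10), bool)
        b = np.zeros((10, 10), bool)
        a[0:2, 0:4] = True
        b[0:2, 2:6] = True
        assert mask_iou(a, b) == pytest.approx(4 / 12)

    def test_both_empty_rejected(self):
        with pytest.raises(ValueError):
            mask_iou(np.zeros((4, 4), bool), np.zeros((4, 4), bool))

    @given(st.integers(0, 2**16 - 1), st.integers(0, 2**16 - 1))
    @settings(max_examples=100, deadline=None)
    def test_symmetric_and_bounded(self, bits_a, bits_b):
        a = np.array([(bits_a >> i) & 1 for i in range(16)], bool).reshape(4, 4)
        b = np.array([(bits_b >> i) & 1 for i in range(16)], bool).reshape(4, 4)
        if not (a.any() or b.any()):
            return
        v = mask_iou(a, b)
        assert v == mask_iou(b, a)
        assert 0.0 <= v <= 1.0
        assert (v == 1.0) == bool(np.array_equal(a, b))


class TestLinkFrames:
    def test_static_identity_matching(self):
        dets = [make_det(rect(0, 0, 2, 5), det_id=0),
                make_det(rect(10, 0, 2, 5), det_id=1),
                make_det(rect(20, 0, 2, 5), det_id=2)]
        matches, deaths, births = link_frames(dets, dets)
        assert sorted(matches) == [(0, 0), (1, 1), (2, 2)]
        assert deaths == [] and births == []

    def test_all_disappear(self):
        dets = [make_det(rect(0, 0, 2, 3)), make_det(rect(9, 0, 2, 3), det_id=1)]
        matches, deaths, births = link_frames(dets, [])
        assert matches == [] and deaths == [0, 1] and births == []

    def test_matches_brute_force_optimum(self):
        """1000 random instances up to 6x6: total IoU equals the
        exhaustive-search maximum over all partial matchings, exactly."""
        rng = np.random.default_rng(2415)
        for _ in range(1000):
            n, m = rng.integers(1, 7, size=2)
            dets_t, dets_t1 = [], []
            for i in range(n):
                r, c = rng.integers(0, 24, size=2)
                dets_t.append(make_det(rect(r, c, 2, int(rng.integers(2, 6))),
                                       det_id=i))
            for j in range(m):
                r, c = rng.integers(0, 24, size=2)
                dets_t1.append(make_det(rect(r, c, 2, int(rng.integers(2, 6))),
                                        det_id=j))
            iou = np.zeros((n, m))
            for i, a in enumerate(dets_t):
                pa = set(map(tuple, a.pixels))
                for j, b in enumerate(dets_t1):
                    pb = set(map(tuple, b.pixels))
                    u = len(pa | pb)
                    iou[i, j] = len(pa & pb) / u if u else 0.0
            matches, _, _ = link_frames(dets_t, dets_t1, iou_min=0.2)
            total = sum(iou[i, j] for i, j in matches)
            best = brute_force_max_matching(iou, iou_min=0.2)
            assert total == pytest.approx(best, abs=1e-9)


class TestBuildTracks:
    def test_single_filopodium_censored_both(self):
        dets = {f: [make_det(rect(5, 5, 2, 6), frame=f)] for f in range(10)}
        tracks = build_tracks(dets)
        assert len(tracks) == 1
        t = tracks[0]
        assert t.censored_start and t.censored_end
        assert t.n_frames == 10

    def test_gap_splits_track_without_gap_closing(self):
        """A 2-frame disappearance with max_gap 0 yields two tracks."""
        dets = {}
        for f in list(range(0, 5)) + list(range(7, 12)):
            dets[f] = [make_det(rect(5, 5, 2, 6), frame=f)]
        dets[5] = []
        dets[6] = []
        tracks = build_tracks(dets, max_gap=0)
        assert len(tracks) == 2
        tracks = build_tracks(dets, max_gap=2)
        assert len(tracks) == 1

    def test_every_detection_in_exactly_one_track(self, paper_movie):
        dets = paper_movie["detections"]
        tracks = paper_movie["tracks"]
        seen = {}
        for t in tracks:
            for f, j in t.steps:
                assert (f, j) not in seen
                seen[(f, j)] = t.id
        n_dets = sum(len(v) for v in dets.values())
        assert len(seen) == n_dets

    def test_reversal_symmetry(self):
        """Reversing the frame order yields the same partition with
        births and deaths swapped."""
        rng = np.random.default_rng(7)
        n_frames = 12
        dets = {}
        walkers = [(5, 5), (15, 20), (25, 3)]
        for f in range(n_frames):
            frame_dets = []
            for i, (r, c) in enumerate(walkers):
                if (i == 1 and f >= 8) or (i == 2 and f < 3):
                    continue  # walker 1 dies, walker 2 born late
                frame_dets.append(make_det(rect(r, c, 2, 6), frame=f,
                                           det_id=len(frame_dets)))
            dets[f] = frame_dets
            walkers = [(r + int(rng.integers(0, 2)), c) for r, c in walkers]
        fwd = build_tracks(dets)
        rev_dets = {n_frames - 1 - f: v for f, v in dets.items()}
        rev = build_tracks(rev_dets)
        def partition(tracks, flip):
            out = []
            for t in tracks:
                steps = [((n_frames - 1 - f) if flip else f, j)
                         for f, j in t.steps]
                out.append(frozenset(steps))
            return set(out)
        assert partition(fwd, False) == partition(rev, True)
        assert sum(t.censored_start for t in fwd) == sum(t.censored_end for t in rev)

    def test_track_purity_on_paper_default(self, paper_movie):
        """Linking ground-truth detections of a paper-default movie:
        >=90% of filopodia end up covered by exactly one track."""
        gts = paper_movie["gt_filopodia"]
        px = paper_movie["rcfg"].pixel_size
        dets = {}
        truth = {}
        for gt in gts:
            for i, f in enumerate(gt.frames):
                f = int(f)
                base = np.array([gt.base_um[1] / px, gt.base_um[0] / px])
                tip = np.array([gt.tip_um(i)[1] / px, gt.tip_um(i)[0] / px])
                n = max(int(np.linalg.norm(tip - base)) + 1, 2)
                line = base[None, :] + np.linspace(0, 1, n)[:, None] * (tip - base)
                pix = set()
                for r, c in np.round(line).astype(int):
                    for dr in (-1, 0, 1):
                        for dc in (-1, 0, 1):
                            pix.add((r + dr, c + dc))
                d = make_det(sorted(pix), frame=f,
                             det_id=len(dets.setdefault(f, [])))
                dets[f].append(d)
                truth[(f, d.id)] = gt.id
        tracks = build_tracks(dets, max_gap=0)
        step2track = {}
        for t in tracks:
            for s_ in t.steps:
                step2track[s_] = t.id
        by_gt = {}
        for s_, g in truth.items():
            by_gt.setdefault(g, set()).add(step2track[s_])
        nframes = {g.id: len(g.frames) for g in gts}
        multi = [g for g in by_gt if nframes[g] >= 2]
        pure = sum(1 for g in multi if len(by_gt[g]) == 1)
        assert multi
        assert pure / len(multi) >= 0.9


class TestAssignExtremities:
    def test_perpendicular_filopodium_polarity(self):
        body = np.zeros((40, 40), bool)
        body[:, :10] = True
        pix = [(20, c) for c in range(12, 24)]
        det = make_det(pix, frame=0)
        dets = {0: [det]}
        track = build_tracks(dets)[0]
        assign_extremities(track, dets, {0: body})
        assert track.minus_end[0][1] == 12  # body-proximal column
        assert track.plus_end[0][1] == 23
        assert not track.ambiguous_polarity

    def test_detached_fragment_flagged(self):
        body = np.zeros((40, 40), bool)
        body[:, :2] = True
        pix = [(20, c) for c in range(19, 23)]  # centred, equidistant-ish
        det = make_det(pix)
        dets = {0: [det]}
        track = build_tracks(dets)[0]
        # symmetric distances within the ambiguity margin -> flag
        body2 = np.zeros((40, 40), bool)
        body2[:, :19] = True
        body2[:, 23:] = True
        assign_extremities(track, dets, {0: body2})
        assert track.ambiguous_polarity

    def test_plus_end_matches_gt_tip(self, paper_movie):
        """The (+) label lands on the planted tip for >=95% of frames."""
        gts = paper_movie["gt_filopodia"]
        tracks = paper_movie["tracks"]
        dets = paper_movie["detections"]
        px = paper_movie["rcfg"].pixel_size
        gt_tip = {}
        for gt in gts:
            for i, f in enumerate(gt.frames):
                tip = gt.tip_um(i)
                gt_tip[(gt.id, int(f))] = np.array([tip[1] / px, tip[0] / px])
        det2gt = {}
        for gt in gts:
            for i, f in enumerate(gt.frames):
                target = gt_tip[(gt.id, int(f))]
                for j, d in enumerate(dets.get(int(f), [])):
                    if np.linalg.norm(d.tip - target) <= 3:
                        det2gt[(int(f), j)] = gt.id
                        break
        good = bad = 0
        for t in tracks:
            if not t.plus_end:
                continue
            for i, (f, j) in enumerate(t.steps):
                g = det2gt.get((f, j))
                if g is None:
                    continue
                tgt = gt_tip[(g, f)]
                if np.linalg.norm(t.plus_end[i] - tgt) <= 3.5:
                    good += 1
                else:
                    bad += 1
        assert good + bad > 100
        assert good / (good + bad) >= 0.95
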