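"""Shared fixtures.

The paper-default movie plus its full pipeline run is expensive (~40 s),
so it is rendered once per session and shared by the detection, tracking
and dynamics tests.
"""

from __future__ import annotations

import numpy as np
import pytest

from filoscaffold.io import ImageMeta
from filoscaffold.pipeline import process_movie
from filoscaffold.synthetic import paper_default_config, render_movie


@pytest.fixture(scope="session")
def default_configs():
    return paper_default_config()


@pytest.fixture(scope="session")
def paper_movie(default_configs):
    """Seed-1 paper-default movie with ground truth and pipeline output."""
    kcfg, rcfg = default_configs
    movie, masks, islets, gts = render_movie("l7L14-open", kcfg, rcfg, 1)
    meta = ImageMeta(pixel_size=rcfg.pixel_size, z_step=rcfg.z_step,
                     frame_interval=kcfg.frame_interval)
    summary, tracks, detections, islets_by_frame = process_movie(movie, meta)
    return {
        "kcfg": kcfg, "rcfg": rcfg, "meta": meta, "movie": movie,
        "gt_masks": masks, "gt_islets": islets, "gt_filopodia": gts,
        "summary": summary, "tracks": tracks, "detections": detections,
        "islets_by_frame": islets_by_frame,
    }


@pytest.fixture(scope="session")
def short_clean_movie(default_configs):
    """A short noise-free movie for geometric detection checks."""
    from dataclasses import replace

    kcfg, rcfg = default_configs
    kcfg = replace(kcfg, movie_duration=200.0)
    rcfg = replace(rcfg, apply_shot_noise=False, gaussian_read_noise_sd=0.0)
    movie, masks, islets, gts = render_movie("l7L14-open", kcfg, rcfg, 5)
    meta = ImageMeta(pixel_size=rcfg.pixel_size, frame_interval=kcfg.frame_interval)
    return {"kcfg": kcfg, "rcfg": rcfg, "meta": meta, "movie": movie,
            "gt_masks": masks, "gt_islets": islets, "gt_filopodia": gts}
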