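# filoscaffold

Quantification of endothelial filopodia dynamics and nuclei engagement in
3D hexagonal microscaffolds.

Endothelial cells cultured on two-photon-polymerized hexagonal lattices
("closed" lattices on the substrate, or "open" lattices raised on
micropillars) form a monolayer on top of the structures. On open lattices
they additionally engage vertically toward the glass substrate and emit
dynamic filopodia in the bottom plane — a protrusive state evocative of
angiogenic tip cells. `filoscaffold` implements the image-analysis chain
needed to quantify that behaviour:

* **Nuclei** — 3D segmentation of nuclei z-stacks; in-plane orientation of
  the principal nucleus axis against the scaffold reference axis, folded
  to [0°, 90°] (a random orientation averages 45°); vertical engagement as
  the bottom-z of each nucleus (0 µm = substrate contact, 7 µm = structure
  top) and the fraction below a 5 µm threshold.
* **Filopodia detection** — per-frame segmentation of cell islets
  (threshold + opening + hole filling; perimeter in µm) and of the thin
  protrusions outside them, via a detection-map contract: the default map
  is multiscale Hessian tubeness of a variance-stabilized,
  background-flattened frame, but any callable producing a per-pixel map
  (e.g. a learned model) plugs in unchanged.
* **Tracking** — frame-to-frame linking by linear assignment on the mask
  Intersection-over-Union, `IoU(A, B) = |A∩B| / |A∪B|`, with an IoU floor
  and optimal partial matching; censoring flags for tracks alive at the
  movie boundaries; barbed (+) / pointed (−) extremity labels from the
  distance to the parent cell body.
* **Dynamics** — mean lengths, lifetimes (uncensored tracks only,
  `(death − birth + 1)·Δt`), per-extremity elongation/retraction speeds
  from endpoint displacements projected on the filopodium axis, filopodia
  number normalized by islet perimeter, Savitzky–Golay smoothing of
  kinetic curves (window 21 intervals = 7 min, cubic), and paired
  pre/post-treatment statistics (fixed 10.3-min windows; Shapiro–Wilk gate
  + paired t-test).
* **Synthetic data** — a calibrated fluorescence-microscopy generator
  (islets emitting filopodia with piecewise-linear length profiles; nuclei
  as oriented ellipsoids at controlled depths; PSF blur and
  Poisson–Gaussian noise) that provides exact ground truth for every
  stage. The default preset is solved numerically so its ensemble ground
  truth reproduces the reference dynamics: mean length 3.36 µm, mean
  lifetime ≈233 s, (+)-end elongation ≈45.8 nm/s, 0.037 filopodia per µm
  of islet perimeter.

## Worked example

Simulate a 45-minute movie and run the full pipeline:

```bash
filoscaffold simulate --preset paper-default --structure l7L14-open --seed 1 -o demo/
filoscaffold metrics demo/movie.tif -o demo/out
```

which prints (seed 1):

```
mean length 3.48 um, lifetime 236 s, (+)-elongation 40.5 nm/s, normalized number 0.0286 /um
```

i.e. the filopodia in this movie average 3.48 µm in length; fully observed
filopodia live 236 s on average; their barbed ends elongate at ~40 nm/s;
and at any instant there are ~0.029 filopodia per µm of cell-islet
perimeter. `demo/out/` holds `summary.csv` (the numbers above),
`tracks.csv` (per-frame endpoints and censor flags of every track) and
`curves.csv` (raw and smoothed kinetic curves).

The same pipeline runs on real multi-page TIFF movies — pass
`--pixel-size`/`--frame-interval` if the file carries no calibration.
For fixed 3D stacks:

```bash
filoscaffold simulate --nuclei-stack --structure l7L14-open --seed 7 -o demo/
filoscaffold nuclei demo/nuclei_stack.tif -o demo/out
# -> 200 nuclei; 62.0% below 5 um; orientation 43 +/- 25 deg
```

In Python, the same analysis is three calls:

```python
from filoscaffold import ImageMeta, paper_default_config, process_movie, render_movie

kcfg, rcfg = paper_default_config()
movie, masks, islets, truth = render_movie("l7L14-open", kcfg, rcfg, seed=1)
meta = ImageMeta(pixel_size=rcfg.pixel_size, frame_interval=kcfg.frame_interval)
summary, tracks, detections, islets_by_frame = process_movie(movie, meta)
```

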