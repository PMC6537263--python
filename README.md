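# cvdenhance

Saliency-guided image enhancement for dichromatic (protan/deutan)
observers, with the evaluation apparatus needed to test it end to end on
synthetic data.

The core pipeline renders an image as a dichromat would perceive it
(Viénot-style linear-RGB reduction), computes bottom-up saliency of both
versions from the spatial density of difference-of-Gaussians keypoints
per CIE L\*a\*b\* channel, weights the per-channel L\*a\*b\* difference
between the two versions by the saliency error, collapses the weighted
difference into a single map, smooths it with a 3×3 Gaussian, segments
it with Otsu's method, and recolors the segmented regions by negating
a\* and b\* (a 180° rotation of the chroma plane) so red–green detail
that the observer cannot discriminate is moved toward the blue spectrum.

Supporting modules build smoothed fixation maps from binocular gaze logs
(55 Hz-style traces, optional exclusion of the center-biased first
200 ms), score saliency maps against fixation points with NSS and AUC,
and generate deterministic synthetic stimuli (pseudo-isochromatic dot
plates and red–green scenes with confusion-line colors) so nothing
requires human-subject data.

## Command line

All functionality is behind one entry point:

```sh
cvdenhance simulate --deficiency protan input.png simulated.png
cvdenhance saliency input.png --out map.png [--bandwidth-frac 0.05]
cvdenhance enhance --deficiency deutan [--correction 1,1,1] \
    [--debug-dir debug/] input.png enhanced.png
cvdenhance fixmap gaze.csv --screen 1920x1080 --exclude-ms 200 \
    --sigma-px 48 --out fixmap.png
cvdenhance evaluate --map map.png --fixations gaze.csv --metrics nss,auc
cvdenhance fixtures scene --seed 1 --size 128x128 --out scene.png
cvdenhance batch manifest.json --out-dir out/ [--config config.yaml]
```

Gaze CSVs use the dialect `t_ms,lx,ly,rx,ry,valid` with empty fields
for missing eyes.  Batch manifests are JSON lists of
`{"image": path, "gaze": optional path}` entries resolved relative to
the manifest; the run writes per-image enhanced PNGs plus a
`report.json` with thresholds, mask areas, metrics and the effective
config.  Pipeline configs (YAML or JSON) accept `deficiency`,
`bandwidth_frac`, `gaussian_sigma`, `correction`, `otsu_mode`,
`mask_cleanup`, `gaze_sigma_px`, `exclude_ms`, `seed`; unknown keys are
rejected.

## Library example

```python
from cvdenhance import enhance_image
from cvdenhance.fixtures import make_redgreen_scene

img = make_redgreen_scene((128, 128), seed=0)
result = enhance_image(img, "protan", debug=True)
result.enhanced        # recolored EncodedImage
result.mask            # Otsu SegmentationMask + threshold
result.error_map       # normalized saliency difference
result.simulated_view  # the enhanced image as the dichromat sees it
```
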