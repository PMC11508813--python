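# whealmeter

Automated reading of skin-prick-test (SPT) photographs: semantic
segmentation of wheals, reference-tag-calibrated area measurement,
diameter-based clinical approximations, and the agreement statistics needed
to compare area-measurement protocols on regular and irregular (pseudopod)
wheal shapes.

The package is organized around six stages:

| module | what it does |
| --- | --- |
| `whealmeter.synthetic` | labeled SPT-like scenes, regular/irregular shape sets with known analytic geometry, chained mirroring augmentation |
| `whealmeter.nn` | fully convolutional segmentation network (VGG-16-style encoder, skip-connected decoder) implemented in pure NumPy with a `width_multiplier` for CPU-scale training |
| `whealmeter.geometry` | 8-connected wheal clustering, cm²-per-pixel calibration from the 3 × 3 cm reference tag, pixel-proportion areas, centroid-chord LD/PD diameters, MA1/MA2 areas |
| `whealmeter.evaluation` | detection matching (type I/II errors, detection accuracy), per-wheal confusion-matrix metrics (accuracy, sensitivity, specificity, DSC, IoU) |
| `whealmeter.comparison` | Bland–Altman agreement, paired Wilcoxon signed-rank (exact for small n), ECDF bias-shift superposition, cumulative-mean convergence, percentage-deviation studies |
| `whealmeter.pipeline` / `whealmeter.cli` | end-to-end runs, annotated overlay reports, JSON/CSV records, `whealmeter` command line |

Label masks use a fixed three-color code on disk: magenta `(255, 0, 255)`
wheal, black `(0, 0, 0)` reference tag, red `(255, 0, 0)` background.

## Command line

```sh
# generate labeled shape sets or scenes (with JSON ground-truth sidecars)
whealmeter generate --group regular --n-files 15 --shapes-per-file 10 \
    --axis-range 0.5 1.5 --ppcm 33.33 --seed 1 --out data/regular

# mirroring augmentation: one labeled pair -> four
whealmeter augment --image scene.png --mask scene_mask.png --out aug/

# train a width-reduced network on image/mask pairs (full width is GPU-scale)
whealmeter train --data data/scenes --epochs 300 --batch-size 8 --lr 1e-3 \
    --width-mult 0.0625 --input-size 96 96 --seed 0 --out model.npz

# segment one image, measure a mask, score predictions, compare methods
whealmeter segment --model model.npz --image photo.png --out mask.png
whealmeter measure --mask mask.png --min-size 10 --angle-step 1.0 --out wheals.csv
whealmeter evaluate --pred pred_masks/ --truth truth_masks/ --pad 5 --out metrics.json
whealmeter compare --table areas.csv --reference AIS --out agreement.json
whealmeter deviation-study --group irregular --seed 1 --out deviations.csv

# full pipeline with annotated overlay reports
whealmeter report --model model.npz --image photo.png --out reports/
```

## Notes

- The network trains at full 640 × 480 / 4096-filter width only on GPU-class
  hardware; all tested configurations use `width_multiplier ≤ 1/16` on small
  canvases, which the NumPy backend handles on a single CPU core.
- Model checkpoints are NumPy `.npz` archives; training is reproducible
  given the config seeds.
- Diameters are chords through the cluster centroid (not the maximal
  pairwise point distance); on strongly non-convex shapes whose centroid
  falls outside the region the chord is the extreme-intersection extent and
  a warning is logged.
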