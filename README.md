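# ctcscope

Label-free detection of circulating tumor cells (CTCs) in bright-field
microscopy images of enriched blood samples.

CTCs are tumor-derived cells found in peripheral blood at a few per
10 billion blood cells. After immunomagnetic enrichment the remaining
population is mostly white blood cells (WBCs), and the standard way to tell
the two apart is fluorescent antibody staining — costly, slow, and
unreliable for tumors (such as renal cell carcinoma) that underexpress the
usual epithelial markers. `ctcscope` implements the label-free alternative:
classify each cell from its bright-field appearance alone, using
fluorescence only once, to label the training data.

The pipeline:

1. **Segment** the bright-field frame: cap outlier brightness (a few
   near-saturated cells otherwise pull the global Otsu threshold away from
   the cell/background boundary), Otsu-threshold the smoothed gradient
   magnitude into rim edges, flood-fill closed rims, morphologically open
   and area-filter, and split touching cells with a marker watershed on the
   Euclidean distance transform.
2. **Build the dataset**: crop a 30×30 patch at each region centroid
   (coordinates recorded), transfer the class label from the registered
   two-channel fluorescence frame (green = WBC marker, red = CTC marker),
   reject non-single-cell regions with explicit quality rules, and
   normalize each crop (border plane fit + standardization).
3. **Augment** the labeled crops (rotation, shear, reflections) to a fixed
   per-class target, tracking each synthetic crop's origin.
4. **Classify** with a CNN on 34×34 inputs: fully connected ReLU head,
   dropout 0.6, softmax with cross-entropy, Adam at a learning rate of
   1e-4, minibatches of 16. A from-scratch CPU backbone (3 conv blocks)
   is the default; a `pretrained-resnet50` transfer-learning backbone is on
   the API surface and reports clearly when its weights are unavailable.
5. **Evaluate** with leakage-safe five-fold cross-validation: folds are made
   from *original* crops only, augmentation happens after the split, the
   80/20 train/validation split is taken at the origin level, and test
   predictions are made on originals only. Metrics: confusion matrices,
   accuracy, precision/recall/F-score (CTC positive), pooled and mean
   ROC-AUC, learning curves, and a t-SNE embedding (perplexity 50,
   learning rate 100).

Because no public image set exists for this workflow, the package ships a
first-class synthetic generator (`ctcscope.synthgen`) producing paired
bright-field + fluorescence frames with full ground truth: 480×640 frames
at 0.46 µm/px, round cells of mean diameter 11.5 µm in both classes (CTCs
with a wider size spread), touching pairs, debris specks, vignetting and
rare very-bright cells. Every stage of the pipeline is tested against it.

## Worked example

```python
import numpy as np
from ctcscope import synthgen, segment, dataset, classify, evaluate

# two synthetic frames of 40 WBCs + 40 CTCs, ground truth attached
cfg = synthgen.GeneratorConfig(touching_fraction=0.0)
originals = []
for seed in (100, 101):
    pair = synthgen.generate_pair(40, 40, cfg, seed=seed, frame_id=f"f{seed}")
    _, regions = segment.segment_frame(pair.bright)
    crops = dataset.crop_cells(pair.bright, regions, frame_id=pair.frame_id)
    crops = dataset.transfer_labels(crops, pair.fluor_green, pair.fluor_red)
    kept, _ = dataset.quality_filter(crops, regions, frame_shape=pair.bright.shape)
    originals += [dataset.normalize_crop(c) for c in kept if c.label != "UNLABELED"]

plan = evaluate.make_folds(originals, k=5, seed=0)
spec = dataset.AugmentSpec(target_per_class=150, seed=0)
tcfg = classify.TrainConfig(head_hidden_units=64, learning_rate=1e-3,
                            max_epochs=12, patience=4, seed=0)
report = evaluate.run_cv(originals, plan, spec, tcfg)
print(f"pooled accuracy {report.pooled_accuracy:.3f}  "
      f"mean AUC {report.mean_auc:.3f}  pooled AUC {report.pooled_auc:.3f}")
```

prints (one CPU, ~20 s):

```
pooled accuracy 0.924  mean AUC 0.990  pooled AUC 0.991
```

i.e. on held-out original crops (158 from the two frames: 78 WBC, 80 CTC)
the scratch CNN separates the two rendered classes (rim depth/width,
interior brightness and texture — not size) with 92.4% pooled accuracy
over the five folds and a mean per-fold AUC of 0.99.

The same flow is available from the shell:

```bash
ctcscope synth --n-wbc 45 --n-ctc 5 --seed 1 --frames 3 --out frames/
ctcscope segment --image frames/frame0/bright.png --out seg/
ctcscope run --config pipeline.yaml --out run/    # end-to-end count report
ctcscope evaluate --dataset frames/ --folds 5 --seed 0 --out eval/
```

`ctcscope run` ends with a per-frame label-free count report combining each
crop's recorded coordinates with its predicted class:

```
frame0: 50 cells detected, 5 CTC, 44 WBC, 1 unclassified
```

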