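# equipain

Automated pain assessment for horses from facial expressions.

Trained observers score equine pain with the Horse Grimace Scale (HGS): six
facial parameters (ear position, orbital tightening, tension above the eye,
strained chewing muscles, strained mouth/pronounced chin, strained nostrils),
each graded *not present* / *moderately present* / *obviously present*.
Applying the scale continuously is impractical — it needs a trained human on
site, and horses, as prey animals, suppress pain behaviour when an unfamiliar
observer is near.  `equipain` implements an automated pipeline that replaces
the observer with fixed-camera video and a cascade of classifiers:

1. **frame harvest** — motion-triggered frame extraction from fixed-camera
   video (mean absolute pixel difference between consecutive frames,
   threshold + minimum-gap + cap policy);
2. **dataset** — a CSV-manifest image database of cropped facial regions
   (*ears*, *eyes*, *mouth-and-nostrils*) with three-level pain labels and a
   stratified train/validation/test split (floor-per-class 10%/10% rule);
3. **region CNNs** — one convolutional classifier per region:
   conv(60×7×7, ReLU) → maxpool(2×2) → batchnorm → conv(32×5×5, ReLU) →
   maxpool(2×2) → batchnorm → dense(500 or 1000, ReLU) → dense(3, softmax),
   trained with three independent replicates per region and early stopping
   on validation loss;
4. **fusion** — the three softmax confidence triples, concatenated into a
   9-vector, feed a small perceptron (9 → 5 sigmoid → 3 linear; learning
   rate 0.3, momentum 0.2, MSE to one-hot targets) evaluated by stratified
   10-fold cross-validation;
5. **evaluation** — K×K confusion matrices (reference labels on rows) with
   recall = diag/rowsum, precision = diag/colsum, overall accuracy =
   trace/total, and a binary collapse merging the two pain levels into a
   single "pain present" class.

Because the original footage was never published, the package also ships a
fully seeded **synthetic generator** (region images, whole-face scenes,
longitudinal cohorts, toy motion videos) with a tunable class-separability
dial and a closed-form pixel rule that provably classifies fully separable
renders — giving the CNNs and the fusion net a benchmark with known ground
truth.  The published evaluation matrices are included as fixtures, and
every reported accuracy, recall and precision derives from them exactly.

## Worked example

Evaluate the shipped whole-face (fused) reference matrix:

```bash
$ equipain evaluate --matrix fused.csv       # fused.csv via ep.reference_matrices()["fused"].write_csv(...)
Reference \ Predicted  Not Present  Moderately Present  Obviously Present  Recall
Not Present            32*          7                   1                  80.0%
Moderately Present     7            27*                 6                  67.5%
Obviously Present      0            8                   32*                80.0%
Precision              82.1%        64.3%               82.1%              75.8%
```

120 whole-face images, 40 per pain level; the starred diagonal counts are
the correct calls.  Overall accuracy is 91/120 = 75.8%; e.g. recall 80.0%
for "Not Present" means 32 of the 40 truly pain-free faces were called
pain-free, and precision 82.1% means 32 of the 39 faces *called* pain-free
truly were.  Collapsing the two pain levels (`--binary`) merges rows and
columns 2–3 and can only convert cross-level errors into correct calls:

```
Reference \ Predicted  Not Present  Present  Recall
Not Present            32*          8        80.0%
Present                7            73*      91.3%
Precision              82.1%        90.1%    87.5%
```

The synthetic pipeline end-to-end (scenes → region CNNs → fusion):

```python
>>> from equipain.benchmark import run_pipeline_benchmark
>>> bench = run_pipeline_benchmark(seed=1)   # separable, noise-free scenes
>>> bench.region_val_accuracy
{'ears': 1.0, 'eyes': 1.0, 'mouth_nostrils': 1.0}
>>> bench.fusion.mean_accuracy_pct
100.0
```

CLI subcommands: `synth`, `harvest`, `split`, `fusion-set`, `train-region`,
`predict-region`, `train-fusion`, `predict`... — run `equipain --help`.

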