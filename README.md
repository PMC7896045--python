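# wsiweak

Annotation-free whole-slide image classification: train a slide-level
cancer-type classifier (non-cancer vs lung adenocarcinoma vs squamous
cell carcinoma) from slide-level diagnoses only — no pixel or patch
annotations — and compare the whole-slide training route against the
full family of multiple-instance-learning (MIL) baselines, with
CAM-based lesion localization, receptive-field arithmetic, an abstract
memory-group scheduler for oversized inputs, and DeLong-based AUC
evaluation. Everything runs end to end on synthetic slides generated by
the package, at desk scale on one CPU.

## Who this is for

Researchers in computational pathology and weakly supervised learning
who want a tested, self-contained reference implementation of:

* **Whole-slide training** — feed the entire (downscaled, white-padded)
  slide through a CNN and train end-to-end from the slide label. The
  head matters: with global average pooling (GAP) the few feature-map
  cells covering a small lesion are averaged with hundreds of irrelevant
  ones; replacing GAP with global max pooling (GMP) keeps the strongest
  activation per channel, so one receptive field covering the lesion
  drives the slide logit — the MIL "max" assumption moved inside the
  network head.
* **MIL baselines** — standard top-k instance selection (k ∈ {1, 3, 5})
  with max-pooling bag inference; EM-based adaptive selection with
  Gaussian-blurred prediction maps and percentile thresholds feeding
  class-histogram LR/SVM bag classifiers; CNN-MaxFeat + random forest;
  MIL-RNN with 128 hidden units.
* **Receptive-field calculus** — the recurrence `r ← r + (k−1)·d·j`,
  `j ← j·s` over a layer sequence, giving 483 px for the reference
  ResNet-50 description, a 7-cell output side for a 224 px input, and
  physical fields of 1111 µm / 2222 µm at ×4 / ×2 magnification.
* **Group Execution / Group Prefetch** — a compute-graph planner that
  cuts a topologically sorted operation sequence into memory-bounded
  groups and overlaps explicit-copy prefetch with compute, plus an
  analytic swap-traffic simulator.
* **Evaluation statistics** — Mann-Whitney AUC, DeLong confidence
  intervals and paired two-sided tests, bootstrap box-whisker summaries.

The scientific background, model assumptions, desk-scale parameter
choices and limitations are documented in `docs/methods.md`.

## Worked example

Train the whole-slide GMP classifier on a small synthetic corpus and
evaluate per-class AUCs:

```python
from wsiweak.experiment import ExperimentConfig, run_experiment

cfg = ExperimentConfig(method="WSI_GMP", n_per_class=20, seed=1)
report = run_experiment(cfg)
for cls, res in report["methods"]["WSI_GMP"]["test"].items():
    print(cls, res)
```

```
ADC {'auc': 0.8671875, 'ci_low': 0.7195444958, 'ci_high': 1.0}
SqCC {'auc': 1.0, 'ci_low': 1.0, 'ci_high': 1.0}
```

The corpus (20 slides per class, 512×512 px at 2.3 µm/px, 30% of the
cancerous slides in the small-lesion regime — tumour area below 10% of
tissue) is generated on the fly; with only 60 training slides the
adenocarcinoma-vs-rest AUC is 0.87 (DeLong 95% CI 0.72–1.0) while
squamous separates perfectly. The report also contains the same AUCs
restricted to the small-lesion subset (small-lesion cancers plus all
benign test slides), the derived seeds, and the split sizes. The
interesting science is in the *comparisons*: run `run_benchmark([...],
cfg)` over `WSI_GMP, WSI_GAP, MIL_topk, MaxFeat_RF, MIL_RNN` on the
full 67-per-class corpus to see average pooling and max-rule MIL
degrade on small lesions while whole-slide GMP holds — on that corpus
(seed 0) the GMP head reaches per-class AUCs of 1.000/1.000 against the
GAP head's 0.953/0.811, and the acceptance test suite asserts exactly
these orderings.

The receptive-field calculus is a one-liner:

```python
from wsiweak.arch import resnet50_spec, receptive_field, output_spatial_size
receptive_field(resnet50_spec())      # -> (483, 32)
output_spatial_size(resnet50_spec(), 224)   # -> 7
```

A command-line interface covers the pipeline stages:

```bash
wsiweak synth --n-per-class 10 --out corpus/       # synthetic slides + manifest
wsiweak tile  --corpus corpus/ --out tiles.csv     # tiling + background flags
wsiweak train --config experiment.yaml             # full experiment
wsiweak eval  --scores predictions.csv             # AUC + DeLong CIs
wsiweak sched --graph graph.json --budget 32e9     # memory-group planning
wsiweak cam   --model ckpt.npz --corpus corpus/ --slide-id ADC_0001 \
              --target-class ADC --out heatmap.png
```

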