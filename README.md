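# pdl1tps

Tooling for **PD-L1 Tumour Proportion Score (TPS) assistance** in non-small
cell lung cancer (NSCLC) pathology: a tested implementation of the full
pipeline from IHC patch to clinical routing decision, built for researchers
and engineers developing or validating TPS-assist algorithms.

PD-L1 TPS is the fraction of viable (intact) tumour cells showing membrane
staining:

```
TPS% = 100 · n_positive / (n_positive + n_negative)
```

Clinical reporting uses the categories `<1%`, `1–49%` and `≥50%`, and
inter-observer variation concentrates near the 1% and 50% cut-offs. The
pipeline therefore ends in a triage step that flags scores in the 1–5% and
40–60% bands for mandatory pathologist review.

## What is in the package

| module | role |
|---|---|
| `pdl1tps.synthetic` | seeded synthetic IHC-like patches/cases/cohorts with known cell tallies and TPS (DAB-brown positive cells, haematoxylin-blue negative cells, macrophage-like stained distractors labelled background) |
| `pdl1tps.segmenter` | trainable U-Net-style encoder–decoder (ResNet-pattern residual encoder, transpose-convolution decoder with skip connections) classifying pixels as background / positive / negative; weighted cross-entropy loss (0.4, 0.9, 0.9), Adam, flip/rotation augmentation, 0.5 mask threshold |
| `pdl1tps.nn` | the minimal numpy layer library (conv, transpose conv, group norm, pooling, Adam) with explicit backpropagation that the segmenter is built on |
| `pdl1tps.quantify` | connected-component cell counting with a radius-4 Chebyshev merge, TPS computation, ROI tiling (GeoJSON polygons, 256 px tiles) and score aggregation |
| `pdl1tps.evaluate` | pixel-level (accuracy/sensitivity/specificity), object-level (precision/recall by greedy one-to-one matching) and patient-level (Pearson/Spearman r, interval concordance) evaluation |
| `pdl1tps.router` | clinical interval routing: confident/unconfident bands with edges at 1, 5, 40 and 60 TPS points, pathologist-override workflow with provenance |
| `pdl1tps.cli` | `pdl1-tps simulate / train / segment / score / evaluate / route` |

Real PD-L1 slide cohorts are access-controlled, so the synthetic module is a
first-class component: every generated patch carries an exact label mask and
cell tally, giving closed-loop ground truth for the whole pipeline.

## Worked example

```python
from pdl1tps import (SyntheticPatchSpec, generate_case, assign_interval,
                     route_case)
from pdl1tps.quantify import CellTally, count_cells, compute_tps

# a 4-patch case: each patch has 3 positive, 12 negative tumour cells and
# one macrophage-like distractor (stained but labelled background)
spec = SyntheticPatchSpec(n_positive=3, n_negative=12, n_distractor=1)
case = generate_case(spec, n_patches=4, seed=7)
print("true tally:", case.true_tally, "true TPS:", case.true_tps)

tally = CellTally(0, 0)
for _, mask in case.patches:            # count cells patch by patch, sum
    tally = tally + count_cells(mask)
tps = compute_tps(tally)
print("counted tally:", tally, "TPS: %.1f%%" % tps)

decision = assign_interval(tps)
print("band:", decision.band, "| category:", decision.clinical_category)
print("status:", route_case(decision).status)
```

prints

```
true tally: CellTally(n_positive=12, n_negative=48) true TPS: 20.0
counted tally: CellTally(n_positive=12, n_negative=48) TPS: 20.0%
band: confident_mid | category: 1-49%
status: finalized
```

The connected-component counter recovers the construction-time tally
exactly (cells are generated with gaps wider than the merge radius), the
TPS of 20% falls in the `1–49%` category, and — being outside the 1–5% and
40–60% review bands — the case auto-finalises with algorithm provenance. A
score of, say, 45% would instead return `status: pending_review` until a
pathologist enters a score.

The same flow from the shell:

```bash
pdl1-tps simulate --cases 5 --seed 1 --output cohort/
pdl1-tps train --data cohort/ --epochs 5 --output model.npz
pdl1-tps score --model model.npz --image cohort/case_000_patch00.png
pdl1-tps route --tps 45.0            # exits 4: pending pathologist review
```

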