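# manoclass

Automated Chicago Classification v3.0 of esophageal motility disorders from
high-resolution manometry (HRM) pressure-topography images.

HRM is the gold standard for diagnosing esophageal motility disorders: a
36-sensor catheter records pressures during ten wet swallows, each displayed
as a color pressure-topography plot.  Reading those plots — judging the
integrated relaxation pressure (IRP) of the esophago-gastric junction and
the contractile pattern of every swallow, then walking the Chicago v3.0
decision tree — is manual, and inter-observer agreement is only fair to
moderate outside achalasia.  `manoclass` automates the whole chain for
gastroenterology/motility-lab tooling and for methods research on automated
manometry reading:

* **preprocess** — binarize the raster, locate the white swallow-onset
  marker by the column histogram of white pixels, crop the swallow and IRP
  regions of interest, resize (299×299×3 / 224×224×3) and rescale to [−1, 1];
* **classify** — frozen convolutional backbone + trained head (global
  average pooling, 20 % dropout, softmax; Adam, batch 32) for a 2-class IRP
  call and a 5-class swallow-pattern call per image;
* **chicago_rules** — the v3.0 decision tree: study IRP verdict first
  (majority over swallows, cutoff 28 mmHg), then fixed count thresholds, e.g.

  ```
  high IRP:   pan = 0 → achalasia I;  pan ≥ 2 → achalasia II;
              premature ≥ 3 → achalasia III;  else EGJ outflow obstruction
  normal IRP: premature ≥ 3 → distal esophageal spasm;  DCI>8000 ≥ 2 →
              hypercontractile;  weak ≥ 5 → ineffective motility;
              fragmented ≥ 5 → fragmented peristalsis;  else normal
  ```

* **synth_hrm** — a parametric simulator (traveling Gaussian pressure ridge
  on a 36 × 600 grid, LES band with or without deglutitive relaxation,
  palette renderer with the white onset marker) that generates labeled
  swallows and whole studies, so every stage is testable without patient
  data.  Ground-truth IRP (mean of the lowest 4 s of LES pressure in the
  10 s post-onset window) and DCI (∫ max(p − 20, 0) dx dt over the distal
  segment) are measured from the simulated fields;
* **evalmetrics** — confusion matrices, accuracy, one-vs-rest
  precision/recall/F1 (harmonic mean), truncated two-decimal reporting;
* **pipeline / cli** — end-to-end orchestration with one seed feeding every
  stage.

See `docs/methods.md` for the model, parameter defaults, and limitations.

## Worked example

```python
from manoclass import synth_hrm, chicago_rules
from manoclass.types import Diagnosis

batch = synth_hrm.generate_study(Diagnosis.ACHALASIA_TYPE_II, seed=42)
for s in batch.swallows[:3]:
    t = s.truth
    print(f"{t.pattern.value:14s} IRP={t.irp_mmHg:5.1f} mmHg  DCI={t.dci:7.1f} mmHg.cm.s")

study_irp = chicago_rules.aggregate_irp(batch.irp_classes)
counts = chicago_rules.count_patterns(batch.patterns)
dx, rule = chicago_rules.diagnose_with_rule(study_irp, counts)
print(f"study IRP: {study_irp.value}  counts: pan={counts.panesophageal} other={counts.other}")
print(f"diagnosis: {dx.value}  ({rule})")
```

prints

```
failed         IRP= 43.1 mmHg  DCI=    0.0 mmHg.cm.s
failed         IRP=  4.9 mmHg  DCI=    0.0 mmHg.cm.s
panesophageal  IRP= 40.7 mmHg  DCI= 1900.8 mmHg.cm.s
study IRP: high  counts: pan=2 other=8
diagnosis: achalasia_type_2  (high IRP and >= 2 panesophageal pressurization)
```

The batch was seeded as type II achalasia: most swallows show a high IRP
(the first failed swallow's LES never relaxes, IRP 43.1 mmHg; the second
relaxes normally to 4.9), two show panesophageal pressurization, and the
decision tree recovers the seeding diagnosis from the ground-truth labels.

The same flow runs from the shell, end to end from pixels:

```sh
manoclass synth --diagnosis all --n-studies 1 --seed 3 --out data/
manoclass experiment --seed 1 --out results/        # train + benchmark
manoclass diagnose --study data/study_0001 --models results/models --out report.json
# study_0001: achalasia_type_2 (high IRP and >= 2 panesophageal pressurization)
```

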