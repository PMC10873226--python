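# twistcad

Two-stage breast lesion detection for **ultrafast (TWIST) screening DCE-MRI**,
with a synthetic contrast-kinetics phantom so the entire pipeline is testable
on a desk without any patient data.

Ultrafast breast MRI acquires one pre-contrast volume *t0* and a rapid train
of post-contrast volumes *t1..t14* within ~102 s of contrast-agent inflow.
Screening cohorts are overwhelmingly lesion-free, so a usable
computer-aided-detection system must keep false positives low at screening
prevalence. `twistcad` implements the standard two-stage recipe:

1. **Preprocessing** — subtraction volumes `sub_i = max(0, t_i − t0)`, breast
   masking, maximum-intensity projection (MIP), left/right splitting, 8-bit
   normalisation (`twistcad.preprocess`).
2. **Stage 1: candidate detection** on the *last* subtraction MIP (late
   enough that slowly enhancing benign lesions are visible), behind a
   pluggable `DetectorBackend` contract with an analytic multi-scale
   difference-of-Gaussians backend and a trainable logistic
   objectness-heatmap backend (`twistcad.detect`).
3. **Stage 2: temporal false-positive reduction** — each candidate box is
   cut from all 14 MIPs into a clip; a small gated recurrent network scores
   its enhancement dynamics. Lesions keep enhancing; vessels and nipples
   enhance early and wash out; noise stays flat. A candidate is accepted iff
   `det_score ≥ th0` **and** `seq_score ≥ th1` (defaults 0.5/0.5), with
   `final_score = det_score · seq_score` (`twistcad.fpreduce`).
4. **Evaluation** — greedy one-to-one matching (centre-in-box or IoU ≥ 0.3),
   free-response (FROC) analysis with sensitivity reported at 0.125 / 0.25 /
   0.5 / 1 / 2 false positives per breast, and per-fold
   sensitivity / PPV / FP-reduction bookkeeping (`twistcad.evaluate`).
5. **Cross-validation** — five-fold, group-bound at the breast level,
   stratified by lesion presence; training sets are balanced (all involved
   breasts + an equal number of uninvolved ones) and the remaining
   *isolated negatives* are merged back into each fold's test data to
   restore screening prevalence (`twistcad.cohortcv`).
6. **Phantom** — a seeded generator of synthetic cohorts (17 % lesion
   prevalence, benign/malignant piecewise-linear kinetics with median
   diameters 9 / 22 mm, vessel/nipple/parenchyma confounders, Gaussian
   noise, NIfTI + LabelMe output) that makes every stage testable
   (`twistcad.phantom`).

## Worked example

```python
from twistcad import Cohort, CohortConfig, run_crossval

cohort = Cohort(CohortConfig(n_breasts=200, seed=1))   # synthetic cohort
result = run_crossval(cohort, k=5, seed=1)             # full two-stage CV
print(result.summary())
```

prints (seed 1):

```
{'stage1_sensitivity':     {'mean': 0.93, 'min': 0.82, 'max': 1.0},
 'integrated_sensitivity': {'mean': 0.91, 'min': 0.73, 'max': 1.0},
 'stage1_ppv':             {'mean': 0.01, 'min': 0.01, 'max': 0.02},
 'integrated_ppv':         {'mean': 0.91, 'min': 0.8,  'max': 1.0},
 'fp_reduction_fraction':  {'mean': 1.0,  'min': 1.0,  'max': 1.0},
 'pooled_fp_reduction':    0.9985431841831426}
```

Reading: on a 200-breast synthetic screening cohort the analytic stage-1
detector finds 93 % of lesions but accepts thousands of false positives
(PPV 0.01 — mostly vessels, nipples and noise peaks). The temporal stage
removes ~99.9 % of those false positives while average sensitivity falls by
only 0.02 — the phantom's confounders are fully separable from lesions by
their wash-out kinetics, so the second stage is far more effective here than
it can be on clinical data.

The same pipeline is available from the shell:

```bash
twistcad simulate --seed 1 --n-breasts 20 --out runs/sim     # NIfTI cohort
twistcad crossval --seed 1 --n-breasts 100 --out runs/cv     # CV + FROC csv/png
twistcad report --run runs/cv
```

## Layout

```
src/twistcad/        phantom, preprocess, detect, fpreduce, evaluate,
                     cohortcv, config, cli
tests/               unit + property + acceptance test suite
scripts/acceptance.py
docs/methods.md      models, assumptions, parameter choices, limitations
```
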