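# lmradapt — adaptive locomotion-mode recognition for powered prosthetic legs

Locomotion-mode recognition (LMR) lets a powered lower-limb prosthesis
infer what its user is doing — level walking (W), ramp ascent/descent
(RA/RD), stair ascent/descent (SA/SD) — from surface EMG of the residual
thigh muscles fused with the prosthesis load-cell signals, and switch its
impedance controller accordingly. A classifier trained once, however,
degrades as the input signals drift: electrodes shift, skin impedance and
temperature change, and the user's gait itself evolves while they adapt to
the device. `lmradapt` implements the recognition pipeline together with
three *unsupervised* adaptation strategies that keep it reliable without
ever collecting new labels, and a seeded synthetic gait-signal simulator to
exercise the whole system end to end. It is aimed at researchers in
myoelectric control and neural-machine interfaces who want a reproducible,
testable reference implementation of self-adapting pattern recognition
under concept drift.

## The method

Signals (7 EMG + 6 mechanical channels, 1000 Hz) are segmented into 160 ms
windows sliding by 20 ms. Per window, EMG is band-passed (20–420 Hz,
8th-order Butterworth) and reduced to four time-domain features per channel
(MAV, WL, SSC, ZC); each mechanical channel contributes max/min/mean/std.
The fused 52-dimensional vector goes to one of five gait-phase-specific
classifiers — a one-against-all (OAA) bank of RBF-kernel SVMs with
per-binary Platt calibration — and the renormalized 5-class posterior
p_k(n) yields a label and a confidence,

    E(n) = − Σ_{k=1..5} p_k(n) ln p_k(n)      (entropy, nats)

followed by a 5-decision majority vote. After each testing trial the bank
can retrain itself from pseudo-labeled testing windows chosen by one of:

- **EBA** — entropy-based adaptation: keep windows with E(n) < τ (τ = 0.6);
- **LIFT** — keep windows claimed by *exactly one* OAA binary;
- **TSVM** — transductive SVM: per binary, iteratively absorb up to m = 5
  within-margin unlabeled points per side (distance to the hyperplane in
  (0, 1), closest to 1) until all testing windows are assigned.

Performance is reported as static-state accuracy (%) and missed
transitions (a terrain change not recognized by the end of its transitional
period — one gait cycle plus two stance phases around the change).

## Worked example

```python
import numpy as np
from lmradapt.evaluation import run_part1_experiment

reports = run_part1_experiment(seed=5, strategies=("none", "eba"))
for name, rep in reports.items():
    print(f"{name:>4}: trial-1 {rep.accuracy[0]:.1f}%  trial-10 {rep.accuracy[-1]:.1f}%  "
          f"last-5 mean {np.mean(rep.accuracy[5:]):.1f}%  missed {rep.total_missed}/80")
```

prints

```
none: trial-1 97.4%  trial-10 84.4%  last-5 mean 87.8%  missed 9/80
 eba: trial-1 97.4%  trial-10 89.5%  last-5 mean 91.6%  missed 6/80
```

One synthetic session is generated (3 training repetitions, then 10 testing
trials of the sequence W→SA→W→SD→W→RA→W→RD→W under gradually drifting
signals), a phase-classifier bank is trained, and the same testing trials
are classified twice: statically (`none`) and with entropy-based
self-retraining after every trial (`eba`). The static classifier loses
~13 accuracy points across the session as the signals drift away from the
training distribution and misses 9 of the 80 terrain transitions; the
adaptive classifier holds its last-five-trial accuracy ~4 points higher
and misses only 6.

The same pipeline is scriptable from the shell:

```bash
lmradapt simulate --seed 5 --out session/          # trial CSVs + manifest
lmradapt train    --manifest session/manifest.yaml --out bank.joblib
lmradapt run      --manifest session/manifest.yaml --bank bank.joblib \
                  --strategy eba --out decisions/
lmradapt evaluate --manifest session/manifest.yaml --decisions decisions/ \
                  --out summary.csv
lmradapt all --experiment part2 --seed 5 --out part2/   # one-shot experiment
```

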