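# svsdg — directional brain-heart interplay under graded mental stress

`svsdg` quantifies the bidirectional, time-resolved functional coupling
between cortical oscillations (EEG band power) and cardiac autonomic
activity (sympathetic and parasympathetic indices estimated from
RR intervals), and tests how that coupling's *variability* changes across a
graded mental-stress protocol (rest plus three increasingly demanding
stressor blocks). It is aimed at computational-physiology researchers
working with heartbeat dynamics and low-density EEG.

## The model

**Autonomic indices.** The RR series is expanded on a discrete orthonormal
Laguerre basis, L_j(k) = Σ_n φ_j(n)·RR(k−n−1), and the time-varying
expansion coefficients g(k) of

RR(k) = g0(k) + Σ_{j=0}^{8} g1,j(k)·L_j(k) + ε_RR(k)

are tracked by a random-walk Kalman filter. Fixed published kernels read
out the sympathetic and parasympathetic activity indices:

SAI(k) = [Ψs0 + Ψs1·g1,0 + Ψs2·g1,1] / RR(k),  PAI(k) = [Ψp0 + Σ Ψpj·g1,j+1]·2·RR(k).

**Directional coupling.** On a shared 1-s grid, the heart-rate modulation
m(t) (fluctuation of 1/RR about a 15-s sliding baseline) is regressed per
window, with no intercept, on SAI and PAI, giving control coefficients
C_SAI(t), C_PAI(t); the descending coupling per band F and channel is
SDG_{EEG_F→X}(t) = C_X(t)/EEG_F(t−1). Ascending, band power follows a lag-1
adaptive Markov model EEG_F(t) = κ_F·EEG_F(t−1) + Ψ_F(t−1) + ε_F, and
SDG_{X→EEG_F}(t) = Ψ_F(t)/X(t). With 2 directions × 2 autonomic branches ×
5 bands × 9 channels this yields 180 coupling series, condensed per
condition into their median absolute deviation (MAD), screened with
Friedman/Wilcoxon tests under a Bonferroni threshold (0.05/9 ≈ 0.0056),
ranked by minimum-redundancy maximum-relevance (mutual-information
quotient), and fed to cross-validated stress models (Gaussian-kernel ridge
regression onto the stress level 0/1/4/5 and a kernel naive Bayes low- vs
high-stress classifier).

A synthetic protocol generator (integrate-and-fire heartbeats driven by
planted sympathovagal modulation; adaptive-Markov band power with a planted
heart drive) produces full cohorts with known ground truth, so every stage
is testable without any recording. See `docs/methods.md` for the model
details, defaults and limitations.

## Worked example

```python
import numpy as np
from svsdg import (AutonomicIndexModel, BrainHeartModel,
                   SyntheticConfig, generate_protocol_dataset)

cfg = SyntheticConfig(n_subjects=1, seed=3)
ds = generate_protocol_dataset(cfg)
subj = ds.subjects[0]

res = AutonomicIndexModel(subj.full_rr()).fit()
print(res.summary())

coupling = BrainHeartModel(subj.full_rr(), subj.bandpower["stress2"],
                           autonomic=res.autonomic).fit()
print(coupling.summary())
```

prints (numbers from this exact run):

```
Autonomic index estimation (Laguerre + Kalman)
====================================================
beats analysed        : 1532
Laguerre basis        : alpha=0.2, orders 0..8
state noise q         : 1e-05
warm-up beats         : 50
innovation mean (s)   : -1.297e-05 (SE 1.538e-04)
innovation lag-1 rho  : +0.681
SAI median [IQR] a.u. : 53.43 [52.69, 54.13]
PAI median [IQR] a.u. : 43.99 [43.32, 44.58]

Bidirectional brain-heart coupling (SV-SDG)
====================================================
coupling series       : 180 (2 directions x 2 branches x 5 bands x 9 channels)
window length         : 15 s (1-s step)
valid points          : 52516 / 52650 (99.7%)
kappa median [IQR]    : 0.998 [0.976, 1.018]
C_SAI median          : +0.03677
C_PAI median          : +0.01824
```

The innovation mean sits well within one standard error of zero (the filter
is unbiased); the positive lag-1 innovation autocorrelation reflects the
slow sympathovagal modulation this subject carries, which the random-walk
state model tracks but does not whiten. SAI/PAI sit in the tens of
arbitrary units; the windowed lag-1 power ratio κ̂ sits near 1 on
mean-dominated band power (see the methods note); and the C's are the
per-window descending control coefficients whose variability across
conditions is the downstream discriminative feature.

The full pipeline (features → Friedman battery → MRMR → cross-validated
models) runs from the shell:

```bash
svsdg simulate --seed 1 --n-subjects 5 --out data/
svsdg run-all --input-dir data/ --out results/ --seed 1
```

writing `features.csv` (180 coupling features per subject-condition row),
`friedman_coupling.csv`, `mrmr_*.csv`, `cv_metrics.json` and a checksum
manifest.

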