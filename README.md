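# gtrca

Group task-related component analysis (gTRCA) for epoched evoked-potential
EEG, with circular-shift permutation tests.

## The problem

Characterizing evoked potentials at the group level — TMS-evoked
potentials especially — usually relies on the grand average: mean over
trials, then over subjects, at fixed electrodes. That assumes evoked
waveforms are comparable across individuals at fixed channels, which
often fails: different subjects' electrodes sample different neural
sources, topographies vary, and polarity inversions across subjects can
cancel a perfectly reproducible component out of the grand average
entirely.

gTRCA replaces the fixed-channel assumption with one spatial filter
`w_a` *per subject*, chosen jointly so the projected single-trial time
courses `y_a(k) = w_aᵀ X_a(k)` are maximally correlated across trials and
across subjects. With `S` the block matrix of average cross-trial
correlations (within-subject blocks `S_aa = Σ_{k≠l} X_a(k)X_a(l)ᵀ /
(K(K−1)τ)` on the diagonal with a factor 2, between-subject blocks
`S_ab = Σ_{k,l} X_a(k)X_b(l)ᵀ / (K_aK_bτ)` off it) and `Q` the
block-diagonal matrix of per-subject data covariances, the stacked
filters solve the Rayleigh-quotient problem

    ŵ = argmax_w (wᵀ S w)/(wᵀ Q w)   ⇔   S w = λ Q w,  wᵀQw = 1.

Eigenvalues λ (and the cohort-size-normalized `λ_A = λ/A`) measure joint
reproducibility; per-subject scalp maps are the forward patterns
`m_a = Q_a w_a`.

Because any dataset yields rank-many components, significance comes from
circular-shift surrogates of the maximum eigenvalue: **trial-based
shifting** (every trial rotated independently; null: no temporal locking
at all) and **subject-based shifting** (all of a subject's trials rotated
together; null: no locking *between* subjects). P-values use the add-one
convention `p = (1+#{null ≥ λ})/(N+1)`.

The package also provides: two-step polarity orientation (temporal or
spatial), a validation simulator (Gaussian-windowed sinusoids mixed to a
59-channel 10–20 montage over spatially correlated noise), descriptive
statistics (GMFP, Fisher-z correlation summaries with bootstrap CIs, IQR
outliers, Morlet ERSP, subject-randomization cohort comparison with
BH-FDR), and robustness analyses (trial/subject stability curves,
leave-one-out significance). See `docs/methods.md` for the full model
description and numerical choices.

## Worked example

```python
import numpy as np
from gtrca.simulate import SimulationSpec, build_dataset2
from gtrca.decomposition import fit_gtrca, component_timecourses
from gtrca.orientation import orient
from gtrca.surrogates import null_distribution, p_values

# a 5-subject, 20-trial group with one shared 10 Hz component at 125 ms,
# polarity randomized per subject (plus per-subject nuisance components)
spec = SimulationSpec(n_subjects=5, n_trials=20, sfreq=128.0,
                      tmin=-0.5, tmax=0.5, n_channels=16, lowpass_hz=40.0)
group = build_dataset2(spec, seed=7)

fit = fit_gtrca(group)                       # all rank-many components
null = null_distribution(group, "subject", n_surrogates=200, seed=1)
p = p_values(fit, null)
print("eigenvalues:", np.round(fit.eigenvalues[:4], 3))
print("threshold95:", round(null.threshold_95, 3))
print("significant:", np.flatnonzero(p <= 0.05))

view = component_timecourses(fit, group, 0)
view = view.with_signs(orient(view, "temporal").signs)
peak_ms = 1000 * group.times[np.argmax(np.abs(view.group_waveform))]
print("group-average peak at %.0f ms" % peak_ms)
```

Output:

```
eigenvalues: [2.861 1.129 1.082 1.036]
threshold95: 1.775
significant: [0]
group-average peak at 102 ms
```

Exactly one component exceeds the subject-based threshold — the planted
shared component; its eigenvalue (2.86) measures its joint inter-trial
and inter-subject reproducibility, and the oriented group average peaks
inside the planted 10 Hz burst centered at 125 ms (largest swing one
half-cycle before the envelope center). The per-subject nuisance
components are reproducible across trials but not subjects, so they stay
below the subject-based threshold.

A command-line interface covers the same workflows:

```bash
gtrca simulate --scenario dataset2 --seed 7 --subjects 5 --trials 20 --out sim.h5
gtrca fit sim.h5 --out fit.h5
gtrca surrogate sim.h5 --mode subject --n-surrogates 500 --seed 1 --out null.h5
gtrca report fit.h5 --null null.h5 --out report.txt
```

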