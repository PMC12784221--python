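# Methods

## The decomposition

Let `X_a(k) ∈ R^{n_a×τ}` be the `k`-th artifact-cleaned epoch of subject
`a` (`a = 1..A`, `k = 1..K_a`), after concatenating all of a subject's
epochs along time and z-scoring each channel over the concatenation
(`T_a = K_a·τ` samples). Component waveforms are therefore in normalized
units (n.u.), not volts.

The reproducibility matrix `S` is a block matrix over subjects:

* off-diagonal blocks, the inter-subject reproducibility,
  `S_ab = (1/(K_a K_b τ)) Σ_{k,l} X_a(k) X_b(l)ᵀ`;
* diagonal blocks, the inter-trial reproducibility,
  `S_aa = (1/(K_a(K_a−1) τ)) Σ_{k≠l} X_a(k) X_a(l)ᵀ`, entering `S` with a
  factor 2.

With `Q = blockdiag(Q_a)`, `Q_a = X_a X_aᵀ / T_a` the per-subject data
covariance, the stacked spatial filters `w = (w_1, …, w_A)` solve

    ŵ = argmax_w (wᵀ S w) / (wᵀ Q w),

the generalized symmetric eigenvalue problem `S w = λ Q w` with the
normalization `wᵀ Q w = 1`. Eigenvalues measure joint within/between
subject reproducibility; because λ grows linearly with the cohort size,
`λ_A = λ/A` is reported alongside. Per-subject component time courses are
`y_a(k) = w_aᵀ X_a(k)` and scalp maps (forward patterns) are
`m_a = Q_a w_a`. The equal-`n`/equal-`K` notation is relaxed throughout:
denominators use `K_a K_b` and `K_a(K_a−1)`, and the block layout carries
per-subject offsets.

### Numerical path

`S_aa` and `S_ab` are computed with the sum-of-trials identities
(`Σ_{k≠l} X(k)X(l)ᵀ = RRᵀ − Σ_k X(k)X(k)ᵀ`, `R = Σ_k X(k)`), which are
O(K) and agree with the literal double loops to 1e−12 (tested).

Average-referenced, ICA-cleaned EEG makes `Q_a` rank-deficient, so the
problem is solved in a per-subject reduced space: eigendirections of `Q_a`
are retained up to a configurable variance fraction (default 0.999, with
directions below 1e−12 of the leading eigenvalue always dropped), the
reduced data are whitened so `Q` becomes the identity, and one ordinary
symmetric `eigh` yields all rank-many components. Filters are mapped back
to channel space through the whitening basis; with full retention the
eigenvalues coincide with a dense solve of `eigh(S, Q)` and with a
brute-force eigensolve of `Q⁻¹S` to 1e−8 (tested). Ties and the arbitrary
eigenvector sign are fixed deterministically (first sizeable coefficient
of the first subject's filter positive). All components are returned;
deciding significance is the statistics layer's job. `A = 1` is accepted
as a degenerate single-subject fit with a warning.

## Orientation

Component polarity is arbitrary per subject. Alignment is the two-step
procedure: (1) find the extremum of the group mean (largest absolute
value over latencies in temporal mode, over channels in spatial mode) and
flip subjects whose value there opposes its sign; (2) recompute the group
mean and flip subjects negatively correlated with it. The group-level
"peak" of step 1 is read as the single global extremum of the group mean
— the only parameter-free reading. Exactly two steps are run by default;
an iterate-to-fixed-point flag exists but is off. A zero peak value or
zero correlation is a tie and keeps sign +1 with a logged warning. For
display, a final global sign makes the extremum of the early response
(default window 0–100 ms, configurable) of the group average positive.
Oriented polarities are a convention and are not interpretable as
physical EEG polarities.

## Surrogate statistics

Two circular-shift schemes build null distributions of the maximum
eigenvalue (familywise over components):

* **trial mode** — every trial shifted independently (uniform on
  `{0, …, τ−1}`; zero allowed, keeping the null exchangeable); null: no
  temporal locking at all;
* **subject mode** — all trials of a subject shifted together; null: no
  locking *between* subjects, locking within subjects preserved.

For each of N surrogates the decomposition is re-run and the maximum
eigenvalue recorded. P-values use the add-one convention
`p = (1+#{null ≥ λ})/(N+1)` (so the smallest attainable p at N = 5000 is
1/5001 ≈ 0.0002); significance is `p ≤ 0.05`. The library default is
N = 500, which keeps desk-scale runs tractable while resolving the 95%
quantile; N = 5000 is recommended for reporting.

Circular shifts leave every per-channel moment over the concatenation
unchanged, so standardization and `Q_a` are invariant in both modes, and
`S_aa` is invariant in subject mode. The surrogate engine exploits this:
it standardizes, reduces and whitens once with the real data's bases
(surrogate fits therefore share the real fit's model capacity) and per
surrogate recomputes only the trial sums and, in trial mode, the diagonal
blocks — making the preserved blocks exactly (bit-for-bit) those of the
real fit. A from-scratch refit of a materialized shifted copy agrees to
~1e−12 (summation order differs). Shifts are drawn serially from one
seeded generator, so runs are exactly reproducible; surrogate fit
failures are retried with fresh shifts up to 5 times.

## The simulator

The generator reproduces the statistical structure the method is meant to
resolve, with a parametric mixing model in place of an anatomical forward
solution (the conclusions rest on temporal-locking structure, not a
particular leadfield):

* **Sources** are sinusoids under Gaussian envelopes, `σ = duration/6`
  (≈99.7% of envelope mass inside `duration`; the width convention is a
  package choice, configurable).
* **Mixing** uses unit-norm Gaussian bumps over a shipped 59-channel
  10–20 montage (2-D positions, unit head radius). Dataset 1 anchors at
  CP3 (left central), the shared component of dataset 2 at FC4 (right
  central). Per-subject jitter of the bump center (SD 0.05 head radii)
  emulates inter-individual spatial variability.
* **Noise** is multivariate Gaussian with exponential spatial-decay
  covariance over montage distances (e-folding 0.5 head radii), low-passed
  at 60 Hz with a zero-phase 3rd-order Butterworth filter applied to the
  continuous record before segmentation. Everything is average-referenced.
* **Defaults** mirror the reference conditions: A = 10 subjects,
  K = 100 trials, 1.2 s epochs (−0.6 to 0.6 s) at 600 Hz, 59 channels.

**Scenarios.** Dataset 1 plants one 19 Hz / 250 ms component per subject
at linearly spaced latencies (margins of 0.6·duration at each epoch edge)
with per-subject random polarity fixed across trials — locking across
trials, none across subjects. Dataset 2 adds a shared 10 Hz / 300 ms
component peaking at 125 ms in every subject, polarity again random per
subject, so the grand average suppresses it by roughly `1/|mean polarity|`
while the decomposition recovers it.

**Amplitude.** No source amplitude is given for the original simulations,
so it is calibrated: the planted component accounts for a configurable
fraction of the trial-averaged evoked variance at its peak channel, where
the evoked noise floor is `σ_noise²/K` (the per-channel noise SD is
estimated from a deterministic pilot draw). The default fraction is 0.92:
since the correlation between the evoked average and the planted waveform
is the square root of the fraction, 0.92 puts that correlation at ≈0.96 —
the clean-evoked regime in which a 100-trial average visibly shows the
component, which is the regime the reference simulations display. At this
default the single-trial signal is still an order of magnitude below the
noise (≈10% of single-trial variance at the peak channel).

**What the simulator does not emulate:** realistic leadfields and volume
conduction, non-Gaussian or non-stationary noise (eye blinks, muscle,
residual stimulation artifacts), latency jitter across trials, and
amplitude variability across subjects. Passing tests therefore show that
the algorithm and its statistics behave as specified under controlled
temporal-locking structure, not that any particular real cohort will
yield the same counts.

**Calibration datasets.** Type-I-error checks need data that satisfy each
test's null *exactly*. For the trial test this is temporally white noise
(i.i.d. samples are invariant under per-trial rotation). For the subject
test, each subject receives its own component at an independent uniform
latency on a circular time axis (the waveform wraps around the epoch)
over white noise — the construction is invariant in distribution under
per-subject circular shifts, making the nominal 5% level exact rather
than approximate.

## Metrics

GMFP is the per-sample RMS over channels. Correlation summaries Fisher-z
transform Pearson r (clipping |r| at 1−1e−12 with a warning), average in
z, back-transform with tanh, and bootstrap the z vector (default 5000
resamples) for a 2.5/97.5 percentile CI. Outliers are values beyond
1.5·IQR from the quartiles, with type-7 (linear-interpolation) quartiles.
ERSP maps use Morlet wavelets (3.5 cycles, 10–50 Hz by default) with
power averaged over trials and divided per frequency by its mean over a
pre-stimulus baseline window. The two-cohort comparison permutes subject
labels (default 500 permutations), computes two-tailed add-one p-values
per time sample and controls FDR with Benjamini–Hochberg at 0.05.

## Robustness

Trial-stability curves refit on random trial subsets (without
replacement, independently per subject); subject-stability curves refit
on subject subsets, enumerating all combinations when fewer than 600
exist and sampling 600 otherwise. Refit components are matched to the
full-data components greedily by maximal |temporal correlation| of
oriented group-average waveforms (matching is sign-invariant); curves
report mean |correlation| with normal-approximation 95% bands and the
smallest size at which both temporal and spatial means reach 0.95 (the
conventional stability threshold, overridable). Leave-one-out refits the
decomposition and regenerates the subject-based null (default 500
surrogates) with each subject omitted; it requires A ≥ 3. Very small
trial counts inflate eigenvalues through poor covariance estimates, so
eigenvalue comparisons across datasets should use similar trial counts.

## Problem sizes used by the shipped validation

The end-to-end checks run the full study scale (A = 10, K = 100, 600 Hz,
59 channels, 500 surrogates per null) on three fixed seeds. Type-I-error
calibration uses 600 replicate datasets per test at A = 5, K = 20,
n = 16, τ = 128 with 100 surrogates each. Oracle equivalence uses 50
random problems with A ≤ 3, n ≤ 4, K ≤ 5, τ ≤ 32. Stability and
leave-one-out analogues run at A = 4, K = 16, n = 16, τ = 128. These
sizes are the package's own trade-off between statistical resolution and
a test suite that completes in minutes on one CPU.

## Known limitations

* The per-subject variance-fraction reduction is this package's
  regularization; other rank choices (fixed rank, shrinkage) are not
  implemented.
* No parametric approximation to the max-eigenvalue null is offered; the
  cost of a null distribution is N full refits (mitigated by the
  invariant-block engine).
* Spatial orientation and group-average maps require a shared montage;
  no interpolation to a common montage is provided.
* The CLI covers the standard workflows; programmatic use is the primary
  interface.
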