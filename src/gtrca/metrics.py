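"""Descriptive and comparative statistics for evoked responses and components.

Covers: global mean field power (GMFP); Fisher-z pairwise correlation
summaries with bootstrap confidence intervals; representativeness of a
group reference for individual signals; interquartile-range outlier
flagging; Morlet-wavelet event-related spectral perturbation (ERSP) maps;
and a subject-randomization permutation comparison of two cohorts with
Benjamini-Hochberg FDR control over time samples.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
from statsmodels.stats.multitest import multipletests

__all__ = [
    "CorrelationSummary",
    "ERSPMap",
    "gmfp",
    "pairwise_correlation_summary",
    "representativeness",
    "iqr_outliers",
    "ersp",
    "permutation_group_compare",
]

_Z_CLIP = np.arctanh(1 - 1e-12)


@dataclass
class CorrelationSummary:
    """Mean pairwise correlation with a bootstrap percentile CI.

    Pearson r values are variance-stabilized with Fisher's transform
    ``z = atanh(r)``; the point estimate is ``tanh(mean z)`` and the 95% CI
    comes from resampling the z vector with replacement and taking the
    empirical 2.5th/97.5th percentiles of the back-transformed means.
    """

    mean_r: float
    ci95: tuple[float, float]
    n_pairs: int
    bootstrap_iters: int
    seed: int | None
    r_values: np.ndarray


def gmfp(evoked: np.ndarray) -> np.ndarray:
    """Global mean field power: per-sample RMS of voltage across channels."""
    evoked = np.atleast_2d(np.asarray(evoked, dtype=float))
    return np.sqrt(np.mean(evoked**2, axis=0))


def _fisher_z(r: np.ndarray) -> np.ndarray:
    r = np.asarray(r, dtype=float)
    if np.any(np.abs(r) >= 1 - 1e-12):
        warnings.warn("|r| ~ 1 clipped before Fisher transform", stacklevel=3)
    return np.arctanh(np.clip(r, -np.tanh(_Z_CLIP), np.tanh(_Z_CLIP)))


def _summarize(r_values: np.ndarray, n_boot: int, seed: int | None) -> CorrelationSummary:
    z = _fisher_z(r_values)
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, z.size, size=(n_boot, z.size))
    boot = np.tanh(z[idx].mean(axis=1))
    lo, hi = np.percentile(boot, [2.5, 97.5])
    return CorrelationSummary(
        mean_r=float(np.tanh(z.mean())),
        ci95=(float(lo), float(hi)),
        n_pairs=int(z.size),
        bootstrap_iters=n_boot,
        seed=seed,
        r_values=np.asarray(r_values, dtype=float),
    )


def pairwise_correlation_summary(
    signals: Sequence[np.ndarray], n_boot: int = 5000, seed: int | None = None
) -> CorrelationSummary:
    """Mean Pearson correlation over all unordered signal pairs."""
    signals = [np.asarray(s, dtype=float) for s in signals]
    if len(signals) < 2:
        raise ValueError("need at least two signals")
    rs = [
        np.corrcoef(a, b)[0, 1] for a, b in combinations(signals, 2)
    ]
    return _summarize(np.array(rs), n_boot, seed)


def representativeness(
    reference: np.ndarray,
    individuals: Sequence[np.ndarray],
    n_boot: int = 5000,
    seed: int | None = None,
) -> CorrelationSummary:
    """How well a group reference correlates with each individual signal."""
    reference = np.asarray(reference, dtype=float)
    rs = [np.corrcoef(reference, np.asarray(x, dtype=float))[0, 1] for x in individuals]
    return _summarize(np.array(rs), n_boot, seed)


def iqr_outliers(values: Sequence[float]) -> np.ndarray:
    """Indices outside ``[Q1 - 1.5 IQR, Q3 + 1.5 IQR]`` (type-7 quartiles)."""
    values = np.asarray(values, dtype=float)
    if values.size < 4:
        raise ValueError("need at least 4 values for quartile-based outliers")
    q1, q3 = np.percentile(values, [25, 75])
    iqr = q3 - q1
    lo, hi = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    return np.flatnonzero((values < lo) | (values > hi))


@dataclass
class ERSPMap:
    """Event-related spectral perturbation: post/pre-stimulus power ratio."""

    freqs: np.ndarray
    times: np.ndarray
    ratio: np.ndarray  # (n_freqs, n_times), > 0
    cycles: float

    def band_spectrum(self, tmin: float, tmax: float) -> np.ndarray:
        """Average ratio per frequency inside a time window (e.g. 0-200 ms)."""
        mask = (self.times >= tmin) & (self.times <= tmax)
        return self.ratio[:, mask].mean(axis=1)


def ersp(
    trials: np.ndarray,
    sfreq: float,
    times: np.ndarray,
    freqs: np.ndarray | None = None,
    cycles: float = 3.5,
    baseline: tuple[float, float] = (-0.4, -0.1),
) -> ERSPMap:
    """Morlet-wavelet ERSP of a set of single-channel trials.

    ``trials`` is ``(n_trials, n_samples)`` — a channel's epochs or a
    component's single-trial time courses, optionally concatenated across
    subjects. Power is averaged over trials, then divided per frequency by
    its mean over the pre-stimulus ``baseline`` window.
    """
    from mne.time_frequency import tfr_array_morlet

    trials = np.asarray(trials, dtype=float)
    if trials.ndim != 2:
        raise ValueError("trials must be (n_trials, n_samples)")
    if freqs is None:
        freqs = np.arange(10.0, 51.0, 1.0)
    freqs = np.asarray(freqs, dtype=float)
    if freqs.max() >= sfreq / 2:
        raise ValueError(
            f"frequency band exceeds Nyquist ({sfreq / 2:g} Hz)"
        )
    b0, b1 = baseline
    if b0 >= 0 or b1 > 0:
        raise ValueError("baseline window must be pre-stimulus (t < 0)")
    power = tfr_array_morlet(
        trials[:, None, :], sfreq=sfreq, freqs=freqs, n_cycles=cycles,
        output="power", zero_mean=True,
    )[:, 0]  # (n_trials, n_freqs, n_times)
    mean_power = power.mean(axis=0)
    bmask = (times >= b0) & (times <= b1)
    base = mean_power[:, bmask].mean(axis=1)
    return ERSPMap(freqs=freqs, times=np.asarray(times), ratio=mean_power / base[:, None], cycles=cycles)


def permutation_group_compare(
    group_a: Sequence[np.ndarray],
    group_b: Sequence[np.ndarray],
    n_permutations: int = 500,
    seed: int | None = None,
    alpha: float = 0.05,
):
    """Subject-randomization test of a per-sample group-mean difference.

    Subjects are randomly reassigned to two surrogate groups of the
    original sizes; the two-tailed add-one rank p-value of the observed
    mean difference is computed at every time sample and thresholded at
    ``alpha`` after Benjamini-Hochberg FDR correction.

    Returns ``(p_per_sample, fdr_mask, observed_difference)``.
    """
    A = np.stack([np.asarray(x, dtype=float) for x in group_a])
    B = np.stack([np.asarray(x, dtype=float) for x in group_b])
    if A.shape[1] != B.shape[1]:
        raise ValueError("groups must share the time axis (resample first)")
    if len(A) + len(B) < 4:
        raise ValueError("need at least 4 subjects in total")
    if n_permutations < 100:
        raise ValueError("need at least 100 permutations")
    rng = np.random.default_rng(seed)
    pooled = np.concatenate([A, B], axis=0)
    na = len(A)
    obs = A.mean(axis=0) - B.mean(axis=0)
    count = np.zeros(A.shape[1])
    for _ in range(n_permutations):
        perm = rng.permutation(len(pooled))
        diff = pooled[perm[:na]].mean(axis=0) - pooled[perm[na:]].mean(axis=0)
        count += np.abs(diff) >= np.abs(obs)
    p = (1.0 + count) / (n_permutations + 1.0)
    reject, _, _, _ = multipletests(p, alpha=alpha, method="fdr_bh")
    return p, reject, obs
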