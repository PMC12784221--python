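"""Circular-shift permutation tests for gTRCA eigenvalues.

Two surrogate schemes destroy temporal locking while preserving the
spatiotemporal structure of the signals:

* **trial mode** — every trial of every subject is rotated along time by an
  independent uniform shift (all channels of a trial move together). Null
  hypothesis: no temporal locking across trials or subjects.
* **subject mode** — all trials of a subject are rotated by one common
  shift, preserving within-subject trial alignment. Null hypothesis: no
  temporal locking *between* subjects.

For each of N surrogates, the full decomposition is re-run and the maximum
eigenvalue over all components recorded; a component of the real fit is
significant when its eigenvalue falls in the upper tail of that
max-eigenvalue distribution (which controls the family-wise error over
components). P-values use the add-one convention
``p = (1 + #{null >= lambda}) / (N + 1)``.

Circular shifting leaves every per-channel moment over the concatenation
unchanged, so the standardization, the covariances ``Q_a`` (both modes) and
the within-subject blocks ``S_aa`` (subject mode) of the surrogate data are
exactly those of the real data. The engine below exploits this: it
precomputes the standardized, whitened per-subject trials once and, per
surrogate, rebuilds only the blocks a shift can change, reusing the real
fit's regularization basis (the threshold then reflects the same model
capacity as the real fit).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg

from .decomposition import GTRCAFit, regularize_subject, standardize_and_concatenate
from .epochs import EpochSet, GroupDataset

__all__ = [
    "NullDistribution",
    "circular_shift",
    "make_surrogate",
    "SurrogateEngine",
    "null_distribution",
    "p_values",
    "significant_components",
]


def circular_shift(epoch: np.ndarray, shift: int) -> np.ndarray:
    """Rotate an ``(n, tau)`` epoch along time; wrapped samples re-enter at the start."""
    tau = epoch.shape[-1]
    if not (0 <= shift < tau):
        raise ValueError(f"shift must be in [0, {tau}), got {shift}")
    return np.roll(epoch, shift, axis=-1)


def draw_shifts(group: GroupDataset, mode: str, rng: np.random.Generator) -> list[np.ndarray]:
    """Per-subject arrays of per-trial shifts implementing one surrogate."""
    tau = group.n_samples
    out = []
    for subj in group:
        K = subj.n_trials
        if mode == "trial":
            out.append(rng.integers(0, tau, size=K))
        elif mode == "subject":
            out.append(np.full(K, rng.integers(0, tau)))
        else:
            raise ValueError(f"mode must be 'trial' or 'subject', got {mode!r}")
    return out


def make_surrogate(
    group: GroupDataset, mode: str, rng: np.random.Generator
) -> GroupDataset:
    """Materialize one circularly shifted surrogate dataset.

    Mostly useful for testing; :func:`null_distribution` uses an
    algebraically equivalent fast path that avoids copying the data.
    """
    shifts = draw_shifts(group, mode, rng)
    subjects = []
    for subj, s in zip(group, shifts):
        data = np.empty_like(subj.data)
        for k in range(subj.n_trials):
            data[:, :, k] = circular_shift(subj.data[:, :, k], int(s[k]))
        subjects.append(
            EpochSet(
                data=data,
                sfreq=subj.sfreq,
                times=subj.times.copy(),
                channel_labels=list(subj.channel_labels),
                subject_id=subj.subject_id,
            )
        )
    return GroupDataset(subjects)


@dataclass
class NullDistribution:
    """Max-eigenvalue distribution of one surrogate mode."""

    mode: str
    max_eigenvalues: np.ndarray
    n_surrogates: int
    seed: int | None
    threshold_95: float = 0.0

    def __post_init__(self):
        self.max_eigenvalues = np.asarray(self.max_eigenvalues, dtype=float)
        if self.max_eigenvalues.size != self.n_surrogates:
            raise ValueError("length of max_eigenvalues must equal n_surrogates")
        self.threshold_95 = float(np.quantile(self.max_eigenvalues, 0.95))


class SurrogateEngine:
    """Precomputed workspace for fast surrogate refits.

    Holds, per subject and in the real fit's whitened reduced space: the
    standardized trials, their sum over trials, and the per-trial Gram sum
    (the latter two make every S block O(K) per surrogate via the
    sum-of-trials identities).
    """

    def __init__(self, group: GroupDataset, variance_fraction: float = 0.999):
        self.tau = group.n_samples
        self.A = group.n_subjects
        self.mode_cache: dict = {}
        self.trials = []       # (K, r, tau) whitened
        self.trial_sums = []   # (r, tau)
        self.grams = []        # (r, r) sum_k X(k) X(k)^T
        self.within = []       # S_aa of the real data (reduced space)
        for subj in group:
            za = standardize_and_concatenate(subj)
            U, red, evals, _ = regularize_subject(za, variance_fraction)
            red = np.ascontiguousarray(red / np.sqrt(evals)[None, :, None])
            K, r, _ = red.shape
            R = red.sum(axis=0)
            flat = red.transpose(1, 0, 2).reshape(r, K * self.tau)
            gram = flat @ flat.T
            self.trials.append(red)
            self.trial_sums.append(R)
            self.grams.append(gram)
            self.within.append((R @ R.T - gram) / (K * (K - 1) * self.tau))
        self.sizes = [r.shape[1] for r in self.trials]
        self.offsets = np.concatenate([[0], np.cumsum(self.sizes)[:-1]]).astype(int)
        self.dim = int(np.sum(self.sizes))

    def _assemble(self, sums: list[np.ndarray], within: list[np.ndarray]) -> np.ndarray:
        S = np.zeros((self.dim, self.dim))
        for a in range(self.A):
            sa = slice(self.offsets[a], self.offsets[a] + self.sizes[a])
            S[sa, sa] = 2.0 * within[a]
            Ka = self.trials[a].shape[0]
            for b in range(a + 1, self.A):
                Kb = self.trials[b].shape[0]
                sb = slice(self.offsets[b], self.offsets[b] + self.sizes[b])
                Sab = (sums[a] @ sums[b].T) / (Ka * Kb * self.tau)
                S[sa, sb] = Sab
                S[sb, sa] = Sab.T
        return 0.5 * (S + S.T)

    def real_max_eigenvalue(self) -> float:
        S = self._assemble(self.trial_sums, self.within)
        return float(
            scipy.linalg.eigh(
                S, subset_by_index=(self.dim - 1, self.dim - 1), eigvals_only=True
            )[0]
        )

    def _shifted_sum(self, a: int, shifts: np.ndarray) -> np.ndarray:
        """Sum over trials of circularly shifted trials of subject ``a``."""
        red = self.trials[a]
        tau = self.tau
        acc = np.zeros_like(self.trial_sums[a])
        for k in range(red.shape[0]):
            s = int(shifts[k])
            if s == 0:
                acc += red[k]
            else:
                acc[:, s:] += red[k, :, : tau - s]
                acc[:, :s] += red[k, :, tau - s :]
        return acc

    def surrogate_blocks(self, shifts: list[np.ndarray], mode: str):
        """Trial sums and within-subject blocks of one surrogate (reduced space).

        In subject mode the within-subject block of the real data is reused
        unchanged — a common circular shift of all trials leaves it exactly
        invariant.
        """
        sums, within = [], []
        for a in range(self.A):
            sa = shifts[a]
            if mode == "subject":
                sums.append(np.roll(self.trial_sums[a], int(sa[0]), axis=-1))
                within.append(self.within[a])
            else:
                R = self._shifted_sum(a, sa)
                K = self.trials[a].shape[0]
                sums.append(R)
                within.append((R @ R.T - self.grams[a]) / (K * (K - 1) * self.tau))
        return sums, within

    def surrogate_max_eigenvalue(self, shifts: list[np.ndarray], mode: str) -> float:
        sums, within = self.surrogate_blocks(shifts, mode)
        S = self._assemble(sums, within)
        return float(
            scipy.linalg.eigh(
                S, subset_by_index=(self.dim - 1, self.dim - 1), eigvals_only=True
            )[0]
        )

    def null_distribution(
        self,
        mode: str,
        n_surrogates: int,
        seed: int | None = None,
        rng: np.random.Generator | None = None,
        max_retries: int = 5,
    ) -> NullDistribution:
        if n_surrogates < 100:
            raise ValueError("need at least 100 surrogates for a usable 95% quantile")
        if rng is None:
            rng = np.random.default_rng(seed)
        group_sizes = [t.shape[0] for t in self.trials]
        maxima = np.empty(n_surrogates)
        for i in range(n_surrogates):
            for attempt in range(max_retries + 1):
                shifts = _draw_shifts_from_sizes(group_sizes, self.tau, mode, rng)
                try:
                    maxima[i] = self.surrogate_max_eigenvalue(shifts, mode)
                    break
                except scipy.linalg.LinAlgError:
                    if attempt == max_retries:
                        raise
        return NullDistribution(
            mode=mode, max_eigenvalues=maxima, n_surrogates=n_surrogates, seed=seed
        )


def _draw_shifts_from_sizes(sizes, tau, mode, rng):
    out = []
    for K in sizes:
        if mode == "trial":
            out.append(rng.integers(0, tau, size=K))
        else:
            out.append(np.full(K, rng.integers(0, tau)))
    return out


def null_distribution(
    group: GroupDataset,
    mode: str,
    n_surrogates: int = 500,
    seed: int | None = None,
    variance_fraction: float = 0.999,
) -> NullDistribution:
    """Build the max-eigenvalue null for ``mode`` with ``n_surrogates`` refits."""
    if mode not in ("trial", "subject"):
        raise ValueError(f"mode must be 'trial' or 'subject', got {mode!r}")
    engine = SurrogateEngine(group, variance_fraction=variance_fraction)
    return engine.null_distribution(mode, n_surrogates, seed=seed)


def p_values(fit: GTRCAFit, null: NullDistribution) -> np.ndarray:
    """Add-one permutation p-value of every component against the max-null."""
    lam = fit.eigenvalues[:, None]
    counts = (null.max_eigenvalues[None, :] >= lam).sum(axis=1)
    return (1.0 + counts) / (null.n_surrogates + 1.0)


def significant_components(
    fit: GTRCAFit, null: NullDistribution, alpha: float = 0.05
) -> np.ndarray:
    """Indices of components with ``p <= alpha`` under the max-eigenvalue null."""
    return np.flatnonzero(p_values(fit, null) <= alpha)
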