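"""Core gTRCA decomposition.

The method searches for one spatial filter per subject such that the
projected single-trial time courses are maximally correlated across trials
(within subjects) and across subjects. Writing ``X_a(k)`` for the
standardized epoch ``k`` of subject ``a`` (channels x samples), the
reproducibility matrix ``S`` is a block matrix whose off-diagonal blocks are
average cross-trial, cross-subject correlations,

    S_ab = 1/(K_a K_b tau) * sum_{k,l} X_a(k) X_b(l)^T,

and whose diagonal blocks are average cross-trial correlations within a
subject (excluding identical trial pairs),

    S_aa = 1/(K_a (K_a - 1) tau) * sum_{k != l} X_a(k) X_a(l)^T,

entering ``S`` with a factor 2. With ``Q`` the block-diagonal matrix of
per-subject data covariances ``Q_a = X_a X_a^T / T_a`` over the
concatenation (``T_a = K_a * tau``), the stacked filters ``w`` solve the
Rayleigh-quotient problem

    w_hat = argmax_w (w^T S w) / (w^T Q w),

i.e. the generalized eigenvalue problem ``S w = lambda Q w``. Eigenvalues
measure joint inter-trial/inter-subject reproducibility; ``lambda_A =
lambda / A`` removes the linear scaling with the number of subjects ``A``.

Average-referenced, ICA-cleaned EEG makes ``Q_a`` rank deficient, so the
problem is solved after a per-subject principal-direction reduction of
``Q_a`` (retaining a configurable variance fraction) and the filters are
mapped back to channel space afterwards.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import scipy.linalg

from .epochs import EpochSet, GroupDataset
from .exceptions import (
    EigendecompositionError,
    EpochMismatchError,
    RankDeficiencyError,
    TooFewTrialsError,
    ZeroVarianceChannelError,
)

__all__ = [
    "StandardizedSubject",
    "BlockMatrices",
    "GTRCAFit",
    "ComponentView",
    "standardize_and_concatenate",
    "within_subject_block",
    "between_subject_block",
    "assemble_blocks",
    "regularize_subject",
    "solve_gevd",
    "fit_gtrca",
    "component_timecourses",
    "scalp_maps",
]


@dataclass
class StandardizedSubject:
    """One subject's epochs concatenated along time and z-scored per channel."""

    concatenated: np.ndarray  # (n_channels, K * tau)
    mean: np.ndarray          # per-channel mean removed
    std: np.ndarray           # per-channel std divided out
    n_trials: int
    n_samples: int
    subject_id: str = ""

    @property
    def n_channels(self) -> int:
        return self.concatenated.shape[0]

    @property
    def total_samples(self) -> int:
        return self.concatenated.shape[1]

    def trials(self) -> np.ndarray:
        """Standardized epochs as a ``(K, n, tau)`` view."""
        n, _ = self.concatenated.shape
        return self.concatenated.reshape(n, self.n_trials, self.n_samples).transpose(1, 0, 2)

    def trial_sum(self) -> np.ndarray:
        """Sum of standardized epochs over trials, shape ``(n, tau)``."""
        n = self.n_channels
        return self.concatenated.reshape(n, self.n_trials, self.n_samples).sum(axis=1)

    def covariance(self) -> np.ndarray:
        """``Q_a = X X^T / T`` over the concatenation."""
        Z = self.concatenated
        return (Z @ Z.T) / Z.shape[1]


def standardize_and_concatenate(epochs: EpochSet) -> StandardizedSubject:
    """Concatenate all epochs along time and z-score each channel.

    The recorded affine transform (per-channel mean/std) defines the
    standardized per-trial matrices used by every downstream block
    computation.

    Raises
    ------
    TooFewTrialsError
        Fewer than two trials.
    ZeroVarianceChannelError
        A channel is constant over the concatenation.
    """
    n, tau, K = epochs.data.shape
    if K < 2:
        raise TooFewTrialsError(
            f"subject {epochs.subject_id!r}: need at least 2 trials, got {K}"
        )
    # (n, tau, K) -> trials consecutive along time: (n, K*tau)
    X = epochs.data.transpose(0, 2, 1).reshape(n, K * tau)
    mean = X.mean(axis=1)
    std = X.std(axis=1)
    dead = np.flatnonzero(std == 0)
    if dead.size:
        labels = [epochs.channel_labels[i] for i in dead]
        raise ZeroVarianceChannelError(epochs.subject_id, labels)
    Z = (X - mean[:, None]) / std[:, None]
    return StandardizedSubject(
        concatenated=Z, mean=mean, std=std, n_trials=K, n_samples=tau,
        subject_id=epochs.subject_id,
    )


def within_subject_block(subject: StandardizedSubject) -> np.ndarray:
    """Average cross-trial correlation matrix of one subject (``S_aa``).

    Computed with the sum-of-trials identity
    ``sum_{k != l} X(k) X(l)^T = R R^T - sum_k X(k) X(k)^T`` with
    ``R = sum_k X(k)``, which matches the literal double loop to machine
    precision and is O(K) instead of O(K^2) in trial count.
    """
    K, tau = subject.n_trials, subject.n_samples
    if K < 2:
        raise TooFewTrialsError("within-subject reproducibility undefined for K < 2")
    R = subject.trial_sum()
    Z = subject.concatenated
    gram = Z @ Z.T  # sum_k X(k) X(k)^T over the concatenation
    return (R @ R.T - gram) / (K * (K - 1) * tau)


def between_subject_block(
    subj_a: StandardizedSubject, subj_b: StandardizedSubject
) -> np.ndarray:
    """Average cross-trial correlation between two subjects (``S_ab``).

    Generalizes the equal-trial-count denominator ``1/K^2`` to
    ``1/(K_a K_b)`` when trial counts differ.
    """
    if subj_a.n_samples != subj_b.n_samples:
        raise EpochMismatchError(
            f"subjects {subj_a.subject_id!r}/{subj_b.subject_id!r} differ in epoch length"
        )
    tau = subj_a.n_samples
    Ra = subj_a.trial_sum()
    Rb = subj_b.trial_sum()
    return (Ra @ Rb.T) / (subj_a.n_trials * subj_b.n_trials * tau)


@dataclass
class BlockMatrices:
    """Full reproducibility matrix ``S`` and block-diagonal covariance ``Q``.

    Diagonal blocks of ``S`` carry the factor 2; ``block_offsets`` gives the
    start row/column of each subject (channel counts may differ).
    """

    S: np.ndarray
    Q: np.ndarray
    block_offsets: list[int]
    q_blocks: list[np.ndarray] = field(default_factory=list)
    subjects: list[StandardizedSubject] = field(default_factory=list)

    @property
    def dim(self) -> int:
        return self.S.shape[0]

    def slices(self) -> list[slice]:
        ends = self.block_offsets[1:] + [self.dim]
        return [slice(o, e) for o, e in zip(self.block_offsets, ends)]


def assemble_blocks(group: GroupDataset) -> BlockMatrices:
    """Standardize every subject and assemble ``S`` and ``Q`` in channel space."""
    std = [standardize_and_concatenate(s) for s in group]
    sizes = [s.n_channels for s in std]
    offsets = list(np.concatenate([[0], np.cumsum(sizes)[:-1]]).astype(int))
    dim = int(np.sum(sizes))
    S = np.zeros((dim, dim))
    Q = np.zeros((dim, dim))
    sl = []
    ends = offsets[1:] + [dim]
    sl = [slice(o, e) for o, e in zip(offsets, ends)]
    q_blocks = []
    for a, za in enumerate(std):
        Saa = within_subject_block(za)
        S[sl[a], sl[a]] = 2.0 * Saa
        Qa = za.covariance()
        Q[sl[a], sl[a]] = Qa
        q_blocks.append(Qa)
        for b in range(a + 1, len(std)):
            Sab = between_subject_block(za, std[b])
            S[sl[a], sl[b]] = Sab
            S[sl[b], sl[a]] = Sab.T
    S = 0.5 * (S + S.T)
    return BlockMatrices(S=S, Q=Q, block_offsets=offsets, q_blocks=q_blocks, subjects=std)


def regularize_subject(
    subject: StandardizedSubject, variance_fraction: float = 0.999
):
    """Principal-direction reduction of a subject's covariance.

    Returns the orthonormal basis ``U_r`` (channels x rank) of leading
    eigenvectors of ``Q_a`` retaining at least ``variance_fraction`` of
    total variance (directions below numerical rank are always dropped),
    together with the reduced trial array ``(K, r, tau)``. S/Q blocks formed
    from the reduced data live in this basis; filters solved there are
    mapped back to channel space through it.
    """
    if not (0.0 < variance_fraction <= 1.0):
        raise ValueError("variance_fraction must be in (0, 1]")
    Qa = subject.covariance()
    evals, evecs = np.linalg.eigh(Qa)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    total = evals.sum()
    # numerical-rank floor, then the variance-fraction criterion
    keep = evals > max(evals[0], 0.0) * 1e-12
    rank = int(np.searchsorted(np.cumsum(evals) / total, variance_fraction) + 1)
    rank = min(rank, int(keep.sum()))
    if rank < 1:
        raise RankDeficiencyError(
            f"subject {subject.subject_id!r}: no directions retained"
        )
    basis = evecs[:, :rank]
    reduced = np.matmul(basis.T[None, :, :], subject.trials())  # (K, r, tau)
    return basis, reduced, evals[:rank], total


@dataclass
class GTRCAFit:
    """Result of a gTRCA decomposition.

    ``filters[a]`` is the ``(n_channels_a, n_components)`` matrix of the
    subject's spatial filters in channel space; column ``j`` across subjects
    forms the stacked eigenvector of component ``j``, scaled so that
    ``w^T Q w = 1``. ``eigenvalues`` are sorted descending and
    ``normalized_eigenvalues`` are ``lambda / A``.
    """

    eigenvalues: np.ndarray
    normalized_eigenvalues: np.ndarray
    filters: list[np.ndarray]
    regularization: list[dict]
    n_components: int
    subject_ids: list[str]
    channel_labels: list[list[str]]
    times: np.ndarray
    sfreq: float
    q_blocks: list[np.ndarray] = field(default_factory=list)
    variance_fraction: float = 1.0

    @property
    def n_subjects(self) -> int:
        return len(self.filters)

    def stacked_filter(self, j: int) -> np.ndarray:
        return np.concatenate([W[:, j] for W in self.filters])


def _sign_fix(filters: list[np.ndarray]) -> None:
    """Deterministic per-component sign: first subject's first sizeable
    coefficient is positive (component signs are arbitrary anyway)."""
    W0 = filters[0]
    for j in range(W0.shape[1]):
        col = np.concatenate([W[:, j] for W in filters])
        nz = np.flatnonzero(np.abs(col) > 1e-12 * np.abs(col).max())
        if nz.size and col[nz[0]] < 0:
            for W in filters:
                W[:, j] *= -1.0


def solve_gevd(blocks: BlockMatrices) -> GTRCAFit:
    """Solve ``S w = lambda Q w`` directly in the space of ``blocks``.

    Requires ``Q`` positive definite in that space (use
    :func:`fit_gtrca` for rank-deficient data, which reduces per subject
    first). Eigenvectors are scaled so ``w^T Q w = 1``.
    """
    try:
        evals, evecs = scipy.linalg.eigh(blocks.S, blocks.Q)
    except scipy.linalg.LinAlgError as exc:
        raise RankDeficiencyError(
            "Q is singular; regularize (see fit_gtrca variance_fraction)"
        ) from exc
    if not np.all(np.isfinite(evals)):
        raise EigendecompositionError(
            "non-finite eigenvalues; check the regularization settings"
        )
    order = np.argsort(evals)[::-1]
    evals = evals[order]
    evecs = evecs[:, order]  # scipy returns w^T Q w = 1 normalization
    A = len(blocks.block_offsets)
    filters = [evecs[s, :].copy() for s in blocks.slices()]
    _sign_fix(filters)
    subj = blocks.subjects
    return GTRCAFit(
        eigenvalues=evals,
        normalized_eigenvalues=evals / A,
        filters=filters,
        regularization=[
            {"rank": W.shape[0], "variance_fraction": 1.0} for W in filters
        ],
        n_components=evals.size,
        subject_ids=[s.subject_id for s in subj] if subj else [str(a) for a in range(A)],
        channel_labels=[[f"ch{i:02d}" for i in range(W.shape[0])] for W in filters],
        times=np.array([]),
        sfreq=0.0,
        q_blocks=list(blocks.q_blocks),
        variance_fraction=1.0,
    )


def fit_gtrca(group: GroupDataset, variance_fraction: float = 0.999) -> GTRCAFit:
    """Fit gTRCA to a group of subjects.

    Standardizes each subject, reduces each covariance to its leading
    principal directions (``variance_fraction``), whitens, assembles the
    reproducibility matrix in the reduced space and solves the resulting
    ordinary symmetric eigenvalue problem. All rank-many components are
    returned; deciding which are significant is the job of the surrogate
    statistics.
    """
    if group.n_subjects < 2:
        warnings.warn(
            "single-subject fit: S reduces to the within-subject block "
            "(plain task-related component analysis); group statistics need A >= 2",
            stacklevel=2,
        )
    std = [standardize_and_concatenate(s) for s in group]
    tau = group.n_samples
    A = group.n_subjects

    bases = []        # whitening bases, channel space -> reduced space
    reduced = []      # (K, r, tau) per subject
    reginfo = []
    for za in std:
        U, red, evals, total = regularize_subject(za, variance_fraction)
        white = U / np.sqrt(evals)[None, :]   # n x r, maps Q_a to identity
        red = red / np.sqrt(evals)[None, :, None]
        bases.append(white)
        reduced.append(np.ascontiguousarray(red))
        reginfo.append(
            {"rank": int(evals.size), "variance_fraction": float(evals.sum() / total)}
        )

    S = _assemble_whitened(reduced, tau)
    try:
        evals, evecs = np.linalg.eigh(S)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - defensive
        raise EigendecompositionError(str(exc)) from exc
    if not np.all(np.isfinite(evals)):
        raise EigendecompositionError(
            "non-finite eigenvalues; check the regularization settings"
        )
    order = np.argsort(evals)[::-1]
    evals = evals[order]
    evecs = evecs[:, order]

    sizes = [r.shape[1] for r in reduced]
    offsets = np.concatenate([[0], np.cumsum(sizes)[:-1]]).astype(int)
    filters = []
    for a, (B, off, r) in enumerate(zip(bases, offsets, sizes)):
        filters.append(B @ evecs[off : off + r, :])
    _sign_fix(filters)

    return GTRCAFit(
        eigenvalues=evals,
        normalized_eigenvalues=evals / A,
        filters=filters,
        regularization=reginfo,
        n_components=evals.size,
        subject_ids=[s.subject_id for s in group],
        channel_labels=[list(s.channel_labels) for s in group],
        times=group.times.copy(),
        sfreq=group.sfreq,
        q_blocks=[za.covariance() for za in std],
        variance_fraction=variance_fraction,
    )


def _assemble_whitened(reduced: list[np.ndarray], tau: int) -> np.ndarray:
    """S in the per-subject whitened spaces (where Q is the identity)."""
    sizes = [r.shape[1] for r in reduced]
    offsets = np.concatenate([[0], np.cumsum(sizes)[:-1]]).astype(int)
    dim = int(np.sum(sizes))
    S = np.zeros((dim, dim))
    sums = [r.sum(axis=0) for r in reduced]  # (r, tau)
    for a, red in enumerate(reduced):
        K, r, _ = red.shape
        R = sums[a]
        flat = red.transpose(1, 0, 2).reshape(r, K * tau)
        gram = flat @ flat.T
        Saa = (R @ R.T - gram) / (K * (K - 1) * tau)
        sa = slice(offsets[a], offsets[a] + sizes[a])
        S[sa, sa] = 2.0 * Saa
        for b in range(a + 1, len(reduced)):
            Kb = reduced[b].shape[0]
            Sab = (R @ sums[b].T) / (K * Kb * tau)
            sb = slice(offsets[b], offsets[b] + sizes[b])
            S[sa, sb] = Sab
            S[sb, sa] = Sab.T
    return 0.5 * (S + S.T)


@dataclass
class ComponentView:
    """Per-subject time courses, average waveforms and scalp maps of one component.

    ``signs`` holds the per-subject orientation (+/-1, all +1 before
    orientation). Group averages honor the signs. Waveforms are in
    normalized units (the standardized-channel scale).
    """

    component: int
    timecourses: list[np.ndarray]     # per subject, (K, tau)
    waveforms: np.ndarray             # (A, tau) trial averages
    maps: list[np.ndarray]            # per subject, (n_a,)
    times: np.ndarray
    signs: np.ndarray                 # (A,) in {-1, +1}
    channel_labels: list[list[str]]
    subject_ids: list[str]

    @property
    def n_subjects(self) -> int:
        return self.waveforms.shape[0]

    def oriented_waveforms(self) -> np.ndarray:
        return self.signs[:, None] * self.waveforms

    @property
    def group_waveform(self) -> np.ndarray:
        return self.oriented_waveforms().mean(axis=0)

    @property
    def group_map(self) -> np.ndarray | None:
        """Group-average scalp map; None unless all subjects share labels."""
        first = self.channel_labels[0]
        if any(lbl != first for lbl in self.channel_labels):
            return None
        M = np.stack([s * m for s, m in zip(self.signs, self.maps)])
        return M.mean(axis=0)

    def with_signs(self, signs: np.ndarray) -> "ComponentView":
        signs = np.asarray(signs, dtype=float)
        if not np.all(np.isin(signs, (-1.0, 1.0))):
            raise ValueError("signs must be +/-1")
        return ComponentView(
            component=self.component,
            timecourses=self.timecourses,
            waveforms=self.waveforms,
            maps=self.maps,
            times=self.times,
            signs=signs,
            channel_labels=self.channel_labels,
            subject_ids=self.subject_ids,
        )


def component_timecourses(
    fit: GTRCAFit, group: GroupDataset, j: int
) -> ComponentView:
    """Project standardized epochs onto component ``j``: ``y_a(k) = w_a^T X_a(k)``."""
    if not (0 <= j < fit.n_components):
        raise IndexError(f"component {j} out of range (n_components={fit.n_components})")
    tcs = []
    avgs = []
    for a, subj in enumerate(group):
        za = standardize_and_concatenate(subj)
        w = fit.filters[a][:, j]
        y = np.einsum("n,knt->kt", w, za.trials())
        tcs.append(y)
        avgs.append(y.mean(axis=0))
    return ComponentView(
        component=j,
        timecourses=tcs,
        waveforms=np.stack(avgs),
        maps=scalp_maps(fit, j),
        times=fit.times if fit.times.size else group.times,
        signs=np.ones(group.n_subjects),
        channel_labels=[list(s.channel_labels) for s in group],
        subject_ids=[s.subject_id for s in group],
    )


def scalp_maps(fit: GTRCAFit, j: int) -> list[np.ndarray]:
    """Per-subject forward patterns ``m_a = Q_a w_a`` in channel space."""
    if not (0 <= j < fit.n_components):
        raise IndexError(f"component {j} out of range")
    return [Q @ W[:, j] for Q, W in zip(fit.q_blocks, fit.filters)]
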