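"""In-memory containers for epoched multichannel evoked-potential data.

An :class:`EpochSet` holds one subject's artifact-cleaned epochs as a dense
``channels x samples x trials`` array together with the sampling rate, the
epoch time axis (seconds, stimulus at t=0 by convention) and channel labels.
A :class:`GroupDataset` is an ordered collection of subjects sharing the
epoch length and sampling rate; channel and trial counts may differ between
subjects.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np

from .exceptions import EpochMismatchError


@dataclass
class EpochSet:
    """Cleaned epochs of a single subject.

    Parameters
    ----------
    data
        Array of shape ``(n_channels, n_samples, n_trials)``. Units are
        whatever the recording used (volts or normalized units); the
        decomposition standardizes each channel anyway.
    sfreq
        Sampling frequency in Hz.
    times
        Relative latencies in seconds, length ``n_samples``, uniformly
        spaced at ``1/sfreq``.
    channel_labels
        One label per channel.
    subject_id
        Free-form identifier.
    """

    data: np.ndarray
    sfreq: float
    times: np.ndarray
    channel_labels: list[str] = field(default_factory=list)
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        self.times = np.asarray(self.times, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError(
                f"data must be (n_channels, n_samples, n_trials); got shape {self.data.shape}"
            )
        if not np.all(np.isfinite(self.data)):
            raise ValueError(f"subject {self.subject_id!r}: non-finite values in data")
        if self.sfreq <= 0:
            raise ValueError("sfreq must be positive")
        n, tau, _ = self.data.shape
        if self.times.shape != (tau,):
            raise ValueError("times must have one entry per sample")
        dt = np.diff(self.times)
        if tau > 1 and not np.allclose(dt, 1.0 / self.sfreq, rtol=1e-6, atol=1e-9):
            raise ValueError("times must be uniformly spaced at 1/sfreq and increasing")
        if not self.channel_labels:
            self.channel_labels = [f"ch{i:02d}" for i in range(n)]
        if len(self.channel_labels) != n:
            raise ValueError("one channel label per channel required")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def n_trials(self) -> int:
        return self.data.shape[2]

    def copy(self) -> "EpochSet":
        return EpochSet(
            data=self.data.copy(),
            sfreq=self.sfreq,
            times=self.times.copy(),
            channel_labels=list(self.channel_labels),
            subject_id=self.subject_id,
        )


class GroupDataset:
    """Ordered collection of subjects sharing the epoch grid.

    Group fitting requires at least two subjects; a single subject is
    accepted (the decomposition then degenerates to the single-subject
    variant) but group statistics refuse it.
    """

    def __init__(self, subjects: Sequence[EpochSet]):
        subjects = list(subjects)
        if not subjects:
            raise ValueError("GroupDataset needs at least one subject")
        tau = subjects[0].n_samples
        sfreq = subjects[0].sfreq
        offenders = [
            s.subject_id
            for s in subjects
            if s.n_samples != tau or not np.isclose(s.sfreq, sfreq)
        ]
        if offenders:
            raise EpochMismatchError(
                f"subjects {offenders} do not share the epoch length/sampling rate "
                f"(expected tau={tau}, sfreq={sfreq})"
            )
        self.subjects = subjects

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    @property
    def n_samples(self) -> int:
        return self.subjects[0].n_samples

    @property
    def sfreq(self) -> float:
        return self.subjects[0].sfreq

    @property
    def times(self) -> np.ndarray:
        return self.subjects[0].times

    def __len__(self) -> int:
        return len(self.subjects)

    def __iter__(self) -> Iterator[EpochSet]:
        return iter(self.subjects)

    def __getitem__(self, idx) -> EpochSet:
        return self.subjects[idx]

    def shared_channel_labels(self) -> bool:
        """True when all subjects carry identical channel label lists."""
        first = self.subjects[0].channel_labels
        return all(s.channel_labels == first for s in self.subjects)

    def copy(self) -> "GroupDataset":
        return GroupDataset([s.copy() for s in self.subjects])
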