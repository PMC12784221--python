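"""Readers and writers for epoch containers, fits and null distributions.

The canonical on-disk format is a portable HDF5 container with one group
per subject::

    /subjects/<id>/data            float64, (n_channels, n_samples, n_trials)
    /subjects/<id>/sfreq
    /subjects/<id>/times
    /subjects/<id>/channel_labels
    /subjects/<id>/subject_id
    /subject_order                 preserves group ordering

Adapters normalize epoched FIF and EEGLAB .set files (one subject per
file, read through mne) to the same in-memory types. Subjects must share
the epoch length and sampling rate; a polyphase resampling hook equalizes
mixed rates on request.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from fractions import Fraction
from pathlib import Path
from typing import Sequence

import h5py
import numpy as np
import scipy.signal

from .decomposition import GTRCAFit
from .epochs import EpochSet, GroupDataset
from .exceptions import EpochMismatchError, UnknownFormatError
from .surrogates import NullDistribution

__all__ = [
    "RunConfig",
    "read_epochs",
    "write_group",
    "read_group",
    "write_fit",
    "read_fit",
    "write_null",
    "read_null",
    "resample_epochs",
]


@dataclass
class RunConfig:
    """Resolved configuration of a run; written beside every artifact."""

    input_paths: list[str] = field(default_factory=list)
    variance_fraction: float = 0.999
    surrogate_mode: str = "subject"
    n_surrogates: int = 500
    orientation_mode: str = "temporal"
    convention_window: tuple[float, float] = (0.0, 0.1)
    seed: int | None = None
    output_dir: str = "."

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)

    def hash(self) -> str:
        return hashlib.sha256(self.to_json().encode()).hexdigest()[:16]

    def write(self, path) -> None:
        Path(path).write_text(self.to_json() + "\n")

    @classmethod
    def read(cls, path) -> "RunConfig":
        d = json.loads(Path(path).read_text())
        d["convention_window"] = tuple(d["convention_window"])
        return cls(**d)


def write_group(group: GroupDataset, path, config: RunConfig | None = None) -> None:
    """Write a group dataset to the portable HDF5 container."""
    with h5py.File(path, "w") as f:
        f.attrs["format"] = "gtrca-epochs-v1"
        if config is not None:
            f.attrs["config_hash"] = config.hash()
            if config.seed is not None:
                f.attrs["seed"] = config.seed
        f.create_dataset(
            "subject_order",
            data=np.array([s.subject_id for s in group], dtype=h5py.string_dtype()),
        )
        root = f.create_group("subjects")
        for s in group:
            g = root.create_group(s.subject_id)
            g.create_dataset("data", data=s.data)
            g.create_dataset("sfreq", data=s.sfreq)
            g.create_dataset("times", data=s.times)
            g.create_dataset(
                "channel_labels",
                data=np.array(s.channel_labels, dtype=h5py.string_dtype()),
            )
            g.create_dataset("subject_id", data=s.subject_id)


def read_group(path) -> GroupDataset:
    """Read a group dataset from the portable HDF5 container."""
    subjects = []
    with h5py.File(path, "r") as f:
        order = [x.decode() for x in f["subject_order"][()]]
        for sid in order:
            g = f["subjects"][sid]
            subjects.append(
                EpochSet(
                    data=g["data"][()],
                    sfreq=float(g["sfreq"][()]),
                    times=g["times"][()],
                    channel_labels=[x.decode() for x in g["channel_labels"][()]],
                    subject_id=sid,
                )
            )
    return GroupDataset(subjects)


def _read_fif(path) -> EpochSet:
    import mne

    ep = mne.read_epochs(path, preload=True, verbose="error")
    data = ep.get_data(copy=True)  # (K, n, tau)
    return EpochSet(
        data=np.transpose(data, (1, 2, 0)),
        sfreq=float(ep.info["sfreq"]),
        times=ep.times.copy(),
        channel_labels=list(ep.ch_names),
        subject_id=Path(path).stem,
    )


def _read_set(path) -> EpochSet:
    import mne

    ep = mne.io.read_epochs_eeglab(path, verbose="error")
    data = ep.get_data(copy=True)
    return EpochSet(
        data=np.transpose(data, (1, 2, 0)),
        sfreq=float(ep.info["sfreq"]),
        times=ep.times.copy(),
        channel_labels=list(ep.ch_names),
        subject_id=Path(path).stem,
    )


def resample_epochs(epochs: EpochSet, sfreq: float) -> EpochSet:
    """Polyphase-resample an epoch set to a new sampling rate."""
    frac = Fraction(sfreq / epochs.sfreq).limit_denominator(1000)
    data = scipy.signal.resample_poly(
        epochs.data, frac.numerator, frac.denominator, axis=1
    )
    tau = data.shape[1]
    times = epochs.times[0] + np.arange(tau) / sfreq
    return EpochSet(
        data=data,
        sfreq=sfreq,
        times=times,
        channel_labels=list(epochs.channel_labels),
        subject_id=epochs.subject_id,
    )


def read_epochs(
    paths: str | Path | Sequence[str | Path],
    fmt: str = "auto",
    resample: bool = False,
) -> GroupDataset:
    """Read one or more epoch files into a validated group dataset.

    An HDF5 container holds a whole group; FIF/.set files hold one subject
    each and are combined in the given order. With ``resample=True``,
    mixed sampling rates are equalized to the lowest rate by polyphase
    resampling; otherwise a mismatch is an error naming the offenders.
    """
    if isinstance(paths, (str, Path)):
        paths = [paths]
    subjects: list[EpochSet] = []
    for p in paths:
        p = Path(p)
        kind = fmt
        if kind == "auto":
            suffix = p.suffix.lower()
            kind = {".h5": "hdf5", ".hdf5": "hdf5", ".fif": "fif", ".set": "set"}.get(
                suffix
            )
            if kind is None:
                raise UnknownFormatError(f"unrecognized extension {suffix!r} for {p}")
        if kind == "hdf5":
            subjects.extend(read_group(p).subjects)
        elif kind == "fif":
            subjects.append(_read_fif(p))
        elif kind == "set":
            subjects.append(_read_set(p))
        else:
            raise UnknownFormatError(f"unknown format {kind!r}")
    rates = {s.sfreq for s in subjects}
    if len(rates) > 1:
        if not resample:
            offenders = {s.subject_id: s.sfreq for s in subjects}
            raise EpochMismatchError(
                f"mixed sampling rates {offenders}; pass resample=True to equalize"
            )
        target = min(rates)
        subjects = [
            resample_epochs(s, target) if s.sfreq != target else s for s in subjects
        ]
        tau = min(s.n_samples for s in subjects)
        subjects = [
            EpochSet(
                data=s.data[:, :tau, :],
                sfreq=s.sfreq,
                times=s.times[:tau],
                channel_labels=list(s.channel_labels),
                subject_id=s.subject_id,
            )
            for s in subjects
        ]
    return GroupDataset(subjects)


def write_fit(
    fit: GTRCAFit,
    path,
    config: RunConfig | None = None,
    orientation_signs: np.ndarray | None = None,
    orientation_mode: str | None = None,
) -> None:
    """Persist a fit (eigenvalues, filters, maps, regularization metadata)."""
    with h5py.File(path, "w") as f:
        f.attrs["format"] = "gtrca-fit-v1"
        if config is not None:
            f.attrs["config_hash"] = config.hash()
            if config.seed is not None:
                f.attrs["seed"] = config.seed
        f.create_dataset("eigenvalues", data=fit.eigenvalues)
        f.create_dataset("normalized_eigenvalues", data=fit.normalized_eigenvalues)
        f.create_dataset("times", data=fit.times)
        f.attrs["sfreq"] = fit.sfreq
        f.attrs["n_components"] = fit.n_components
        f.attrs["variance_fraction"] = fit.variance_fraction
        if orientation_signs is not None:
            f.create_dataset("orientation_signs", data=np.asarray(orientation_signs))
            f.attrs["orientation_mode"] = orientation_mode or "temporal"
        f.create_dataset(
            "subject_order",
            data=np.array(fit.subject_ids, dtype=h5py.string_dtype()),
        )
        root = f.create_group("subjects")
        for a, sid in enumerate(fit.subject_ids):
            g = root.create_group(sid)
            g.create_dataset("filters", data=fit.filters[a])
            g.create_dataset("q_block", data=fit.q_blocks[a])
            g.create_dataset(
                "channel_labels",
                data=np.array(fit.channel_labels[a], dtype=h5py.string_dtype()),
            )
            g.attrs["rank"] = fit.regularization[a]["rank"]
            g.attrs["variance_fraction"] = fit.regularization[a]["variance_fraction"]


def read_fit(path) -> GTRCAFit:
    with h5py.File(path, "r") as f:
        order = [x.decode() for x in f["subject_order"][()]]
        filters, q_blocks, labels, reg = [], [], [], []
        for sid in order:
            g = f["subjects"][sid]
            filters.append(g["filters"][()])
            q_blocks.append(g["q_block"][()])
            labels.append([x.decode() for x in g["channel_labels"][()]])
            reg.append(
                {
                    "rank": int(g.attrs["rank"]),
                    "variance_fraction": float(g.attrs["variance_fraction"]),
                }
            )
        return GTRCAFit(
            eigenvalues=f["eigenvalues"][()],
            normalized_eigenvalues=f["normalized_eigenvalues"][()],
            filters=filters,
            regularization=reg,
            n_components=int(f.attrs["n_components"]),
            subject_ids=order,
            channel_labels=labels,
            times=f["times"][()],
            sfreq=float(f.attrs["sfreq"]),
            q_blocks=q_blocks,
            variance_fraction=float(f.attrs["variance_fraction"]),
        )


def write_null(null: NullDistribution, path) -> None:
    with h5py.File(path, "w") as f:
        f.attrs["format"] = "gtrca-null-v1"
        f.attrs["mode"] = null.mode
        f.attrs["n_surrogates"] = null.n_surrogates
        if null.seed is not None:
            f.attrs["seed"] = null.seed
        f.create_dataset("max_eigenvalues", data=null.max_eigenvalues)


def read_null(path) -> NullDistribution:
    with h5py.File(path, "r") as f:
        return NullDistribution(
            mode=str(f.attrs["mode"]),
            max_eigenvalues=f["max_eigenvalues"][()],
            n_surrogates=int(f.attrs["n_surrogates"]),
            seed=int(f.attrs["seed"]) if "seed" in f.attrs else None,
        )
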