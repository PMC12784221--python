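"""Synthetic evoked-EEG group datasets for validating the decomposition.

Two scenarios mirror the structure a group decomposition has to cope with:

* **dataset 1** — each of A subjects carries one Gaussian-enveloped 19 Hz
  sinusoid (250 ms), time-locked across that subject's trials but placed at
  subject-specific, linearly spaced latencies so the components barely
  overlap across subjects. Polarity is random per subject, fixed across
  trials. This violates the trial-shifting null (within-subject locking)
  while satisfying the subject-shifting null (no cross-subject locking).
* **dataset 2** — dataset 1 plus one *shared* 10 Hz sinusoid (300 ms)
  peaking at 125 ms in every subject, again with per-subject random
  polarity — so a plain grand average cancels it while the decomposition
  should recover it.

Sources are mixed to the scalp with smooth parametric topographies
(Gaussian bumps over a shipped 59-channel 10-20 montage) instead of an
anatomical forward model; the statistical structure the tests rely on is
temporal locking, not a particular leadfield. Noise is spatially correlated
Gaussian (exponential distance decay over the montage), zero-phase
low-passed at 60 Hz, and everything is average-referenced.

Defaults: A=10 subjects, K=100 trials, 1.2 s epochs (-0.6 to 0.6 s) at
600 Hz, 59 channels. Component amplitude is calibrated so the planted
component accounts for a configurable fraction (default 0.92) of the
trial-averaged evoked variance at its peak channel; at that fraction the
trial-averaged waveform at the peak channel correlates ~0.96 with the
planted waveform (the correlation is the square root of the fraction),
i.e. the component clearly dominates the evoked average as in a clean
evoked-potential recording.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import scipy.signal

from .epochs import EpochSet, GroupDataset
from .exceptions import CovarianceNotSPDError, LatencyOverflowError

__all__ = [
    "PlantedComponent",
    "SimulationSpec",
    "load_montage",
    "gaussian_sine",
    "smooth_topography",
    "correlated_noise",
    "calibrate_amplitude",
    "noise_channel_std",
    "build_dataset1",
    "build_dataset2",
    "noise_dataset",
    "calibration_dataset",
]


def load_montage() -> pd.DataFrame:
    """59-channel 10-20 montage with 2-D positions (unit head radius)."""
    ref = importlib.resources.files("gtrca.data").joinpath("montage59.csv")
    with importlib.resources.as_file(ref) as path:
        return pd.read_csv(path)


@dataclass
class PlantedComponent:
    """One source: a Gaussian-windowed sinusoid mixed to the scalp.

    ``latency`` is the envelope peak in seconds; ``None`` means
    subject-specific latencies assigned by the dataset builder.
    ``amplitude`` is in single-trial noise-SD units at the peak channel;
    ``None`` triggers calibration against the evoked noise floor.
    """

    freq: float
    duration: float
    latency: float | None
    amplitude: float | None = None
    center: str = "CP3"          # electrode name anchoring the topography
    spread: float = 0.45         # Gaussian bump width, head-radius units
    shared: bool = False         # same latency across subjects?
    evoked_fraction: float = 0.92  # calibration target when amplitude is None


@dataclass
class SimulationSpec:
    """Group-simulation geometry and noise model."""

    n_subjects: int = 10
    n_trials: int = 100
    sfreq: float = 600.0
    tmin: float = -0.6
    tmax: float = 0.6
    n_channels: int = 59
    lowpass_hz: float = 60.0
    noise_decay: float = 0.5      # spatial covariance e-folding, head radii
    topography_jitter: float = 0.05  # per-subject bump-center jitter (SD)
    white_noise: bool = False     # skip spatial correlation + filtering

    @property
    def times(self) -> np.ndarray:
        n = int(round((self.tmax - self.tmin) * self.sfreq))
        return self.tmin + np.arange(n) / self.sfreq

    @property
    def n_samples(self) -> int:
        return self.times.size


def gaussian_sine(
    freq: float,
    duration: float,
    latency: float,
    times: np.ndarray,
    wrap: bool = False,
) -> np.ndarray:
    """Sinusoid under a Gaussian envelope peaking at ``latency``.

    ``sigma = duration / 6`` puts ~99.7% of the envelope's mass inside
    ``duration``. With ``wrap=True`` the waveform is placed on a circular
    time axis (images at +/- one epoch length are added), which makes the
    construction exactly invariant under circular shifts — used by the
    calibration datasets.
    """
    sigma = duration / 6.0
    span = times[-1] - times[0] + (times[1] - times[0])

    def _one(lat):
        dt = times - lat
        return np.sin(2 * np.pi * freq * dt) * np.exp(-(dt**2) / (2 * sigma**2))

    if not wrap:
        return _one(latency)
    return _one(latency) + _one(latency - span) + _one(latency + span)


def smooth_topography(
    positions: np.ndarray,
    center: np.ndarray,
    spread: float,
) -> np.ndarray:
    """Unit-norm Gaussian bump over 2-D electrode positions."""
    d2 = ((positions - center[None, :]) ** 2).sum(axis=1)
    topo = np.exp(-d2 / (2 * spread**2))
    return topo / np.linalg.norm(topo)


def _noise_covariance(positions: np.ndarray, decay: float) -> np.ndarray:
    d = np.linalg.norm(positions[:, None, :] - positions[None, :, :], axis=-1)
    return np.exp(-d / decay) + 1e-8 * np.eye(len(positions))


def _lowpass_sos(lowpass_hz: float, sfreq: float):
    return scipy.signal.butter(3, lowpass_hz / (sfreq / 2), btype="low", output="sos")


def correlated_noise(
    n_channels: int,
    n_samples: int,
    n_trials: int,
    covariance: np.ndarray,
    lowpass_hz: float,
    sfreq: float,
    rng: np.random.Generator,
    average_reference: bool = True,
) -> np.ndarray:
    """Spatially correlated Gaussian noise, zero-phase low-passed.

    The noise is generated as one continuous record, filtered (3rd-order
    Butterworth, forward and reverse) and then cut into trials, avoiding
    per-trial filter edges. Returns ``(n_channels, n_samples, n_trials)``.
    """
    covariance = np.asarray(covariance, dtype=float)
    try:
        L = np.linalg.cholesky(covariance)
    except np.linalg.LinAlgError as exc:
        raise CovarianceNotSPDError("noise covariance is not SPD") from exc
    raw = L @ rng.standard_normal((n_channels, n_samples * n_trials))
    sos = _lowpass_sos(lowpass_hz, sfreq)
    filt = scipy.signal.sosfiltfilt(sos, raw, axis=1)
    out = filt.reshape(n_channels, n_trials, n_samples).transpose(0, 2, 1)
    if average_reference:
        out = out - out.mean(axis=0, keepdims=True)
    return np.ascontiguousarray(out)


def noise_channel_std(
    spec: SimulationSpec, seed: int = 12345, n_pilot_samples: int = 60_000
) -> float:
    """Empirical per-channel SD of the average-referenced, filtered noise.

    Deterministic pilot draw used by the amplitude calibration; returns the
    SD at the channel with the median variance (channel SDs are nearly
    uniform by construction).
    """
    rng = np.random.default_rng(seed)
    pos = load_montage()[["x", "y"]].to_numpy()[: spec.n_channels]
    if spec.white_noise:
        return 1.0
    cov = _noise_covariance(pos, spec.noise_decay)
    n_trials = max(1, n_pilot_samples // spec.n_samples)
    noise = correlated_noise(
        spec.n_channels, spec.n_samples, n_trials, cov, spec.lowpass_hz, spec.sfreq, rng
    )
    stds = noise.std(axis=(1, 2))
    return float(np.median(stds))


def calibrate_amplitude(
    waveform: np.ndarray,
    topography: np.ndarray,
    n_trials: int,
    noise_std: float,
    fraction: float = 0.5,
) -> float:
    """Amplitude so the component is ``fraction`` of evoked variance at its peak channel.

    The trial-averaged noise has variance ``noise_std**2 / K`` at every
    channel; the planted signal (identical across trials) contributes
    ``a**2 * topo_peak**2 * mean(waveform**2)`` over the epoch. Solving
    ``signal / (signal + noise) = fraction`` for ``a`` gives the returned
    amplitude.
    """
    if not (0 < fraction < 1):
        raise ValueError("fraction must be in (0, 1)")
    topo = topography - topography.mean()  # data are average-referenced
    peak = float(np.max(np.abs(topo)))
    unit_var = peak**2 * float(np.mean(waveform**2))
    target = fraction / (1 - fraction) * noise_std**2 / n_trials
    return float(np.sqrt(target / unit_var))


def _subject_noise(spec: SimulationSpec, pos: np.ndarray, rng: np.random.Generator):
    if spec.white_noise:
        return rng.standard_normal((spec.n_channels, spec.n_samples, spec.n_trials))
    cov = _noise_covariance(pos, spec.noise_decay)
    return correlated_noise(
        spec.n_channels,
        spec.n_samples,
        spec.n_trials,
        cov,
        spec.lowpass_hz,
        spec.sfreq,
        rng,
        average_reference=False,
    )


def _electrode_position(montage: pd.DataFrame, name: str) -> np.ndarray:
    row = montage[montage["name"] == name]
    if row.empty:
        raise KeyError(f"electrode {name!r} not in the shipped montage")
    return row[["x", "y"]].to_numpy()[0]


def _build(
    spec: SimulationSpec,
    components: list[PlantedComponent],
    latencies: list[np.ndarray],
    seed: int | None,
    wrap: bool = False,
):
    """Shared dataset builder.

    ``latencies[c][a]`` is the envelope peak of component ``c`` in subject
    ``a``. Returns the group plus a ground-truth dict (waveforms, latencies,
    polarities, topographies, amplitudes) for validation.
    """
    full_montage = load_montage()
    montage = full_montage.iloc[: spec.n_channels]
    pos = montage[["x", "y"]].to_numpy()
    times = spec.times
    ss = np.random.SeedSequence(seed)
    subj_seeds = ss.spawn(spec.n_subjects)
    noise_std = noise_channel_std(spec, seed=int(ss.generate_state(1)[0] % 2**31))

    truth = {
        "latencies": np.array([lat for lat in latencies]),  # (C, A)
        "polarities": np.zeros((len(components), spec.n_subjects)),
        "topographies": np.zeros((len(components), spec.n_subjects, spec.n_channels)),
        "amplitudes": np.zeros(len(components)),
        "waveforms": [],
        "times": times,
        "channel_names": list(montage["name"]),
    }

    amps = []
    for c, comp in enumerate(components):
        wf_ref = gaussian_sine(comp.freq, comp.duration, float(np.mean(latencies[c])), times, wrap=wrap)
        center = _electrode_position(full_montage, comp.center)
        topo_ref = smooth_topography(pos, center, comp.spread)
        if comp.amplitude is None:
            amps.append(
                calibrate_amplitude(
                    wf_ref, topo_ref, spec.n_trials, noise_std, comp.evoked_fraction
                )
            )
        else:
            amps.append(comp.amplitude * noise_std)
        truth["amplitudes"][c] = amps[-1]

    subjects = []
    for a in range(spec.n_subjects):
        rng = np.random.default_rng(subj_seeds[a])
        data = _subject_noise(spec, pos, rng)
        for c, comp in enumerate(components):
            pol = rng.choice([-1.0, 1.0])
            center = _electrode_position(full_montage, comp.center)
            if spec.topography_jitter > 0:
                center = center + rng.normal(0, spec.topography_jitter, size=2)
            topo = smooth_topography(pos, center, comp.spread)
            wf = gaussian_sine(comp.freq, comp.duration, float(latencies[c][a]), times, wrap=wrap)
            data += amps[c] * pol * topo[:, None, None] * wf[None, :, None]
            truth["polarities"][c, a] = pol
            truth["topographies"][c, a] = topo
        data -= data.mean(axis=0, keepdims=True)  # average reference
        subjects.append(
            EpochSet(
                data=data,
                sfreq=spec.sfreq,
                times=times,
                channel_labels=list(montage["name"]),
                subject_id=f"sim{a:02d}",
            )
        )
    for c, comp in enumerate(components):
        truth["waveforms"].append(
            np.stack(
                [
                    gaussian_sine(comp.freq, comp.duration, float(latencies[c][a]), times, wrap=wrap)
                    for a in range(spec.n_subjects)
                ]
            )
        )
    return GroupDataset(subjects), truth


def _spread_latencies(spec: SimulationSpec, duration: float) -> np.ndarray:
    """Linearly spaced per-subject latencies with envelope margins."""
    margin = 0.6 * duration
    lo, hi = spec.tmin + margin, spec.tmax - margin
    if lo >= hi:
        raise LatencyOverflowError(
            f"{spec.n_subjects} components of duration {duration}s do not fit "
            f"in the epoch [{spec.tmin}, {spec.tmax}]s"
        )
    return np.linspace(lo, hi, spec.n_subjects)


_SUBJECT_COMPONENT = PlantedComponent(
    freq=19.0, duration=0.25, latency=None, center="CP3", shared=False
)
_SHARED_COMPONENT = PlantedComponent(
    freq=10.0, duration=0.30, latency=0.125, center="FC4", shared=True
)


def build_dataset1(
    spec: SimulationSpec | None = None,
    seed: int | None = None,
    component: PlantedComponent | None = None,
    return_truth: bool = False,
):
    """Dataset 1: subject-specific components, reproducible across trials only."""
    spec = spec or SimulationSpec()
    comp = component or _SUBJECT_COMPONENT
    lats = _spread_latencies(spec, comp.duration)
    group, truth = _build(spec, [comp], [lats], seed)
    return (group, truth) if return_truth else group


def build_dataset2(
    spec: SimulationSpec | None = None,
    seed: int | None = None,
    return_truth: bool = False,
):
    """Dataset 2: dataset 1 plus a shared-latency component with random polarity."""
    spec = spec or SimulationSpec()
    c1 = _SUBJECT_COMPONENT
    c2 = _SHARED_COMPONENT
    lats1 = _spread_latencies(spec, c1.duration)
    lats2 = np.full(spec.n_subjects, c2.latency)
    group, truth = _build(spec, [c1, c2], [lats1, lats2], seed)
    return (group, truth) if return_truth else group


def noise_dataset(spec: SimulationSpec | None = None, seed: int | None = None) -> GroupDataset:
    """Pure noise: no planted components at all."""
    spec = spec or SimulationSpec()
    group, _ = _build(spec, [], [], seed)
    return group


def calibration_dataset(
    spec: SimulationSpec, mode: str, seed: int | None = None
) -> GroupDataset:
    """Data generated *under the null* of the requested surrogate test.

    ``mode='trial'`` — temporally unstructured (white) noise: no locking of
    any kind. ``mode='subject'`` — each subject carries its own circularly
    wrapped component at an independent uniform latency over white noise:
    locking across trials, none across subjects, and the construction is
    exactly invariant in distribution under per-subject circular shifts.
    """
    spec = replace(spec, white_noise=True)
    if mode == "trial":
        return noise_dataset(spec, seed)
    if mode != "subject":
        raise ValueError("mode must be 'trial' or 'subject'")
    rng = np.random.default_rng(np.random.SeedSequence(seed).generate_state(1)[0])
    span = spec.tmax - spec.tmin
    lats = spec.tmin + rng.uniform(0, span, size=spec.n_subjects)
    comp = _SUBJECT_COMPONENT
    group, _ = _build(spec, [comp], [np.asarray(lats)], seed, wrap=True)
    return group
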