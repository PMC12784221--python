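"""Synthetic-data generator: waveforms, topographies, noise, scenario builders."""

import numpy as np
import pytest

from gtrca.exceptions import CovarianceNotSPDError, LatencyOverflowError
from gtrca.simulate import (
    SimulationSpec,
    build_dataset1,
    build_dataset2,
    calibrate_amplitude,
    calibration_dataset,
    correlated_noise,
    gaussian_sine,
    load_montage,
    noise_dataset,
    smooth_topography,
)

from conftest import small_sim_spec


def test_montage_fixture():
    m = load_montage()
    assert len(m) == 59
    assert {"name", "x", "y"} <= set(m.columns)
    # positions within ~unit head radius (a touch outside for the lowest ring)
    assert np.hypot(m.x, m.y).max() < 1.3


# ------------------------------------------------------------ waveform

def test_gaussian_sine_closed_form_values():
    times = np.linspace(-0.5, 0.5, 1201)
    w = gaussian_sine(19.0, 0.25, 0.1, times)
    i = np.argmin(np.abs(times - 0.1))
    assert abs(w[i]) < 1e-10  # sine phase zero at the envelope peak
    env = np.exp(-((times - 0.1) ** 2) / (2 * (0.25 / 6) ** 2))
    np.testing.assert_allclose(np.abs(w), env * np.abs(np.sin(2 * np.pi * 19 * (times - 0.1))), atol=1e-12)


def test_gaussian_sine_energy_concentration():
    times = np.linspace(-0.6, 0.6, 1441)
    w = gaussian_sine(19.0, 0.25, 0.0, times)
    inside = (times >= -0.125) & (times <= 0.125)
    total = np.sum(w**2)
    assert np.sum(w[~inside] ** 2) < 0.01 * total


def test_gaussian_sine_wrap_is_circular():
    times = -0.5 + np.arange(128) / 128.0
    w = gaussian_sine(10.0, 0.3, 0.45, times, wrap=True)  # envelope crosses the edge
    rolled = np.roll(w, 64)
    w2 = gaussian_sine(10.0, 0.3, 0.45 - 0.5, times, wrap=True)
    np.testing.assert_allclose(rolled, w2, atol=1e-10)


# ---------------------------------------------------------- topography

def test_smooth_topography_limits_and_overlap(rng):
    m = load_montage()
    pos = m[["x", "y"]].to_numpy()
    # spread -> infinity: uniform map
    t = smooth_topography(pos, np.zeros(2), spread=1e6)
    np.testing.assert_allclose(t, t[0], rtol=1e-6)
    # mirrored, well-separated bumps barely overlap
    left = smooth_topography(pos, np.array([-0.6, 0.0]), spread=0.25)
    right = smooth_topography(pos, np.array([0.6, 0.0]), spread=0.25)
    assert np.corrcoef(left, right)[0, 1] < 0.3
    assert np.isclose(np.linalg.norm(left), 1.0)


# --------------------------------------------------------------- noise

def test_correlated_noise_matches_requested_covariance(rng):
    n = 12
    pos = load_montage()[["x", "y"]].to_numpy()[:n]
    d = np.linalg.norm(pos[:, None] - pos[None, :], axis=-1)
    cov = np.exp(-d / 0.5)
    # near-Nyquist cutoff: the filter is essentially transparent, so the
    # empirical covariance of many samples approaches the requested one
    noise = correlated_noise(
        n, 500, 200, cov, lowpass_hz=0.49 * 256, sfreq=256.0, rng=rng,
        average_reference=False,
    )
    emp = np.cov(noise.reshape(n, -1))
    assert np.linalg.norm(emp - cov) / np.linalg.norm(cov) < 0.05


def test_correlated_noise_spectrum_and_reference(rng):
    import scipy.signal

    n = 8
    cov = np.eye(n)
    noise = correlated_noise(n, 600, 40, cov, lowpass_hz=60.0, sfreq=600.0, rng=rng)
    np.testing.assert_allclose(noise.mean(axis=0), 0, atol=1e-10)  # avg reference
    x = noise[0].T.ravel()
    f, pxx = scipy.signal.welch(x, fs=600.0, nperseg=512)
    passband = pxx[(f > 5) & (f < 40)].mean()
    stopband = pxx[f > 90].mean()
    assert 10 * np.log10(passband / stopband) > 30


def test_correlated_noise_rejects_non_spd(rng):
    bad = np.array([[1.0, 2.0], [2.0, 1.0]])  # indefinite
    with pytest.raises(CovarianceNotSPDError):
        correlated_noise(2, 16, 2, bad, 30.0, 128.0, rng)


def test_calibrate_amplitude_scaling():
    times = np.linspace(-0.5, 0.5, 512)
    w = gaussian_sine(10, 0.3, 0.0, times)
    topo = np.zeros(8)
    topo[3] = 1.0
    a = calibrate_amplitude(w, topo, n_trials=100, noise_std=2.0, fraction=0.5)
    # doubling the noise SD doubles the amplitude; quadrupling trials halves it
    assert np.isclose(calibrate_amplitude(w, topo, 100, 4.0, 0.5), 2 * a)
    assert np.isclose(calibrate_amplitude(w, topo, 400, 2.0, 0.5), a / 2)
    with pytest.raises(ValueError):
        calibrate_amplitude(w, topo, 100, 2.0, fraction=1.0)


# ------------------------------------------------------------ builders

def test_dataset1_defaults_match_study_conditions():
    spec = SimulationSpec()
    assert (spec.n_subjects, spec.n_trials) == (10, 100)
    assert spec.sfreq == 600.0 and spec.n_samples == 720
    assert spec.n_channels == 59 and spec.lowpass_hz == 60.0


def test_dataset1_structure_and_self_check():
    spec = small_sim_spec(n_subjects=4, n_trials=30)
    group, truth = build_dataset1(spec, seed=1, return_truth=True)
    assert group.n_subjects == 4
    # planted polarities are +/-1, fixed across trials by construction
    assert set(np.unique(truth["polarities"])) <= {-1.0, 1.0}
    # trial-averaged evoked response at the peak channel tracks the planted
    # waveform (amplitude calibration puts the component well above the
    # evoked noise floor)
    for a, subj in enumerate(group):
        topo = truth["topographies"][0][a]
        topo = topo - topo.mean()
        pk = np.argmax(np.abs(topo))
        evoked = subj.data[pk].mean(axis=1)
        r = abs(np.corrcoef(evoked, truth["waveforms"][0][a])[0, 1])
        assert r > 0.9
    # distinct-latency envelopes are near-orthogonal across subjects
    W = truth["waveforms"][0]
    G = W @ W.T
    off = G - np.diag(np.diag(G))
    assert np.abs(off).max() < 0.05 * np.diag(G).min()


def test_dataset1_latency_overflow_guard():
    spec = small_sim_spec(tmin=-0.05, tmax=0.05)
    with pytest.raises(LatencyOverflowError):
        build_dataset1(spec, seed=0)


def test_dataset2_shared_component_and_reproducibility():
    spec = small_sim_spec(n_subjects=3, n_trials=10)
    g1, truth = build_dataset2(spec, seed=5, return_truth=True)
    np.testing.assert_allclose(truth["latencies"][1], 0.125)
    g2 = build_dataset2(spec, seed=5)
    for a, b in zip(g1, g2):
        np.testing.assert_array_equal(a.data, b.data)  # bit-identical rebuild
    g3 = build_dataset2(spec, seed=6)
    assert not np.array_equal(g1[0].data, g3[0].data)


def test_dataset2_grand_average_cancellation(small_dataset2):
    """Random per-subject polarity attenuates the shared component in the
    sign-ignorant grand average relative to the polarity-aligned average."""
    group, truth = small_dataset2
    pol = truth["polarities"][1]
    topo = truth["topographies"][1].mean(axis=0)
    topo = topo - topo.mean()
    pk = np.argmax(np.abs(topo))
    evoked = np.stack([s.data[pk].mean(axis=1) for s in group])
    times = group.times
    win = (times > 0.125 - 0.15) & (times < 0.125 + 0.15)
    grand = evoked.mean(axis=0)
    aligned = (pol[:, None] * evoked).mean(axis=0)
    att = np.sqrt((aligned[win] ** 2).mean() / (grand[win] ** 2).mean())
    # signal-dominated theory: attenuation ~ 1/|mean(polarity)|
    assert abs(pol.mean()) > 0  # this seed draws mixed but unbalanced signs
    expected = 1.0 / abs(pol.mean())
    assert 0.6 * expected < att < 2.0 * expected


def test_noise_and_calibration_datasets():
    spec = small_sim_spec(n_subjects=3, n_trials=8)
    g = noise_dataset(spec, seed=2)
    assert g.n_subjects == 3
    c = calibration_dataset(spec, "subject", seed=2)
    assert c.n_subjects == 3
    c2 = calibration_dataset(spec, "trial", seed=2)
    assert c2.n_subjects == 3
    with pytest.raises(ValueError):
        calibration_dataset(spec, "bogus", seed=2)
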