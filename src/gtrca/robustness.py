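"""Stability of gTRCA components under data reduction.

Three analyses quantify how much a fitted component depends on the amount
of data: refitting on random trial subsets of increasing size, refitting on
subject subsets, and a leave-one-out significance check in which the
decomposition and its subject-based null distribution are regenerated with
each subject omitted in turn.

Refit components are matched to the full-data reference greedily by maximal
absolute temporal correlation of oriented group-average waveforms (signs
are arbitrary across refits, so all bookkeeping uses |r|). A component is
conventionally called stable at the smallest size where both the mean
temporal and the mean spatial correlation with the full-data component
reach 0.95.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd

from .decomposition import GTRCAFit, component_timecourses, fit_gtrca
from .epochs import EpochSet, GroupDataset
from .orientation import orient
from .surrogates import SurrogateEngine, p_values

__all__ = [
    "StabilityCurve",
    "trial_stability",
    "subject_stability",
    "leave_one_out_significance",
]

STABILITY_THRESHOLD = 0.95


@dataclass
class StabilityCurve:
    """Mean |correlation| with the full-data component vs. subset size."""

    sizes: np.ndarray
    temporal_mean: np.ndarray
    temporal_ci95: np.ndarray   # (n_sizes, 2)
    spatial_mean: np.ndarray
    spatial_ci95: np.ndarray
    reps: np.ndarray
    component: int
    threshold: float = STABILITY_THRESHOLD

    @property
    def threshold_crossing(self) -> int | None:
        """Smallest size with both mean correlations >= the threshold."""
        ok = (self.temporal_mean >= self.threshold) & (
            self.spatial_mean >= self.threshold
        )
        idx = np.flatnonzero(ok)
        return int(self.sizes[idx[0]]) if idx.size else None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "size": self.sizes,
                "temporal_mean": self.temporal_mean,
                "temporal_lo": self.temporal_ci95[:, 0],
                "temporal_hi": self.temporal_ci95[:, 1],
                "spatial_mean": self.spatial_mean,
                "spatial_lo": self.spatial_ci95[:, 0],
                "spatial_hi": self.spatial_ci95[:, 1],
                "reps": self.reps,
            }
        )


def _reference_signature(fit: GTRCAFit, group: GroupDataset, j: int):
    """Oriented group-average waveform and scalp map of component ``j``."""
    view = component_timecourses(fit, group, j)
    if group.n_subjects < 2:
        return view.group_waveform, view.group_map
    wave = view.with_signs(orient(view, "temporal").signs).group_waveform
    gmap = view.with_signs(orient(view, "spatial").signs).group_map
    return wave, gmap


def _abs_corr(a: np.ndarray, b: np.ndarray) -> float:
    return float(abs(np.corrcoef(a, b)[0, 1]))


def _match_components(
    ref_waves: list[np.ndarray], sub_waves: list[np.ndarray]
) -> list[int]:
    """Greedy assignment of refit components to reference components."""
    remaining = list(range(len(sub_waves)))
    out = []
    for rw in ref_waves:
        scores = [_abs_corr(rw, sub_waves[i]) for i in remaining]
        best = remaining[int(np.argmax(scores))]
        out.append(best)
        remaining.remove(best)
    return out


def _compare_to_reference(
    sub_fit: GTRCAFit,
    sub_group: GroupDataset,
    ref_waves: list[np.ndarray],
    ref_maps: list[np.ndarray],
    n_track: int,
):
    n_cand = min(sub_fit.n_components, max(3 * n_track, n_track + 3))
    waves, maps = [], []
    for j in range(n_cand):
        w, m = _reference_signature(sub_fit, sub_group, j)
        waves.append(w)
        maps.append(m)
    sel = _match_components(ref_waves, waves)
    t = [_abs_corr(ref_waves[c], waves[i]) for c, i in enumerate(sel)]
    s = [_abs_corr(ref_maps[c], maps[i]) for c, i in enumerate(sel)]
    return t, s


def _curve_from_samples(sizes, tcorr, scorr, reps, component) -> StabilityCurve:
    tmean = np.array([np.mean(v) for v in tcorr])
    smean = np.array([np.mean(v) for v in scorr])

    def ci(vals):
        vals = np.asarray(vals)
        if vals.size < 2:
            return (vals.mean(), vals.mean())
        se = vals.std(ddof=1) / np.sqrt(vals.size)
        return (vals.mean() - 1.96 * se, vals.mean() + 1.96 * se)

    return StabilityCurve(
        sizes=np.asarray(sizes),
        temporal_mean=tmean,
        temporal_ci95=np.array([ci(v) for v in tcorr]),
        spatial_mean=smean,
        spatial_ci95=np.array([ci(v) for v in scorr]),
        reps=np.asarray(reps),
        component=component,
    )


def _subsample_trials(group: GroupDataset, size: int, rng) -> GroupDataset:
    subs = []
    for s in group:
        idx = np.sort(rng.choice(s.n_trials, size=size, replace=False))
        subs.append(
            EpochSet(
                data=s.data[:, :, idx],
                sfreq=s.sfreq,
                times=s.times,
                channel_labels=list(s.channel_labels),
                subject_id=s.subject_id,
            )
        )
    return GroupDataset(subs)


def trial_stability(
    group: GroupDataset,
    sizes: list[int],
    reps: int = 100,
    seed: int | None = None,
    components: list[int] | None = None,
    variance_fraction: float = 0.999,
) -> list[StabilityCurve]:
    """Refit on random trial subsets and correlate against the full fit.

    Trial subsets are drawn without replacement, independently per subject;
    at the full trial count the subset is the data itself and the
    correlation is exactly 1.
    """
    components = components or [0]
    min_k = min(s.n_trials for s in group)
    if max(sizes) > min_k:
        raise ValueError(f"sizes must not exceed the smallest trial count {min_k}")
    rng = np.random.default_rng(seed)
    full_fit = fit_gtrca(group, variance_fraction)
    refs = [_reference_signature(full_fit, group, j) for j in components]
    ref_waves = [r[0] for r in refs]
    ref_maps = [r[1] for r in refs]

    tcorr = {c: [[] for _ in sizes] for c in range(len(components))}
    scorr = {c: [[] for _ in sizes] for c in range(len(components))}
    reps_used = []
    for i, size in enumerate(sizes):
        n_rep = 1 if size == min_k else reps
        reps_used.append(n_rep)
        for _ in range(n_rep):
            sub = _subsample_trials(group, size, rng)
            sub_fit = fit_gtrca(sub, variance_fraction)
            t, s = _compare_to_reference(
                sub_fit, sub, ref_waves, ref_maps, len(components)
            )
            for c in range(len(components)):
                tcorr[c][i].append(t[c])
                scorr[c][i].append(s[c])
    return [
        _curve_from_samples(sizes, tcorr[c], scorr[c], reps_used, components[c])
        for c in range(len(components))
    ]


def subject_stability(
    group: GroupDataset,
    sizes: list[int],
    max_subsets: int = 600,
    seed: int | None = None,
    components: list[int] | None = None,
    variance_fraction: float = 0.999,
) -> list[StabilityCurve]:
    """Refit on subject subsets; exhaustive when few combinations exist.

    All ``C(A, size)`` combinations are evaluated when fewer than
    ``max_subsets``; otherwise ``max_subsets`` random subsets are drawn.
    """
    components = components or [0]
    A = group.n_subjects
    if max(sizes) > A:
        raise ValueError("subset size exceeds the number of subjects")
    rng = np.random.default_rng(seed)
    full_fit = fit_gtrca(group, variance_fraction)
    refs = [_reference_signature(full_fit, group, j) for j in components]
    ref_waves = [r[0] for r in refs]
    ref_maps = [r[1] for r in refs]

    tcorr = {c: [[] for _ in sizes] for c in range(len(components))}
    scorr = {c: [[] for _ in sizes] for c in range(len(components))}
    reps_used = []
    for i, size in enumerate(sizes):
        if comb(A, size) < max_subsets:
            subsets = list(combinations(range(A), size))
        else:
            subsets = [
                tuple(np.sort(rng.choice(A, size=size, replace=False)))
                for _ in range(max_subsets)
            ]
        reps_used.append(len(subsets))
        for idx in subsets:
            sub = GroupDataset([group[i2] for i2 in idx])
            sub_fit = fit_gtrca(sub, variance_fraction)
            t, s = _compare_to_reference(
                sub_fit, sub, ref_waves, ref_maps, len(components)
            )
            for c in range(len(components)):
                tcorr[c][i].append(t[c])
                scorr[c][i].append(s[c])
    return [
        _curve_from_samples(sizes, tcorr[c], scorr[c], reps_used, components[c])
        for c in range(len(components))
    ]


def leave_one_out_significance(
    group: GroupDataset,
    n_surrogates: int = 500,
    seed: int | None = None,
    n_components: int = 3,
    variance_fraction: float = 0.999,
) -> pd.DataFrame:
    """Refit with each subject omitted and regenerate the subject-based null.

    Returns a tidy frame with one row per (left-out subject, component):
    the component's eigenvalue, add-one p-value and significance flag.
    Requires at least 3 subjects so every reduced fit is still a group fit.
    """
    if group.n_subjects < 3:
        raise ValueError("leave-one-out needs at least 3 subjects")
    ss = np.random.SeedSequence(seed)
    child_seeds = ss.generate_state(group.n_subjects)
    rows = []
    for a in range(group.n_subjects):
        sub = GroupDataset([s for i, s in enumerate(group) if i != a])
        fit = fit_gtrca(sub, variance_fraction)
        engine = SurrogateEngine(sub, variance_fraction)
        null = engine.null_distribution(
            "subject", n_surrogates, seed=int(child_seeds[a] % 2**31)
        )
        p = p_values(fit, null)
        for j in range(min(n_components, fit.n_components)):
            rows.append(
                {
                    "left_out": group[a].subject_id,
                    "component": j,
                    "eigenvalue": fit.eigenvalues[j],
                    "p_value": p[j],
                    "significant": p[j] <= 0.05,
                }
            )
    return pd.DataFrame(rows)
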