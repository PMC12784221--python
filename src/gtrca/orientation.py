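"""Polarity alignment of gTRCA components across subjects.

Each subject's spatial filter — and hence its component time course and
scalp map — has an arbitrary sign. Averaging unaligned components across
subjects can cancel them entirely, so polarities are resolved with a
two-step procedure: (1) flip each subject whose value at the group-level
peak (the latency/channel of largest absolute group-mean value) opposes the
peak's sign; (2) recompute the group mean and flip subjects negatively
correlated with it. The procedure runs either on trial-averaged waveforms
(temporal mode) or on scalp maps (spatial mode; requires a shared montage).

The resulting polarity is a convention, not a physical EEG polarity. For
display, a final global sign can be set so that the extremum of the early
response (default 0-100 ms) of the group-average waveform is positive.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .decomposition import ComponentView

__all__ = ["OrientationResult", "orient", "apply_peak_convention"]


@dataclass
class OrientationResult:
    """Per-subject orientation signs plus the reference they were aligned to."""

    signs: np.ndarray            # (A,) +/-1
    mode: str                    # "temporal" | "spatial"
    reference: np.ndarray        # final group-average waveform or map
    convention_window: tuple[float, float] | None = None


def _subject_vectors(view: ComponentView, mode: str) -> np.ndarray:
    if mode == "temporal":
        return view.waveforms
    if mode == "spatial":
        first = view.channel_labels[0]
        if any(lbl != first for lbl in view.channel_labels):
            raise ValueError(
                "spatial orientation requires all subjects to share channel labels"
            )
        return np.stack(view.maps)
    raise ValueError(f"mode must be 'temporal' or 'spatial', got {mode!r}")


def _safe_sign(x: float, context: str) -> float:
    if x == 0:
        warnings.warn(f"zero {context}; keeping sign +1", stacklevel=3)
        return 1.0
    return float(np.sign(x))


def orient(
    view: ComponentView, mode: str = "temporal", iterate: bool = False
) -> OrientationResult:
    """Two-step polarity alignment of one component across subjects.

    With ``iterate=True`` step 2 is repeated until the signs reach a fixed
    point (off by default; the printed procedure has exactly two steps).
    """
    vecs = _subject_vectors(view, mode)
    A = vecs.shape[0]
    if A < 2:
        raise ValueError("orientation needs at least two subjects")

    # step 1: align to the sign of the group-mean extremum
    mean = vecs.mean(axis=0)
    peak = int(np.argmax(np.abs(mean)))
    peak_sign = _safe_sign(mean[peak], "group-mean peak value")
    signs = np.array(
        [_safe_sign(v[peak] * peak_sign, "peak value") for v in vecs]
    )

    # step 2: recompute the group mean, align by correlation sign
    for _ in range(100 if iterate else 1):
        ref = (signs[:, None] * vecs).mean(axis=0)
        new = np.array(
            [
                _safe_sign(np.dot(v - v.mean(), ref - ref.mean()), "correlation")
                for v in vecs
            ]
        )
        if np.array_equal(new, signs):
            signs = new
            break
        signs = new
        if not iterate:
            break

    reference = (signs[:, None] * vecs).mean(axis=0)
    return OrientationResult(signs=signs, mode=mode, reference=reference)


def apply_peak_convention(
    view: ComponentView, window: tuple[float, float] = (0.0, 0.1)
) -> ComponentView:
    """Global sign so the early-response extremum of the group average is positive.

    ``window`` is in seconds on the component time axis; applying the
    convention twice is a no-op.
    """
    t = view.times
    lo, hi = window
    mask = (t >= lo) & (t <= hi)
    if not mask.any():
        raise ValueError(f"window {window} lies outside the epoch [{t[0]}, {t[-1]}]")
    g = view.group_waveform
    seg = g[mask]
    extremum = seg[np.argmax(np.abs(seg))]
    flip = -1.0 if extremum < 0 else 1.0
    return view.with_signs(view.signs * flip)
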