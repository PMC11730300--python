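"""Integrated-gradients attribution and beat-aligned relevance aggregation.

Integrated gradients assigns each input sample a "relevance": its accumulated
gradient contribution along the straight path from a baseline input to the
actual record.  The attributions satisfy the completeness axiom (they sum to
the prediction difference f(x) - f(baseline)); the residual quadrature error
is tracked as ``completeness_gap``.  Positive relevance pushes the predicted
age up (more pronounced aging effects), negative pushes it down.

Relevance maps are normalised to [-1, 1] per record, sliced into the 650 ms
beat segments produced by :mod:`ecgaging.preprocessing`, aligned on the
R-peak, and averaged lead-wise across all beats and records.  Lead importance
is the lead-wise sum of relevance normalised across leads.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .ecg_age import AgeModel
from .preprocessing import BeatSegment, WaveformWindows, default_windows
from .synthetic import EcgRecord

__all__ = [
    "RelevanceMap",
    "AlignedRelevance",
    "LeadImportance",
    "integrated_gradients",
    "normalize_relevance",
    "beat_align",
    "lead_importance",
]

IG_STEPS_DEFAULT = 64


@dataclass
class RelevanceMap:
    values: np.ndarray  # (12, N), same shape as the record
    baseline_ref: str
    steps: int
    completeness_gap: float
    prediction: float
    baseline_prediction: float
    normalized: bool = False
    all_zero: bool = False  # set when normalisation met an all-zero map


def integrated_gradients(
    model: AgeModel,
    record: EcgRecord,
    baseline: EcgRecord | np.ndarray | None = None,
    steps: int = IG_STEPS_DEFAULT,
) -> RelevanceMap:
    """Midpoint-rule integrated gradients from ``baseline`` (default: zeros).

    attribution_i = (x_i - b_i) * (1/steps) * sum_k grad_i(b + (k-0.5)/steps * (x-b))
    """
    if steps < 1:
        raise ValueError("steps must be >= 1")
    x = record.signals
    if baseline is None:
        b = np.zeros_like(x)
        baseline_ref = "zero record"
    else:
        b = baseline.signals if isinstance(baseline, EcgRecord) else np.asarray(baseline, float)
        baseline_ref = "user baseline"
    if b.shape != x.shape:
        raise ValueError("baseline shape must match the record")

    delta = x - b
    g_sum = np.zeros_like(x)
    for k in range(1, steps + 1):
        g = model.gradient_signal(b + ((k - 0.5) / steps) * delta)
        if not np.all(np.isfinite(g)):
            raise FloatingPointError(f"non-finite gradient at integration step {k}")
        g_sum += g
    values = delta * g_sum / steps

    f_x = model.predict_signal(x)
    f_b = model.predict_signal(b)
    gap = float(abs(values.sum() - (f_x - f_b)))
    return RelevanceMap(
        values=values,
        baseline_ref=baseline_ref,
        steps=steps,
        completeness_gap=gap,
        prediction=f_x,
        baseline_prediction=f_b,
    )


def normalize_relevance(rmap: RelevanceMap) -> RelevanceMap:
    """Scale so the record-level max absolute relevance is 1; sign preserved.

    An all-zero map is returned unchanged with ``all_zero`` set.
    """
    peak = float(np.max(np.abs(rmap.values)))
    if peak == 0.0:
        return RelevanceMap(
            values=rmap.values.copy(),
            baseline_ref=rmap.baseline_ref,
            steps=rmap.steps,
            completeness_gap=rmap.completeness_gap,
            prediction=rmap.prediction,
            baseline_prediction=rmap.baseline_prediction,
            normalized=True,
            all_zero=True,
        )
    return RelevanceMap(
        values=rmap.values / peak,
        baseline_ref=rmap.baseline_ref,
        steps=rmap.steps,
        completeness_gap=rmap.completeness_gap,
        prediction=rmap.prediction,
        baseline_prediction=rmap.baseline_prediction,
        normalized=True,
    )


@dataclass
class AlignedRelevance:
    """Per-lead mean relevance curve over the 650 ms beat window."""

    curves: np.ndarray  # (12, L); sample 0 corresponds to -250 ms
    n_beats: int
    fs: float
    window_means: dict[str, np.ndarray] = field(default_factory=dict)  # name -> (12,)


def beat_align(
    maps: list[RelevanceMap],
    segments: list[list[BeatSegment]],
    fs: float,
    windows: WaveformWindows | None = None,
) -> AlignedRelevance:
    """Average normalised relevance lead-wise over all retained beats.

    ``maps`` and ``segments`` are parallel per-record lists; segments marked
    invalid by the overlap rule contribute nothing.
    """
    if len(maps) != len(segments):
        raise ValueError("maps and segments must be parallel per-record lists")
    windows = windows or default_windows()
    total = None
    count = 0
    for rmap, segs in zip(maps, segments):
        for seg in segs:
            if not seg.valid:
                continue
            sl = rmap.values[:, seg.start_sample : seg.start_sample + seg.n_samples]
            if total is None:
                total = np.zeros_like(sl)
            elif sl.shape != total.shape:
                raise ValueError("inconsistent segment lengths across records")
            total += sl
            count += 1
    if count == 0:
        raise ValueError("no retained beat segments to aggregate")
    curves = total / count
    means = {
        name: curves[:, sl].mean(axis=1) for name, sl in windows.sample_slices(fs).items()
    }
    return AlignedRelevance(curves=curves, n_beats=count, fs=fs, window_means=means)


@dataclass
class LeadImportance:
    weights: np.ndarray  # 12 nonnegative entries summing to 1
    signed: bool
    degenerate: bool = False  # all lead-sums were zero -> uniform fallback


def lead_importance(rmap: RelevanceMap, signed: bool = False) -> LeadImportance:
    """Lead-wise relevance totals normalised across leads.

    By default the absolute value of each lead-sum is taken before
    normalisation so the result is a proper distribution over leads; the
    signed variant divides raw lead-sums by their absolute total.
    """
    if not np.all(np.isfinite(rmap.values)):
        raise ValueError("relevance map contains non-finite values")
    sums = rmap.values.sum(axis=1)
    mags = sums if signed else np.abs(sums)
    total = float(np.abs(sums).sum())
    if total == 0.0:
        return LeadImportance(weights=np.full(12, 1.0 / 12.0), signed=signed, degenerate=True)
    return LeadImportance(weights=mags / total, signed=signed)
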