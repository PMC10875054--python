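"""Detector evaluation against labeled events.

Because different detectors filter in different bands, detected and reference
event boundaries rarely coincide sample-for-sample.  Matching is therefore by
temporal overlap: a detected event is a true positive if it overlaps some
reference SO by at least half of the detected event's duration; a reference
non-SO with no such overlapping detection is a true negative; a reference SO
never matched is a false negative.  Matching is one-to-one and greedy by
overlap size.  Balanced accuracy is the mean of sensitivity and specificity:

    BAcc = 0.5 * (TP/(TP+FN) + TN/(TN+FP))

Inter-rater agreement is the fraction of events two raters label identically.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .exceptions import InsufficientDataError, ParameterError, ValidationError
from .io import EEGRecording, Hypnogram, LabeledEvent

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class EvaluationCounts:
    """TP / FP / TN / FN tallies from overlap matching."""

    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "tn", "fn"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class AgreementCounts:
    """Concordance tallies between two raters."""

    so_both: int
    nonso_both: int
    events_total: int

    def __post_init__(self) -> None:
        if min(self.so_both, self.nonso_both, self.events_total) < 0:
            raise ValidationError("agreement counts must be >= 0")
        if self.so_both + self.nonso_both > self.events_total:
            raise ValidationError("concordant counts exceed total")


def _overlap(a_start: int, a_end: int, b_start: int, b_end: int) -> int:
    return max(0, min(a_end, b_end) - max(a_start, b_start))


def match_events(
    detected: list,
    reference: list[LabeledEvent],
    min_overlap: float = 0.5,
    denominator: str = "decided",
) -> EvaluationCounts:
    """Overlap-match detections against a labeled reference set.

    Parameters
    ----------
    detected
        Detected events (any objects with ``channel``, ``start_sample``,
        ``end_sample``).
    reference
        Labeled events; labels ``SO`` and ``nonSO`` participate, ``unlabeled``
        entries are ignored.
    min_overlap
        Overlap fraction required for a match (default 0.5).
    denominator
        ``"decided"`` — the overlap fraction is measured against the duration
        of the event whose status is being decided (detected-event duration
        for TP/FP, reference duration for the TN screen); ``"iou"`` —
        intersection over union for both directions.

    Returns
    -------
    EvaluationCounts
        With TP + FN equal to the number of reference SOs.
    """
    if denominator not in ("decided", "iou"):
        raise ParameterError(f"unknown overlap denominator {denominator!r}")
    if not 0 < min_overlap <= 1:
        raise ParameterError("min_overlap must be in (0, 1]")

    ref_so = [e for e in reference if e.label == "SO"]
    ref_non = [e for e in reference if e.label == "nonSO"]

    def frac(det, ref) -> float:
        if det.channel != ref.channel:
            return 0.0
        inter = _overlap(det.start_sample, det.end_sample, ref.start_sample, ref.end_sample)
        if inter == 0:
            return 0.0
        if denominator == "iou":
            union = (det.end_sample - det.start_sample) + (
                ref.end_sample - ref.start_sample
            ) - inter
            return inter / union
        return inter / (det.end_sample - det.start_sample)

    # candidate (detected, reference-SO) pairs above threshold, greedy by overlap
    pairs = []
    for di, det in enumerate(detected):
        for ri, ref in enumerate(ref_so):
            f = frac(det, ref)
            if f >= min_overlap:
                inter = _overlap(det.start_sample, det.end_sample,
                                 ref.start_sample, ref.end_sample)
                pairs.append((inter, di, ri))
    pairs.sort(key=lambda t: (-t[0], t[1], t[2]))
    det_matched: set[int] = set()
    ref_matched: set[int] = set()
    for _, di, ri in pairs:
        if di in det_matched or ri in ref_matched:
            continue
        det_matched.add(di)
        ref_matched.add(ri)

    tp = len(det_matched)
    fp = len(detected) - tp
    fn = len(ref_so) - len(ref_matched)

    # TN screen: reference non-SO untouched by any sufficiently overlapping detection
    tn = 0
    for ref in ref_non:
        touched = False
        for det in detected:
            if denominator == "iou":
                f = frac(det, ref)
            else:
                if det.channel != ref.channel:
                    continue
                inter = _overlap(det.start_sample, det.end_sample,
                                 ref.start_sample, ref.end_sample)
                f = inter / (ref.end_sample - ref.start_sample)
            if f >= min_overlap:
                touched = True
                break
        if not touched:
            tn += 1
    return EvaluationCounts(tp=tp, fp=fp, tn=tn, fn=fn)


def balanced_accuracy(counts: EvaluationCounts) -> float:
    """Mean of sensitivity and specificity, in [0, 1]."""
    if counts.tp + counts.fn == 0 or counts.tn + counts.fp == 0:
        raise InsufficientDataError(
            "balanced accuracy undefined: one class has zero reference events"
        )
    sens = counts.tp / (counts.tp + counts.fn)
    spec = counts.tn / (counts.tn + counts.fp)
    return 0.5 * (sens + spec)


def inter_rater_agreement(labels_a: list[str], labels_b: list[str]) -> float:
    """Fraction of events given identical labels by two raters."""
    if len(labels_a) != len(labels_b):
        raise ParameterError(
            f"label vectors differ in length ({len(labels_a)} vs {len(labels_b)})"
        )
    if not labels_a:
        raise InsufficientDataError("no events to compare")
    agree = sum(a == b for a, b in zip(labels_a, labels_b))
    return agree / len(labels_a)


def agreement_counts(labels_a: list[str], labels_b: list[str]) -> AgreementCounts:
    """Concordance tallies feeding :func:`inter_rater_agreement`."""
    if len(labels_a) != len(labels_b):
        raise ParameterError("label vectors differ in length")
    so_both = sum(a == b == "SO" for a, b in zip(labels_a, labels_b))
    non_both = sum(a == b == "nonSO" for a, b in zip(labels_a, labels_b))
    return AgreementCounts(so_both=so_both, nonso_both=non_both,
                           events_total=len(labels_a))


def so_density(
    events: list,
    hypnogram: Hypnogram,
    fs: float,
    filtered: EEGRecording | None = None,
    exclude_artifact: bool = True,
) -> dict[str, float]:
    """Events per minute per sleep stage.

    An event is assigned to the stage of the epoch containing its negative
    peak (taken from ``filtered`` when given, else the interval midpoint).
    Artifact epochs are excluded from the denominators by default.
    """
    epoch_samples = hypnogram.epoch_length_s * fs
    minutes: dict[str, float] = {}
    for code in hypnogram.epoch_stages:
        minutes[code] = minutes.get(code, 0.0) + hypnogram.epoch_length_s / 60.0
    counts = {code: 0 for code in minutes}
    for ev in events:
        if filtered is not None and hasattr(ev, "channel"):
            seg = filtered.channel(ev.channel)[ev.start_sample:ev.end_sample]
            anchor = ev.start_sample + int(np.argmin(seg))
        else:
            anchor = (ev.start_sample + ev.end_sample) // 2
        epoch = int(anchor / epoch_samples)
        if not 0 <= epoch < hypnogram.n_epochs:
            raise ValidationError(
                f"event anchored at sample {anchor} lies beyond the hypnogram span"
            )
        counts[hypnogram.epoch_stages[epoch]] += 1
    out = {}
    for code, mins in minutes.items():
        if exclude_artifact and code == "artifact":
            continue
        out[code] = counts[code] / mins if mins > 0 else 0.0
    return out


def average_waveform(
    events: list,
    recording: EEGRecording,
    half_window_s: float = 1.25,
) -> tuple[np.ndarray, np.ndarray, int]:
    """Point-wise mean and SD waveform, aligned at the negative peak.

    Each event contributes the trace in a window of ``±half_window_s`` around
    its negative peak; events near the recording edges are zero-padded and the
    per-sample contribution counts are tracked so edges do not bias the mean.

    Returns ``(mean, sd, n_events)`` with ``mean.size == 2*half_window+1``
    samples.
    """
    if not events:
        raise InsufficientDataError("no events to average")
    fs = recording.sampling_rate
    half = int(round(half_window_s * fs))
    width = 2 * half + 1
    windows = np.zeros((len(events), width))
    for k, ev in enumerate(events):
        trace = recording.channel(ev.channel)
        seg = trace[ev.start_sample:ev.end_sample]
        anchor = ev.start_sample + int(np.argmin(seg))
        lo, hi = anchor - half, anchor + half + 1
        src_lo, src_hi = max(lo, 0), min(hi, trace.size)
        windows[k, src_lo - lo:src_hi - lo] = trace[src_lo:src_hi]
    return windows.mean(axis=0), windows.std(axis=0), len(events)
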