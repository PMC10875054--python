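"""Classical threshold-based slow-oscillation detectors.

Three detectors from the sleep literature, all operating on a 2nd-order
Butterworth band-passed trace and on candidates bounded by consecutive
positive-to-negative zero-crossings:

``absolute``
    Band 0.1–4 Hz.  A candidate is an SO if the positive-to-negative crossing
    and the *following* negative-to-positive crossing are separated by
    0.3–1 s, the negative peak between them is below −40 µV, and the
    negative-to-positive peak-to-peak amplitude exceeds 70 µV.  (The classic
    thresholds of −80 µV / 140 µV are appropriate for young adults; the
    defaults here are the values adjusted for older cohorts.)

``relative``
    Band 0.1–2 Hz.  Candidates of 0.9–2 s; channel averages of peak-to-peak
    amplitude and negative-peak voltage are computed over all such
    candidates, and events pass with amplitude > 2/3 of the average and a
    negative peak below 1/3 of the average negative-peak voltage.

``percentile``
    Band 0.16–1.25 Hz.  Candidates of 0.8–2 s; the 25% with the largest
    peak-to-peak amplitudes are marked, i.e. exactly ``floor(0.25 * n)``
    events per channel, ties broken by earlier onset.

Detected events are reported as full candidate spans (crossing to crossing)
for every algorithm so that overlap-based evaluation treats them uniformly,
even though the absolute detector's criteria are evaluated on the half-wave.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .events import bandpass, find_pn_crossings, measure_event, CandidateEvent, extract_candidates
from .evaluation import balanced_accuracy, match_events
from .exceptions import ParameterError, ValidationError
from .io import EEGRecording, LabeledEvent

logger = logging.getLogger(__name__)

_TABLE_DEFAULTS = {
    "absolute": dict(band=(0.1, 4.0), duration_bounds=(0.3, 1.0)),
    "relative": dict(band=(0.1, 2.0), duration_bounds=(0.9, 2.0)),
    "percentile": dict(band=(0.16, 1.25), duration_bounds=(0.8, 2.0)),
}


@dataclass(frozen=True)
class DetectorConfig:
    """Configuration of one classical detector.

    For ``absolute``, ``duration_bounds`` constrains the separation between
    the positive-to-negative crossing and the following negative-to-positive
    crossing (the down-state half-wave); for the other two it constrains the
    full candidate duration.
    """

    algorithm: str
    band: tuple[float, float]
    duration_bounds: tuple[float, float]
    abs_p2p_min_uV: float = 70.0
    abs_negpeak_max_uV: float = -40.0
    rel_amp_fraction: float = 2.0 / 3.0
    rel_negpeak_fraction: float = 1.0 / 3.0
    percentile_fraction: float = 0.25
    filter_order: int = 2
    negpeak_on_magnitude: bool = False  # alternative reading of "smaller than"
    assume_filtered: bool = False  # input already band-limited; skip filtering

    def __post_init__(self) -> None:
        if self.algorithm not in _TABLE_DEFAULTS:
            raise ParameterError(f"unknown detector algorithm {self.algorithm!r}")
        lo, hi = self.band
        if not 0 < lo < hi:
            raise ParameterError(f"invalid band {self.band}")
        dlo, dhi = self.duration_bounds
        if not 0 < dlo < dhi:
            raise ParameterError(f"invalid duration bounds {self.duration_bounds}")
        for frac in (self.rel_amp_fraction, self.rel_negpeak_fraction,
                     self.percentile_fraction):
            if not 0 < frac <= 1:
                raise ParameterError(f"fraction {frac} outside (0, 1]")

    @classmethod
    def defaults(cls, algorithm: str, **overrides) -> "DetectorConfig":
        """Literature-default configuration for one of the three algorithms."""
        if algorithm not in _TABLE_DEFAULTS:
            raise ParameterError(f"unknown detector algorithm {algorithm!r}")
        kwargs = dict(_TABLE_DEFAULTS[algorithm])
        kwargs.update(overrides)
        return cls(algorithm=algorithm, **kwargs)


def _as_events(cands: list[CandidateEvent]) -> list[LabeledEvent]:
    return [
        LabeledEvent(channel=c.channel, start_sample=c.start_sample,
                     end_sample=c.end_sample, label="SO")
        for c in cands
    ]


def detect_absolute(recording: EEGRecording, cfg: DetectorConfig) -> list[LabeledEvent]:
    """Fixed-threshold detector (absolute amplitude criteria)."""
    if cfg.algorithm != "absolute":
        raise ParameterError("config is not for the absolute algorithm")
    filtered = recording if cfg.assume_filtered else bandpass(
        recording, *cfg.band, order=cfg.filter_order
    )
    fs = filtered.sampling_rate
    lo = cfg.duration_bounds[0] * fs
    hi = cfg.duration_bounds[1] * fs
    detected: list[CandidateEvent] = []
    for name in filtered.channel_names:
        trace = filtered.channel(name)
        pn = find_pn_crossings(trace)
        np_cross = np.flatnonzero((trace[:-1] <= 0) & (trace[1:] > 0))
        for i, j in zip(pn[:-1], pn[1:]):
            # first negative-to-positive crossing after the p->n crossing
            k_idx = np.searchsorted(np_cross, i + 1)
            if k_idx >= np_cross.size or np_cross[k_idx] >= j:
                continue
            k = np_cross[k_idx]
            if not (lo <= k - i <= hi):
                continue
            neg_peak = trace[i:k + 1].min()
            if neg_peak >= cfg.abs_negpeak_max_uV:
                continue
            seg = trace[i:j]
            i_neg = int(np.argmin(seg))
            p2p = seg[i_neg:].max() - seg[i_neg]
            if p2p <= cfg.abs_p2p_min_uV:
                continue
            detected.append(CandidateEvent(name, int(i), int(j), cfg.band))
    return _as_events(detected)


def detect_relative(recording: EEGRecording, cfg: DetectorConfig) -> list[LabeledEvent]:
    """Individually adjusted (relative-threshold) detector."""
    if cfg.algorithm != "relative":
        raise ParameterError("config is not for the relative algorithm")
    cands, filtered = extract_candidates(
        recording, cfg.band, *cfg.duration_bounds, order=cfg.filter_order,
        prefiltered=cfg.assume_filtered,
    )
    detected: list[CandidateEvent] = []
    for name in recording.channel_names:
        chan = [c for c in cands if c.channel == name]
        if not chan:
            logger.warning("relative detector: channel %s has no candidates", name)
            continue
        morphs = [measure_event(c, filtered) for c in chan]
        avg_p2p = float(np.mean([m.p2p_amplitude_uV for m in morphs]))
        avg_neg = float(np.mean([m.neg_peak_uV for m in morphs]))
        amp_thr = cfg.rel_amp_fraction * avg_p2p
        neg_thr = cfg.rel_negpeak_fraction * avg_neg
        for c, m in zip(chan, morphs):
            if m.p2p_amplitude_uV <= amp_thr:
                continue
            if cfg.negpeak_on_magnitude:
                ok = abs(m.neg_peak_uV) > abs(neg_thr)
            else:
                ok = m.neg_peak_uV < neg_thr
            if ok:
                detected.append(c)
    return _as_events(detected)


def detect_percentile(recording: EEGRecording, cfg: DetectorConfig) -> list[LabeledEvent]:
    """Top-amplitude-quartile detector."""
    if cfg.algorithm != "percentile":
        raise ParameterError("config is not for the percentile algorithm")
    cands, filtered = extract_candidates(
        recording, cfg.band, *cfg.duration_bounds, order=cfg.filter_order,
        prefiltered=cfg.assume_filtered,
    )
    detected: list[CandidateEvent] = []
    for name in recording.channel_names:
        chan = [c for c in cands if c.channel == name]
        if not chan:
            continue
        n_keep = int(np.floor(cfg.percentile_fraction * len(chan)))
        if n_keep == 0:
            continue
        amps = [measure_event(c, filtered).p2p_amplitude_uV for c in chan]
        order = sorted(range(len(chan)), key=lambda i: (-amps[i], chan[i].start_sample))
        detected.extend(chan[i] for i in order[:n_keep])
    detected.sort(key=lambda c: (c.channel, c.start_sample))
    return _as_events(detected)


_DISPATCH = {
    "absolute": detect_absolute,
    "relative": detect_relative,
    "percentile": detect_percentile,
}


def detect(recording: EEGRecording, cfg: DetectorConfig) -> list[LabeledEvent]:
    """Run the detector selected by ``cfg.algorithm``."""
    return _DISPATCH[cfg.algorithm](recording, cfg)


def sweep_detector_grid(
    recording: EEGRecording,
    reference_labels: list[LabeledEvent],
    base_cfg: DetectorConfig,
    grid: dict[str, list],
) -> tuple[pd.DataFrame, dict]:
    """Exhaustive parameter sweep of one detector against a labeled reference.

    ``grid`` maps :class:`DetectorConfig` field names to candidate values;
    every combination in the Cartesian product is run through detection and
    overlap evaluation.  Returns the full result table (one row per
    combination, with TP/FP/TN/FN and balanced accuracy) and the best row.
    """
    if not grid:
        raise ParameterError("grid must contain at least one parameter")
    if not any(e.label in ("SO", "nonSO") for e in reference_labels):
        raise ValidationError("reference set contains no labeled events")
    keys = sorted(grid)
    rows = []
    for combo in itertools.product(*(grid[k] for k in keys)):
        params = dict(zip(keys, combo))
        cfg = replace(base_cfg, **params)
        detected = detect(recording, cfg)
        counts = match_events(detected, reference_labels)
        row = dict(params)
        row.update(
            tp=counts.tp, fp=counts.fp, tn=counts.tn, fn=counts.fn,
            n_detected=len(detected),
            balanced_accuracy=balanced_accuracy(counts),
        )
        rows.append(row)
    table = pd.DataFrame(rows)
    best = table.loc[table["balanced_accuracy"].idxmax()].to_dict()
    return table, best
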