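"""Candidate slow-oscillation extraction and event morphology.

A candidate SO event is the stretch of band-pass-filtered signal between two
consecutive positive-to-negative zero-crossings.  Its morphology is summarised
by the quantities used throughout labeling, pre-filtering and classification:

* ``d_total``        — total event duration (s),
* ``d_to_negpeak``   — first crossing to the negative peak (s),
* ``d_neg_to_pospeak`` — negative peak to the positive peak (s),
* ``d_pospeak_to_end`` — positive peak to the second crossing (s),
* ``n_pos_peaks``    — number of positive wave peaks,
* ``neg_peak_uV`` / ``pos_peak_uV`` / ``p2p_amplitude_uV`` — amplitudes.

Filtering is a 2nd-order Butterworth band-pass (default 0.1–1.25 Hz), applied
zero-phase (forward-backward) so event timing is not shifted by filter delay;
a causal mode is kept for experiments (note the effective magnitude order
doubles under zero-phase filtering).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .exceptions import DegenerateEventError, ParameterError
from .io import EEGRecording

#: Band used for labeling and pre-filtering, in Hz.
LABELING_BAND = (0.1, 1.25)

#: Candidate duration bounds used for labeling, in seconds.
LABELING_DURATION_BOUNDS = (0.8, 3.5)


@dataclass(frozen=True)
class CandidateEvent:
    """A zero-crossing-bounded candidate event on one channel.

    ``[start_sample, end_sample)`` is half-open; the filtered trace is > 0 at
    ``start_sample`` and <= 0 at ``start_sample + 1``.
    """

    channel: str
    start_sample: int
    end_sample: int
    source_band: tuple[float, float]

    @property
    def n_samples(self) -> int:
        return self.end_sample - self.start_sample

    def duration_s(self, fs: float) -> float:
        return self.n_samples / fs


@dataclass(frozen=True)
class EventMorphology:
    """Shape and amplitude summary of one candidate event."""

    d_total: float
    d_to_negpeak: float
    d_neg_to_pospeak: float
    d_pospeak_to_end: float
    n_pos_peaks: int
    neg_peak_uV: float
    pos_peak_uV: float
    p2p_amplitude_uV: float
    neg_peak_sample: int


def bandpass(
    recording: EEGRecording,
    low: float,
    high: float,
    order: int = 2,
    zero_phase: bool = True,
) -> EEGRecording:
    """Butterworth band-pass filter, applied per channel.

    Parameters
    ----------
    low, high
        Band edges in Hz; must satisfy ``0 < low < high < fs/2``.
    order
        Filter order of the underlying Butterworth design (default 2).
    zero_phase
        Apply forward-backward (``filtfilt``) so the output has zero phase
        shift; set False for a causal single pass.
    """
    fs = recording.sampling_rate
    nyq = fs / 2.0
    if not (0 < low < high):
        raise ParameterError(f"need 0 < low < high, got ({low}, {high})")
    if high >= nyq:
        raise ParameterError(f"upper band edge {high} Hz >= Nyquist {nyq} Hz")
    sos = signal.butter(order, [low, high], btype="bandpass", fs=fs, output="sos")
    if zero_phase:
        filtered = signal.sosfiltfilt(sos, recording.data, axis=1)
    else:
        filtered = signal.sosfilt(sos, recording.data, axis=1)
    return EEGRecording(
        channel_names=list(recording.channel_names),
        data=np.ascontiguousarray(filtered),
        sampling_rate=fs,
        reference_label=recording.reference_label,
    )


def find_pn_crossings(samples: np.ndarray) -> np.ndarray:
    """Indices ``i`` with ``samples[i] > 0`` and ``samples[i+1] <= 0``, ascending.

    Crossings are snapped to integer samples (no sub-sample interpolation); a
    one-sample position error is negligible against the 0.8-s minimum event
    duration.
    """
    x = np.asarray(samples, dtype=np.float64)
    if x.ndim != 1:
        raise ParameterError("samples must be a 1-D sequence")
    if x.size < 2:
        return np.empty(0, dtype=np.int64)
    if not np.all(np.isfinite(x)):
        raise ParameterError("samples must be finite")
    return np.flatnonzero((x[:-1] > 0) & (x[1:] <= 0)).astype(np.int64)


def extract_candidates(
    recording: EEGRecording,
    band: tuple[float, float] = LABELING_BAND,
    min_dur: float = LABELING_DURATION_BOUNDS[0],
    max_dur: float = LABELING_DURATION_BOUNDS[1],
    order: int = 2,
    zero_phase: bool = True,
    prefiltered: bool = False,
) -> tuple[list[CandidateEvent], EEGRecording]:
    """Extract duration-gated candidate events from every channel.

    Each pair of consecutive positive-to-negative zero-crossings of the
    filtered trace bounds one candidate; candidates whose duration falls in
    ``[min_dur, max_dur]`` are kept.  Within a channel the result is
    non-overlapping and sorted by onset.

    Returns the candidate list together with the filtered recording the
    candidates refer to (pass ``prefiltered=True`` if ``recording`` is already
    in-band to skip filtering).
    """
    if not min_dur < max_dur:
        raise ParameterError(f"need min_dur < max_dur, got ({min_dur}, {max_dur})")
    if min_dur <= 0:
        raise ParameterError("min_dur must be positive")
    filtered = recording if prefiltered else bandpass(
        recording, band[0], band[1], order=order, zero_phase=zero_phase
    )
    fs = filtered.sampling_rate
    lo = int(np.ceil(min_dur * fs))
    hi = int(np.floor(max_dur * fs))
    out: list[CandidateEvent] = []
    for name in filtered.channel_names:
        crossings = find_pn_crossings(filtered.channel(name))
        if crossings.size < 2:
            continue
        spans = np.diff(crossings)
        for i in np.flatnonzero((spans >= lo) & (spans <= hi)):
            out.append(
                CandidateEvent(
                    channel=name,
                    start_sample=int(crossings[i]),
                    end_sample=int(crossings[i + 1]),
                    source_band=(float(band[0]), float(band[1])),
                )
            )
    return out, filtered


def count_positive_peaks(
    segment: np.ndarray,
    positive_half_only: bool = False,
    prominence_fraction: float = 0.1,
) -> int:
    """Count positive wave peaks: local maxima with positive voltage.

    A "wave peak" is what a rater sees at the scale of the event, so maxima
    must have a prominence of at least ``prominence_fraction`` of the
    segment's peak-to-peak range (set 0 to count every strict local maximum,
    including sub-microvolt ripples).  Plateaus count once.  Peaks are
    counted over the whole event by default; set ``positive_half_only`` to
    restrict to samples after the negative peak.
    """
    seg = np.asarray(segment, dtype=np.float64)
    if positive_half_only:
        seg = seg[int(np.argmin(seg)):]
    if seg.size < 3:
        return 1 if seg.size and seg.max() > 0 else 0
    p2p = float(seg.max() - seg.min())
    prominence = prominence_fraction * p2p if p2p > 0 else None
    peaks, _ = signal.find_peaks(seg, height=1e-12, prominence=prominence)
    return int(peaks.size)


def measure_event(
    candidate: CandidateEvent,
    filtered: EEGRecording,
    positive_half_only: bool = False,
    prominence_fraction: float = 0.1,
) -> EventMorphology:
    """Measure the morphology of one candidate on the filtered trace.

    The negative peak is the segment minimum; the positive peak is the
    maximum over ``[neg_peak_sample, end)`` (the up-state follows the
    down-state).  The three partial durations sum to ``d_total`` to within
    one sample period by construction.
    """
    trace = filtered.channel(candidate.channel)
    if not (0 <= candidate.start_sample < candidate.end_sample <= trace.size):
        raise ParameterError(
            f"candidate [{candidate.start_sample}, {candidate.end_sample}) outside "
            f"trace of length {trace.size}"
        )
    seg = trace[candidate.start_sample:candidate.end_sample]
    if seg.size < 3:
        raise DegenerateEventError(
            f"segment of {seg.size} samples is too short to measure"
        )
    fs = filtered.sampling_rate
    i_neg = int(np.argmin(seg))
    i_pos = i_neg + int(np.argmax(seg[i_neg:]))
    neg_peak = float(seg[i_neg])
    pos_peak = float(seg[i_pos])
    return EventMorphology(
        d_total=seg.size / fs,
        d_to_negpeak=i_neg / fs,
        d_neg_to_pospeak=(i_pos - i_neg) / fs,
        d_pospeak_to_end=(seg.size - i_pos) / fs,
        n_pos_peaks=count_positive_peaks(
            seg, positive_half_only=positive_half_only,
            prominence_fraction=prominence_fraction,
        ),
        neg_peak_uV=neg_peak,
        pos_peak_uV=pos_peak,
        p2p_amplitude_uV=pos_peak - neg_peak,
        neg_peak_sample=candidate.start_sample + i_neg,
    )


def measure_all(
    candidates: list[CandidateEvent],
    filtered: EEGRecording,
    positive_half_only: bool = False,
) -> list[EventMorphology]:
    """Vector convenience: morphology for every candidate."""
    return [
        measure_event(c, filtered, positive_half_only=positive_half_only)
        for c in candidates
    ]
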