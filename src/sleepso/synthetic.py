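"""Synthetic sleep-EEG generator with exact ground truth.

Real overnight EEG with expert SO labels is rarely shareable, so every part
of the toolkit is exercisable on simulated recordings: a hypnogram of stage
blocks, stage-dependent rates and amplitudes of implanted slow oscillations,
low-amplitude "distractor" slow events (the look-alikes that make labeling
slow), and 1/f-like Gaussian background activity.

The SO template is a raised-cosine biphasic wave — a negative (down-state)
lobe followed by a positive (up-state) lobe — which starts and ends at 0 µV
and is bounded by positive-to-negative zero-crossings by construction (its
first sample carries a +0.5 µV epsilon so that the leading crossing exists
even on a silent baseline).  The stage defaults follow the qualitative
physiology of non-REM sleep: SO density and amplitude both increase from
wakefulness through N1 and N2 to N3.  The numbers are modeling choices, not
measurements: densities 0.5 / 1.5 / 4 / 7 events per minute and mean
peak-to-peak amplitudes 55 / 65 / 80 / 95 µV for Wa / N1 / N2 / N3.

Everything is reproducible from the config seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .events import extract_candidates, measure_all, LABELING_BAND, LABELING_DURATION_BOUNDS
from .exceptions import ParameterError, SleepsoError
from .io import EEGRecording, Hypnogram, LabeledEvent

#: Fraction of the peak-to-peak amplitude carried by the negative lobe.
NEG_AMP_FRACTION = 0.6


class GenerationError(SleepsoError):
    """Events could not be placed without overlap."""


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for the simulator.

    ``stage_blocks`` is an ordered list of ``(stage, minutes)``; densities are
    events/minute; amplitudes are (mean, SD) peak-to-peak in µV; SO durations
    are drawn uniformly from ``so_duration_s``.  Distractors reuse the SO
    template scaled to ``distractor_amp_fraction`` of the stage mean.
    """

    fs: float = 500.0
    channel_names: tuple[str, ...] = ("Fz",)
    # a ~90-minute nap: light sleep descending into consolidated N2/N3
    stage_blocks: tuple[tuple[str, float], ...] = (
        ("Wa", 10.0), ("N1", 10.0), ("N2", 40.0), ("N3", 30.0)
    )
    so_density_per_stage: dict = field(
        default_factory=lambda: {"Wa": 0.5, "N1": 1.5, "N2": 4.0, "N3": 7.0}
    )
    so_p2p_uV: dict = field(
        default_factory=lambda: {
            "Wa": (70.0, 10.0), "N1": (80.0, 10.0), "N2": (90.0, 12.0),
            "N3": (105.0, 15.0),
        }
    )
    so_duration_s: tuple[float, float] = (0.9, 1.8)
    so_min_p2p_uV: float = 60.0
    distractor_rate: float = 3.0
    distractor_amp_fraction: float = 0.4
    noise_exponent: float = 1.5
    noise_rms_uV: float = 10.0
    min_gap_s: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fs <= 2 * LABELING_BAND[1]:
            raise ParameterError("fs must exceed twice the SO band upper edge")
        lo, hi = self.so_duration_s
        if not 0.8 <= lo < hi <= 2.0:
            raise ParameterError("so_duration_s must lie within [0.8, 2.0]")
        for stage, _ in self.stage_blocks:
            if stage not in self.so_density_per_stage and stage != "artifact":
                raise ParameterError(f"no SO density configured for stage {stage!r}")
        if any(d < 0 for d in self.so_density_per_stage.values()):
            raise ParameterError("densities must be >= 0")

    @property
    def duration_min(self) -> float:
        return sum(minutes for _, minutes in self.stage_blocks)


@dataclass
class GroundTruth:
    """Implanted events with their template parameters."""

    so_events: list[LabeledEvent]
    distractor_events: list[LabeledEvent]
    so_params: list[dict]
    distractor_params: list[dict]

    @property
    def all_events(self) -> list[LabeledEvent]:
        return sorted(
            self.so_events + self.distractor_events,
            key=lambda e: (e.channel, e.start_sample),
        )


def make_so_template(
    duration_s: float,
    neg_amp_uV: float,
    pos_amp_uV: float,
    fs: float,
    neg_fraction: float | None = None,
    epsilon_uV: float = 0.5,
) -> np.ndarray:
    """Raised-cosine biphasic SO waveform.

    A negative lobe of depth ``neg_amp_uV`` followed by a positive lobe of
    height ``pos_amp_uV``; exactly one negative then one positive extremum.
    Unless ``neg_fraction`` is given, lobe durations are chosen so the two
    lobe areas cancel (the deeper down-state is shorter, the shallower
    up-state broader — also the physiological shape), which keeps the
    template mean near zero and avoids rebound under high-pass filtering.
    The first sample is a small positive epsilon so the leading
    positive-to-negative zero-crossing exists by construction.
    """
    if not 0.8 <= duration_s <= 3.5:
        raise ParameterError(f"duration {duration_s} s outside [0.8, 3.5]")
    if not (neg_amp_uV < 0 < pos_amp_uV):
        raise ParameterError(
            f"need neg_amp < 0 < pos_amp, got ({neg_amp_uV}, {pos_amp_uV})"
        )
    if neg_fraction is None:
        neg_fraction = pos_amp_uV / (abs(neg_amp_uV) + pos_amp_uV)
    n = int(round(duration_s * fs))
    n1 = int(round(neg_fraction * n))
    n2 = n - n1
    if min(n1, n2) < 4:
        raise ParameterError("duration too short for the sampling rate")
    t = np.arange(n, dtype=np.float64)
    wave = np.empty(n)
    wave[:n1] = neg_amp_uV * np.sin(np.pi * t[:n1] / n1) ** 2
    wave[n1:] = pos_amp_uV * np.sin(np.pi * (t[n1:] - n1) / n2) ** 2
    wave[0] = epsilon_uV
    return wave


def one_over_f_noise(
    n_samples: int, fs: float, exponent: float, rms_uV: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Spectrally shaped Gaussian noise with a 1/f^exponent amplitude profile."""
    white = rng.standard_normal(n_samples)
    spectrum = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / fs)
    shaping = np.zeros_like(freqs)
    shaping[1:] = freqs[1:] ** (-exponent / 2.0)
    noise = np.fft.irfft(spectrum * shaping, n=n_samples)
    scale = rms_uV / max(np.sqrt(np.mean(noise**2)), 1e-30)
    return noise * scale


def _place_events(
    rng: np.random.Generator,
    block_start: int,
    block_len: int,
    n_events: int,
    durations: np.ndarray,
    min_gap: int,
    occupied: list[tuple[int, int]],
) -> list[tuple[int, int]]:
    """Place non-overlapping events inside a block; raise if impossible."""
    placed: list[tuple[int, int]] = []
    for dur in durations[:n_events]:
        ok = False
        for _ in range(200):
            start = block_start + int(rng.integers(0, max(1, block_len - dur)))
            end = start + int(dur)
            clash = any(
                start - min_gap < e and end + min_gap > s for s, e in occupied
            )
            if not clash:
                occupied.append((start, end))
                placed.append((start, end))
                ok = True
                break
        if not ok:
            raise GenerationError(
                "could not place events without overlap; configuration too dense"
            )
    return placed


def simulate_recording(
    config: SyntheticConfig | None = None,
) -> tuple[EEGRecording, GroundTruth, Hypnogram]:
    """Simulate a multichannel recording with implanted SOs and distractors.

    Event counts per stage block are Poisson with the configured density;
    event times are uniform within the block subject to non-overlap (with a
    minimum gap).  Distractors are scaled-down SO templates.  Background is
    1/f-shaped Gaussian noise.  Fully reproducible from ``config.seed``.
    """
    cfg = config or SyntheticConfig()
    fs = cfg.fs
    n_total = int(round(cfg.duration_min * 60 * fs))
    rng = np.random.default_rng(cfg.seed)

    epoch_stages: list[str] = []
    for stage, minutes in cfg.stage_blocks:
        epoch_stages.extend([stage] * int(round(minutes * 2)))
    hypnogram = Hypnogram(epoch_stages=epoch_stages)

    data = np.zeros((len(cfg.channel_names), n_total))
    so_events: list[LabeledEvent] = []
    distractors: list[LabeledEvent] = []
    so_params: list[dict] = []
    distractor_params: list[dict] = []

    for ch_idx, ch_name in enumerate(cfg.channel_names):
        occupied: list[tuple[int, int]] = []
        block_start = 0
        for stage, minutes in cfg.stage_blocks:
            block_len = int(round(minutes * 60 * fs))
            density = cfg.so_density_per_stage.get(stage, 0.0)
            amp_mean, amp_sd = cfg.so_p2p_uV.get(stage, (80.0, 10.0))
            n_so = int(rng.poisson(density * minutes))
            n_dis = int(rng.poisson(cfg.distractor_rate * minutes))
            dur_s = rng.uniform(*cfg.so_duration_s, size=n_so + n_dis)
            durations = np.round(dur_s * fs).astype(np.int64)
            min_gap = int(round(cfg.min_gap_s * fs))

            spans = _place_events(
                rng, block_start, block_len, n_so + n_dis, durations, min_gap,
                occupied,
            )
            # truncated at so_min_p2p_uV: an SO is by definition a
            # large-amplitude event, raters do not tag smaller ones
            p2ps = np.maximum(
                rng.normal(amp_mean, amp_sd, size=n_so), cfg.so_min_p2p_uV
            )
            for k, (start, end) in enumerate(spans[:n_so]):
                p2p = float(p2ps[k])
                neg, pos = -NEG_AMP_FRACTION * p2p, (1 - NEG_AMP_FRACTION) * p2p
                wave = make_so_template((end - start) / fs, neg, pos, fs)
                data[ch_idx, start:start + wave.size] += wave
                so_events.append(LabeledEvent(ch_name, start, start + wave.size, "SO"))
                so_params.append(
                    {"stage": stage, "p2p_uV": p2p, "neg_uV": neg, "pos_uV": pos}
                )
            for start, end in spans[n_so:]:
                p2p = cfg.distractor_amp_fraction * amp_mean
                neg, pos = -NEG_AMP_FRACTION * p2p, (1 - NEG_AMP_FRACTION) * p2p
                wave = make_so_template((end - start) / fs, neg, pos, fs)
                data[ch_idx, start:start + wave.size] += wave
                distractors.append(
                    LabeledEvent(ch_name, start, start + wave.size, "nonSO")
                )
                distractor_params.append(
                    {"stage": stage, "p2p_uV": p2p, "neg_uV": neg, "pos_uV": pos}
                )
            block_start += block_len
        if cfg.noise_rms_uV > 0:
            data[ch_idx] += one_over_f_noise(
                n_total, fs, cfg.noise_exponent, cfg.noise_rms_uV, rng
            )

    recording = EEGRecording(
        channel_names=list(cfg.channel_names), data=data, sampling_rate=fs
    )
    truth = GroundTruth(
        so_events=sorted(so_events, key=lambda e: (e.channel, e.start_sample)),
        distractor_events=sorted(distractors, key=lambda e: (e.channel, e.start_sample)),
        so_params=so_params,
        distractor_params=distractor_params,
    )
    return recording, truth, hypnogram


def label_candidates(
    candidates: list,
    truth: GroundTruth,
    fs: float | None = None,
    min_overlap: float = 0.5,
    mutual: bool = True,
    max_so_duration_s: float = 2.0,
) -> list[str]:
    """Tag extracted candidates the way an expert rater would.

    Returns one of ``"SO"``, ``"distractor"`` or ``"noise"`` per candidate.
    A candidate is tagged when the intersection covers at least
    ``min_overlap`` of the candidate *and* (with ``mutual``, the default) of
    the implanted event — a fragment that clips only part of an implanted
    template is not the event a rater would see, and is left as noise.
    Likewise, when ``fs`` is given, a candidate stretched beyond
    ``max_so_duration_s`` by surrounding slow activity is not tagged SO even
    if it contains one: raters mark only events whose total duration looks
    like an SO (roughly 0.8–2 s).
    """
    def overlaps(cand, events) -> bool:
        for ev in events:
            if ev.channel != cand.channel:
                continue
            inter = min(cand.end_sample, ev.end_sample) - max(
                cand.start_sample, ev.start_sample
            )
            if inter <= 0:
                continue
            if inter / cand.n_samples < min_overlap:
                continue
            if mutual and inter / ev.n_samples < min_overlap:
                continue
            return True
        return False

    labels = []
    for cand in candidates:
        too_long = (
            fs is not None and cand.n_samples / fs > max_so_duration_s
        )
        if not too_long and overlaps(cand, truth.so_events):
            labels.append("SO")
        elif overlaps(cand, truth.distractor_events):
            labels.append("distractor")
        else:
            labels.append("noise")
    return labels


#: Conditions used when building labeled corpora: a denser, lower-rate
#: recording so a target event count is reachable in reasonable simulated time.
CORPUS_CONFIG = SyntheticConfig(
    fs=100.0,
    stage_blocks=(("N2", 10.0), ("N3", 10.0)),
    so_density_per_stage={"N2": 5.0, "N3": 8.0},
    distractor_rate=4.0,
)


def labeled_candidate_corpus(
    n_events: int,
    so_fraction: float = 0.6,
    config: SyntheticConfig | None = None,
    resample_to: int | None = None,
    seed: int | None = None,
) -> tuple[list[np.ndarray], list, list[str]]:
    """Build a labeled SO / non-SO candidate corpus from simulated recordings.

    Candidates are extracted in the labeling band (0.1–1.25 Hz, 0.8–3.5 s)
    and labeled by ground-truth overlap; the corpus is subsampled to
    ``n_events`` with an SO proportion of ``so_fraction`` (default 0.6,
    matching the roughly 60/40 class balance a pre-filtered labeled data set
    shows).  Additional recordings with derived seeds are simulated until
    both classes are filled.

    Returns ``(waveforms, morphologies, labels)`` with labels in
    {``"SO"``, ``"nonSO"``}; waveforms are the filtered candidate segments,
    optionally linearly resampled to a common length.
    """
    if n_events < 10:
        raise ParameterError("n_events must be >= 10")
    if not 0 < so_fraction < 1:
        raise ParameterError("so_fraction must be in (0, 1)")
    base_cfg = config or CORPUS_CONFIG
    base_seed = base_cfg.seed if seed is None else int(seed)

    n_so_needed = int(round(so_fraction * n_events))
    n_non_needed = n_events - n_so_needed
    so_pool: list[tuple[np.ndarray, object]] = []
    non_pool: list[tuple[np.ndarray, object]] = []
    for round_idx in range(64):
        cfg = replace(base_cfg, seed=(base_seed + 7919 * round_idx) % (2**31 - 1))
        recording, truth, _ = simulate_recording(cfg)
        cands, filtered = extract_candidates(
            recording, LABELING_BAND, *LABELING_DURATION_BOUNDS
        )
        tags = label_candidates(cands, truth, fs=recording.sampling_rate)
        morphs = measure_all(cands, filtered)
        for cand, morph, tag in zip(cands, morphs, tags):
            seg = filtered.channel(cand.channel)[cand.start_sample:cand.end_sample]
            item = (seg.copy(), morph)
            if tag == "SO":
                so_pool.append(item)
            else:
                non_pool.append(item)
        if len(so_pool) >= n_so_needed and len(non_pool) >= n_non_needed:
            break
    else:  # pragma: no cover - would require a pathological config
        raise GenerationError("could not accumulate the requested corpus size")

    rng = np.random.default_rng(base_seed + 1)
    so_idx = rng.permutation(len(so_pool))[:n_so_needed]
    non_idx = rng.permutation(len(non_pool))[:n_non_needed]
    items = [(so_pool[i], "SO") for i in so_idx] + [
        (non_pool[i], "nonSO") for i in non_idx
    ]
    order = rng.permutation(len(items))
    waveforms, morphologies, labels = [], [], []
    for i in order:
        (wave, morph), lab = items[i]
        if resample_to is not None:
            old = np.linspace(0.0, 1.0, wave.size)
            new = np.linspace(0.0, 1.0, resample_to)
            wave = np.interp(new, old, wave)
        waveforms.append(wave)
        morphologies.append(morph)
        labels.append(lab)
    return waveforms, morphologies, labels
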