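"""Semi-automatic pre-filtering of candidate SO events.

Manual labeling of every zero-crossing candidate in an overnight EEG is
infeasible (tens of thousands of events per recording), but true SOs are
sparse.  The pre-filter derives, from a modest hand-labeled sample on one
channel, data-driven thresholds on five morphology parameters —

1. total event duration,
2. duration from the first crossing to the negative peak,
3. duration from the negative peak to the positive peak,
4. duration from the positive peak to the second crossing,
5. number of positive wave peaks —

plus two amplitude scale factors (peak-to-peak and negative-peak), and then
discards candidates that violate any of them.  For each duration/shape
parameter, nine equally spaced values spanning mean ± 2 SD over the labeled
SOs form the candidate-threshold grid.  Starting from the largest (most
permissive, under the upper-bound reading) grid value, the walk steps to the
next smaller value as long as the TPR lost does not exceed the FPR lost, and
stops — keeping the current value — as soon as it would lose more true than
false positives.  The scale factors are the minimum divided by the average of
the corresponding amplitude quantity over the labeled SOs, so every labeled
SO passes by construction.  The minimum event duration stays fixed at 0.8 s.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .events import EventMorphology
from .evaluation import EvaluationCounts
from .exceptions import InsufficientDataError, ValidationError

logger = logging.getLogger(__name__)

#: The five gridded morphology parameters, in their conventional order.
GRID_PARAMETERS = (
    "d_total",
    "d_to_negpeak",
    "d_neg_to_pospeak",
    "d_pospeak_to_end",
    "n_pos_peaks",
)

#: Fixed lower duration bound in seconds; shorter events are always excluded.
MIN_DURATION_S = 0.8


def tpr(counts: EvaluationCounts) -> float:
    """True positive rate TP / (TP + FN); 0 (with a warning) if no positives."""
    if counts.tp + counts.fn == 0:
        logger.warning("TPR undefined (TP + FN = 0); returning 0")
        return 0.0
    return counts.tp / (counts.tp + counts.fn)


def fpr(counts: EvaluationCounts) -> float:
    """False positive rate FP / (FP + TN); 0 (with a warning) if no negatives."""
    if counts.fp + counts.tn == 0:
        logger.warning("FPR undefined (FP + TN = 0); returning 0")
        return 0.0
    return counts.fp / (counts.fp + counts.tn)


@dataclass(frozen=True)
class PrefilterStats:
    """Per-channel statistics over the labeled SO events.

    ``min_negpeak_uV`` is the negative-peak value of smallest magnitude (the
    least negative), so both scale factors land in (0, 1] and the derived
    amplitude thresholds retain every labeled SO.
    """

    mean: dict[str, float]
    sd: dict[str, float]
    min_p2p_uV: float
    avg_p2p_uV: float
    min_negpeak_uV: float
    avg_negpeak_uV: float
    n_so: int


@dataclass(frozen=True)
class PrefilterCriteria:
    """Derived pre-filter thresholds.

    ``upper_bounds`` maps each of the five gridded parameters to its upper
    threshold; ``amp_scale`` and ``negpeak_scale`` are dimensionless factors
    applied to the channel-average peak-to-peak amplitude and negative-peak
    voltage.  ``avg_p2p_uV`` / ``avg_negpeak_uV`` record the averages of the
    derivation channel so the criteria are self-contained.
    """

    upper_bounds: dict[str, float]
    amp_scale: float
    negpeak_scale: float
    avg_p2p_uV: float
    avg_negpeak_uV: float
    min_duration_s: float = MIN_DURATION_S

    def to_dict(self) -> dict:
        return {
            "upper_bounds": dict(self.upper_bounds),
            "amp_scale": self.amp_scale,
            "negpeak_scale": self.negpeak_scale,
            "avg_p2p_uV": self.avg_p2p_uV,
            "avg_negpeak_uV": self.avg_negpeak_uV,
            "min_duration_s": self.min_duration_s,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PrefilterCriteria":
        return cls(
            upper_bounds=dict(d["upper_bounds"]),
            amp_scale=float(d["amp_scale"]),
            negpeak_scale=float(d["negpeak_scale"]),
            avg_p2p_uV=float(d["avg_p2p_uV"]),
            avg_negpeak_uV=float(d["avg_negpeak_uV"]),
            min_duration_s=float(d.get("min_duration_s", MIN_DURATION_S)),
        )


def _param_value(m: EventMorphology, name: str) -> float:
    return float(getattr(m, name))


def channel_stats(
    labeled: list[tuple[EventMorphology, str]], ddof: int = 0
) -> PrefilterStats:
    """Mean/SD of the five gridded parameters and amplitude extrema over SOs.

    The SD is the population SD by default (``ddof=0``); pass ``ddof=1`` for
    the sample estimator.
    """
    so = [m for m, lab in labeled if lab == "SO"]
    if not so:
        raise InsufficientDataError("channel_stats requires at least one SO event")
    mean: dict[str, float] = {}
    sd: dict[str, float] = {}
    for name in GRID_PARAMETERS:
        vals = np.array([_param_value(m, name) for m in so])
        mean[name] = float(vals.mean())
        sd[name] = float(vals.std(ddof=ddof)) if vals.size > ddof else 0.0
    p2p = np.array([m.p2p_amplitude_uV for m in so])
    neg = np.array([m.neg_peak_uV for m in so])
    return PrefilterStats(
        mean=mean,
        sd=sd,
        min_p2p_uV=float(p2p.min()),
        avg_p2p_uV=float(p2p.mean()),
        min_negpeak_uV=float(neg.max()),  # least negative = smallest magnitude
        avg_negpeak_uV=float(neg.mean()),
        n_so=len(so),
    )


def criterion_grid(mean: float, sd: float, integer: bool = False) -> np.ndarray:
    """Nine equally spaced candidate thresholds on [mean − 2 SD, mean + 2 SD]."""
    grid = np.linspace(mean - 2 * sd, mean + 2 * sd, 9)
    if integer:
        grid = np.round(grid)
    return grid


def _rates_for_threshold(
    values: np.ndarray, labels: np.ndarray, threshold: float
) -> tuple[float, float]:
    """TPR/FPR when retaining events with value <= threshold."""
    keep = values <= threshold
    so = labels
    counts = EvaluationCounts(
        tp=int(np.sum(keep & so)),
        fn=int(np.sum(~keep & so)),
        fp=int(np.sum(keep & ~so)),
        tn=int(np.sum(~keep & ~so)),
    )
    return tpr(counts), fpr(counts)


def derive_criteria(
    labeled: list[tuple[EventMorphology, str]],
    ddof: int = 0,
) -> PrefilterCriteria:
    """Derive pre-filter thresholds from a labeled candidate sample.

    Each of the five gridded parameters is treated independently: its
    nine-value grid is walked from the maximum (mean + 2 SD) downward, and the
    walk stops at the current value as soon as stepping further would lose
    more TPR than FPR.  The two amplitude scale factors come directly from
    :func:`channel_stats`.
    """
    if not labeled:
        raise InsufficientDataError("derive_criteria requires labeled events")
    stats = channel_stats(labeled, ddof=ddof)
    values = {
        name: np.array([_param_value(m, name) for m, _ in labeled])
        for name in GRID_PARAMETERS
    }
    is_so = np.array([lab == "SO" for _, lab in labeled])

    upper_bounds: dict[str, float] = {}
    for name in GRID_PARAMETERS:
        grid = criterion_grid(
            stats.mean[name], stats.sd[name], integer=(name == "n_pos_peaks")
        )
        vals = values[name]
        k = len(grid) - 1  # start at the maximum (most permissive) value
        while k > 0:
            tpr_cur, fpr_cur = _rates_for_threshold(vals, is_so, grid[k])
            tpr_next, fpr_next = _rates_for_threshold(vals, is_so, grid[k - 1])
            d_tpr = tpr_cur - tpr_next
            d_fpr = fpr_cur - fpr_next
            if d_tpr > d_fpr:
                break  # stepping down would lose more TPs than FPs
            k -= 1
        upper_bounds[name] = float(grid[k])

    return PrefilterCriteria(
        upper_bounds=upper_bounds,
        amp_scale=stats.min_p2p_uV / stats.avg_p2p_uV,
        negpeak_scale=stats.min_negpeak_uV / stats.avg_negpeak_uV,
        avg_p2p_uV=stats.avg_p2p_uV,
        avg_negpeak_uV=stats.avg_negpeak_uV,
    )


def apply_prefilter(
    morphologies: list[EventMorphology],
    criteria: PrefilterCriteria,
    avg_p2p_uV: float | None = None,
    avg_negpeak_uV: float | None = None,
) -> tuple[list[int], dict[str, int]]:
    """Apply derived criteria to a candidate set.

    Parameters
    ----------
    morphologies
        One morphology per candidate event.
    criteria
        Thresholds from :func:`derive_criteria` (or hand-set).
    avg_p2p_uV, avg_negpeak_uV
        Channel averages the scale factors multiply; default to the averages
        stored in ``criteria`` (the derivation channel's).

    Returns
    -------
    (retained_indices, rejection_tally)
        Indices of retained events, and a tally keyed by the first violated
        criterion for each rejected event.
    """
    avg_p2p = criteria.avg_p2p_uV if avg_p2p_uV is None else avg_p2p_uV
    avg_neg = criteria.avg_negpeak_uV if avg_negpeak_uV is None else avg_negpeak_uV
    amp_floor = criteria.amp_scale * avg_p2p
    neg_ceiling = criteria.negpeak_scale * avg_neg  # a (weakly) negative voltage

    retained: list[int] = []
    tally: dict[str, int] = {}

    def reject(reason: str) -> None:
        tally[reason] = tally.get(reason, 0) + 1

    for i, m in enumerate(morphologies):
        if m.d_total < criteria.min_duration_s:
            reject("min_duration")
            continue
        violated = None
        for name in GRID_PARAMETERS:
            if _param_value(m, name) > criteria.upper_bounds[name]:
                violated = name
                break
        if violated is not None:
            reject(violated)
            continue
        if m.p2p_amplitude_uV < amp_floor:
            reject("amp_scale")
            continue
        if m.neg_peak_uV > neg_ceiling:  # must be at least as negative
            reject("negpeak_scale")
            continue
        retained.append(i)
    return retained, tally
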