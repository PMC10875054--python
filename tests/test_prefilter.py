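import numpy as np
import pytest

from sleepso.events import EventMorphology
from sleepso.evaluation import EvaluationCounts
from sleepso.exceptions import InsufficientDataError, ValidationError
from sleepso.prefilter import (
    GRID_PARAMETERS,
    PrefilterCriteria,
    apply_prefilter,
    channel_stats,
    criterion_grid,
    derive_criteria,
    fpr,
    tpr,
)


def make_morph(
    d_total=1.2,
    d_to_negpeak=0.4,
    d_neg_to_pospeak=0.5,
    d_pospeak_to_end=0.3,
    n_pos_peaks=1,
    neg=-60.0,
    pos=40.0,
):
    return EventMorphology(
        d_total=d_total,
        d_to_negpeak=d_to_negpeak,
        d_neg_to_pospeak=d_neg_to_pospeak,
        d_pospeak_to_end=d_pospeak_to_end,
        n_pos_peaks=n_pos_peaks,
        neg_peak_uV=neg,
        pos_peak_uV=pos,
        p2p_amplitude_uV=pos - neg,
        neg_peak_sample=0,
    )


class TestRates:
    def test_tpr_arithmetic(self):
        assert tpr(EvaluationCounts(tp=8, fn=2, fp=0, tn=0)) == pytest.approx(0.8)
        assert tpr(EvaluationCounts(tp=57_936, fn=0, fp=0, tn=0)) == 1.0

    def test_degenerate_rates_are_zero(self):
        empty = EvaluationCounts(tp=0, fn=0, fp=0, tn=0)
        assert tpr(empty) == 0.0
        assert fpr(empty) == 0.0

    def test_fpr_matches_direct_formula_on_random_counts(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            fp, tn = int(rng.integers(0, 100)), int(rng.integers(1, 100))
            counts = EvaluationCounts(tp=0, fn=0, fp=fp, tn=tn)
            assert fpr(counts) == pytest.approx(fp / (fp + tn))
        assert fpr(EvaluationCounts(tp=0, fn=0, fp=3, tn=7)) == pytest.approx(0.3)
        assert fpr(EvaluationCounts(tp=0, fn=0, fp=0, tn=10)) == 0.0

    def test_negative_counts_rejected(self):
        with pytest.raises(ValidationError):
            EvaluationCounts(tp=-1, fn=0, fp=0, tn=0)


class TestChannelStats:
    def test_single_event_degenerate_stats(self):
        stats = channel_stats([(make_morph(), "SO")])
        assert all(stats.sd[name] == 0.0 for name in GRID_PARAMETERS)
        assert stats.min_p2p_uV == stats.avg_p2p_uV
        assert stats.min_negpeak_uV == stats.avg_negpeak_uV

    def test_two_event_population_sd(self):
        labeled = [(make_morph(d_total=1.0), "SO"), (make_morph(d_total=2.0), "SO")]
        stats = channel_stats(labeled)
        assert stats.mean["d_total"] == pytest.approx(1.5)
        assert stats.sd["d_total"] == pytest.approx(0.5)  # population SD

    def test_matches_streaming_recomputation(self):
        rng = np.random.default_rng(5)
        labeled = []
        for _ in range(200):
            lab = "SO" if rng.random() < 0.6 else "nonSO"
            labeled.append((make_morph(
                d_total=float(rng.uniform(0.8, 3.0)),
                neg=float(-rng.uniform(20, 100)),
                pos=float(rng.uniform(10, 60)),
                n_pos_peaks=int(rng.integers(1, 4)),
            ), lab))
        stats = channel_stats(labeled)
        # independent streaming (Welford) second pass over SO events only
        n = 0
        mean = 0.0
        m2 = 0.0
        for m, lab in labeled:
            if lab != "SO":
                continue
            n += 1
            delta = m.d_total - mean
            mean += delta / n
            m2 += delta * (m.d_total - mean)
        assert stats.mean["d_total"] == pytest.approx(mean, abs=1e-12)
        assert stats.sd["d_total"] == pytest.approx(np.sqrt(m2 / n), abs=1e-12)
        assert stats.n_so == n

    def test_no_so_events_rejected(self):
        with pytest.raises(InsufficientDataError):
            channel_stats([(make_morph(), "nonSO")])


class TestDeriveCriteria:
    def test_grid_spacing(self):
        grid = criterion_grid(mean=1.5, sd=0.25)
        np.testing.assert_allclose(grid, np.arange(1.0, 2.001, 0.125))

    def test_integer_grid_is_rounded(self):
        grid = criterion_grid(mean=1.3, sd=0.5, integer=True)
        assert np.all(grid == np.round(grid))

    def test_all_so_walk_matches_enumeration(self):
        # with FPR pinned at 0, the walk stops at the first step that loses
        # any TP; enumerating the nine grid evaluations gives the expected
        # stopping value (the maximum, unless top grid cells are empty)
        rng = np.random.default_rng(2)
        labeled = [
            (make_morph(
                d_total=float(rng.uniform(1.0, 2.0)),
                d_to_negpeak=float(rng.uniform(0.2, 0.8)),
                d_neg_to_pospeak=float(rng.uniform(0.2, 0.8)),
                d_pospeak_to_end=float(rng.uniform(0.2, 0.8)),
            ), "SO")
            for _ in range(60)
        ]
        crit = derive_criteria(labeled)
        stats = channel_stats(labeled)
        for name in ("d_total", "d_to_negpeak", "d_neg_to_pospeak",
                     "d_pospeak_to_end"):
            grid = criterion_grid(stats.mean[name], stats.sd[name])
            values = np.array([getattr(m, name) for m, _ in labeled])
            k = 8
            while k > 0 and np.sum(values <= grid[k]) == np.sum(values <= grid[k - 1]):
                k -= 1  # no TP lost and no FP gained: keep stepping
            assert crit.upper_bounds[name] == pytest.approx(grid[k])
            # and the stopping value never cuts into the labeled SOs
            assert np.sum(values <= crit.upper_bounds[name]) == len(values)

    def test_pure_fp_tail_advances_below_maximum(self):
        # one SO outlier widens the grid so that the top grid cell contains
        # only non-SO events: the first step down loses no TPs but removes
        # FPs, so the walk must advance below the maximum
        labeled = [(make_morph(d_total=v), "SO")
                   for v in np.linspace(1.0, 1.4, 20)]
        labeled.append((make_morph(d_total=2.2), "SO"))
        labeled += [(make_morph(d_total=1.65), "nonSO") for _ in range(30)]
        crit = derive_criteria(labeled)
        stats = channel_stats(labeled)
        grid = criterion_grid(stats.mean["d_total"], stats.sd["d_total"])
        assert 1.65 < grid[8]  # the FP tail sits inside the top grid cell
        assert crit.upper_bounds["d_total"] < grid[8]
        # ... and the chosen bound excludes the planted non-SO cluster
        assert crit.upper_bounds["d_total"] < 1.65

    def test_recovers_planted_threshold_within_one_grid_step(self):
        # SO durations ~ U(1.0, 1.8); non-SO durations sit above 1.9:
        # the separating threshold is ~1.85
        rng = np.random.default_rng(3)
        labeled = [(make_morph(d_total=float(rng.uniform(1.0, 1.8))), "SO")
                   for _ in range(120)]
        labeled += [(make_morph(d_total=float(rng.uniform(1.9, 3.2))), "nonSO")
                    for _ in range(120)]
        crit = derive_criteria(labeled)
        stats = channel_stats(labeled)
        step = 4 * stats.sd["d_total"] / 8
        assert 1.8 - step <= crit.upper_bounds["d_total"] <= 1.9 + step

    def test_scale_factors_are_min_over_avg(self):
        labeled = [
            (make_morph(neg=-80.0, pos=40.0), "SO"),
            (make_morph(neg=-40.0, pos=20.0), "SO"),
        ]
        crit = derive_criteria(labeled)
        # p2p: 120 and 60 -> min/avg = 60/90
        assert crit.amp_scale == pytest.approx(60 / 90)
        # neg peaks -80, -40 -> least negative / avg = -40 / -60
        assert crit.negpeak_scale == pytest.approx(40 / 60)

    def test_deterministic(self):
        rng = np.random.default_rng(9)
        labeled = [(make_morph(d_total=float(rng.uniform(0.9, 3.0))),
                    "SO" if rng.random() < 0.5 else "nonSO")
                   for _ in range(80)]
        assert derive_criteria(labeled) == derive_criteria(labeled)

    def test_empty_set_rejected(self):
        with pytest.raises(InsufficientDataError):
            derive_criteria([])


def permissive_criteria() -> PrefilterCriteria:
    return PrefilterCriteria(
        upper_bounds={name: np.inf for name in GRID_PARAMETERS},
        amp_scale=0.0,
        negpeak_scale=0.0,
        avg_p2p_uV=100.0,
        avg_negpeak_uV=-60.0,
    )


class TestApplyPrefilter:
    def test_permissive_criteria_keep_all_long_enough(self):
        morphs = [make_morph(d_total=d) for d in (0.8, 1.2, 3.4)]
        retained, tally = apply_prefilter(morphs, permissive_criteria())
        assert retained == [0, 1, 2]
        assert tally == {}

    def test_minimum_duration_is_absolute(self):
        # 0.7 s is rejected regardless of every other criterion
        retained, tally = apply_prefilter(
            [make_morph(d_total=0.7)], permissive_criteria()
        )
        assert retained == []
        assert tally == {"min_duration": 1}

    def test_matches_bruteforce_on_random_events(self):
        rng = np.random.default_rng(11)
        morphs = [
            make_morph(
                d_total=float(rng.uniform(0.5, 4.0)),
                d_to_negpeak=float(rng.uniform(0.1, 1.5)),
                d_neg_to_pospeak=float(rng.uniform(0.1, 1.5)),
                d_pospeak_to_end=float(rng.uniform(0.1, 1.5)),
                n_pos_peaks=int(rng.integers(1, 5)),
                neg=float(-rng.uniform(10, 120)),
                pos=float(rng.uniform(5, 80)),
            )
            for _ in range(1000)
        ]
        crit = PrefilterCriteria(
            upper_bounds={
                "d_total": 2.5, "d_to_negpeak": 0.9, "d_neg_to_pospeak": 1.0,
                "d_pospeak_to_end": 1.1, "n_pos_peaks": 2,
            },
            amp_scale=0.5, negpeak_scale=0.5,
            avg_p2p_uV=100.0, avg_negpeak_uV=-60.0,
        )
        retained, tally = apply_prefilter(morphs, crit)
        expected = [
            i for i, m in enumerate(morphs)
            if m.d_total >= 0.8
            and m.d_total <= 2.5
            and m.d_to_negpeak <= 0.9
            and m.d_neg_to_pospeak <= 1.0
            and m.d_pospeak_to_end <= 1.1
            and m.n_pos_peaks <= 2
            and m.p2p_amplitude_uV >= 0.5 * 100.0
            and m.neg_peak_uV <= 0.5 * -60.0
        ]
        assert retained == expected
        assert len(retained) + sum(tally.values()) == len(morphs)

    def test_relaxing_a_threshold_never_shrinks_retention(self):
        rng = np.random.default_rng(13)
        morphs = [
            make_morph(
                d_total=float(rng.uniform(0.5, 4.0)),
                n_pos_peaks=int(rng.integers(1, 5)),
                neg=float(-rng.uniform(10, 120)),
            )
            for _ in range(300)
        ]
        crit = PrefilterCriteria(
            upper_bounds={
                "d_total": 2.0, "d_to_negpeak": 0.5, "d_neg_to_pospeak": 0.6,
                "d_pospeak_to_end": 0.5, "n_pos_peaks": 2,
            },
            amp_scale=0.6, negpeak_scale=0.6,
            avg_p2p_uV=100.0, avg_negpeak_uV=-60.0,
        )
        base = set(apply_prefilter(morphs, crit)[0])
        for name in GRID_PARAMETERS:
            relaxed_bounds = dict(crit.upper_bounds)
            relaxed_bounds[name] = relaxed_bounds[name] * 2
            relaxed = PrefilterCriteria(
                upper_bounds=relaxed_bounds,
                amp_scale=crit.amp_scale, negpeak_scale=crit.negpeak_scale,
                avg_p2p_uV=crit.avg_p2p_uV, avg_negpeak_uV=crit.avg_negpeak_uV,
            )
            assert base <= set(apply_prefilter(morphs, relaxed)[0])

    def test_criteria_json_roundtrip(self):
        crit = permissive_criteria()
        assert PrefilterCriteria.from_dict(crit.to_dict()) == crit
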