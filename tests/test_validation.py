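"""Validation-battery tests: concordance vs exhaustive enumeration and
reference implementations, E-value closed forms, CV/stratified/landmark
behavior, and the proportional-hazards score test."""

import numpy as np
import pandas as pd
import pytest

from sleeproutine import GeneratorConfig, generate_cohort
from sleeproutine import smoothcox as sx
from sleeproutine.validation import (
    CVResult,
    ValidationError,
    evalue,
    harrell_c,
    kfold_cv,
    landmark_refit,
    ph_check,
    stratified_refits,
    uno_c,
)


def brute_force_harrell(risk, time, event):
    """Independent O(n^2) pair enumeration."""
    num = den = 0.0
    n = len(risk)
    for i in range(n):
        if event[i] != 1:
            continue
        for j in range(n):
            if time[j] > time[i]:
                den += 1
                if risk[i] > risk[j]:
                    num += 1
                elif risk[i] == risk[j]:
                    num += 0.5
    return num / den


def brute_force_uno(risk, time, event, tau):
    """Independent enumeration with hand-rolled censoring KM weights."""
    # censoring KM: treat censorings as events
    order = np.argsort(time)
    G = 1.0
    G_at = {}
    t_sorted = np.asarray(time)[order]
    e_sorted = np.asarray(event)[order]
    for k, (t, e) in enumerate(zip(t_sorted, e_sorted)):
        # G just BEFORE t: current G
        G_at.setdefault(t, G)
        if e == 0:
            at_risk = np.sum(t_sorted >= t)
            d = np.sum((t_sorted == t) & (e_sorted == 0))
            if t not in getattr(brute_force_uno, "_done", set()):
                pass
    # recompute cleanly: unique censoring times
    G = 1.0
    G_before = {}
    for t in np.unique(t_sorted):
        G_before[t] = G
        d = np.sum((t_sorted == t) & (e_sorted == 0))
        r = np.sum(t_sorted >= t)
        if d:
            G *= 1 - d / r
    num = den = 0.0
    n = len(risk)
    for i in range(n):
        if event[i] != 1 or time[i] >= tau:
            continue
        w = 1.0 / G_before[time[i]] ** 2
        for j in range(n):
            if time[j] > time[i]:
                den += w
                if risk[i] > risk[j]:
                    num += w
                elif risk[i] == risk[j]:
                    num += 0.5 * w
    return num / den


class TestHarrell:
    def test_perfect_ordering_uncensored(self):
        time = np.array([1.0, 2, 3, 4, 5])
        risk = -time  # higher risk fails earlier
        assert harrell_c(risk, time, np.ones(5, int)) == 1.0

    def test_random_scores_near_half(self):
        rng = np.random.default_rng(0)
        n = 3000
        time = rng.exponential(1, n)
        event = np.ones(n, int)
        c = harrell_c(rng.normal(size=n), time, event)
        assert c == pytest.approx(0.5, abs=0.03)

    def test_worked_set_matches_enumeration(self):
        time = np.array([2.0, 4.0, 4.5, 6.0, 7.0])
        event = np.array([1, 1, 0, 1, 0])
        risk = np.array([0.9, 0.1, 0.4, 0.4, 0.2])
        expected = brute_force_harrell(risk, time, event)
        assert harrell_c(risk, time, event) == pytest.approx(expected)

    def test_no_comparable_pairs_error(self):
        with pytest.raises(ValidationError):
            harrell_c(np.r_[1.0, 2.0], np.r_[1.0, 1.0], np.r_[0, 0])

    def test_matches_lifelines_on_random_data(self):
        from lifelines.utils import concordance_index

        rng = np.random.default_rng(4)
        for _ in range(5):
            n = 80
            risk = rng.normal(size=n)
            t = rng.exponential(1 / np.exp(risk))
            c = rng.exponential(1.5, n)
            time, event = np.minimum(t, c), (t <= c).astype(int)
            ours = harrell_c(risk, time, event)
            ref = concordance_index(time, -risk, event)
            assert ours == pytest.approx(ref, abs=1e-10)


class TestUno:
    def test_equals_harrell_without_censoring(self):
        rng = np.random.default_rng(2)
        n = 200
        risk = rng.normal(size=n)
        time = rng.exponential(1 / np.exp(risk))
        event = np.ones(n, int)
        tau = time.max() + 1
        assert uno_c(risk, time, event, tau) == pytest.approx(
            harrell_c(risk, time, event), abs=1e-12
        )

    def test_toy_set_matches_hand_weighted_enumeration(self):
        time = np.array([1.0, 2.0, 2.5, 3.0, 5.0, 6.0])
        event = np.array([1, 0, 1, 1, 0, 1])
        risk = np.array([0.8, 0.3, 0.6, 0.1, 0.2, 0.4])
        expected = brute_force_uno(risk, time, event, tau=8.0)
        assert uno_c(risk, time, event, 8.0) == pytest.approx(expected)

    def test_invariant_to_monotone_score_transform(self):
        rng = np.random.default_rng(3)
        n = 150
        risk = rng.normal(size=n)
        t = rng.exponential(1 / np.exp(risk))
        c = rng.exponential(2, n)
        time, event = np.minimum(t, c), (t <= c).astype(int)
        a = uno_c(risk, time, event, 8.0)
        b = uno_c(np.exp(3 * risk), time, event, 8.0)
        assert a == pytest.approx(b, abs=1e-12)

    def test_matches_scikit_survival(self):
        from sksurv.metrics import concordance_index_ipcw
        from sksurv.util import Surv

        rng = np.random.default_rng(9)
        n = 300
        risk = rng.normal(size=n)
        t = rng.exponential(1 / np.exp(risk))
        c = rng.exponential(2, n)
        time, event = np.minimum(t, c), (t <= c).astype(int)
        tau = np.quantile(time, 0.8)
        y = Surv.from_arrays(event.astype(bool), time)
        ref = concordance_index_ipcw(y, y, risk, tau=tau)[0]
        assert uno_c(risk, time, event, tau) == pytest.approx(ref, abs=1e-8)


class TestEValue:
    @pytest.mark.parametrize(
        "hr,expected",
        [
            (1.0, 1.0),
            (2.0, 2.0 + np.sqrt(2.0)),
            (0.79, 1.8459),
        ],
    )
    def test_closed_forms(self, hr, expected):
        assert evalue(hr).evalue == pytest.approx(expected, abs=1e-4)

    def test_self_inverse_in_hr(self):
        rng = np.random.default_rng(1)
        for hr in rng.uniform(0.1, 5.0, 25):
            assert evalue(hr).evalue == pytest.approx(evalue(1 / hr).evalue)

    def test_ordering_invariant(self):
        for hr in (0.3, 0.9, 1.5, 4.0):
            r = evalue(hr)
            assert r.evalue >= r.rr_star >= 1.0

    def test_invalid_hr(self):
        with pytest.raises(ValidationError):
            evalue(-1.0)


class TestKFoldCV:
    def test_signal_gives_discrimination_above_chance(self, small_cohort):
        cv = kfold_cv(small_cohort, k=3, seed=0)
        assert cv.fold_count == 3
        assert cv.harrell_test_mean > 0.53
        assert all(0 <= c <= 1 for c in cv.harrell_train + cv.uno_test)
        assert cv.frame().shape == (3, 5)

    def test_train_at_least_test_on_average(self, small_cohort):
        cv = kfold_cv(small_cohort, k=3, seed=1)
        assert cv.optimism > -0.05  # train should not trail test materially


class TestStratifiedAndLandmark:
    def test_landmark_window_zero_is_pooled_fit(self, small_cohort):
        pooled = sx.fit(small_cohort)
        lm = landmark_refit(small_cohort, window=0.0)
        assert np.allclose(pooled.beta, lm.beta)

    def test_landmark_excludes_early_events_only(self, small_cohort):
        lm = landmark_refit(small_cohort, window=2.0)
        pooled = sx.fit(small_cohort)
        n_early = int(
            (
                (small_cohort["event"] == 1)
                & (small_cohort["time_years"] < 2.0)
                & (small_cohort["prior_diagnosis"] == 0)
            ).sum()
        )
        assert lm.n == pooled.n - n_early

    def test_landmark_removing_all_events_errors(self, small_cohort):
        with pytest.raises(ValidationError):
            landmark_refit(small_cohort, window=100.0)

    def test_stratified_structure_and_skipping(self, small_cohort):
        res = stratified_refits(small_cohort, min_events=40)
        assert set(res) == {"pooled", "female", "male", "younger", "older"}
        for name, r in res.items():
            if not r.skipped:
                assert np.isfinite(r.argmin.asd) and np.isfinite(r.argmin.rsh)
        tiny = stratified_refits(small_cohort, min_events=10**6)
        assert all(r.skipped for k, r in tiny.items() if k != "pooled")


class _StubModel:
    """Minimal model stand-in for ph_check: identity sleep effect."""

    def __init__(self, effect=lambda a, r: a, eta=None):
        self._effect = effect
        self._eta = eta

    def sleep_effect(self, a, r):
        return np.asarray(self._effect(np.asarray(a, float), np.asarray(r, float)))

    def linear_predictor(self, df):
        if self._eta is None:
            return np.zeros(len(df))
        return self._eta(df)


def _ph_frame(s, time, event):
    return pd.DataFrame(
        {
            "asd": s,
            "rsh": np.zeros_like(s),
            "time_years": time,
            "event": event,
            "prior_diagnosis": np.zeros_like(event),
        }
    )


class TestPHCheck:
    def test_residuals_match_hand_computation(self):
        s = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        time = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        event = np.array([1, 1, 0, 1, 1])
        # pad with later events so the 10-event minimum is met; everyone is
        # still at risk at the first event time, keeping the hand value
        s_full = np.r_[s, np.full(10, 3.0)]
        t_full = np.r_[time, np.linspace(10, 19, 10)]
        e_full = np.r_[event, np.ones(10, int)]
        res = ph_check(_StubModel(), _ph_frame(s_full, t_full, e_full))
        # hand-computed residual at the first event: s=1 minus risk-set mean
        mean_all = s_full.mean()
        assert res.residuals["residual"].iloc[0] == pytest.approx(1.0 - mean_all)

    def test_type_one_error_under_proportional_hazards(self):
        rng = np.random.default_rng(30)
        reject = 0
        reps = 120
        for _ in range(reps):
            n = 150
            s = rng.normal(size=n)
            t = rng.exponential(1 / np.exp(0.5 * s))
            c = rng.exponential(2, n)
            time, event = np.minimum(t, c), (t <= c).astype(int)
            # the residual weights must use the model's linear predictor
            stub = _StubModel(
                effect=lambda a, r: 0.5 * a,
                eta=lambda df: 0.5 * df["asd"].to_numpy(),
            )
            res = ph_check(stub, _ph_frame(s, time, event))
            reject += res.p < 0.05
        assert abs(reject / reps - 0.05) < 3 * np.sqrt(0.05 * 0.95 / reps) + 0.01

    def test_time_varying_effect_is_detected(self):
        rng = np.random.default_rng(31)
        n = 3000
        s = rng.normal(size=n)
        # effect reverses over time: high-s fails early, low-s fails late
        t = np.where(s > 0, rng.exponential(0.5, n), 2.0 + rng.exponential(2.0, n))
        event = np.ones(n, int)
        res = ph_check(_StubModel(), _ph_frame(s, t, event))
        assert res.p < 1e-4

    def test_too_few_events_rejected(self):
        s = np.arange(12.0)
        res_frame = _ph_frame(s, s + 1, np.r_[np.ones(5, int), np.zeros(7, int)])
        with pytest.raises(ValidationError):
            ph_check(_StubModel(), res_frame)
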