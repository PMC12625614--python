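"""Validation battery for the 2D-smooth Cox model.

Cross-validated concordance (Harrell's C and Uno's IPCW C), the VanderWeele
E-value for unmeasured confounding, stratified refits (sex, median-age
split), landmark exclusion of early events, and a Grambsch-Therneau-style
proportional-hazards check on the fitted sleep-effect predictor.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import smoothcox as sx

__all__ = [
    "harrell_c",
    "uno_c",
    "kfold_cv",
    "evalue",
    "stratified_refits",
    "landmark_refit",
    "ph_check",
    "CVResult",
    "EValueResult",
]


class ValidationError(ValueError):
    pass


# ---------------------------------------------------------------------------
# concordance


def harrell_c(risk: np.ndarray, time: np.ndarray, event: np.ndarray) -> float:
    """Harrell's concordance index.

    A pair (i, j) is comparable when ``t_i < t_j`` and subject *i* had the
    event; it is concordant when the earlier-failing subject has the higher
    risk score.  Ties in risk count one half.
    """
    risk = np.asarray(risk, float)
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    ev_idx = np.nonzero(event == 1)[0]
    num = den = 0.0
    for i in ev_idx:
        comparable = time > time[i]
        n_comp = int(comparable.sum())
        if n_comp == 0:
            continue
        den += n_comp
        num += (risk[i] > risk[comparable]).sum()
        num += 0.5 * (risk[i] == risk[comparable]).sum()
    if den == 0:
        raise ValidationError("no comparable pairs; concordance undefined")
    return float(num / den)


def _censoring_km(time: np.ndarray, event: np.ndarray):
    """Kaplan-Meier estimate of the censoring survival function G(t).

    Censoring is the 'event' here; deaths are censored observations.
    Returns step times (ascending) and G values just after each step.
    """
    order = np.argsort(time, kind="stable")
    t, e = time[order], event[order]
    n = len(t)
    at_risk = n - np.arange(n)
    is_cens = e == 0
    uniq = np.unique(t[is_cens])
    G = 1.0
    times, values = [], []
    for u in uniq:
        d = int(np.sum((t == u) & is_cens))
        r = int(np.sum(t >= u))
        G *= 1.0 - d / r
        times.append(u)
        values.append(G)
    return np.asarray(times), np.asarray(values)


def _G_at(times: np.ndarray, values: np.ndarray, query: np.ndarray, before=True):
    """Censoring survival G(t-) (left limit) at query times."""
    if len(times) == 0:
        return np.ones_like(np.asarray(query, float))
    side = "left" if before else "right"
    idx = np.searchsorted(times, query, side=side)
    out = np.r_[1.0, values][idx]
    return out


def uno_c(
    risk: np.ndarray,
    time: np.ndarray,
    event: np.ndarray,
    truncation: float = 8.0,
) -> float:
    """Uno's IPCW concordance, truncated at ``truncation`` years.

    Comparable pairs (t_i < t_j, event_i = 1, t_i < truncation) are weighted
    by 1 / G(t_i-)^2 where G is the Kaplan-Meier estimate of the censoring
    distribution.  Reduces exactly to Harrell's C when censoring is absent.
    """
    risk = np.asarray(risk, float)
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    gt, gv = _censoring_km(time, event)
    ev_idx = np.nonzero((event == 1) & (time < truncation))[0]
    if ev_idx.size == 0:
        raise ValidationError("no events before the truncation time")
    Gi = _G_at(gt, gv, time[ev_idx])
    if np.any(Gi <= 0):
        raise ValidationError(
            "censoring survival reaches 0 before the truncation time; "
            "lower the truncation"
        )
    w = 1.0 / Gi**2
    num = den = 0.0
    for k, i in enumerate(ev_idx):
        comparable = time > time[i]
        n_comp = int(comparable.sum())
        if n_comp == 0:
            continue
        den += w[k] * n_comp
        num += w[k] * (
            (risk[i] > risk[comparable]).sum()
            + 0.5 * (risk[i] == risk[comparable]).sum()
        )
    if den == 0:
        raise ValidationError("no comparable pairs; concordance undefined")
    return float(num / den)


# ---------------------------------------------------------------------------
# cross-validation


@dataclass
class CVResult:
    fold_count: int
    harrell_train: list
    harrell_test: list
    uno_train: list
    uno_test: list

    @property
    def harrell_train_mean(self):
        return float(np.mean(self.harrell_train))

    @property
    def harrell_test_mean(self):
        return float(np.mean(self.harrell_test))

    @property
    def uno_train_mean(self):
        return float(np.mean(self.uno_train))

    @property
    def uno_test_mean(self):
        return float(np.mean(self.uno_test))

    @property
    def optimism(self):
        return self.harrell_train_mean - self.harrell_test_mean

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "fold": np.arange(self.fold_count),
                "harrell_train": self.harrell_train,
                "harrell_test": self.harrell_test,
                "uno_train": self.uno_train,
                "uno_test": self.uno_test,
            }
        )


def kfold_cv(
    cohort: pd.DataFrame,
    spec: sx.ModelSpec | None = None,
    k: int = 10,
    seed: int = 0,
    truncation: float = 8.0,
    **fit_kwargs,
) -> CVResult:
    """k-fold cross-validated concordance, folds stratified by event status.

    Each fold's model is fitted on the remaining folds and scored (linear
    predictor as the risk score) on both splits.
    """
    df = cohort
    if "prior_diagnosis" in df.columns:
        df = df[df["prior_diagnosis"] == 0]
    df = df.reset_index(drop=True)
    event = df["event"].to_numpy(int)
    rng = np.random.default_rng(seed)
    fold = np.empty(len(df), dtype=int)
    for grp in (event == 1, event == 0):
        idx = np.nonzero(grp)[0]
        fold[rng.permutation(idx)] = np.arange(len(idx)) % k
    # guard: every fold needs at least one event; refold deterministically
    for attempt in range(10):
        counts = np.bincount(fold[event == 1], minlength=k)
        if counts.min() > 0:
            break
        warnings.warn("a fold had no events; refolding")
        idx = np.nonzero(event == 1)[0]
        fold[rng.permutation(idx)] = np.arange(len(idx)) % k

    ht, hs, ut, us = [], [], [], []
    for f in range(k):
        tr = df[fold != f]
        te = df[fold == f]
        model = sx.fit(tr, spec, **fit_kwargs)
        for part, H, U in ((tr, ht, ut), (te, hs, us)):
            risk = model.linear_predictor(part)
            t = part["time_years"].to_numpy(float)
            e = part["event"].to_numpy(int)
            H.append(harrell_c(risk, t, e))
            U.append(uno_c(risk, t, e, truncation))
    return CVResult(k, ht, hs, ut, us)


# ---------------------------------------------------------------------------
# E-value


@dataclass
class EValueResult:
    hr: float
    rr_star: float
    evalue: float


def evalue(hr: float) -> EValueResult:
    """VanderWeele E-value for a hazard ratio (rare-outcome approximation).

    The minimum strength of association, on the risk-ratio scale, that an
    unmeasured confounder would need with both exposure and outcome to
    explain away the observed ratio:  E = RR* + sqrt(RR* (RR* - 1)) with
    RR* = max(HR, 1/HR).
    """
    if not np.isfinite(hr) or hr <= 0:
        raise ValidationError(f"hazard ratio must be positive; got {hr}")
    rr = hr if hr >= 1 else 1.0 / hr
    ev = rr + np.sqrt(rr * (rr - 1.0))
    return EValueResult(hr=float(hr), rr_star=float(rr), evalue=float(ev))


# ---------------------------------------------------------------------------
# stratified and landmark refits


@dataclass
class StratumResult:
    name: str
    n: int
    n_events: int
    argmin: sx.SurfaceArgmin | None
    skipped: bool = False
    departs: bool = False


def stratified_refits(
    cohort: pd.DataFrame,
    spec: sx.ModelSpec | None = None,
    min_events: int = 50,
    departure_hours: float = 1.0,
    **fit_kwargs,
) -> dict:
    """Refit per stratum (female, male, younger, older at the median age).

    Sex is removed from the stratified specs (it is constant within the sex
    strata).  Flags strata whose surface argmin departs more than
    ``departure_hours`` from the pooled argmin on either axis.
    """
    spec = spec or sx.default_model_spec()
    df = cohort
    if "prior_diagnosis" in df.columns:
        df = df[df["prior_diagnosis"] == 0]
    pooled = sx.fit(df, spec, **fit_kwargs)
    pooled_am = sx.surface_argmin(pooled)
    med_age = float(df["age"].median())
    strata = {
        "female": df[df["sex"] == "female"],
        "male": df[df["sex"] == "male"],
        "younger": df[df["age"] < med_age],
        "older": df[df["age"] >= med_age],
    }
    out = {"pooled": StratumResult("pooled", len(df), int(df["event"].sum()), pooled_am)}
    for name, sub in strata.items():
        n_ev = int(sub["event"].sum())
        if n_ev < min_events or len(sub) == 0:
            warnings.warn(f"stratum {name}: only {n_ev} events; skipped")
            out[name] = StratumResult(name, len(sub), n_ev, None, skipped=True)
            continue
        sspec = spec
        if name in ("female", "male") and "sex" in spec.linear_terms:
            sspec = spec.drop_term("sex")
        m = sx.fit(sub, sspec, **fit_kwargs)
        am = sx.surface_argmin(m)
        departs = (
            abs(am.asd - pooled_am.asd) > departure_hours
            or abs(am.rsh - pooled_am.rsh) > departure_hours
        )
        out[name] = StratumResult(name, len(sub), n_ev, am, departs=departs)
    return out


def landmark_refit(
    cohort: pd.DataFrame,
    spec: sx.ModelSpec | None = None,
    window: float = 2.0,
    **fit_kwargs,
) -> sx.SmoothCoxModel:
    """Refit ignoring any event within ``window`` years of the sleep study.

    Participants whose event occurred inside the window are excluded
    entirely; everyone else enters unchanged.  With ``window = 0`` this is
    identical to the pooled fit.  Probes reverse causation: undiagnosed
    disease at baseline that disturbs sleep would load on early events.
    """
    if window < 0:
        raise ValidationError("landmark window must be non-negative")
    df = cohort
    if "prior_diagnosis" in df.columns:
        df = df[df["prior_diagnosis"] == 0]
    early = (df["event"] == 1) & (df["time_years"] < window)
    kept = df[~early]
    if kept["event"].sum() == 0:
        raise ValidationError("the landmark window removes every event")
    return sx.fit(kept, spec, **fit_kwargs)


# ---------------------------------------------------------------------------
# proportional-hazards check


@dataclass
class PHCheckResult:
    statistic: float
    p: float
    residuals: pd.DataFrame = field(repr=False)


def ph_check(model: sx.SmoothCoxModel, cohort: pd.DataFrame) -> PHCheckResult:
    """Schoenfeld-residual test of proportional hazards for the sleep term.

    The fitted 2D sleep effect is treated as a single predictor ``s_i``;
    at each event time the Schoenfeld residual is ``s_event - E_w[s | risk
    set]`` with weights ``exp(eta)``.  A Grambsch-Therneau-style score test
    correlates the residuals with event time (identity transform):

        X^2 = [ sum (t_k - tbar) r_k ]^2 / [ sum (t_k - tbar)^2 v_k ]

    with ``v_k`` the weighted risk-set variance of ``s``; X^2 ~ chi2(1)
    under proportional hazards.  The residual table is returned for
    plotting residuals against time.
    """
    df = cohort
    if "prior_diagnosis" in df.columns:
        df = df[df["prior_diagnosis"] == 0]
    df = df.reset_index(drop=True)
    time = df["time_years"].to_numpy(float)
    event = df["event"].to_numpy(int)
    if event.sum() < 10:
        raise ValidationError("fewer than 10 events; PH check unreliable")
    s = model.sleep_effect(df["asd"].to_numpy(float), df["rsh"].to_numpy(float))
    eta = model.linear_predictor(df)
    w = np.exp(eta)

    order = np.argsort(time, kind="stable")
    t_s, e_s, s_s, w_s = time[order], event[order], s[order], w[order]
    ev_pos = np.nonzero(e_s == 1)[0]
    res, var, times = [], [], []
    # suffix sums for risk sets (t >= t_i)
    cw = np.cumsum(w_s[::-1])[::-1]
    cws = np.cumsum((w_s * s_s)[::-1])[::-1]
    cws2 = np.cumsum((w_s * s_s**2)[::-1])[::-1]
    for i in ev_pos:
        j = np.searchsorted(t_s, t_s[i], side="left")
        W, M1, M2 = cw[j], cws[j], cws2[j]
        mean = M1 / W
        v = max(M2 / W - mean**2, 1e-12)
        res.append(s_s[i] - mean)
        var.append(v)
        times.append(t_s[i])
    res = np.asarray(res)
    var = np.asarray(var)
    times = np.asarray(times)
    g = times - times.mean()
    num = float(np.sum(g * res)) ** 2
    den = float(np.sum(g**2 * var))
    stat = num / den if den > 0 else np.nan
    from scipy.stats import chi2

    p = float(chi2.sf(stat, 1))
    table = pd.DataFrame(
        {"time_years": times, "residual": res, "scaled_residual": res / var}
    )
    return PHCheckResult(statistic=float(stat), p=p, residuals=table)
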