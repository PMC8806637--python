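"""Survival evaluation: KM curves, log-rank, time-dependent AUC, C-index,
and uni-/multivariable Cox tables over clinical factors plus risk score.

Time-dependent AUC follows the cumulative-case / dynamic-control
definition with inverse-probability-of-censoring weights (IPCW): at
horizon t, cases are subjects with an observed event by t and controls
are subjects still event-free beyond t. Without censoring the estimator
reduces exactly to the empirical probability that a random case
outranks a random control (ties count one half).

Harrell's C considers a subject pair comparable when the earlier time
is an observed event and the times differ; concordant pairs have the
higher risk score on the earlier failure, tied scores count one half.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from scipy import stats
from sksurv.metrics import cumulative_dynamic_auc
from sksurv.util import Surv

from .signature import CoxFitResult

__all__ = [
    "KMEstimate",
    "EvaluationReport",
    "km_estimate",
    "logrank_test",
    "time_dependent_auc",
    "harrell_cindex",
    "multivariate_cox",
    "group_score_comparison",
]

CLINICAL_FACTORS = ("age", "gender", "grade", "stage")


@dataclass
class KMEstimate:
    """Product-limit survival estimate for one group."""

    group: str
    times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    events: np.ndarray

    def survival_at(self, t: float) -> float:
        """Right-continuous step-function lookup."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


@dataclass
class EvaluationReport:
    """Collected evaluation results for one cohort."""

    cohort: str = ""
    logrank_chi2: float | None = None
    logrank_p: float | None = None
    auc: dict[float, float] = field(default_factory=dict)
    c_index: float | None = None
    univariate: list[CoxFitResult] = field(default_factory=list)
    multivariate: list[CoxFitResult] = field(default_factory=list)

    def to_dict(self) -> dict:
        def rows(results):
            return [vars(r) for r in results]

        return {
            "cohort": self.cohort,
            "logrank_chi2": self.logrank_chi2,
            "logrank_p": self.logrank_p,
            "auc": {str(k): v for k, v in self.auc.items()},
            "c_index": self.c_index,
            "univariate": rows(self.univariate),
            "multivariate": rows(self.multivariate),
        }


def _check_surv(times, events):
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if (times < 0).any():
        raise ValueError("survival times must be non-negative")
    if not np.isin(events, (0, 1)).all():
        raise ValueError("event indicators must be 0 or 1")
    return times, events


def km_estimate(times, events, groups=None) -> list[KMEstimate]:
    """Kaplan-Meier estimate per group (one overall group if none given)."""
    times, events = _check_surv(times, events)
    if groups is None:
        groups = np.full(times.size, "all")
    groups = np.asarray(groups)
    out = []
    for g in pd.unique(groups):
        mask = groups == g
        if not mask.any():
            raise ValueError(f"empty group {g!r}")
        kmf = KaplanMeierFitter()
        kmf.fit(times[mask], events[mask])
        ev = kmf.event_table
        # drop the synthetic t=0 anchor row unless subjects actually exit there
        ev = ev[(ev["observed"] + ev["censored"]) > 0]
        out.append(
            KMEstimate(
                group=str(g),
                times=ev.index.to_numpy(dtype=float),
                survival=kmf.survival_function_.reindex(ev.index).iloc[:, 0].to_numpy(),
                at_risk=ev["at_risk"].to_numpy(dtype=float),
                events=ev["observed"].to_numpy(dtype=float),
            )
        )
    return out


def logrank_test(times, events, groups) -> tuple[float, float]:
    """Log-rank test across groups (chi-square, p; df = n_groups - 1)."""
    times, events = _check_surv(times, events)
    groups = np.asarray(groups)
    labels = pd.unique(groups)
    if labels.size < 2:
        raise ValueError("log-rank test needs at least two groups")
    res = multivariate_logrank_test(times, groups, events)
    return float(res.test_statistic), float(res.p_value)


def time_dependent_auc(scores, times, events, horizon: float) -> float:
    """IPCW cumulative/dynamic AUC at one horizon."""
    times, events = _check_surv(times, events)
    scores = np.asarray(scores, dtype=float)
    horizon = float(horizon)
    cases = (times <= horizon) & (events == 1)
    controls = times > horizon
    if not cases.any() or not controls.any():
        raise ValueError(
            f"horizon {horizon} leaves no cases or no controls "
            f"({int(cases.sum())} cases, {int(controls.sum())} controls)"
        )
    y = Surv.from_arrays(event=events.astype(bool), time=times)
    auc, _ = cumulative_dynamic_auc(y, y, scores, [horizon])
    return float(auc[0])


def harrell_cindex(scores, times, events) -> float:
    """Harrell's concordance index with tied scores counting one half."""
    times, events = _check_surv(times, events)
    scores = np.asarray(scores, dtype=float)
    t_i = times[:, None]
    t_j = times[None, :]
    d_i = (events == 1)[:, None]
    # pair (i, j) comparable when i fails first (observed) strictly before j
    comparable = (t_i < t_j) & d_i
    s_i = scores[:, None]
    s_j = scores[None, :]
    credit = np.where(s_i > s_j, 1.0, np.where(s_i == s_j, 0.5, 0.0))
    n_comp = int(comparable.sum())
    if n_comp == 0:
        raise ValueError("no comparable pairs under censoring")
    return float(credit[comparable].sum() / n_comp)


def multivariate_cox(
    clinical: pd.DataFrame,
    scores: pd.Series,
    entry_alpha: float = 0.001,
) -> tuple[list[CoxFitResult], list[CoxFitResult]]:
    """Univariate Cox per prognostic indicator, then a joint model.

    The five indicators are age, gender (male=1), grade, stage (both
    ordinal 1-4) and the continuous risk score. Indicators with
    univariate Wald p <= ``entry_alpha`` enter the joint fit. Returns
    (univariate table, multivariate table); the latter is empty when no
    indicator passes entry.
    """
    df = clinical.loc[scores.index, list(CLINICAL_FACTORS) + ["os_time", "os_event"]].copy()
    df["gender"] = (df["gender"].astype(str).str.lower() == "male").astype(float)
    for c in ("age", "grade", "stage"):
        df[c] = pd.to_numeric(df[c])
    df["risk_score"] = scores.to_numpy(dtype=float)
    covariates = list(CLINICAL_FACTORS) + ["risk_score"]

    uni: list[CoxFitResult] = []
    for cov in covariates:
        cph = CoxPHFitter()
        cph.fit(df[[cov, "os_time", "os_event"]], "os_time", "os_event")
        uni.append(
            CoxFitResult.from_wald(
                cov, float(cph.params_[cov]), float(cph.standard_errors_[cov])
            )
        )

    entrants = [r.covariate for r in uni if r.p <= entry_alpha]
    multi: list[CoxFitResult] = []
    if entrants:
        sub = df[entrants + ["os_time", "os_event"]]
        rank = np.linalg.matrix_rank(sub[entrants].to_numpy())
        if rank < len(entrants):
            raise ValueError(f"singular design among covariates {entrants}")
        cph = CoxPHFitter()
        cph.fit(sub, "os_time", "os_event")
        multi = [
            CoxFitResult.from_wald(
                cov, float(cph.params_[cov]), float(cph.standard_errors_[cov])
            )
            for cov in entrants
        ]
    return uni, multi


def group_score_comparison(scores, group_mask) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum comparison of scores between groups.

    ``group_mask`` is a boolean vector (e.g. stage 3-4 vs stage 1-2).
    Returns (U statistic, p-value).
    """
    scores = np.asarray(scores, dtype=float)
    group_mask = np.asarray(group_mask, dtype=bool)
    a, b = scores[group_mask], scores[~group_mask]
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    res = stats.mannwhitneyu(a, b, alternative="two-sided")
    return float(res.statistic), float(res.pvalue)
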