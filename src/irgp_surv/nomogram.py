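"""United prognostic model: clinical stage + gene-pair risk score.

A two-covariate Cox proportional-hazards fit combines tumour stage
(ordinal 1-4) with the continuous pair-signature risk score. The fit is
re-expressed as a nomogram: each covariate's contribution to the linear
predictor is mapped affinely to a points scale on which the
widest-range covariate spans exactly 0-100, and total points translate
into predicted survival at fixed horizons through the Breslow baseline
cumulative hazard, ``S(t | x) = S0(t) ** exp(beta' x)``.

Calibration bins a cohort by predicted survival at a horizon and
compares each bin's mean prediction with the Kaplan-Meier estimate
observed in that bin.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter

from ._cox import breslow_baseline_hazard
from .metrics import km_estimate
from .signature import RiskProfile

__all__ = [
    "NomogramModel",
    "CalibrationTable",
    "fit_united_model",
    "united_risk_stratify",
    "calibration_table",
    "simulate_from_model",
]


@dataclass
class NomogramModel:
    """Two-covariate Cox model with points mapping and baseline hazard."""

    coefficients: dict[str, float]
    covariate_ranges: dict[str, tuple[float, float]]  # training min/max
    baseline_times: np.ndarray
    baseline_cumhaz: np.ndarray

    def linear_predictor(self, covariates: pd.DataFrame) -> pd.Series:
        lp = np.zeros(len(covariates))
        for name, beta in self.coefficients.items():
            lp = lp + beta * covariates[name].to_numpy(dtype=float)
        return pd.Series(lp, index=covariates.index, name="united_score")

    def points(self, covariates: pd.DataFrame) -> pd.DataFrame:
        """Per-covariate nomogram points; widest covariate spans [0, 100].

        The mapping is affine in each covariate: the value minimising
        the hazard contribution over the training range earns 0 points.
        Validation samples outside the training range may exceed 100.
        """
        spans = {
            name: abs(beta) * (hi - lo)
            for name, beta in self.coefficients.items()
            for lo, hi in [self.covariate_ranges[name]]
        }
        denom = max(spans.values())
        if denom == 0:
            raise ValueError("all covariates are constant; no points scale")
        cols = {}
        for name, beta in self.coefficients.items():
            lo, hi = self.covariate_ranges[name]
            x = covariates[name].to_numpy(dtype=float)
            contrib = beta * x
            base = min(beta * lo, beta * hi)  # lowest-risk end of the range
            cols[name] = 100.0 * (contrib - base) / denom
        out = pd.DataFrame(cols, index=covariates.index)
        out["total"] = out.sum(axis=1)
        return out

    def baseline_survival_at(self, t: float) -> float:
        idx = np.searchsorted(self.baseline_times, t, side="right") - 1
        h0 = 0.0 if idx < 0 else float(self.baseline_cumhaz[idx])
        return float(np.exp(-h0))

    def predict_survival(self, covariates: pd.DataFrame, t: float) -> pd.Series:
        s0 = self.baseline_survival_at(t)
        lp = self.linear_predictor(covariates)
        return pd.Series(s0 ** np.exp(lp.to_numpy()), index=covariates.index)

    def to_json(self) -> str:
        return json.dumps(
            {
                "coefficients": self.coefficients,
                "covariate_ranges": {
                    k: list(v) for k, v in self.covariate_ranges.items()
                },
                "baseline_times": self.baseline_times.tolist(),
                "baseline_cumhaz": self.baseline_cumhaz.tolist(),
            },
            indent=1,
        )

    @classmethod
    def from_json(cls, text: str) -> "NomogramModel":
        d = json.loads(text)
        return cls(
            coefficients={k: float(v) for k, v in d["coefficients"].items()},
            covariate_ranges={
                k: (float(v[0]), float(v[1])) for k, v in d["covariate_ranges"].items()
            },
            baseline_times=np.asarray(d["baseline_times"], dtype=float),
            baseline_cumhaz=np.asarray(d["baseline_cumhaz"], dtype=float),
        )


@dataclass
class CalibrationTable:
    """Predicted vs observed survival per risk bin at one horizon."""

    horizon: float
    predicted: list[float]
    observed: list[float]
    bin_sizes: list[int]
    flagged: list[bool] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "horizon": self.horizon,
                "predicted": self.predicted,
                "observed": self.observed,
                "n": self.bin_sizes,
                "flagged": self.flagged or [False] * len(self.predicted),
            }
        )


def fit_united_model(
    stage, risk_scores, times, events, covariate_names=("stage", "risk_score")
) -> NomogramModel:
    """Fit the two-covariate (stage, risk score) Cox model.

    Baseline cumulative hazard is the Breslow estimator at covariate
    values of zero, so survival lookups are ``S0(t) ** exp(lp)`` with
    the uncentred linear predictor.
    """
    stage = np.asarray(stage, dtype=float)
    risk_scores = np.asarray(risk_scores, dtype=float)
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    s_name, r_name = covariate_names
    for name, arr in ((s_name, stage), (r_name, risk_scores)):
        if np.ptp(arr) == 0:
            raise ValueError(f"covariate {name!r} does not vary; cannot fit")
    df = pd.DataFrame(
        {s_name: stage, r_name: risk_scores, "os_time": times, "os_event": events}
    )
    cph = CoxPHFitter()
    cph.fit(df, "os_time", "os_event")
    coefs = {s_name: float(cph.params_[s_name]), r_name: float(cph.params_[r_name])}
    lp = stage * coefs[s_name] + risk_scores * coefs[r_name]
    bt, bh = breslow_baseline_hazard(lp, times, events)
    return NomogramModel(
        coefficients=coefs,
        covariate_ranges={
            s_name: (float(stage.min()), float(stage.max())),
            r_name: (float(risk_scores.min()), float(risk_scores.max())),
        },
        baseline_times=bt,
        baseline_cumhaz=bh,
    )


def united_risk_stratify(model: NomogramModel, covariates: pd.DataFrame) -> RiskProfile:
    """Median split of the united model's linear predictor (per cohort)."""
    scores = model.linear_predictor(covariates)
    cutoff = float(scores.median())
    groups = pd.Series(
        np.where(scores.to_numpy() > cutoff, "high", "low"),
        index=scores.index,
        name="risk_group",
    )
    return RiskProfile(scores=scores, cutoff=cutoff, groups=groups)


def simulate_from_model(
    model: NomogramModel, covariates: pd.DataFrame, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Draw survival data from the fitted model itself.

    Inverse-transform sampling through the Breslow baseline: for
    u ~ U(0,1) the event time is the first baseline time where
    H0(t) >= -log(u) / exp(lp). Subjects whose target exceeds the
    observed baseline range are administratively censored at the last
    baseline time. Useful for calibration self-consistency checks.
    """
    lp = model.linear_predictor(covariates).to_numpy()
    n = lp.size
    u = rng.uniform(size=n)
    target = -np.log(u) / np.exp(lp)
    idx = np.searchsorted(model.baseline_cumhaz, target, side="left")
    beyond = idx >= model.baseline_times.size
    idx = np.clip(idx, 0, model.baseline_times.size - 1)
    times = model.baseline_times[idx]
    events = np.where(beyond, 0, 1)
    return times, events


def calibration_table(
    model: NomogramModel,
    covariates: pd.DataFrame,
    times,
    events,
    horizon: float,
    n_bins: int = 3,
) -> CalibrationTable:
    """Bin by predicted survival quantiles; compare with observed KM.

    Bins with no usable follow-up information at the horizon (no events
    and nobody at risk beyond it) are flagged rather than dropped.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if horizon > times.max():
        raise ValueError(f"horizon {horizon} exceeds observed follow-up {times.max():.3g}")
    pred = model.predict_survival(covariates, horizon).to_numpy()
    order = np.argsort(pred, kind="stable")
    bins = np.array_split(order, n_bins)

    predicted, observed, sizes, flagged = [], [], [], []
    for idx in bins:
        if idx.size == 0:
            continue
        t_b, e_b = times[idx], events[idx]
        km = km_estimate(t_b, e_b)[0]
        usable = (e_b[t_b <= horizon].sum() > 0) or (t_b > horizon).any()
        predicted.append(float(pred[idx].mean()))
        observed.append(km.survival_at(horizon))
        sizes.append(int(idx.size))
        flagged.append(not usable)
    return CalibrationTable(
        horizon=float(horizon),
        predicted=predicted,
        observed=observed,
        bin_sizes=sizes,
        flagged=flagged,
    )
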