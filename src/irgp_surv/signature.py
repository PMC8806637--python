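"""Prognostic gene-pair signature: screening, selection, and scoring.

The signature is built in two stages on the training cohort. First every
candidate pair indicator is screened with a single-covariate Cox
proportional-hazards model, retaining pairs with Wald p below a strict
threshold (default 0.001). Second, the screened indicators enter an
L1-penalised (LASSO) Cox regression; the penalty is chosen by k-fold
cross-validated partial-likelihood deviance, and pairs with a non-zero
coefficient at that penalty form the signature.

A sample's risk score is the dot product of its 0/1 pair indicators
with the signature coefficients:

    risk = sum_k  I(expr[gene_a_k] > expr[gene_b_k]) * coef_k

Cohorts are dichotomised at the median risk score (ties go to the
low-risk group).

The 11-pair clear-cell renal cell carcinoma signature published with
this method ships as package data; see :func:`load_published_signature`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.model_selection import KFold
from sksurv.linear_model import CoxnetSurvivalAnalysis
from sksurv.util import Surv

from ._cox import cox_partial_loglik, fit_univariate_cox
from .cohorts import ExpressionCohort
from .pairs import Pair, PairIndicatorMatrix

__all__ = [
    "CoxFitResult",
    "IRGPSignature",
    "RiskProfile",
    "univariate_cox_screen",
    "lasso_cox_select",
    "risk_score",
    "score_expression",
    "median_stratify",
    "load_published_signature",
]


@dataclass(frozen=True)
class CoxFitResult:
    """Wald summary of one covariate in a Cox PH fit."""

    covariate: str
    coef: float
    hr: float
    se: float
    z: float
    p: float
    ci_lower: float
    ci_upper: float

    @classmethod
    def from_wald(cls, covariate: str, coef: float, se: float) -> "CoxFitResult":
        from scipy import stats

        z = coef / se
        half = 1.959963984540054 * se
        return cls(
            covariate=covariate,
            coef=coef,
            hr=float(np.exp(coef)),
            se=se,
            z=z,
            p=float(2.0 * stats.norm.sf(abs(z))),
            ci_lower=float(np.exp(coef - half)),
            ci_upper=float(np.exp(coef + half)),
        )


@dataclass
class IRGPSignature:
    """Ordered list of (gene_a, gene_b, coefficient) entries.

    Orientation is as stored: the entry's indicator is 1 when gene_a is
    expressed above gene_b.
    """

    entries: list[tuple[str, str, float]]
    provenance: str = "fitted"

    def __post_init__(self) -> None:
        pairs = [(a, b) for a, b, _ in self.entries]
        if len(set(pairs)) != len(pairs):
            raise ValueError("duplicate pairs in signature")
        coefs = np.array([c for _, _, c in self.entries], dtype=float)
        if coefs.size and (~np.isfinite(coefs) | (coefs == 0)).any():
            raise ValueError("signature coefficients must be finite and non-zero")

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def pairs(self) -> list[Pair]:
        return [(a, b) for a, b, _ in self.entries]

    @property
    def coefficients(self) -> np.ndarray:
        return np.array([c for _, _, c in self.entries], dtype=float)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.entries, columns=["gene_a", "gene_b", "coefficient"])

    def write(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def read(cls, path, provenance: str | None = None) -> "IRGPSignature":
        df = pd.read_csv(Path(path), sep="\t")
        entries = [
            (str(r.gene_a), str(r.gene_b), float(r.coefficient))
            for r in df.itertuples(index=False)
        ]
        return cls(entries=entries, provenance=provenance or str(path))


@dataclass
class RiskProfile:
    """Per-sample continuous risk score and high/low group label."""

    scores: pd.Series
    cutoff: float | None = None
    groups: pd.Series | None = None  # "high" / "low"


def load_published_signature() -> IRGPSignature:
    """The published 11-pair ccRCC prognostic signature (package data)."""
    ref = resources.files("irgp_surv").joinpath("data/ccrcc_11_pair_signature.tsv")
    with resources.as_file(ref) as path:
        sig = IRGPSignature.read(path, provenance="published")
    return sig


def univariate_cox_screen(
    m: PairIndicatorMatrix,
    clinical: pd.DataFrame,
    alpha: float = 0.001,
    return_all: bool = False,
) -> list[tuple[Pair, CoxFitResult]]:
    """Screen pair indicators with single-covariate Cox models.

    Each pair's 0/1 indicator is the lone covariate of a Cox PH fit on
    (os_time, os_event); pairs with Wald p < ``alpha`` are returned.
    Pairs that are constant in the cohort (or separate the likelihood)
    cannot be fitted and are skipped with a warning.
    """
    clin = clinical.loc[m.sample_ids]
    time = clin["os_time"].to_numpy(dtype=float)
    event = clin["os_event"].to_numpy(dtype=int)
    if event.sum() < 2:
        raise ValueError("need at least two events for the univariate screen")
    res = fit_univariate_cox(m.values.astype(float), time, event)
    n_skipped = int((~res.converged).sum())
    if n_skipped:
        warnings.warn(
            f"{n_skipped} pair(s) skipped in the univariate screen "
            "(constant indicator or monotone likelihood)",
            stacklevel=2,
        )
    out = []
    for i, pair in enumerate(m.pairs):
        if not res.converged[i]:
            continue
        if return_all or res.p[i] < alpha:
            out.append(
                (pair, CoxFitResult.from_wald("|".join(pair), res.coef[i], res.se[i]))
            )
    return out


def lasso_cox_select(
    m: PairIndicatorMatrix,
    clinical: pd.DataFrame,
    max_iter: int = 10_000,
    seed: int = 0,
    n_folds: int = 10,
    l1_ratio: float = 1.0,
) -> IRGPSignature:
    """LASSO-penalised Cox fit with cross-validated penalty choice.

    Fits the full regularisation path, then scores each penalty by
    k-fold cross-validated partial-likelihood deviance (Breslow form)
    with a seeded fold assignment, and keeps the coefficients at the
    deviance-minimising penalty. Pairs with non-zero coefficients form
    the signature.
    """
    if m.n_pairs == 0:
        raise ValueError("no screened pairs to select from")
    clin = clinical.loc[m.sample_ids]
    time = clin["os_time"].to_numpy(dtype=float)
    event = clin["os_event"].to_numpy(dtype=int)
    X = m.values.T.astype(float)  # samples x pairs
    y = Surv.from_arrays(event=event.astype(bool), time=time)

    path = CoxnetSurvivalAnalysis(
        l1_ratio=l1_ratio, alpha_min_ratio=0.001, n_alphas=60, max_iter=max_iter
    )
    path.fit(X, y)
    alphas = np.asarray(path.alphas_)

    n_folds_eff = min(n_folds, int(event.sum()))
    kf = KFold(n_splits=n_folds_eff, shuffle=True, random_state=seed)
    # CV deviance at each alpha: -2 * held-out Breslow partial log-likelihood
    dev = np.zeros((n_folds_eff, alphas.size))
    for k, (tr, te) in enumerate(kf.split(X)):
        fold = CoxnetSurvivalAnalysis(
            l1_ratio=l1_ratio, alphas=alphas, max_iter=max_iter
        )
        fold.fit(X[tr], y[tr])
        # a fold may truncate the path; interpolate its coefficients in
        # log-penalty onto the global grid (clamped at the ends)
        coefs = _coefs_on_grid(alphas, np.asarray(fold.alphas_), fold.coef_)
        for j in range(alphas.size):
            lp = X[te] @ coefs[:, j]
            dev[k, j] = -2.0 * cox_partial_loglik(lp, time[te], event[te])
    best = int(np.argmin(dev.mean(axis=0)))
    coef = path.coef_[:, best]

    entries = [
        (a, b, float(c)) for (a, b), c in zip(m.pairs, coef) if c != 0.0
    ]
    if not entries:
        raise ValueError(
            "LASSO shrank every coefficient to zero; consider a weaker penalty rule"
        )
    return IRGPSignature(entries=entries, provenance="fitted")


def _coefs_on_grid(
    grid: np.ndarray, fitted_alphas: np.ndarray, fitted_coefs: np.ndarray
) -> np.ndarray:
    """Interpolate a coefficient path onto a target penalty grid."""
    if fitted_alphas.size == fitted_coefs.shape[1] and np.array_equal(
        fitted_alphas, grid
    ):
        return fitted_coefs
    lg = np.log(grid)
    lf = np.log(fitted_alphas)
    order = np.argsort(lf)
    out = np.empty((fitted_coefs.shape[0], grid.size))
    for i in range(fitted_coefs.shape[0]):
        out[i] = np.interp(lg, lf[order], fitted_coefs[i, order])
    return out


def risk_score(m: PairIndicatorMatrix, sig: IRGPSignature) -> RiskProfile:
    """Weighted sum of pair indicators with the signature coefficients.

    Signature pairs are looked up in the matrix first in their stored
    orientation; when only the reversed orientation is present the
    indicator is flipped (1 - value), which is exact in the absence of
    within-pair expression ties.
    """
    rows = np.zeros((len(sig), m.n_samples))
    index = {p: i for i, p in enumerate(m.pairs)}
    for k, (a, b) in enumerate(sig.pairs):
        if (a, b) in index:
            rows[k] = m.values[index[(a, b)]]
        elif (b, a) in index:
            rows[k] = 1.0 - m.values[index[(b, a)]]
        else:
            raise KeyError(f"signature pair {a}|{b} not computable from the pair matrix")
    scores = sig.coefficients @ rows
    return RiskProfile(scores=pd.Series(scores, index=m.sample_ids, name="risk_score"))


def score_expression(cohort: ExpressionCohort, sig: IRGPSignature) -> RiskProfile:
    """Risk scores straight from an expression cohort (no pair matrix)."""
    genes = {g for p in sig.pairs for g in p}
    missing = sorted(genes - set(cohort.values.index))
    if missing:
        raise KeyError(f"signature genes absent from cohort: {missing}")
    expr = cohort.values
    indicators = np.vstack(
        [
            (expr.loc[a].to_numpy() > expr.loc[b].to_numpy()).astype(float)
            for a, b in sig.pairs
        ]
    )
    scores = sig.coefficients @ indicators
    return RiskProfile(scores=pd.Series(scores, index=cohort.sample_ids, name="risk_score"))


def median_stratify(profile: RiskProfile, cutoff: float | None = None) -> RiskProfile:
    """Dichotomise at the median score (or a supplied reference cutoff).

    A sample is high-risk iff its score strictly exceeds the cutoff;
    scores equal to the cutoff fall in the low-risk group. By default
    each cohort is stratified at its own median.
    """
    scores = profile.scores
    if scores.empty:
        raise ValueError("no scores to stratify")
    if cutoff is None:
        cutoff = float(scores.median())
    groups = pd.Series(
        np.where(scores.to_numpy() > cutoff, "high", "low"),
        index=scores.index,
        name="risk_group",
    )
    return RiskProfile(scores=scores, cutoff=float(cutoff), groups=groups)
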