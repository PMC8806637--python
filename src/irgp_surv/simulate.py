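"""Synthetic multi-platform expression cohorts with survival ground truth.

The generator emulates the data regime the gene-pair method targets:
two cohorts measured on different platforms (an RNA-seq-like cohort on
a log2 scale and a microarray-like cohort emitted on a linear scale,
with platform-specific offset and gain), a designated immune-gene
subset, ordinal tumour stage, and overall survival whose hazard is
driven by a known set of gene-pair indicators. Every downstream stage
therefore has a recoverable truth.

Generative model
----------------
* Per-gene baseline ``mu_g`` drawn once from a normal on the log2 scale
  (lognormal expression); per-sample biological noise N(0, noise_sd^2)
  added on that scale.
* Platform transform: strictly increasing affine map of the log2 signal
  (gain ``platform_scales[k]``, shift ``platform_offsets[k]``); the
  second platform is exponentiated back to a linear scale. Being
  strictly increasing, the transform leaves within-sample gene ranks —
  and hence all pair indicators — untouched.
* True pairs: disjoint gene pairs whose two members share a baseline, so
  the indicator is an even coin flip per sample; the log hazard adds
  ``true_log_hazard_ratios[k]`` when the indicator is 1.
* Survival: proportional hazards with a Weibull baseline (shape 1 =
  exponential by default, for closed-form checks);
  ``h(t | x) = baseline_hazard * shape * t^(shape-1) * exp(lp - E[lp])``
  with ``lp = sum_k beta_k I_k + stage_effect_log_hr * (stage - 1)``.
  Centring at the analytic mean E[lp] makes ``baseline_hazard`` the
  event rate of the typical patient regardless of effect sizes; Cox
  fits are invariant to the shift.
* Censoring: independent Uniform(0, c) with c solved numerically so the
  expected censored fraction matches the target.

Default parameters mirror a two-platform renal-carcinoma study: cohort
sizes 537 and 101, stage marginals 0.50/0.10/0.22/0.18, roughly 30%
observed deaths (censoring target 0.7).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .cohorts import ExpressionCohort, write_clinical, write_expression

__all__ = ["SimulationConfig", "SimulationTruth", "simulate_cohorts", "write_fixture"]

_STAGE_PROBS = (0.50, 0.10, 0.22, 0.18)
_GRADE_PROBS = (0.03, 0.44, 0.39, 0.14)


@dataclass(frozen=True)
class SimulationConfig:
    n_samples: tuple[int, ...] = (537, 101)
    n_genes: int = 600
    n_immune_genes: int = 250
    n_true_pairs: int = 5
    true_log_hazard_ratios: tuple[float, ...] = (0.7, 0.7, 0.7, 0.7, 0.7)
    baseline_hazard: float = 0.12  # events per year at lp = 0
    weibull_shape: float = 1.0  # 1.0 -> exponential baseline
    censoring_rate: float = 0.7
    platform_offsets: tuple[float, ...] = (0.0, 1.0)
    platform_scales: tuple[float, ...] = (1.0, 1.2)
    noise_sd: float = 1.0
    stage_effect_log_hr: float = 0.4
    stage_probs: tuple[float, ...] = _STAGE_PROBS
    seed: int = 0

    def __post_init__(self) -> None:
        if any(n <= 0 for n in self.n_samples):
            raise ValueError("sample counts must be positive")
        if not 0 < self.n_immune_genes <= self.n_genes:
            raise ValueError("n_immune_genes must be in (0, n_genes]")
        if self.n_true_pairs < 0:
            raise ValueError("n_true_pairs must be non-negative")
        if len(self.true_log_hazard_ratios) != self.n_true_pairs:
            raise ValueError("need one log hazard ratio per true pair")
        if 2 * self.n_true_pairs > self.n_immune_genes:
            raise ValueError(
                f"{self.n_true_pairs} true pairs need "
                f"{2 * self.n_true_pairs} distinct immune genes, only "
                f"{self.n_immune_genes} available"
            )
        if self.baseline_hazard <= 0 or self.noise_sd <= 0 or self.weibull_shape <= 0:
            raise ValueError("baseline_hazard, noise_sd, weibull_shape must be positive")
        if not 0 <= self.censoring_rate < 1:
            raise ValueError("censoring_rate must lie in [0, 1)")
        if not (
            len(self.platform_offsets) == len(self.platform_scales) == len(self.n_samples)
        ):
            raise ValueError("per-platform parameter lengths must match n_samples")
        if any(s <= 0 for s in self.platform_scales):
            raise ValueError("platform scales must be positive (order-preserving)")
        if abs(sum(self.stage_probs) - 1.0) > 1e-9 or len(self.stage_probs) != 4:
            raise ValueError("stage_probs must be 4 probabilities summing to 1")


@dataclass
class SimulationTruth:
    """Ground truth behind a simulated study."""

    true_pairs: list[tuple[str, str]]
    true_coefficients: list[float]
    immune_genes: list[str]
    linear_predictors: list[pd.Series]  # one per platform, incl. stage effect
    stages: list[pd.Series]

    def __post_init__(self) -> None:
        if len(self.true_pairs) != len(self.true_coefficients):
            raise ValueError("pair/coefficient length mismatch")


def _solve_censoring_bound(
    cum_hazard_coefs: np.ndarray, shape: float, target: float
) -> float:
    """Upper bound c of Uniform(0, c) censoring hitting the target rate.

    For subject i with cumulative hazard H_i(t) = k_i * t^shape the
    probability of being censored is (1/c) * \\int_0^c exp(-k_i u^shape) du;
    the mean over subjects is matched to ``target`` by bisection.
    """

    def censored_fraction(c: float) -> float:
        u = np.linspace(0.0, c, 513)
        surv = np.exp(-np.outer(cum_hazard_coefs, u**shape))
        mean_surv = surv.mean(axis=0)
        return float(np.trapezoid(mean_surv, u) / c)

    lo, hi = 1e-9, 1.0
    while censored_fraction(hi) > target:
        hi *= 2.0
        if hi > 1e9:  # pragma: no cover - pathological hazards
            raise RuntimeError("cannot reach target censoring rate")
    return brentq(lambda c: censored_fraction(c) - target, lo, hi, xtol=1e-10)


def simulate_cohorts(
    config: SimulationConfig,
) -> tuple[list[ExpressionCohort], list[pd.DataFrame], SimulationTruth]:
    """Draw expression, clinical covariates, and survival for each platform."""
    rng = np.random.default_rng(config.seed)
    genes = [f"G{i:04d}" for i in range(config.n_genes)]
    immune = genes[: config.n_immune_genes]

    mu = rng.normal(3.0, 1.5, size=config.n_genes)
    # true pairs: first 2*k immune genes, members sharing a baseline so the
    # indicator is a fair coin; orientation stored lexicographically
    true_pairs: list[tuple[str, str]] = []
    for k in range(config.n_true_pairs):
        ga, gb = immune[2 * k], immune[2 * k + 1]
        shared = 0.5 * (mu[2 * k] + mu[2 * k + 1])
        mu[2 * k] = mu[2 * k + 1] = shared
        true_pairs.append((ga, gb) if ga < gb else (gb, ga))
    betas = list(config.true_log_hazard_ratios)

    cohorts: list[ExpressionCohort] = []
    clinicals: list[pd.DataFrame] = []
    lps: list[pd.Series] = []
    stages_out: list[pd.Series] = []
    for plat_idx, n in enumerate(config.n_samples):
        sample_ids = [f"P{plat_idx + 1}S{i:04d}" for i in range(n)]
        base = mu[:, None] + rng.normal(0.0, config.noise_sd, size=(config.n_genes, n))

        # hazard driven by indicators of the *base* signal; the platform
        # transform below is strictly increasing, so emitted-scale
        # indicators are identical
        gpos = {g: i for i, g in enumerate(genes)}
        lp = np.zeros(n)
        for (ga, gb), beta in zip(true_pairs, betas):
            ind = base[gpos[ga]] > base[gpos[gb]]
            lp += beta * ind

        stage = rng.choice([1, 2, 3, 4], size=n, p=config.stage_probs)
        grade = rng.choice([1, 2, 3, 4], size=n, p=_GRADE_PROBS)
        age = np.clip(np.round(rng.normal(60.0, 10.0, size=n)), 30, 90).astype(int)
        gender = rng.choice(["male", "female"], size=n, p=(0.67, 0.33))
        lp = lp + config.stage_effect_log_hr * (stage - 1)

        # centre the hazard at the analytic mean linear predictor so
        # baseline_hazard is the event rate of the typical patient
        # (Cox fits are invariant to the constant shift)
        mean_lp = 0.5 * float(np.sum(betas)) + config.stage_effect_log_hr * float(
            np.dot(config.stage_probs, (0, 1, 2, 3))
        )
        k_i = config.baseline_hazard * np.exp(lp - mean_lp)
        # inverse-transform sampling: H(T) = k_i * T^shape ~ Exp(1)
        t_event = (rng.exponential(1.0, size=n) / k_i) ** (1.0 / config.weibull_shape)
        if config.censoring_rate > 0:
            c = _solve_censoring_bound(k_i, config.weibull_shape, config.censoring_rate)
            t_cens = rng.uniform(0.0, c, size=n)
            os_time = np.minimum(t_event, t_cens)
            os_event = (t_event <= t_cens).astype(int)
        else:
            os_time = t_event
            os_event = np.ones(n, dtype=int)

        log2_vals = base * config.platform_scales[plat_idx] + config.platform_offsets[plat_idx]
        if plat_idx == 0:
            values, log_scale = log2_vals, True
        else:  # microarray-like platform emitted linear to exercise log2 ingest
            values, log_scale = np.power(2.0, log2_vals), False
        cohorts.append(
            ExpressionCohort(
                values=pd.DataFrame(values, index=genes, columns=sample_ids),
                platform=f"platform{plat_idx + 1}",
                log_scale=log_scale,
            )
        )
        clinicals.append(
            pd.DataFrame(
                {
                    "age": age,
                    "gender": gender,
                    "grade": grade,
                    "stage": stage,
                    "os_time": os_time,
                    "os_event": os_event,
                },
                index=pd.Index(sample_ids, name="sample_id"),
            )
        )
        lps.append(pd.Series(lp, index=sample_ids, name="linear_predictor"))
        stages_out.append(pd.Series(stage, index=sample_ids, name="stage"))

    truth = SimulationTruth(
        true_pairs=true_pairs,
        true_coefficients=betas,
        immune_genes=list(immune),
        linear_predictors=lps,
        stages=stages_out,
    )
    return cohorts, clinicals, truth


def write_fixture(cohorts, clinicals, truth: SimulationTruth, dir_path) -> list[Path]:
    """Write round-trippable TSVs: expression + clinical per platform, one truth file."""
    out = Path(dir_path)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    try:
        for i, (cohort, clin) in enumerate(zip(cohorts, clinicals), start=1):
            ep = out / f"expression_platform{i}.tsv"
            write_expression(cohort, ep)
            cp = out / f"clinical_platform{i}.tsv"
            write_clinical(clin, cp)
            written += [ep, cp]
        tp = out / "truth_pairs.tsv"
        pd.DataFrame(
            {
                "gene_a": [a for a, _ in truth.true_pairs],
                "gene_b": [b for _, b in truth.true_pairs],
                "log_hazard_ratio": truth.true_coefficients,
            }
        ).to_csv(tp, sep="\t", index=False)
        written.append(tp)
        gl = out / "immune_genes.txt"
        gl.write_text("\n".join(truth.immune_genes) + "\n")
        written.append(gl)
    except OSError as exc:  # pragma: no cover
        raise OSError(f"cannot write fixture under {out}: {exc}") from exc
    return written
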