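"""End-to-end orchestration of the gene-pair prognostic workflow.

Stages: simulate (or load) two-platform cohorts -> ingest (log2 where
needed, drop incomplete records) -> variability filter and candidate
pair construction with cross-platform intersection -> 7:3 split of the
first platform into training / validation 1 (platform 2 = validation 2)
-> univariate Cox screen and LASSO-Cox signature on training -> risk
scores and median stratification per cohort -> survival evaluation ->
united stage+score nomogram with calibration.

Every run emits a manifest recording the resolved configuration, seeds,
the record-count funnel (genes retained, pairs built, screened,
selected) and SHA-256 digests of all written artifacts, so identical
seeds reproduce identical runs bit for bit.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import cohorts as cio
from . import metrics as met
from . import nomogram as nom
from . import pairs as prs
from . import signature as sig
from .simulate import SimulationConfig, simulate_cohorts

__all__ = ["PipelineConfig", "RunManifest", "run_pipeline"]

log = logging.getLogger("irgp_surv")


@dataclass
class PipelineConfig:
    """All tunables of the workflow, with the method's standard defaults."""

    # data source: either a simulation config, or file paths
    simulation: SimulationConfig | None = None
    expression_paths: tuple[str, ...] = ()
    clinical_paths: tuple[str, ...] = ()
    log_scale_flags: tuple[bool, ...] = ()
    gene_list_path: str | None = None

    mad_threshold: float = 0.5
    prevalence_bound: float = 0.8
    screen_alpha: float = 0.001
    multivariate_entry_alpha: float = 0.001
    nomogram_entry_alpha: float = 0.05
    lasso_max_iter: int = 10_000
    cv_folds: int = 10
    split_threshold: float = 0.7
    horizons: tuple[float, ...] = (1.0, 3.0, 5.0)
    split_seed: int = 7
    cv_seed: int = 11
    out_dir: str = "irgp_run"

    def __post_init__(self) -> None:
        if list(self.horizons) != sorted(self.horizons) or any(
            h <= 0 for h in self.horizons
        ):
            raise ValueError("horizons must be positive and ascending")
        for name in ("screen_alpha", "multivariate_entry_alpha", "nomogram_entry_alpha"):
            if not 0 < getattr(self, name) < 1:
                raise ValueError(f"{name} must lie in (0, 1)")


@dataclass
class RunManifest:
    config: dict
    counts: dict = field(default_factory=dict)
    digests: dict = field(default_factory=dict)
    notes: list[str] = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=1, sort_keys=True)


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _config_snapshot(config: PipelineConfig) -> dict:
    d = dataclasses.asdict(config)
    return json.loads(json.dumps(d, default=list))


def _load_inputs(config: PipelineConfig):
    if config.simulation is not None:
        cohorts, clinicals, truth = simulate_cohorts(config.simulation)
        return cohorts, clinicals, truth.immune_genes
    if not config.expression_paths:
        raise ValueError("config needs either a simulation block or input paths")
    cohorts = [
        cio.read_expression(p, platform=f"platform{i + 1}", log_scale=flag)
        for i, (p, flag) in enumerate(
            zip(config.expression_paths, config.log_scale_flags)
        )
    ]
    clinicals = [cio.read_clinical(p) for p in config.clinical_paths]
    if config.gene_list_path is None:
        raise ValueError("an immune gene list is required for file inputs")
    return cohorts, clinicals, cio.read_gene_list(config.gene_list_path)


def run_pipeline(config: PipelineConfig) -> RunManifest:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config=_config_snapshot(config))
    counts = manifest.counts

    def stage(name):
        log.info("stage: %s", name)
        return name

    current = stage("load")
    try:
        cohorts, clinicals, immune_genes = _load_inputs(config)

        current = stage("ingest")
        ingested = []
        for cohort, clin in zip(cohorts, clinicals):
            if not cohort.log_scale:
                cohort = cio.log2_transform(cohort)
            clin, cohort = cio.drop_incomplete(clin, cohort)
            ingested.append((cohort, clin))
        counts["samples_per_platform"] = [c.n_samples for c, _ in ingested]

        current = stage("build-pairs")
        fcfg = prs.FilterConfig(
            mad_threshold=config.mad_threshold, prevalence_bound=config.prevalence_bound
        )
        gene_sets = [
            set(prs.mad_filter(cohort, immune_genes, fcfg)) for cohort, _ in ingested
        ]
        common_genes = sorted(set.intersection(*gene_sets))
        counts["genes_retained_per_platform"] = [len(g) for g in gene_sets]
        counts["genes_retained_common"] = len(common_genes)
        if len(common_genes) < 2:
            raise ValueError("fewer than two genes pass the MAD filter on all platforms")

        built = [prs.build_pairs(cohort, common_genes) for cohort, _ in ingested]
        counts["pairs_built"] = built[0].n_pairs
        filtered = [prs.prevalence_filter(m, fcfg) for m in built]
        counts["pairs_after_prevalence"] = [m.n_pairs for m in filtered]
        candidates = prs.intersect_pairs(filtered)
        counts["candidate_pairs"] = len(candidates)
        matrices = [m.subset_pairs(candidates) for m in filtered]

        current = stage("split")
        split = cio.split_cohort(
            matrices[0].sample_ids, seed=config.split_seed, threshold=config.split_threshold
        )
        train_m = matrices[0].subset_samples(split.training)
        train_clin = ingested[0][1].loc[list(split.training)]
        eval_sets = [("training", train_m, train_clin)]
        if split.validation:
            eval_sets.append(
                (
                    "validation1",
                    matrices[0].subset_samples(split.validation),
                    ingested[0][1].loc[list(split.validation)],
                )
            )
        for i in range(1, len(matrices)):
            eval_sets.append((f"validation{i + 1}", matrices[i], ingested[i][1]))
        counts["cohort_sizes"] = {name: m.n_samples for name, m, _ in eval_sets}

        current = stage("fit")
        screened = sig.univariate_cox_screen(train_m, train_clin, alpha=config.screen_alpha)
        counts["pairs_screened"] = len(screened)
        if not screened:
            raise ValueError("no pairs pass the univariate screen")
        screened_m = train_m.subset_pairs([p for p, _ in screened])
        signature = sig.lasso_cox_select(
            screened_m,
            train_clin,
            max_iter=config.lasso_max_iter,
            seed=config.cv_seed,
            n_folds=config.cv_folds,
        )
        counts["signature_size"] = len(signature)
        sig_path = out / "signature.tsv"
        signature.write(sig_path)

        current = stage("score+evaluate")
        reports = []
        profiles = {}
        for name, m, clin in eval_sets:
            profile = sig.median_stratify(sig.risk_score(m, signature))
            profiles[name] = (profile, clin)
            pd.DataFrame(
                {"risk_score": profile.scores, "risk_group": profile.groups}
            ).to_csv(out / f"risk_{name}.tsv", sep="\t")
            reports.append(_evaluate(name, profile, clin, config))
        (out / "evaluation.json").write_text(
            json.dumps([r.to_dict() for r in reports], indent=1)
        )

        current = stage("nomogram")
        train_profile, train_clin2 = profiles["training"]
        _, multi = met.multivariate_cox(
            train_clin2, train_profile.scores, entry_alpha=config.multivariate_entry_alpha
        )
        significant = {
            r.covariate for r in multi if r.p < config.nomogram_entry_alpha
        }
        if {"stage", "risk_score"} <= significant:
            model = nom.fit_united_model(
                train_clin2["stage"],
                train_profile.scores,
                train_clin2["os_time"],
                train_clin2["os_event"],
            )
            (out / "nomogram.json").write_text(model.to_json())
            united = {}
            for name, (profile, clin) in profiles.items():
                cov = pd.DataFrame(
                    {"stage": clin["stage"].astype(float), "risk_score": profile.scores}
                )
                up = nom.united_risk_stratify(model, cov)
                united[name] = float(
                    met.harrell_cindex(
                        up.scores.to_numpy(), clin["os_time"], clin["os_event"]
                    )
                )
                for h in config.horizons:
                    if h > float(clin["os_time"].max()):
                        manifest.notes.append(
                            f"{name}: horizon {h} beyond follow-up, calibration skipped"
                        )
                        continue
                    tab = nom.calibration_table(
                        model, cov, clin["os_time"], clin["os_event"], horizon=h
                    )
                    tab.to_frame().to_csv(
                        out / f"calibration_{name}_{h:g}y.tsv", sep="\t", index=False
                    )
            counts["united_c_index"] = united
        else:
            manifest.notes.append(
                "united model skipped: stage and risk score not both significant "
                f"(significant: {sorted(significant)})"
            )
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {current!r} failed: {exc}") from exc

    for path in sorted(out.glob("*")):
        if path.is_file() and path.name != "manifest.json":
            manifest.digests[path.name] = _digest(path)
    (out / "manifest.json").write_text(manifest.to_json())
    return manifest


def _evaluate(name, profile, clin, config) -> met.EvaluationReport:
    times = clin["os_time"].to_numpy(dtype=float)
    events = clin["os_event"].to_numpy(dtype=int)
    report = met.EvaluationReport(cohort=name)
    chi2, p = met.logrank_test(times, events, profile.groups.to_numpy())
    report.logrank_chi2, report.logrank_p = chi2, p
    scores = profile.scores.to_numpy()
    for h in config.horizons:
        try:
            report.auc[h] = met.time_dependent_auc(scores, times, events, h)
        except ValueError as exc:
            log.warning("%s: AUC at %gy unavailable (%s)", name, h, exc)
    report.c_index = met.harrell_cindex(scores, times, events)
    report.univariate, report.multivariate = met.multivariate_cox(
        clin, profile.scores, entry_alpha=config.multivariate_entry_alpha
    )
    return report
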