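"""Expression/clinical cohort containers, file I/O, and cohort splitting.

Expression matrices are genes x samples TSV files. Clinical tables carry
age, gender, tumour grade and stage (ordinal 1-4), overall-survival time
and event status. Records with any missing required field are dropped
wholesale before modelling, and microarray-style linear-scale cohorts are
brought onto a log2 scale so the two platforms are of comparable
magnitude (pair indicators are unaffected by this, being rank-based).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionCohort",
    "CohortSplit",
    "CLINICAL_COLUMNS",
    "read_expression",
    "read_clinical",
    "read_gene_list",
    "log2_transform",
    "drop_incomplete",
    "split_cohort",
]

#: required clinical fields, one row per sample (index = sample id)
CLINICAL_COLUMNS = ("age", "gender", "grade", "stage", "os_time", "os_event")

_ROMAN = {"i": 1, "ii": 2, "iii": 3, "iv": 4}


@dataclass
class ExpressionCohort:
    """A genes x samples expression matrix with platform metadata.

    ``log_scale`` records whether values are already log-like (log2
    microarray intensities or log-transformed FPKM); linear-scale
    cohorts must pass through :func:`log2_transform` before any
    magnitude-based filtering.
    """

    values: pd.DataFrame
    platform: str = "unknown"
    log_scale: bool = True

    def __post_init__(self) -> None:
        self.values.index.name = "gene"
        self.values.columns.name = None
        if self.values.index.duplicated().any():
            dup = self.values.index[self.values.index.duplicated()][0]
            raise ValueError(f"duplicate gene id: {dup!r}")
        if self.values.columns.duplicated().any():
            dup = self.values.columns[self.values.columns.duplicated()][0]
            raise ValueError(f"duplicate sample id: {dup!r}")
        if not np.isfinite(self.values.to_numpy()).all():
            raise ValueError("expression matrix contains non-finite values")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def subset_samples(self, sample_ids) -> "ExpressionCohort":
        return replace(self, values=self.values.loc[:, list(sample_ids)])

    def subset_genes(self, gene_ids) -> "ExpressionCohort":
        return replace(self, values=self.values.loc[list(gene_ids)])


@dataclass(frozen=True)
class CohortSplit:
    """A seeded uniform-random partition into training and validation."""

    training: tuple[str, ...]
    validation: tuple[str, ...]
    seed: int
    threshold: float = 0.7


def read_expression(path, platform: str = "unknown", log_scale: bool = True) -> ExpressionCohort:
    """Read a genes x samples TSV matrix (first column = gene symbols)."""
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", index_col=0)
    except Exception as exc:  # pragma: no cover - message wrapping
        raise ValueError(f"cannot parse expression matrix {path}: {exc}") from exc
    if not all(np.issubdtype(dt, np.number) for dt in df.dtypes):
        bad = [c for c, dt in df.dtypes.items() if not np.issubdtype(dt, np.number)]
        raise ValueError(f"non-numeric expression values in {path}, columns {bad}")
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return ExpressionCohort(values=df.astype(float), platform=platform, log_scale=log_scale)


def write_expression(cohort: ExpressionCohort, path) -> None:
    df = cohort.values.copy()
    df.index.name = "gene"
    df.to_csv(path, sep="\t")


def _parse_ordinal(value):
    """Grade/stage given as Arabic (1-4) or Roman (I-IV) numerals."""
    if pd.isna(value):
        return np.nan
    s = str(value).strip().lower()
    s = s.removeprefix("stage").removeprefix("grade").strip()
    if s in _ROMAN:
        return _ROMAN[s]
    try:
        iv = int(float(s))
    except ValueError:
        return np.nan
    return iv if 1 <= iv <= 4 else np.nan


def read_clinical(path) -> pd.DataFrame:
    """Read a clinical TSV table indexed by sample id.

    Required columns: age, gender, grade, stage, os_time, os_event.
    Missing values may be empty cells or 'NA'; they are preserved as NaN
    and handled by :func:`drop_incomplete`.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", na_values=["NA", ""], dtype={0: str})
    first = df.columns[0]
    df = df.set_index(first)
    df.index.name = "sample_id"
    missing = [c for c in CLINICAL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"clinical table {path} lacks columns {missing}")
    df["grade"] = df["grade"].map(_parse_ordinal)
    df["stage"] = df["stage"].map(_parse_ordinal)
    return df


def write_clinical(clinical: pd.DataFrame, path) -> None:
    out = clinical.copy()
    out.index.name = "sample_id"
    out.to_csv(path, sep="\t")


def read_gene_list(path) -> list[str]:
    """One gene symbol per line; '#' starts a comment."""
    genes: list[str] = []
    seen = set()
    for raw in Path(path).read_text().splitlines():
        line = raw.split("#", 1)[0].strip()
        if line and line not in seen:
            genes.append(line)
            seen.add(line)
    return genes


def log2_transform(cohort: ExpressionCohort) -> ExpressionCohort:
    """Apply ``log2(x + 1)`` to a linear-scale cohort.

    The unit pseudocount keeps zero expression at zero and avoids
    divergence, while preserving within-sample ranks exactly.
    """
    if cohort.log_scale:
        raise ValueError(f"cohort {cohort.platform!r} is already on a log scale")
    vals = cohort.values.to_numpy()
    if (vals < 0).any():
        raise ValueError("negative expression values cannot be log-transformed")
    out = pd.DataFrame(
        np.log2(vals + 1.0), index=cohort.values.index, columns=cohort.values.columns
    )
    return ExpressionCohort(values=out, platform=cohort.platform, log_scale=True)


def drop_incomplete(
    clinical: pd.DataFrame, cohort: ExpressionCohort
) -> tuple[pd.DataFrame, ExpressionCohort]:
    """Keep only samples present in both tables with complete records.

    A record is complete when every required clinical field is non-missing,
    survival time is non-negative, and the event flag is 0/1.
    """
    clin = clinical.loc[clinical.index.intersection(cohort.sample_ids)]
    ok = clin[list(CLINICAL_COLUMNS)].notna().all(axis=1)
    ok &= pd.to_numeric(clin["os_time"], errors="coerce") >= 0
    ok &= pd.to_numeric(clin["os_event"], errors="coerce").isin([0, 1])
    kept = clin.index[ok.fillna(False)]
    # preserve expression column order
    kept = [s for s in cohort.sample_ids if s in set(kept)]
    if not kept:
        raise ValueError("no samples with complete clinical records remain")
    return clin.loc[kept], cohort.subset_samples(kept)


def split_cohort(sample_ids, seed: int, threshold: float = 0.7) -> CohortSplit:
    """Assign each sample a Uniform(0,1) draw; u <= threshold -> training.

    With the default threshold of 0.7 this yields the conventional 7:3
    training/validation partition in expectation.
    """
    sample_ids = list(sample_ids)
    if not sample_ids:
        raise ValueError("cannot split an empty sample list")
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    u = rng.uniform(size=len(sample_ids))
    train = tuple(s for s, ui in zip(sample_ids, u) if ui <= threshold)
    valid = tuple(s for s, ui in zip(sample_ids, u) if ui > threshold)
    return CohortSplit(training=train, validation=valid, seed=seed, threshold=threshold)
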