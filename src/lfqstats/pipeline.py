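"""End-to-end orchestration: convert, process, compare.

``process`` chains the log transform, between-run normalization, censoring
classification, per-protein imputation and median-polish summarization on a
canonical long-format table, collecting a processing report (percentiles,
threshold, per-status cell counts, normalization shifts).  These functions
back both the command-line interface and programmatic use.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field

import pandas as pd

from . import __version__
from .censoring import CENSORED, MAR, OBSERVED, STATUS, classify_cells, estimate_threshold
from .imputation import IMPUTED, impute_dataset
from .io import RUN, ToolDialect, ValidationError, get_dialect
from .normalize import RUN_SHIFT, NormalizationConfig, log_transform, normalize
from .preprocess import AnnotatedDataset, PreprocessConfig, preprocess
from .summarization import summarize_dataset


@dataclass
class ProcessConfig:
    """Options for the processing stage (transform through summarization)."""

    normalization: NormalizationConfig = field(default_factory=NormalizationConfig)
    censoring_enabled: bool = True
    max_quantile: float = 0.999
    imputation_enabled: bool = True
    cap_at_bound: bool = True
    summary_method: str = "tmp"

    def __post_init__(self) -> None:
        if not (0.75 < self.max_quantile <= 1.0):
            raise ValidationError("max_quantile must lie in (0.75, 1]")


@dataclass
class ProcessResult:
    features: pd.DataFrame  # per-cell table with status/imputation provenance
    summaries: pd.DataFrame  # run-level log2 abundances
    report: dict


def convert(raw, dialect, annotation, preprocess_config: PreprocessConfig | None = None
            ) -> AnnotatedDataset:
    """Reshape a tool export to canonical format and run the cleaning pipeline."""
    from .io import reshape_to_long

    if isinstance(dialect, str):
        dialect = get_dialect(dialect)
    records = reshape_to_long(raw, dialect, annotation)
    return preprocess(records, annotation, preprocess_config)


def process(
    dataset: pd.DataFrame,
    config: ProcessConfig | None = None,
    dialect: ToolDialect | str | None = None,
) -> ProcessResult:
    """Transform, normalize, classify, impute and summarize a canonical table."""
    config = config or ProcessConfig()
    if isinstance(dialect, str):
        dialect = get_dialect(dialect)

    df = log_transform(dataset, base=config.normalization.log_base)
    df = normalize(df, config.normalization)

    report: dict = {
        "log_base": config.normalization.log_base,
        "normalization": config.normalization.method,
        "run_shifts": df.drop_duplicates(RUN).set_index(RUN)[RUN_SHIFT].to_dict()
        if RUN_SHIFT in df.columns
        else {},
        "censoring_enabled": config.censoring_enabled,
    }

    model = None
    if config.censoring_enabled:
        model = estimate_threshold(df, max_quantile=config.max_quantile)
    df = classify_cells(df, model, dialect, enabled=config.censoring_enabled)
    status_counts = df[STATUS].value_counts().to_dict()
    report["cell_counts"] = {
        OBSERVED: int(status_counts.get(OBSERVED, 0)),
        CENSORED: int(status_counts.get(CENSORED, 0)),
        MAR: int(status_counts.get(MAR, 0)),
    }
    if model is not None:
        report["censoring"] = {
            "q25": model.q25,
            "q50": model.q50,
            "q75": model.q75,
            "q999": model.q999,
            "threshold": model.threshold,
        }

    if config.imputation_enabled and config.censoring_enabled:
        df, diagnostics = impute_dataset(df, cap=config.cap_at_bound)
        report["imputation"] = {
            "n_imputed_cells": int(df[IMPUTED].sum()),
            "n_proteins_fit": sum(1 for f in diagnostics.values() if f is not None),
            "n_unconverged": sum(
                1 for f in diagnostics.values() if f is not None and not f.converged
            ),
        }
    else:
        df = df.copy()
        df[IMPUTED] = False
        report["imputation"] = {"n_imputed_cells": 0, "n_proteins_fit": 0,
                               "n_unconverged": 0}

    summaries = summarize_dataset(df, method=config.summary_method)
    return ProcessResult(features=df, summaries=summaries, report=report)


def config_hash(*configs) -> str:
    """Stable short hash of the resolved configuration (for provenance)."""
    def default(o):
        if hasattr(o, "__dataclass_fields__"):
            return asdict(o)
        if isinstance(o, (set, frozenset, tuple)):
            return sorted(map(str, o))
        return str(o)

    blob = json.dumps(configs, default=default, sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def provenance_lines(seed=None, *configs) -> list[str]:
    lines = [f"lfqstats version={__version__}", f"config_hash={config_hash(*configs)}"]
    if seed is not None:
        lines.append(f"seed={seed}")
    return lines
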