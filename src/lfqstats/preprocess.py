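"""Post-conversion cleaning of canonical feature tables.

The generic pipeline, in fixed order: shared-peptide removal, sparse-feature
removal, optional removal of single-feature proteins, duplicate aggregation,
fraction handling, and balanced-design expansion (one row per feature per
run, missing or not).  Every stage appends a row-count entry to a provenance
log so that ``rows_in == rows_out + rows_removed - rows_added`` holds for
each stage.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import pandas as pd

from .io import (
    BIOREPLICATE,
    CONDITION,
    FEATURE_COLUMNS,
    FRACTION,
    INTENSITY,
    PEPTIDE,
    PROTEIN,
    RUN,
    TECHREPLICATE,
    ValidationError,
    feature_ids,
    validate_annotation,
)

_FEATURE_KEY = [PROTEIN] + FEATURE_COLUMNS


@dataclass
class StageLog:
    stage: str
    rows_in: int
    rows_out: int
    detail: str = ""

    @property
    def rows_removed(self) -> int:
        return max(self.rows_in - self.rows_out, 0)

    @property
    def rows_added(self) -> int:
        return max(self.rows_out - self.rows_in, 0)


@dataclass
class PreprocessConfig:
    """Cleaning options applied after conversion.

    ``min_measurements_per_feature`` removes features observed (non-missing)
    in fewer runs than the threshold.  ``duplicate_aggregation`` resolves
    multiple intensities reported for the same feature in the same run;
    ``max`` is the default as it is conservative against double counting of
    re-quantified peaks.
    """

    remove_shared_peptides: bool = True
    min_measurements_per_feature: int = 2
    remove_single_feature_proteins: bool = False
    duplicate_aggregation: str = "max"

    def __post_init__(self) -> None:
        if self.duplicate_aggregation not in ("max", "sum"):
            raise ValidationError(
                f"unknown duplicate_aggregation {self.duplicate_aggregation!r}"
            )
        if self.min_measurements_per_feature < 0:
            raise ValidationError("min_measurements_per_feature must be >= 0")


@dataclass
class AnnotatedDataset:
    """Balanced feature-by-run table plus the provenance log of cleaning."""

    data: pd.DataFrame
    annotation: pd.DataFrame
    log: list = field(default_factory=list)


def remove_shared_peptides(records: pd.DataFrame) -> tuple[pd.DataFrame, StageLog]:
    """Drop every row of any peptide assigned to more than one protein."""
    n_in = len(records)
    mapping = records[[PEPTIDE, PROTEIN]].drop_duplicates()
    counts = mapping.groupby(PEPTIDE)[PROTEIN].nunique()
    shared = set(counts.index[counts > 1])
    out = records[~records[PEPTIDE].isin(shared)].reset_index(drop=True)
    if out.empty and n_in:
        warnings.warn("all peptides are shared between proteins; no rows remain")
    log = StageLog("remove_shared_peptides", n_in, len(out), f"{len(shared)} shared peptides")
    return out, log


def filter_sparse_features(
    records: pd.DataFrame, min_measurements: int
) -> tuple[pd.DataFrame, StageLog]:
    """Remove features observed in fewer than ``min_measurements`` runs."""
    n_in = len(records)
    if min_measurements <= 0:
        return records.reset_index(drop=True), StageLog("filter_sparse_features", n_in, n_in)
    fid = feature_ids(records) + "\x1f" + records[PROTEIN].astype(str)
    observed = records[INTENSITY].notna()
    n_runs = (
        records.loc[observed]
        .assign(_fid=fid[observed])
        .groupby("_fid")[RUN]
        .nunique()
    )
    keep_ids = set(n_runs.index[n_runs >= min_measurements])
    out = records[fid.isin(keep_ids)].reset_index(drop=True)
    return out, StageLog("filter_sparse_features", n_in, len(out))


def remove_single_feature_proteins(records: pd.DataFrame) -> tuple[pd.DataFrame, StageLog]:
    n_in = len(records)
    fid = feature_ids(records)
    n_feat = records.assign(_fid=fid).groupby(PROTEIN)["_fid"].nunique()
    keep = set(n_feat.index[n_feat > 1])
    out = records[records[PROTEIN].isin(keep)].reset_index(drop=True)
    return out, StageLog("remove_single_feature_proteins", n_in, len(out))


def aggregate_duplicates(
    records: pd.DataFrame, method: str = "max"
) -> tuple[pd.DataFrame, StageLog]:
    """Collapse multiple intensities per (feature, run) into one.

    Aggregates over non-missing values only; a (feature, run) whose
    duplicates are all missing stays missing.
    """
    if method not in ("max", "sum"):
        raise ValidationError(f"unknown aggregation method {method!r}")
    n_in = len(records)
    key = [c for c in _FEATURE_KEY + [RUN, FRACTION] if c in records.columns]
    other = [c for c in records.columns if c not in key + [INTENSITY]]
    agg = {INTENSITY: (lambda s: s.max(skipna=True)) if method == "max" else (
        lambda s: s.sum(min_count=1))}
    agg.update({c: "first" for c in other})
    out = records.groupby(key, as_index=False, sort=False, dropna=False).agg(agg)
    out = out[records.columns].reset_index(drop=True)
    return out, StageLog("aggregate_duplicates", n_in, len(out), f"method={method}")


def handle_fractions(
    records: pd.DataFrame, annotation: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame, StageLog]:
    """Resolve fractionated runs to one logical run per sample.

    Each feature is kept in the single fraction where its mean observed
    intensity is highest (ties broken by the lexicographically first
    fraction); runs are then relabelled to one logical run per
    (condition, bio replicate, tech replicate) and the fraction column is
    dropped.  Returns the reduced records, the collapsed annotation, and the
    stage log.  Unfractionated input is returned unchanged.
    """
    n_in = len(records)
    if FRACTION not in annotation.columns or annotation[FRACTION].nunique() <= 1:
        return (
            records.reset_index(drop=True),
            annotation,
            StageLog("handle_fractions", n_in, n_in, "unfractionated"),
        )

    df = records.copy()
    if FRACTION not in df.columns:
        df = df.merge(annotation[[RUN, FRACTION]], on=RUN, how="left")

    fid = feature_ids(df) + "\x1f" + df[PROTEIN].astype(str)
    df = df.assign(_fid=fid)
    means = (
        df[df[INTENSITY].notna()]
        .groupby(["_fid", FRACTION])[INTENSITY]
        .mean()
        .reset_index()
        .sort_values([INTENSITY, FRACTION], ascending=[False, True], kind="stable")
    )
    best = means.drop_duplicates("_fid").set_index("_fid")[FRACTION]
    # features never observed in any fraction: keep their first fraction
    fallback = df.groupby("_fid")[FRACTION].min()
    chosen = fallback.copy()
    chosen.update(best)
    keep = df[FRACTION].values == chosen.reindex(df["_fid"]).values
    out = df.loc[keep].drop(columns=["_fid"])

    key_cols = [CONDITION, BIOREPLICATE] + (
        [TECHREPLICATE] if TECHREPLICATE in annotation.columns else []
    )
    ann = annotation.copy()
    logical = ann[key_cols].astype(str).agg("_".join, axis=1)
    run_map = dict(zip(ann[RUN].astype(str), logical))
    out = out.drop(columns=[FRACTION])
    out[RUN] = out[RUN].astype(str).map(run_map)

    new_ann = (
        ann.assign(**{RUN: logical})
        .drop(columns=[FRACTION])
        .drop_duplicates(subset=[RUN])
        .reset_index(drop=True)
    )
    out = out.reset_index(drop=True)
    return out, new_ann, StageLog("handle_fractions", n_in, len(out))


def balance_design(
    records: pd.DataFrame, annotation: pd.DataFrame
) -> tuple[pd.DataFrame, StageLog]:
    """Complete each protein's feature-by-run table (Cartesian expansion).

    Every (feature, run) cell of every protein gets exactly one row; cells
    with no measurement carry a missing intensity.  Annotation columns are
    populated on every row.
    """
    annotation = validate_annotation(annotation)
    n_in = len(records)
    data_runs = set(records[RUN].astype(str).unique())
    ann_runs = set(annotation[RUN].astype(str).unique())
    unmatched = sorted(data_runs - ann_runs)
    if unmatched:
        raise ValidationError(f"runs without annotation: {unmatched}")

    features = records[_FEATURE_KEY].astype(str).drop_duplicates()
    ann_cols = [RUN, CONDITION, BIOREPLICATE] + (
        [TECHREPLICATE] if TECHREPLICATE in annotation.columns else []
    )
    runs = annotation[ann_cols].astype(str).drop_duplicates(subset=[RUN])
    grid = features.merge(runs, how="cross")

    values = records[_FEATURE_KEY + [RUN, INTENSITY]].copy()
    for c in _FEATURE_KEY + [RUN]:
        values[c] = values[c].astype(str)
    out = grid.merge(values, on=_FEATURE_KEY + [RUN], how="left", validate="one_to_one")
    out = out.sort_values(_FEATURE_KEY + [RUN], kind="stable").reset_index(drop=True)
    return out, StageLog("balance_design", n_in, len(out))


def preprocess(
    records: pd.DataFrame,
    annotation: pd.DataFrame,
    config: PreprocessConfig | None = None,
) -> AnnotatedDataset:
    """Run the full cleaning pipeline in its fixed order.

    Re-running the pipeline on its own output is a no-op.
    """
    config = config or PreprocessConfig()
    annotation = validate_annotation(annotation)
    log: list[StageLog] = []
    df = records

    if config.remove_shared_peptides:
        df, entry = remove_shared_peptides(df)
        log.append(entry)
    df, entry = filter_sparse_features(df, config.min_measurements_per_feature)
    log.append(entry)
    if config.remove_single_feature_proteins:
        df, entry = remove_single_feature_proteins(df)
        log.append(entry)
    df, entry = aggregate_duplicates(df, config.duplicate_aggregation)
    log.append(entry)
    df, annotation, entry = handle_fractions(df, annotation)
    log.append(entry)
    df, entry = balance_design(df, annotation)
    log.append(entry)
    return AnnotatedDataset(data=df, annotation=annotation, log=log)
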