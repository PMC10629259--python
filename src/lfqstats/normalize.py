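"""Log transformation and between-run normalization.

All normalization methods are per-run location shifts on the log scale, so
within-run differences between features are preserved exactly.  They operate
on observed (non-missing) values only and run before censoring/imputation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import INTENSITY, LOG_INTENSITY, PROTEIN, RUN, ValidationError

#: per-run shift applied by normalization, recorded for provenance.
RUN_SHIFT = "RunShift"


@dataclass
class NormalizationConfig:
    log_base: int = 2
    method: str = "equalize_medians"
    standard_proteins: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.log_base not in (2, 10):
            raise ValidationError("log_base must be 2 or 10")
        if self.method not in ("equalize_medians", "quantile", "global_standards", "none"):
            raise ValidationError(f"unknown normalization method {self.method!r}")
        if self.method == "global_standards" and not self.standard_proteins:
            raise ValidationError("global_standards normalization requires standard proteins")


def log_transform(dataset: pd.DataFrame, base: int = 2) -> pd.DataFrame:
    """Replace raw intensities by log-scale values in ``LogIntensity``.

    Missing values pass through; raw zeros are treated as missing (never
    mapped to -inf).  Negative intensities are an error.
    """
    if base not in (2, 10):
        raise ValidationError("log base must be 2 or 10")
    raw = dataset[INTENSITY].astype(float)
    if (raw < 0).any():
        raise ValidationError("negative intensity cannot be log transformed")
    with np.errstate(divide="ignore"):
        logged = np.log(raw.to_numpy()) / np.log(base)
    logged[~np.isfinite(logged)] = np.nan
    out = dataset.copy()
    out[LOG_INTENSITY] = logged
    out.attrs["log_base"] = base
    return out


def _apply_shifts(dataset: pd.DataFrame, shifts: pd.Series) -> pd.DataFrame:
    out = dataset.copy()
    shift_per_row = out[RUN].map(shifts).fillna(0.0).astype(float)
    out[LOG_INTENSITY] = out[LOG_INTENSITY] + shift_per_row
    out[RUN_SHIFT] = shift_per_row
    return out


def normalize_equalize_medians(dataset: pd.DataFrame) -> pd.DataFrame:
    """Shift each run so its median log intensity equals the grand median.

    The target is the median of per-run medians (invariant to run sizes).
    Runs with no observed values are left unshifted with a warning.
    """
    medians = dataset.groupby(RUN)[LOG_INTENSITY].median()
    empty = medians.index[medians.isna()]
    if len(empty):
        warnings.warn(f"runs with no observed values left unshifted: {list(empty)}")
    grand = medians.dropna().median()
    shifts = (grand - medians).fillna(0.0)
    return _apply_shifts(dataset, shifts)


def normalize_global_standards(
    dataset: pd.DataFrame, standard_proteins: list[str]
) -> pd.DataFrame:
    """Shift each run so the mean log intensity of spiked standards is constant."""
    if not standard_proteins:
        raise ValidationError("standard protein list is empty")
    known = set(dataset[PROTEIN].unique())
    absent = sorted(set(standard_proteins) - known)
    if absent:
        raise ValidationError(f"standard protein(s) not in dataset: {absent}")
    std = dataset[dataset[PROTEIN].isin(standard_proteins)]
    means = std.groupby(RUN)[LOG_INTENSITY].mean()
    all_runs = dataset[RUN].unique()
    for run in all_runs:
        if run not in means.index or pd.isna(means.loc[run]):
            raise ValidationError(f"standards have no observed value in run {run!r}")
    target = means.mean()
    shifts = target - means
    return _apply_shifts(dataset, shifts)


def normalize_quantile(dataset: pd.DataFrame) -> pd.DataFrame:
    """Map each run's observed quantiles to the mean quantile function.

    Runs may have unequal numbers of observed values; each run's sorted
    values are interpolated onto a common probability grid, the grid values
    are averaged across runs, and every observed value is replaced by the
    mean quantile at its within-run rank.  Missing cells are untouched.
    This is not a pure location shift (unlike the other methods).
    """
    out = dataset.copy()
    obs = out[LOG_INTENSITY].notna()
    groups = out.loc[obs].groupby(RUN)[LOG_INTENSITY]
    sorted_vals = {run: np.sort(v.to_numpy()) for run, v in groups}
    if not sorted_vals:
        return out
    n_grid = max(len(v) for v in sorted_vals.values())
    grid = (np.arange(n_grid) + 0.5) / n_grid
    mean_q = np.mean(
        [
            np.interp(grid, (np.arange(len(v)) + 0.5) / len(v), v)
            for v in sorted_vals.values()
        ],
        axis=0,
    )
    new_vals = out[LOG_INTENSITY].to_numpy(copy=True)
    for run, v in sorted_vals.items():
        idx = out.index[(out[RUN] == run) & obs]
        ranks = out.loc[idx, LOG_INTENSITY].rank(method="first").to_numpy()
        p = (ranks - 0.5) / len(v)
        new_vals[out.index.get_indexer(idx)] = np.interp(p, grid, mean_q)
    out[LOG_INTENSITY] = new_vals
    return out


def normalize(dataset: pd.DataFrame, config: NormalizationConfig) -> pd.DataFrame:
    if config.method == "none":
        out = dataset.copy()
        out[RUN_SHIFT] = 0.0
        return out
    if config.method == "equalize_medians":
        return normalize_equalize_medians(dataset)
    if config.method == "quantile":
        return normalize_quantile(dataset)
    return normalize_global_standards(dataset, config.standard_proteins)
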