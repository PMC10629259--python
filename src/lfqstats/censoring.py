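"""Experiment-wide censoring threshold and per-cell missingness status.

Low-abundance analytes fall below the instrument's limit of quantification:
their intensities are either reported as missing or are unreliably small.
Such values are *censored* — informative about low abundance — as opposed to
*missing at random* (MAR), e.g. truncated or overlapped peaks.

The threshold for "high-confidence" log intensities is the estimated 0.1th
percentile of the log intensities in the linear regime of the dynamic range.
Assuming the linear-regime distribution is symmetric, the upper-tail spread
``q99.9 - q75`` is used to learn the lower-tail deviation ``q25 - q0.1``::

    threshold = q25 - (q99.9 - q75)

with percentiles taken over all observed log intensities exceeding 0, pooled
across runs and proteins (one threshold per experiment).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import LABEL, LOG_INTENSITY, REFERENCE_LABELS, ToolDialect, ValidationError

#: per-cell status column: "observed", "censored" or "mar".
STATUS = "CellStatus"
OBSERVED = "observed"
CENSORED = "censored"
MAR = "mar"


@dataclass
class CensoringModel:
    """Pooled percentiles of observed log intensities and the threshold."""

    q25: float
    q50: float
    q75: float
    q999: float
    threshold: float
    max_quantile: float = 0.999
    na_is_censored: bool = True
    counts: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (self.q25 <= self.q50 <= self.q75 <= self.q999):
            raise ValidationError("percentiles must be nondecreasing")


def estimate_threshold(dataset: pd.DataFrame, max_quantile: float = 0.999) -> CensoringModel:
    """Estimate the censoring threshold from observed log intensities > 0.

    Percentiles use linear interpolation between order statistics (type 7).
    Requires at least 4 distinct positive observed values.
    """
    values = dataset[LOG_INTENSITY].to_numpy()
    values = values[np.isfinite(values) & (values > 0)]
    if np.unique(values).size < 4:
        raise ValidationError(
            "need at least 4 distinct observed log intensities > 0 to "
            "estimate the censoring threshold"
        )
    q25, q50, q75, q_hi = np.percentile(
        values, [25, 50, 75, 100 * max_quantile], method="linear"
    )
    threshold = q25 - (q_hi - q75)
    return CensoringModel(
        q25=float(q25),
        q50=float(q50),
        q75=float(q75),
        q999=float(q_hi),
        threshold=float(threshold),
        max_quantile=max_quantile,
    )


def classify_cells(
    dataset: pd.DataFrame,
    model: CensoringModel | None,
    dialect: ToolDialect | None = None,
    enabled: bool = True,
    reference_labels_mar: bool = True,
) -> pd.DataFrame:
    """Assign every cell exactly one status: observed, censored, or MAR.

    Missing cells are censored, with two exceptions: dialects whose missing
    values are not abundance-related (Skyline) and reference/heavy-label
    features, both of which are MAR.  Observed values below the threshold are
    re-marked censored but keep their magnitude for use by imputation.  With
    ``enabled=False`` (censoring switched off) all missing cells are MAR and
    no observed value is re-marked.
    """
    na_is_censored = dialect.na_is_censored if dialect is not None else (
        model.na_is_censored if model is not None else True
    )
    out = dataset.copy()
    missing = out[LOG_INTENSITY].isna().to_numpy()
    status = np.where(missing, CENSORED if (enabled and na_is_censored) else MAR, OBSERVED)

    if enabled and model is not None:
        low = (out[LOG_INTENSITY] < model.threshold).fillna(False).to_numpy()
        status = np.where(~missing & low, CENSORED, status)

    if reference_labels_mar and LABEL in out.columns:
        is_ref = out[LABEL].astype(str).isin(REFERENCE_LABELS).to_numpy()
        status = np.where(missing & is_ref, MAR, status)

    out[STATUS] = status
    if model is not None:
        unique, counts = np.unique(status, return_counts=True)
        model.counts = dict(zip(unique.tolist(), counts.tolist()))
    return out


def detection_indicator(dataset: pd.DataFrame) -> pd.Series:
    """Indicator of whether the peak was detected and quantified (1 iff observed)."""
    return (dataset[STATUS] == OBSERVED).astype(int)
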