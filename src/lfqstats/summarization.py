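"""Run-level protein summarization by Tukey median polish.

All features of a protein in one run are condensed to a single log2
abundance.  The additive model ``y = overall + feature + run + residual`` is
fitted robustly by iteratively sweeping medians out of rows (features) and
columns (runs); the run-level summary is ``overall + run_effect``.  The
median is resistant to outlying feature measurements, unlike a mean.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .imputation import IMPUTED
from .io import (
    BIOREPLICATE,
    CONDITION,
    LOG_INTENSITY,
    PROTEIN,
    RUN,
    TECHREPLICATE,
    ValidationError,
    feature_ids,
)

LOG2_ABUNDANCE = "Log2Abundance"
N_FEATURES_OBSERVED = "NFeaturesObserved"
ANY_IMPUTED = "AnyImputed"


@dataclass
class PolishFit:
    overall: float
    row_effects: np.ndarray  # features
    col_effects: np.ndarray  # runs
    residuals: np.ndarray  # features x runs, NaN where missing
    iterations: int
    converged: bool


def _nanmedian(a: np.ndarray, axis: int) -> np.ndarray:
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        out = np.nanmedian(a, axis=axis)
    return np.nan_to_num(out, nan=0.0)


def median_polish(
    matrix: np.ndarray, max_iter: int = 100, tol: float = 1e-8
) -> PolishFit:
    """Additive decomposition of a feature-by-run matrix by median sweeps.

    Rows are swept first, then columns (Tukey's convention); medians over an
    even number of values are the midpoint of the two central order
    statistics; missing cells are skipped.  Convergence: the maximum
    absolute change of any effect in a sweep falls below ``tol``.
    """
    z = np.asarray(matrix, dtype=float)
    if z.ndim != 2 or z.size == 0:
        raise ValidationError("median polish needs a non-empty 2-D matrix")
    if np.isnan(z).all():
        raise ValidationError("median polish on an all-missing matrix")
    z = z.copy()
    nr, nc = z.shape
    overall = 0.0
    row = np.zeros(nr)
    col = np.zeros(nc)

    converged = False
    iterations = 0
    for iterations in range(1, max_iter + 1):
        delta = 0.0

        rmed = _nanmedian(z, axis=1)
        z -= rmed[:, None]
        row += rmed
        delta = max(delta, np.abs(rmed).max(initial=0.0))

        cshift = np.median(col)
        col -= cshift
        overall += cshift

        cmed = _nanmedian(z, axis=0)
        z -= cmed[None, :]
        col += cmed
        delta = max(delta, np.abs(cmed).max(initial=0.0))

        rshift = np.median(row)
        row -= rshift
        overall += rshift

        if delta < tol:
            converged = True
            break

    return PolishFit(
        overall=float(overall),
        row_effects=row,
        col_effects=col,
        residuals=z,
        iterations=iterations,
        converged=converged,
    )


def _protein_matrix(protein_df: pd.DataFrame) -> tuple[np.ndarray, list, list, pd.DataFrame]:
    df = protein_df.copy()
    df["_fid"] = feature_ids(df)
    wide = df.pivot_table(
        index="_fid", columns=RUN, values=LOG_INTENSITY, aggfunc="mean", dropna=False
    )
    return wide.to_numpy(float), list(wide.index), list(wide.columns), df


def summarize_protein(protein_df: pd.DataFrame, method: str = "tmp") -> pd.DataFrame:
    """Summaries for one protein: one log2 abundance per run with >=1 value.

    ``method="mean"`` (plain column means, skipping missing) exists only for
    robustness comparisons; ``"tmp"`` is the production path.
    """
    mat, feats, runs, df = _protein_matrix(protein_df)
    if np.isnan(mat).all():
        raise ValidationError("protein has no quantified cells to summarize")

    n_obs = (~np.isnan(mat)).sum(axis=0)
    if method == "tmp":
        fit = median_polish(mat)
        summary = fit.overall + fit.col_effects
    elif method == "mean":
        with np.errstate(all="ignore"):
            summary = np.nanmean(mat, axis=0)
    else:
        raise ValidationError(f"unknown summarization method {method!r}")

    run_meta_cols = [c for c in (CONDITION, BIOREPLICATE, TECHREPLICATE) if c in df.columns]
    meta = df.drop_duplicates(subset=[RUN]).set_index(RUN)
    if IMPUTED in df.columns:
        imputed_runs = df.groupby(RUN)[IMPUTED].any()
    else:
        imputed_runs = pd.Series(False, index=meta.index)

    rows = []
    for k, run in enumerate(runs):
        if n_obs[k] == 0:
            continue
        rec = {
            PROTEIN: protein_df[PROTEIN].iloc[0],
            RUN: run,
            LOG2_ABUNDANCE: float(summary[k]),
            N_FEATURES_OBSERVED: int(n_obs[k]),
            ANY_IMPUTED: bool(imputed_runs.get(run, False)),
        }
        for c in run_meta_cols:
            rec[c] = meta.loc[run, c]
        rows.append(rec)
    cols = [PROTEIN, RUN] + run_meta_cols + [LOG2_ABUNDANCE, N_FEATURES_OBSERVED, ANY_IMPUTED]
    return pd.DataFrame(rows, columns=cols)


def summarize_dataset(dataset: pd.DataFrame, method: str = "tmp") -> pd.DataFrame:
    """Per-protein run-level summaries for a whole processed table."""
    pieces = []
    for _, grp in dataset.groupby(PROTEIN, sort=True):
        if grp[LOG_INTENSITY].notna().any():
            pieces.append(summarize_protein(grp, method=method))
    if not pieces:
        raise ValidationError("no protein has quantified cells")
    return pd.concat(pieces, ignore_index=True)
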