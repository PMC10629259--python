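"""Reading, reshaping and writing of quantified-feature tables.

The canonical interchange format is a comma-separated, UTF-8 text file with a
mandatory header and ten columns::

    ProteinName, PeptideSequence, PrecursorCharge, FragmentIon, ProductCharge,
    IsotopeLabelType, Condition, BioReplicate, Run, Intensity

``Fraction`` and ``TechReplicate`` are optional extra columns.  The literal
``NA`` marks a missing intensity; a missing value is always distinct from an
intensity of zero.  Intensities are on the raw (linear) scale.

Spectral processing tools report missingness differently — some report ``NA``
and no zeros, others report zeros and no ``NA`` — and attach tool-specific
quality columns.  A :class:`ToolDialect` declares, per tool, which raw cell
values denote a missing intensity, whether a missing value should later be
treated as censored (below the limit of quantification) or as missing at
random, and which row filters to apply.  Dialects are declarative so that new
tools can be supported from a small config file without code changes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import yaml

PROTEIN = "ProteinName"
PEPTIDE = "PeptideSequence"
PRECURSOR_CHARGE = "PrecursorCharge"
FRAGMENT_ION = "FragmentIon"
PRODUCT_CHARGE = "ProductCharge"
LABEL = "IsotopeLabelType"
CONDITION = "Condition"
BIOREPLICATE = "BioReplicate"
RUN = "Run"
INTENSITY = "Intensity"
FRACTION = "Fraction"
TECHREPLICATE = "TechReplicate"

#: log2 intensity column used by the processing stages (raw ``Intensity`` is
#: replaced by this after the log transform).
LOG_INTENSITY = "LogIntensity"

CANONICAL_COLUMNS = [
    PROTEIN,
    PEPTIDE,
    PRECURSOR_CHARGE,
    FRAGMENT_ION,
    PRODUCT_CHARGE,
    LABEL,
    CONDITION,
    BIOREPLICATE,
    RUN,
    INTENSITY,
]
OPTIONAL_COLUMNS = [FRACTION, TECHREPLICATE]

#: columns that jointly identify a spectral feature (a feature belongs to
#: exactly one protein).
FEATURE_COLUMNS = [PEPTIDE, PRECURSOR_CHARGE, FRAGMENT_ION, PRODUCT_CHARGE, LABEL]

ANNOTATION_REQUIRED = [RUN, CONDITION, BIOREPLICATE]

#: isotope label values treated as reference/heavy channels.
REFERENCE_LABELS = frozenset({"H", "h", "heavy", "Heavy", "reference", "Reference"})

MISSING_SENTINEL = "NA"


class ValidationError(ValueError):
    """Raised when an input table violates the format contract."""


def feature_ids(df: pd.DataFrame) -> pd.Series:
    """Return a single string id per row identifying the spectral feature."""
    cols = [c for c in FEATURE_COLUMNS if c in df.columns]
    out = df[cols[0]].astype(str)
    for c in cols[1:]:
        out = out + "_" + df[c].astype(str)
    return out


# ---------------------------------------------------------------------------
# dialects
# ---------------------------------------------------------------------------

_FILTER_OPS = {
    "<": lambda s, v: pd.to_numeric(s, errors="coerce") < v,
    "<=": lambda s, v: pd.to_numeric(s, errors="coerce") <= v,
    ">": lambda s, v: pd.to_numeric(s, errors="coerce") > v,
    ">=": lambda s, v: pd.to_numeric(s, errors="coerce") >= v,
    "==": lambda s, v: s.astype(str) == str(v),
    "!=": lambda s, v: s.astype(str) != str(v),
    "in": lambda s, v: s.astype(str).isin([str(x) for x in v]),
    "not_in": lambda s, v: ~s.astype(str).isin([str(x) for x in v]),
}


@dataclass(frozen=True)
class ColumnFilter:
    """Keep only rows of the raw table for which ``column op value`` holds.

    Rows where the column is absent are kept (the filter does not apply).
    """

    column: str
    op: str
    value: object

    def __post_init__(self) -> None:
        if self.op not in _FILTER_OPS:
            raise ValidationError(f"unknown filter operator {self.op!r}")

    def mask(self, df: pd.DataFrame) -> pd.Series:
        if self.column not in df.columns:
            return pd.Series(True, index=df.index)
        return _FILTER_OPS[self.op](df[self.column], self.value).fillna(False)


@dataclass(frozen=True)
class ToolDialect:
    """How one spectral processing tool's export is to be interpreted.

    ``missing_markers`` are raw intensity cell values (compared as stripped
    strings) that denote a missing measurement.  ``zero_is_missing`` states
    whether a numeric 0 is a missing-value marker (Spectronaut convention).
    ``na_is_censored`` states whether a missing value is later interpreted as
    censored (low abundance); Skyline uses ``NA`` for truncated/overlapped
    peaks, which are missing at random, so it sets this to False.
    """

    name: str
    missing_markers: frozenset = frozenset({"NA", "", "NaN", "nan", "#N/A"})
    zero_is_missing: bool = True
    na_is_censored: bool = True
    filters: tuple = ()
    column_map: Mapping[str, str] = field(default_factory=dict)


DIALECTS: dict[str, ToolDialect] = {
    "generic": ToolDialect(name="generic"),
    "maxquant": ToolDialect(
        name="maxquant",
        filters=(
            ColumnFilter("Potential.contaminant", "!=", "+"),
            ColumnFilter("Reverse", "!=", "+"),
        ),
    ),
    "spectronaut": ToolDialect(
        name="spectronaut",
        zero_is_missing=True,
        filters=(ColumnFilter("EG.Qvalue", "<=", 0.01),),
    ),
    "skyline": ToolDialect(
        name="skyline",
        zero_is_missing=False,
        na_is_censored=False,
        filters=(ColumnFilter("Truncated", "!=", "True"),),
    ),
}


def get_dialect(name: str, zero_is_missing: bool | None = None) -> ToolDialect:
    try:
        dialect = DIALECTS[name.lower()]
    except KeyError:
        raise ValidationError(
            f"unknown dialect {name!r}; known: {sorted(DIALECTS)}"
        ) from None
    if zero_is_missing is not None:
        dialect = replace(dialect, zero_is_missing=zero_is_missing)
    return dialect


def dialect_from_config(config: Mapping | str | Path) -> ToolDialect:
    """Build a dialect from a mapping or a YAML/JSON config file."""
    if isinstance(config, (str, Path)):
        text = Path(config).read_text()
        config = yaml.safe_load(text)
    if not isinstance(config, Mapping) or "name" not in config:
        raise ValidationError("dialect config must be a mapping with a 'name'")
    filters = tuple(
        ColumnFilter(f["column"], f["op"], f["value"])
        for f in config.get("filters", ())
    )
    return ToolDialect(
        name=str(config["name"]),
        missing_markers=frozenset(
            str(m) for m in config.get("missing_markers", ["NA", ""])
        ),
        zero_is_missing=bool(config.get("zero_is_missing", True)),
        na_is_censored=bool(config.get("na_is_censored", True)),
        filters=filters,
        column_map=dict(config.get("column_map", {})),
    )


# ---------------------------------------------------------------------------
# annotation
# ---------------------------------------------------------------------------


def validate_annotation(ann: pd.DataFrame) -> pd.DataFrame:
    for col in ANNOTATION_REQUIRED:
        if col not in ann.columns:
            raise ValidationError(f"annotation is missing required column {col!r}")
    key = [RUN] + ([FRACTION] if FRACTION in ann.columns else [])
    dup = ann.duplicated(subset=key, keep=False)
    if dup.any():
        runs = sorted(ann.loc[dup, RUN].unique())
        raise ValidationError(f"duplicate annotation rows for run(s): {runs}")
    return ann.reset_index(drop=True)


def read_annotation(path: str | Path, sep: str = ",") -> pd.DataFrame:
    """Read and validate a run annotation table.

    Requires ``Run``, ``Condition`` and ``BioReplicate`` columns; ``Fraction``
    and ``TechReplicate`` are honoured when present and any further columns
    are preserved untouched.
    """
    ann = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False, comment="#")
    ann.columns = [c.strip() for c in ann.columns]
    return validate_annotation(ann)


# ---------------------------------------------------------------------------
# reshaping
# ---------------------------------------------------------------------------


def _classify_intensity(raw: pd.Series, dialect: ToolDialect) -> pd.Series:
    """Convert raw intensity cells to float with NaN as the missing marker."""
    as_str = raw.astype(str).str.strip()
    missing = as_str.isin(dialect.missing_markers) | raw.isna()
    values = pd.to_numeric(as_str.where(~missing), errors="raise").astype(float)
    if dialect.zero_is_missing:
        values = values.where(values != 0.0)
    if (values < 0).any():
        bad = values[values < 0].iloc[0]
        raise ValidationError(f"negative intensity encountered: {bad}")
    return values


def reshape_to_long(
    raw: pd.DataFrame, dialect: ToolDialect, annotation: pd.DataFrame
) -> pd.DataFrame:
    """Reshape a tool export into the canonical long format.

    The raw table is either already long (one ``Intensity`` column plus a
    ``Run`` column) or wide with one intensity column per run, in which case
    the run columns are recognised by matching the annotation's run names.
    Dialect row filters are applied first; raw intensity cells matching the
    dialect's missing markers become NaN; the annotation is joined onto every
    record.
    """
    annotation = validate_annotation(annotation)
    df = raw.copy()
    if dialect.column_map:
        df = df.rename(columns=dict(dialect.column_map))

    keep = pd.Series(True, index=df.index)
    for filt in dialect.filters:
        keep &= filt.mask(df)
    df = df.loc[keep]

    ann_runs = annotation[RUN].astype(str).unique().tolist()
    if INTENSITY not in df.columns or RUN not in df.columns:
        run_cols = [c for c in df.columns if str(c) in set(ann_runs)]
        if not run_cols:
            raise ValidationError(
                "raw table has neither Run/Intensity columns nor columns "
                "matching annotated run names"
            )
        id_cols = [c for c in df.columns if c not in run_cols]
        df = df.melt(
            id_vars=id_cols, value_vars=run_cols, var_name=RUN, value_name=INTENSITY
        )

    missing_cols = [c for c in [PROTEIN, PEPTIDE] if c not in df.columns]
    if missing_cols:
        raise ValidationError(f"raw table is missing column(s) {missing_cols}")
    for col, default in [
        (PRECURSOR_CHARGE, "NA"),
        (FRAGMENT_ION, "NA"),
        (PRODUCT_CHARGE, "NA"),
        (LABEL, "L"),
    ]:
        if col not in df.columns:
            df[col] = default

    df[RUN] = df[RUN].astype(str)
    data_runs = set(df[RUN].unique())
    unmatched = sorted(data_runs - set(ann_runs))
    if unmatched:
        raise ValidationError(f"runs present in data but not in annotation: {unmatched}")

    df[INTENSITY] = _classify_intensity(df[INTENSITY], dialect)

    ann_cols = [c for c in annotation.columns if c == RUN or c not in df.columns]
    out = df.merge(annotation[ann_cols], on=RUN, how="left", validate="many_to_one")

    cols = CANONICAL_COLUMNS + [c for c in OPTIONAL_COLUMNS if c in out.columns]
    extra = [c for c in out.columns if c not in cols]
    out = out[cols + extra].reset_index(drop=True)
    for c in cols:
        if c != INTENSITY:
            out[c] = out[c].astype(str)
    return out


# ---------------------------------------------------------------------------
# canonical read/write
# ---------------------------------------------------------------------------


def write_canonical(
    df: pd.DataFrame, path: str | Path, header_lines: Iterable[str] = ()
) -> None:
    """Write a canonical long-format table; NaN intensities become ``NA``.

    ``header_lines`` are written as ``#``-prefixed comment lines before the
    header row (used for provenance: version, config hash, seed).
    """
    path = Path(path)
    ordered = [c for c in CANONICAL_COLUMNS + OPTIONAL_COLUMNS if c in df.columns]
    ordered += [c for c in df.columns if c not in ordered]
    with path.open("w", encoding="utf-8", newline="") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        df[ordered].to_csv(fh, index=False, na_rep=MISSING_SENTINEL)


def read_canonical(path: str | Path) -> pd.DataFrame:
    """Read a canonical long-format table written by :func:`write_canonical`."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False, comment="#")
    missing = [c for c in CANONICAL_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"canonical file is missing column(s) {missing}")
    for col in (INTENSITY, LOG_INTENSITY):
        if col in df.columns:
            vals = df[col].replace(MISSING_SENTINEL, np.nan)
            df[col] = pd.to_numeric(vals, errors="raise").astype(float)
    if (df[INTENSITY] < 0).any():
        raise ValidationError("negative intensity in canonical file")
    return df


def write_table(df: pd.DataFrame, path: str | Path, header_lines: Iterable[str] = ()) -> None:
    """Write any result table as CSV with optional ``#`` provenance header."""
    with Path(path).open("w", encoding="utf-8", newline="") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        df.to_csv(fh, index=False, na_rep=MISSING_SENTINEL)


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#", keep_default_na=False, na_values=[MISSING_SENTINEL])
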