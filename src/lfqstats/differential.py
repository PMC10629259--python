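"""Whole-plot modeling of run-level summaries and contrast-based inference.

The run-level log2 abundances of one protein are modeled per experimental
design, inferred automatically from the annotation (no user formulas):

* group comparison without technical replicates — fixed-effects model
  ``z = mu + Condition + error`` fitted by least squares, exact ANOVA
  degrees of freedom (``I(J-1)`` in the balanced case);
* technical replicates, paired or time-course designs — a random intercept
  per biological subject, estimated by restricted maximum likelihood
  (REML), with Satterthwaite degrees of freedom for each contrast.

A comparison is any linear combination ``L = sum_i c_i mu_i`` of condition
expected values; its estimate, standard error and degrees of freedom yield a
t-statistic and p-value, and Benjamini-Hochberg adjustment is applied across
proteins within each comparison.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.stats import t as t_dist
from statsmodels.stats.multitest import multipletests

from .io import BIOREPLICATE, CONDITION, PROTEIN, RUN, ValidationError
from .summarization import LOG2_ABUNDANCE

ISSUE_NONE = "none"
ISSUE_ONE_CONDITION = "one_condition_missing"
ISSUE_COMPLETE = "complete_missing"
ISSUE_UNCONVERGED = "unconverged"

RESULT_COLUMNS = [
    PROTEIN,
    "Label",
    "log2FC",
    "SE",
    "Tvalue",
    "DF",
    "pvalue",
    "adj_pvalue",
    "issue",
]


# ---------------------------------------------------------------------------
# design detection
# ---------------------------------------------------------------------------


@dataclass
class DesignInfo:
    design_type: str  # "group_comparison" | "paired_or_timecourse"
    has_tech_replicates: bool
    conditions: list
    subjects_per_condition: dict
    balanced: bool

    @property
    def mixed(self) -> bool:
        return self.has_tech_replicates or self.design_type == "paired_or_timecourse"


def detect_design(annotation: pd.DataFrame) -> DesignInfo:
    """Infer the experimental design from the annotation alone.

    A design is paired/time-course when some biological replicate appears
    under more than one condition (subjects are not nested within
    conditions); technical replicates are present when a subject has more
    than one run within a condition.
    """
    ann = annotation.drop_duplicates(subset=[RUN])
    conditions = sorted(ann[CONDITION].astype(str).unique())
    if len(conditions) < 2:
        raise ValidationError("need at least two conditions to compare")

    per_subject = ann.groupby(BIOREPLICATE)[CONDITION].nunique()
    paired = bool((per_subject > 1).any())
    runs_per_cell = ann.groupby([CONDITION, BIOREPLICATE])[RUN].nunique()
    has_tech = bool((runs_per_cell > 1).any())
    subjects = ann.groupby(CONDITION)[BIOREPLICATE].nunique().to_dict()
    balanced = len(set(subjects.values())) == 1 and runs_per_cell.nunique() == 1
    return DesignInfo(
        design_type="paired_or_timecourse" if paired else "group_comparison",
        has_tech_replicates=has_tech,
        conditions=conditions,
        subjects_per_condition={str(k): int(v) for k, v in subjects.items()},
        balanced=balanced,
    )


# ---------------------------------------------------------------------------
# per-protein model
# ---------------------------------------------------------------------------


@dataclass
class FittedProteinModel:
    protein: str
    condition_means: dict
    cov_means: np.ndarray  # covariance of condition-mean estimates
    conditions: list  # order matching cov_means
    sigma_subject2: float
    sigma_error2: float
    residual_df: float
    fit_method: str  # "ols" | "reml"
    df_method: str  # "exact_anova" | "satterthwaite"
    singular: bool = False
    converged: bool = True
    # internals needed for Satterthwaite df
    _X: np.ndarray | None = None
    _Z: np.ndarray | None = None


def _reml_neg2loglik(lam: float, y: np.ndarray, X: np.ndarray, ZZt: np.ndarray):
    """Profiled -2 REML log likelihood at variance ratio lam = s_subj2/s_err2."""
    n, p = X.shape
    W = np.eye(n) + lam * ZZt
    cW, low = np.linalg.cholesky(W), True
    logdetW = 2 * np.log(np.diag(cW)).sum()
    Wi_X = np.linalg.solve(W, X)
    Wi_y = np.linalg.solve(W, y)
    XtWiX = X.T @ Wi_X
    beta = np.linalg.solve(XtWiX, X.T @ Wi_y)
    r = y - X @ beta
    quad = float(r @ np.linalg.solve(W, r))
    sign, logdetXtWiX = np.linalg.slogdet(XtWiX)
    s2 = quad / (n - p)
    crit = logdetW + logdetXtWiX + (n - p) * np.log(max(s2, 1e-300))
    return crit, beta, s2, W, XtWiX


def fit_protein_model(
    summaries: pd.DataFrame, design: DesignInfo, protein: str | None = None
) -> FittedProteinModel:
    """Fit the whole-plot model for one protein's run summaries."""
    df = summaries.dropna(subset=[LOG2_ABUNDANCE])
    protein = protein if protein is not None else str(df[PROTEIN].iloc[0])
    conds = [c for c in design.conditions if c in set(df[CONDITION].astype(str))]
    if len(conds) < 2:
        raise ValidationError("fewer than two conditions with summaries")

    y = df[LOG2_ABUNDANCE].to_numpy(float)
    cond = df[CONDITION].astype(str).to_numpy()
    n = y.size
    I = len(conds)
    cidx = {c: i for i, c in enumerate(conds)}
    X = np.zeros((n, I))
    X[np.arange(n), [cidx[c] for c in cond]] = 1.0

    if design.mixed:
        if design.design_type == "paired_or_timecourse":
            subj = df[BIOREPLICATE].astype(str).to_numpy()
        else:
            subj = (cond + "\x1f" + df[BIOREPLICATE].astype(str)).astype(object)
        subjects = sorted(set(subj))
        sidx = {s: i for i, s in enumerate(subjects)}
        Z = np.zeros((n, len(subjects)))
        Z[np.arange(n), [sidx[s] for s in subj]] = 1.0
        ZZt = Z @ Z.T

        def crit(u: float) -> float:
            return _reml_neg2loglik(np.exp(u), y, X, ZZt)[0]

        # profile the variance ratio on a log grid, then refine; always try
        # the boundary lam = 0 explicitly
        best_u, best_val = None, np.inf
        for u in np.linspace(-10, 10, 21):
            try:
                val = crit(u)
            except np.linalg.LinAlgError:
                continue
            if val < best_val:
                best_u, best_val = u, val
        converged = best_u is not None
        if converged:
            res = optimize.minimize_scalar(
                crit, bounds=(best_u - 2.0, best_u + 2.0), method="bounded",
                options={"xatol": 1e-10},
            )
            lam = float(np.exp(res.x)) if res.fun < best_val else float(np.exp(best_u))
        else:
            lam = 0.0
        val0, beta0, s2_0, _, XtWiX0 = _reml_neg2loglik(0.0, y, X, ZZt)
        valh, beta, s2, W, XtWiX = _reml_neg2loglik(lam, y, X, ZZt)
        singular = val0 <= valh + 1e-10
        if singular:
            lam, beta, s2, XtWiX = 0.0, beta0, s2_0, XtWiX0
            W = np.eye(n)
        sigma_e2 = float(s2)
        sigma_s2 = float(lam * s2)
        cov_means = sigma_e2 * np.linalg.inv(XtWiX)
        model = FittedProteinModel(
            protein=protein,
            condition_means=dict(zip(conds, beta.tolist())),
            cov_means=cov_means,
            conditions=conds,
            sigma_subject2=sigma_s2,
            sigma_error2=sigma_e2,
            residual_df=float(n - I),
            fit_method="reml",
            df_method="exact_anova" if singular else "satterthwaite",
            singular=singular,
            converged=converged,
            _X=X,
            _Z=Z,
        )
        return model

    # fixed-effects path: least squares on the condition factor
    means = np.array([y[cond == c].mean() for c in conds])
    counts = np.array([(cond == c).sum() for c in conds], dtype=float)
    sse = float(sum(((y[cond == c] - means[i]) ** 2).sum() for i, c in enumerate(conds)))
    dof = n - I
    sigma_e2 = sse / dof if dof > 0 else np.nan
    cov = np.diag(sigma_e2 / counts) if dof > 0 else np.full((I, I), np.nan)
    return FittedProteinModel(
        protein=protein,
        condition_means=dict(zip(conds, means.tolist())),
        cov_means=cov,
        conditions=conds,
        sigma_subject2=0.0,
        sigma_error2=float(sigma_e2) if dof > 0 else np.nan,
        residual_df=float(dof),
        fit_method="ols",
        df_method="exact_anova",
        singular=bool(dof > 0 and sigma_e2 == 0.0),
    )


def _satterthwaite_df(model: FittedProteinModel, c_full: np.ndarray) -> float:
    """Satterthwaite approximation for df of a contrast under the mixed fit.

    Uses the REML expected information of the variance components
    (sigma_subject^2, sigma_error^2); the balanced fixed-effects case is
    handled upstream with exact ANOVA df.
    """
    X, Z = model._X, model._Z
    n = X.shape[0]
    V = model.sigma_error2 * np.eye(n) + model.sigma_subject2 * (Z @ Z.T)
    Vi = np.linalg.inv(V)
    XtViX = X.T @ Vi @ X
    XtViX_inv = np.linalg.inv(XtViX)
    P = Vi - Vi @ X @ XtViX_inv @ X.T @ Vi

    dV = [Z @ Z.T, np.eye(n)]  # d V / d sigma_subject2, d V / d sigma_error2
    # gradient of g(theta) = c' (X'V^-1 X)^-1 c
    A = Vi @ X @ XtViX_inv @ c_full
    grad = np.array([float(A @ dVi @ A) for dVi in dV])
    info = np.empty((2, 2))
    PdV = [P @ dVi for dVi in dV]
    for i in range(2):
        for j in range(2):
            info[i, j] = 0.5 * np.trace(PdV[i] @ PdV[j])
    try:
        var_theta = np.linalg.inv(info)
    except np.linalg.LinAlgError:
        return model.residual_df
    g = float(c_full @ XtViX_inv @ c_full)
    denom = float(grad @ var_theta @ grad)
    if denom <= 0 or not np.isfinite(denom):
        return model.residual_df
    return 2.0 * g * g / denom


# ---------------------------------------------------------------------------
# contrasts
# ---------------------------------------------------------------------------


@dataclass
class ContrastSpec:
    name: str
    coefficients: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        nonzero = {k: v for k, v in self.coefficients.items() if v != 0}
        if not nonzero:
            raise ValidationError(f"contrast {self.name!r} has all-zero coefficients")


def read_contrast_matrix(path: str | Path) -> list[ContrastSpec]:
    """Read a contrast matrix: rows = named comparisons, columns = conditions."""
    df = pd.read_csv(path, comment="#", keep_default_na=False)
    if df.shape[1] < 2:
        raise ValidationError("contrast matrix needs a name column and condition columns")
    name_col = df.columns[0]
    specs = []
    for _, row in df.iterrows():
        coeffs = {str(c): float(row[c]) for c in df.columns[1:]}
        specs.append(ContrastSpec(name=str(row[name_col]), coefficients=coeffs))
    return specs


def pairwise_contrasts(conditions: list[str], reference: str | None = None) -> list[ContrastSpec]:
    """All pairwise comparisons, or each condition vs a reference."""
    specs = []
    if reference is not None:
        for c in conditions:
            if c != reference:
                specs.append(ContrastSpec(f"{c} vs {reference}", {c: 1.0, reference: -1.0}))
        return specs
    for i, a in enumerate(conditions):
        for b in conditions[i + 1 :]:
            specs.append(ContrastSpec(f"{a} vs {b}", {a: 1.0, b: -1.0}))
    return specs


def test_contrast(model: FittedProteinModel, spec: ContrastSpec) -> dict:
    """Estimate and test one linear combination of condition means."""
    needed = [c for c, v in spec.coefficients.items() if v != 0]
    missing = [c for c in needed if c not in model.condition_means]
    base = {
        PROTEIN: model.protein,
        "Label": spec.name,
        "log2FC": np.nan,
        "SE": np.nan,
        "Tvalue": np.nan,
        "DF": np.nan,
        "pvalue": np.nan,
        "adj_pvalue": np.nan,
        "issue": ISSUE_NONE,
    }
    if missing:
        base["issue"] = ISSUE_ONE_CONDITION
        return base
    if not model.converged:
        base["issue"] = ISSUE_UNCONVERGED
        return base

    c_full = np.array([spec.coefficients.get(c, 0.0) for c in model.conditions])
    beta = np.array([model.condition_means[c] for c in model.conditions])
    L = float(c_full @ beta)
    var = float(c_full @ model.cov_means @ c_full)
    base["log2FC"] = L
    if not np.isfinite(var) or var <= 0 or model.residual_df <= 0:
        base["issue"] = ISSUE_UNCONVERGED if not np.isfinite(var) else ISSUE_NONE
        if model.residual_df <= 0 or var <= 0:
            base["issue"] = ISSUE_UNCONVERGED
        return base
    se = float(np.sqrt(var))
    if model.df_method == "satterthwaite" and model._X is not None:
        dof = _satterthwaite_df(model, c_full)
    else:
        dof = model.residual_df
    tval = L / se
    base.update(
        SE=se,
        Tvalue=tval,
        DF=float(dof),
        pvalue=float(2 * t_dist.sf(abs(tval), dof)),
    )
    return base


def adjust_fdr(results: pd.DataFrame) -> pd.DataFrame:
    """Benjamini-Hochberg adjustment within each comparison across proteins.

    Proteins with issues (no p-value) are excluded from the family size.
    """
    out = results.copy()
    out["adj_pvalue"] = np.nan
    for label, idx in out.groupby("Label").groups.items():
        sub = out.loc[idx]
        ok = sub["pvalue"].notna() & (sub["issue"] == ISSUE_NONE)
        if ok.sum() == 0:
            continue
        _, adj, _, _ = multipletests(sub.loc[ok, "pvalue"], method="fdr_bh")
        out.loc[sub.index[ok], "adj_pvalue"] = adj
    return out


def group_comparison(
    summaries: pd.DataFrame,
    contrasts: list[ContrastSpec],
    annotation: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Fit the whole-plot model per protein and test every comparison.

    The design is inferred from the annotation (or the summary table's own
    metadata columns when no annotation is given).
    """
    meta_cols = [c for c in (RUN, CONDITION, BIOREPLICATE) if c in summaries.columns]
    ann = annotation if annotation is not None else summaries[meta_cols].drop_duplicates()
    design = detect_design(ann)
    for spec in contrasts:
        unknown = [c for c, v in spec.coefficients.items() if v != 0 and c not in design.conditions]
        if unknown:
            raise ValidationError(
                f"contrast {spec.name!r} references unknown condition(s) {unknown}"
            )

    rows = []
    for protein, grp in summaries.groupby(PROTEIN, sort=True):
        usable = grp.dropna(subset=[LOG2_ABUNDANCE])
        if usable.empty:
            for spec in contrasts:
                rows.append(
                    {
                        PROTEIN: protein, "Label": spec.name, "log2FC": np.nan,
                        "SE": np.nan, "Tvalue": np.nan, "DF": np.nan,
                        "pvalue": np.nan, "adj_pvalue": np.nan,
                        "issue": ISSUE_COMPLETE,
                    }
                )
            continue
        try:
            model = fit_protein_model(usable, design, protein=str(protein))
        except ValidationError:
            for spec in contrasts:
                rows.append(
                    {
                        PROTEIN: protein, "Label": spec.name, "log2FC": np.nan,
                        "SE": np.nan, "Tvalue": np.nan, "DF": np.nan,
                        "pvalue": np.nan, "adj_pvalue": np.nan,
                        "issue": ISSUE_ONE_CONDITION,
                    }
                )
            continue
        for spec in contrasts:
            rows.append(test_contrast(model, spec))
    results = pd.DataFrame(rows, columns=RESULT_COLUMNS)
    return adjust_fdr(results)
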