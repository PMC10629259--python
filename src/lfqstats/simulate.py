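"""Synthetic label-free experiments with known ground truth.

Intensities are built additively on the log2 scale — protein base +
condition effect + subject effect + run effect + feature effect + Normal
noise — then exponentiated to the raw scale, mirroring the generative
structure assumed by the imputation, summarization and whole-plot models.
Missingness has two mechanisms: *censoring* removes cells whose true log2
value falls below a threshold (abundance-dependent), and *MAR* drops each
remaining cell independently with a fixed rate.  Everything is deterministic
given the seed.

Default magnitudes emulate a small spike-in style benchmark: a protein base
around 20 on the log2 scale with a spread of 2 across proteins, feature
effects with SD 1 (ionization efficiency differences span orders of
magnitude), run effects with SD 0.2 (between-run drift before
normalization), and residual feature noise with SD 0.2.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .io import (
    BIOREPLICATE,
    CANONICAL_COLUMNS,
    CONDITION,
    INTENSITY,
    PEPTIDE,
    PROTEIN,
    RUN,
    TECHREPLICATE,
    ValidationError,
)

TRUE_LOG2FC = "TrueLog2FC"
IS_CHANGED = "IsChanged"
MECHANISM = "Mechanism"


@dataclass
class SimulationSpec:
    """Design and effect sizes of a simulated experiment.

    ``n_changed`` proteins receive ``log2_fc`` added to every non-reference
    condition effect listed in ``changed_conditions`` (default: the second
    condition); the rest are null.  ``design_type`` is ``"group"`` (subjects
    nested in conditions) or ``"paired"`` (every subject measured in every
    condition).
    """

    n_proteins: int = 100
    n_changed: int = 0
    features_per_protein: int | tuple = 5
    conditions: tuple = ("C1", "C2")
    changed_conditions: tuple | None = None
    log2_fc: float = 1.0
    subjects_per_condition: int = 3
    tech_replicates: int = 1
    design_type: str = "group"
    base_log2: float = 20.0
    sigma_protein: float = 2.0
    sigma_feature: float = 1.0
    sigma_run: float = 0.2
    sigma_subject: float = 0.0
    sigma_error: float = 0.2
    censor_threshold: float | None = None
    mar_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("sigma_protein", "sigma_feature", "sigma_run", "sigma_subject",
                     "sigma_error"):
            if getattr(self, name) < 0 or not np.isfinite(getattr(self, name)):
                raise ValidationError(f"{name} must be a finite nonnegative real")
        if not (0 <= self.mar_rate < 1 or self.mar_rate == 1.0):
            raise ValidationError("mar_rate must lie in [0, 1]")
        if self.design_type not in ("group", "paired"):
            raise ValidationError("design_type must be 'group' or 'paired'")
        if self.n_changed > self.n_proteins:
            raise ValidationError("n_changed cannot exceed n_proteins")


@dataclass
class SyntheticExperiment:
    data: pd.DataFrame  # canonical long format (with Intensity on raw scale)
    truth: pd.DataFrame  # one row per protein: IsChanged, TrueLog2FC, effects
    cells: pd.DataFrame  # per-cell truth: true log2 value and Mechanism
    spec: SimulationSpec


def _runs_for_design(spec: SimulationSpec) -> pd.DataFrame:
    rows = []
    if spec.design_type == "group":
        for ci, cond in enumerate(spec.conditions):
            for j in range(spec.subjects_per_condition):
                subj = f"{cond}_S{j + 1}"
                for k in range(spec.tech_replicates):
                    rows.append((f"{cond}_S{j + 1}_R{k + 1}", cond, subj))
    else:
        for j in range(spec.subjects_per_condition):
            subj = f"S{j + 1}"
            for cond in spec.conditions:
                for k in range(spec.tech_replicates):
                    rows.append((f"{cond}_{subj}_R{k + 1}", cond, subj))
    ann = pd.DataFrame(rows, columns=[RUN, CONDITION, BIOREPLICATE])
    if spec.tech_replicates > 1:
        ann[TECHREPLICATE] = [r.rsplit("_R", 1)[1] for r in ann[RUN]]
    return ann


def generate_experiment(spec: SimulationSpec) -> SyntheticExperiment:
    """Generate a canonical-format dataset plus its ground truth tables."""
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed))
    ann = _runs_for_design(spec)
    n_runs = len(ann)
    conds = list(spec.conditions)
    changed_conds = (
        list(spec.changed_conditions)
        if spec.changed_conditions is not None
        else conds[1:2]
    )

    run_effects = rng.normal(0.0, spec.sigma_run, n_runs)
    # subject effects: one per distinct (condition-nested or crossed) subject
    subj_ids = (
        (ann[CONDITION] + "\x1f" + ann[BIOREPLICATE])
        if spec.design_type == "group"
        else ann[BIOREPLICATE]
    )
    uniq_subj = list(dict.fromkeys(subj_ids))
    subj_eff = dict(zip(uniq_subj, rng.normal(0.0, spec.sigma_subject, len(uniq_subj))))

    records = []
    cell_true = []
    truth_rows = []
    for p in range(spec.n_proteins):
        protein = f"Prot{p:04d}"
        changed = p < spec.n_changed
        base = spec.base_log2 + rng.normal(0.0, spec.sigma_protein)
        cond_eff = {c: (spec.log2_fc if (changed and c in changed_conds) else 0.0)
                    for c in conds}
        if isinstance(spec.features_per_protein, tuple):
            lo, hi = spec.features_per_protein
            n_feat = int(rng.integers(lo, hi + 1))
        else:
            n_feat = int(spec.features_per_protein)
        feat_eff = rng.normal(0.0, spec.sigma_feature, n_feat)

        noise = rng.normal(0.0, spec.sigma_error, (n_feat, n_runs))
        for l in range(n_feat):
            peptide = f"{protein}_PEP{l + 1}"
            for k in range(n_runs):
                cond = ann[CONDITION].iloc[k]
                true_log2 = (
                    base
                    + cond_eff[cond]
                    + subj_eff[subj_ids.iloc[k]]
                    + run_effects[k]
                    + feat_eff[l]
                    + noise[l, k]
                )
                records.append(
                    (
                        protein, peptide, "2", "NA", "NA", "L",
                        cond, ann[BIOREPLICATE].iloc[k], ann[RUN].iloc[k],
                        2.0 ** true_log2,
                    )
                )
                cell_true.append(true_log2)
        truth_rows.append(
            {
                PROTEIN: protein,
                IS_CHANGED: changed,
                TRUE_LOG2FC: (spec.log2_fc if changed else 0.0),
                **{f"effect_{c}": cond_eff[c] for c in conds},
            }
        )

    data = pd.DataFrame(records, columns=CANONICAL_COLUMNS)
    if spec.tech_replicates > 1:
        data = data.merge(ann[[RUN, TECHREPLICATE]], on=RUN, how="left")
    cells = data[[PROTEIN, PEPTIDE, RUN]].copy()
    cells["true_log2"] = np.asarray(cell_true)
    cells[MECHANISM] = "observed"
    truth = pd.DataFrame(truth_rows)
    exp = SyntheticExperiment(data=data, truth=truth, cells=cells, spec=spec)
    if spec.censor_threshold is not None or spec.mar_rate > 0:
        exp = apply_missingness(exp, rng=rng)
    return exp


def apply_missingness(
    exp: SyntheticExperiment, rng: np.random.Generator | None = None
) -> SyntheticExperiment:
    """Remove cells by the censoring and MAR mechanisms of the spec.

    Cells whose *true* log2 value lies below ``censor_threshold`` become
    missing (mechanism "censored"); each surviving cell is then dropped
    independently with probability ``mar_rate`` (mechanism "mar").
    """
    spec = exp.spec
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence((spec.seed, 1)))
    data = exp.data.copy()
    cells = exp.cells.copy()
    true_vals = cells["true_log2"].to_numpy()

    censored = np.zeros(len(data), dtype=bool)
    if spec.censor_threshold is not None:
        censored = true_vals < spec.censor_threshold
    mar = np.zeros(len(data), dtype=bool)
    if spec.mar_rate > 0:
        mar = (~censored) & (rng.random(len(data)) < spec.mar_rate)
        if spec.mar_rate >= 1.0:
            warnings.warn("mar_rate = 1: every remaining cell is missing")

    data.loc[censored | mar, INTENSITY] = np.nan
    cells.loc[censored, MECHANISM] = "censored"
    cells.loc[mar, MECHANISM] = "mar"
    return replace(exp, data=data, cells=cells)


def dialect_flavored(data: pd.DataFrame, flavor: str) -> pd.DataFrame:
    """Rewrite missing intensities as a tool would report them.

    ``"spectronaut"`` writes 0 in place of a missing value; ``"maxquant"``
    and ``"skyline"`` write the literal ``NA``.  Used to exercise the
    converter dialects against generated data.
    """
    out = data.copy()
    missing = out[INTENSITY].isna()
    if flavor == "spectronaut":
        out[INTENSITY] = out[INTENSITY].fillna(0.0)
    elif flavor in ("maxquant", "skyline", "generic"):
        out[INTENSITY] = out[INTENSITY].astype(object).where(~missing, "NA")
    else:
        raise ValidationError(f"unknown flavor {flavor!r}")
    return out


# ---------------------------------------------------------------------------
# scoring
# ---------------------------------------------------------------------------


@dataclass
class ConfusionCounts:
    tp: int = 0
    fp: int = 0
    tn: int = 0
    fn: int = 0

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @property
    def efdr(self) -> float:
        """Empirical false discovery rate FP/(TP+FP); 0 when nothing called."""
        pos = self.tp + self.fp
        return self.fp / pos if pos else 0.0

    @property
    def tpr(self) -> float:
        cond_pos = self.tp + self.fn
        return self.tp / cond_pos if cond_pos else 0.0


def score_detections(
    results: pd.DataFrame, truth: pd.DataFrame, fdr_cutoff: float = 0.05
) -> ConfusionCounts:
    """Confusion counts of detections against ground truth.

    A tested (protein, comparison) pair is positive when its adjusted
    p-value is below the cutoff; pairs without an adjusted p-value (issues)
    are not counted.
    """
    merged = results.merge(truth[[PROTEIN, IS_CHANGED]], on=PROTEIN, how="left")
    tested = merged["adj_pvalue"].notna()
    called = tested & (merged["adj_pvalue"] < fdr_cutoff)
    changed = merged[IS_CHANGED].astype(bool)
    return ConfusionCounts(
        tp=int((called & changed).sum()),
        fp=int((called & ~changed).sum()),
        tn=int((tested & ~called & ~changed).sum()),
        fn=int((tested & ~called & changed).sum()),
    )
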