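"""Per-protein imputation of censored intensities.

A censored cell is known to lie below its feature's lowest quantifiable log
intensity ``m_l``, estimated by the smallest observed log intensity of that
feature.  For each protein, an accelerated failure time model

    y_{kl} = mu + Run_k + Feature_l + eps,   eps ~ Normal(0, sigma^2)

is fitted by maximizing the product of the likelihoods of observed and
censored cells: observed cells contribute the Normal density f(y; eta,
sigma^2), censored cells the cumulative probability F(m_l; eta, sigma^2).
Censored cells are then replaced by the fitted linear predictor, optionally
capped at m_l.  Imputation leans on the assumption that features of a
protein have parallel profiles across runs; it never touches observed or
missing-at-random cells, and a cell is imputable only when its run has an
observed value from another feature and its feature an observed value in
another run (so a protein entirely missing in a run is never imputed there).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import log_ndtr
from scipy.stats import norm

from .censoring import CENSORED, OBSERVED, STATUS
from .io import LOG_INTENSITY, PROTEIN, RUN, ValidationError, feature_ids

#: provenance column marking cells whose value was filled in by the model.
IMPUTED = "Imputed"

#: optional per-cell censoring bound column; when present (e.g. a known limit
#: of quantification) it overrides the feature-minimum estimate.
BOUND = "CensorBound"

_SIGMA_FLOOR = 1e-6
_LOG2PI = float(np.log(2 * np.pi))


@dataclass
class AFTFit:
    """Censored-Normal additive fit for one protein.

    ``run_effects`` and ``feature_effects`` sum to zero.  ``sigma`` is the
    degrees-of-freedom corrected error scale ``sigma_ml * sqrt(n/(n-p))``
    (p counts the location parameters); it equals the ordinary least-squares
    residual SD when no cell is censored.
    """

    mu: float
    run_effects: dict = field(default_factory=dict)
    feature_effects: dict = field(default_factory=dict)
    sigma: float = np.nan
    sigma_ml: float = np.nan
    converged: bool = False
    loglik: float = np.nan
    n_obs: int = 0
    n_cens: int = 0

    def predict(self, run: str, feature: str) -> float:
        return (
            self.mu
            + self.run_effects.get(run, 0.0)
            + self.feature_effects.get(feature, 0.0)
        )


def censor_bounds(protein_df: pd.DataFrame) -> pd.Series:
    """Feature-specific censoring bound: smallest quantified log intensity."""
    fid = feature_ids(protein_df)
    mins = protein_df.groupby(fid)[LOG_INTENSITY].min()
    return fid.map(mins)


def _nll_and_grad(params, obs_y, obs_run, obs_feat, cens_m, cens_run, cens_feat, R, F):
    """Negative censored-Normal log likelihood with analytic gradient.

    Parameters: [mu, run_1..run_{R-1}, feat_1..feat_{F-1}, log_sigma] with
    sum-to-zero effect coding.
    """
    mu = params[0]
    r_free = params[1 : R]
    f_free = params[R : R + F - 1]
    log_sigma = params[R + F - 1]
    sigma = max(np.exp(log_sigma), _SIGMA_FLOOR)

    r_full = np.append(r_free, -r_free.sum()) if R > 1 else np.zeros(1)
    f_full = np.append(f_free, -f_free.sum()) if F > 1 else np.zeros(1)

    nll = 0.0
    g_run = np.zeros(R)
    g_feat = np.zeros(F)
    g_mu = 0.0
    g_logsig = 0.0

    if obs_y.size:
        eta = mu + r_full[obs_run] + f_full[obs_feat]
        resid = obs_y - eta
        z2 = (resid / sigma) ** 2
        nll += 0.5 * (_LOG2PI + z2).sum() + obs_y.size * np.log(sigma)
        d_eta = -resid / sigma**2
        g_mu += d_eta.sum()
        np.add.at(g_run, obs_run, d_eta)
        np.add.at(g_feat, obs_feat, d_eta)
        g_logsig += (1.0 - z2).sum()

    if cens_m.size:
        eta = mu + r_full[cens_run] + f_full[cens_feat]
        z = (cens_m - eta) / sigma
        log_cdf = log_ndtr(z)
        nll -= log_cdf.sum()
        ratio = np.exp(norm.logpdf(z) - log_cdf)  # hazard phi/Phi
        d_eta = ratio / sigma
        g_mu += d_eta.sum()
        np.add.at(g_run, cens_run, d_eta)
        np.add.at(g_feat, cens_feat, d_eta)
        g_logsig += (ratio * z).sum()

    grad = np.empty_like(params)
    grad[0] = g_mu
    if R > 1:
        grad[1:R] = g_run[:-1] - g_run[-1]
    if F > 1:
        grad[R : R + F - 1] = g_feat[:-1] - g_feat[-1]
    grad[R + F - 1] = g_logsig
    return nll, grad


def fit_aft(protein_df: pd.DataFrame) -> AFTFit:
    """Fit the censored-Normal additive model for one protein.

    Only runs and features with at least one observed cell enter the
    likelihood; censored cells outside them are not imputable and are
    ignored.  Raises if the protein has no observed cell at all.
    """
    df = protein_df.copy()
    df["_fid"] = feature_ids(df)
    df["_bound"] = censor_bounds(df)
    if BOUND in df.columns:
        df["_bound"] = df[BOUND].where(df[BOUND].notna(), df["_bound"])

    obs_mask = (df[STATUS] == OBSERVED) & df[LOG_INTENSITY].notna()
    if not obs_mask.any():
        raise ValidationError("protein has no observed cells; cannot fit AFT model")

    runs_ok = set(df.loc[obs_mask, RUN])
    feats_ok = set(df.loc[obs_mask, "_fid"])
    cens_mask = (
        (df[STATUS] == CENSORED)
        & df[RUN].isin(runs_ok)
        & df["_fid"].isin(feats_ok)
        & df["_bound"].notna()
    )

    lik = df.loc[obs_mask | cens_mask]
    runs = sorted(lik[RUN].unique())
    feats = sorted(lik["_fid"].unique())
    run_idx = {r: i for i, r in enumerate(runs)}
    feat_idx = {f: i for i, f in enumerate(feats)}
    R, F = len(runs), len(feats)

    obs = df.loc[obs_mask]
    cen = df.loc[cens_mask]
    obs_y = obs[LOG_INTENSITY].to_numpy(float)
    obs_run = obs[RUN].map(run_idx).to_numpy(int)
    obs_feat = obs["_fid"].map(feat_idx).to_numpy(int)
    cens_m = cen["_bound"].to_numpy(float)
    cens_run = cen[RUN].map(run_idx).to_numpy(int)
    cens_feat = cen["_fid"].map(feat_idx).to_numpy(int)

    mu0 = obs_y.mean()
    r0 = np.zeros(R)
    f0 = np.zeros(F)
    for i, r in enumerate(runs):
        vals = obs_y[obs_run == i]
        if vals.size:
            r0[i] = vals.mean() - mu0
    for i, f in enumerate(feats):
        vals = obs_y[obs_feat == i]
        if vals.size:
            f0[i] = vals.mean() - mu0
    r0 -= r0.mean()
    f0 -= f0.mean()
    resid0 = obs_y - (mu0 + r0[obs_run] + f0[obs_feat])
    sigma0 = max(float(np.std(resid0)), 0.05)

    x0 = np.concatenate(([mu0], r0[:-1] if R > 1 else [], f0[:-1] if F > 1 else [],
                         [np.log(sigma0)]))
    args = (obs_y, obs_run, obs_feat, cens_m, cens_run, cens_feat, R, F)
    res = optimize.minimize(
        _nll_and_grad,
        x0,
        args=args,
        jac=True,
        method="L-BFGS-B",
        bounds=[(None, None)] * (1 + (R - 1) + (F - 1)) + [(np.log(_SIGMA_FLOOR), None)],
        options={"maxiter": 500, "ftol": 1e-12, "gtol": 1e-9},
    )

    mu = float(res.x[0])
    r_free = res.x[1:R]
    f_free = res.x[R : R + F - 1]
    r_full = np.append(r_free, -r_free.sum()) if R > 1 else np.zeros(1)
    f_full = np.append(f_free, -f_free.sum()) if F > 1 else np.zeros(1)
    sigma_ml = float(max(np.exp(res.x[-1]), _SIGMA_FLOOR))
    p = 1 + (R - 1) + (F - 1)
    # effective residual degrees of freedom from the observed information for
    # log sigma (equals n for fully observed data, where this reduces to the
    # usual least-squares n/(n-p) variance correction)
    delta = 1e-4
    xp, xm = res.x.copy(), res.x.copy()
    xp[-1] += delta
    xm[-1] -= delta
    info = (_nll_and_grad(xp, *args)[1][-1] - _nll_and_grad(xm, *args)[1][-1]) / (2 * delta)
    n_eff = max(info / 2.0, p + 1.0)
    sigma = sigma_ml * np.sqrt(n_eff / (n_eff - p))

    return AFTFit(
        mu=mu,
        run_effects=dict(zip(runs, r_full.tolist())),
        feature_effects=dict(zip(feats, f_full.tolist())),
        sigma=float(sigma),
        sigma_ml=sigma_ml,
        converged=bool(res.success),
        loglik=float(-res.fun),
        n_obs=int(obs_y.size),
        n_cens=int(cens_m.size),
    )


def impute_censored(protein_df: pd.DataFrame, fit: AFTFit, cap: bool = True) -> pd.DataFrame:
    """Replace imputable censored cells by the model prediction.

    With ``cap=True`` (default) the prediction is capped at the cell's
    censoring bound m_l, respecting that a censored value lies below it.
    Observed and MAR cells are never altered; censored cells whose run or
    feature has no observed value remain missing.
    """
    out = protein_df.copy()
    if IMPUTED not in out.columns:
        out[IMPUTED] = False
    fid = feature_ids(out)
    bounds = censor_bounds(out)

    imputable = (
        (out[STATUS] == CENSORED)
        & out[RUN].isin(fit.run_effects)
        & fid.isin(fit.feature_effects)
    )
    if not imputable.any():
        return out

    preds = np.array(
        [fit.predict(r, f) for r, f in zip(out.loc[imputable, RUN], fid[imputable])]
    )
    if cap:
        b = bounds[imputable].to_numpy(float)
        with np.errstate(invalid="ignore"):
            preds = np.fmin(preds, b)
    out.loc[imputable, LOG_INTENSITY] = preds
    out.loc[imputable, IMPUTED] = True
    return out


def impute_dataset(
    dataset: pd.DataFrame, cap: bool = True
) -> tuple[pd.DataFrame, dict]:
    """Impute censored cells protein by protein (independent fits).

    Proteins whose fit fails or does not converge are skipped with a
    warning and left unimputed.  Returns the imputed table and per-protein
    fit diagnostics.
    """
    pieces = []
    diagnostics: dict[str, AFTFit | None] = {}
    for protein, grp in dataset.groupby(PROTEIN, sort=False):
        if not (grp[STATUS] == CENSORED).any():
            piece = grp.copy()
            piece[IMPUTED] = False
            pieces.append(piece)
            diagnostics[protein] = None
            continue
        try:
            fit = fit_aft(grp)
        except ValidationError as exc:
            warnings.warn(f"protein {protein!r}: {exc}; imputation skipped")
            piece = grp.copy()
            piece[IMPUTED] = False
            pieces.append(piece)
            diagnostics[protein] = None
            continue
        if not fit.converged:
            warnings.warn(f"protein {protein!r}: AFT fit did not converge; imputation skipped")
            piece = grp.copy()
            piece[IMPUTED] = False
            pieces.append(piece)
            diagnostics[protein] = fit
            continue
        pieces.append(impute_censored(grp, fit, cap=cap))
        diagnostics[protein] = fit
    out = pd.concat(pieces).loc[dataset.index]
    return out, diagnostics
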