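"""Medication-effect estimation via transfer adjustment.

Drug use correlates with the very covariates that drive protein levels, so a
naive user/non-user comparison mixes drug effects with confounding.  The
procedure here isolates the drug effect by (1) modelling each protein on its
significant covariates *in non-users only*, (2) subtracting the predicted
covariate component (centered at the non-user training mean) from everyone,
and (3) comparing adjusted levels of users and non-users with a two-sided
Wilcoxon rank-sum test, Benjamini-Hochberg corrected across proteins within
each drug.

Eligible covariates include the top genetic marker of the protein and
indicators for other drugs; the covariate set is restricted to covariates
significant among the non-users.  Only drugs with at least ``min_users``
users (default 10) are scanned.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from ._lm import add_intercept, gaussian_loglik, ols
from .config import AnalysisConfig
from .covariates import (
    bonferroni_threshold,
    cox_snell_r2,
    fit_combined_model,
    significant_covariates,
)

__all__ = [
    "wilcoxon_rank_sum",
    "bh_fdr",
    "raw_drug_scan",
    "TransferModel",
    "fit_nonuser_model",
    "apply_adjustment",
    "adjusted_drug_scan",
    "stratified_comparison",
]

_EXACT_MAX_N = 8


def wilcoxon_rank_sum(x, y) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test.

    Exact enumeration when min(n1, n2) <= 8 and the pooled sample has no
    ties; otherwise the normal approximation with tie and continuity
    corrections.  Returns (U statistic of the first sample, p).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    x, y = x[~np.isnan(x)], y[~np.isnan(y)]
    if len(x) == 0 or len(y) == 0:
        return np.nan, np.nan
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        return float(len(x) * len(y) / 2.0), 1.0
    no_ties = len(np.unique(pooled)) == len(pooled)
    if min(len(x), len(y)) <= _EXACT_MAX_N and no_ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method, use_continuity=True)
    return float(res.statistic), float(res.pvalue)


def bh_fdr(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone-enforced)."""
    p = np.asarray(p, dtype=float)
    if len(p) == 0:
        return p
    if np.any((p <= 0) | (p > 1) | np.isnan(p)):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def raw_drug_scan(
    npx_wide: pd.DataFrame,
    medication_wide: pd.DataFrame,
    config: AnalysisConfig | None = None,
) -> pd.DataFrame:
    """Unadjusted per-(drug, protein) Wilcoxon scan, Bonferroni over all
    pairs tested; drugs with fewer than ``min_users`` users are excluded."""
    config = config or AnalysisConfig()
    med = medication_wide.reindex(npx_wide.index).fillna(False)
    drugs = [a for a in med.columns if int(med[a].sum()) >= config.min_users]
    rows = []
    for atc in drugs:
        users = med[atc].to_numpy(dtype=bool)
        for pid in npx_wide.columns:
            y = npx_wide[pid].to_numpy(dtype=float)
            yu, yn = y[users], y[~users]
            _, p = wilcoxon_rank_sum(yu, yn)
            rows.append(
                {
                    "atc_code": atc,
                    "protein_id": pid,
                    "n_users": int(np.isfinite(yu).sum()),
                    "n_nonusers": int(np.isfinite(yn).sum()),
                    "delta_npx": float(np.nanmean(yu) - np.nanmean(yn)),
                    "p_wilcoxon": p,
                }
            )
    out = pd.DataFrame(rows)
    if len(out):
        m = out["p_wilcoxon"].notna().sum()
        out["p_bonferroni"] = np.minimum(out["p_wilcoxon"] * m, 1.0)
        out["significant"] = out["p_bonferroni"] < config.alpha
        # per-drug FDR, comparable with the adjusted scan's criterion
        out["q_fdr"] = np.nan
        for atc in out["atc_code"].unique():
            sel = out["atc_code"] == atc
            out.loc[sel, "q_fdr"] = bh_fdr(out.loc[sel, "p_wilcoxon"].to_numpy())
    return out


# ---------------------------------------------------------------------------
# transfer adjustment

@dataclass
class TransferModel:
    """Covariate model fitted in non-users, transferable to all individuals."""

    params: pd.Series      # intercept + coefficients, indexed by column name
    columns: list[str]
    train_mean: float
    n_train: int

    def predict(self, X: pd.DataFrame | np.ndarray) -> np.ndarray:
        if not self.columns:
            return np.full(len(X), self.train_mean)
        Xm = (
            X[self.columns].to_numpy(dtype=float)
            if isinstance(X, pd.DataFrame)
            else np.asarray(X, dtype=float)
        )
        return self.params.iloc[0] + Xm @ self.params.iloc[1:].to_numpy()


def fit_nonuser_model(
    y,
    X: pd.DataFrame | None,
    nonuser_mask,
    min_nonusers: int = 30,
) -> TransferModel:
    """Fit the covariate model on non-users only.

    Covariate columns constant among non-users (e.g. a drug used only by
    users) are dropped with a warning.  With no covariates the model is the
    non-user mean.  Refuses to train on fewer than ``min_nonusers`` complete
    non-user records.
    """
    y = np.asarray(y, dtype=float)
    nonuser_mask = np.asarray(nonuser_mask, dtype=bool)
    cols = list(X.columns) if X is not None else []
    Xm = X.to_numpy(dtype=float) if cols else np.empty((len(y), 0))
    mask = nonuser_mask & ~np.isnan(y) & ~np.isnan(Xm).any(axis=1)
    n = int(mask.sum())
    if n < min_nonusers:
        raise ValueError(f"only {n} complete non-user records (< {min_nonusers})")
    Xt = Xm[mask]
    keep = [i for i in range(Xt.shape[1]) if np.ptp(Xt[:, i]) > 0]
    if len(keep) < len(cols):
        dropped = [cols[i] for i in range(len(cols)) if i not in keep]
        warnings.warn(f"covariates constant among non-users dropped: {dropped}", stacklevel=2)
        cols = [cols[i] for i in keep]
        Xt = Xt[:, keep]
    fit = ols(y[mask], add_intercept(Xt, n), ["intercept", *cols])
    return TransferModel(
        params=pd.Series(fit.params, index=["intercept", *cols]),
        columns=cols,
        train_mean=float(y[mask].mean()),
        n_train=n,
    )


def apply_adjustment(model: TransferModel, y, X: pd.DataFrame | None) -> np.ndarray:
    """Remove the covariate component predicted by a non-user model.

    adjusted = observed - (prediction - non-user training mean); applied to
    users and non-users alike so the groups stay comparable.  Individuals
    with a missing covariate come back NaN.
    """
    y = np.asarray(y, dtype=float)
    if not model.columns:
        return y.copy()
    Xm = X[model.columns].to_numpy(dtype=float)
    pred = model.predict(X)
    out = y - (pred - model.train_mean)
    out[np.isnan(Xm).any(axis=1)] = np.nan
    return out


def adjusted_drug_scan(
    npx_wide: pd.DataFrame,
    cohort: pd.DataFrame,
    medication_wide: pd.DataFrame,
    screen: pd.DataFrame | None = None,
    top_marker_dosage: pd.DataFrame | None = None,
    config: AnalysisConfig | None = None,
) -> pd.DataFrame:
    """Per-drug scan on transfer-adjusted abundances.

    For every drug with >= ``min_users`` users and every protein: restrict
    the protein's screen-significant covariates (plus other-drug indicators
    and the top genetic marker, when provided) to those significant among the
    drug's non-users, train the covariate model on non-users, adjust
    everyone, and test users against non-users (Wilcoxon, BH within drug).
    ``delta_npx`` is the adjusted user minus non-user mean; ``r2_medication``
    the Cox & Snell variance explained by the use indicator.
    """
    from .pqtl import _screen_design

    config = config or AnalysisConfig()
    med = medication_wide.reindex(npx_wide.index).fillna(False)
    tab = cohort.set_index("individual_id").loc[npx_wide.index]
    design, groups = _screen_design(tab, screen, med, npx_wide.index)
    sig = significant_covariates(screen, combined=True) if screen is not None else {}
    drugs = [a for a in med.columns if int(med[a].sum()) >= config.min_users]
    n_prot = npx_wide.shape[1]

    rows = []
    for atc in drugs:
        users = med[atc].to_numpy(dtype=bool)
        nonusers = ~users
        for pid in npx_wide.columns:
            y = npx_wide[pid].to_numpy(dtype=float)
            covs = [c for c in sig.get(pid, []) if c != f"med:{atc}"]
            local = design.copy()
            local_groups = {c: groups[c] for c in covs}
            if top_marker_dosage is not None and pid in top_marker_dosage.columns:
                local["top_marker"] = (
                    top_marker_dosage[pid].reindex(npx_wide.index).to_numpy(dtype=float)
                )
                covs = covs + ["top_marker"]
                local_groups["top_marker"] = ["top_marker"]
            selected = _select_among_nonusers(
                y, local, local_groups, nonusers, config, n_prot
            )
            cols = [c for cov in selected for c in local_groups[cov]]
            X = local[cols] if cols else None
            try:
                model = fit_nonuser_model(y, X, nonusers, config.min_nonusers)
            except ValueError:
                continue
            adj = apply_adjustment(model, y, X)
            yu, yn = adj[users], adj[nonusers]
            _, p = wilcoxon_rank_sum(yu, yn)
            ind = users.astype(float)
            ok = np.isfinite(adj)
            fit = ols(adj[ok], add_intercept(ind[ok], int(ok.sum())))
            rss0 = float(np.sum((adj[ok] - adj[ok].mean()) ** 2))
            r2_med = cox_snell_r2(gaussian_loglik(rss0, int(ok.sum())), fit.loglik, int(ok.sum()))
            rows.append(
                {
                    "atc_code": atc,
                    "protein_id": pid,
                    "n_users": int(np.isfinite(yu).sum()),
                    "n_nonusers": int(np.isfinite(yn).sum()),
                    "delta_npx": float(np.nanmean(yu) - np.nanmean(yn)),
                    "p_wilcoxon": p,
                    "r2_medication": r2_med,
                    "covariates_adjusted": ",".join(selected),
                }
            )
    out = pd.DataFrame(rows)
    if len(out):
        if config.fdr_family == "global":
            out["q_fdr"] = bh_fdr(out["p_wilcoxon"].to_numpy())
        else:
            out["q_fdr"] = np.nan
            for atc in out["atc_code"].unique():
                m = out["atc_code"] == atc
                out.loc[m, "q_fdr"] = bh_fdr(out.loc[m, "p_wilcoxon"].to_numpy())
    return out


def _select_among_nonusers(y, design, groups, nonuser_mask, config, n_proteins):
    """Restrict candidate covariates to those significant among non-users.

    The candidates already passed the Bonferroni screen on the full cohort,
    so the non-user restriction is at the nominal level: it guards against
    covariates whose apparent effect is a user-group artifact without
    re-imposing the family-wise threshold on the smaller subset (which would
    drop true confounders and leave residual confounding in the users)."""
    if not groups:
        return []
    yn = np.where(nonuser_mask, y, np.nan)
    try:
        fit = fit_combined_model(yn, design, groups)
    except ValueError:
        return []
    return [
        cov
        for cov, p in zip(fit.covariates, fit.p_contribution)
        if np.isfinite(p) and p < config.alpha
    ]


def stratified_comparison(
    adjusted,
    user_mask,
    stratum: pd.Series | np.ndarray,
    min_cell: int = 5,
) -> pd.DataFrame:
    """Adjusted user/non-user Wilcoxon within each stratum level.

    Strata with any (stratum x use) cell under ``min_cell`` complete values
    are skipped."""
    adjusted = np.asarray(adjusted, dtype=float)
    user_mask = np.asarray(user_mask, dtype=bool)
    stratum = pd.Series(np.asarray(stratum), dtype="object")
    rows = []
    for level in stratum.dropna().unique():
        m = (stratum == level).to_numpy()
        yu = adjusted[m & user_mask]
        yn = adjusted[m & ~user_mask]
        nu, nn = int(np.isfinite(yu).sum()), int(np.isfinite(yn).sum())
        if min(nu, nn) < min_cell:
            continue
        _, p = wilcoxon_rank_sum(yu, yn)
        rows.append(
            {
                "stratum": level,
                "n_users": nu,
                "n_nonusers": nn,
                "delta_npx": float(np.nanmean(yu) - np.nanmean(yn)),
                "p_wilcoxon": p,
            }
        )
    return pd.DataFrame(rows, columns=["stratum", "n_users", "n_nonusers", "delta_npx", "p_wilcoxon"])
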