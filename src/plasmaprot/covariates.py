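"""Per-protein covariate modelling and variance decomposition.

Each protein's NPX level is modelled with Gaussian linear models: every
covariate separately (single-covariate fits) and all covariates together
(combined fit).  The combined model's per-covariate contribution is a
sequential (type-I) deviance decomposition, mirroring R's ``anova`` on a
``glm`` object, with F-tests against the full-model residual mean square.
Variance explained is the Cox & Snell pseudo-R², which for Gaussian models
coincides with the classical R².  Family-wise significance uses a Bonferroni
threshold over (covariates x proteins).

Missing values are handled by listwise deletion per fit (per protein, per
covariate set), never by global row deletion.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._lm import add_intercept, gaussian_loglik, ols
from .config import AnalysisConfig

__all__ = [
    "cox_snell_r2",
    "bonferroni_threshold",
    "expand_covariates",
    "fit_single_covariate",
    "fit_combined_model",
    "screen_all",
    "significant_covariates",
    "SingleCovariateFit",
    "CombinedFit",
]


def cox_snell_r2(loglik_null: float, loglik_model: float, n: int) -> float:
    """Cox & Snell pseudo-R²: ``1 - (L0/L1)^(2/n)`` on the likelihood scale.

    For a Gaussian linear model this equals the classical R² =
    1 - RSS_model/RSS_null.  Returns a value in [0, 1).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if loglik_model < loglik_null - 1e-8:
        raise ValueError("loglik_model must be >= loglik_null")
    r2 = 1.0 - np.exp((2.0 / n) * (loglik_null - loglik_model))
    return float(min(max(r2, 0.0), 1.0 - 1e-16))


def bonferroni_threshold(alpha: float, *m_counts: int) -> float:
    """``alpha`` divided by the product of the test-family sizes."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0,1)")
    thr = alpha
    for m in m_counts:
        if m < 1:
            raise ValueError("family sizes must be >= 1")
        thr /= m
    return thr


# ---------------------------------------------------------------------------
# design construction

def expand_covariates(
    table: pd.DataFrame, covariates: list[str] | None = None
) -> tuple[pd.DataFrame, dict[str, list[str]]]:
    """Expand a covariate table to a numeric design.

    Boolean columns become 0/1; categorical (object) columns become indicator
    contrasts with the most frequent level as reference.  Returns the numeric
    design and a mapping covariate -> its design columns.
    """
    if covariates is None:
        covariates = [c for c in table.columns if c != "individual_id"]
    design = {}
    groups: dict[str, list[str]] = {}
    for cov in covariates:
        s = table[cov]
        if s.dtype == bool or str(s.dtype) == "boolean":
            col = f"{cov}"
            design[col] = s.astype("float64")
            groups[cov] = [col]
        elif s.dtype == object or isinstance(s.dtype, pd.CategoricalDtype):
            levels = s.value_counts()  # most frequent first
            ref = levels.index[0]
            cols = []
            for lev in levels.index[1:]:
                col = f"{cov}[{lev}]"
                design[col] = (s == lev).astype("float64").where(s.notna())
                cols.append(col)
            groups[cov] = cols
        else:
            design[cov] = pd.to_numeric(s, errors="coerce").astype("float64")
            groups[cov] = [cov]
    return pd.DataFrame(design, index=table.index), groups


# ---------------------------------------------------------------------------
# fits

@dataclass
class SingleCovariateFit:
    beta: float
    p: float
    r2: float
    n_used: int
    estimable: bool


@dataclass
class CombinedFit:
    covariates: list[str]
    seq_ss: np.ndarray
    df: np.ndarray
    f_stat: np.ndarray
    p_contribution: np.ndarray
    r2_combined: float
    n_used: int
    rss: float
    rss_null: float
    params: pd.Series
    dropped: list[str]

    def contribution_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "covariate": self.covariates,
                "seq_ss": self.seq_ss,
                "df": self.df,
                "F": self.f_stat,
                "p": self.p_contribution,
            }
        )


def fit_single_covariate(y, x, name: str = "x") -> SingleCovariateFit:
    """Gaussian fit of one covariate (multi-column for categoricals).

    ``beta`` is the first design coefficient; ``p`` is the Wald two-sided
    p-value for a single column and the model F-test otherwise; ``r2`` is
    the Cox & Snell value.  Requires >=3 complete pairs and a non-constant
    covariate, otherwise the result is flagged inestimable.
    """
    if isinstance(x, pd.Series) and (x.dtype == object or x.dtype == bool):
        X, _ = expand_covariates(x.to_frame(name), [name])
        X = X.to_numpy()
    else:
        X = np.asarray(x, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
    y = np.asarray(y, dtype=float)
    mask = ~np.isnan(y) & ~np.isnan(X).any(axis=1)
    y, X = y[mask], X[mask]
    n = len(y)
    if n < 3 or np.all(X == X[0:1, :]):
        return SingleCovariateFit(np.nan, np.nan, np.nan, n, False)
    fit = ols(y, add_intercept(X, n))
    rss0 = float(np.sum((y - y.mean()) ** 2))
    r2 = cox_snell_r2(gaussian_loglik(rss0, n), fit.loglik, n)
    q = fit.rank - 1
    if q <= 0 or fit.df_resid <= 0:
        return SingleCovariateFit(np.nan, np.nan, np.nan, n, False)
    if X.shape[1] == 1:
        p = float(fit.pvalues()[1])
    else:
        f = ((rss0 - fit.rss) / q) / (fit.rss / fit.df_resid)
        p = float(stats.f.sf(f, q, fit.df_resid))
    return SingleCovariateFit(float(fit.params[1]), p, r2, n, True)


def fit_combined_model(
    y, X: pd.DataFrame, groups: dict[str, list[str]] | None = None
) -> CombinedFit:
    """Combined Gaussian model with sequential (type-I) decomposition.

    Covariates enter in the order of ``groups`` (or column order); each
    term's contribution is the drop in residual sum of squares when it is
    added, tested with an F-statistic against the full model's residual mean
    square.  Collinear columns contribute no degrees of freedom and are
    reported in ``dropped`` with a warning.
    """
    if groups is None:
        groups = {c: [c] for c in X.columns}
    names = list(groups)
    cols = [c for g in names for c in groups[g]]
    Xm = X[cols].to_numpy(dtype=float)
    y = np.asarray(y, dtype=float)
    mask = ~np.isnan(y) & ~np.isnan(Xm).any(axis=1)
    y, Xm = y[mask], Xm[mask]
    n = len(y)
    if n <= len(cols) + 1:
        raise ValueError(f"need n > p + 1 (n={n}, p={len(cols)})")

    rss_null = float(np.sum((y - y.mean()) ** 2))
    seq_ss, dfs = [], []
    dropped: list[str] = []
    prev_rss, prev_rank = rss_null, 1
    used = np.ones((n, 1))
    for g in names:
        used = np.hstack([used, Xm[:, [cols.index(c) for c in groups[g]]]])
        fit = ols(y, used)
        d = fit.rank - prev_rank
        if d < len(groups[g]):
            dropped.extend(groups[g][d:])
        seq_ss.append(prev_rss - fit.rss)
        dfs.append(d)
        prev_rss, prev_rank = fit.rss, fit.rank
    if dropped:
        warnings.warn(f"collinear design columns dropped: {dropped}", stacklevel=2)
    full = ols(y, add_intercept(Xm, n), ["intercept", *cols])
    df_resid = full.df_resid
    mse = full.rss / df_resid
    seq_ss = np.asarray(seq_ss)
    dfs = np.asarray(dfs, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        f_stat = (seq_ss / dfs) / mse
    p = np.where(dfs > 0, stats.f.sf(f_stat, dfs, df_resid), np.nan)
    r2 = cox_snell_r2(gaussian_loglik(rss_null, n), full.loglik, n)
    return CombinedFit(
        covariates=names,
        seq_ss=seq_ss,
        df=dfs,
        f_stat=f_stat,
        p_contribution=p,
        r2_combined=r2,
        n_used=n,
        rss=full.rss,
        rss_null=rss_null,
        params=pd.Series(full.params, index=full.columns),
        dropped=dropped,
    )


# ---------------------------------------------------------------------------
# the screen

DEFAULT_COVARIATES = [
    "sex", "age", "height", "weight", "smoking", "traditional_lifestyle",
    "sampling_round", "sbp", "dbp", "ldl", "hdl", "mi_history",
    "self_reported_hypertension",
]


def screen_all(
    npx_wide: pd.DataFrame,
    cohort: pd.DataFrame,
    medication_wide: pd.DataFrame | None = None,
    config: AnalysisConfig | None = None,
    covariates: list[str] | None = None,
) -> pd.DataFrame:
    """Fit every (protein, covariate) pair singly and all together.

    Medication indicators for drugs with at least ``config.min_users`` users
    are included as covariates.  The result has one row per (protein,
    covariate) with single-fit and combined-fit statistics; ``significant``
    marks single-fit p below the Bonferroni threshold
    alpha/(n_covariates*n_proteins) and ``significant_combined`` the same for
    the sequential-ANOVA contribution (the set carried forward to the
    genetic and medication stages).
    """
    config = config or AnalysisConfig()
    covariates = covariates or [c for c in DEFAULT_COVARIATES if c in cohort.columns]
    tab = cohort.set_index("individual_id").loc[npx_wide.index]
    ctab = tab[covariates].copy()
    if "sampling_round" in ctab.columns:
        ctab["sampling_round"] = ctab["sampling_round"].astype("float64")
    design, groups = expand_covariates(ctab, covariates)
    if medication_wide is not None and len(medication_wide.columns):
        med = medication_wide.reindex(npx_wide.index).fillna(False)
        for atc in med.columns:
            if int(med[atc].sum()) >= config.min_users:
                col = f"med:{atc}"
                design[col] = med[atc].astype(float).to_numpy()
                groups[col] = [col]
    names = list(groups)
    thr = bonferroni_threshold(config.alpha, len(names), npx_wide.shape[1])

    rows = []
    for pid in npx_wide.columns:
        y = npx_wide[pid].to_numpy(dtype=float)
        try:
            comb = fit_combined_model(y, design, groups)
            comb_p = dict(zip(comb.covariates, comb.p_contribution))
            comb_r2 = comb.r2_combined
        except ValueError:
            comb_p, comb_r2 = {}, np.nan
        for name in names:
            sub = design[groups[name]]
            single = fit_single_covariate(y, sub.to_numpy(), name)
            pc = comb_p.get(name, np.nan)
            rows.append(
                {
                    "protein_id": pid,
                    "covariate": name,
                    "n_used": single.n_used,
                    "beta": single.beta,
                    "p_single": single.p,
                    "r2_single": single.r2,
                    "p_combined_anova": pc,
                    "r2_combined": comb_r2,
                    "significant": bool(single.estimable and single.p < thr),
                    "significant_combined": bool(pc == pc and pc < thr),
                }
            )
    return pd.DataFrame(rows)


def significant_covariates(screen: pd.DataFrame, combined: bool = True) -> dict[str, list[str]]:
    """Per protein, the covariates passing the Bonferroni screen."""
    col = "significant_combined" if combined else "significant"
    out: dict[str, list[str]] = {}
    for pid, sub in screen.groupby("protein_id", sort=False):
        out[pid] = sub.loc[sub[col], "covariate"].tolist()
    return out
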