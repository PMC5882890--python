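"""Two-stage protein quantitative trait locus (pQTL) mapping.

Variant QC (minor-allele frequency of at least one chromosome, exact
Hardy-Weinberg test with Bonferroni correction), covariate residualization
followed by rank-inverse-normal transformation, per-variant linear
association scans, discovery/replication selection, cis/trans annotation
against the encoding gene (<35 kb window, strict), and top-marker variance
attribution on the raw abundance scale.

The sample is modelled as unrelated; kinship-aware mixed models are out of
scope (an optional genomic-control style correction can be applied
downstream by the caller).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln

from ._lm import add_intercept, gaussian_loglik, ols
from .config import AnalysisConfig
from .covariates import cox_snell_r2, significant_covariates, expand_covariates
from .io import dosage_values

__all__ = [
    "hwe_exact_test",
    "variant_qc",
    "rank_inverse_normal",
    "residualize",
    "association_scan",
    "two_stage_select",
    "annotate_cis_trans",
    "top_marker_variance",
    "pqtl_pipeline",
    "TwoStageResult",
    "PqtlResult",
]

_DOSAGE_HARDCALL_TOL = 0.1
_DOSAGE_UNCERTAIN_FRACTION = 0.05


def hwe_exact_test(n_het: int, n_hom_ref: int, n_hom_alt: int) -> float:
    """Exact Hardy-Weinberg test p-value from genotype counts.

    Conditions on the observed allele counts and sums the probabilities of
    all heterozygote counts at most as probable as the observed one.
    """
    if min(n_het, n_hom_ref, n_hom_alt) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_het + n_hom_ref + n_hom_alt
    if n == 0:
        raise ValueError("no genotypes")
    n_rare = 2 * min(n_hom_ref, n_hom_alt) + n_het
    hets = np.arange(n_rare % 2, min(n_rare, 2 * n - n_rare) + 1, 2)
    hom_rare = (n_rare - hets) // 2
    hom_common = n - hets - hom_rare
    logp = (
        hets * np.log(2.0)
        + gammaln(n + 1)
        - gammaln(hets + 1)
        - gammaln(hom_rare + 1)
        - gammaln(hom_common + 1)
    )
    logp -= logp.max()
    prob = np.exp(logp)
    prob /= prob.sum()
    obs = prob[np.nonzero(hets == n_het)[0][0]]
    return float(min(1.0, prob[prob <= obs * (1 + 1e-12)].sum()))


def variant_qc(dosage: pd.DataFrame, config: AnalysisConfig | None = None) -> pd.DataFrame:
    """Per-variant QC on a dosage table.

    MAF is the folded mean dosage / 2; the MAF floor is one chromosome in the
    whole sample, 1/(2n).  Hardy-Weinberg is tested on hard-called genotypes
    (nearest-integer dosage) with the exact test, Bonferroni-corrected over
    the tested variants; variants whose dosages are too far from integers for
    more than 5% of individuals (imputation-uncertainty proxy) are exempt
    from the HWE filter.
    """
    config = config or AnalysisConfig()
    meta, mat, _ = dosage_values(dosage)  # individuals x variants
    n_ind = mat.shape[0]
    min_maf = 1.0 / (2.0 * n_ind)

    rows = []
    for j, vid in enumerate(meta["variant_id"]):
        d = mat[:, j]
        d = d[~np.isnan(d)]
        if d.size == 0:
            rows.append({"variant_id": vid, "maf": np.nan, "hwe_p": np.nan,
                         "hwe_exempt": False, "reason": "all_missing"})
            continue
        af = float(d.mean() / 2.0)
        maf = min(af, 1.0 - af)
        hard = np.rint(d)
        uncertain = float(np.mean(np.abs(d - hard) > _DOSAGE_HARDCALL_TOL))
        exempt = uncertain > _DOSAGE_UNCERTAIN_FRACTION
        if exempt:
            hwe_p = np.nan
        else:
            counts = [int((hard == g).sum()) for g in (0, 1, 2)]
            hwe_p = hwe_exact_test(counts[1], counts[0], counts[2])
        rows.append({"variant_id": vid, "maf": maf, "hwe_p": hwe_p,
                     "hwe_exempt": exempt, "reason": ""})
    out = pd.DataFrame(rows)
    tested = out["hwe_p"].notna()
    hwe_thr = config.hwe_alpha / max(int(tested.sum()), 1)
    fail_maf = out["maf"].isna() | (out["maf"] < min_maf)
    fail_hwe = tested & (out["hwe_p"] < hwe_thr)
    out["passed"] = ~fail_maf & ~fail_hwe
    out.loc[fail_maf & (out["reason"] == ""), "reason"] = f"maf < {min_maf:.3g}"
    out.loc[fail_hwe, "reason"] = f"hwe_p < {hwe_thr:.3g}"
    return out


def rank_inverse_normal(x) -> np.ndarray:
    """Rank-based inverse normal transform: Phi^-1((rank - 0.5)/n).

    Ties get averaged ranks; the input must contain at least two distinct
    values and no missing values (remove them first).
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or len(x) < 2:
        raise ValueError("need a 1-D vector of length >= 2")
    if np.isnan(x).any():
        raise ValueError("missing values not allowed; remove them first")
    if np.all(x == x[0]):
        raise ValueError("constant vector cannot be rank-transformed")
    ranks = stats.rankdata(x, method="average")
    return stats.norm.ppf((ranks - 0.5) / len(x))


def residualize(
    y, X: pd.DataFrame | np.ndarray | None, rint: bool = True
) -> np.ndarray:
    """OLS residuals of a protein on its significant covariates, then RINT.

    With no covariates the residuals are the centered values.  Rows with a
    missing outcome or covariate come back NaN.  If the residuals are
    constant (degenerate fit) a ValueError propagates from the transform.
    """
    y = np.asarray(y, dtype=float)
    if X is None or (hasattr(X, "shape") and (np.size(X) == 0 or X.shape[1] == 0)):
        Xm = np.empty((len(y), 0))
    else:
        Xm = np.asarray(X, dtype=float)
        if Xm.ndim == 1:
            Xm = Xm[:, None]
    mask = ~np.isnan(y) & ~np.isnan(Xm).any(axis=1)
    out = np.full(len(y), np.nan)
    Xi = add_intercept(Xm[mask], int(mask.sum()))
    beta, *_ = np.linalg.lstsq(Xi, y[mask], rcond=None)
    resid = y[mask] - Xi @ beta
    if rint and np.ptp(resid) <= 1e-10 * max(1.0, float(np.ptp(y[mask]))):
        raise ValueError("residuals are (numerically) constant; nothing to transform")
    out[mask] = rank_inverse_normal(resid) if rint else resid
    return out


def association_scan(
    residuals,
    dosage_mat: np.ndarray,
    variant_ids,
    stage: str = "discovery",
) -> pd.DataFrame:
    """Per-variant linear regression of a (transformed) trait on dosage.

    Vectorized over variants; rows with a missing trait value are dropped.
    Variants with zero dosage variance after subsetting are skipped.
    Returns beta, se and a two-sided t-distribution p per variant.
    """
    y = np.asarray(residuals, dtype=float)
    mask = ~np.isnan(y)
    y = y[mask]
    D = np.asarray(dosage_mat, dtype=float)[mask]
    n = len(y)
    if n < 3:
        raise ValueError("need at least 3 complete observations")
    xc = D - D.mean(axis=0)
    yc = y - y.mean()
    sxx = np.einsum("ij,ij->j", xc, xc)
    keep = sxx > 0
    sxy = yc @ xc
    syy = float(yc @ yc)
    with np.errstate(divide="ignore", invalid="ignore"):
        beta = sxy / sxx
        rss = syy - beta * sxy
        rss = np.maximum(rss, 0.0)
        se = np.sqrt(rss / (n - 2) / sxx)
        tval = beta / se
    p = 2.0 * stats.t.sf(np.abs(tval), n - 2)
    p = np.maximum(p, np.finfo(float).tiny)  # keep p in (0,1]
    out = pd.DataFrame(
        {
            "variant_id": np.asarray(variant_ids),
            "beta": beta,
            "se": se,
            "p": p,
            "n": n,
            "stage": stage,
        }
    )
    return out[keep].reset_index(drop=True)


@dataclass
class TwoStageResult:
    discovery_threshold: float
    discovery_hits: pd.DataFrame
    replicated: pd.DataFrame
    proteins_discovery: list[str] = field(default_factory=list)
    proteins_replicated: list[str] = field(default_factory=list)


def two_stage_select(
    discovery: pd.DataFrame,
    replication: pd.DataFrame,
    n_variants: int,
    config: AnalysisConfig | None = None,
) -> TwoStageResult:
    """Discovery/replication selection.

    Discovery hits need p < alpha/n_variants (genome-wide Bonferroni over
    the analysed panel).  Replication is tested only for discovery hits at
    alpha/k, where k is the protein's discovery hit count (or the global
    count with ``per_protein_replication_k=False``).  Proteins with at least
    one replicated hit are flagged for the combined-cohort analysis.
    """
    config = config or AnalysisConfig()
    thr = config.alpha / n_variants
    disc = discovery[discovery["p"] < thr].copy()
    if disc.empty:
        return TwoStageResult(thr, disc, disc.copy())
    k_global = len(disc)
    merged = disc.merge(
        replication[["protein_id", "variant_id", "beta", "se", "p"]],
        on=["protein_id", "variant_id"],
        suffixes=("_discovery", "_replication"),
    )
    if config.per_protein_replication_k:
        k = disc.groupby("protein_id")["variant_id"].size()
        merged["replication_threshold"] = config.alpha / merged["protein_id"].map(k)
    else:
        merged["replication_threshold"] = config.alpha / k_global
    rep = merged[merged["p_replication"] < merged["replication_threshold"]].reset_index(drop=True)
    return TwoStageResult(
        discovery_threshold=thr,
        discovery_hits=disc.reset_index(drop=True),
        replicated=rep,
        proteins_discovery=sorted(disc["protein_id"].unique()),
        proteins_replicated=sorted(rep["protein_id"].unique()),
    )


def annotate_cis_trans(
    assoc: pd.DataFrame,
    genemap: pd.DataFrame,
    variant_meta: pd.DataFrame,
    window: int = 35_000,
) -> pd.DataFrame:
    """Flag associations as cis (distance to the encoding gene body < window,
    strict; 0 inside the gene) or trans; proteins missing from the gene map
    get a null flag."""
    out = assoc.merge(
        genemap.rename(
            columns={"chromosome": "gene_chrom", "start": "gene_start", "end": "gene_end"}
        )[["protein_id", "gene_chrom", "gene_start", "gene_end"]],
        on="protein_id",
        how="left",
    ).merge(
        variant_meta.rename(columns={"chromosome": "var_chrom", "position": "var_pos"})[
            ["variant_id", "var_chrom", "var_pos"]
        ],
        on="variant_id",
        how="left",
    )
    pos = out["var_pos"].astype(float)
    start = out["gene_start"].astype(float)
    end = out["gene_end"].astype(float)
    inside = (pos >= start) & (pos <= end)
    dist = np.where(inside, 0.0, np.minimum(np.abs(pos - start), np.abs(pos - end)))
    same_chrom = out["gene_chrom"].astype(str) == out["var_chrom"].astype(str)
    cis = pd.array(same_chrom & (dist < window), dtype="boolean")
    known = out["gene_chrom"].notna() & out["var_pos"].notna()
    cis[~known.to_numpy()] = pd.NA
    out = out.drop(columns=["gene_chrom", "gene_start", "gene_end", "var_chrom", "var_pos"])
    out["cis"] = cis
    return out


def top_marker_variance(raw_npx, dosage_vec) -> float:
    """Fraction of raw (unadjusted, untransformed) abundance variance
    explained by a single marker's dosage (Cox & Snell of the one-predictor
    Gaussian fit, i.e. the squared correlation)."""
    y = np.asarray(raw_npx, dtype=float)
    d = np.asarray(dosage_vec, dtype=float)
    mask = ~np.isnan(y) & ~np.isnan(d)
    y, d = y[mask], d[mask]
    n = len(y)
    fit = ols(y, add_intercept(d, n))
    rss0 = float(np.sum((y - y.mean()) ** 2))
    return cox_snell_r2(gaussian_loglik(rss0, n), fit.loglik, n)


# ---------------------------------------------------------------------------
# pipeline

@dataclass
class PqtlResult:
    variant_qc: pd.DataFrame
    discovery: pd.DataFrame
    replication: pd.DataFrame
    two_stage: TwoStageResult
    combined: pd.DataFrame
    top_markers: pd.DataFrame


def pqtl_pipeline(
    npx_wide: pd.DataFrame,
    cohort: pd.DataFrame,
    dosage: pd.DataFrame,
    genemap: pd.DataFrame,
    screen: pd.DataFrame,
    medication_wide: pd.DataFrame | None = None,
    config: AnalysisConfig | None = None,
) -> PqtlResult:
    """Run QC, both association stages, selection, annotation and top-marker
    variance attribution for every protein.

    Residualization uses each protein's Bonferroni-significant covariates
    from the combined-model screen; the combined stage pools both subcohorts
    with a subcohort indicator covariate.
    """
    config = config or AnalysisConfig()
    qc_tab = variant_qc(dosage, config)
    passed = set(qc_tab.loc[qc_tab["passed"], "variant_id"])
    meta, mat, ids = dosage_values(dosage)
    keep = meta["variant_id"].isin(passed).to_numpy()
    meta, mat = meta[keep].reset_index(drop=True), mat[:, keep]
    # align dosage rows to the NPX matrix
    order = pd.Index(ids).get_indexer(npx_wide.index)
    if (order < 0).any():
        raise ValueError("dosage table missing individuals present in the NPX matrix")
    mat = mat[order]
    n_variants = mat.shape[1]

    tab = cohort.set_index("individual_id").loc[npx_wide.index]
    stages = {
        "discovery": (tab["subcohort"] == "discovery").to_numpy(),
        "replication": (tab["subcohort"] == "replication").to_numpy(),
    }
    sig = significant_covariates(screen, combined=True)
    design_all, groups = _screen_design(tab, screen, medication_wide, npx_wide.index)

    scans: dict[str, list[pd.DataFrame]] = {"discovery": [], "replication": []}
    for pid in npx_wide.columns:
        y = npx_wide[pid].to_numpy(dtype=float)
        cols = [c for cov in sig.get(pid, []) for c in groups.get(cov, [])]
        X = design_all[cols] if cols else None
        for stage, smask in stages.items():
            ys = np.where(smask, y, np.nan)
            if np.isfinite(ys).sum() < 10:
                continue
            try:
                resid = residualize(ys, X)
            except ValueError:
                continue
            res = association_scan(resid, mat, meta["variant_id"], stage)
            res.insert(0, "protein_id", pid)
            scans[stage].append(res)
    disc = _concat(scans["discovery"])
    rep = _concat(scans["replication"])
    ts = two_stage_select(disc, rep, n_variants, config)

    # combined stage for replicated proteins, pooling subcohorts
    combined_rows = []
    subcoh = (tab["subcohort"] == "replication").astype(float).to_numpy()
    for pid in ts.proteins_replicated:
        y = npx_wide[pid].to_numpy(dtype=float)
        cols = [c for cov in sig.get(pid, []) for c in groups.get(cov, [])]
        X = np.column_stack([design_all[cols].to_numpy(), subcoh]) if cols else subcoh[:, None]
        resid = residualize(y, X)
        res = association_scan(resid, mat, meta["variant_id"], "combined")
        res.insert(0, "protein_id", pid)
        combined_rows.append(res)
    combined = _concat(combined_rows)
    if len(combined):
        combined = annotate_cis_trans(combined, genemap, meta, config.cis_window_bp)

    top_rows = []
    for pid in ts.proteins_replicated:
        sub = combined[combined["protein_id"] == pid]
        best = sub.loc[sub["p"].idxmin()]
        j = int(np.nonzero((meta["variant_id"] == best["variant_id"]).to_numpy())[0][0])
        r2 = top_marker_variance(npx_wide[pid].to_numpy(dtype=float), mat[:, j])
        top_rows.append(
            {
                "protein_id": pid,
                "variant_id": best["variant_id"],
                "p_combined": best["p"],
                "cis": best["cis"],
                "variance_explained": r2,
            }
        )
    top = pd.DataFrame(
        top_rows, columns=["protein_id", "variant_id", "p_combined", "cis", "variance_explained"]
    )
    return PqtlResult(qc_tab, disc, rep, ts, combined, top)


def _screen_design(tab, screen, medication_wide, index):
    """Rebuild the screen's design so covariate names resolve to columns."""
    from .covariates import DEFAULT_COVARIATES

    covs = [c for c in DEFAULT_COVARIATES if c in tab.columns]
    ctab = tab[covs].copy()
    if "sampling_round" in ctab.columns:
        ctab["sampling_round"] = ctab["sampling_round"].astype("float64")
    design, groups = expand_covariates(ctab, covs)
    if medication_wide is not None:
        med = medication_wide.reindex(index).fillna(False)
        for atc in med.columns:
            col = f"med:{atc}"
            design[col] = med[atc].astype(float).to_numpy()
            groups[col] = [col]
    return design, groups


def _concat(frames: list[pd.DataFrame]) -> pd.DataFrame:
    if not frames:
        return pd.DataFrame(
            columns=["protein_id", "variant_id", "beta", "se", "p", "n", "stage"]
        )
    return pd.concat(frames, ignore_index=True)
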