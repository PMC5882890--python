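"""Statin and hypertension workflows built on the transfer adjustment.

The statin workflow pools statin substances after a poolability check,
scans adjusted abundances, and screens significant proteins for LDL-mediated
confounding with Spearman correlation in the controls.  The hypertension
workflow defines the hypertensive group from blood pressure, self-report and
antihypertensive use, trains control-group covariate models, and compares
each drug class against controls, summarising the overlap of affected
proteins across classes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .config import AnalysisConfig
from .covariates import bonferroni_threshold, significant_covariates
from .medication import (
    apply_adjustment,
    bh_fdr,
    fit_nonuser_model,
    wilcoxon_rank_sum,
)

__all__ = [
    "define_hypertension_group",
    "spearman_confound_screen",
    "statin_workflow",
    "hypertension_workflow",
    "StatinResult",
    "HypertensionResult",
]


# ---------------------------------------------------------------------------
# group definition

def define_hypertension_group(
    cohort: pd.DataFrame,
    medication_wide: pd.DataFrame,
    config: AnalysisConfig | None = None,
) -> pd.DataFrame:
    """Hypertension group membership and treatment regimen per individual.

    An individual is in the group if any criterion holds: blood pressure over
    the 140/90 mmHg thresholds (both SBP and DBP by default, ``bp_rule='or'``
    for either), self-reported hypertension, or use of any antihypertensive
    drug class.  ``regimen_class`` is none/mono/combination by the number of
    distinct antihypertensive ATC codes used.
    """
    config = config or AnalysisConfig()
    tab = cohort.set_index("individual_id")
    med = medication_wide.reindex(tab.index).fillna(False)
    aht_cols = [
        c for c in med.columns if any(str(c).startswith(p) for p in config.antihypertensive_atc)
    ]
    has_med_record = tab.index.isin(medication_wide.index)
    rows = []
    excluded = []
    for (iid, row), med_known in zip(tab.iterrows(), has_med_record):
        sbp, dbp = row.get("sbp"), row.get("dbp")
        sr = row.get("self_reported_hypertension")
        if pd.isna(sbp) and pd.isna(dbp) and pd.isna(sr) and not med_known:
            excluded.append(iid)
            continue
        basis = set()
        high_sbp = pd.notna(sbp) and sbp > config.sbp_threshold
        high_dbp = pd.notna(dbp) and dbp > config.dbp_threshold
        bp_high = (high_sbp and high_dbp) if config.bp_rule == "and" else (high_sbp or high_dbp)
        if bp_high:
            basis.add("blood_pressure")
        if pd.notna(sr) and bool(sr):
            basis.add("self_report")
        regimen = sorted(c for c in aht_cols if bool(med.loc[iid, c]))
        if regimen:
            basis.add("medication")
        n_drugs = len(regimen)
        rows.append(
            {
                "individual_id": iid,
                "in_group": bool(basis),
                "basis": ",".join(sorted(basis)),
                "regimen": ",".join(regimen),
                "regimen_class": "none" if n_drugs == 0 else ("mono" if n_drugs == 1 else "combination"),
            }
        )
    if excluded:
        warnings.warn(
            f"{len(excluded)} individuals excluded from the hypertension grouping "
            f"(no blood pressure, self-report or medication information)",
            stacklevel=2,
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# confounding screen

def spearman_confound_screen(protein_values, lipid_values, alpha: float = 0.05) -> dict:
    """Spearman correlation of a protein with a lipid measure.

    Tie-averaged ranks, two-sided p; flagged confounded at nominal p < alpha.
    Constant input yields an inestimable flag.
    """
    x = np.asarray(protein_values, dtype=float)
    y = np.asarray(lipid_values, dtype=float)
    mask = ~np.isnan(x) & ~np.isnan(y)
    x, y = x[mask], y[mask]
    if len(x) < 5:
        raise ValueError("need at least 5 complete pairs")
    if np.all(x == x[0]) or np.all(y == y[0]):
        return {"rho": np.nan, "p": np.nan, "confounded": False, "estimable": False}
    rho, p = stats.spearmanr(x, y)
    return {"rho": float(rho), "p": float(p), "confounded": bool(p < alpha), "estimable": True}


# ---------------------------------------------------------------------------
# statins

@dataclass
class StatinResult:
    lipid_comparisons: pd.DataFrame
    poolability: pd.DataFrame
    pooled: bool
    comparisons: pd.DataFrame          # adjusted scan, q_fdr across proteins
    confound_flags: pd.DataFrame
    clean_proteins: list[str] = field(default_factory=list)
    sensitivity: pd.DataFrame = field(default_factory=pd.DataFrame)


def _transfer_scan(
    npx_wide, design, groups, sig, train_mask, group_a, group_b, config, select_mask=None
):
    """Shared helper: per protein, train on ``train_mask``, adjust, compare
    ``group_a`` (users) vs ``group_b`` (controls); BH across proteins."""
    from .medication import _select_among_nonusers

    rows = []
    n_prot = npx_wide.shape[1]
    sel_mask = train_mask if select_mask is None else select_mask
    for pid in npx_wide.columns:
        y = npx_wide[pid].to_numpy(dtype=float)
        covs = sig.get(pid, [])
        local_groups = {c: groups[c] for c in covs if c in groups}
        selected = _select_among_nonusers(y, design, local_groups, sel_mask, config, n_prot)
        cols = [c for cov in selected for c in local_groups[cov]]
        X = design[cols] if cols else None
        try:
            model = fit_nonuser_model(y, X, train_mask, config.min_nonusers)
        except ValueError:
            continue
        adj = apply_adjustment(model, y, X)
        ya, yb = adj[group_a], adj[group_b]
        _, p = wilcoxon_rank_sum(ya, yb)
        rows.append(
            {
                "protein_id": pid,
                "n_users": int(np.isfinite(ya).sum()),
                "n_nonusers": int(np.isfinite(yb).sum()),
                "delta_npx": float(np.nanmean(ya) - np.nanmean(yb)),
                "p_wilcoxon": p,
                "covariates_adjusted": ",".join(selected),
            }
        )
    out = pd.DataFrame(rows)
    if len(out):
        out["q_fdr"] = bh_fdr(out["p_wilcoxon"].to_numpy())
    return out


def statin_workflow(
    npx_wide: pd.DataFrame,
    cohort: pd.DataFrame,
    medication_wide: pd.DataFrame,
    screen: pd.DataFrame,
    config: AnalysisConfig | None = None,
) -> StatinResult:
    """Statin analysis: lipid comparisons, substance poolability, adjusted
    scan against non-users of any lipid-modifying drug, LDL confounding
    screen, and an antihypertensive-free sensitivity rerun."""
    from .pqtl import _screen_design

    config = config or AnalysisConfig()
    med = medication_wide.reindex(npx_wide.index).fillna(False)
    tab = cohort.set_index("individual_id").loc[npx_wide.index]
    lipid_cols = [c for c in med.columns if str(c).startswith(config.lipid_lowering_prefix)]
    statin_cols = [c for c in med.columns if str(c).startswith(config.statin_prefix)]
    lipid_user = med[lipid_cols].any(axis=1).to_numpy() if lipid_cols else np.zeros(len(med), bool)
    statin_user = med[statin_cols].any(axis=1).to_numpy() if statin_cols else np.zeros(len(med), bool)
    controls = ~lipid_user

    empty = StatinResult(
        pd.DataFrame(), pd.DataFrame(), True, pd.DataFrame(), pd.DataFrame()
    )
    if not statin_user.any():
        return empty

    # 1) lipid levels, statin users vs non-users of lipid-modifying drugs
    lipid_rows = []
    for lip in ("hdl", "ldl"):
        if lip not in tab.columns or tab[lip].isna().all():
            warnings.warn(f"missing {lip} column; lipid comparison skipped", stacklevel=2)
            continue
        v = tab[lip].to_numpy(dtype=float)
        _, p = wilcoxon_rank_sum(v[statin_user], v[controls])
        lipid_rows.append(
            {
                "measure": lip,
                "mean_users": float(np.nanmean(v[statin_user])),
                "mean_controls": float(np.nanmean(v[controls])),
                "p_wilcoxon": p,
            }
        )
    lipid_cmp = pd.DataFrame(lipid_rows)

    design, groups = _screen_design(tab, screen, med, npx_wide.index)
    sig_all = significant_covariates(screen, combined=True)
    # statin indicators cannot adjust their own comparison
    sig = {
        pid: [c for c in covs if not c.startswith("med:" + config.lipid_lowering_prefix)]
        for pid, covs in sig_all.items()
    }

    # 2) poolability of the two most used statin substances, on adjusted data
    counts = {c: int(med[c].sum()) for c in statin_cols if int(med[c].sum()) > 0}
    top2 = sorted(counts, key=counts.get, reverse=True)[:2]
    pool_rows = []
    pooled = True
    if len(top2) == 2:
        ga = med[top2[0]].to_numpy(bool) & statin_user
        gb = med[top2[1]].to_numpy(bool) & statin_user & ~ga
        pool = _transfer_scan(
            npx_wide, design, groups, sig, controls, ga, gb, config
        ).rename(columns={"n_users": f"n_{top2[0]}", "n_nonusers": f"n_{top2[1]}"})
        pool_thr = bonferroni_threshold(config.alpha, npx_wide.shape[1])
        pooled = bool((pool["p_wilcoxon"].dropna() >= pool_thr).all()) if len(pool) else True
        pool_rows = pool
    poolability = pool_rows if isinstance(pool_rows, pd.DataFrame) else pd.DataFrame()

    # 3) pooled adjusted scan: statin users vs controls
    comparisons = _transfer_scan(
        npx_wide, design, groups, sig, controls, statin_user, controls, config
    )

    # 4) LDL confounding screen among significant proteins
    flags = []
    ldl = tab["ldl"].to_numpy(dtype=float) if "ldl" in tab.columns else None
    sig_prot = (
        comparisons.loc[comparisons["q_fdr"] < config.alpha, "protein_id"].tolist()
        if len(comparisons)
        else []
    )
    for pid in sig_prot:
        if ldl is None:
            break
        y = npx_wide[pid].to_numpy(dtype=float)
        res = spearman_confound_screen(y[controls], ldl[controls], config.alpha)
        flags.append({"protein_id": pid, "rho_ldl": res["rho"], "p_rho": res["p"],
                      "confounded": res["confounded"]})
    confound = pd.DataFrame(flags, columns=["protein_id", "rho_ldl", "p_rho", "confounded"])
    confounded = set(confound.loc[confound["confounded"], "protein_id"]) if len(confound) else set()
    clean = [p for p in sig_prot if p not in confounded]

    # 5) sensitivity: exclude antihypertensive users from both groups
    aht_cols = [
        c for c in med.columns if any(str(c).startswith(p) for p in config.antihypertensive_atc)
    ]
    no_aht = ~med[aht_cols].any(axis=1).to_numpy() if aht_cols else np.ones(len(med), bool)
    sens = pd.DataFrame()
    if clean:
        sub = npx_wide[clean]
        sens = _transfer_scan(
            sub, design, groups, sig,
            controls & no_aht, statin_user & no_aht, controls & no_aht, config,
        )
    return StatinResult(lipid_cmp, poolability, pooled, comparisons, confound, clean, sens)


# ---------------------------------------------------------------------------
# hypertension

@dataclass
class HypertensionResult:
    group: pd.DataFrame
    comparisons: pd.DataFrame           # per (drug class, protein)
    overlap: pd.DataFrame               # class x class shared significant proteins
    centered_distributions: pd.DataFrame


def hypertension_workflow(
    npx_wide: pd.DataFrame,
    cohort: pd.DataFrame,
    medication_wide: pd.DataFrame,
    screen: pd.DataFrame,
    config: AnalysisConfig | None = None,
) -> HypertensionResult:
    """Per-antihypertensive-class comparisons against non-hypertensive
    controls, with transfer models trained in the controls and a per-class
    FDR; includes the untreated hypertensive subgroup as class 'none'."""
    from .pqtl import _screen_design

    config = config or AnalysisConfig()
    med = medication_wide.reindex(npx_wide.index).fillna(False)
    tab = cohort.set_index("individual_id").loc[npx_wide.index]
    group = define_hypertension_group(cohort, medication_wide, config)
    group = group.set_index("individual_id").reindex(npx_wide.index)
    in_group = group["in_group"].fillna(False).to_numpy(dtype=bool)
    controls = ~in_group
    if not in_group.any():
        return HypertensionResult(group.reset_index(), pd.DataFrame(), pd.DataFrame(), pd.DataFrame())

    design, groups_map = _screen_design(tab, screen, med, npx_wide.index)
    sig_all = significant_covariates(screen, combined=True)
    sig = {
        pid: [
            c for c in covs
            if not any(c.startswith(f"med:{p}") for p in config.antihypertensive_atc)
        ]
        for pid, covs in sig_all.items()
    }

    class_members: dict[str, np.ndarray] = {}
    for atc in config.antihypertensive_atc:
        cols = [c for c in med.columns if str(c).startswith(atc)]
        if not cols:
            continue
        members = med[cols].any(axis=1).to_numpy() & in_group
        if int(members.sum()) >= config.min_users:
            class_members[atc] = members
    aht_cols = [
        c for c in med.columns if any(str(c).startswith(p) for p in config.antihypertensive_atc)
    ]
    untreated = in_group & (~med[aht_cols].any(axis=1).to_numpy() if aht_cols else True)
    if int(untreated.sum()) >= config.min_users:
        class_members["none"] = untreated

    frames = []
    for cls, members in class_members.items():
        res = _transfer_scan(
            npx_wide, design, groups_map, sig, controls, members, controls, config
        )
        res.insert(0, "drug_class", cls)
        frames.append(res)
    comparisons = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()

    sig_sets = {
        cls: set(sub.loc[sub["q_fdr"] < config.alpha, "protein_id"])
        for cls, sub in (comparisons.groupby("drug_class") if len(comparisons) else [])
    }
    classes = list(sig_sets)
    overlap = pd.DataFrame(
        [[len(sig_sets[a] & sig_sets[b]) for b in classes] for a in classes],
        index=classes,
        columns=classes,
        dtype=int,
    )

    # control-centered distributions for the union of significant proteins
    all_sig = sorted(set().union(*sig_sets.values())) if sig_sets else []
    dist_rows = []
    for pid in all_sig:
        y = npx_wide[pid].to_numpy(dtype=float)
        c_mean = float(np.nanmean(y[controls]))
        for cls, members in class_members.items():
            for v in y[members]:
                if np.isfinite(v):
                    dist_rows.append({"protein_id": pid, "drug_class": cls, "npx_centered": v - c_mean})
        for v in y[controls]:
            if np.isfinite(v):
                dist_rows.append({"protein_id": pid, "drug_class": "control", "npx_centered": v - c_mean})
    centered = pd.DataFrame(dist_rows, columns=["protein_id", "drug_class", "npx_centered"])
    return HypertensionResult(group.reset_index(), comparisons, overlap, centered)
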