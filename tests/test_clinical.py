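"""Hypertension grouping, Spearman confound screen, statin/hypertension flows."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import plasmaprot as pp
from plasmaprot.io import medication_wide, npx_wide


def _mini_cohort(rows, med_rows=()):
    base = {
        "sex": "female", "age": 50.0, "height": 165.0, "weight": 70.0,
        "smoking": "never", "traditional_lifestyle": False, "sampling_round": 2006,
        "sbp": 120.0, "dbp": 80.0, "ldl": 3.0, "hdl": 1.5,
        "mi_history": False, "self_reported_hypertension": False,
        "subcohort": "discovery",
    }
    recs = []
    for i, override in enumerate(rows):
        r = dict(base, individual_id=f"I{i}", **override)
        recs.append(r)
    cohort = pd.DataFrame(recs)
    med = pd.DataFrame(
        [{"individual_id": iid, "atc_code": atc, "used": True} for iid, atc in med_rows],
        columns=["individual_id", "atc_code", "used"],
    )
    return cohort, med


# ---------------------------------------------------------------------------
# hypertension group definition

def test_bp_criterion_requires_both_by_default():
    cohort, med = _mini_cohort(
        [
            {"sbp": 145.0, "dbp": 95.0},   # both above -> in
            {"sbp": 145.0, "dbp": 85.0},   # only SBP -> out under "and"
            {"sbp": 120.0, "dbp": 80.0},   # control
            {"sbp": 140.0, "dbp": 90.0},   # exactly at thresholds: strict > -> out
        ]
    )
    mw = medication_wide(med, cohort["individual_id"])
    grp = pp.define_hypertension_group(cohort, mw).set_index("individual_id")
    assert bool(grp.loc["I0", "in_group"]) and grp.loc["I0", "basis"] == "blood_pressure"
    assert not grp.loc["I1", "in_group"]
    assert not grp.loc["I2", "in_group"]
    assert not grp.loc["I3", "in_group"]
    # "or" mode admits the SBP-only individual
    cfg = pp.AnalysisConfig(bp_rule="or")
    grp2 = pp.define_hypertension_group(cohort, mw, cfg).set_index("individual_id")
    assert bool(grp2.loc["I1", "in_group"])


def test_group_via_self_report_and_medication_and_regimen_class():
    cohort, med = _mini_cohort(
        [
            {"self_reported_hypertension": True},
            {},  # on two antihypertensive classes
            {},  # on one
            {},
        ],
        med_rows=[("I1", "C07AB02"), ("I1", "C09AA02"), ("I2", "C08CA01")],
    )
    mw = medication_wide(med, cohort["individual_id"])
    grp = pp.define_hypertension_group(cohort, mw).set_index("individual_id")
    assert grp.loc["I0", "basis"] == "self_report"
    assert grp.loc["I1", "regimen_class"] == "combination"
    assert grp.loc["I2", "regimen_class"] == "mono"
    assert not grp.loc["I3", "in_group"] and grp.loc["I3", "regimen_class"] == "none"


def test_group_membership_is_monotone_in_criteria():
    # adding a qualifying criterion never removes an individual
    cohort, med = _mini_cohort([{"sbp": 150.0, "dbp": 95.0}])
    mw = medication_wide(med, cohort["individual_id"])
    base = pp.define_hypertension_group(cohort, mw)["in_group"].iloc[0]
    cohort2 = cohort.assign(self_reported_hypertension=True)
    plus = pp.define_hypertension_group(cohort2, mw)["in_group"].iloc[0]
    assert base and plus


# ---------------------------------------------------------------------------
# Spearman confound screen

def test_spearman_perfect_monotone():
    x = np.array([1.0, 2.0, 5.0, 9.0, 11.0, 20.0])
    out = pp.spearman_confound_screen(x, np.exp(x / 10))
    assert out["rho"] == pytest.approx(1.0)
    assert out["confounded"]


def test_spearman_matches_rank_formula(rng):
    # no-ties fixture: rho = 1 - 6*sum(d^2)/(n(n^2-1))
    for _ in range(10):
        n = 6
        x = rng.permutation(np.arange(n)).astype(float)
        y = rng.permutation(np.arange(n)).astype(float) + rng.uniform(0, 0.1, n)
        rx = stats.rankdata(x)
        ry = stats.rankdata(y)
        rho_formula = 1 - 6 * np.sum((rx - ry) ** 2) / (n * (n**2 - 1))
        out = pp.spearman_confound_screen(x, y)
        assert out["rho"] == pytest.approx(rho_formula, rel=1e-10)


def test_spearman_invariant_to_monotone_transform(rng):
    x = rng.normal(size=30)
    y = rng.normal(size=30)
    a = pp.spearman_confound_screen(x, y)
    b = pp.spearman_confound_screen(np.exp(x), 5 * y - 2)
    assert a["rho"] == pytest.approx(b["rho"], rel=1e-12)
    assert a["confounded"] == b["confounded"]


def test_spearman_null_flag_rate(rng):
    flags = [
        pp.spearman_confound_screen(rng.normal(size=50), rng.normal(size=50))["confounded"]
        for _ in range(400)
    ]
    assert np.mean(flags) == pytest.approx(0.05, abs=0.03)


def test_spearman_degenerate_inputs():
    with pytest.raises(ValueError):
        pp.spearman_confound_screen([1, 2], [3, 4])
    out = pp.spearman_confound_screen(np.ones(10), np.arange(10.0))
    assert not out["estimable"] and not out["confounded"]


# ---------------------------------------------------------------------------
# statin workflow

def _statin_cohort(seed=31, statin_delta=0.6):
    """Two channels: PROT0001 gets a true statin effect, PROT0002 an
    LDL-driven shift only."""
    n_cov = 13
    n_prot = 6
    B = np.zeros((n_cov, n_prot))
    B[9, 1] = 0.8  # ldl drives protein 2
    spec = [
        pp.MedicationSpec("C10AA01", 0.08, ((0, statin_delta),), {"ldl": 0.8, "age": 0.6}),
        pp.MedicationSpec("C10AA05", 0.03, ((0, statin_delta),), {"ldl": 0.8, "age": 0.6}),
        pp.MedicationSpec("C07AB02", 0.06, (), {"age": 0.5}),
    ]
    cfg = pp.SimulationConfig(
        n_discovery=500, n_replication=250, n_proteins=n_prot, n_variants=5,
        covariate_effect_matrix=B, pqtl_spec=[], medication_spec=spec,
        n_low_abundance=0, seed=seed,
    )
    c = pp.generate_cohort(cfg)
    wide = npx_wide(c.npx)
    mw = medication_wide(c.medication, wide.index)
    screen = pp.screen_all(wide, c.cohort, mw)
    return c, wide, mw, screen


def test_statin_workflow_two_channel_separation():
    # identical substance effects -> poolable in the clear majority of draws
    pooled_runs = []
    for seed in (31, 32, 33):
        c, wide, mw, screen = _statin_cohort(seed=seed)
        res = pp.statin_workflow(wide, c.cohort, mw, screen)
        pooled_runs.append(res.pooled)
    assert sum(pooled_runs) >= 2
    c, wide, mw, screen = _statin_cohort(seed=32)
    res = pp.statin_workflow(wide, c.cohort, mw, screen)
    assert "PROT0001" in res.clean_proteins
    flagged = set(res.confound_flags.loc[res.confound_flags["confounded"], "protein_id"])
    assert "PROT0002" not in res.clean_proteins or "PROT0002" not in set(
        res.comparisons.loc[res.comparisons["q_fdr"] < 0.05, "protein_id"]
    ) or "PROT0002" in flagged
    # the true statin target shows a positive adjusted delta near truth
    row = res.comparisons.set_index("protein_id").loc["PROT0001"]
    assert row["delta_npx"] == pytest.approx(0.6, abs=0.25)
    assert row["q_fdr"] < 0.05


def test_statin_workflow_reports_lipid_differences():
    c, wide, mw, screen = _statin_cohort()
    res = pp.statin_workflow(wide, c.cohort, mw, screen)
    assert set(res.lipid_comparisons["measure"]) == {"hdl", "ldl"}
    # statin users were sampled preferentially at high LDL
    ldl = res.lipid_comparisons.set_index("measure").loc["ldl"]
    assert ldl["mean_users"] > ldl["mean_controls"]


def test_statin_workflow_empty_without_users():
    cohort, med = _mini_cohort([{} for _ in range(40)])
    mw = medication_wide(med, cohort["individual_id"])
    wide = pd.DataFrame(
        np.random.default_rng(0).normal(size=(40, 2)),
        index=cohort["individual_id"],
        columns=["P1", "P2"],
    )
    screen = pd.DataFrame(
        columns=["protein_id", "covariate", "significant", "significant_combined"]
    )
    res = pp.statin_workflow(wide, cohort, mw, screen)
    assert res.comparisons.empty and res.clean_proteins == []


# ---------------------------------------------------------------------------
# hypertension workflow

def test_hypertension_workflow_disjoint_class_effects():
    n_cov, n_prot = 13, 9
    B = np.zeros((n_cov, n_prot))
    # classes hit disjoint protein targets
    spec = [
        pp.MedicationSpec("C07AB02", 0.10, ((0, 0.9), (1, 0.9)), {"sbp": 1.2}),
        pp.MedicationSpec("C09AA02", 0.10, ((3, 0.9), (4, 0.9)), {"sbp": 1.2}),
        pp.MedicationSpec("C08CA01", 0.10, ((6, 0.9), (7, 0.9)), {"sbp": 1.2}),
    ]
    cfg = pp.SimulationConfig(
        n_discovery=600, n_replication=300, n_proteins=n_prot, n_variants=5,
        covariate_effect_matrix=B, pqtl_spec=[], medication_spec=spec,
        n_low_abundance=0, seed=41,
    )
    c = pp.generate_cohort(cfg)
    wide = npx_wide(c.npx)
    mw = medication_wide(c.medication, wide.index)
    screen = pp.screen_all(wide, c.cohort, mw)
    res = pp.hypertension_workflow(wide, c.cohort, mw, screen)
    classes = [cl for cl in res.overlap.index if cl != "none"]
    assert len(classes) == 3
    targets = {"C07AB": {"PROT0001", "PROT0002"}, "C09AA": {"PROT0004", "PROT0005"},
               "C08CA": {"PROT0007", "PROT0008"}}
    sig = {
        cl: set(sub.loc[sub["q_fdr"] < 0.05, "protein_id"])
        for cl, sub in res.comparisons.groupby("drug_class")
    }
    for cl in classes:
        assert targets[cl] <= sig[cl]
    # diagonal-dominant overlap: each class recovers its own targets, while
    # sharing (through co-users of two drug classes) stays smaller
    for a in classes:
        assert res.overlap.loc[a, a] >= 2
        for b in classes:
            if a != b:
                assert res.overlap.loc[a, b] <= res.overlap.loc[a, a]
    off = [res.overlap.loc[a, b] for a in classes for b in classes if a != b]
    assert np.mean(off) < 2.5
    assert len(res.centered_distributions)


def test_hypertension_workflow_empty_without_group():
    cohort, med = _mini_cohort([{} for _ in range(30)])
    mw = medication_wide(med, cohort["individual_id"])
    wide = pd.DataFrame(
        np.random.default_rng(0).normal(size=(30, 2)),
        index=cohort["individual_id"],
        columns=["P1", "P2"],
    )
    screen = pd.DataFrame(
        columns=["protein_id", "covariate", "significant", "significant_combined"]
    )
    res = pp.hypertension_workflow(wide, cohort, mw, screen)
    assert res.comparisons.empty
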