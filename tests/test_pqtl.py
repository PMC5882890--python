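"""Variant QC, rank-normal transform, association scans and two-stage logic."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy import stats
from scipy.special import comb

import plasmaprot as pp
from plasmaprot.io import npx_wide


def _dosage_frame(mat, chrom=None, pos=None):
    """individuals x variants array -> dosage table."""
    n, v = mat.shape
    chrom = chrom if chrom is not None else np.ones(v, dtype=int)
    pos = pos if pos is not None else np.arange(1, v + 1) * 1000
    meta = pd.DataFrame(
        {
            "variant_id": [f"v{j}" for j in range(v)],
            "chromosome": chrom,
            "position": pos,
            "ref": "A",
            "alt": "G",
        }
    )
    dos = pd.DataFrame(mat.T, columns=[f"I{i}" for i in range(n)])
    return pd.concat([meta, dos], axis=1)


# ---------------------------------------------------------------------------
# rank-inverse-normal transform

def test_rint_three_values():
    out = pp.rank_inverse_normal([5.0, 1.0, 3.0])
    expected = stats.norm.ppf([5 / 6, 1 / 6, 3 / 6])
    np.testing.assert_allclose(out, expected, atol=1e-12)
    assert out[0] == pytest.approx(0.9674, abs=1e-4)


def test_rint_invariant_to_monotone_transform(rng):
    x = rng.normal(size=50)
    for f in (np.exp, lambda v: 3 * v + 1, lambda v: v**3):
        np.testing.assert_allclose(
            pp.rank_inverse_normal(x), pp.rank_inverse_normal(f(x)), atol=1e-12
        )


def test_rint_normal_scores_moments(rng):
    out = pp.rank_inverse_normal(rng.normal(size=1000))
    assert abs(out.mean()) < 0.01
    assert 0.95 < out.std(ddof=1) < 1.05


def test_rint_rejects_constant_and_missing():
    with pytest.raises(ValueError):
        pp.rank_inverse_normal(np.ones(10))
    with pytest.raises(ValueError):
        pp.rank_inverse_normal([1.0, np.nan, 2.0])


# ---------------------------------------------------------------------------
# Hardy-Weinberg exact test

def _hwe_oracle(n_het, n_hom1, n_hom2):
    """Direct enumeration with binomial coefficients."""
    n = n_het + n_hom1 + n_hom2
    n_a = 2 * min(n_hom1, n_hom2) + n_het

    def prob(h):
        hr = (n_a - h) // 2
        hc = n - h - hr
        return (
            2**h
            * comb(n, h, exact=True)
            * comb(n - h, hr, exact=True)
            / comb(2 * n, n_a, exact=True)
            * comb(n_a, 0, exact=True)  # 1; keep integers exact
        )

    hs = range(n_a % 2, min(n_a, 2 * n - n_a) + 1, 2)
    probs = {h: prob(h) for h in hs}
    total = sum(probs.values())
    p_obs = probs[n_het]
    return sum(p for p in probs.values() if p <= p_obs * (1 + 1e-12)) / total


def test_hwe_exact_equilibrium_counts():
    p = pp.hwe_exact_test(50, 25, 25)
    assert p == pytest.approx(_hwe_oracle(50, 25, 25), rel=1e-10)
    assert p > 0.9


def test_hwe_exact_matches_enumeration_oracle(rng):
    for _ in range(25):
        n = int(rng.integers(10, 80))
        maf = rng.uniform(0.05, 0.5)
        g = rng.binomial(2, maf, size=n)
        counts = [(g == k).sum() for k in (0, 1, 2)]
        ours = pp.hwe_exact_test(counts[1], counts[0], counts[2])
        assert ours == pytest.approx(_hwe_oracle(counts[1], counts[0], counts[2]), rel=1e-9)


def test_hwe_detects_disequilibrium():
    # far too few heterozygotes
    assert pp.hwe_exact_test(0, 50, 50) < 1e-20


# ---------------------------------------------------------------------------
# variant QC

def test_monomorphic_variant_fails_maf():
    mat = np.zeros((100, 1))
    qc = pp.variant_qc(_dosage_frame(mat))
    assert not qc["passed"].iloc[0]
    assert "maf" in qc["reason"].iloc[0]


def test_singleton_passes_maf_floor():
    # one heterozygote: MAF = 1/(2n) is exactly the "one chromosome" floor
    mat = np.zeros((903, 1))
    mat[0, 0] = 1.0
    qc = pp.variant_qc(_dosage_frame(mat))
    assert qc["maf"].iloc[0] == pytest.approx(1 / 1806)
    assert bool(qc["passed"].iloc[0])


def test_uncertain_dosages_exempt_from_hwe(rng):
    mat = rng.uniform(0.3, 1.7, size=(50, 1))  # far from integers
    qc = pp.variant_qc(_dosage_frame(mat))
    assert bool(qc["hwe_exempt"].iloc[0]) and np.isnan(qc["hwe_p"].iloc[0])


def test_all_missing_variant_fails_with_reason():
    mat = np.full((20, 1), np.nan)
    qc = pp.variant_qc(_dosage_frame(mat))
    assert not qc["passed"].iloc[0] and qc["reason"].iloc[0] == "all_missing"


# ---------------------------------------------------------------------------
# residualization

def test_residualize_without_covariates_is_centered(rng):
    y = rng.normal(5, 1, 40)
    out = pp.residualize(y, None, rint=False)
    np.testing.assert_allclose(out, y - y.mean(), atol=1e-12)


def test_residualize_removes_injected_covariate(rng):
    n = 900
    x = rng.normal(size=n)
    y = 1.5 * x + rng.normal(size=n)
    resid = pp.residualize(y, x[:, None])
    assert abs(np.corrcoef(resid, x)[0, 1]) < 0.05


def test_residualize_degenerate_constant_flagged(rng):
    x = rng.normal(size=30)
    y = 2.0 * x  # fully explained -> residuals constant zero
    with pytest.raises(ValueError):
        pp.residualize(y, x[:, None])


# ---------------------------------------------------------------------------
# association scan

def test_scan_matches_statsmodels(rng):
    n, v = 80, 6
    D = rng.binomial(2, 0.3, size=(n, v)).astype(float)
    y = 0.4 * D[:, 2] + rng.normal(size=n)
    res = pp.association_scan(y, D, [f"v{j}" for j in range(v)])
    for j in range(v):
        ref = sm.OLS(y, sm.add_constant(D[:, j])).fit()
        row = res[res["variant_id"] == f"v{j}"].iloc[0]
        assert row["beta"] == pytest.approx(ref.params[1], rel=1e-9)
        assert row["se"] == pytest.approx(ref.bse[1], rel=1e-9)
        assert row["p"] == pytest.approx(ref.pvalues[1], rel=1e-7)


def test_scan_skips_zero_variance_dosage(rng):
    D = np.hstack([np.ones((30, 1)), rng.binomial(2, 0.4, (30, 1)).astype(float)])
    res = pp.association_scan(rng.normal(size=30), D, ["mono", "ok"])
    assert res["variant_id"].tolist() == ["ok"]


def test_scan_p_matches_permutation_oracle(rng):
    n = 12
    d = rng.binomial(2, 0.4, n).astype(float)
    y = rng.normal(size=n) + 0.8 * d
    p_model = pp.association_scan(y, d[:, None], ["v"]).loc[0, "p"]
    obs = abs(np.corrcoef(d, y)[0, 1])
    nperm = 20_000
    hits = sum(
        abs(np.corrcoef(d, rng.permutation(y))[0, 1]) >= obs - 1e-12 for _ in range(nperm)
    )
    p_perm = (hits + 1) / (nperm + 1)
    assert abs(p_model - p_perm) < 4 * np.sqrt(p_perm * (1 - p_perm) / nperm) + 2 / nperm


def test_injected_pqtl_power_at_genomewide_threshold(rng):
    # 10% variance explained at n=663: analytic power at p < 4.79e-9 exceeds 95%
    n, vf, alpha = 663, 0.10, 4.79e-9
    lam = n * vf / (1 - vf)
    crit = stats.f.isf(alpha, 1, n - 2)
    power = stats.ncf.sf(crit, 1, n - 2, lam)
    assert power > 0.95
    # and simulated scans at that threshold reach it
    hits = 0
    for _ in range(20):
        d = rng.binomial(2, 0.3, n).astype(float)
        beta = np.sqrt(vf / (1 - vf) / d.var())
        y = beta * d + rng.normal(size=n)
        res = pp.association_scan(pp.rank_inverse_normal(y), d[:, None], ["v"])
        hits += res.loc[0, "p"] < alpha
    assert hits >= 18


# ---------------------------------------------------------------------------
# two-stage selection

def _assoc(protein, variant, p, stage):
    return {
        "protein_id": protein, "variant_id": variant, "beta": 0.1, "se": 0.01,
        "p": p, "n": 100, "stage": stage,
    }


def test_replication_threshold_is_alpha_over_k():
    disc = pd.DataFrame([_assoc("P1", f"v{i}", 1e-10, "discovery") for i in range(10)])
    rep = pd.DataFrame(
        [_assoc("P1", f"v{i}", 0.004 if i == 0 else 0.006, "replication") for i in range(10)]
    )
    res = pp.two_stage_select(disc, rep, n_variants=1000)
    assert res.replicated["replication_threshold"].iloc[0] == pytest.approx(0.005)
    assert res.replicated["variant_id"].tolist() == ["v0"]  # 0.006 misses 0.05/10


def test_no_discovery_hits_gives_empty_replication():
    disc = pd.DataFrame([_assoc("P1", "v0", 0.5, "discovery")])
    rep = pd.DataFrame([_assoc("P1", "v0", 1e-9, "replication")])
    res = pp.two_stage_select(disc, rep, n_variants=100)
    assert res.replicated.empty and res.proteins_replicated == []


def test_true_pqtl_passes_both_stages(rng):
    n1, n2, v = 400, 200, 50
    D1 = rng.binomial(2, 0.3, (n1, v)).astype(float)
    D2 = rng.binomial(2, 0.3, (n2, v)).astype(float)
    beta = 0.8
    y1 = beta * D1[:, 7] + rng.normal(size=n1)
    y2 = beta * D2[:, 7] + rng.normal(size=n2)
    ids = [f"v{j}" for j in range(v)]
    disc = pp.association_scan(pp.rank_inverse_normal(y1), D1, ids, "discovery")
    rep = pp.association_scan(pp.rank_inverse_normal(y2), D2, ids, "replication")
    disc.insert(0, "protein_id", "P1")
    rep.insert(0, "protein_id", "P1")
    res = pp.two_stage_select(disc, rep, n_variants=v)
    assert "v7" in res.replicated["variant_id"].tolist()


# ---------------------------------------------------------------------------
# cis/trans annotation

def _annotate_one(pos, chrom=1, start=100_000, end=120_000):
    assoc = pd.DataFrame([{"protein_id": "P1", "variant_id": "v", "p": 1e-10}])
    gm = pd.DataFrame(
        [{"protein_id": "P1", "gene": "G", "chromosome": 1, "start": start, "end": end}]
    )
    vm = pd.DataFrame(
        [{"variant_id": "v", "chromosome": chrom, "position": pos, "ref": "A", "alt": "G"}]
    )
    return pp.annotate_cis_trans(assoc, gm, vm)["cis"].iloc[0]


@pytest.mark.parametrize(
    "pos, chrom, expected",
    [
        (110_000, 1, True),        # inside gene body
        (100_000 - 34_999, 1, True),   # 34,999 bp upstream: strict <35 kb
        (100_000 - 35_000, 1, False),  # exactly 35,000 bp: trans
        (120_000 + 34_999, 1, True),
        (120_000 + 35_000, 1, False),
        (110_000, 2, False),       # other chromosome
    ],
)
def test_cis_window_strict_boundary(pos, chrom, expected):
    assert bool(_annotate_one(pos, chrom)) is expected


def test_missing_genemap_entry_gives_null_flag():
    assoc = pd.DataFrame([{"protein_id": "PX", "variant_id": "v", "p": 1e-10}])
    gm = pd.DataFrame(columns=["protein_id", "gene", "chromosome", "start", "end"])
    vm = pd.DataFrame(
        [{"variant_id": "v", "chromosome": 1, "position": 5, "ref": "A", "alt": "G"}]
    )
    out = pp.annotate_cis_trans(assoc, gm, vm)
    assert out["cis"].isna().all()


# ---------------------------------------------------------------------------
# top-marker variance

def test_top_marker_variance_identities(rng):
    n = 900
    d = rng.binomial(2, 0.4, n).astype(float)
    y_null = rng.normal(size=n)
    assert pp.top_marker_variance(y_null, d) < 0.02
    y = 0.9 * d + rng.normal(size=n)
    r2 = pp.top_marker_variance(y, d)
    assert r2 == pytest.approx(np.corrcoef(y, d)[0, 1] ** 2, rel=1e-10)


def test_pipeline_recovers_injected_pqtls(demo):
    c = demo["cohort"]
    res = pp.pqtl_pipeline(
        demo["npx_wide"], c.cohort, c.dosage, c.genemap, demo["screen"],
        demo["medication_wide"],
    )
    truth = set(
        zip(c.truth.pqtl_effects["protein_id"], c.truth.pqtl_effects["variant_id"])
    )
    found = set(
        zip(res.two_stage.replicated["protein_id"], res.two_stage.replicated["variant_id"])
    )
    retained_truth = {t for t in truth if t[0] in demo["npx_wide"].columns}
    # most injected pQTLs replicate, and cis flags agree with the construction
    assert len(found & retained_truth) >= 0.6 * len(retained_truth)
    top = res.top_markers.merge(
        c.truth.pqtl_effects, on=["protein_id", "variant_id"], how="inner"
    )
    agree = (top["cis_x"].astype(bool) == top["cis_y"].astype(bool)).mean()
    assert agree > 0.9
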