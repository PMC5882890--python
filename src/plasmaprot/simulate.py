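"""Synthetic population cohort generator.

Emulates a two-phase population study in which plasma protein abundance
(NPX, a relative log-type unit from the proximity extension assay) is driven
additively by anthropometric/lifestyle/clinical covariates, sparse cis/trans
genetic effects on the dosage scale, binary medication use, plate-level batch
shifts, and Gaussian noise.  Medication use is drawn with a logistic model on
the covariates, so drug users differ systematically from non-users
(confounding), which is the premise of the transfer-adjustment analysis.

Every generated quantity is recorded in a :class:`SyntheticTruth` object so
downstream stages can be tested for parameter recovery and calibration.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit, logit

__all__ = [
    "ConfigurationError",
    "SimulationConfig",
    "MedicationSpec",
    "PqtlEffect",
    "SyntheticTruth",
    "SyntheticCohort",
    "generate_cohort",
    "generate_genotypes",
    "COVARIATE_COLUMNS",
    "PANELS",
]


class ConfigurationError(ValueError):
    """Inconsistent simulation configuration."""


#: Canonical numeric covariate design built from the cohort table, in order.
#: Effects are expressed per standard deviation of each (standardized) column.
COVARIATE_COLUMNS = (
    "sex_male",
    "age",
    "height",
    "weight",
    "smoking_current",
    "smoking_former",
    "traditional_lifestyle",
    "sbp",
    "dbp",
    "ldl",
    "hdl",
    "mi_history",
    "self_reported_hypertension",
)

PANELS = ("CVD2", "CVD3", "INF1", "NEU", "ONC2")

_N_CHROM = 22
_CHROM_LEN = 100_000_000
_PLATE_SIZE = 90


@dataclass(frozen=True)
class PqtlEffect:
    """A single protein quantitative trait locus to inject.

    Either ``beta`` (NPX per dosage unit) or ``variance_fraction`` (target
    fraction of the protein's non-genetic variance explained) must be given;
    with ``variance_fraction`` the dosage effect size is solved at generation
    time from the realized allele frequency.
    """

    protein: int
    variant: int
    beta: float | None = None
    variance_fraction: float | None = None
    cis: bool = True

    def __post_init__(self) -> None:
        if (self.beta is None) == (self.variance_fraction is None):
            raise ConfigurationError("give exactly one of beta / variance_fraction")


@dataclass(frozen=True)
class MedicationSpec:
    """One drug: its prevalence, protein effects and confounding structure.

    ``confounder_weights`` maps covariate names to logit-scale weights per SD
    of the covariate; an empty mapping gives unconfounded random use.
    """

    atc: str
    prevalence: float
    protein_effects: tuple[tuple[int, float], ...] = ()
    confounder_weights: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0 < self.prevalence < 1:
            raise ConfigurationError(f"prevalence must be in (0,1): {self.atc}")


@dataclass
class SimulationConfig:
    """Study-design parameters of a synthetic cohort.

    Defaults mirror the two-phase design the pipeline targets: a discovery
    subcohort of 663 and a replication subcohort of 240 individuals, 441
    assayed proteins of which 16 are low-abundance (under 20% of values above
    the limit of detection), 13 base covariates, and about a dozen drugs with
    at least 10 users each.  ``n_variants`` defaults to a 2000-variant panel;
    genome-wide thresholds always refer to the analysed panel size.
    """

    n_discovery: int = 663
    n_replication: int = 240
    n_proteins: int = 441
    n_variants: int = 2000
    n_covariates: int = len(COVARIATE_COLUMNS)
    covariate_effect_matrix: np.ndarray | None = None  # (n_covariates, n_proteins)
    pqtl_spec: Sequence[PqtlEffect] | None = None
    medication_spec: Sequence[MedicationSpec] | None = None
    lod_quantile: float = 0.03
    n_low_abundance: int = 16
    low_abundance_censored_fraction: float = 0.85
    batch_shift_sd: float = 0.20
    noise_sd: float = 1.0
    maf_range: tuple[float, float] = (0.05, 0.5)
    pqtl_protein_fraction: float = 0.30
    family_effect_sd: float = 0.0  # optional block-exchangeable relatedness
    family_size: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_discovery", "n_replication", "n_proteins", "n_variants", "n_covariates"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be > 0")
        if self.n_covariates > len(COVARIATE_COLUMNS):
            raise ConfigurationError(
                f"n_covariates <= {len(COVARIATE_COLUMNS)} (canonical covariate list)"
            )
        if self.noise_sd <= 0:
            raise ConfigurationError("noise_sd must be > 0")
        if not 0 <= self.lod_quantile < 1:
            raise ConfigurationError("lod_quantile must be in [0,1)")
        if not 0 < self.maf_range[0] <= self.maf_range[1] <= 0.5:
            raise ConfigurationError("maf_range must be within (0, 0.5]")
        if self.n_low_abundance >= self.n_proteins:
            raise ConfigurationError("n_low_abundance must be < n_proteins")
        if self.covariate_effect_matrix is not None:
            B = np.asarray(self.covariate_effect_matrix, dtype=float)
            if B.shape != (self.n_covariates, self.n_proteins):
                raise ConfigurationError(
                    f"covariate_effect_matrix shape {B.shape} != "
                    f"({self.n_covariates}, {self.n_proteins})"
                )
            self.covariate_effect_matrix = B
        if self.pqtl_spec is not None:
            for q in self.pqtl_spec:
                if not 0 <= q.variant < self.n_variants:
                    raise ConfigurationError(f"pqtl variant index {q.variant} out of range")
                if not 0 <= q.protein < self.n_proteins:
                    raise ConfigurationError(f"pqtl protein index {q.protein} out of range")
        if self.medication_spec is not None:
            for m in self.medication_spec:
                for idx, _ in m.protein_effects:
                    if not 0 <= idx < self.n_proteins:
                        raise ConfigurationError(
                            f"medication {m.atc}: protein index {idx} out of range"
                        )

    @property
    def n_total(self) -> int:
        return self.n_discovery + self.n_replication


@dataclass
class SyntheticTruth:
    """Ground truth of one generated cohort, for recovery/calibration tests."""

    covariate_effects: pd.DataFrame    # covariate x protein, NPX per SD
    pqtl_effects: pd.DataFrame         # protein_id, variant_id, beta, target vf, cis
    medication_deltas: pd.DataFrame    # atc, protein_id, delta
    variance_fractions: pd.DataFrame   # per protein realized component fractions

    def to_json(self, path) -> None:
        payload = {
            "covariate_effects": self.covariate_effects.to_dict(),
            "pqtl_effects": self.pqtl_effects.to_dict(orient="records"),
            "medication_deltas": self.medication_deltas.to_dict(orient="records"),
            "variance_fractions": self.variance_fractions.to_dict(),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


class SyntheticCohort(NamedTuple):
    cohort: pd.DataFrame       # per-individual covariates (data_io schema)
    medication: pd.DataFrame   # long: individual_id, atc_code, used
    npx: pd.DataFrame          # long: individual_id, protein_id, panel, plate, npx, below_lod, lod
    dosage: pd.DataFrame       # variant metadata + one column per individual
    genemap: pd.DataFrame      # protein_id, gene, chromosome, start, end
    truth: SyntheticTruth


# ---------------------------------------------------------------------------
# genotypes

def _draw_dosages(rng: np.random.Generator, n: int, mafs: np.ndarray) -> np.ndarray:
    """Hardy-Weinberg genotypes: dosage = Binomial(2, maf) per (individual, variant)."""
    return rng.binomial(2, mafs[None, :], size=(n, len(mafs))).astype(float)


def generate_genotypes(
    n: int,
    n_variants: int,
    maf_range: tuple[float, float] = (0.05, 0.5),
    seed: int = 0,
) -> pd.DataFrame:
    """Unlinked Hardy-Weinberg genotypes on a toy genome.

    Returns a variant-major table: ``variant_id, chromosome, position, ref,
    alt`` followed by one dosage column per individual (``I000001`` ...).
    Positions are sorted within chromosome.
    """
    lo, hi = maf_range
    if not 0 < lo <= hi <= 0.5:
        raise ConfigurationError("maf_range must be a non-empty interval within (0, 0.5]")
    rng = np.random.default_rng(seed)
    mafs = rng.uniform(lo, hi, size=n_variants)
    chrom = rng.integers(1, _N_CHROM + 1, size=n_variants)
    pos = rng.integers(1, _CHROM_LEN, size=n_variants)
    dosages = _draw_dosages(rng, n, mafs)
    ids = [f"I{i + 1:06d}" for i in range(n)]
    return _assemble_dosage_frame(chrom, pos, dosages, ids, rng)


def _assemble_dosage_frame(chrom, pos, dosages, individual_ids, rng) -> pd.DataFrame:
    n_variants = len(chrom)
    bases = np.array(list("ACGT"))
    ref = bases[rng.integers(0, 4, size=n_variants)]
    alt = bases[(np.char.find("ACGT", ref) + rng.integers(1, 4, size=n_variants)) % 4]
    df = pd.DataFrame(
        {
            "variant_id": [f"var_{c}_{p}_{i}" for i, (c, p) in enumerate(zip(chrom, pos))],
            "chromosome": chrom.astype(int),
            "position": pos.astype(int),
            "ref": ref,
            "alt": alt,
        }
    )
    dos = pd.DataFrame(dosages.T, columns=individual_ids)
    df = pd.concat([df, dos], axis=1)
    df = df.sort_values(["chromosome", "position"], kind="mergesort").reset_index(drop=True)
    return df


# ---------------------------------------------------------------------------
# cohort table

def _draw_cohort_table(rng: np.random.Generator, cfg: SimulationConfig) -> pd.DataFrame:
    n = cfg.n_total
    sex_male = rng.random(n) < 0.5
    age = np.clip(rng.normal(50, 17, n), 18, 95)
    height = np.where(sex_male, rng.normal(177, 7, n), rng.normal(164, 6.5, n))
    bmi = np.clip(rng.normal(26.5, 4.0, n), 16, None)
    weight = bmi * (height / 100.0) ** 2
    smoking = rng.choice(["never", "former", "current"], size=n, p=[0.55, 0.25, 0.20])
    tls = rng.random(n) < 0.30
    sbp = rng.normal(112 + 0.5 * age, 14)
    dbp = 0.45 * sbp + rng.normal(12, 6, n)
    dbp = np.minimum(dbp, sbp - 5.0)
    ldl = np.clip(rng.normal(3.3 + 0.012 * age, 0.9), 0.5, None)
    hdl = np.clip(rng.normal(1.55, 0.40, n), 0.4, None)
    mi = rng.random(n) < expit(-6.0 + 0.06 * age)
    srh = rng.random(n) < expit(-5.5 + 0.045 * age + 0.02 * (sbp - 130))
    subcohort = np.array(
        ["discovery"] * cfg.n_discovery + ["replication"] * cfg.n_replication
    )
    sampling_round = np.where(subcohort == "discovery", 2006, 2009)
    return pd.DataFrame(
        {
            "individual_id": [f"I{i + 1:06d}" for i in range(n)],
            "sex": np.where(sex_male, "male", "female"),
            "age": np.round(age, 1),
            "height": np.round(height, 1),
            "weight": np.round(weight, 1),
            "smoking": smoking,
            "traditional_lifestyle": tls,
            "sampling_round": sampling_round.astype(int),
            "sbp": np.round(sbp, 1),
            "dbp": np.round(dbp, 1),
            "ldl": np.round(ldl, 2),
            "hdl": np.round(hdl, 2),
            "mi_history": mi,
            "self_reported_hypertension": srh,
            "subcohort": subcohort,
        }
    )


def covariate_design(cohort: pd.DataFrame, standardize: bool = True) -> pd.DataFrame:
    """Numeric design in the canonical covariate order (used by the generator)."""
    Z = pd.DataFrame(index=cohort.index)
    Z["sex_male"] = (cohort["sex"] == "male").astype(float)
    for col in ("age", "height", "weight"):
        Z[col] = cohort[col].astype(float)
    Z["smoking_current"] = (cohort["smoking"] == "current").astype(float)
    Z["smoking_former"] = (cohort["smoking"] == "former").astype(float)
    Z["traditional_lifestyle"] = cohort["traditional_lifestyle"].astype(float)
    for col in ("sbp", "dbp", "ldl", "hdl"):
        Z[col] = cohort[col].astype(float)
    Z["mi_history"] = cohort["mi_history"].astype(float)
    Z["self_reported_hypertension"] = cohort["self_reported_hypertension"].astype(float)
    if standardize:
        sd = Z.std(ddof=0).replace(0.0, 1.0)
        Z = (Z - Z.mean()) / sd
    return Z[list(COVARIATE_COLUMNS)]


# ---------------------------------------------------------------------------
# default effect structures

def _default_effect_matrix(rng, cfg: SimulationConfig) -> np.ndarray:
    """Sparse covariate effects whose combined R2 spans roughly 0.12-0.67."""
    B = np.zeros((cfg.n_covariates, cfg.n_proteins))
    sigma_rest2 = cfg.noise_sd**2 + cfg.batch_shift_sd**2
    target_r2 = rng.uniform(0.123, 0.669, size=cfg.n_proteins)
    for j in range(cfg.n_proteins):
        k = int(rng.integers(2, min(7, cfg.n_covariates + 1)))
        idx = rng.choice(cfg.n_covariates, size=k, replace=False)
        w = rng.normal(size=k)
        total = target_r2[j] / (1.0 - target_r2[j]) * sigma_rest2
        w *= np.sqrt(total / np.sum(w**2))
        B[idx, j] = w
    return B


def _default_pqtl_spec(rng, cfg: SimulationConfig) -> list[PqtlEffect]:
    n_hit = int(round(cfg.pqtl_protein_fraction * cfg.n_proteins))
    eligible = np.arange(cfg.n_proteins - cfg.n_low_abundance)
    n_hit = min(n_hit, len(eligible), cfg.n_variants)
    proteins = rng.choice(eligible, size=n_hit, replace=False)
    variants = rng.choice(cfg.n_variants, size=n_hit, replace=False)
    out = []
    for p, v in zip(proteins, variants):
        vf = float(rng.uniform(0.10, 0.60))
        out.append(PqtlEffect(int(p), int(v), variance_fraction=vf, cis=rng.random() < 0.8))
    return out


_DEFAULT_DRUGS: tuple[tuple[str, float, int, float, dict[str, float]], ...] = (
    # atc, prevalence, n affected proteins, delta scale, confounder weights
    ("C10AA01", 0.076, 8, 0.35, {"age": 0.8, "ldl": 0.5, "mi_history": 0.6}),
    ("C10AA05", 0.020, 8, 0.35, {"age": 0.8, "ldl": 0.5, "mi_history": 0.6}),
    ("B01AC06", 0.136, 10, 0.45, {"age": 0.9, "mi_history": 0.8}),
    ("C07AB02", 0.060, 5, 0.40, {"age": 0.7, "sbp": 0.5}),
    ("C08CA01", 0.045, 5, 0.40, {"age": 0.6, "sbp": 0.5}),
    ("C09AA02", 0.050, 5, 0.40, {"age": 0.6, "sbp": 0.6}),
    ("C03CA01", 0.055, 25, 0.30, {"age": 0.8}),
    ("A10AB01", 0.022, 3, 0.50, {"weight": 0.5, "age": 0.4}),
    ("A02BC01", 0.050, 2, 0.35, {"age": 0.3}),
    ("N02BE01", 0.060, 2, 0.30, {}),
    ("L04AX03", 0.014, 1, 0.60, {}),
    ("C09CA01", 0.025, 4, 0.40, {"age": 0.5, "sbp": 0.5}),
    ("H03AA01", 0.040, 3, 0.40, {"sex_male": -0.8, "age": 0.4}),
)


def _default_medication_spec(rng, cfg: SimulationConfig) -> list[MedicationSpec]:
    specs: list[MedicationSpec] = []
    eligible = cfg.n_proteins - cfg.n_low_abundance
    statin_targets: tuple[tuple[int, float], ...] | None = None
    for atc, prev, n_aff, scale, conf in _DEFAULT_DRUGS:
        n_aff = min(n_aff, eligible)
        idx = rng.choice(eligible, size=n_aff, replace=False)
        if atc.startswith("C10AA"):
            # statin substances share one class-level effect profile (all
            # positive), so substance groups are poolable by construction
            if statin_targets is None:
                deltas = rng.uniform(0.15, scale + 0.15, size=n_aff)
                statin_targets = tuple((int(i), float(d)) for i, d in zip(idx, deltas))
            effects = statin_targets
        else:
            deltas = rng.uniform(0.2, scale + 0.4, size=n_aff) * rng.choice([-1, 1], size=n_aff)
            effects = tuple((int(i), float(d)) for i, d in zip(idx, deltas))
        conf = {k: v for k, v in conf.items() if k in COVARIATE_COLUMNS[: cfg.n_covariates]}
        specs.append(MedicationSpec(atc, prev, effects, conf))
    return specs


# ---------------------------------------------------------------------------
# main generator

def generate_cohort(config: SimulationConfig) -> SyntheticCohort:
    """Generate one synthetic cohort with full ground truth.

    NPX is assembled as ``intercept + Z@B + D@G + M@deltas + plate shift +
    (family effect) + noise``; the per-protein limit of detection is placed
    at ``lod_quantile`` of the protein's marginal distribution (higher for
    the constructed low-abundance proteins) and values below it are flagged
    censored.  All randomness derives from ``config.seed``.
    """
    cfg = config
    ss = np.random.SeedSequence(cfg.seed)
    (r_cohort, r_geno, r_effects, r_med, r_npx) = [
        np.random.default_rng(s) for s in ss.spawn(5)
    ]
    n = cfg.n_total

    cohort = _draw_cohort_table(r_cohort, cfg)
    ids = cohort["individual_id"].tolist()
    Z = covariate_design(cohort).to_numpy()[:, : cfg.n_covariates]

    B = cfg.covariate_effect_matrix
    if B is None:
        B = _default_effect_matrix(r_effects, cfg)

    protein_ids = [f"PROT{j + 1:04d}" for j in range(cfg.n_proteins)]
    genemap = _build_genemap(protein_ids)

    pqtl_spec = list(cfg.pqtl_spec) if cfg.pqtl_spec is not None else _default_pqtl_spec(
        r_effects, cfg
    )
    mafs = r_geno.uniform(cfg.maf_range[0], cfg.maf_range[1], size=cfg.n_variants)
    chrom = r_geno.integers(1, _N_CHROM + 1, size=cfg.n_variants)
    pos = r_geno.integers(1, _CHROM_LEN, size=cfg.n_variants)
    # place pQTL variants relative to the target protein's gene
    for q in pqtl_spec:
        g = genemap.iloc[q.protein]
        if q.cis:
            chrom[q.variant] = g["chromosome"]
            pos[q.variant] = int(r_geno.integers(g["start"], g["end"] + 1))
        else:
            chrom[q.variant] = 1 + (int(g["chromosome"]) % _N_CHROM)
            pos[q.variant] = int(r_geno.integers(1, _CHROM_LEN))
    dosages = _draw_dosages(r_geno, n, mafs)  # (n, n_variants), original order
    dosage_df = _assemble_dosage_frame(chrom, pos, dosages, ids, r_geno)
    # map original variant index -> variant_id after sorting
    order_ids = [None] * cfg.n_variants
    for vid in dosage_df["variant_id"]:
        order_ids[int(vid.rsplit("_", 1)[1])] = vid

    med_spec = (
        list(cfg.medication_spec)
        if cfg.medication_spec is not None
        else _default_medication_spec(r_effects, cfg)
    )
    med_wide, med_long = _draw_medication(r_med, cfg, Z, med_spec, ids)

    # component assembly -----------------------------------------------------
    sigma_rest2 = cfg.noise_sd**2 + cfg.batch_shift_sd**2
    G = np.zeros((cfg.n_variants, cfg.n_proteins))
    pqtl_rows = []
    for q in pqtl_spec:
        if q.beta is not None:
            beta = q.beta
            vf = None
        else:
            vf = q.variance_fraction
            covar_var = float(np.var(Z @ B[:, q.protein]))
            var_d = 2.0 * mafs[q.variant] * (1.0 - mafs[q.variant])
            beta = float(np.sqrt(vf / (1.0 - vf) * (sigma_rest2 + covar_var) / var_d))
        G[q.variant, q.protein] += beta
        pqtl_rows.append(
            {
                "protein_id": protein_ids[q.protein],
                "variant_id": order_ids[q.variant],
                "beta": beta,
                "variance_fraction_target": vf,
                "cis": q.cis,
            }
        )

    med_delta_mat = np.zeros((len(med_spec), cfg.n_proteins))
    med_rows = []
    for k, m in enumerate(med_spec):
        for idx, delta in m.protein_effects:
            med_delta_mat[k, idx] += delta
            med_rows.append({"atc_code": m.atc, "protein_id": protein_ids[idx], "delta": delta})

    intercepts = r_npx.normal(5.0, 1.0, size=cfg.n_proteins)
    comp_cov = Z @ B
    comp_gen = dosages @ G
    comp_med = med_wide.to_numpy(dtype=float) @ med_delta_mat if med_spec else np.zeros((n, cfg.n_proteins))

    plates = _assign_plates(cohort)
    plate_levels = pd.unique(plates)
    shift = r_npx.normal(0.0, cfg.batch_shift_sd, size=(len(plate_levels), cfg.n_proteins))
    plate_idx = pd.Categorical(plates, categories=plate_levels).codes
    comp_batch = shift[plate_idx, :]

    if cfg.family_effect_sd > 0:
        fam = np.arange(n) // cfg.family_size
        fam_eff = r_npx.normal(0.0, cfg.family_effect_sd, size=(fam.max() + 1, cfg.n_proteins))
        comp_fam = fam_eff[fam, :]
    else:
        comp_fam = np.zeros((n, cfg.n_proteins))

    comp_noise = r_npx.normal(0.0, cfg.noise_sd, size=(n, cfg.n_proteins))
    npx_mat = intercepts[None, :] + comp_cov + comp_gen + comp_med + comp_batch + comp_fam + comp_noise

    # LOD ------------------------------------------------------------------
    lod_q = np.full(cfg.n_proteins, cfg.lod_quantile)
    if cfg.n_low_abundance:
        lod_q[cfg.n_proteins - cfg.n_low_abundance :] = cfg.low_abundance_censored_fraction
    lod = np.array([np.quantile(npx_mat[:, j], lod_q[j]) for j in range(cfg.n_proteins)])
    below = npx_mat < lod[None, :]

    panels = np.array([PANELS[j % len(PANELS)] for j in range(cfg.n_proteins)])
    npx_long = pd.DataFrame(
        {
            "individual_id": np.repeat(ids, cfg.n_proteins),
            "protein_id": np.tile(protein_ids, n),
            "panel": np.tile(panels, n),
            "plate": np.repeat(plates, cfg.n_proteins),
            "npx": np.round(npx_mat.ravel(), 6),
            "below_lod": below.ravel(),
            "lod": np.round(np.tile(lod, n), 6),
        }
    )

    truth = SyntheticTruth(
        covariate_effects=pd.DataFrame(
            B, index=list(COVARIATE_COLUMNS[: cfg.n_covariates]), columns=protein_ids
        ),
        pqtl_effects=pd.DataFrame(
            pqtl_rows,
            columns=["protein_id", "variant_id", "beta", "variance_fraction_target", "cis"],
        ),
        medication_deltas=pd.DataFrame(med_rows, columns=["atc_code", "protein_id", "delta"]),
        variance_fractions=_variance_fractions(
            protein_ids,
            covariates=comp_cov,
            genetic=comp_gen,
            medication=comp_med,
            batch=comp_batch,
            family=comp_fam,
            noise=comp_noise,
        ),
    )
    return SyntheticCohort(cohort, med_long, npx_long, dosage_df, genemap, truth)


def _build_genemap(protein_ids: list[str]) -> pd.DataFrame:
    rows = []
    for j, pid in enumerate(protein_ids):
        chrom = 1 + (j % _N_CHROM)
        start = 1_000_000 + (j // _N_CHROM) * 2_000_000
        rows.append(
            {
                "protein_id": pid,
                "gene": f"GENE{j + 1:04d}",
                "chromosome": chrom,
                "start": start,
                "end": start + 20_000,
            }
        )
    return pd.DataFrame(rows)


def _assign_plates(cohort: pd.DataFrame) -> np.ndarray:
    plates = np.empty(len(cohort), dtype=object)
    for rnd in sorted(cohort["sampling_round"].unique()):
        mask = (cohort["sampling_round"] == rnd).to_numpy()
        k = np.arange(mask.sum()) // _PLATE_SIZE
        plates[mask] = [f"{rnd}_P{i + 1:02d}" for i in k]
    return plates


def _draw_medication(rng, cfg, Z, med_spec, ids):
    cols = {}
    cov_index = {name: i for i, name in enumerate(COVARIATE_COLUMNS[: cfg.n_covariates])}
    for m in med_spec:
        eta = np.zeros(len(ids))
        for name, w in m.confounder_weights.items():
            if name not in cov_index:
                raise ConfigurationError(
                    f"medication {m.atc}: unknown confounder covariate '{name}'"
                )
            eta = eta + w * Z[:, cov_index[name]]
        # calibrate the intercept so the expected use fraction equals the
        # stated prevalence despite the nonlinear (logistic) link
        lo, hi = logit(m.prevalence) - 6.0, logit(m.prevalence) + 6.0
        for _ in range(60):
            mid = 0.5 * (lo + hi)
            if expit(mid + eta).mean() < m.prevalence:
                lo = mid
            else:
                hi = mid
        cols[m.atc] = rng.random(len(ids)) < expit(0.5 * (lo + hi) + eta)
    med_wide = pd.DataFrame(cols, index=ids, dtype=bool)
    if med_spec:
        med_long = (
            med_wide.rename_axis("individual_id")
            .reset_index()
            .melt(id_vars="individual_id", var_name="atc_code", value_name="used")
            .sort_values(["individual_id", "atc_code"], kind="mergesort")
            .reset_index(drop=True)
        )
    else:
        med_long = pd.DataFrame(columns=["individual_id", "atc_code", "used"])
    return med_wide, med_long


def _variance_fractions(protein_ids, **components) -> pd.DataFrame:
    total = sum(np.var(c, axis=0) for c in components.values())
    total = np.where(total <= 0, 1.0, total)
    data = {name: np.var(c, axis=0) / total for name, c in components.items()}
    return pd.DataFrame(data, index=protein_ids)
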