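"""Tab-separated readers/writers for all pipeline tables, with validation.

Native format is UTF-8 TSV with a fixed header.  Coordinates are 1-based
inclusive.  Floats are serialized with 17 significant digits so that
round-tripping preserves values (p-values re-read equal to >=15 significant
digits).  An optional VCF dialect maps DS (preferred) or GT fields to
dosages.
"""

from __future__ import annotations

import re
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "SchemaError",
    "read_cohort",
    "read_medication",
    "read_npx",
    "read_dosage",
    "read_genemap",
    "read_dosage_vcf",
    "read_table",
    "write_table",
    "write_results",
    "npx_wide",
    "medication_wide",
    "dosage_values",
]

FLOAT_FORMAT = "%.17g"

COHORT_COLUMNS = [
    "individual_id", "sex", "age", "height", "weight", "smoking",
    "traditional_lifestyle", "sampling_round", "sbp", "dbp", "ldl", "hdl",
    "mi_history", "self_reported_hypertension", "subcohort",
]
MEDICATION_COLUMNS = ["individual_id", "atc_code", "used"]
NPX_COLUMNS = ["individual_id", "protein_id", "panel", "plate", "npx", "below_lod", "lod"]
DOSAGE_META_COLUMNS = ["variant_id", "chromosome", "position", "ref", "alt"]
GENEMAP_COLUMNS = ["protein_id", "gene", "chromosome", "start", "end"]

# ATC code, hierarchical levels 1-5: A, A10, A10B, A10BA, A10BA02
_ATC_RE = re.compile(r"^[A-Z](\d{2}([A-Z]([A-Z](\d{2})?)?)?)?$")


class SchemaError(ValueError):
    """Input table violates its schema; message carries 1-based row numbers."""


def _check_header(df: pd.DataFrame, required: list[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required columns {missing}")


def _read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype=str, keep_default_na=True)


def _to_bool(s: pd.Series, path, col) -> pd.Series:
    mapping = {"true": True, "false": False, "1": True, "0": False}
    out = s.astype(str).str.strip().str.lower().map(mapping)
    bad = out.isna() & s.notna()
    if bad.any():
        rows = (np.flatnonzero(bad) + 2).tolist()
        raise SchemaError(f"{path}: column '{col}' not boolean at rows {rows[:20]}")
    return out


def read_cohort(path: str | Path) -> pd.DataFrame:
    df = _read_tsv(path)
    _check_header(df, COHORT_COLUMNS[:-1], path)  # subcohort optional
    dup = df["individual_id"].duplicated()
    if dup.any():
        rows = (np.flatnonzero(dup) + 2).tolist()
        raise SchemaError(f"{path}: duplicate individual_id at rows {rows[:20]}")
    out = df.copy()
    for col in ("age", "height", "weight", "sbp", "dbp", "ldl", "hdl"):
        out[col] = pd.to_numeric(out[col], errors="coerce")
    out["sampling_round"] = pd.to_numeric(out["sampling_round"], errors="coerce").astype("Int64")
    for col in ("traditional_lifestyle", "mi_history", "self_reported_hypertension"):
        out[col] = _to_bool(out[col], path, col)
    both = out["sbp"].notna() & out["dbp"].notna()
    inverted = both & (out["sbp"] <= out["dbp"])
    if inverted.any():
        rows = (np.flatnonzero(inverted) + 2).tolist()
        warnings.warn(f"{path}: SBP <= DBP at rows {rows[:20]}", stacklevel=2)
    if "subcohort" not in out.columns:
        out["subcohort"] = pd.NA
    return out[COHORT_COLUMNS]


def read_medication(path: str | Path) -> pd.DataFrame:
    df = _read_tsv(path)
    _check_header(df, MEDICATION_COLUMNS, path)
    bad_atc = ~df["atc_code"].astype(str).str.match(_ATC_RE)
    if bad_atc.any():
        rows = (np.flatnonzero(bad_atc) + 2).tolist()
        warnings.warn(
            f"{path}: {bad_atc.sum()} rows with invalid ATC codes skipped "
            f"(rows {rows[:20]})",
            stacklevel=2,
        )
        df = df[~bad_atc].reset_index(drop=True)
    out = df[MEDICATION_COLUMNS].copy()
    out["used"] = _to_bool(out["used"], path, "used")
    return out


def read_npx(path: str | Path) -> pd.DataFrame:
    df = _read_tsv(path)
    _check_header(df, NPX_COLUMNS, path)
    out = df[NPX_COLUMNS].copy()
    out["npx"] = pd.to_numeric(out["npx"], errors="coerce")
    out["lod"] = pd.to_numeric(out["lod"], errors="coerce")
    out["below_lod"] = _to_bool(out["below_lod"], path, "below_lod")
    dup = out.duplicated(subset=["individual_id", "protein_id", "panel"])
    if dup.any():
        rows = (np.flatnonzero(dup) + 2).tolist()
        raise SchemaError(
            f"{path}: duplicate (individual, protein, panel) records at rows {rows[:20]}"
        )
    # a missing NPX value is only legal for censored records
    bad = out["npx"].isna() & ~out["below_lod"].fillna(False).astype(bool)
    if bad.any():
        rows = (np.flatnonzero(bad) + 2).tolist()
        raise SchemaError(f"{path}: npx missing without below_lod flag at rows {rows[:20]}")
    return out


def read_dosage(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    _check_header(df, DOSAGE_META_COLUMNS, path)
    sample_cols = [c for c in df.columns if c not in DOSAGE_META_COLUMNS]
    if not sample_cols:
        raise SchemaError(f"{path}: no individual dosage columns")
    vals = df[sample_cols].to_numpy(dtype=float)
    bad = (vals < 0) | (vals > 2)
    if np.any(bad):
        rows = sorted(set((np.nonzero(bad.any(axis=1))[0] + 2).tolist()))
        raise SchemaError(f"{path}: dosage outside [0,2] at rows {rows[:20]}")
    dup = df["variant_id"].duplicated()
    if dup.any():
        rows = (np.flatnonzero(dup) + 2).tolist()
        raise SchemaError(f"{path}: duplicate variant_id at rows {rows[:20]}")
    df = df.sort_values(["chromosome", "position"], kind="mergesort").reset_index(drop=True)
    return df


def read_genemap(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    _check_header(df, GENEMAP_COLUMNS, path)
    bad = df["start"] > df["end"]
    if bad.any():
        rows = (np.flatnonzero(bad) + 2).tolist()
        raise SchemaError(f"{path}: gene start > end at rows {rows[:20]}")
    return df[GENEMAP_COLUMNS]


def read_dosage_vcf(path: str | Path) -> pd.DataFrame:
    """Read dosages from a VCF: FORMAT/DS preferred, else GT allele counts."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    rows, dosages = [], []
    for var in vcf:
        try:
            ds = var.format("DS")
        except KeyError:
            ds = None
        if ds is not None:
            d = np.asarray(ds, dtype=float).reshape(len(samples))
        else:
            gt = np.asarray(var.genotype.array())[:, :2]
            d = np.where((gt < 0).any(axis=1), np.nan, (gt > 0).sum(axis=1)).astype(float)
        rows.append(
            {
                "variant_id": var.ID or f"{var.CHROM}_{var.POS}",
                "chromosome": var.CHROM,
                "position": var.POS,
                "ref": var.REF,
                "alt": var.ALT[0] if var.ALT else ".",
            }
        )
        dosages.append(d)
    meta = pd.DataFrame(rows, columns=DOSAGE_META_COLUMNS)
    dos = pd.DataFrame(np.asarray(dosages), columns=samples)
    return pd.concat([meta, dos], axis=1)


# ---------------------------------------------------------------------------
# writing

def write_table(df: pd.DataFrame, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT)


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_results(tables: dict[str, pd.DataFrame], out_dir: str | Path) -> list[Path]:
    """Write each named result table to ``<out_dir>/<name>.tsv``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for name, df in tables.items():
        p = out_dir / f"{name}.tsv"
        write_table(df, p)
        paths.append(p)
    return paths


# ---------------------------------------------------------------------------
# in-memory shape converters

def npx_wide(npx: pd.DataFrame, drop_censored: bool = True) -> pd.DataFrame:
    """Long NPX records -> individuals x proteins matrix (NaN where absent)."""
    df = npx
    if drop_censored:
        df = df[~df["below_lod"].astype(bool)]
    return df.pivot_table(index="individual_id", columns="protein_id", values="npx", aggfunc="mean")


def medication_wide(medication: pd.DataFrame, individuals: pd.Index | list | None = None) -> pd.DataFrame:
    """Long medication records -> individuals x ATC boolean matrix."""
    if len(medication) == 0:
        idx = pd.Index(individuals if individuals is not None else [], name="individual_id")
        wide = pd.DataFrame(index=idx)
    else:
        wide = (
            medication.assign(used=medication["used"].astype(bool))
            .pivot_table(index="individual_id", columns="atc_code", values="used", aggfunc="any")
            .astype("boolean")
            .fillna(False)
        )
    if individuals is not None:
        wide = wide.reindex(pd.Index(individuals), fill_value=False)
    return wide.astype(bool)


def dosage_values(dosage: pd.DataFrame) -> tuple[pd.DataFrame, np.ndarray, list[str]]:
    """Split a dosage table into (variant metadata, individuals x variants array, ids)."""
    sample_cols = [c for c in dosage.columns if c not in DOSAGE_META_COLUMNS]
    meta = dosage[DOSAGE_META_COLUMNS].copy()
    mat = dosage[sample_cols].to_numpy(dtype=float).T  # individuals x variants
    return meta, mat, sample_cols
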