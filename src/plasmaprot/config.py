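"""Analysis thresholds and settings shared across pipeline stages."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

# ATC classes with antihypertensive action used by the stratified workflows.
# The list is configuration, not a fixed fact of the method.
DEFAULT_ANTIHYPERTENSIVE_ATC: tuple[str, ...] = (
    "C03CA",  # sulfonamide diuretics
    "C07AB",  # beta blocking agents, selective
    "C08CA",  # dihydropyridine calcium channel blockers
    "C09AA",  # ACE inhibitors, plain
    "C09CA",  # angiotensin II receptor blockers, plain
)


@dataclass
class AnalysisConfig:
    """Thresholds governing every pipeline stage.

    alpha
        Base significance level for all Bonferroni / FDR procedures.
    lod_min_fraction
        Minimum fraction of measurements above the limit of detection a
        protein needs to be retained (strict-less removal below this).
    cis_window_bp
        Maximum distance (strict <) from the gene body for a variant to be
        called cis to the encoding gene.
    min_users
        Minimum number of medication users for a drug to enter any scan.
    min_nonusers
        Minimum number of non-users required to train a transfer model.
    hwe_alpha
        Base level for the Bonferroni-corrected Hardy-Weinberg filter.
    per_protein_replication_k
        If True, the replication threshold 0.05/k uses k = that protein's
        discovery hits; if False, k is the global discovery hit count.
    bp_rule
        "and": hypertension blood-pressure criterion requires SBP>140 and
        DBP>90; "or": either suffices.
    """

    alpha: float = 0.05
    lod_min_fraction: float = 0.20
    cis_window_bp: int = 35_000
    min_users: int = 10
    min_nonusers: int = 30
    hwe_alpha: float = 0.05
    per_protein_replication_k: bool = True
    bp_rule: str = "and"
    sbp_threshold: float = 140.0
    dbp_threshold: float = 90.0
    antihypertensive_atc: tuple[str, ...] = DEFAULT_ANTIHYPERTENSIVE_ATC
    lipid_lowering_prefix: str = "C10"
    statin_prefix: str = "C10AA"
    fdr_family: str = "per_drug"  # or "global"

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError(f"alpha must be in (0,1), got {self.alpha}")
        if not 0 <= self.lod_min_fraction < 1:
            raise ValueError("lod_min_fraction must be in [0,1)")
        if self.bp_rule not in ("and", "or"):
            raise ValueError("bp_rule must be 'and' or 'or'")
        self.antihypertensive_atc = tuple(self.antihypertensive_atc)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        d["antihypertensive_atc"] = list(self.antihypertensive_atc)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)
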