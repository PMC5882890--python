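"""Pipeline summary: stage counts with full provenance.

The summary is a pure function of the result tables — identical inputs give
an identical report.  Percentages are rounded to one decimal at output only;
counts are never rounded.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import pandas as pd

from . import __version__
from .config import AnalysisConfig

__all__ = ["PipelineSummary", "summarize"]


@dataclass
class PipelineSummary:
    proteins_tested: int = 0
    proteins_retained: int = 0
    covariate_pairs_nominal: int = 0
    covariate_pairs_bonferroni: int = 0
    proteins_with_nominal_covariate: int = 0
    proteins_with_bonferroni_covariate: int = 0
    proteins_pqtl_discovery: int = 0
    proteins_pqtl_replicated: int = 0
    pct_cis_of_top_markers: float | None = None
    drug_hits: pd.DataFrame = field(default_factory=pd.DataFrame)
    hits_before_total: int = 0
    hits_after_total: int = 0
    pct_reduction: float | None = None
    thresholds: dict = field(default_factory=dict)
    seed: int | None = None
    version: str = __version__
    gaps: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["drug_hits"] = self.drug_hits.to_dict(orient="records")
        return d

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1, default=str)

    def to_markdown(self) -> str:
        lines = [
            "# Pipeline summary",
            "",
            f"- proteins tested / retained: {self.proteins_tested} / {self.proteins_retained}",
            f"- (protein, covariate) associations nominal / Bonferroni: "
            f"{self.covariate_pairs_nominal} / {self.covariate_pairs_bonferroni}",
            f"- proteins with >=1 nominal / Bonferroni covariate: "
            f"{self.proteins_with_nominal_covariate} / {self.proteins_with_bonferroni_covariate}",
            f"- proteins with pQTL: discovery {self.proteins_pqtl_discovery}, "
            f"replicated {self.proteins_pqtl_replicated}",
        ]
        if self.pct_cis_of_top_markers is not None:
            lines.append(f"- top markers in cis: {self.pct_cis_of_top_markers:.1f}%")
        lines.append(
            f"- medication hits before / after adjustment: "
            f"{self.hits_before_total} / {self.hits_after_total}"
            + (f" ({self.pct_reduction:.0f}% reduction)" if self.pct_reduction is not None else "")
        )
        if len(self.drug_hits):
            lines += ["", "| drug | before | after |", "|---|---|---|"]
            for _, r in self.drug_hits.iterrows():
                lines.append(f"| {r['atc_code']} | {r['before']} | {r['after']} |")
        if self.gaps:
            lines += ["", f"Missing stages: {', '.join(self.gaps)}"]
        return "\n".join(lines)


def summarize(
    qc_report=None,
    screen: pd.DataFrame | None = None,
    pqtl_result=None,
    raw_scan: pd.DataFrame | None = None,
    adjusted_scan: pd.DataFrame | None = None,
    config: AnalysisConfig | None = None,
    seed: int | None = None,
) -> PipelineSummary:
    """Aggregate the result tables of completed stages; stages not supplied
    are reported as explicit gaps."""
    config = config or AnalysisConfig()
    s = PipelineSummary(seed=seed)
    s.thresholds = {
        "alpha": config.alpha,
        "lod_min_fraction": config.lod_min_fraction,
        "cis_window_bp": config.cis_window_bp,
        "min_users": config.min_users,
        "min_nonusers": config.min_nonusers,
    }
    if qc_report is not None:
        s.proteins_tested = qc_report.proteins_in
        s.proteins_retained = qc_report.proteins_retained
    else:
        s.gaps.append("qc")
    if screen is not None and len(screen):
        nominal = screen["p_single"] < config.alpha
        s.covariate_pairs_nominal = int(nominal.sum())
        s.covariate_pairs_bonferroni = int(screen["significant"].sum())
        s.proteins_with_nominal_covariate = int(
            screen.loc[nominal, "protein_id"].nunique()
        )
        s.proteins_with_bonferroni_covariate = int(
            screen.loc[screen["significant"], "protein_id"].nunique()
        )
    else:
        s.gaps.append("covariates")
    if pqtl_result is not None:
        s.proteins_pqtl_discovery = len(pqtl_result.two_stage.proteins_discovery)
        s.proteins_pqtl_replicated = len(pqtl_result.two_stage.proteins_replicated)
        top = pqtl_result.top_markers
        if len(top) and top["cis"].notna().any():
            s.pct_cis_of_top_markers = round(
                100.0 * float(top["cis"].astype("boolean").mean()), 1
            )
    else:
        s.gaps.append("pqtl")
    if raw_scan is not None and adjusted_scan is not None and len(adjusted_scan):
        # before/after at the same criterion (per-drug FDR) when available
        if len(raw_scan) and "q_fdr" in raw_scan.columns:
            before = (
                raw_scan[raw_scan["q_fdr"] < config.alpha]
                .groupby("atc_code")["protein_id"].size()
            )
        elif len(raw_scan):
            before = (
                raw_scan[raw_scan["significant"]].groupby("atc_code")["protein_id"].size()
            )
        else:
            before = pd.Series(dtype=int)
        after = (
            adjusted_scan[adjusted_scan["q_fdr"] < config.alpha]
            .groupby("atc_code")["protein_id"].size()
        )
        drugs = sorted(set(before.index) | set(after.index))
        s.drug_hits = pd.DataFrame(
            {
                "atc_code": drugs,
                "before": [int(before.get(d, 0)) for d in drugs],
                "after": [int(after.get(d, 0)) for d in drugs],
            }
        )
        s.hits_before_total = int(s.drug_hits["before"].sum())
        s.hits_after_total = int(s.drug_hits["after"].sum())
        if s.hits_before_total:
            s.pct_reduction = round(
                100.0 * (1.0 - s.hits_after_total / s.hits_before_total), 1
            )
    else:
        s.gaps.append("medication")
    return s
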