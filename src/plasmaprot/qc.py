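"""NPX quality control: batch (plate x sampling-round) normalization and
limit-of-detection filtering.

Normalization is a median-of-group strategy: per protein, each (plate,
round) group is shifted so its median equals the protein-level target, the
median of the group medians.  Using the median of group medians (rather than
the pooled median) makes the operation exactly idempotent.  Shifts are
computed on non-censored values only; censored values are left unchanged.
The group-center statistic is pluggable via ``center``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["QCReport", "normalize_batches", "filter_lod"]

_MIN_GROUP = 3


@dataclass
class QCReport:
    proteins_in: int = 0
    proteins_removed: pd.DataFrame = field(default_factory=pd.DataFrame)
    fraction_above_lod: pd.Series = field(default_factory=pd.Series)
    batch_shifts: pd.DataFrame = field(default_factory=pd.DataFrame)

    @property
    def proteins_retained(self) -> int:
        return self.proteins_in - len(self.proteins_removed)


def normalize_batches(
    npx: pd.DataFrame,
    center=np.median,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Align per-protein (plate, round) group centers.

    Plates are nested within sampling rounds in the native layout, so the
    plate label identifies the (plate, round) group.  Groups with fewer than
    3 non-censored values are left un-normalized with a warning.  Returns the
    normalized long table and the applied shifts per (protein, plate).
    """
    out = npx.copy()
    ok = ~out["below_lod"].astype(bool)
    shifts = []
    small_groups = []
    for pid, sub in out[ok].groupby("protein_id", sort=False):
        centers: dict[str, float] = {}
        groups = {plate: grp for plate, grp in sub.groupby("plate", sort=False)}
        for plate, grp in groups.items():
            if len(grp) < _MIN_GROUP:
                small_groups.append((pid, plate, len(grp)))
            else:
                centers[plate] = float(center(grp["npx"].to_numpy()))
        if not centers:
            continue
        target = float(np.median(list(centers.values())))
        for plate, c in centers.items():
            delta = c - target
            if delta != 0.0:
                out.loc[groups[plate].index, "npx"] = groups[plate]["npx"] - delta
            shifts.append({"protein_id": pid, "plate": plate, "shift": delta})
    if small_groups:
        warnings.warn(
            f"{len(small_groups)} (protein, plate) groups with <{_MIN_GROUP} "
            f"non-censored values left un-normalized",
            stacklevel=2,
        )
    shift_df = pd.DataFrame(shifts, columns=["protein_id", "plate", "shift"])
    return out, shift_df


def filter_lod(npx: pd.DataFrame, min_fraction: float = 0.20) -> tuple[pd.DataFrame, QCReport]:
    """Drop proteins with fraction of measurements above LOD < ``min_fraction``
    (strict less-than); for retained proteins remove the censored records from
    the analysis set."""
    above = (~npx["below_lod"].astype(bool)).groupby(npx["protein_id"]).mean()
    frac = above.rename("fraction_above_lod")
    removed = frac[frac < min_fraction]
    removed_df = pd.DataFrame(
        {
            "protein_id": removed.index,
            "fraction_above_lod": removed.to_numpy(),
            "reason": f"fraction above LOD < {min_fraction:g}",
        }
    ).reset_index(drop=True)
    keep = ~npx["protein_id"].isin(removed.index)
    out = npx[keep & ~npx["below_lod"].astype(bool)].reset_index(drop=True)
    report = QCReport(
        proteins_in=int(frac.size),
        proteins_removed=removed_df,
        fraction_above_lod=frac,
    )
    return out, report
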