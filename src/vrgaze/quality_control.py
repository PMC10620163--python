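"""Participant-level data-quality cascade.

Participants are excluded, in order, for (1) technical failure during
recording, (2) mean data loss strictly above 5% of expected samples,
(3) failed gaze-validation assessment, (4) reported ADHD history.  Each
participant is counted at the first stage that catches them.  A
deterministic surrogate replaces the study-style visual QQ inspection
for the depth analysis: participants with any |standardized residual|
above 3.0 under the group-by-object-type cell-means model are flagged
as outliers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ExclusionReport",
    "DATA_LOSS_CUTOFF",
    "OUTLIER_Z",
    "apply_exclusions",
    "detect_mixed_model_outliers",
]

DATA_LOSS_CUTOFF = 0.05   # strict exceedance; exactly 5% is retained
OUTLIER_Z = 3.0

STAGES = ("technical", "data_loss", "validation", "adhd")


@dataclass
class ExclusionReport:
    """Counts per exclusion stage and what remains."""

    input_n: int
    counts: dict[str, int]
    retained_n_per_group: dict[str, int]
    mean_residual_data_loss: float
    retained_ids: list[str] = field(default_factory=list)

    @property
    def excluded_n(self) -> int:
        return sum(self.counts.values())

    @property
    def retained_n(self) -> int:
        return self.input_n - self.excluded_n

    def to_dict(self) -> dict:
        return {
            "input_n": self.input_n,
            "counts": dict(self.counts),
            "retained_n": self.retained_n,
            "retained_n_per_group": dict(self.retained_n_per_group),
            "mean_residual_data_loss": self.mean_residual_data_loss,
        }


def apply_exclusions(
    records: pd.DataFrame,
    metrics: pd.DataFrame,
    data_loss_cutoff: float = DATA_LOSS_CUTOFF,
) -> tuple[pd.DataFrame, ExclusionReport]:
    """Run the exclusion cascade and report per-stage counts.

    ``records`` carries participant_id, group, technical_failure,
    validation_ok, adhd_history; ``metrics`` carries participant_id and
    mean_data_loss (one row per record).  Returns the retained subset of
    ``records`` (joined with metrics) and an :class:`ExclusionReport`.
    """
    rec = records.set_index("participant_id")
    met = metrics.set_index("participant_id")
    if set(rec.index) != set(met.index):
        raise ValueError("records and metrics must cover the same participants")
    df = rec.join(met[["mean_data_loss"]]).sort_index()

    stage = pd.Series("retained", index=df.index)
    mask = df["technical_failure"].astype(bool)
    stage[mask] = "technical"
    mask = (stage == "retained") & (df["mean_data_loss"] > data_loss_cutoff)
    stage[mask] = "data_loss"
    mask = (stage == "retained") & (~df["validation_ok"].astype(bool))
    stage[mask] = "validation"
    mask = (stage == "retained") & df["adhd_history"].astype(bool)
    stage[mask] = "adhd"

    retained = df[stage == "retained"]
    report = ExclusionReport(
        input_n=len(df),
        counts={s: int((stage == s).sum()) for s in STAGES},
        retained_n_per_group=retained.groupby("group").size().to_dict(),
        mean_residual_data_loss=float(retained["mean_data_loss"].mean())
        if len(retained)
        else float("nan"),
        retained_ids=sorted(retained.index.astype(str)),
    )
    return retained.reset_index(), report


def detect_mixed_model_outliers(
    depth_table: pd.DataFrame, z_threshold: float = OUTLIER_Z
) -> list[str]:
    """Flag gross outliers in the closer/further dwell table.

    Fits the group-by-object-type cell-means model to the long-format
    dwell values, standardizes the residuals by their pooled SD, and
    flags any participant with |z| above ``z_threshold`` in either cell.
    ``depth_table`` needs columns participant_id, group,
    mean_closer_dwell_ms, mean_further_dwell_ms.
    """
    counts = depth_table.groupby("group").size()
    if (counts < 3).any():
        small = counts[counts < 3].index.tolist()
        raise ValueError(f"groups with n < 3 cannot be screened: {small}")
    long = depth_table.melt(
        id_vars=["participant_id", "group"],
        value_vars=["mean_closer_dwell_ms", "mean_further_dwell_ms"],
        var_name="type",
        value_name="dwell",
    )
    cell_means = long.groupby(["group", "type"])["dwell"].transform("mean")
    resid = long["dwell"] - cell_means
    sd = resid.std(ddof=long.groupby(["group", "type"]).ngroups)
    if sd == 0 or not np.isfinite(sd):
        return []
    flagged = long.loc[(resid.abs() / sd) > z_threshold, "participant_id"]
    return sorted(flagged.astype(str).unique())
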