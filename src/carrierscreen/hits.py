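"""Resistance/sensitivity calling from drug- and control-plate measurements.

The screen's scoring procedure: drop the WT border (edge effects), take the
median of each strain's four replicate spots on the drug plate, divide by
the same strain's median on the control plate, multiply by 100. A strain is
called *resistant* when its score lies more than ``resistant_sd`` sample
standard deviations above the plate average (3 by default; 2.5 or 2 when
extreme outliers inflate the SD) and *sensitive* when more than 2.5 SD
below. Plate mean and SD are computed over all scored strains, WT interior
replicates included; WT rows are flagged so reports can drop them without
touching the statistics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._exceptions import InputError, PairingError
from .catalog import PlateLayout, WILDTYPE_ID

logger = logging.getLogger(__name__)

SENSITIVE_SD = 2.5
RESISTANT_SD_MENU = (3.0, 2.5, 2.0)


@dataclass
class ExclusionReport:
    """Strains dropped or degraded during scoring, for the plain-text report."""

    short_replicates: list[tuple[str, int]] = field(default_factory=list)
    all_missing: list[str] = field(default_factory=list)
    zero_control: list[str] = field(default_factory=list)
    degenerate_plate: bool = False
    calls_per_threshold: dict[float, int] = field(default_factory=dict)

    def lines(self) -> list[str]:
        out = []
        for strain, n in self.short_replicates:
            out.append(f"short-replicates\t{strain}\t{n}")
        for strain in self.all_missing:
            out.append(f"all-replicates-missing\t{strain}")
        for strain in self.zero_control:
            out.append(f"zero-control-median\t{strain}")
        if self.degenerate_plate:
            out.append("degenerate-plate\tSD=0, no calls made")
        for sd, n in sorted(self.calls_per_threshold.items()):
            out.append(f"resistant-calls-at-{sd}SD\t{n}")
        return out


def exclude_edges(layout: PlateLayout, measurements: pd.DataFrame) -> pd.DataFrame:
    """Drop border spots (the WT buffer) from a measurement table.

    Edge colonies grow larger for lack of neighbours, so they contribute to
    no median, plate mean, or SD.
    """
    if "is_edge" in measurements.columns:
        keep = ~measurements["is_edge"].astype(bool)
        return measurements.loc[keep].reset_index(drop=True)
    edges = layout.frame.loc[layout.frame["is_edge"], ["row", "col"]]
    marked = measurements.merge(edges, on=["row", "col"], how="left", indicator=True)
    return (
        marked.loc[marked["_merge"] == "left_only"]
        .drop(columns="_merge")
        .reset_index(drop=True)
    )


def replicate_median(
    measurements: pd.DataFrame, report: ExclusionReport | None = None
) -> pd.DataFrame:
    """Median pixel count of each strain's replicate spots on one plate.

    Strains with fewer than four usable replicates are kept (median of the
    available spots) but logged; strains with every replicate missing are
    dropped and recorded in the report.
    """
    report = report if report is not None else ExclusionReport()
    rows = []
    for strain, group in measurements.groupby("strain_id", sort=True):
        counts = group["pixel_count"].dropna()
        if counts.empty:
            report.all_missing.append(str(strain))
            logger.warning("strain %s: all replicates missing; dropped", strain)
            continue
        if len(counts) < 4:
            report.short_replicates.append((str(strain), len(counts)))
            logger.warning("strain %s: only %d replicates", strain, len(counts))
        rows.append({"strain_id": strain, "median_px": float(counts.median()), "n_replicates": len(counts)})
    return pd.DataFrame(rows, columns=["strain_id", "median_px", "n_replicates"])


def normalize_scores(
    drug_medians: pd.DataFrame,
    control_medians: pd.DataFrame,
    report: ExclusionReport | None = None,
) -> pd.DataFrame:
    """Relative growth score: 100 x drug median / control median per strain.

    Strains whose control median is zero cannot be normalized; they are
    excluded from scoring and listed in the report.
    """
    report = report if report is not None else ExclusionReport()
    merged = drug_medians.merge(
        control_medians, on="strain_id", suffixes=("_drug", "_control")
    )
    if merged.empty:
        raise PairingError("drug and control plates share no strains")
    zero = merged["median_px_control"] == 0
    for strain in merged.loc[zero, "strain_id"]:
        report.zero_control.append(str(strain))
        logger.warning("strain %s: control median 0; cannot normalize", strain)
    scored = merged.loc[~zero].copy()
    scored["score"] = 100.0 * scored["median_px_drug"] / scored["median_px_control"]
    scored = scored.rename(
        columns={"median_px_drug": "median_drug", "median_px_control": "median_control"}
    )
    return scored[["strain_id", "median_drug", "median_control", "score"]].reset_index(drop=True)


def call_hits(
    scores: pd.DataFrame,
    resistant_sd: float = 3.0,
    sensitive_sd: float = SENSITIVE_SD,
    report: ExclusionReport | None = None,
) -> pd.DataFrame:
    """Z-score every strain against the plate and call resistant/sensitive.

    ``z = (score - plate mean) / plate SD`` with the sample SD (n-1). Calls
    use strict inequalities ("more than N SD above the average"). A plate
    with zero SD yields no calls and a degenerate-plate warning. For
    transparency the report records how many strains would be called
    resistant at each threshold of the menu (3, 2.5, 2 SD).
    """
    report = report if report is not None else ExclusionReport()
    if len(scores) < 3:
        raise InputError(f"need at least 3 scored strains, got {len(scores)}")
    if resistant_sd not in RESISTANT_SD_MENU:
        logger.warning("non-standard resistant threshold %.2f SD", resistant_sd)
    out = scores.copy()
    mean = float(out["score"].mean())
    sd = float(out["score"].std(ddof=1))
    if sd == 0 or not np.isfinite(sd):
        logger.warning("degenerate plate: score SD is zero; no calls made")
        report.degenerate_plate = True
        out["z"] = 0.0
        out["call"] = "none"
    else:
        out["z"] = (out["score"] - mean) / sd
        out["call"] = "none"
        out.loc[out["z"] > resistant_sd, "call"] = "resistant"
        out.loc[out["z"] < -sensitive_sd, "call"] = "sensitive"
        for threshold in RESISTANT_SD_MENU:
            report.calls_per_threshold[threshold] = int((out["z"] > threshold).sum())
    out["resistant_threshold_sd"] = resistant_sd
    out["sensitive_threshold_sd"] = sensitive_sd
    out["is_wildtype"] = out["strain_id"] == WILDTYPE_ID
    return out


def score_plate_pair(
    layout: PlateLayout,
    drug_measurements: pd.DataFrame,
    control_measurements: pd.DataFrame,
    resistant_sd: float = 3.0,
) -> tuple[pd.DataFrame, ExclusionReport]:
    """Full scoring path: edge exclusion -> medians -> normalize -> calls."""
    report = ExclusionReport()
    drug_med = replicate_median(exclude_edges(layout, drug_measurements), report)
    ctrl_med = replicate_median(exclude_edges(layout, control_measurements), report)
    scores = normalize_scores(drug_med, ctrl_med, report)
    calls = call_hits(scores, resistant_sd=resistant_sd, report=report)
    return calls, report
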