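"""Enrichment analysis of barcoded deletion-pool competitions.

Each strain's barcode abundance is read out as arbitrary fluorescence units
(AFU) in an untreated and a drug-treated pool. Resistant deletants enrich in
the treated arm: a strain is called *enriched* when its treated-minus-
untreated AFU difference exceeds a noise band (the half-width within which
98% of deletants fall when comparing untreated replicate pools; +/-1000 AFU
by default) AND its treated/untreated ratio reaches a threshold (3 by
default, 2 as the relaxed setting). Strains are ranked by treated AFU,
mirroring the 'top-ranked on the drug-treated axis' reading of the scatter.
"""

from __future__ import annotations

import logging
import math

import numpy as np
import pandas as pd

from ._exceptions import DomainError, InputError, NormalizationError
from .catalog import StrainCatalog

logger = logging.getLogger(__name__)

DEFAULT_BAND_AFU = 1000.0
DEFAULT_RATIO = 3.0
RATIO_MENU = (2.0, 3.0)


def normalize_afu(profiles: pd.DataFrame, columns: tuple[str, str] = ("afu_untreated", "afu_treated")) -> pd.DataFrame:
    """Total-sum scaling across conditions.

    Each condition is rescaled so its total AFU equals the mean of the
    per-condition totals; within-condition proportions are untouched. This
    replaces the external array-normalization protocol and is declared in
    output metadata by the pipeline.
    """
    out = profiles.copy()
    totals = np.array([float(out[c].sum()) for c in columns])
    if (totals == 0).any():
        raise NormalizationError("a condition has zero total AFU; cannot normalize")
    target = totals.mean()
    for col, total in zip(columns, totals):
        out[col] = out[col] * (target / total)
    return out


def estimate_noise_band(
    rep_a: np.ndarray | pd.Series,
    rep_b: np.ndarray | pd.Series,
    coverage: float = 0.98,
) -> float:
    """Noise-band half-width from two untreated replicate profiles.

    Returns the smallest half-width ``b`` such that at least ``coverage`` of
    strains satisfy ``|AFU_b - AFU_a| <= b`` — the ceil(coverage * n)-th
    smallest absolute replicate difference.
    """
    if not (0.0 < coverage <= 1.0):
        raise DomainError(f"coverage must be in (0, 1], got {coverage}")
    diffs = np.sort(np.abs(np.asarray(rep_b, dtype=float) - np.asarray(rep_a, dtype=float)))
    if diffs.size == 0:
        raise InputError("empty replicate profiles")
    k = math.ceil(coverage * diffs.size)
    return float(diffs[k - 1])


def call_enrichment(
    profiles: pd.DataFrame,
    band_halfwidth: float = DEFAULT_BAND_AFU,
    ratio_threshold: float = DEFAULT_RATIO,
) -> pd.DataFrame:
    """Call enriched (drug-resistant) deletants from a pool profile table.

    ``profiles`` needs ``strain_id``, ``afu_untreated``, ``afu_treated``.
    Enriched iff (treated - untreated) > band AND ratio >= threshold. A
    strain with zero untreated AFU has an undefined ratio (not imputed);
    there the band criterion alone governs and the row is flagged.
    Ranking is by treated AFU descending, ties broken by strain_id.
    """
    if profiles.empty:
        raise InputError("empty profile set")
    if ratio_threshold not in RATIO_MENU:
        logger.warning("non-standard ratio threshold %.2f", ratio_threshold)
    out = profiles.copy()
    out["difference"] = out["afu_treated"] - out["afu_untreated"]
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = out["afu_treated"] / out["afu_untreated"]
    undefined = out["afu_untreated"] == 0
    out["ratio"] = ratio.where(~undefined, np.nan)
    out["ratio_undefined"] = undefined
    above_band = out["difference"] > band_halfwidth
    out["enriched"] = np.where(
        undefined, above_band, above_band & (out["ratio"] >= ratio_threshold)
    )
    out = out.sort_values(
        ["afu_treated", "strain_id"], ascending=[False, True]
    ).reset_index(drop=True)
    out["rank_on_treated"] = np.arange(1, len(out) + 1)
    out["band_halfwidth"] = band_halfwidth
    out["ratio_threshold"] = ratio_threshold
    return out


def annotate_transporters(calls: pd.DataFrame, catalog: StrainCatalog) -> pd.DataFrame:
    """Overlay the transporter flag and summary counts on an enrichment table."""
    out = calls.copy()
    transporters = set(catalog.transporter_ids)
    known = transporters | {catalog.wildtype_id}
    unknown = ~out["strain_id"].isin(known)
    if unknown.any():
        logger.warning(
            "%d strains absent from the catalog; flagged non-transporter",
            int(unknown.sum()),
        )
    out["is_transporter"] = out["strain_id"].isin(transporters)
    enriched = out[out["enriched"]]
    out.attrs["n_enriched_transporter"] = int(enriched["is_transporter"].sum())
    out.attrs["n_enriched_other"] = int((~enriched["is_transporter"]).sum())
    return out
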