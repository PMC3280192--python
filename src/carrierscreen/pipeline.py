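"""End-to-end orchestration: simulate -> quantify -> call -> enrich -> validate.

A single YAML config drives every run. All outputs are TSV files whose
metadata header records the tool version, the rng seed, the thresholds used
and a hash of the config, so a run is reproducible from its outputs alone.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from ._exceptions import ConfigError
from .catalog import PlateLayout, StrainCatalog, build_master_layout, build_test_layout, default_catalog
from .colony import PlateImage, quantify_plate
from .growth import dose_response, final_od, ic_level, mu_max, protection_profile
from .hits import RESISTANT_SD_MENU, score_plate_pair
from .pool import RATIO_MENU, annotate_transporters, call_enrichment, normalize_afu
from .simulate import SimParams, make_truth, render_plate_image, simulate_growth_curve, simulate_pool

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Parsed run configuration with the screen's threshold menu enforced."""

    rng_seed: int = 0
    drug: str = "drug"
    conc_uM: float = 10.0
    resistant_strains: list[str] = field(default_factory=list)
    inhibition: float = 0.9
    resistant_sd: float = 3.0
    band_halfwidth: float = 1000.0
    ratio_threshold: float = 3.0
    ic_level: float = 0.9
    competitor_concs_uM: list[float] = field(
        default_factory=lambda: [0.0, 0.5, 1.0, 2.0, 5.0, 10.0, 50.0, 200.0]
    )
    replicates: int = 3
    sim_overrides: dict[str, Any] = field(default_factory=dict)
    out_dir: Path = Path("carrierscreen_out")
    config_hash: str = "unconfigured"

    def __post_init__(self) -> None:
        if self.resistant_sd not in RESISTANT_SD_MENU:
            logger.warning(
                "resistant threshold %.2f SD outside the standard menu %s",
                self.resistant_sd, RESISTANT_SD_MENU,
            )
        if self.ratio_threshold not in RATIO_MENU:
            logger.warning(
                "ratio threshold %.2f outside the standard menu %s",
                self.ratio_threshold, RATIO_MENU,
            )

    @property
    def params(self) -> SimParams:
        return SimParams(rng_seed=self.rng_seed, **self.sim_overrides)

    def metadata(self) -> dict[str, Any]:
        return {
            "rng_seed": self.rng_seed,
            "config_hash": self.config_hash,
            "drug": self.drug,
            "resistant_sd": self.resistant_sd,
            "band_halfwidth": self.band_halfwidth,
            "ratio_threshold": self.ratio_threshold,
        }

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        text = path.read_text(encoding="utf-8")
        try:
            raw = yaml.safe_load(text) or {}
        except yaml.YAMLError as exc:
            raise ConfigError(f"cannot parse config {path}: {exc}") from exc
        if not isinstance(raw, dict):
            raise ConfigError(f"config {path} must be a mapping")
        known = {f for f in cls.__dataclass_fields__ if f != "config_hash"}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        if "out_dir" in raw:
            raw["out_dir"] = (path.parent / raw["out_dir"]).resolve()
        cfg = cls(**raw)
        cfg.config_hash = hashlib.sha256(text.encode()).hexdigest()[:16]
        return cfg


def _write(frame: pd.DataFrame, config: RunConfig, name: str) -> Path:
    from .io import write_table

    return write_table(frame, Path(config.out_dir) / name, config.metadata())


@dataclass
class RobotScreenResult:
    layout: PlateLayout
    calls: pd.DataFrame
    report_lines: list[str]
    n_suppressors_planted: int
    resistant_strains: list[str]


def run_robot_screen(
    config: RunConfig,
    catalog: StrainCatalog | None = None,
    write: bool = False,
) -> RobotScreenResult:
    """Simulated robot screen: plates -> quantification -> hit calls."""
    catalog = catalog or default_catalog()
    layout = build_test_layout(build_master_layout(catalog))
    truth = make_truth(catalog, resistant=config.resistant_strains, inhibition=config.inhibition)
    params = config.params
    control = render_plate_image(layout, truth, params, treated=False)
    drug = render_plate_image(layout, truth, params, treated=True)
    m_control = quantify_plate(PlateImage(control.image, control.corners), layout)
    m_drug = quantify_plate(PlateImage(drug.image, drug.corners), layout)
    calls, report = score_plate_pair(layout, m_drug, m_control, resistant_sd=config.resistant_sd)
    n_sup = int(drug.truth_sizes["is_suppressor"].sum())
    resistant = sorted(calls.loc[(calls["call"] == "resistant") & ~calls["is_wildtype"], "strain_id"])
    lines = [
        f"drug\t{config.drug}",
        f"suppressors-planted\t{n_sup}",
        f"resistant-calls\t{','.join(resistant) or '-'}",
        *report.lines(),
    ]
    if write:
        _write(calls, config, "robot_calls.tsv")
        report_path = Path(config.out_dir) / "robot_report.txt"
        report_path.parent.mkdir(parents=True, exist_ok=True)
        report_path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    return RobotScreenResult(layout, calls, lines, n_sup, resistant)


@dataclass
class PoolScreenResult:
    profiles: pd.DataFrame
    calls: pd.DataFrame
    scatter_path: Path | None


def run_pool_screen(
    config: RunConfig,
    catalog: StrainCatalog | None = None,
    write: bool = False,
) -> PoolScreenResult:
    """Simulated pool competition -> normalization -> enrichment calls."""
    catalog = catalog or default_catalog()
    truth = make_truth(catalog, resistant=config.resistant_strains, inhibition=config.inhibition)
    profiles = simulate_pool(catalog, truth, config.params)
    normalized = normalize_afu(profiles)
    calls = annotate_transporters(
        call_enrichment(normalized, config.band_halfwidth, config.ratio_threshold),
        catalog,
    )
    scatter = None
    if write:
        _write(calls, config, "pool_calls.tsv")
        from .plots import pool_scatter

        scatter = pool_scatter(
            calls,
            Path(config.out_dir) / "pool_scatter.png",
            band_halfwidth=config.band_halfwidth,
            title=f"Pool competition: {config.drug}",
        )
    return PoolScreenResult(normalized, calls, scatter)


@dataclass
class ValidationResult:
    rates: pd.DataFrame
    dose_response: pd.DataFrame
    ic_estimate: Any
    protection: pd.DataFrame
    final_ods: pd.DataFrame


def run_validation(
    config: RunConfig,
    concs_uM: list[float] | None = None,
    write: bool = False,
) -> ValidationResult:
    """Growth-curve validation: dose-response, IC estimate, protection sweep."""
    params = config.params
    if concs_uM is None:
        ic50 = params.ic50_uM
        concs_uM = [0.0, ic50 / 4, ic50 / 2, ic50, 2 * ic50, 4 * ic50, 8 * ic50]
    rate_rows, od_rows = [], []
    for conc in concs_uM:
        for rep in range(1, config.replicates + 1):
            curve = simulate_growth_curve(params.mu_wt, conc, params, replicate=rep)
            est = mu_max(curve)
            rate_rows.append({"conc_uM": conc, "replicate": rep, "mu_max": est.mu_max,
                              "r_squared": est.r_squared})
            od_rows.append({"conc_uM": conc, "replicate": rep, "final_od": final_od(curve)})
    rates = pd.DataFrame(rate_rows)
    dr = dose_response(rates)
    estimate = ic_level(dr, level=config.ic_level)
    protection = protection_profile(
        drug_conc=estimate.concentration,
        competitor_concs=np.asarray(config.competitor_concs_uM),
        ic50=estimate.ic50 if estimate.ic50 else params.ic50_uM,
        h=estimate.h if estimate.h else params.hill_h,
        ks=params.ks_uM,
        mu0=estimate.mu0,
    )
    final_ods = pd.DataFrame(od_rows)
    if write:
        _write(rates, config, "growth_rates.tsv")
        _write(dr, config, "dose_response.tsv")
        _write(protection, config, "protection.tsv")
        _write(final_ods, config, "final_od.tsv")
        ic_frame = pd.DataFrame(
            [{"level": estimate.level, "concentration_uM": estimate.concentration,
              "method": estimate.method, "mu0": estimate.mu0,
              "ic50_uM": estimate.ic50, "hill_h": estimate.h}]
        )
        _write(ic_frame, config, "ic_estimate.tsv")
    return ValidationResult(rates, dr, estimate, protection, final_ods)
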