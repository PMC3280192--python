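"""Seeded synthetic-data generators for every input the pipeline consumes.

The generators emulate the three experimental platforms of the screen:

* **Robot plates** — a rendered photograph of a 768-spot agar plate. Each
  colony is a filled disc centred in its diamond window, radius proportional
  to the strain's growth score (untreated: fitness; drug plate: fitness x
  (1 - inhibition)). Border spots are inflated by a multiplicative edge
  boost; spontaneous suppressor colonies (full-size discs on susceptible
  spots) appear at a Poisson rate per treated plate; signal is carried on
  the blue channel with multiplicative pixel noise.

* **Pool competitions** — exponential co-growth of all deletants from equal
  inoculum proportions, each strain at rate mu_wt x fitness (x (1 -
  inhibition) in the drug arm), integrated until total biomass reaches a
  stop multiple of the inoculum (sampling at exit from exponential phase).
  Strain abundances are read out as arbitrary fluorescence units (AFU):
  scale x final proportion x log-normal noise.

* **Growth curves** — OD600 every 10 minutes: a media-blank startup read,
  a lag phase, then logistic growth at the Hill-inhibited rate
  mu(c) = mu0 / (1 + (c / IC50)^h), with optional multiplicative OD noise.
  Competitive-substrate protection rescales the drug concentration by
  1 / (1 + competitor / Ks) before the Hill term (shared carrier site).

Identical parameters (including the seed) give bit-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from ._exceptions import DomainError, GeometryError, StagnationError
from .catalog import PlateLayout, StrainCatalog
from .colony import Corners, grid_centers, window_size

__all__ = [
    "SimParams",
    "TruthTable",
    "RenderResult",
    "render_plate_image",
    "simulate_pool",
    "simulate_growth_curve",
    "apply_protection",
    "hill_rate",
    "make_truth",
]


@dataclass(frozen=True)
class SimParams:
    """All tunable generator parameters, with the study's default conditions."""

    rng_seed: int = 0

    # plate image geometry and colony intensity model
    px_per_window: int = 20          # pixels per grid cell (square cells)
    corner_jitter: float = 0.0       # uniform +/- jitter of grid corners, px
    colony_radius_frac: float = 0.45  # full-growth disc radius / half-diagonal
    bg_level: float = 40.0           # blue-channel agar background
    fg_level: float = 200.0          # blue-channel colony foreground
    pixel_noise_sd: float = 0.05     # multiplicative Gaussian pixel noise
    edge_boost: float = 1.3          # radius multiplier on border spots
    suppressor_rate: float = 1.0     # expected suppressor colonies per plate

    # pool competition model
    mu_wt: float = 0.35              # WT max specific growth rate, 1/h
    stop_mult: float = 100.0         # stop when biomass = stop_mult x inoculum
    afu_scale: float = 1.0e5         # total AFU per condition before noise
    afu_noise_sd: float = 0.15       # log-normal readout sd (log scale)

    # growth-curve model
    lag_h: float = 2.0               # lag-phase duration, h
    od_init: float = 0.01            # inoculum OD above blank
    carrying_od: float = 0.9         # final OD of the untreated culture
    blank_od: float = 0.05           # media blank
    sample_interval_min: float = 10.0
    duration_h: float = 24.0
    od_noise_sd: float = 0.0         # multiplicative OD noise (0 = noiseless)

    # dose-response (Hill) and protection models
    ic50_uM: float = 10.0
    hill_h: float = 2.0
    ks_uM: float = 2.0               # competitor binding constant, uM

    def __post_init__(self) -> None:
        positive = {
            "px_per_window": self.px_per_window,
            "colony_radius_frac": self.colony_radius_frac,
            "mu_wt": self.mu_wt,
            "stop_mult": self.stop_mult,
            "afu_scale": self.afu_scale,
            "carrying_od": self.carrying_od,
            "od_init": self.od_init,
            "sample_interval_min": self.sample_interval_min,
            "duration_h": self.duration_h,
            "ic50_uM": self.ic50_uM,
            "hill_h": self.hill_h,
            "ks_uM": self.ks_uM,
        }
        for name, value in positive.items():
            if value <= 0:
                raise DomainError(f"{name} must be positive, got {value}")

    def with_(self, **kwargs) -> "SimParams":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class TruthTable:
    """Planted ground truth per strain.

    ``frame`` columns: ``strain_id``, ``fitness`` (relative untreated growth,
    ~1), ``inhibition`` (fraction of growth rate removed by the drug, in
    [0, 1]) and ``planted_call`` in {resistant, sensitive, none}.
    """

    frame: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        inhib = self.frame["inhibition"]
        if ((inhib < 0) | (inhib > 1)).any():
            raise DomainError("inhibition must lie in [0, 1]")
        resistant = self.frame.loc[self.frame["planted_call"] == "resistant", "inhibition"]
        if len(resistant) and (resistant >= float(inhib.median())).any():
            raise DomainError("planted resistant strains must have below-median inhibition")

    def inhibition_of(self) -> pd.Series:
        return self.frame.set_index("strain_id")["inhibition"]

    def fitness_of(self) -> pd.Series:
        return self.frame.set_index("strain_id")["fitness"]


def make_truth(
    catalog: StrainCatalog,
    resistant: list[str] | None = None,
    sensitive: list[str] | None = None,
    inhibition: float = 0.9,
    resistant_inhibition: float = 0.0,
    fitness: float = 1.0,
) -> TruthTable:
    """Plant resistance: listed strains escape the drug, everyone else is hit."""
    resistant = set(resistant or [])
    sensitive = set(sensitive or [])
    rows = []
    for sid in catalog.frame["strain_id"]:
        if sid in resistant:
            rows.append((sid, fitness, resistant_inhibition, "resistant"))
        elif sid in sensitive:
            rows.append((sid, fitness, inhibition, "sensitive"))
        else:
            rows.append((sid, fitness, inhibition, "none"))
    return TruthTable(
        pd.DataFrame(rows, columns=["strain_id", "fitness", "inhibition", "planted_call"])
    )


@dataclass(frozen=True)
class RenderResult:
    """A rendered plate: image, the grid corners used, and per-spot truth."""

    image: np.ndarray          # H x W x 3 uint8
    corners: Corners
    truth_sizes: pd.DataFrame  # row, col, strain_id, radius_px, true_pixels, is_suppressor


def _disc_pixels(img: np.ndarray, cx: float, cy: float, radius: float, level: float) -> int:
    """Paint a filled disc (pixel centres within ``radius``) and return its area."""
    if radius <= 0:
        return 0
    h, w = img.shape
    x0, x1 = max(int(cx - radius) - 1, 0), min(int(cx + radius) + 2, w)
    y0, y1 = max(int(cy - radius) - 1, 0), min(int(cy + radius) + 2, h)
    xs = np.arange(x0, x1) + 0.5
    ys = np.arange(y0, y1) + 0.5
    mask = (xs[None, :] - cx) ** 2 + (ys[:, None] - cy) ** 2 <= radius**2
    img[y0:y1, x0:x1][mask] = level
    return int(mask.sum())


def render_plate_image(
    layout: PlateLayout,
    truth: TruthTable,
    params: SimParams,
    treated: bool,
) -> RenderResult:
    """Render a photograph of one robot plate with planted ground truth.

    The drawn disc radius is ``colony_radius_frac x half-diagonal x score``
    (score = fitness, times (1 - inhibition) on treated plates), multiplied
    by ``edge_boost`` on border spots. Suppressor colonies are planted on
    treated plates only. Returns the image together with the exact pixel
    count of every drawn disc, for oracle tests of the quantifier.
    """
    px = params.px_per_window
    H, W = layout.n_rows * px, layout.n_cols * px
    rng = np.random.default_rng(
        np.random.SeedSequence((params.rng_seed, 1 if treated else 0))
    )
    base: Corners = ((0.0, 0.0), (float(W), 0.0), (0.0, float(H)), (float(W), float(H)))
    if params.corner_jitter > 0:
        jit = rng.uniform(-params.corner_jitter, params.corner_jitter, size=(4, 2))
        corners = tuple((x + dx, y + dy) for (x, y), (dx, dy) in zip(base, jit))
    else:
        corners = base
    half = window_size(corners, layout.n_rows, layout.n_cols) / 2.0
    if 2 * half < 8:
        raise GeometryError("geometry yields fewer than 8 pixels per window diagonal")
    r_full = params.colony_radius_frac * half
    centers = grid_centers(corners, layout.n_rows, layout.n_cols)

    inhib = truth.inhibition_of()
    fitness = truth.fitness_of()
    frame = layout.frame.sort_values(["row", "col"]).reset_index(drop=True)
    scores = fitness.reindex(frame["strain_id"]).to_numpy(dtype=float)
    if treated:
        scores = scores * (1.0 - inhib.reindex(frame["strain_id"]).to_numpy(dtype=float))
    radii = r_full * scores
    radii[frame["is_edge"].to_numpy(dtype=bool)] *= params.edge_boost

    is_suppressor = np.zeros(len(frame), dtype=bool)
    if treated and params.suppressor_rate > 0:
        n_sup = rng.poisson(params.suppressor_rate)
        susceptible = np.flatnonzero(radii < 0.5 * r_full)
        if n_sup > 0 and len(susceptible):
            chosen = rng.choice(susceptible, size=min(n_sup, len(susceptible)), replace=False)
            radii[chosen] = r_full
            is_suppressor[chosen] = True

    img = np.full((H, W), params.bg_level, dtype=float)
    true_px = np.zeros(len(frame), dtype=int)
    for k, rec in enumerate(frame.itertuples(index=False)):
        cx, cy = centers[rec.row, rec.col]
        true_px[k] = _disc_pixels(img, cx, cy, radii[k], params.fg_level)
    if params.pixel_noise_sd > 0:
        img = img * (1.0 + rng.normal(0.0, params.pixel_noise_sd, size=img.shape))
    blue = np.clip(img, 0, 255)
    red = np.clip(0.25 * blue, 0, 255)
    green = np.clip(0.5 * blue, 0, 255)
    image = np.stack([red, green, blue], axis=-1).astype(np.uint8)

    truth_sizes = frame[["row", "col", "strain_id"]].copy()
    truth_sizes["radius_px"] = radii
    truth_sizes["true_pixels"] = true_px
    truth_sizes["is_suppressor"] = is_suppressor
    return RenderResult(image, corners, truth_sizes)


def _pool_rates(truth: TruthTable, params: SimParams, treated: bool) -> np.ndarray:
    mu = params.mu_wt * truth.frame["fitness"].to_numpy(dtype=float)
    if treated:
        mu = mu * (1.0 - truth.frame["inhibition"].to_numpy(dtype=float))
    return mu


def pool_stop_time(mu: np.ndarray, stop_mult: float) -> float:
    """Time at which total abundance sum exp(mu_i t) / N reaches stop_mult."""
    if not (mu > 0).any():
        raise StagnationError("no strain grows; stop biomass is unreachable")
    n = len(mu)

    def excess(t: float) -> float:
        return float(np.exp(mu * t).sum() / n - stop_mult)

    hi = 1.0
    while excess(hi) < 0:
        hi *= 2.0
        if hi > 1e6:  # pragma: no cover - defensive
            raise StagnationError("stop biomass unreachable within integration horizon")
    return float(brentq(excess, 0.0, hi, xtol=1e-12, rtol=1e-14))


def final_proportions(mu: np.ndarray, stop_mult: float) -> np.ndarray:
    """Closed-form strain proportions at the stop time (equal inoculum)."""
    t_star = pool_stop_time(mu, stop_mult)
    weights = np.exp(mu * t_star)
    return weights / weights.sum()


def simulate_pool(
    catalog: StrainCatalog,
    truth: TruthTable,
    params: SimParams,
    noise: bool = True,
) -> pd.DataFrame:
    """Simulate one untreated/treated pool competition pair.

    Both arms start from equal strain proportions and grow exponentially at
    per-strain rates until total abundance reaches ``stop_mult`` times the
    inoculum; the readout is AFU = afu_scale x proportion x log-normal noise
    (independent noise per arm). Pre-noise proportions sum to one exactly.
    """
    order = catalog.frame["strain_id"]
    truth_frame = truth.frame.set_index("strain_id").loc[order].reset_index()
    truth_ordered = TruthTable(truth_frame)
    rng = np.random.default_rng(np.random.SeedSequence((params.rng_seed, 2)))
    result = {"strain_id": list(order)}
    for arm, treated in (("untreated", False), ("treated", True)):
        mu = _pool_rates(truth_ordered, params, treated)
        p = final_proportions(mu, params.stop_mult)
        eps = (
            np.exp(rng.normal(0.0, params.afu_noise_sd, size=len(p)))
            if noise and params.afu_noise_sd > 0
            else np.ones(len(p))
        )
        result[f"p_{arm}"] = p
        result[f"afu_{arm}"] = params.afu_scale * p * eps
    frame = pd.DataFrame(result)
    frame["is_transporter"] = frame["strain_id"].isin(catalog.transporter_ids)
    return frame


def apply_protection(conc_drug: float, conc_competitor: float, ks: float) -> float:
    """Effective drug concentration under competitive uptake inhibition.

    A non-toxic native substrate sharing the carrier's binding site dilutes
    drug uptake: c_eff = c_drug / (1 + c_competitor / Ks). The result never
    exceeds the drug concentration and decreases monotonically in the
    competitor; an infinite competitor concentration gives full protection.
    """
    if ks <= 0:
        raise DomainError(f"Ks must be positive, got {ks}")
    if conc_drug < 0 or conc_competitor < 0:
        raise DomainError("concentrations must be non-negative")
    return conc_drug / (1.0 + conc_competitor / ks)


def hill_rate(mu0: float, conc: float, ic50: float, h: float) -> float:
    """Hill-inhibited growth rate mu(c) = mu0 / (1 + (c / IC50)^h)."""
    if conc < 0:
        raise DomainError("concentration must be non-negative")
    return mu0 / (1.0 + (conc / ic50) ** h)


def simulate_growth_curve(
    mu0: float,
    conc: float,
    params: SimParams,
    competitor_uM: float = 0.0,
    strain_id: str = "WT",
    replicate: int = 1,
) -> pd.DataFrame:
    """Simulate one OD600 time series at 10-minute sampling.

    The first sample is the instrument's media-blank startup read (no
    measurable biomass); thereafter the culture sits at the inoculum OD for
    the lag phase and then grows logistically towards the carrying OD at
    the Hill-inhibited rate. Noise, when enabled, is multiplicative on OD.

    Returns a long-format frame: strain_id, conc_uM, competitor_uM,
    replicate, time_min, od600.
    """
    if mu0 <= 0:
        raise DomainError(f"mu0 must be positive, got {mu0}")
    if conc < 0:
        raise DomainError(f"concentration must be non-negative, got {conc}")
    c_eff = apply_protection(conc, competitor_uM, params.ks_uM) if competitor_uM else conc
    mu = hill_rate(mu0, c_eff, params.ic50_uM, params.hill_h)

    times = np.arange(0.0, params.duration_h * 60.0 + 1e-9, params.sample_interval_min)
    tau_h = np.maximum(times / 60.0 - params.lag_h, 0.0)
    K, x0 = params.carrying_od, params.od_init
    growth = K * x0 * np.exp(mu * tau_h) / (K + x0 * (np.exp(mu * tau_h) - 1.0))
    od = params.blank_od + growth
    od[0] = params.blank_od  # startup read: media blank only
    if params.od_noise_sd > 0:
        rng = np.random.default_rng(
            np.random.SeedSequence(
                (params.rng_seed, 3, int(round(conc * 1e6)), int(round(competitor_uM * 1e6)), replicate)
            )
        )
        od = od * (1.0 + rng.normal(0.0, params.od_noise_sd, size=od.shape))
    return pd.DataFrame(
        {
            "strain_id": strain_id,
            "conc_uM": conc,
            "competitor_uM": competitor_uM,
            "replicate": replicate,
            "time_min": times,
            "od600": od,
        }
    )
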