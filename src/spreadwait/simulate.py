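"""Synthetic invasion generator.

Produces trap-catch monitoring datasets with the statistical structure the
downstream analysis assumes: a kinematic invasion wave travelling outward
from an origin, covariate-dependent establishment lags with a nested
eco-region random-intercept hierarchy, overdispersed trap counts from a
latent abundance surface, and yearly treatment discs covering a small
fraction of the area.  Full ground truth (arrival year, establishment year,
waiting time, lag coefficients, random intercepts, latent abundance) is
retained so that every downstream stage can be checked against a known
answer.

The generative model is deliberately simple and additive: the waiting time
(lag) of a cell is ``round(mu_lag + sum_j beta_j x_j + alpha_level4 +
noise)`` clipped at zero, because the regression stage assumes additive
covariate effects on waiting time — this makes parameter-recovery tests
well-posed.  Latent abundance is zero before arrival, sits at a low
"sputtering" plateau from arrival until the establishment year, then grows
logistically to carrying capacity.  Holding abundance at a detectable but
non-established plateau during the waiting period is what makes the waiting
time observable from count data at all; a population that grows smoothly
from arrival would encode its lag only in the growth rate.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

__all__ = [
    "CovariateSpec",
    "SimConfig",
    "Landscape",
    "SyntheticTruth",
    "TreatmentEvent",
    "generate_landscape",
    "simulate_invasion",
    "simulate_trapping",
    "simulate_all",
    "write_traps",
    "read_traps",
    "write_treatments",
    "read_treatments",
    "write_truth",
    "write_covariate_layer",
    "read_covariate_layer",
]

#: canonical driver names, mirroring the ten environmental/anthropogenic
#: factors used in the regression stage
DEFAULT_DRIVERS = (
    "winter_temp",
    "spring_tmax",
    "summer_precip",
    "elevation",
    "host_basal_area",
    "pop_density",
    "wood_use",
    "highway_density",
    "anthro_frag",
    "natural_frag",
)


@dataclass(frozen=True)
class CovariateSpec:
    """One spatially smooth driver field.

    Parameters
    ----------
    name : driver name (column in the analysis table).
    corr_length : spatial correlation length in cells (Gaussian kernel
        sigma); 0 gives an i.i.d. field.
    mean, sd : marginal mean and standard deviation after standardization.
    """

    name: str
    corr_length: float = 2.0
    mean: float = 0.0
    sd: float = 1.0


def _default_covariates() -> tuple[CovariateSpec, ...]:
    # marginal scales loosely typical of the US transition zone
    scales = {
        "winter_temp": (-6.0, 3.0),
        "spring_tmax": (21.0, 2.5),
        "summer_precip": (100.0, 25.0),
        "elevation": (300.0, 150.0),
        "host_basal_area": (8.0, 4.0),
        "pop_density": (40.0, 30.0),
        "wood_use": (120.0, 80.0),
        "highway_density": (0.6, 0.3),
        "anthro_frag": (0.12, 0.06),
        "natural_frag": (0.18, 0.08),
    }
    return tuple(
        CovariateSpec(name, 2.0, m, s) for name, (m, s) in scales.items()
    )


def _default_betas() -> dict[str, float]:
    # yr of extra waiting per 1 sd of the driver; warmer winters shorten
    # waits (negative beta on temperature), hot springs / wet summers /
    # fragmentation lengthen them; the rest are true nulls
    return {
        "winter_temp": -2.0,
        "spring_tmax": 1.0,
        "summer_precip": 0.8,
        "elevation": 0.5,
        "anthro_frag": 0.6,
    }


@dataclass(frozen=True)
class SimConfig:
    """Configuration for the synthetic invasion.

    Defaults emulate the monitoring-programme setting scaled down: a 20x20
    grid of 5 km quadrats observed 1985-2015, a wave spreading at 5 km/yr
    from the grid origin, a mean establishment lag of 8 yr modulated by
    covariates, and 1-4 traps per cell depending on position relative to
    the front (the real network spaces traps 0.5-2 km near the front and
    3-8 km behind it; one trap per 1.5-5 km here).
    """

    n_rows: int = 20
    n_cols: int = 20
    cell_km: float = 5.0
    start_year: int = 1985
    end_year: int = 2015
    origin: tuple[int, int] = (0, 0)  # (row, col) of the wave origin
    speed_km_yr: float = 5.0
    covariates: tuple[CovariateSpec, ...] = field(
        default_factory=_default_covariates
    )
    betas: dict[str, float] = field(default_factory=_default_betas)
    mean_lag_yr: float = 8.0
    intercept_sd_yr: float = 1.0  # level-IV random-intercept sd
    resid_sd_yr: float = 1.5  # residual lag noise
    # latent abundance (moth density per trap-equivalent area)
    plateau_abundance: float = 0.7  # mean catch during the waiting period
    growth_rate: float = 2.5  # logistic r (1/yr) after establishment
    carrying_capacity: float = 300.0
    # trapping
    traps_per_cell_front: int = 3
    traps_per_cell_behind: int = 1
    detection_scale: float = 1.0  # k: mean count = k * abundance
    nb_dispersion: float = 5.0  # NegBin size parameter theta
    treatment_fraction: float = 0.01  # area fraction treated per year
    treatment_radius_m: tuple[float, float] = (800.0, 2000.0)
    # eco-region hierarchy
    n_level2: int = 3
    level4_block: int = 5  # level-IV units are blocks of this many cells
    seed: int = 0

    def __post_init__(self) -> None:
        if self.speed_km_yr <= 0:
            raise ValueError("wave speed must be > 0")
        if not 0 <= self.treatment_fraction <= 0.02:
            raise ValueError("treatment fraction must lie in [0, 0.02]")
        for name in ("intercept_sd_yr", "resid_sd_yr"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.detection_scale < 0:
            raise ValueError("detection scale k must be >= 0")
        if self.n_level2 < 2:
            raise ValueError("need >= 2 level-II subregions")
        # each level-II band must hold >= 2 level-IV blocks
        rows_per_band = self.n_rows / self.n_level2
        if rows_per_band < 1 or self.n_rows * self.n_cols == 0:
            raise ValueError("grid too small for the eco-region hierarchy")

    @property
    def years(self) -> np.ndarray:
        return np.arange(self.start_year, self.end_year + 1)

    @property
    def cell_m(self) -> float:
        return self.cell_km * 1000.0


LEVEL2_NAMES = (
    "northern mixed wood shield",
    "central plains",
    "southeastern forests and plains",
)


@dataclass
class Landscape:
    """Covariate fields plus eco-region labels on the quadrat grid."""

    fields: dict[str, np.ndarray]  # name -> (n_rows, n_cols)
    level2: np.ndarray  # (n_rows, n_cols) of str labels
    level4: np.ndarray  # (n_rows, n_cols) of str labels
    config: SimConfig

    def labels_table(self) -> pd.DataFrame:
        rows, cols = np.indices(self.level2.shape)
        return pd.DataFrame(
            {
                "row": rows.ravel(),
                "col": cols.ravel(),
                "level2": self.level2.ravel(),
                "level4": self.level4.ravel(),
            }
        )


@dataclass
class SyntheticTruth:
    """Ground truth for the simulated invasion.

    ``arrival``, ``establishment`` and ``waiting`` are (n_rows, n_cols)
    integer arrays of years / year counts; ``abundance`` is
    (n_years, n_rows, n_cols).
    """

    arrival: np.ndarray
    establishment: np.ndarray
    waiting: np.ndarray
    abundance: np.ndarray
    betas: dict[str, float]
    intercepts: dict[str, float]  # level-IV unit -> random intercept (yr)
    config: SimConfig

    def table(self) -> pd.DataFrame:
        rows, cols = np.indices(self.arrival.shape)
        return pd.DataFrame(
            {
                "row": rows.ravel(),
                "col": cols.ravel(),
                "arrival_year": self.arrival.ravel(),
                "establishment_year": self.establishment.ravel(),
                "waiting_time": self.waiting.ravel(),
            }
        )


@dataclass(frozen=True)
class TreatmentEvent:
    """A treatment disc applied in one year (planar meters)."""

    x: float
    y: float
    radius_m: float
    year: int


def _stream(seed: int, *key: int) -> np.random.Generator:
    """Independent, reproducible RNG stream for one stage of the generator.

    All randomness flows from the single config seed; stages draw from
    SeedSequence children keyed by small integers so each stage can be
    regenerated independently.
    """
    return np.random.default_rng(np.random.SeedSequence([seed, *key]))


# ---------------------------------------------------------------------------
# landscape


def gaussian_random_field(
    shape: tuple[int, int],
    corr_length: float,
    mean: float,
    sd: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Spatially autocorrelated Gaussian field with exact marginal moments.

    White noise is smoothed with a Gaussian kernel of sigma ``corr_length``
    (cells) and re-standardized, so the marginal mean/sd are honoured for
    any correlation length; ``corr_length == 0`` returns the i.i.d. field.
    """
    white = rng.standard_normal(shape)
    if corr_length > 0:
        f = ndimage.gaussian_filter(white, sigma=corr_length, mode="wrap")
    else:
        f = white
    if sd == 0:
        return np.full(shape, float(mean))
    f = (f - f.mean()) / f.std()
    return mean + sd * f


def generate_landscape(config: SimConfig) -> Landscape:
    """Generate one covariate field per driver plus nested eco-region labels.

    Level-II subregions are horizontal bands of the grid (named after the
    three transition-zone subregions when there are three); level-IV units
    are square blocks of ``config.level4_block`` cells nested inside them.
    """
    if config.n_rows < 3 or config.n_cols < 3:
        raise ValueError(
            "grid extent below 3x3: neighborhood statistics undefined"
        )
    shape = (config.n_rows, config.n_cols)
    fields: dict[str, np.ndarray] = {}
    for i, spec in enumerate(config.covariates):
        rng = _stream(config.seed, 1, i)
        fields[spec.name] = gaussian_random_field(
            shape, spec.corr_length, spec.mean, spec.sd, rng
        )

    rows, cols = np.indices(shape)
    band = np.minimum(
        (rows * config.n_level2) // config.n_rows, config.n_level2 - 1
    )
    if config.n_level2 == len(LEVEL2_NAMES):
        names = np.array(LEVEL2_NAMES, dtype=object)
    else:
        names = np.array(
            [f"subregion_{i}" for i in range(config.n_level2)], dtype=object
        )
    level2 = names[band]
    b = config.level4_block
    block = rows // b * ((config.n_cols + b - 1) // b) + cols // b
    level4 = np.char.add(
        np.char.add(band.astype(str), "."), block.astype(str)
    ).astype(object)
    return Landscape(fields=fields, level2=level2, level4=level4, config=config)


# ---------------------------------------------------------------------------
# invasion


def simulate_invasion(landscape: Landscape, config: SimConfig) -> SyntheticTruth:
    """Run the kinematic wave and the additive lag model.

    Arrival year of a cell is start_year + round(distance-to-origin /
    speed).  The establishment lag is ``max(0, round(mu + sum beta_j x_j +
    alpha_level4 + eps))`` with x_j the driver field standardized to z-scores
    and alpha a level-IV random intercept.  Latent abundance is 0 before
    arrival, ``plateau_abundance`` from arrival to establishment, then
    logistic toward carrying capacity.
    """
    cfg = config
    shape = (cfg.n_rows, cfg.n_cols)
    rows, cols = np.indices(shape)
    r0, c0 = cfg.origin
    dist_km = np.hypot(rows - r0, cols - c0) * cfg.cell_km
    arrival = cfg.start_year + np.rint(dist_km / cfg.speed_km_yr).astype(int)

    rng = _stream(cfg.seed, 2)
    lag = np.full(shape, float(cfg.mean_lag_yr))
    for name, beta in cfg.betas.items():
        if beta == 0:
            continue
        f = landscape.fields[name]
        spec = next(s for s in cfg.covariates if s.name == name)
        z = (f - spec.mean) / spec.sd if spec.sd > 0 else np.zeros(shape)
        lag = lag + beta * z

    units = np.unique(landscape.level4)
    alphas = {
        str(u): float(a)
        for u, a in zip(units, rng.normal(0.0, cfg.intercept_sd_yr, len(units)))
    }
    for u in units:
        lag[landscape.level4 == u] += alphas[str(u)]
    lag = lag + rng.normal(0.0, cfg.resid_sd_yr, shape)
    waiting = np.maximum(0, np.rint(lag)).astype(int)
    establishment = arrival + waiting

    # abundance: plateau during the waiting phase, logistic through the
    # establishment year with its midpoint (K/2) AT establishment — the
    # establishment year marks a population already past extinction risk,
    # so the growth ramp precedes it
    years = cfg.years
    abundance = np.zeros((len(years), *shape))
    n0 = cfg.plateau_abundance
    k_cap = cfg.carrying_capacity
    for t, year in enumerate(years):
        active = year >= arrival
        tau = np.clip(year - establishment, -50, 50).astype(float)
        logistic = k_cap / (1.0 + np.exp(-cfg.growth_rate * tau))
        abundance[t] = np.where(active, np.maximum(n0, logistic), 0.0)
    return SyntheticTruth(
        arrival=arrival,
        establishment=establishment,
        waiting=waiting,
        abundance=abundance,
        betas=dict(cfg.betas),
        intercepts=alphas,
        config=cfg,
    )


# ---------------------------------------------------------------------------
# trapping


def simulate_trapping(
    truth: SyntheticTruth, landscape: Landscape, config: SimConfig
) -> tuple[pd.DataFrame, list[TreatmentEvent]]:
    """Observe the latent abundance through a pheromone-trap network.

    Cells whose arrival falls in the first half of the study period count
    as "behind the front" and get the sparse trap density; the rest get the
    dense density.  Trap positions are jittered uniformly inside their cell
    and kept fixed across years.  Counts are negative-binomial with mean
    ``k * N(cell, year)`` and size ``nb_dispersion``.  Treatment discs are
    drawn each year until the configured area fraction is reached; they
    only matter downstream through the exclusion geometry (counts are not
    suppressed).

    Returns the trap table (trap_id, x, y, year, count) and the treatment
    events.  Deterministic given (config, seed).
    """
    cfg = config
    if cfg.detection_scale < 0:
        raise ValueError("detection scale k must be >= 0")
    rng_layout = _stream(cfg.seed, 3)
    mid_year = (cfg.start_year + cfg.end_year) // 2
    cell_m = cfg.cell_m

    trap_rows = []
    trap_xy = []
    trap_cell = []
    tid = 0
    for r in range(cfg.n_rows):
        for c in range(cfg.n_cols):
            behind = truth.arrival[r, c] <= mid_year
            n_traps = (
                cfg.traps_per_cell_behind if behind else cfg.traps_per_cell_front
            )
            for _ in range(n_traps):
                x = (c + rng_layout.uniform(0.05, 0.95)) * cell_m
                y = (r + rng_layout.uniform(0.05, 0.95)) * cell_m
                trap_xy.append((x, y))
                trap_cell.append((r, c))
                trap_rows.append(tid)
                tid += 1

    rng_counts = _stream(cfg.seed, 4)
    years = cfg.years
    n_traps_total = len(trap_rows)
    records = {
        "trap_id": np.repeat(trap_rows, len(years)),
        "x": np.repeat([xy[0] for xy in trap_xy], len(years)),
        "y": np.repeat([xy[1] for xy in trap_xy], len(years)),
        "year": np.tile(years, n_traps_total),
    }
    mean = np.empty(n_traps_total * len(years))
    for i, (r, c) in enumerate(trap_cell):
        mean[i * len(years) : (i + 1) * len(years)] = (
            cfg.detection_scale * truth.abundance[:, r, c]
        )
    theta = cfg.nb_dispersion
    p = theta / (theta + mean)
    counts = np.where(
        mean > 0, rng_counts.negative_binomial(theta, np.minimum(p, 1.0)), 0
    )
    records["count"] = counts.astype(int)
    traps = pd.DataFrame(records)

    rng_treat = _stream(cfg.seed, 5)
    area_total = cfg.n_rows * cfg.n_cols * cell_m**2
    treatments: list[TreatmentEvent] = []
    for year in years:
        budget = cfg.treatment_fraction * area_total
        used = 0.0
        while True:
            radius = rng_treat.uniform(*cfg.treatment_radius_m)
            if used + np.pi * radius**2 > budget:
                break
            treatments.append(
                TreatmentEvent(
                    x=rng_treat.uniform(0, cfg.n_cols * cell_m),
                    y=rng_treat.uniform(0, cfg.n_rows * cell_m),
                    radius_m=radius,
                    year=int(year),
                )
            )
            used += np.pi * radius**2
    return traps, treatments


def simulate_all(
    config: SimConfig,
) -> tuple[Landscape, SyntheticTruth, pd.DataFrame, list[TreatmentEvent]]:
    """Convenience wrapper running the three stages in order."""
    landscape = generate_landscape(config)
    truth = simulate_invasion(landscape, config)
    traps, treatments = simulate_trapping(truth, landscape, config)
    return landscape, truth, traps, treatments


def with_seed(config: SimConfig, seed: int) -> SimConfig:
    """Copy of ``config`` with a different seed."""
    return replace(config, seed=seed)


# ---------------------------------------------------------------------------
# i/o (all plain text)


def write_traps(traps: pd.DataFrame, path: str | Path) -> None:
    traps.to_csv(path, index=False, columns=["trap_id", "x", "y", "year", "count"])


def read_traps(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_treatments(treatments: list[TreatmentEvent], path: str | Path) -> None:
    """Treatment discs as GeoJSON point features with radius_m/year."""
    features = [
        {
            "type": "Feature",
            "geometry": {"type": "Point", "coordinates": [t.x, t.y]},
            "properties": {"radius_m": t.radius_m, "year": t.year},
        }
        for t in treatments
    ]
    obj = {"type": "FeatureCollection", "features": features}
    Path(path).write_text(json.dumps(obj, indent=1))


def read_treatments(path: str | Path) -> list[TreatmentEvent]:
    obj = json.loads(Path(path).read_text())
    out = []
    for feat in obj["features"]:
        x, y = feat["geometry"]["coordinates"]
        props = feat["properties"]
        out.append(
            TreatmentEvent(
                x=float(x),
                y=float(y),
                radius_m=float(props["radius_m"]),
                year=int(props["year"]),
            )
        )
    return out


def write_truth(truth: SyntheticTruth, path: str | Path) -> None:
    truth.table().to_csv(path, index=False)


def write_covariate_layer(layer: np.ndarray, path: str | Path) -> None:
    np.savetxt(path, layer)


def read_covariate_layer(path: str | Path) -> np.ndarray:
    return np.loadtxt(path)
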