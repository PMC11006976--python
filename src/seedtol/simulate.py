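"""Synthetic multi-population seed germination study generator.

Emulates the design the analyses assume: 21 source populations across an
arid high-plateau envelope (35.83-38.32 deg N, 90.86-102.76 deg E,
1,866-3,832 m a.s.l., MAP 67-427 mm, MAT -1.5 to 8.3 deg C), three
replicate seed lots per population, and three five-level stress
experiments (drought, cold, saline) with 50-seed dishes counted daily for
up to 15 days.

The causal structure is a linear-Gaussian version of the path diagram the
downstream analyses fit: geography drives climate; climate drives soil
chemistry; latent soil and climate composites drive the seed morphology
and seed nutrient blocks; and a per-population latent stress tolerance,
one per experiment, is a linear function of the climate/soil/morphology/
nutrient composites.  Germination follows a discrete daily-hazard model:
a seed still dormant on day d germinates with probability
``base_hazard * exp(tolerance_scale * latent) * exp(-sensitivity * severity)``
(clipped to [0, 1]) where severity is the treatment level's normalized
harshness.  The latent tolerance enters the hazard, never the index
arithmetic, so the weighted-index computation is tested against data it
did not generate.

Direct trait-on-geography effects default to zero — gradient patterns
emerge through the environment — but a ``gradient_effects`` map lets tests
inject known slopes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .errors import InvalidInputError
from .germination import GerminationTrial, TreatmentScheme

GEO_ENVELOPE = {
    "latitude": (35.83, 38.32),
    "longitude": (90.86, 102.76),
    "altitude": (1866.0, 3832.0),
}
CLIMATE_RANGES = {"MAT": (-1.5, 8.3), "MAP": (67.0, 427.0)}

#: natural-unit (location, scale) used to map z-scale traits to measurements
TRAIT_UNITS = {
    "length": (3.31, 0.52), "width": (1.00, 0.11), "TGW": (0.55, 0.12),
    "CSP": (28.16, 3.6), "CSS": (28.45, 6.8), "CS": (49.12, 5.6),
    "CCF": (0.21, 0.037),
}
SOIL_UNITS = {"SOC": (10.0, 4.0), "AN": (80.0, 30.0), "AP": (8.0, 3.0), "pH": (8.2, 0.4)}
SOIL_LOADINGS = {"SOC": 0.8, "AN": 0.7, "AP": 0.6, "pH": -0.6}
MORPH_LOADINGS = {"length": 0.7, "width": 0.6, "TGW": 0.8}
NUTRIENT_LOADINGS = {"CSP": 0.8, "CSS": 0.6, "CS": 0.7, "CCF": 0.6}

#: composite-level structural coefficients (edge -> standardized value)
DEFAULT_STRUCTURE = {
    ("climate", "soil"): 0.5,
    ("soil", "morphology"): 0.6,
    ("climate", "nutrients"): 0.5,
    ("soil", "nutrients"): 0.4,
    ("climate", "GDTI"): 0.35,
    ("morphology", "GDTI"): 0.55,
    ("climate", "GCTI"): 0.35,
    ("soil", "GCTI"): 0.25,
    ("nutrients", "GCTI"): 0.5,
    ("climate", "GSTI"): 0.35,
    ("morphology", "GSTI"): 0.55,
}

EXPERIMENT_FOR_INDEX = {"GDTI": "drought", "GCTI": "cold", "GSTI": "saline"}


@dataclass
class SimulationConfig:
    """Study-design and causal parameters of the generator."""

    n_populations: int = 21
    n_replicates: int = 3
    seeds_per_dish: int = 50
    n_days: int = 15
    random_seed: int = 0
    structural_coefficients: dict = field(default_factory=lambda: dict(DEFAULT_STRUCTURE))
    gradient_effects: dict = field(default_factory=dict)  # trait -> {lat/lon/alt: slope}
    noise_sds: dict = field(
        default_factory=lambda: {
            "climate": 0.4,        # z-scale noise on MAT/MAP around their geographic trend
            "soil": 0.6,           # unique noise of each soil variable
            "trait_population": 0.5,
            "trait_replicate": 0.3,
            "tolerance": 0.4,
        }
    )
    stress_sensitivity: dict = field(
        default_factory=lambda: {"drought": 2.5, "cold": 2.0, "saline": 2.0}
    )
    base_hazard: float = 0.35
    tolerance_scale: float = 0.5
    apply_stop_rule: bool = False  # terminate after 5 consecutive zero-count days
    scheme: TreatmentScheme = field(default_factory=TreatmentScheme)

    def __post_init__(self) -> None:
        if self.n_populations < 3:
            raise InvalidInputError("need at least 3 populations")
        if any(sd <= 0 for sd in self.noise_sds.values()):
            raise InvalidInputError("all noise SDs must be positive")
        if not 0.0 <= self.base_hazard <= 1.0:
            raise InvalidInputError("base_hazard must lie in [0, 1]")

    def coeff(self, src: str, dst: str) -> float:
        return float(self.structural_coefficients.get((src, dst), 0.0))


def _zscore(x: np.ndarray) -> np.ndarray:
    sd = x.std(ddof=1)
    return (x - x.mean()) / sd if sd > 0 else np.zeros_like(x)


def generate_sites(config: SimulationConfig, rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Site table: geography uniform in the envelope, climate linear in
    geography, soil chemistry driven by the climate composite."""
    rng = rng or np.random.default_rng(config.random_seed)
    n = config.n_populations
    lat = rng.uniform(*GEO_ENVELOPE["latitude"], n)
    lon = rng.uniform(*GEO_ENVELOPE["longitude"], n)
    alt = rng.uniform(*GEO_ENVELOPE["altitude"], n)
    z_lat, z_lon, z_alt = _zscore(lat), _zscore(lon), _zscore(alt)

    sd_c = config.noise_sds["climate"]
    # MAT falls with altitude and latitude; MAP rises eastward
    mat = 3.4 - 2.2 * z_alt - 0.5 * z_lat + rng.normal(0, sd_c * 0.75, n)
    mat = np.clip(mat, *CLIMATE_RANGES["MAT"])
    map_ = 247.0 + 104.0 * z_lon + rng.normal(0, sd_c * 45.0, n)
    map_ = np.clip(map_, *CLIMATE_RANGES["MAP"])

    s_clim = _zscore(_zscore(mat) + _zscore(map_))
    g_cs = config.coeff("climate", "soil")
    sd_s = config.noise_sds["soil"]
    s_soil = g_cs * s_clim + np.sqrt(max(1.0 - g_cs**2, 0.0)) * rng.normal(0, 1, n)
    sites = pd.DataFrame(
        {
            "population_id": [f"P{i + 1:02d}" for i in range(n)],
            "latitude": lat,
            "longitude": lon,
            "altitude": alt,
            "MAT": mat,
            "MAP": map_,
        }
    )
    for var, loading in SOIL_LOADINGS.items():
        z = loading * s_soil + np.sqrt(max(1.0 - loading**2, 0.0)) * rng.normal(0, sd_s, n)
        loc, scale = SOIL_UNITS[var]
        sites[var] = np.maximum(loc + scale * z, 0.01)
    return sites


def _composites(sites: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    s_clim = _zscore(_zscore(sites["MAT"].to_numpy()) + _zscore(sites["MAP"].to_numpy()))
    soil_z = sum(
        np.sign(SOIL_LOADINGS[v]) * _zscore(sites[v].to_numpy()) for v in SOIL_LOADINGS
    )
    return s_clim, _zscore(soil_z)


def generate_traits(
    sites: pd.DataFrame, config: SimulationConfig, rng: np.random.Generator | None = None
) -> pd.DataFrame:
    """Replicate-level trait table with population random intercepts.

    Returns one row per (population_id, replicate) carrying the 8 seed
    traits plus the per-population latent stress tolerances (columns
    ``latent_tolerance_<experiment>``) consumed by
    :func:`generate_germination`.  Replicate draws that would produce a
    non-positive measurement are resampled (with a warning counting them).
    """
    rng = rng or np.random.default_rng(config.random_seed + 1)
    n = len(sites)
    s_clim, s_soil = _composites(sites)
    sd_pop = config.noise_sds["trait_population"]
    sd_rep = config.noise_sds["trait_replicate"]

    g_sm = config.coeff("soil", "morphology")
    s_morph = g_sm * s_soil + np.sqrt(max(1.0 - g_sm**2, 0.0)) * rng.normal(0, 1, n)
    g_cn, g_sn = config.coeff("climate", "nutrients"), config.coeff("soil", "nutrients")
    resid = max(1.0 - g_cn**2 - g_sn**2, 0.04)
    s_nut = g_cn * s_clim + g_sn * s_soil + np.sqrt(resid) * rng.normal(0, 1, n)

    geo_z = {
        "lat": _zscore(sites["latitude"].to_numpy()),
        "lon": _zscore(sites["longitude"].to_numpy()),
        "alt": _zscore(sites["altitude"].to_numpy()),
    }

    block_score = {**{t: s_morph for t in MORPH_LOADINGS}, **{t: s_nut for t in NUTRIENT_LOADINGS}}
    loadings = {**MORPH_LOADINGS, **NUTRIENT_LOADINGS}
    pop_z = {}
    for trait, loading in loadings.items():
        drift = sum(
            slope * geo_z[g]
            for g, slope in config.gradient_effects.get(trait, {}).items()
        )
        pop_z[trait] = (
            loading * block_score[trait]
            + drift
            + sd_pop * rng.normal(0, 1, n)
        )

    composites = {"climate": s_clim, "soil": s_soil, "morphology": s_morph, "nutrients": s_nut}
    sd_tol = config.noise_sds["tolerance"]
    latent = {}
    for index, experiment in EXPERIMENT_FOR_INDEX.items():
        signal = sum(
            config.coeff(block, index) * composites[block] for block in composites
        )
        latent[experiment] = signal + sd_tol * rng.normal(0, 1, n)

    rows = []
    resampled = 0
    for i, pop in enumerate(sites["population_id"]):
        for rep in range(1, config.n_replicates + 1):
            row = {"population_id": pop, "replicate": rep}
            for trait in loadings:
                loc, scale = TRAIT_UNITS[trait]
                value = loc + scale * (pop_z[trait][i] + sd_rep * rng.normal())
                tries = 0
                while value <= 0 and tries < 100:
                    value = loc + scale * (pop_z[trait][i] + sd_rep * rng.normal())
                    tries += 1
                    resampled += 1
                if value <= 0:
                    raise InvalidInputError(
                        f"cannot draw a positive value for {trait} in {pop}"
                    )
                row[trait] = value
            row["LWR"] = row["length"] / row["width"]
            for experiment, values in latent.items():
                row[f"latent_tolerance_{experiment}"] = values[i]
            rows.append(row)
    if resampled:
        warnings.warn(f"resampled {resampled} non-positive trait draws", stacklevel=2)
    columns = [
        "population_id", "replicate", "length", "width", "LWR", "TGW",
        "CSP", "CSS", "CS", "CCF",
        "latent_tolerance_drought", "latent_tolerance_cold", "latent_tolerance_saline",
    ]
    return pd.DataFrame(rows)[columns]


def _severity(experiment: str, level_index: int, scheme: TreatmentScheme) -> float:
    """Normalized harshness in [0, 1]: 0 at the control, 1 at the harshest level."""
    value = scheme.levels(experiment)[level_index - 1]
    if experiment == "drought":
        return abs(value) / abs(scheme.drought_levels[-1])
    if experiment == "cold":
        t1 = scheme.reference_temperature
        return (t1 - value) / (t1 - scheme.cold_levels[-1])
    return value / scheme.saline_levels[-1]


def generate_germination(
    traits: pd.DataFrame, config: SimulationConfig, rng: np.random.Generator | None = None
) -> list[GerminationTrial]:
    """Dish-level daily germination counts from the discrete-hazard model."""
    rng = rng or np.random.default_rng(config.random_seed + 2)
    scheme = config.scheme
    pops = traits.drop_duplicates("population_id")
    trials: list[GerminationTrial] = []
    for _, pop_row in pops.iterrows():
        pop = pop_row["population_id"]
        for experiment in ("drought", "cold", "saline"):
            latent = float(pop_row[f"latent_tolerance_{experiment}"])
            tol_mult = float(np.exp(config.tolerance_scale * latent))
            sens = config.stress_sensitivity[experiment]
            for level_index in range(1, 6):
                sev = _severity(experiment, level_index, scheme)
                hazard = config.base_hazard * tol_mult * float(np.exp(-sens * sev))
                hazard = min(max(hazard, 0.0), 1.0)
                for rep in range(1, config.n_replicates + 1):
                    remaining = config.seeds_per_dish
                    counts = []
                    for _day in range(config.n_days):
                        n_new = int(rng.binomial(remaining, hazard)) if remaining else 0
                        counts.append(n_new)
                        remaining -= n_new
                    if config.apply_stop_rule:
                        counts = _apply_stop_rule(counts)
                    trials.append(
                        GerminationTrial(
                            population_id=pop,
                            experiment=experiment,
                            level_index=level_index,
                            level_value=scheme.levels(experiment)[level_index - 1],
                            replicate=rep,
                            daily_counts=tuple(counts),
                            seeds_per_dish=config.seeds_per_dish,
                        )
                    )
    return trials


def _apply_stop_rule(counts: list[int], window: int = 5) -> list[int]:
    """Truncate the series after the first run of `window` zero-count days."""
    zeros = 0
    for day, n in enumerate(counts, start=1):
        zeros = zeros + 1 if n == 0 else 0
        if zeros == window:
            return counts[:day]
    return counts


def trials_to_frame(trials) -> pd.DataFrame:
    """Long dish-day table (one row per observed day)."""
    rows = [
        {
            "population_id": t.population_id,
            "experiment": t.experiment,
            "level_index": t.level_index,
            "level_value": t.level_value,
            "replicate": t.replicate,
            "day": day,
            "n_germinated": n,
        }
        for t in trials
        for day, n in enumerate(t.daily_counts, start=1)
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "population_id", "experiment", "level_index", "level_value",
            "replicate", "day", "n_germinated",
        ],
    )


def simulate_study(config: SimulationConfig | None = None):
    """Generate (sites, traits, trials) for one full synthetic study."""
    config = config or SimulationConfig()
    rng = np.random.default_rng(config.random_seed)
    sites = generate_sites(config, rng)
    traits = generate_traits(sites, config, rng)
    trials = generate_germination(traits, config, rng)
    return sites, traits, trials
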