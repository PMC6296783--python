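"""Synthetic grassland-experiment generator.

Emulates a long-running split-plot biodiversity experiment: 16 herbaceous
species from four functional groups sown at richness 1, 4, 9, or 16 into
364 plots nested in six rings, with ring-level CO2 enrichment crossed
with plot-level N addition (32/32/15/12 replicates per richness level in
each of the four CO2 x N cells, i.e. 91 plots per cell).

The generator produces every input the analysis pipeline consumes —
design table, plot x species covers, species x trait matrix, plot x
function table, and raw hourly respiration series — with the statistical
structure the downstream analyses assume:

* log-linear positive richness effects on root biomass, respiration, and
  microbial biomass C, and a weak effect on aggregate stability;
* ring-level block variation and small CO2/N offsets;
* a shared latent factor coupling respiration and microbial biomass C
  (their only strong pairwise correlation) while other function pairs
  stay near-independent;
* community evenness that erodes under resource addition (Dirichlet
  covers whose concentration drops under enriched N and, more mildly,
  elevated CO2) and per-species extinctions whose odds rise with sown
  richness and N addition.

Effect sizes default to the magnitudes implied by the motivating
experiment's published F tables (see docs/methods.md); all randomness
derives from the single ``SimulationParams.seed``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .assays import RespirationSeries
from .errors import InvalidInputError

__all__ = [
    "SpeciesPool",
    "FunctionParams",
    "SimulationParams",
    "FUNCTION_NAMES",
    "build_species_pool",
    "generate_design",
    "generate_traits",
    "generate_covers",
    "generate_soil_functions",
    "generate_respiration_series",
]

FUNCTION_NAMES = ("root_biomass", "respiration", "microbial_biomass_c", "wsa")

_POOL = {
    "C3 grass": (
        "Agropyron repens",
        "Bromus inermis",
        "Koeleria cristata",
        "Poa pratensis",
    ),
    "C4 grass": (
        "Andropogon gerardii",
        "Bouteloua gracilis",
        "Schizachyrium scoparium",
        "Sorghastrum nutans",
    ),
    "forb": (
        "Achillea millefolium",
        "Anemone cylindrica",
        "Asclepias tuberosa",
        "Solidago rigida",
    ),
    "legume": (
        "Amorpha canescens",
        "Lespedeza capitata",
        "Lupinus perennis",
        "Petalostemum villosum",
    ),
}

# Functional-group trait centroids: height (cm), SLA (mm2/mg), LDMC (mg/g),
# leaf N (%), seed mass (mg). Groups separate in trait space by construction.
_GROUP_TRAITS = {
    "C3 grass": (70.0, 20.0, 280.0, 2.0, 1.5),
    "C4 grass": (120.0, 12.0, 330.0, 1.2, 2.0),
    "forb": (80.0, 15.0, 220.0, 2.2, 3.0),
    "legume": (60.0, 18.0, 240.0, 3.5, 8.0),
}
TRAIT_NAMES = ("height", "sla", "ldmc", "leaf_n", "seed_mass")


@dataclass(frozen=True)
class SpeciesPool:
    """The 16-species pool: names and functional-group membership."""

    species: tuple[str, ...]
    groups: dict[str, str]  # species -> functional group

    def group_members(self, group: str) -> list[str]:
        return [s for s in self.species if self.groups[s] == group]


@dataclass
class FunctionParams:
    """Linear generating model for one soil function.

    ``y = mu + slope * ln(richness) + co2 * [elevated] + n * [enriched]
    + ring effect + latent * u + eps`` with ring effects N(0, ring_sd^2)
    per ring and eps N(0, resid_sd^2) redrawn until the value is valid
    (positive; within [0, 1] for the aggregate fraction).
    """

    mu: float
    slope: float
    co2: float
    n: float
    ring_sd: float
    resid_sd: float
    latent: float = 0.0

    def __post_init__(self) -> None:
        if self.ring_sd < 0 or self.resid_sd < 0:
            raise InvalidInputError("standard deviations must be >= 0")


def _default_functions() -> dict[str, FunctionParams]:
    return {
        # g m^-2
        "root_biomass": FunctionParams(300.0, 120.0, 10.0, 15.0, 30.0, 228.0),
        # ul O2 h^-1 g^-1 dry soil
        "respiration": FunctionParams(1.2, 0.145, 0.02, 0.04, 0.12, 0.33, latent=0.40),
        # ug C g^-1 dry soil
        "microbial_biomass_c": FunctionParams(200.0, 42.0, 5.0, 8.0, 10.0, 41.0, latent=67.5),
        # fraction of water-stable aggregates
        "wsa": FunctionParams(0.55, 0.009, 0.002, 0.004, 0.07, 0.056),
    }


@dataclass
class SimulationParams:
    """All knobs of the synthetic experiment; defaults are the study
    conditions the downstream analyses are validated against."""

    seed: int = 0
    replicates: tuple[int, int, int, int] = (32, 32, 15, 12)
    richness_levels: tuple[int, int, int, int] = (1, 4, 9, 16)
    functions: dict[str, FunctionParams] = field(default_factory=_default_functions)
    # Dirichlet concentration and its multiplicative erosion under treatments
    alpha0: float = 2.0
    alpha_mult_n: float = 0.5
    alpha_mult_co2: float = 0.8
    # per-species extinction: logit(p) = a + b * sown richness + c * [N]
    ext_intercept: float = -4.0
    ext_richness: float = 0.15
    ext_n: float = 0.5
    # traits: lognormal within-group scatter (sd on the log scale)
    trait_log_sd: float = 0.12
    # glucose-amended respiration series template
    series_trough: float = 2.0
    series_disturbance: float = 3.0
    series_growth: float = 6.0
    series_noise_sd: float = 0.15

    def __post_init__(self) -> None:
        if self.alpha0 <= 0:
            raise InvalidInputError("alpha0 must be > 0")
        if any(r < 1 for r in self.replicates):
            raise InvalidInputError("replicate counts must be >= 1")


def _rng(params: SimulationParams, stream: int) -> np.random.Generator:
    """Independent, reproducible substream per generator stage."""
    return np.random.default_rng(np.random.SeedSequence(params.seed, spawn_key=(stream,)))


def build_species_pool() -> SpeciesPool:
    """The fixed 16-species pool (four species per functional group)."""
    species = tuple(s for members in _POOL.values() for s in members)
    groups = {s: g for g, members in _POOL.items() for s in members}
    return SpeciesPool(species=species, groups=groups)


def _choose_species(
    pool: SpeciesPool, richness: int, target_groups: int, rng: np.random.Generator
) -> tuple[str, ...]:
    """Random species set of the given richness spanning target_groups
    functional groups (each chosen group contributes >= 1 species)."""
    group_names = list(_POOL)
    chosen_groups = list(rng.choice(group_names, size=target_groups, replace=False))
    # one guaranteed pick per group, remainder drawn from the chosen groups' pool
    picks: list[str] = []
    for g in chosen_groups:
        members = pool.group_members(g)
        picks.append(members[rng.integers(len(members))])
    remaining = [
        s for g in chosen_groups for s in pool.group_members(g) if s not in picks
    ]
    extra = richness - len(picks)
    if extra > len(remaining):
        raise InvalidInputError(
            f"cannot draw {richness} species from {target_groups} groups"
        )
    if extra:
        picks += list(rng.choice(remaining, size=extra, replace=False))
    return tuple(sorted(picks))


def generate_design(params: SimulationParams) -> pd.DataFrame:
    """Full plot list of the synthetic experiment.

    Rings 1-3 run ambient CO2 and rings 4-6 elevated; plots are allocated
    round-robin to the rings of their CO2 level (the plots carry no
    spatial structure, so only the counts per ring matter). Within each
    CO2 x N cell, each richness
    level gets its replicate count; monocultures cover every species
    (each species replicated equally when the count allows), 4-species
    mixtures cycle through 1-4 functional groups, 9-species mixtures
    carry at least three groups, and 16-species plots the whole pool.

    Returns a DataFrame indexed by ``plot_id`` with columns ``ring``,
    ``co2``, ``n``, ``sown_richness``, ``sown_species`` (tuple), and
    ``n_functional_groups``.
    """
    rng = _rng(params, stream=0)
    pool = build_species_pool()
    rows = []
    counter = 0
    for co2 in ("ambient", "elevated"):
        rings = (1, 2, 3) if co2 == "ambient" else (4, 5, 6)
        for n_level in ("ambient", "enriched"):
            for richness, reps in zip(params.richness_levels, params.replicates):
                for i in range(reps):
                    counter += 1
                    ring = rings[counter % 3]
                    if richness == 1:
                        species = (pool.species[i % 16],)
                    elif richness == len(pool.species):
                        species = tuple(sorted(pool.species))
                    elif richness == 4:
                        species = _choose_species(pool, 4, 1 + i % 4, rng)
                    else:
                        target = 4 if rng.random() < 0.85 else 3
                        species = _choose_species(pool, richness, target, rng)
                    groups = {pool.groups[s] for s in species}
                    rows.append(
                        {
                            "plot_id": f"P{counter:03d}",
                            "ring": ring,
                            "co2": co2,
                            "n": n_level,
                            "sown_richness": richness,
                            "sown_species": species,
                            "n_functional_groups": len(groups),
                        }
                    )
    return pd.DataFrame(rows).set_index("plot_id")


def generate_traits(pool: SpeciesPool, params: SimulationParams) -> pd.DataFrame:
    """Species x trait matrix: lognormal scatter around functional-group
    centroids, so groups separate in trait space and all values are
    strictly positive."""
    rng = _rng(params, stream=1)
    rows = {}
    for s in pool.species:
        centroid = np.array(_GROUP_TRAITS[pool.groups[s]])
        rows[s] = centroid * np.exp(rng.normal(0.0, params.trait_log_sd, size=len(centroid)))
    out = pd.DataFrame.from_dict(rows, orient="index", columns=TRAIT_NAMES)
    out.index.name = "species"
    return out


def _sigmoid(x: float) -> float:
    return 1.0 / (1.0 + np.exp(-x))


def generate_covers(design: pd.DataFrame, params: SimulationParams) -> pd.DataFrame:
    """Plot x species relative covers.

    Each sown species first survives or goes locally extinct (Bernoulli,
    logit-linear in sown richness and N addition); surviving species
    receive covers from a symmetric Dirichlet whose concentration
    ``alpha0`` shrinks multiplicatively under enriched N and elevated
    CO2, eroding evenness under resource addition. Rows sum to 1 unless
    every sown species went extinct (all-zero row).
    """
    rng = _rng(params, stream=2)
    pool = build_species_pool()
    covers = pd.DataFrame(
        0.0, index=design.index, columns=list(pool.species)
    )
    for pid, row in design.iterrows():
        p_ext = _sigmoid(
            params.ext_intercept
            + params.ext_richness * row["sown_richness"]
            + params.ext_n * (row["n"] == "enriched")
        )
        survivors = [s for s in row["sown_species"] if rng.random() >= p_ext]
        if not survivors:
            continue
        alpha = params.alpha0
        if row["n"] == "enriched":
            alpha *= params.alpha_mult_n
        if row["co2"] == "elevated":
            alpha *= params.alpha_mult_co2
        if len(survivors) == 1:
            covers.loc[pid, survivors[0]] = 1.0
        else:
            covers.loc[pid, survivors] = rng.dirichlet(np.full(len(survivors), alpha))
    covers.index.name = "plot_id"
    return covers


def generate_soil_functions(design: pd.DataFrame, params: SimulationParams) -> pd.DataFrame:
    """Plot x function table from the log-linear generating model.

    Respiration and microbial biomass C load on a shared standard-normal
    latent factor per plot, producing their (and only their) strong
    pairwise correlation. Residuals are redrawn, not clipped, when a
    draw falls outside the function's valid range, so the distribution
    keeps no point mass at the boundary.
    """
    rng = _rng(params, stream=3)
    ring_ids = sorted(design["ring"].unique())
    latent = rng.normal(0.0, 1.0, size=len(design))
    ln_r = np.log(design["sown_richness"].to_numpy(dtype=float))
    elevated = (design["co2"] == "elevated").to_numpy()
    enriched = (design["n"] == "enriched").to_numpy()
    ring_idx = design["ring"].map({r: i for i, r in enumerate(ring_ids)}).to_numpy()
    columns = {}
    for f, fp in params.functions.items():
        ring_eff = rng.normal(0.0, fp.ring_sd, size=len(ring_ids))
        mean = (
            fp.mu
            + fp.slope * ln_r
            + fp.co2 * elevated
            + fp.n * enriched
            + ring_eff[ring_idx]
            + fp.latent * latent
        )
        y = mean + rng.normal(0.0, fp.resid_sd, size=len(mean))
        upper = 1.0 if f == "wsa" else np.inf
        if fp.resid_sd > 0:
            bad = ~((y > 0.0) & (y < upper))
            while bad.any():
                y[bad] = mean[bad] + rng.normal(0.0, fp.resid_sd, size=int(bad.sum()))
                bad = ~((y > 0.0) & (y < upper))
        columns[f] = y
    out = pd.DataFrame(columns, index=design.index)
    out.index.name = "plot_id"
    return out


def generate_respiration_series(
    params: SimulationParams, glucose: bool = True
) -> "RespirationSeries":
    """24 hourly O2-consumption values shaped like a glucose-amended run:
    an initial disturbance peak, a trough within the first 10 h, and a
    late microbial growth peak. With ``series_noise_sd = 0`` the series
    equals the deterministic template (trough value known by
    construction)."""
    rng = _rng(params, stream=4)
    hours = np.arange(1, 25, dtype=float)
    template = (
        params.series_trough
        + params.series_disturbance * np.exp(-(hours - 1.0) / 2.0)
        + params.series_growth / (1.0 + np.exp(-(hours - 16.0) / 2.0))
    )
    if not glucose:
        template = np.full(24, params.series_trough)
    series = template + rng.normal(0.0, params.series_noise_sd, size=24)
    return RespirationSeries(rates=np.clip(series, 0.0, None), glucose=glucose)
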