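"""Scenario presets and fixture generators.

Every stage of the pipeline is testable without external data through
three named presets and a dominant-marker generator:

* ``"marseille-like"`` — the full study geometry: four 18 km x 4 km
  transects radiating from the city centre, each split into three 6 km
  zones (high/medium/low urban density, 12 zones), 100 habitat sites per
  zone plus 550 filler sites between the transects.  Per-zone impervious
  and green fractions are drawn uniformly inside per-level ranges
  typical of a Mediterranean city region (high: 56–59% impervious /
  3–7% green; medium: 8–41% / 16–26%; low: 3–13% / 36–66%); forest
  and remaining covers fill
  the rest proportionally within their ranges.  The raster uses 25 m
  pixels so the full geometry stays tractable.
* ``"single-transect-small"`` — one short transect at reduced extent for
  fast tests.
* ``"two-patch-toy"`` — two green patches separated by an impassable
  wall of tall buildings; hand-sized for exhaustive oracle checks.

:func:`make_dominant_dataset` emulates the layout of the empirical
AFLP table (by default 366 presence/absence markers over 36 sites along
a transect) with a controllable urban-gradient diversity signal.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from . import landscape as lc
from .landscape import (
    CompositionSpec,
    LandCoverRaster,
    ResistanceTable,
    SiteSet,
    Zone,
    build_resistance,
    define_zones,
    extract_green_patches,
    generate_landcover,
    place_sites,
)
from .simulator import SimulationParams

__all__ = [
    "Scenario",
    "ScenarioSpec",
    "PRESETS",
    "make_scenario",
    "make_dominant_dataset",
    "DominantDataset",
    "zone_composition",
]

# Per-level land-cover ranges (% of zone area): impervious, green,
# forest, other (water + mixed + open).
LEVEL_RANGES: Mapping[str, Mapping[str, tuple[float, float]]] = {
    "high": {"impervious": (56, 59), "green": (3, 7), "forest": (10, 22), "other": (15, 30)},
    "medium": {"impervious": (8, 41), "green": (16, 26), "forest": (19, 46), "other": (17, 32)},
    "low": {"impervious": (3, 13), "green": (36, 66), "forest": (21, 37), "other": (3, 28)},
}

# Fixed within-group class splits (fractions of the group), chosen once as
# realistic for a dense Mediterranean city.
IMPERVIOUS_SPLIT = {
    lc.ROADS: 0.33,
    lc.BUILDING_LT2: 0.07,
    lc.BUILDING_2_5: 0.12,
    lc.BUILDING_5_10: 0.18,
    lc.BUILDING_GE10: 0.30,
}
GREEN_SPLIT = {lc.GRASSLAND: 0.70, lc.PARK: 0.30}
OTHER_SPLIT = {lc.OPEN: 0.50, lc.MIXED: 0.30, lc.WATER: 0.20}

# Patch correlation length (m) and field roughness per urbanisation
# level, calibrated to the green-space structure of such a region:
# downtown green concentrates in discrete parks separated by wide urban
# matrix; the suburban belt is a fine-grained mosaic of small fragments
# (mean entity around 600 m²) in permeable fabric; rural zones hold one
# large contiguous green network (entities on the km² scale).
PATCH_SCALE = {"high": 40.0, "medium": 250.0, "low": 350.0}
ROUGHNESS = {"high": 0.0, "medium": 0.45, "low": 0.15}
BACKGROUND_PATCH_SCALE = 350.0
BACKGROUND_ROUGHNESS = 0.15

# Inter-transect (rural) background composition, class-code fractions.
BACKGROUND_FRACTIONS = {
    lc.GRASSLAND: 0.28,
    lc.PARK: 0.12,
    lc.FOREST: 0.25,
    lc.OPEN: 0.15,
    lc.MIXED: 0.08,
    lc.WATER: 0.04,
    lc.ROADS: 0.05,
    lc.BUILDING_LT2: 0.01,
    lc.BUILDING_2_5: 0.01,
    lc.BUILDING_5_10: 0.005,
    lc.BUILDING_GE10: 0.005,
}


def zone_composition(level: str, rng: np.random.Generator) -> dict[int, float]:
    """Draw a per-class composition for a zone of the given level.

    Impervious and green fractions are drawn uniformly inside the
    per-level ranges and kept exactly; forest and "other" are drawn in
    their ranges and rescaled to fill the remainder.
    """
    ranges = LEVEL_RANGES[level]
    imperv = rng.uniform(*ranges["impervious"]) / 100.0
    green = rng.uniform(*ranges["green"]) / 100.0
    forest0 = rng.uniform(*ranges["forest"]) / 100.0
    other0 = rng.uniform(*ranges["other"]) / 100.0
    remainder = max(0.0, 1.0 - imperv - green)
    scale = remainder / (forest0 + other0)
    forest, other = forest0 * scale, other0 * scale
    fractions: dict[int, float] = {}
    for code, share in IMPERVIOUS_SPLIT.items():
        fractions[code] = imperv * share
    for code, share in GREEN_SPLIT.items():
        fractions[code] = green * share
    fractions[lc.FOREST] = forest
    for code, share in OTHER_SPLIT.items():
        fractions[code] = fractions.get(code, 0.0) + other * share
    return fractions


@dataclass(frozen=True)
class ScenarioSpec:
    """Fully determined inputs of one scenario preset (given a seed)."""

    name: str
    n_transects: int
    transect_length: float
    width: float
    pixel_size: float
    n_sites_per_zone: int
    n_filler_sites: int
    params: SimulationParams


PRESETS: dict[str, ScenarioSpec] = {
    "marseille-like": ScenarioSpec(
        name="marseille-like",
        n_transects=4,
        transect_length=18_000.0,
        width=4_000.0,
        pixel_size=25.0,
        n_sites_per_zone=100,
        n_filler_sites=550,
        params=SimulationParams(),
    ),
    "single-transect-small": ScenarioSpec(
        name="single-transect-small",
        n_transects=1,
        transect_length=3_600.0,
        width=1_200.0,
        pixel_size=20.0,
        n_sites_per_zone=20,
        n_filler_sites=20,
        params=SimulationParams(n_loci=100, n_runs=3, n_generations=30),
    ),
}


@dataclass
class Scenario:
    """A reproducible simulation bundle.

    Binds the land-cover raster, its resistance surface, the habitat
    sites (with zone memberships) and the simulation parameters for one
    preset and seed.
    """

    name: str
    seed: int
    raster: LandCoverRaster
    resistance_table: ResistanceTable
    resistance: np.ndarray
    zones: list[Zone]
    sites: SiteSet
    params: SimulationParams


def _build_gradient_scenario(spec: ScenarioSpec, seed: int) -> Scenario:
    rng = np.random.default_rng(seed)
    zones = define_zones(
        n_transects=spec.n_transects,
        transect_length=spec.transect_length,
        width=spec.width,
    )
    # composition specs: zones first (claim their rectangles), rural
    # background claims the rest
    comp_specs = [
        CompositionSpec(
            fractions=zone_composition(z.level, rng),
            patch_scale=PATCH_SCALE[z.level],
            region=z,
            roughness=ROUGHNESS[z.level],
        )
        for z in zones
    ]
    comp_specs.append(
        CompositionSpec(
            fractions=dict(BACKGROUND_FRACTIONS),
            patch_scale=BACKGROUND_PATCH_SCALE,
            region=None,
            roughness=BACKGROUND_ROUGHNESS,
        )
    )
    pad = 2 * spec.pixel_size
    if spec.n_transects == 1:
        extent = (
            -pad,
            -spec.width / 2 - pad,
            spec.transect_length + pad,
            spec.width / 2 + pad,
        )
    else:
        r = spec.transect_length + pad
        extent = (-r, -r, r, r)
    raster = generate_landcover(comp_specs, extent, spec.pixel_size, rng)
    table = ResistanceTable.default()
    resistance = build_resistance(raster, table)
    patches = extract_green_patches(raster)

    # Zones are processed in order; sites already placed by an earlier
    # zone that fall inside a later zone's rectangle count toward (and
    # join) that zone too, so every zone has exactly n_sites_per_zone
    # members and downtown sites are shared between overlapping zones.
    placed_xy = np.empty((0, 2))
    memberships: list[list[str]] = []
    next_id = 0
    for z in zones:
        if len(placed_xy):
            inside = np.nonzero(z.contains(placed_xy[:, 0], placed_xy[:, 1]))[0]
            for i in inside:
                memberships[i].append(z.id)
        part = place_sites(
            patches,
            z,
            spec.n_sites_per_zone,
            rng,
            existing_xy=placed_xy,
            id_start=next_id,
        )
        next_id += len(part)
        placed_xy = np.vstack([placed_xy, part.xy])
        memberships.extend([z.id] for _ in range(len(part)))
    if spec.n_filler_sites:
        filler = _place_filler_sites(
            raster, zones, spec.n_filler_sites, rng, id_start=next_id,
            exclude_xy=placed_xy,
        )
        placed_xy = np.vstack([placed_xy, filler.xy])
        memberships.extend([] for _ in range(len(filler)))
    sites = SiteSet(
        np.arange(len(placed_xy)),
        placed_xy,
        [tuple(m) for m in memberships],
    )
    return Scenario(
        spec.name, seed, raster, table, resistance, zones, sites, spec.params
    )


def _place_filler_sites(
    raster: LandCoverRaster,
    zones: Sequence[Zone],
    n: int,
    rng: np.random.Generator,
    id_start: int,
    exclude_xy: np.ndarray | None,
) -> SiteSet:
    """Uniform-over-green-pixels sites outside every zone rectangle."""
    green = np.isin(raster.grid, tuple(lc.GREEN_CLASSES))
    xs, ys = raster.pixel_centres()
    outside = np.ones_like(green)
    for z in zones:
        outside &= ~z.contains(xs, ys)
    rows, cols = np.nonzero(green & outside)
    if exclude_xy is not None and len(exclude_xy):
        er, ecol = raster.xy_to_rc(exclude_xy[:, 0], exclude_xy[:, 1])
        used = set(zip(er.tolist(), ecol.tolist()))
        keep = [
            i for i in range(rows.size) if (int(rows[i]), int(cols[i])) not in used
        ]
        rows, cols = rows[keep], cols[keep]
    if rows.size < n:
        raise ValueError(
            f"only {rows.size} green pixels between transects for {n} filler sites"
        )
    picks = rng.choice(rows.size, size=n, replace=False)
    px = raster.pixel_size
    ox, oy = raster.origin
    xy = np.column_stack(
        [ox + (cols[picks] + 0.5) * px, oy + (rows[picks] + 0.5) * px]
    )
    ids = np.arange(id_start, id_start + n)
    return SiteSet(ids, xy, [()] * n)


def _build_two_patch_toy(seed: int) -> Scenario:
    """Two green patches split by a wall of tall buildings (impassable)."""
    nrows, ncols = 24, 40
    grid = np.full((nrows, ncols), lc.OPEN, dtype=np.int16)
    grid[4:20, 2:16] = lc.GRASSLAND
    grid[4:20, 24:38] = lc.GRASSLAND
    grid[:, 17:23] = lc.BUILDING_GE10  # 60 m wall, full height
    raster = LandCoverRaster(grid, pixel_size=10.0, origin=(0.0, 0.0))
    table = ResistanceTable.default()
    zone = Zone(
        id="toy", transect="T", level="low", azimuth=0.0,
        start=0.0, end=ncols * 10.0, width=nrows * 20.0,
        centre=(0.0, nrows * 5.0),
    )
    rng = np.random.default_rng(seed)
    patches = extract_green_patches(raster)
    sites = place_sites(patches, None, 6, rng).with_memberships([zone])
    params = SimulationParams(n_loci=20, n_runs=2, n_generations=10)
    return Scenario(
        "two-patch-toy", seed, raster, table, build_resistance(raster, table),
        [zone], sites, params,
    )


def make_scenario(preset: str, seed: int) -> Scenario:
    """Build the named preset; identical bundles for identical seeds."""
    if preset == "two-patch-toy":
        return _build_two_patch_toy(seed)
    if preset not in PRESETS:
        raise KeyError(
            f"unknown preset {preset!r}; choose from "
            f"{sorted([*PRESETS, 'two-patch-toy'])}"
        )
    return _build_gradient_scenario(PRESETS[preset], seed)


def scenario_from_config(path, seed: int | None = None) -> Scenario:
    """Build a gradient scenario from a YAML config file.

    Recognised keys (all optional, defaults from the marseille-like
    preset): ``n_transects``, ``transect_length``, ``width``,
    ``pixel_size``, ``n_sites_per_zone``, ``n_filler_sites``, ``seed``,
    and a ``params`` mapping of simulation-parameter overrides (e.g.
    ``n_loci``, ``n_generations``, ``n_runs``, ``female_budget``).
    """
    import yaml

    with open(path) as fh:
        cfg = dict(yaml.safe_load(fh) or {})
    base = PRESETS["marseille-like"]
    params = SimulationParams(**cfg.pop("params", {}))
    cfg_seed = cfg.pop("seed", 0)
    spec = ScenarioSpec(
        name=cfg.pop("name", "config"),
        n_transects=cfg.pop("n_transects", base.n_transects),
        transect_length=cfg.pop("transect_length", base.transect_length),
        width=cfg.pop("width", base.width),
        pixel_size=cfg.pop("pixel_size", base.pixel_size),
        n_sites_per_zone=cfg.pop("n_sites_per_zone", base.n_sites_per_zone),
        n_filler_sites=cfg.pop("n_filler_sites", base.n_filler_sites),
        params=params,
    )
    if cfg:
        raise ValueError(f"unknown config keys: {sorted(cfg)}")
    return _build_gradient_scenario(spec, cfg_seed if seed is None else seed)


@dataclass
class DominantDataset:
    """Dominant-marker (AFLP-like) bands with site coordinates."""

    bands: np.ndarray  # (n_individuals, n_markers) 0/1 presence
    site_of_individual: np.ndarray  # (n_individuals,) site index
    site_xy: np.ndarray  # (n_sites, 2)
    distances: np.ndarray  # (n_sites,) Euclidean distance to the centre


def make_dominant_dataset(
    n_sites: int = 36,
    n_markers: int = 366,
    gradient: float = 0.11,
    seed: int | np.random.Generator = 0,
    mean_individuals_per_site: float = 4.0,
    transect_length: float = 18_000.0,
    base_hexp: float = 0.125,
) -> DominantDataset:
    """Generate dominant presence/absence genotypes with a diversity gradient.

    Sites are scattered along a transect from the centre; the site-level
    target expected heterozygosity increases linearly with distance,
    spanning ``gradient`` across the transect around ``base_hexp``
    (defaults span the 0.07–0.18 range of the empirical markers).  Per
    site, the recessive allele frequency q solves 2pq = H; marker-level
    frequencies jitter around it (lognormal, shared across sites so the
    jitter shifts the intercept, not the slope); bands are drawn under
    Hardy–Weinberg within sites (band absent with probability q²).  With
    ``gradient=0`` the regression of per-site H_exp on distance is null.
    """
    if n_markers < 1:
        raise ValueError("need at least one marker")
    rng = np.random.default_rng(seed)
    along = np.sort(rng.uniform(0.02, 1.0, size=n_sites)) * transect_length
    jitter_y = rng.uniform(-500.0, 500.0, size=n_sites)
    site_xy = np.column_stack([along, jitter_y])
    distances = np.hypot(along, jitter_y)

    rel = along / transect_length - 0.5
    target_h = np.clip(base_hexp + gradient * rel, 0.01, 0.45)
    # 2pq = H with q < 0.5  =>  q = (1 - sqrt(1 - 2H)) / 2
    q_site = (1.0 - np.sqrt(1.0 - 2.0 * target_h)) / 2.0
    marker_jitter = rng.lognormal(mean=0.0, sigma=0.3, size=n_markers)
    q = np.clip(q_site[:, None] * marker_jitter[None, :], 1e-3, 0.999)

    counts = np.maximum(1, rng.poisson(mean_individuals_per_site, size=n_sites))
    site_of_individual = np.repeat(np.arange(n_sites), counts)
    f_absent = q[site_of_individual] ** 2
    bands = (rng.random(f_absent.shape) >= f_absent).astype(np.int8)
    return DominantDataset(bands, site_of_individual, site_xy, distances)
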