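"""Synthetic fragmented land-cover landscapes along urbanisation gradients.

This module provides the landscape substrate for the simulation pipeline:

* :class:`LandCoverRaster` — an integer class grid at fixed pixel size,
  emulating a 10 m land-cover classification of a Mediterranean city and
  its suburbs (eleven classes: grasslands, parks, open areas, mixed
  surfaces, water, roads/impervious, four building-height classes and
  forest).
* :func:`generate_landcover` — a neutral-landscape generator: one
  spatially autocorrelated Gaussian field per composition region,
  thresholded at quantiles so that realised class fractions match the
  requested per-zone targets while classes form contiguous patches.
* :func:`build_resistance` — elementwise mapping of land-cover classes to
  dispersal resistance values (dimensionless per-metre multipliers).
* :func:`extract_green_patches` / :func:`place_sites` — green-space patch
  extraction (4-connectivity) and the stepwise habitat-site placement
  rule (three sites per patch of at least 5 ha, one per patch of 1–5 ha,
  remainder random in patches of at least 200 m²).
* :func:`define_zones` — rectangular transect segments (by default four
  18 km × 4 km transects radiating from the city centre, each divided
  into three 6 km segments of high / medium / low urban density).

Coordinates are continuous metres with the origin at the city-centre
point; the raster is indexed row-major with pixel (0, 0) at the origin
corner and site coordinates at pixel centres.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterator, Mapping, Sequence

import numpy as np
from scipy import ndimage

__all__ = [
    "GRASSLAND",
    "PARK",
    "OPEN",
    "MIXED",
    "WATER",
    "ROADS",
    "BUILDING_LT2",
    "BUILDING_2_5",
    "BUILDING_5_10",
    "BUILDING_GE10",
    "FOREST",
    "CLASS_NAMES",
    "GREEN_CLASSES",
    "IMPERVIOUS_CLASSES",
    "LandCoverRaster",
    "ResistanceTable",
    "Zone",
    "SiteSet",
    "CompositionSpec",
    "Patch",
    "PatchSet",
    "generate_landcover",
    "build_resistance",
    "extract_green_patches",
    "place_sites",
    "define_zones",
]

# Land-cover class codes (eight thematic classes, buildings split into four
# height subclasses -> eleven codes).
GRASSLAND = 1
PARK = 2
OPEN = 3
MIXED = 4
WATER = 5
ROADS = 6
BUILDING_LT2 = 7
BUILDING_2_5 = 8
BUILDING_5_10 = 9
BUILDING_GE10 = 10
FOREST = 11

CLASS_NAMES: dict[int, str] = {
    GRASSLAND: "grasslands",
    PARK: "parks",
    OPEN: "open areas (mainly not vegetated)",
    MIXED: "mixed surfaces (artificial and natural)",
    WATER: "water",
    ROADS: "roads and other impervious surfaces",
    BUILDING_LT2: "buildings: maximum height <2 m",
    BUILDING_2_5: "buildings: 2 m <= maximum height < 5 m",
    BUILDING_5_10: "buildings: 5 m <= maximum height < 10 m",
    BUILDING_GE10: "buildings: maximum height >= 10 m",
    FOREST: "forest",
}

#: Classes counted as green space (butterfly habitat).
GREEN_CLASSES = frozenset({GRASSLAND, PARK})

#: Classes counted as impervious cover (buildings, roads, other sealed).
IMPERVIOUS_CLASSES = frozenset(
    {ROADS, BUILDING_LT2, BUILDING_2_5, BUILDING_5_10, BUILDING_GE10}
)

# Classes are assigned in two tiers.  Built surfaces and water (the
# movement barriers) are carved from the *smooth* field so they form
# spatially coherent blocks — building classes cluster by decreasing
# height around the field minima (dense cores), ringed by roads.  The
# natural classes fill the remaining fabric, ranked by the roughened
# field so vegetation interdigitates at fine grain.  Forest sits at the
# bottom of the natural tier (peri-urban belts) and open/mixed ground
# between forest and green, so rural green networks are bridged by
# low-resistance corridors rather than enclosed by closed forest belts —
# the open-woodland (garrigue) mosaic of a Mediterranean region.
_BARRIER_BANDS = (
    BUILDING_GE10,
    BUILDING_5_10,
    BUILDING_2_5,
    BUILDING_LT2,
    ROADS,
    WATER,
)
_NATURAL_BANDS = (
    FOREST,
    MIXED,
    OPEN,
    PARK,
    GRASSLAND,
)


@dataclass(frozen=True)
class ResistanceTable:
    """Map from land-cover class code to dispersal resistance.

    Resistance is a dimensionless per-metre cost multiplier: traversing
    ``x`` metres of resistance ``r`` costs ``r * x`` cost-metres.  All
    resistances must be >= 1 (green space is the unit-cost reference).
    """

    entries: Mapping[int, float]

    def __post_init__(self) -> None:
        for code, value in self.entries.items():
            if value < 1:
                raise ValueError(
                    f"resistance for class {code} is {value}; must be >= 1"
                )

    def __getitem__(self, code: int) -> float:
        return self.entries[code]

    @classmethod
    def default(cls) -> "ResistanceTable":
        """Expert-opinion resistance values for a cabbage white butterfly.

        Green spaces are the unit reference; open ground is mildly
        resistant; sealed surfaces, water and low buildings cost 10x;
        forest and mid-height buildings 20x; tall buildings (>= 10 m) are
        effectively impassable (450: a single 10 m step exceeds any
        dispersal budget used here).
        """
        return cls(
            {
                GRASSLAND: 1,
                PARK: 1,
                OPEN: 3,
                MIXED: 5,
                WATER: 10,
                ROADS: 10,
                BUILDING_LT2: 10,
                BUILDING_2_5: 20,
                BUILDING_5_10: 50,
                BUILDING_GE10: 450,
                FOREST: 20,
            }
        )


@dataclass
class LandCoverRaster:
    """Integer land-cover class grid at fixed pixel size.

    ``grid`` is row-major with row 0 at the low-y edge; pixel centres are
    at ``origin + (col + 0.5, row + 0.5) * pixel_size``.
    """

    grid: np.ndarray
    pixel_size: float = 10.0
    origin: tuple[float, float] = (0.0, 0.0)
    class_table: Mapping[int, str] = field(default_factory=lambda: dict(CLASS_NAMES))

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid)
        if self.grid.ndim != 2 or self.grid.size == 0:
            raise ValueError("grid must be a non-empty 2-D array")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be > 0")
        present = np.unique(self.grid)
        unknown = [int(c) for c in present if int(c) not in self.class_table]
        if unknown:
            raise ValueError(f"grid contains codes absent from class_table: {unknown}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.grid.shape

    def xy_to_rc(self, x, y):
        """Map continuous coordinates to (row, col) pixel indices."""
        col = np.floor((np.asarray(x) - self.origin[0]) / self.pixel_size).astype(int)
        row = np.floor((np.asarray(y) - self.origin[1]) / self.pixel_size).astype(int)
        nrows, ncols = self.grid.shape
        return np.clip(row, 0, nrows - 1), np.clip(col, 0, ncols - 1)

    def pixel_centres(self):
        """x- and y-coordinate arrays of all pixel centres (broadcastable)."""
        nrows, ncols = self.grid.shape
        xs = self.origin[0] + (np.arange(ncols) + 0.5) * self.pixel_size
        ys = self.origin[1] + (np.arange(nrows) + 0.5) * self.pixel_size
        return xs[np.newaxis, :], ys[:, np.newaxis]

    def class_fractions(self, mask: np.ndarray | None = None) -> dict[int, float]:
        """Realised fraction of each class code, optionally within a mask."""
        values = self.grid if mask is None else self.grid[mask]
        total = values.size
        codes, counts = np.unique(values, return_counts=True)
        return {int(c): n / total for c, n in zip(codes, counts)}

    def zone_mask(self, zone: "Zone") -> np.ndarray:
        """Boolean mask of pixels whose centres fall inside a zone."""
        xs, ys = self.pixel_centres()
        return zone.contains(xs, ys)


@dataclass(frozen=True)
class Zone:
    """Rectangular transect segment, axis-aligned to a transect azimuth.

    ``azimuth`` is the transect direction in degrees counterclockwise from
    the +x axis; ``start``/``end`` are along-axis offsets in metres from
    the city centre, ``width`` the across-axis extent.
    """

    id: str
    transect: str
    level: str
    azimuth: float
    start: float
    end: float
    width: float
    centre: tuple[float, float] = (0.0, 0.0)
    index: int = 0

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("zone end must exceed start")
        if self.width <= 0:
            raise ValueError("zone width must be > 0")
        if self.level not in {"low", "medium", "high"}:
            raise ValueError(f"unknown urbanisation level {self.level!r}")

    def contains(self, x, y):
        """Vectorised point-in-rectangle test."""
        theta = np.deg2rad(self.azimuth)
        dx = np.asarray(x) - self.centre[0]
        dy = np.asarray(y) - self.centre[1]
        along = dx * np.cos(theta) + dy * np.sin(theta)
        across = -dx * np.sin(theta) + dy * np.cos(theta)
        return (
            (along >= self.start)
            & (along <= self.end)
            & (np.abs(across) <= self.width / 2)
        )


@dataclass(frozen=True)
class CompositionSpec:
    """Target class composition and patch scale for one raster region.

    ``fractions`` maps class codes to target area fractions (summing to
    at most 1; the remainder is filled with open areas).  ``patch_scale``
    is the correlation length (metres) of the underlying autocorrelated
    field; larger values give larger, fewer patches.  ``roughness`` in
    [0, 1) mixes unsmoothed noise into the field used to rank the
    natural classes, producing the heavy-tailed patch-size distributions
    of vegetation fragments; 0 gives purely smooth patches.
    ``barrier_roughness`` plays the same role for the built tier: it
    interleaves building and road classes at street scale within the
    coherent built blocks, so crossing urban fabric means winding
    through a building/road mixture rather than along wide single-class
    bands.  ``region`` is the zone the spec applies to, or ``None`` for
    all not-yet-claimed pixels (the inter-transect background).
    """

    fractions: Mapping[int, float]
    patch_scale: float
    region: Zone | None = None
    roughness: float = 0.0
    barrier_roughness: float = 0.8

    def __post_init__(self) -> None:
        if self.patch_scale <= 0:
            raise ValueError("patch_scale must be > 0")
        if not 0 <= self.roughness < 1:
            raise ValueError("roughness must lie in [0, 1)")
        if not 0 <= self.barrier_roughness < 1:
            raise ValueError("barrier_roughness must lie in [0, 1)")
        total = float(sum(self.fractions.values()))
        if total > 1 + 1e-9:
            raise ValueError(f"class fractions sum to {total:.3f} > 1")
        for code in self.fractions:
            if code not in CLASS_NAMES:
                raise ValueError(f"unknown class code {code}")
        if any(f < 0 for f in self.fractions.values()):
            raise ValueError("class fractions must be non-negative")


def _exact_counts(fractions: Sequence[float], n: int) -> np.ndarray:
    """Integer class counts matching fractions, largest-remainder rounding."""
    target = np.asarray(fractions, dtype=float) * n
    base = np.floor(target).astype(int)
    leftover = n - int(base.sum())
    if leftover > 0:
        order = np.argsort(-(target - base), kind="stable")
        base[order[:leftover]] += 1
    return base


def generate_landcover(
    zone_specs: Sequence[CompositionSpec],
    extent: tuple[float, float, float, float],
    pixel_size: float,
    seed: int | np.random.Generator,
) -> LandCoverRaster:
    """Generate a synthetic land-cover raster with per-region composition.

    Each spec claims its region's pixels (earlier specs win where zones
    overlap, e.g. downtown); a spec with ``region=None`` claims whatever
    is left.  Within each region an independent Gaussian field smoothed
    to ``patch_scale`` is thresholded at region quantiles so realised
    fractions match targets to within one pixel, while classes form
    contiguous patches.  Pixels claimed by no spec become open areas.

    Parameters
    ----------
    extent : (xmin, ymin, xmax, ymax) in metres.
    seed : int or Generator; the output is deterministic given the seed.
    """
    if pixel_size <= 0:
        raise ValueError("pixel_size must be > 0")
    xmin, ymin, xmax, ymax = extent
    ncols = int(round((xmax - xmin) / pixel_size))
    nrows = int(round((ymax - ymin) / pixel_size))
    if ncols < 1 or nrows < 1:
        raise ValueError("extent smaller than one pixel")
    rng = np.random.default_rng(seed)

    grid = np.full((nrows, ncols), OPEN, dtype=np.int16)
    raster = LandCoverRaster(grid, pixel_size=pixel_size, origin=(xmin, ymin))
    xs, ys = raster.pixel_centres()

    region_of = np.full((nrows, ncols), -1, dtype=np.int32)
    for i, spec in enumerate(zone_specs):
        if spec.region is None:
            mask = region_of < 0
        else:
            mask = (region_of < 0) & spec.region.contains(xs, ys)
        region_of[mask] = i

    for i, spec in enumerate(zone_specs):
        # one smooth field per spec so zone patch structure is independent;
        # a roughened copy drives the fine-grained natural classes
        sigma = spec.patch_scale / pixel_size
        smooth = ndimage.gaussian_filter(rng.standard_normal((nrows, ncols)), sigma)
        smooth = (smooth - smooth.mean()) / smooth.std()
        if spec.roughness > 0:
            a = spec.roughness
            rough = math.sqrt(1 - a) * smooth + math.sqrt(a) * rng.standard_normal(
                (nrows, ncols)
            )
        else:
            rough = smooth
        rows, cols = np.nonzero(region_of == i)
        if rows.size == 0:
            continue
        fractions = dict(spec.fractions)
        remainder = 1.0 - sum(fractions.values())
        if remainder > 0:
            fractions[OPEN] = fractions.get(OPEN, 0.0) + remainder
        barrier = [c for c in _BARRIER_BANDS if fractions.get(c, 0.0) > 0]
        natural = [c for c in _NATURAL_BANDS if fractions.get(c, 0.0) > 0]
        counts_b = _exact_counts(
            [fractions[c] for c in barrier + natural], rows.size
        )
        n_barrier = int(counts_b[: len(barrier)].sum())
        # tier 1: barriers occupy the lowest smooth-field pixels (coherent
        # blocks); subclasses interleave at street scale within them
        order_smooth = np.argsort(smooth[rows, cols], kind="stable")
        ab = spec.barrier_roughness
        if ab > 0 and n_barrier:
            b_rough = math.sqrt(1 - ab) * smooth + math.sqrt(
                ab
            ) * rng.standard_normal((nrows, ncols))
        else:
            b_rough = smooth
        block = order_smooth[:n_barrier]
        order_block = block[
            np.argsort(b_rough[rows[block], cols[block]], kind="stable")
        ]
        pos = 0
        for code, count in zip(barrier, counts_b[: len(barrier)]):
            sel = order_block[pos : pos + count]
            grid[rows[sel], cols[sel]] = code
            pos += count
        # tier 2: natural classes fill the rest, banded by the rough field
        rest = order_smooth[n_barrier:]
        order_rough = rest[np.argsort(rough[rows[rest], cols[rest]], kind="stable")]
        pos = 0
        for code, count in zip(natural, counts_b[len(barrier) :]):
            sel = order_rough[pos : pos + count]
            grid[rows[sel], cols[sel]] = code
            pos += count
    return raster


def build_resistance(raster: LandCoverRaster, table: ResistanceTable) -> np.ndarray:
    """Elementwise lookup of resistance values for every pixel.

    Raises ``KeyError`` naming the offending code if the table does not
    cover a class present in the raster.
    """
    codes = np.unique(raster.grid)
    missing = [int(c) for c in codes if int(c) not in table.entries]
    if missing:
        raise KeyError(
            f"resistance table lacks entries for class codes {missing}"
        )
    lut = np.zeros(int(codes.max()) + 1, dtype=float)
    for code in codes:
        lut[int(code)] = table[int(code)]
    return lut[raster.grid]


@dataclass(frozen=True)
class Patch:
    """One maximal 4-connected component of green-space pixels."""

    label: int
    rows: np.ndarray
    cols: np.ndarray
    xs: np.ndarray
    ys: np.ndarray
    area_m2: float

    @property
    def n_pixels(self) -> int:
        return self.rows.size


class PatchSet(Sequence):
    """Sequence of green patches plus the label grid they came from."""

    def __init__(self, patches: list[Patch], labels: np.ndarray, raster: LandCoverRaster):
        self._patches = patches
        self.labels = labels
        self.raster = raster

    def __len__(self) -> int:
        return len(self._patches)

    def __getitem__(self, i):
        return self._patches[i]

    def __iter__(self) -> Iterator[Patch]:
        return iter(self._patches)


_FOUR_CONN = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)


def extract_green_patches(raster: LandCoverRaster) -> PatchSet:
    """Maximal 4-connected components of green-space pixels.

    Area is pixel count x pixel_size².  Returns an empty set when the
    raster holds no green pixels.
    """
    green = np.isin(raster.grid, tuple(GREEN_CLASSES))
    labels, n = ndimage.label(green, structure=_FOUR_CONN)
    patches: list[Patch] = []
    if n:
        flat_rows, flat_cols = np.nonzero(labels)
        lab = labels[flat_rows, flat_cols]
        order = np.argsort(lab, kind="stable")
        flat_rows, flat_cols, lab = flat_rows[order], flat_cols[order], lab[order]
        bounds = np.searchsorted(lab, np.arange(1, n + 2))
        px = raster.pixel_size
        ox, oy = raster.origin
        for k in range(n):
            rows = flat_rows[bounds[k] : bounds[k + 1]]
            cols = flat_cols[bounds[k] : bounds[k + 1]]
            patches.append(
                Patch(
                    label=k + 1,
                    rows=rows,
                    cols=cols,
                    xs=ox + (cols + 0.5) * px,
                    ys=oy + (rows + 0.5) * px,
                    area_m2=rows.size * px * px,
                )
            )
    return PatchSet(patches, labels, raster)


@dataclass
class SiteSet:
    """Habitat sites: coordinates plus zone memberships.

    A site may belong to 0, 1 or 2+ zones (rectangles overlap near the
    city centre, and overlapping sites are counted for every zone that
    contains them).  Ids are unique integers.
    """

    ids: np.ndarray
    xy: np.ndarray
    memberships: list[tuple[str, ...]]

    def __post_init__(self) -> None:
        self.ids = np.asarray(self.ids, dtype=int)
        self.xy = np.asarray(self.xy, dtype=float)
        if len(np.unique(self.ids)) != len(self.ids):
            raise ValueError("site ids must be unique")
        if self.xy.shape != (len(self.ids), 2):
            raise ValueError("xy must be (n_sites, 2)")
        if len(self.memberships) != len(self.ids):
            raise ValueError("one membership tuple per site required")

    def __len__(self) -> int:
        return len(self.ids)

    def zone_members(self, zone_id: str) -> np.ndarray:
        """Indices (not ids) of sites belonging to a zone."""
        return np.array(
            [i for i, m in enumerate(self.memberships) if zone_id in m], dtype=int
        )

    def nearest_neighbours(self, n: int) -> np.ndarray:
        """(n_sites, n) neighbour index matrix, Euclidean, ties by id."""
        if n >= len(self):
            raise ValueError("need more sites than neighbours requested")
        d = np.hypot(
            self.xy[:, 0][:, None] - self.xy[:, 0][None, :],
            self.xy[:, 1][:, None] - self.xy[:, 1][None, :],
        )
        out = np.empty((len(self), n), dtype=int)
        for i in range(len(self)):
            order = np.lexsort((self.ids, d[i]))
            order = order[order != i]
            out[i] = order[:n]
        return out

    @classmethod
    def concat(cls, parts: Sequence["SiteSet"]) -> "SiteSet":
        ids = np.concatenate([p.ids for p in parts])
        xy = np.vstack([p.xy for p in parts])
        memberships = [m for p in parts for m in p.memberships]
        return cls(ids, xy, memberships)

    def with_memberships(self, zones: Sequence[Zone]) -> "SiteSet":
        """Recompute memberships as every zone whose rectangle contains the site."""
        memberships = []
        for x, y in self.xy:
            memberships.append(
                tuple(z.id for z in zones if bool(z.contains(x, y)))
            )
        return SiteSet(self.ids, self.xy, memberships)


# Stepwise placement thresholds: 5 ha, 1 ha, and a 2-pixel floor (200 m²
# on the original 10 m map; scales with pixel size so a site always sits
# in a resolvable patch, never on an isolated single cell).
_AREA_LARGE = 50_000.0
_AREA_MEDIUM = 10_000.0
_MIN_PIXELS = 2


def place_sites(
    patches: PatchSet,
    zone: Zone | None,
    n_total: int,
    seed: int | np.random.Generator,
    existing_xy: np.ndarray | None = None,
    id_start: int = 0,
) -> SiteSet:
    """Place habitat sites in green patches by the stepwise rule.

    Within the zone (or everywhere when ``zone`` is None): every patch
    with at least 5 ha inside the zone receives three sites, every patch
    of 1–5 ha one site, and the remaining sites are placed uniformly at
    random on pixels of patches of at least two pixels (200 m² at the
    original 10 m resolution), one site per pixel.
    ``existing_xy`` are previously placed sites; those inside the zone
    count toward ``n_total`` and toward the per-patch quotas (zones
    overlap downtown, and shared sites are counted for both zones).

    Raises ``ValueError`` if the forced quota exceeds ``n_total`` or the
    eligible habitat cannot host the requested number of sites.
    """
    rng = np.random.default_rng(seed)

    clipped: list[tuple[Patch, np.ndarray]] = []  # (patch, in-zone pixel idx)
    for patch in patches:
        if zone is None:
            inside = np.arange(patch.n_pixels)
        else:
            inside = np.nonzero(zone.contains(patch.xs, patch.ys))[0]
        if inside.size:
            clipped.append((patch, inside))

    px2 = patches.raster.pixel_size ** 2

    # pre-existing sites inside the zone, mapped to their patch labels
    existing_inside = 0
    existing_per_label: dict[int, int] = {}
    used_pixels: set[tuple[int, int]] = set()
    if existing_xy is not None and len(existing_xy):
        ex = np.asarray(existing_xy, dtype=float)
        if zone is not None:
            ex = ex[zone.contains(ex[:, 0], ex[:, 1])]
        existing_inside = len(ex)
        if len(ex):
            r, c = patches.raster.xy_to_rc(ex[:, 0], ex[:, 1])
            labs = patches.labels[r, c]
            for lab, rr, cc in zip(labs, r, c):
                used_pixels.add((int(rr), int(cc)))
                if lab > 0:
                    existing_per_label[int(lab)] = existing_per_label.get(int(lab), 0) + 1

    n_new = n_total - existing_inside
    if n_new < 0:
        n_new = 0

    chosen: list[tuple[int, int]] = []  # (row, col) of new sites

    def _sample_from(patch: Patch, inside: np.ndarray, k: int) -> None:
        free = [
            j
            for j in inside
            if (int(patch.rows[j]), int(patch.cols[j])) not in used_pixels
        ]
        if len(free) < k:
            raise ValueError(
                f"patch {patch.label} cannot host {k} more sites "
                f"({len(free)} free pixels)"
            )
        picks = rng.choice(len(free), size=k, replace=False)
        for p in picks:
            rc = (int(patch.rows[free[p]]), int(patch.cols[free[p]]))
            used_pixels.add(rc)
            chosen.append(rc)

    # forced quotas
    forced_needed = 0
    quotas: list[tuple[Patch, np.ndarray, int]] = []
    for patch, inside in clipped:
        area = inside.size * px2
        if area >= _AREA_LARGE:
            quota = 3
        elif area >= _AREA_MEDIUM:
            quota = 1
        else:
            continue
        have = existing_per_label.get(patch.label, 0)
        need = max(0, quota - have)
        forced_needed += need
        quotas.append((patch, inside, need))
    if forced_needed > n_new:
        raise ValueError(
            f"stepwise rule forces {forced_needed} sites but only {n_new} "
            f"remain of n_total={n_total}"
        )
    for patch, inside, need in quotas:
        if need:
            _sample_from(patch, inside, need)

    # random fill over eligible pixels (patches >= 200 m² inside the zone)
    n_fill = n_new - forced_needed
    if n_fill > 0:
        pool: list[tuple[int, int]] = []
        for patch, inside in clipped:
            if inside.size < _MIN_PIXELS:
                continue
            for j in inside:
                rc = (int(patch.rows[j]), int(patch.cols[j]))
                if rc not in used_pixels:
                    pool.append(rc)
        if len(pool) < n_fill:
            raise ValueError(
                f"only {len(pool)} eligible green pixels for {n_fill} filler sites"
            )
        picks = rng.choice(len(pool), size=n_fill, replace=False)
        for p in picks:
            used_pixels.add(pool[p])
            chosen.append(pool[p])

    px = patches.raster.pixel_size
    ox, oy = patches.raster.origin
    xy = np.array(
        [(ox + (c + 0.5) * px, oy + (r + 0.5) * px) for r, c in chosen], dtype=float
    ).reshape(len(chosen), 2)
    ids = np.arange(id_start, id_start + len(chosen))
    member = (zone.id,) if zone is not None else ()
    return SiteSet(ids, xy, [member] * len(chosen))


def define_zones(
    n_transects: int = 4,
    azimuths: Sequence[float] | None = None,
    transect_length: float = 18_000.0,
    width: float = 4_000.0,
    n_segments: int = 3,
) -> list[Zone]:
    """Define transect zones radiating from the city centre.

    Defaults give the full gradient design: four transects of 18 km x 4 km at
    evenly spaced azimuths, divided lengthwise into three 6 km segments
    (high urban density 0–6 km from the centre, medium 6–12 km, low
    12–18 km), giving 12 rectangles that partially overlap downtown.
    """
    if transect_length <= 0 or width <= 0 or n_segments < 1 or n_transects < 1:
        raise ValueError("zone dimensions and counts must be positive")
    if azimuths is None:
        azimuths = [360.0 * i / n_transects for i in range(n_transects)]
    if len(azimuths) != n_transects:
        raise ValueError("one azimuth per transect required")
    levels = ["high", "medium", "low"]
    seg_len = transect_length / n_segments
    zones: list[Zone] = []
    idx = 1
    for t in range(n_transects):
        label = chr(ord("A") + t)
        for s in range(n_segments):
            level = levels[s] if s < len(levels) else "low"
            zones.append(
                Zone(
                    id=f"{label}-{level}",
                    transect=label,
                    level=level,
                    azimuth=float(azimuths[t]),
                    start=s * seg_len,
                    end=(s + 1) * seg_len,
                    width=width,
                    index=idx,
                )
            )
            idx += 1
    return zones
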