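"""Heterozygosity statistics for codominant (SNP) and dominant (AFLP) markers.

Observed heterozygosity is the mean over markers of the frequency of
heterozygous individuals, H_obs = (1/k) * sum_i h_i.  Expected
heterozygosity assumes Hardy–Weinberg equilibrium, H_exp = (1/k) *
sum_i 2 p_i q_i, with p_i and q_i the observed allele frequencies at
marker i.  For dominant presence/absence markers heterozygotes are not
observable; only the frequency f of recessive homozygotes (band-absent
individuals) is, so q is estimated as sqrt(f), p = 1 - q, and H_exp
follows from 2pq.  Both indices range from 0 (no diversity) to 1.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "GenotypeMatrix",
    "DiversityRecord",
    "observed_heterozygosity",
    "expected_heterozygosity",
    "dominant_expected_heterozygosity",
    "zone_summary",
    "neighbourhood_hexp",
]


@dataclass
class GenotypeMatrix:
    """Individuals x loci marker calls.

    ``kind="codominant"``: ``data`` has shape (n, k, 2) holding the two
    allele indicators (0/1) per diploid biallelic locus; the allele pair
    is unordered.  ``kind="dominant"``: ``data`` has shape (n, k) holding
    0/1 band presence.
    """

    data: np.ndarray
    kind: str = "codominant"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.kind == "codominant":
            if self.data.ndim != 3 or self.data.shape[2] != 2:
                raise ValueError("codominant data must have shape (n, k, 2)")
        elif self.kind == "dominant":
            if self.data.ndim != 2:
                raise ValueError("dominant data must have shape (n, k)")
        else:
            raise ValueError(f"unknown marker kind {self.kind!r}")
        if self.data.shape[1] == 0:
            raise ValueError("at least one marker required")
        if not np.isin(self.data, (0, 1)).all():
            raise ValueError("marker calls must be 0/1")

    @property
    def n_individuals(self) -> int:
        return self.data.shape[0]

    @property
    def n_loci(self) -> int:
        return self.data.shape[1]


def _as_codominant(genotypes) -> np.ndarray:
    if isinstance(genotypes, GenotypeMatrix):
        if genotypes.kind != "codominant":
            raise ValueError("codominant markers required")
        return genotypes.data
    arr = np.asarray(genotypes)
    if arr.ndim != 3 or arr.shape[2] != 2:
        raise ValueError("codominant markers required (shape (n, k, 2))")
    return arr


def _as_dominant(bands) -> np.ndarray:
    if isinstance(bands, GenotypeMatrix):
        if bands.kind != "dominant":
            raise ValueError("dominant markers required")
        return bands.data
    arr = np.asarray(bands)
    if arr.ndim != 2:
        raise ValueError("dominant markers required (shape (n, k))")
    return arr


def observed_heterozygosity(genotypes) -> float:
    """Mean over loci of the frequency of heterozygous individuals.

    Only defined for codominant markers (dominant markers cannot reveal
    heterozygotes and are rejected).
    """
    g = _as_codominant(genotypes)
    if g.shape[0] == 0:
        raise ValueError("at least one individual required")
    het_per_locus = (g[:, :, 0] != g[:, :, 1]).mean(axis=0)
    return float(het_per_locus.mean())


def expected_heterozygosity(genotypes) -> float:
    """Mean over loci of 2 p q from observed allele frequencies."""
    g = _as_codominant(genotypes)
    if g.shape[0] == 0:
        raise ValueError("at least one individual required")
    p = g.mean(axis=(0, 2))
    return float((2.0 * p * (1.0 - p)).mean())


def dominant_expected_heterozygosity(bands) -> float:
    """H_exp for dominant presence/absence markers via q = sqrt(f).

    ``f`` is the per-marker fraction of band-absent individuals (recessive
    homozygotes under Hardy–Weinberg).  Markers with f = 0 contribute 0
    (q treated as 0, i.e. the marker is taken as fixed for the dominant
    allele), keeping the marker count constant across windows.
    """
    b = _as_dominant(bands)
    if b.shape[0] == 0:
        raise ValueError("at least one individual required")
    f = (b == 0).mean(axis=0)
    q = np.sqrt(f)
    return float((2.0 * (1.0 - q) * q).mean())


@dataclass
class DiversityRecord:
    """Per-zone, per-generation diversity and persistence summary.

    ``n`` is the number of individuals present in the zone (one per
    occupied site); heterozygosities are NaN when the zone is empty
    (``empty`` flag set).
    """

    zone: str
    generation: int
    run: int
    h_obs: float
    h_exp: float
    n: int
    level: str = ""
    transect: str = ""

    @property
    def empty(self) -> bool:
        return self.n == 0


def zone_summary(population, zones, generation: int | None = None, run: int = 0):
    """Diversity record per zone from a simulated population.

    Sites belonging to two overlapping zones contribute to both zones'
    counts and heterozygosities.  Empty zones yield N = 0 with NaN
    heterozygosities.
    """
    records = []
    gen = population.generation if generation is None else generation
    for zone in zones:
        members = population.sites.zone_members(zone.id)
        occupied = members[population.occupied[members]]
        if occupied.size == 0:
            records.append(
                DiversityRecord(zone.id, gen, run, float("nan"), float("nan"), 0,
                                zone.level, zone.transect)
            )
            continue
        g = population.genotypes[occupied]
        records.append(
            DiversityRecord(
                zone.id,
                gen,
                run,
                observed_heterozygosity(g),
                expected_heterozygosity(g),
                int(occupied.size),
                zone.level,
                zone.transect,
            )
        )
    return records


def neighbourhood_hexp(
    site_xy: np.ndarray,
    site_of_individual: np.ndarray,
    genotypes: GenotypeMatrix,
    n_neighbours: int,
    site_ids: Sequence | None = None,
) -> np.ndarray:
    """Per-site expected heterozygosity pooled over nearest neighbours.

    For each site, the individuals of that site and of its ``n_neighbours``
    Euclidean nearest neighbour sites are pooled and H_exp computed with
    the marker-appropriate estimator.  Distance ties are broken by site
    id for determinism.  ``n_neighbours`` must lie in the 3–25 window the
    neighbourhood estimator is defined for; sites without any pooled
    individual yield NaN.
    """
    if not 3 <= n_neighbours <= 25:
        raise ValueError("n_neighbours must be between 3 and 25")
    xy = np.asarray(site_xy, dtype=float)
    n_sites = xy.shape[0]
    if n_sites <= n_neighbours:
        raise ValueError("need more sites than neighbours requested")
    site_of_individual = np.asarray(site_of_individual, dtype=int)
    ids = np.arange(n_sites) if site_ids is None else np.asarray(site_ids)

    d = np.hypot(xy[:, 0][:, None] - xy[:, 0][None, :],
                 xy[:, 1][:, None] - xy[:, 1][None, :])
    estimator = (
        expected_heterozygosity
        if genotypes.kind == "codominant"
        else dominant_expected_heterozygosity
    )
    out = np.full(n_sites, np.nan)
    for i in range(n_sites):
        order = np.lexsort((ids, d[i]))
        order = order[order != i][:n_neighbours]
        pool = np.isin(site_of_individual, np.concatenate(([i], order)))
        if pool.any():
            out[i] = estimator(GenotypeMatrix(genotypes.data[pool], genotypes.kind))
    return out
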