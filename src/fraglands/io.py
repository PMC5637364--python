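"""Plain-text readers and writers for the pipeline's artefacts.

Formats: Esri ASCII grid for rasters, CSV for sites, cost matrices
(+inf serialised as an empty cell), per-generation genotype snapshots
(one row per individual, two allele columns per locus) and dominant
marker tables (a ``# sites`` coordinate block followed by a ``# bands``
block).
"""

from __future__ import annotations

import csv
from pathlib import Path

import numpy as np
import pandas as pd

from .connectivity import CostMatrix
from .genetics import GenotypeMatrix
from .landscape import CLASS_NAMES, LandCoverRaster, SiteSet

__all__ = [
    "write_ascii_grid",
    "read_ascii_grid",
    "write_sites_csv",
    "read_sites_csv",
    "write_cost_matrix_csv",
    "read_cost_matrix_csv",
    "write_genotype_snapshot",
    "read_genotype_snapshot",
    "write_dominant_table",
    "read_dominant_table",
]

_NODATA = -9999


def write_ascii_grid(raster: LandCoverRaster, path) -> None:
    """Esri ASCII grid (rows written north to south)."""
    nrows, ncols = raster.grid.shape
    with open(path, "w") as fh:
        fh.write(f"ncols {ncols}\n")
        fh.write(f"nrows {nrows}\n")
        fh.write(f"xllcorner {raster.origin[0]:.6f}\n")
        fh.write(f"yllcorner {raster.origin[1]:.6f}\n")
        fh.write(f"cellsize {raster.pixel_size:.6f}\n")
        fh.write(f"NODATA_value {_NODATA}\n")
        for row in raster.grid[::-1]:
            fh.write(" ".join(str(int(v)) for v in row) + "\n")


def read_ascii_grid(path, class_table=None) -> LandCoverRaster:
    header: dict[str, float] = {}
    with open(path) as fh:
        for _ in range(6):
            key, value = fh.readline().split()
            header[key.lower()] = float(value)
        grid = np.loadtxt(fh, dtype=np.int16)
    grid = np.atleast_2d(grid)[::-1]
    return LandCoverRaster(
        grid,
        pixel_size=header["cellsize"],
        origin=(header["xllcorner"], header["yllcorner"]),
        class_table=class_table or dict(CLASS_NAMES),
    )


def write_sites_csv(sites: SiteSet, path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["site_id", "x", "y", "zones"])
        for i in range(len(sites)):
            writer.writerow(
                [
                    int(sites.ids[i]),
                    f"{sites.xy[i, 0]:.3f}",
                    f"{sites.xy[i, 1]:.3f}",
                    ";".join(sites.memberships[i]),
                ]
            )


def read_sites_csv(path) -> SiteSet:
    ids, xy, memberships = [], [], []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            ids.append(int(row["site_id"]))
            xy.append((float(row["x"]), float(row["y"])))
            zones = row["zones"]
            memberships.append(tuple(zones.split(";")) if zones else ())
    return SiteSet(np.array(ids), np.array(xy).reshape(len(ids), 2), memberships)


def write_cost_matrix_csv(matrix: CostMatrix, path) -> None:
    """CSV with site-id header row/column; +inf as an empty cell."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["site_id", *[str(i) for i in matrix.ids]])
        for i, sid in enumerate(matrix.ids):
            row = [
                "" if not np.isfinite(c) else f"{c:.6f}" for c in matrix.costs[i]
            ]
            writer.writerow([str(sid), *row])


def read_cost_matrix_csv(path) -> CostMatrix:
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader)
        ids = np.array([int(h) for h in header[1:]])
        costs = np.full((len(ids), len(ids)), np.inf)
        for i, row in enumerate(reader):
            for j, cell in enumerate(row[1:]):
                if cell != "":
                    costs[i, j] = float(cell)
    return CostMatrix(ids, costs)


def write_genotype_snapshot(population, path) -> None:
    """Per-generation CSV: individual id, site, sex, 2 x n_loci alleles."""
    occupied = np.nonzero(population.occupied)[0]
    n_loci = population.genotypes.shape[1]
    columns = ["individual_id", "site_id", "sex"] + [
        f"l{l}a{a}" for l in range(n_loci) for a in range(2)
    ]
    rows = []
    for i in occupied:
        geno = population.genotypes[i].reshape(-1)
        rows.append([int(i), int(population.sites.ids[i]),
                     "F" if population.sex[i] == 0 else "M", *geno.tolist()])
    pd.DataFrame(rows, columns=columns).to_csv(path, index=False)


def read_genotype_snapshot(path) -> tuple[pd.DataFrame, GenotypeMatrix]:
    """Return (metadata frame, codominant genotype matrix)."""
    frame = pd.read_csv(path)
    meta = frame[["individual_id", "site_id", "sex"]]
    allele_cols = [c for c in frame.columns if c.startswith("l")]
    n_loci = len(allele_cols) // 2
    data = frame[allele_cols].to_numpy(dtype=np.int8).reshape(-1, n_loci, 2)
    return meta, GenotypeMatrix(data, "codominant")


def write_dominant_table(dataset, path) -> None:
    """Two-section CSV: '# sites' coordinate block, then '# bands'."""
    with open(path, "w", newline="") as fh:
        fh.write("# sites\n")
        fh.write("site_id,x,y\n")
        for i, (x, y) in enumerate(dataset.site_xy):
            fh.write(f"{i},{x:.3f},{y:.3f}\n")
        fh.write("# bands\n")
        n_markers = dataset.bands.shape[1]
        fh.write(
            "individual_id,site_id,"
            + ",".join(f"m{j}" for j in range(n_markers))
            + "\n"
        )
        for i, site in enumerate(dataset.site_of_individual):
            fh.write(
                f"{i},{int(site)},"
                + ",".join(str(int(b)) for b in dataset.bands[i])
                + "\n"
            )


def read_dominant_table(path):
    """Read a dominant-marker table written by :func:`write_dominant_table`.

    Returns a :class:`~fraglands.synthetic_data.DominantDataset`.
    """
    from .synthetic_data import DominantDataset

    text = Path(path).read_text().splitlines()
    i_sites = text.index("# sites")
    i_bands = text.index("# bands")
    site_rows = [line.split(",") for line in text[i_sites + 2 : i_bands]]
    site_xy = np.array([[float(r[1]), float(r[2])] for r in site_rows])
    band_rows = [line.split(",") for line in text[i_bands + 2 :] if line]
    site_of_individual = np.array([int(r[1]) for r in band_rows])
    bands = np.array([[int(v) for v in r[2:]] for r in band_rows], dtype=np.int8)
    distances = np.hypot(site_xy[:, 0], site_xy[:, 1])
    return DominantDataset(bands, site_of_individual, site_xy, distances)
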