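"""Post-processing of species-distribution-model suitability rasters.

Model fitting itself is out of scope: this module consumes continuous
habitat-suitability rasters produced elsewhere and implements the two
post-processing steps of a multi-model paleoprojection workflow —
correlation-based predictor pruning, and percentile-threshold binarization
followed by a cellwise multi-model consensus (cells scored by how many
models predict presence).

Rasters are single-band grids in ESRI ASCII format (plain text), with
geographic referencing given by the lower-left corner and square cell size
in decimal degrees.  No-data cells are NaN in memory.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np

from .errors import (
    GridMismatchError,
    ParameterError,
    UndefinedCorrelationError,
)

NODATA = -9999.0


@dataclass(frozen=True)
class SuitabilityRaster:
    """Continuous habitat-suitability grid in [0, 1] with NaN as no-data.

    ``grid`` rows run north→south (row 0 is the northern edge), matching
    the ESRI ASCII layout.  ``xll``/``yll`` locate the lower-left corner of
    the lower-left cell; ``cellsize`` is in decimal degrees.
    """

    grid: np.ndarray
    xll: float
    yll: float
    cellsize: float
    crs_label: str = "EPSG:4326"

    def __post_init__(self) -> None:
        g = self.grid
        if g.ndim != 2:
            raise GridMismatchError("raster grid must be 2-D")
        finite = g[np.isfinite(g)]
        if finite.size and (finite.min() < 0.0 or finite.max() > 1.0 + 1e-9):
            # consensus counts re-use this container; allow small ints too
            if not np.allclose(finite, np.round(finite)):
                raise ParameterError("suitability values outside [0, 1]")

    def same_georef(self, other: "SuitabilityRaster") -> bool:
        return (
            self.grid.shape == other.grid.shape
            and np.isclose(self.xll, other.xll)
            and np.isclose(self.yll, other.yll)
            and np.isclose(self.cellsize, other.cellsize)
        )

    def cell_of(self, lat: float, lon: float) -> tuple[int, int]:
        """(row, col) of the cell containing a geographic point."""
        nrows = self.grid.shape[0]
        col = int((lon - self.xll) / self.cellsize)
        row = nrows - 1 - int((lat - self.yll) / self.cellsize)
        if not (0 <= row < nrows and 0 <= col < self.grid.shape[1]):
            raise ParameterError(f"point ({lat}, {lon}) outside raster extent")
        return row, col

    def value_at(self, lat: float, lon: float) -> float:
        r, c = self.cell_of(lat, lon)
        return float(self.grid[r, c])


ConsensusRaster = SuitabilityRaster  # integer agreement counts, same georef


def read_ascii_grid(path: str | Path) -> SuitabilityRaster:
    """Read a single-band ESRI ASCII grid; no-data becomes NaN."""
    header: dict[str, float] = {}
    with open(path) as fh:
        lines = fh.read().split("\n")
    i = 0
    while i < len(lines) and lines[i] and not _is_number(lines[i].split()[0]):
        key, value = lines[i].split(maxsplit=1)
        header[key.lower()] = float(value)
        i += 1
    grid = np.loadtxt(lines[i:], ndmin=2)
    nodata = header.get("nodata_value", NODATA)
    grid[grid == nodata] = np.nan
    if "xllcorner" not in header or "yllcorner" not in header:
        raise ParameterError(f"{path}: missing corner coordinates in header")
    return SuitabilityRaster(
        grid=grid,
        xll=header["xllcorner"],
        yll=header["yllcorner"],
        cellsize=header["cellsize"],
    )


def _is_number(token: str) -> bool:
    try:
        float(token)
        return True
    except ValueError:
        return False


def write_ascii_grid(raster: SuitabilityRaster, path: str | Path) -> None:
    grid = np.where(np.isnan(raster.grid), NODATA, raster.grid)
    with open(path, "w") as fh:
        fh.write(f"ncols {raster.grid.shape[1]}\n")
        fh.write(f"nrows {raster.grid.shape[0]}\n")
        fh.write(f"xllcorner {raster.xll}\n")
        fh.write(f"yllcorner {raster.yll}\n")
        fh.write(f"cellsize {raster.cellsize}\n")
        fh.write(f"NODATA_value {NODATA}\n")
        for row in grid:
            fh.write(" ".join(f"{v:.6g}" for v in row) + "\n")


# ---------------------------------------------------------------------------
# predictor pruning


def prune_correlated(
    predictors: np.ndarray,
    labels: Sequence[str],
    threshold: float = 0.8,
) -> list[str]:
    """Greedy correlation filter over predictor variables.

    ``predictors`` has one column per variable, one row per location.
    Scanning in input order (e.g. BIO variable numbering), a variable is
    dropped iff |Pearson r| ≥ ``threshold`` against any already-kept
    variable; the kept labels are returned in input order.
    """
    x = np.asarray(predictors, dtype=float)
    if x.ndim != 2 or x.shape[1] != len(labels):
        raise ParameterError("predictor matrix does not match labels")
    if x.shape[1] < 2:
        raise ParameterError("need at least 2 variables")
    if not (0.0 < threshold < 1.0):
        raise ParameterError(f"threshold must be in (0, 1), got {threshold}")
    sd = x.std(axis=0)
    zero_var = np.flatnonzero(sd == 0.0)
    if zero_var.size:
        raise UndefinedCorrelationError(
            f"zero-variance variable(s): {[labels[i] for i in zero_var]}"
        )
    corr = np.corrcoef(x, rowvar=False)
    kept: list[int] = []
    for j in range(x.shape[1]):
        if all(abs(corr[j, i]) < threshold for i in kept):
            kept.append(j)
    return [labels[i] for i in kept]


# ---------------------------------------------------------------------------
# thresholding and consensus


def percentile_threshold(
    raster: SuitabilityRaster,
    presence_values: Sequence[float],
    pct: float,
) -> SuitabilityRaster:
    """Binary presence layer from a percentile of training-presence values.

    The cutoff is the ``pct``-th percentile (linear interpolation) of the
    suitability values at occurrence localities; a cell is predicted present
    (1) iff its suitability ≥ cutoff.  No-data cells stay no-data.
    """
    vals = np.asarray(presence_values, dtype=float)
    if vals.size == 0:
        raise ParameterError("presence_values must be non-empty")
    if not (0.0 <= pct <= 100.0):
        raise ParameterError(f"pct must be in [0, 100], got {pct}")
    cutoff = float(np.percentile(vals, pct))
    binary = np.where(raster.grid >= cutoff, 1.0, 0.0)
    binary[np.isnan(raster.grid)] = np.nan
    return replace(raster, grid=binary)


def cellwise_percentile_threshold(
    raster: SuitabilityRaster, pct: float
) -> SuitabilityRaster:
    """Variant taking the percentile over all finite raster cells."""
    finite = raster.grid[np.isfinite(raster.grid)]
    return percentile_threshold(raster, finite, pct)


def consensus(binaries: Sequence[SuitabilityRaster]) -> ConsensusRaster:
    """Cellwise sum of binary layers: how many models predict presence.

    No-data in any input propagates to the output.
    """
    if len(binaries) < 2:
        raise ParameterError("consensus needs at least 2 rasters")
    first = binaries[0]
    for other in binaries[1:]:
        if not first.same_georef(other):
            raise GridMismatchError("rasters differ in shape or georeferencing")
    stack = np.stack([b.grid for b in binaries])
    total = stack.sum(axis=0)  # NaN propagates through the sum
    return replace(first, grid=total)
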