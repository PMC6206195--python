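"""Synthetic geo-referenced mitochondrial datasets with known structure.

The generator emulates the sampling design the pipeline targets: 100–150
georeferenced mitochondrial sequences from a few divergent phylogroups on
an Iberia-sized landscape, with mainly allopatric group ranges, narrow
contact bands where adjacent groups overlap, river basins as longitude
bands, and a controllable fraction of within-group variance structured by
basin.

Sequence model
--------------
Sites evolve independently under the uniform ("Jukes–Cantor-like")
substitution scheme: a layer of rate ``x`` substitutes each site with
probability ``x``, uniformly over the three other bases.  Layers compose
multiplicatively in ``e = 1 − 4x/3``, and two lineages carrying independent
layers ``xa``/``xb`` from a common origin differ at a site with probability

    P(xa, xb) = 1 − [(1 − xa)(1 − xb) + xa·xb/3].

Each sample's sequence is root → group ancestor (rate g) → basin ancestor
(rate q, shared within a group×basin cell) → private mutations (rate r).
The three rates are calibrated numerically from the configuration targets:

* ``within_theta`` (per group) is the expected p-distance between two
  same-basin samples: r solves P(r, r) = t;
* ``basin_effect`` is the expected among-basin variance fraction in a
  one-way AMOVA of p-distances; q is solved from
  f = (E[d²_b] − E[d²_w]) / E[d²_b] with E[d²] = p² + p(1−p)/L
  (the number of differing sites is Binomial(L, p), so the variance term
  p(1−p)/L is part of the expectation of the squared distance);
* ``between_group_div`` is the expected p-distance between SAMPLES of
  different groups (not between bare ancestors); the group-ancestor rate g
  is solved so the compound cross-group difference probability hits it.

Because every expectation is exact under this site-independent model, the
generator's parameters are recoverable by the downstream estimators without
post-hoc tuning.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.ndimage import gaussian_filter
from scipy.optimize import brentq

from .errors import ParameterError
from .sample_filter import SampleRecord
from .sdm_postprocess import SuitabilityRaster
from .seqio_align import Alignment

#: Iberia-sized default landscape: (lat_min, lat_max, lon_min, lon_max).
DEFAULT_LANDSCAPE = (36.0, 44.0, -9.0, 3.0)
_KM_PER_DEG = 111.32

GROUP_LABELS = "ABCDEFGH"


# ---------------------------------------------------------------------------
# closed forms for the site-independent substitution model


def diff_probability(xa: float, xb: float) -> float:
    """P that two lineages with layer rates xa, xb differ at a site."""
    return 1.0 - ((1.0 - xa) * (1.0 - xb) + xa * xb / 3.0)


def compose_rates(*rates: float) -> float:
    """Total substitution probability of stacked independent layers."""
    e = 1.0
    for x in rates:
        e *= 1.0 - 4.0 * x / 3.0
    return 0.75 * (1.0 - e)


def _solve_symmetric_rate(p: float) -> float:
    """Rate x with P(x, x) = p (both lineages carrying the same layer rate)."""
    if p < 0.0 or p >= 0.75:
        raise ParameterError(f"target difference probability {p} infeasible")
    return 0.75 * (1.0 - math.sqrt(1.0 - 4.0 * p / 3.0))


def _expected_d2(p: float, length: int) -> float:
    """E[(p-distance)²] when differing sites are Binomial(length, p)."""
    return p * p + p * (1.0 - p) / length


def _solve_p_from_d2(target: float, length: int) -> float:
    """Invert _expected_d2 for p."""
    a = 1.0 - 1.0 / length
    b = 1.0 / length
    return (-b + math.sqrt(b * b + 4.0 * a * target)) / (2.0 * a)


# ---------------------------------------------------------------------------
# configuration


@dataclass(frozen=True)
class SimConfig:
    """Generator configuration; every default states the emulated study design.

    ``within_theta`` may be a single float (all groups) or one value per
    group; ``basin_effect`` is the target among-basin variance fraction of
    a one-way AMOVA run within groups; ``between_group_div`` the target
    p-distance between samples of different phylogroups.
    """

    seed: int
    n_samples: int = 132
    n_groups: int = 2
    seq_length: int = 752
    between_group_div: float = 0.0116
    within_theta: float | tuple[float, ...] = (0.004, 0.0015)
    landscape: tuple[float, float, float, float] = DEFAULT_LANDSCAPE
    contact_band_km: float = 60.0
    n_basins: int = 10
    basin_effect: float = 0.19
    hotspot_bbox: tuple[float, float, float, float] | None = None
    hotspot_theta_multiplier: float = 2.0

    def __post_init__(self) -> None:
        if self.n_samples < 1 or self.n_groups < 1 or self.n_basins < 1:
            raise ParameterError("counts must be positive")
        if self.seq_length < 1:
            raise ParameterError("seq_length must be positive")
        if not (0.0 <= self.between_group_div < 0.75):
            raise ParameterError("between_group_div outside [0, 0.75)")
        if not (0.0 <= self.basin_effect < 1.0):
            raise ParameterError("basin_effect outside [0, 1)")
        for t in self.theta_per_group():
            if not (0.0 <= t < 0.75):
                raise ParameterError("within_theta outside [0, 0.75)")
        lat0, lat1, lon0, lon1 = self.landscape
        if not (lat0 < lat1 and lon0 < lon1):
            raise ParameterError("degenerate landscape bounding box")

    def theta_per_group(self) -> tuple[float, ...]:
        t = self.within_theta
        if isinstance(t, (int, float)):
            return (float(t),) * self.n_groups
        if len(t) != self.n_groups:
            raise ParameterError(
                f"within_theta has {len(t)} entries for {self.n_groups} groups"
            )
        return tuple(float(v) for v in t)


@dataclass(frozen=True)
class CalibratedRates:
    """Per-layer substitution rates implied by a SimConfig."""

    private: tuple[float, ...]  # per group
    basin: tuple[float, ...]  # per group
    group: float  # group-ancestor rate from the root


def calibrate_rates(cfg: SimConfig) -> CalibratedRates:
    """Solve the layer rates that realize the configuration's targets."""
    length = cfg.seq_length
    private: list[float] = []
    basin: list[float] = []
    for t in cfg.theta_per_group():
        r = _solve_symmetric_rate(t)
        private.append(r)
        if t == 0.0 or cfg.basin_effect == 0.0:
            basin.append(0.0)
            continue
        p_w = diff_probability(r, r)
        d2_b = _expected_d2(p_w, length) / (1.0 - cfg.basin_effect)
        p_b = _solve_p_from_d2(d2_b, length)
        x = _solve_symmetric_rate(p_b)
        e_q = (1.0 - 4.0 * x / 3.0) / (1.0 - 4.0 * r / 3.0)
        q = 0.75 * (1.0 - e_q)
        if q < -1e-12:
            raise ParameterError("basin_effect infeasible for within_theta")
        basin.append(max(0.0, q))

    if cfg.n_groups == 1 or cfg.between_group_div == 0.0:
        return CalibratedRates(tuple(private), tuple(basin), 0.0)

    def cross_group_p(g: float) -> float:
        total = 0.0
        pairs = 0
        for i in range(cfg.n_groups):
            for j in range(i + 1, cfg.n_groups):
                xi = compose_rates(private[i], basin[i], g)
                xj = compose_rates(private[j], basin[j], g)
                total += diff_probability(xi, xj)
                pairs += 1
        return total / pairs

    floor = cross_group_p(0.0)
    if floor > cfg.between_group_div:
        raise ParameterError(
            "between_group_div smaller than the divergence implied by "
            "within-group rates alone"
        )
    g = brentq(
        lambda v: cross_group_p(v) - cfg.between_group_div, 0.0, 0.7, xtol=1e-14
    )
    return CalibratedRates(tuple(private), tuple(basin), float(g))


# ---------------------------------------------------------------------------
# landscape geometry


def _band_degrees(cfg: SimConfig) -> float:
    lat0, lat1, _, _ = cfg.landscape
    mean_lat = math.radians((lat0 + lat1) / 2.0)
    return cfg.contact_band_km / (_KM_PER_DEG * math.cos(mean_lat))


def group_lon_interval(cfg: SimConfig, group_index: int) -> tuple[float, float]:
    """Longitude range of one phylogroup: its slice of the landscape plus
    half the contact band on each interior edge."""
    _, _, lon0, lon1 = cfg.landscape
    width = (lon1 - lon0) / cfg.n_groups
    half_band = _band_degrees(cfg) / 2.0
    lo = lon0 + group_index * width
    hi = lo + width
    if group_index > 0:
        lo -= half_band
    if group_index < cfg.n_groups - 1:
        hi += half_band
    return lo, hi


def overlap_lon_intervals(cfg: SimConfig) -> list[tuple[float, float]]:
    """Contact zones: longitude intervals where adjacent group ranges overlap."""
    out = []
    for i in range(cfg.n_groups - 1):
        _, hi = group_lon_interval(cfg, i)
        lo, _ = group_lon_interval(cfg, i + 1)
        if lo < hi:
            out.append((lo, hi))
    return out


def basin_of(cfg: SimConfig, lon: float) -> str:
    """River basin as a longitude band across the full landscape."""
    _, _, lon0, lon1 = cfg.landscape
    width = (lon1 - lon0) / cfg.n_basins
    idx = min(cfg.n_basins - 1, max(0, int((lon - lon0) / width)))
    return f"basin{idx + 1:02d}"


def _in_bbox(lat: float, lon: float, bbox: tuple[float, float, float, float]) -> bool:
    lat0, lat1, lon0, lon1 = bbox
    return lat0 <= lat <= lat1 and lon0 <= lon <= lon1


# ---------------------------------------------------------------------------
# sequence simulation


def _mutate(seq: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    """Substitute each site with probability ``rate`` to a different base."""
    out = seq.copy()
    if rate <= 0.0:
        return out
    hit = np.flatnonzero(rng.random(seq.size) < rate)
    if hit.size:
        out[hit] = (out[hit] + rng.integers(1, 4, hit.size)) % 4
    return out


_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def simulate_dataset(cfg: SimConfig) -> tuple[Alignment, list[SampleRecord]]:
    """Generate an alignment plus sample table; deterministic given seed."""
    rates = calibrate_rates(cfg)
    if cfg.hotspot_bbox is not None:
        for r in rates.private:
            if compose_rates(r) * cfg.hotspot_theta_multiplier >= 0.75:
                raise ParameterError("hotspot multiplier drives rate past 3/4")
    rng = np.random.default_rng(cfg.seed)
    length = cfg.seq_length
    lat0, lat1, _, _ = cfg.landscape

    root = rng.integers(0, 4, length)
    group_anc = [_mutate(root, rates.group, rng) for _ in range(cfg.n_groups)]
    # basin ancestors for every group×basin cell, in fixed order
    basin_anc = {
        (gi, bi): _mutate(group_anc[gi], rates.basin[gi], rng)
        for gi in range(cfg.n_groups)
        for bi in range(cfg.n_basins)
    }
    _, _, lon0, lon1 = cfg.landscape
    basin_width = (lon1 - lon0) / cfg.n_basins

    names: list[str] = []
    rows: list[str] = []
    samples: list[SampleRecord] = []
    for i in range(cfg.n_samples):
        gi = i % cfg.n_groups  # balanced group sizes
        glo, ghi = group_lon_interval(cfg, gi)
        lon = rng.uniform(glo, ghi)
        lat = rng.uniform(lat0, lat1)
        bi = min(cfg.n_basins - 1, max(0, int((lon - lon0) / basin_width)))
        r = rates.private[gi]
        if cfg.hotspot_bbox is not None and _in_bbox(lat, lon, cfg.hotspot_bbox):
            r = min(0.7499, r * cfg.hotspot_theta_multiplier)
        seq = _mutate(basin_anc[(gi, bi)], r, rng)
        name = f"S{i + 1:04d}"
        names.append(name)
        rows.append(bytes(_BASES[seq]).decode("ascii"))
        samples.append(
            SampleRecord(
                id=name,
                lat=round(lat, 5),
                lon=round(lon, 5),
                basin=f"basin{bi + 1:02d}",
                phylogroup=GROUP_LABELS[gi],
                seq_name=name,
            )
        )
    return Alignment(tuple(names), tuple(rows)), samples


def simulate_flanked_partition(
    cfg: SimConfig,
    names: Sequence[str],
    core_length: int = 272,
    flank_length: int = 89,
) -> Alignment:
    """A second-locus alignment with gappy flanks around a clean core.

    Emulates a control-region fragment whose ends align poorly: every flank
    column carries a gap in at least one row, so gap-position elimination
    reduces the alignment to exactly ``core_length`` columns.
    """
    sub = SimConfig(
        seed=cfg.seed + 1,
        n_samples=len(names),
        n_groups=cfg.n_groups,
        seq_length=core_length + 2 * flank_length,
        between_group_div=cfg.between_group_div,
        within_theta=cfg.within_theta,
        landscape=cfg.landscape,
        contact_band_km=cfg.contact_band_km,
        n_basins=cfg.n_basins,
        basin_effect=cfg.basin_effect,
    )
    aln, _ = simulate_dataset(sub)
    rng = np.random.default_rng(cfg.seed + 2)
    total = sub.seq_length
    rows = []
    for row in aln.rows:
        chars = list(row)
        # each row loses a random-length run at each end (possibly empty)
        left = rng.integers(0, flank_length + 1)
        right = rng.integers(0, flank_length + 1)
        for j in range(left):
            chars[j] = "-"
        for j in range(total - right, total):
            chars[j] = "-"
        rows.append("".join(chars))
    # guarantee every flank column is gapped in >= 1 row
    rows[0] = "-" * flank_length + rows[0][flank_length : total - flank_length] + "-" * flank_length
    return Alignment(tuple(names), tuple(rows))


# ---------------------------------------------------------------------------
# raster simulation


@dataclass(frozen=True)
class RasterSimulation:
    """Suitability rasters sharing a true optimum, plus presence points."""

    rasters: list[SuitabilityRaster]
    presence_lats: np.ndarray
    presence_lons: np.ndarray
    true_center: tuple[float, float]  # (lat, lon) of the suitability optimum


def simulate_rasters(
    cfg: SimConfig,
    n_models: int = 3,
    cellsize: float = 0.25,
    model_noise: float = 0.15,
    n_presence: int = 80,
) -> RasterSimulation:
    """Smooth suitability fields with shared signal and model-specific noise.

    All models see the same Gaussian suitability bump (the "true" optimum)
    plus independent smoothed noise of amplitude ``model_noise``; presence
    points are sampled proportionally to the true field.  A one-cell
    no-data border frames every raster.
    """
    if n_models < 1:
        raise ParameterError("n_models must be positive")
    rng = np.random.default_rng(cfg.seed)
    lat0, lat1, lon0, lon1 = cfg.landscape
    nrows = int(round((lat1 - lat0) / cellsize))
    ncols = int(round((lon1 - lon0) / cellsize))
    # cell centers; row 0 = northern edge
    lats = lat1 - (np.arange(nrows) + 0.5) * cellsize
    lons = lon0 + (np.arange(ncols) + 0.5) * cellsize
    c_lat = rng.uniform(lat0 + 0.25 * (lat1 - lat0), lat1 - 0.25 * (lat1 - lat0))
    c_lon = rng.uniform(lon0 + 0.25 * (lon1 - lon0), lon1 - 0.25 * (lon1 - lon0))
    dlat = (lats[:, None] - c_lat) / 1.5
    dlon = (lons[None, :] - c_lon) / 2.0
    base = 0.1 + 0.85 * np.exp(-(dlat**2 + dlon**2) / 2.0)

    rasters: list[SuitabilityRaster] = []
    for _ in range(n_models):
        noise = gaussian_filter(rng.standard_normal((nrows, ncols)), sigma=2.0)
        noise *= model_noise / max(1e-12, np.abs(noise).max())
        grid = np.clip(base + noise, 0.0, 1.0)
        grid[0, :] = grid[-1, :] = np.nan
        grid[:, 0] = grid[:, -1] = np.nan
        rasters.append(
            SuitabilityRaster(grid=grid, xll=lon0, yll=lat0, cellsize=cellsize)
        )

    interior = base.copy()
    interior[0, :] = interior[-1, :] = 0.0
    interior[:, 0] = interior[:, -1] = 0.0
    prob = interior.ravel() / interior.sum()
    cells = rng.choice(interior.size, size=n_presence, replace=True, p=prob)
    r_idx, c_idx = np.unravel_index(cells, interior.shape)
    return RasterSimulation(
        rasters=rasters,
        presence_lats=lats[r_idx],
        presence_lons=lons[c_idx],
        true_center=(float(c_lat), float(c_lon)),
    )


# ---------------------------------------------------------------------------
# occurrence thinning


def thin_occurrences(
    lats: Sequence[float], lons: Sequence[float], cell_km: float = 1.0
) -> list[int]:
    """Indices of one occurrence per ``cell_km`` × ``cell_km`` grid cell.

    Simple grid snap (first record per cell wins) used to reduce sampling
    imbalance before model fitting.
    """
    if cell_km <= 0:
        raise ParameterError("cell_km must be positive")
    mean_lat = math.radians(float(np.mean(lats))) if len(lats) else 0.0
    dlat = cell_km / _KM_PER_DEG
    dlon = cell_km / (_KM_PER_DEG * max(1e-9, math.cos(mean_lat)))
    seen: set[tuple[int, int]] = set()
    kept: list[int] = []
    for i, (la, lo) in enumerate(zip(lats, lons)):
        key = (int(math.floor(la / dlat)), int(math.floor(lo / dlon)))
        if key not in seen:
            seen.add(key)
            kept.append(i)
    return kept
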