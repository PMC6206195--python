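"""One-way analysis of molecular variance (AMOVA) with permutation test.

Partitions squared pairwise genetic distances into among-group and
within-group variance components following the Excoffier–Smouse–Quattro
method-of-moments construction:

    SS_total  = (1/n)  Σ_{i<j}      d²_ij
    SS_within = Σ_g (1/n_g) Σ_{i<j∈g} d²_ij
    SS_among  = SS_total − SS_within
    MS        = SS / df      (df_among = k−1, df_within = n−k)
    σ²_within = MS_within
    σ²_among  = (MS_among − MS_within) / n̄,  n̄ = (n − Σ n_g²/n)/(k−1)
    Φ_ST      = σ²_among / (σ²_among + σ²_within)

Significance is assessed by permuting group labels (group sizes fixed) and
counting permutations with Φ_ST at least as large as observed, the observed
configuration included once in numerator and denominator.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .errors import (
    DegenerateGroupingError,
    ParameterError,
    UndefinedPercentageError,
)
from .diversity_stats import DistanceMatrix


@dataclass(frozen=True)
class AmovaResult:
    ss_among: float
    ss_within: float
    df_among: int
    df_within: int
    sigma2_among: float
    sigma2_within: float
    phi_st: float
    pct_among: float
    p_value: float
    n_perm: int

    @property
    def ss_total(self) -> float:
        return self.ss_among + self.ss_within

    def write_tsv(self, path: str | Path) -> None:
        fields = [
            ("ss_among", self.ss_among),
            ("ss_within", self.ss_within),
            ("df_among", self.df_among),
            ("df_within", self.df_within),
            ("sigma2_among", self.sigma2_among),
            ("sigma2_within", self.sigma2_within),
            ("phi_st", self.phi_st),
            ("pct_among", self.pct_among),
            ("p_value", self.p_value),
            ("n_perm", self.n_perm),
        ]
        with open(path, "w") as fh:
            fh.write("field\tvalue\n")
            for name, value in fields:
                fh.write(f"{name}\t{value}\n")


def _phi_and_components(
    d2: np.ndarray, group_indices: Sequence[np.ndarray], n: int, nbar: float
) -> tuple[float, float, float, float, float]:
    """(ss_among, ss_within, sigma2_among, sigma2_within, phi) for a labeling."""
    ss_total = d2.sum() / (2.0 * n)  # full matrix counts each pair twice
    ss_within = 0.0
    for idx in group_indices:
        ss_within += d2[np.ix_(idx, idx)].sum() / (2.0 * idx.size)
    ss_among = ss_total - ss_within
    k = len(group_indices)
    ms_among = ss_among / (k - 1)
    ms_within = ss_within / (n - k)
    sigma2_within = ms_within
    sigma2_among = (ms_among - ms_within) / nbar
    denom = sigma2_among + sigma2_within
    if denom == 0.0:
        phi = 0.0
    elif sigma2_within == 0.0 and sigma2_among > 0.0:
        phi = 1.0
    else:
        phi = sigma2_among / denom
    return ss_among, ss_within, sigma2_among, sigma2_within, phi


def amova_oneway(
    dist: DistanceMatrix | np.ndarray,
    groups: Sequence[str],
    n_perm: int = 999,
    seed: int = 0,
) -> AmovaResult:
    """One-level AMOVA of a distance matrix by a single grouping factor.

    Parameters
    ----------
    dist
        Symmetric pairwise distance matrix (distances are squared
        internally, the standard AMOVA convention).
    groups
        Group label per sample, aligned with the matrix order.
    n_perm
        Label permutations for the Φ_ST null; 0 skips the test
        (p_value reported as NaN).
    seed
        RNG seed; identical seeds reproduce the p-value bit-exactly.
    """
    d = dist.values if isinstance(dist, DistanceMatrix) else np.asarray(dist, float)
    n = d.shape[0]
    if len(groups) != n:
        raise ParameterError("group labels do not match matrix dimension")
    if n < 3:
        raise ParameterError("AMOVA needs at least 3 samples")
    if n_perm < 0:
        raise ParameterError("n_perm must be non-negative")

    labels = list(groups)
    unique = sorted(set(labels))
    group_indices = [
        np.flatnonzero(np.array(labels, dtype=object) == g) for g in unique
    ]
    sizes = np.array([idx.size for idx in group_indices])
    if len(unique) < 2 or (sizes == 0).any():
        raise DegenerateGroupingError("need >= 2 non-empty groups")

    k = len(unique)
    nbar = (n - (sizes**2).sum() / n) / (k - 1)
    d2 = d.astype(float) ** 2

    ss_among, ss_within, s2a, s2w, phi = _phi_and_components(
        d2, group_indices, n, nbar
    )

    if n_perm == 0:
        p_value = float("nan")
    else:
        rng = np.random.default_rng(seed)
        order = np.arange(n)
        bounds = np.cumsum(sizes)[:-1]
        exceed = 0
        for _ in range(n_perm):
            perm = rng.permutation(order)
            perm_groups = np.split(perm, bounds)
            _, _, _, _, phi_p = _phi_and_components(d2, perm_groups, n, nbar)
            if phi_p >= phi:
                exceed += 1
        p_value = (1 + exceed) / (1 + n_perm)

    denom = s2a + s2w
    pct = float("nan") if denom == 0 else 100.0 * s2a / denom
    return AmovaResult(
        ss_among=ss_among,
        ss_within=ss_within,
        df_among=k - 1,
        df_within=n - k,
        sigma2_among=s2a,
        sigma2_within=s2w,
        phi_st=phi,
        pct_among=pct,
        p_value=p_value,
        n_perm=n_perm,
    )


def pct_variation(result: AmovaResult) -> int:
    """Percent of variation among groups, rounded to the nearest integer.

    For display the value is clamped to [0, 100]; the raw (possibly
    negative) percentage stays available as ``result.pct_among``.
    """
    if result.sigma2_among == 0.0 and result.sigma2_within == 0.0:
        raise UndefinedPercentageError("both variance components are zero")
    pct = 100.0 * result.sigma2_among / (result.sigma2_among + result.sigma2_within)
    return int(round(min(100.0, max(0.0, pct))))
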