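"""Population-genetic estimators on aligned mitochondrial sequences.

Implements the classical estimators used in desk-scale phylogeography:

* p-distance — raw proportion of differing comparable sites, with pairwise
  deletion of ``N`` and ``-`` (a site is comparable only when both
  characters are in {A, C, G, T});
* nucleotide diversity π — mean pairwise p-distance over all unordered
  pairs in a sample;
* Watterson's θ_W — segregating sites scaled by the harmonic number, with
  complete deletion of columns containing any non-ACGT character so that
  S and L stay consistent;
* haplotype diversity H — unbiased gene-diversity analogue on bitwise
  haplotype frequencies;
* model-corrected pairwise distances (JC69, K80) for downstream AMOVA.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .errors import (
    AlignmentShapeError,
    InsufficientSampleError,
    SaturationError,
    UndefinedDistanceError,
)
from .seqio_align import Alignment

DistanceModel = Literal["p", "jc69", "k80"]

_ACGT = frozenset("ACGT")
_PURINES = frozenset("AG")


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric pairwise distance matrix with named rows/columns."""

    names: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = self.values
        if v.ndim != 2 or v.shape[0] != v.shape[1] or v.shape[0] != len(self.names):
            raise AlignmentShapeError("distance matrix shape does not match names")
        if not np.allclose(v, v.T):
            raise AlignmentShapeError("distance matrix not symmetric")
        if np.diagonal(v).any():
            raise AlignmentShapeError("distance matrix diagonal not zero")
        if (v < 0).any():
            raise AlignmentShapeError("negative distances")

    def write_tsv(self, path: str | Path) -> None:
        pd.DataFrame(self.values, index=self.names, columns=self.names).to_csv(
            path, sep="\t", index_label=""
        )

    @classmethod
    def read_tsv(cls, path: str | Path) -> "DistanceMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(tuple(str(c) for c in df.columns), df.to_numpy(dtype=float))


# ---------------------------------------------------------------------------
# pairwise distances


def _site_counts(a: str, b: str) -> tuple[int, int, int]:
    """(comparable sites, differences, transitions) under pairwise deletion."""
    if len(a) != len(b):
        raise AlignmentShapeError("sequences differ in length")
    comp = diff = ts = 0
    for x, y in zip(a, b):
        if x in _ACGT and y in _ACGT:
            comp += 1
            if x != y:
                diff += 1
                if (x in _PURINES) == (y in _PURINES):
                    ts += 1
    return comp, diff, ts


def pairwise_p_distance(a: str, b: str) -> float:
    """Proportion of differing sites among comparable (both-ACGT) sites."""
    comp, diff, _ = _site_counts(a, b)
    if comp == 0:
        raise UndefinedDistanceError("no comparable sites between the pair")
    return diff / comp


def _jc69(p: float) -> float:
    if p >= 0.75:
        raise SaturationError(f"JC69 undefined for p = {p:.4f} >= 3/4")
    return -0.75 * math.log1p(-4.0 * p / 3.0)


def _k80(p_ts: float, q_tv: float) -> float:
    w1 = 1.0 - 2.0 * p_ts - q_tv
    w2 = 1.0 - 2.0 * q_tv
    if w1 <= 0.0 or w2 <= 0.0:
        raise SaturationError(
            f"K80 undefined for P = {p_ts:.4f}, Q = {q_tv:.4f}"
        )
    return -0.5 * math.log(w1) - 0.25 * math.log(w2)


def pairwise_distance(a: str, b: str, model: DistanceModel = "p") -> float:
    """Pairwise distance under the requested substitution model."""
    comp, diff, ts = _site_counts(a, b)
    if comp == 0:
        raise UndefinedDistanceError("no comparable sites between the pair")
    p = diff / comp
    if model == "p":
        return p
    if model == "jc69":
        return _jc69(p)
    if model == "k80":
        return _k80(ts / comp, (diff - ts) / comp)
    raise ValueError(f"unknown model {model!r}")


def _encoded(rows: Sequence[str]) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """uint8 matrix, is-ACGT mask, is-purine mask."""
    mat = np.frombuffer("".join(rows).encode("ascii"), dtype=np.uint8).reshape(
        len(rows), -1
    )
    valid = (
        (mat == ord("A")) | (mat == ord("C")) | (mat == ord("G")) | (mat == ord("T"))
    )
    purine = (mat == ord("A")) | (mat == ord("G"))
    return mat, valid, purine


def p_distance_matrix(rows: Sequence[str]) -> np.ndarray:
    """All pairwise p-distances (vectorized; pairwise deletion)."""
    if len({len(r) for r in rows}) > 1:
        raise AlignmentShapeError("rows differ in length")
    n = len(rows)
    mat, valid, _ = _encoded(rows)
    out = np.zeros((n, n))
    for i in range(n - 1):
        both = valid[i] & valid[i + 1 :]
        comp = both.sum(axis=1)
        if (comp == 0).any():
            raise UndefinedDistanceError("a pair shares no comparable sites")
        diff = ((mat[i] != mat[i + 1 :]) & both).sum(axis=1)
        out[i, i + 1 :] = out[i + 1 :, i] = diff / comp
    return out


def distance_matrix(aln: Alignment, model: DistanceModel = "p") -> DistanceMatrix:
    """Pairwise distance matrix for an alignment under ``model``."""
    if aln.n_sequences < 2:
        raise InsufficientSampleError("need at least 2 sequences")
    if model == "p":
        return DistanceMatrix(aln.names, p_distance_matrix(aln.rows))
    n = aln.n_sequences
    out = np.zeros((n, n))
    for i in range(n - 1):
        for j in range(i + 1, n):
            out[i, j] = out[j, i] = pairwise_distance(
                aln.rows[i], aln.rows[j], model
            )
    return DistanceMatrix(aln.names, out)


# ---------------------------------------------------------------------------
# sample-level estimators


def nucleotide_diversity(rows: Sequence[str]) -> float:
    """π: mean pairwise p-distance over all n(n−1)/2 unordered pairs."""
    n = len(rows)
    if n < 2:
        raise InsufficientSampleError("π needs at least 2 sequences")
    d = p_distance_matrix(rows)
    return float(d[np.triu_indices(n, k=1)].mean())


def watterson_theta(rows: Sequence[str]) -> float:
    """θ_W = S / (a_n · L) with complete deletion of non-ACGT columns.

    S counts columns with ≥2 distinct bases among the retained columns;
    L is the number of retained columns; a_n = Σ_{i=1}^{n−1} 1/i.
    """
    n = len(rows)
    if n < 2:
        raise InsufficientSampleError("θ_W needs at least 2 sequences")
    mat, valid, _ = _encoded(rows)
    keep = valid.all(axis=0)
    length = int(keep.sum())
    if length == 0:
        raise UndefinedDistanceError("no column free of gaps/missing data")
    cols = mat[:, keep]
    segregating = int((cols != cols[0]).any(axis=0).sum())
    a_n = sum(1.0 / i for i in range(1, n))
    return segregating / (a_n * length)


def haplotype_diversity(rows: Sequence[str]) -> float:
    """H = n/(n−1) · (1 − Σ f_k²) over bitwise-identical haplotype classes."""
    n = len(rows)
    if n < 2:
        raise InsufficientSampleError("H needs at least 2 sequences")
    counts: dict[str, int] = {}
    for r in rows:
        counts[r] = counts.get(r, 0) + 1
    sum_f2 = sum((c / n) ** 2 for c in counts.values())
    return n / (n - 1) * (1.0 - sum_f2)


def between_group_p_distance(
    rows_a: Sequence[str], rows_b: Sequence[str]
) -> float:
    """Mean p-distance over all |A|×|B| cross pairs between two groups."""
    if not rows_a or not rows_b:
        raise InsufficientSampleError("both groups must be non-empty")
    total = 0.0
    for a in rows_a:
        for b in rows_b:
            total += pairwise_p_distance(a, b)
    return total / (len(rows_a) * len(rows_b))
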