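"""Population-genetic summary statistics on haplotype matrices.

These statistics certify which data features each permutation level of
:mod:`hapshuffle.permute` preserves or destroys: the allele frequency
spectrum, nucleotide diversity pi, Tajima's D, pairwise linkage
disequilibrium r^2, and Garud's haplotype-homozygosity statistics.

All statistics are computed over the non-padding columns only (after the
padding-obscuring grouping the whole width is data by construction, so the
same rule applies unchanged).  Sums over columns, pairs and haplotype
classes use :func:`math.fsum`, which returns the correctly rounded sum
independent of summand order; consequently statistics that depend only on
a *multiset* of columns are bit-identical under column permutation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations

import numpy as np

from .matrix import HaplotypeMatrix

__all__ = [
    "StatisticUndefinedError",
    "AFSpectrum",
    "column_frequencies",
    "afs",
    "nucleotide_diversity_pi",
    "tajimas_d",
    "pairwise_r2",
    "mean_r2",
    "garud_h",
    "seg_sites",
]


class StatisticUndefinedError(ValueError):
    """A statistic has no defined value on this input (e.g. S = 0)."""


def _counts(matrix: HaplotypeMatrix) -> np.ndarray:
    """Per-column 1-counts over the non-padding region (int64)."""
    return matrix.region.sum(axis=0, dtype=np.int64)


def column_frequencies(matrix: HaplotypeMatrix) -> np.ndarray:
    """Per-site allele frequency (column sum / n_hap), length n_seg."""
    return _counts(matrix) / matrix.n_hap


@dataclass
class AFSpectrum:
    """Allele frequency spectrum: counts[k] = number of sites with k copies.

    Unfolded spectra run k = 0..n_hap; folded spectra bin k with n_hap-k
    and run k = 0..floor(n_hap/2).  Sites with count 0 (or n_hap, folded
    into 0) arise only after permutation.
    """

    counts: np.ndarray
    folded: bool
    n_hap: int

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, AFSpectrum):
            return NotImplemented
        return (
            self.folded == other.folded
            and self.n_hap == other.n_hap
            and np.array_equal(self.counts, other.counts)
        )


def afs(matrix: HaplotypeMatrix, folded: bool = False) -> AFSpectrum:
    """Histogram of per-column allele counts (the AFS)."""
    n = matrix.n_hap
    c = _counts(matrix)
    hist = np.bincount(c, minlength=n + 1)
    if folded:
        half = n // 2
        folded_counts = np.zeros(half + 1, dtype=hist.dtype)
        for k in range(n + 1):
            folded_counts[min(k, n - k)] += hist[k]
        return AFSpectrum(counts=folded_counts, folded=True, n_hap=n)
    return AFSpectrum(counts=hist, folded=False, n_hap=n)


def nucleotide_diversity_pi(matrix: HaplotypeMatrix) -> float:
    """Mean pairwise Hamming distance between haplotypes (pi).

    Computed from column sums: pi = sum_j 2 c_j (n - c_j) / (n (n-1)),
    equal to the brute-force average over all unordered row pairs.
    """
    n = matrix.n_hap
    if n < 2:
        raise StatisticUndefinedError("pi requires at least 2 haplotypes")
    c = _counts(matrix)
    return math.fsum(int(2 * cj * (n - cj)) for cj in c) / (n * (n - 1))


def _tajima_constants(n: int) -> tuple[float, float]:
    """(a1, e1, e2) -> returns the pieces needed for D."""
    a1 = math.fsum(1.0 / i for i in range(1, n))
    a2 = math.fsum(1.0 / i**2 for i in range(1, n))
    b1 = (n + 1) / (3 * (n - 1))
    b2 = 2 * (n**2 + n + 3) / (9 * n * (n - 1))
    c1 = b1 - 1 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return a1, e1, e2


def tajimas_d(matrix: HaplotypeMatrix) -> float:
    """Tajima's D: normalized difference of the pi- and S-based theta estimators.

    S counts polymorphic columns (0 < c_j < n_hap); monomorphic columns,
    which occur only after permutation, are excluded.  With S = 0 the
    statistic is undefined and :class:`StatisticUndefinedError` is raised.
    """
    n = matrix.n_hap
    if n < 2:
        raise StatisticUndefinedError("Tajima's D requires at least 2 haplotypes")
    c = _counts(matrix)
    s = int(((c > 0) & (c < n)).sum())
    if s == 0:
        raise StatisticUndefinedError("Tajima's D undefined with no polymorphic site")
    a1, e1, e2 = _tajima_constants(n)
    pi = nucleotide_diversity_pi(matrix)
    return (pi - s / a1) / math.sqrt(e1 * s + e2 * s * (s - 1))


def _r2_from_counts(n: int, ca: int, cb: int, n11: int) -> float:
    p_a = ca / n
    p_b = cb / n
    p_ab = n11 / n
    d = p_ab - p_a * p_b
    # grouped so the value is symmetric in (a, b) at the bit level
    return d * d / ((p_a * (1 - p_a)) * (p_b * (1 - p_b)))


def pairwise_r2(matrix: HaplotypeMatrix, site_a: int, site_b: int) -> float:
    """Gametic linkage disequilibrium r^2 between two non-padding columns.

    Uses haplotype (phased) frequencies.  Both columns must be polymorphic.
    """
    n = matrix.n_hap
    col_a = matrix.region[:, site_a].astype(np.int64)
    col_b = matrix.region[:, site_b].astype(np.int64)
    ca, cb = int(col_a.sum()), int(col_b.sum())
    if ca in (0, n) or cb in (0, n):
        raise StatisticUndefinedError("r^2 undefined for a monomorphic column")
    n11 = int((col_a & col_b).sum())
    return _r2_from_counts(n, ca, cb, n11)


def mean_r2(matrix: HaplotypeMatrix) -> tuple[float, int]:
    """Mean r^2 over all unordered polymorphic column pairs, plus pair count."""
    n = matrix.n_hap
    region = matrix.region.astype(np.int64)
    c = region.sum(axis=0)
    poly = np.flatnonzero((c > 0) & (c < n))
    if len(poly) < 2:
        raise StatisticUndefinedError("mean r^2 needs at least two polymorphic columns")
    sub = region[:, poly]
    csub = c[poly]
    joint = sub.T @ sub  # n11 for every pair
    values = [
        _r2_from_counts(n, int(csub[i]), int(csub[j]), int(joint[i, j]))
        for i, j in combinations(range(len(poly)), 2)
    ]
    return math.fsum(values) / len(values), len(values)


def garud_h(matrix: HaplotypeMatrix) -> tuple[float, float, float]:
    """Garud's haplotype homozygosity statistics (H1, H12, H2/H1).

    With sorted haplotype frequencies p1 >= p2 >= ...:
    H1 = sum p_i^2, H12 = (p1 + p2)^2 + sum_{i>=3} p_i^2,
    H2/H1 = (H1 - p1^2) / H1.  Elevated H1 marks reduced haplotype
    diversity, the classic hard-sweep signature.
    """
    n = matrix.n_hap
    _, counts = np.unique(matrix.region, axis=0, return_counts=True)
    p = np.sort(counts / n)[::-1]
    h1 = math.fsum(float(x) ** 2 for x in p)
    if len(p) >= 2:
        h12 = (float(p[0]) + float(p[1])) ** 2 + math.fsum(float(x) ** 2 for x in p[2:])
    else:
        h12 = h1
    h2_h1 = (h1 - float(p[0]) ** 2) / h1
    return h1, h12, h2_h1


def seg_sites(matrix: HaplotypeMatrix) -> tuple[int, int]:
    """(declared, polymorphic) segregating-site counts.

    ``declared`` is the padding-implied count n_seg; ``polymorphic`` counts
    columns with 0 < c_j < n_hap.  The two coincide on freshly simulated
    data and diverge after permutations.
    """
    n = matrix.n_hap
    c = _counts(matrix)
    return matrix.n_seg, int(((c > 0) & (c < n)).sum())
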