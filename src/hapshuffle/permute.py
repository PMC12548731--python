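"""The permutation ladder: five increasingly disruptive matrix shuffles.

Permutation feature importance for haplotype-matrix predictors works by
destroying one population-genetic feature at a time inside each test
matrix and measuring how much a trained model's performance drops.  The
ladder, from least to most disruptive:

ORIGINAL            identity (baseline).
COLS                shuffle whole non-padding columns: destroys genomic
                    positions; preserves the column multiset, hence the
                    AFS, pi, Tajima's D, haplotype classes and the
                    multiset of pairwise r^2 values.
COLS_WITHIN         shuffle columns, then entries within each column:
                    additionally destroys haplotype structure and LD;
                    preserves per-column sums, hence the AFS, pi, D.
ALL_ENTRIES         shuffle every non-padding entry: destroys the AFS
                    (column frequencies become concentrated around the
                    mean); preserves only the grand total of 1s.
GROUP_KEEP_PAD      pack all 1s against the padding boundary: almost all
                    column frequencies become 0 or 1, shifting the median
                    allele frequency; padding stays visible.
GROUP_OBSCURE_PAD   pack all 1s from column 0 so trailing data zeros blend
                    into the padding: additionally erases the implied
                    number of segregating sites.

All shuffles act on non-padding cells only; padding is never touched
(except that the final grouping deliberately erases the boundary).  The
positions vector is dropped by every disruptive level, since genomic
positions are exactly the first feature destroyed.
"""

from __future__ import annotations

from dataclasses import replace
from enum import Enum

import numpy as np

from ._seeding import child_seed, rng_for
from .dataset import LabeledDataset
from .matrix import HaplotypeMatrix

__all__ = [
    "PermutationLevel",
    "permute_columns",
    "permute_within_columns",
    "permute_all_entries",
    "group_alleles",
    "apply_level",
    "apply_to_dataset",
]


class PermutationLevel(Enum):
    """The six treatment levels, ordered by disruptiveness."""

    ORIGINAL = "original"
    COLS = "cols"
    COLS_WITHIN = "cols-within"
    ALL_ENTRIES = "all-entries"
    GROUP_KEEP_PAD = "group-keep-pad"
    GROUP_OBSCURE_PAD = "group-obscure-pad"

    @property
    def disrupted_features(self) -> str:
        return _DISRUPTED[self]

    @property
    def rank(self) -> int:
        return list(PermutationLevel).index(self)


_DISRUPTED = {
    PermutationLevel.ORIGINAL: "nothing (baseline)",
    PermutationLevel.COLS: "genomic positions of segregating sites",
    PermutationLevel.COLS_WITHIN: "haplotype structure and linkage disequilibrium",
    PermutationLevel.ALL_ENTRIES: "allele frequency spectrum",
    PermutationLevel.GROUP_KEEP_PAD: "median allele frequency",
    PermutationLevel.GROUP_OBSCURE_PAD: "implied number of segregating sites",
}


def permute_columns(matrix: HaplotypeMatrix, seed: int) -> HaplotypeMatrix:
    """Uniformly shuffle whole non-padding columns; padding untouched.

    The positions field is dropped: site coordinates are the feature this
    level destroys.  Deterministic given ``seed``.
    """
    out = matrix.copy()
    out = replace(out, positions=None)
    if matrix.n_seg > 1:
        perm = rng_for(seed).permutation(matrix.n_seg)
        out.data[:, : matrix.n_seg] = matrix.data[:, perm]
    return out


def permute_within_columns(matrix: HaplotypeMatrix, seed: int) -> HaplotypeMatrix:
    """Shuffle whole columns, then entries within each column independently.

    Equivalent to :func:`permute_columns` followed by a per-column uniform
    shuffle of the ``n_hap`` entries; per-column sums are preserved.
    """
    out = permute_columns(matrix, child_seed(seed, 0))
    rng = rng_for(child_seed(seed, 1))
    for j in range(out.n_seg):
        out.data[:, j] = rng.permutation(out.data[:, j])
    return out


def permute_all_entries(matrix: HaplotypeMatrix, seed: int) -> HaplotypeMatrix:
    """Uniformly shuffle all n_hap x n_seg non-padding entries as one pool."""
    out = matrix.copy()
    out = replace(out, positions=None)
    if matrix.n_seg > 0:
        flat = matrix.region.reshape(-1)
        out.data[:, : matrix.n_seg] = rng_for(seed).permutation(flat).reshape(
            matrix.n_hap, matrix.n_seg
        )
    return out


def group_alleles(matrix: HaplotypeMatrix, mode: str = "keep_padding") -> HaplotypeMatrix:
    """Pack all 1s into a contiguous column-major block (deterministic).

    ``keep_padding``: 1s fill columns starting from the rightmost
    non-padding column (index ``n_seg - 1``) moving left, rows
    top-to-bottom within a column, so the block abuts the padding boundary
    and the boundary stays visible.

    ``obscure_padding``: 1s fill from column 0 moving right; all remaining
    cells — former data zeros and former padding alike — are
    indistinguishable zeros.  ``n_seg`` becomes ``width`` and
    ``padding_obscured`` is set.

    Either way at most one column is mixed; every other column is all-0 or
    all-1, so almost all allele frequencies become zero or one.
    """
    if mode not in ("keep_padding", "obscure_padding"):
        raise ValueError(f"unknown grouping mode {mode!r}")
    n, width, n_seg = matrix.n_hap, matrix.width, matrix.n_seg
    k = int(matrix.region.sum(dtype=np.int64))
    data = np.zeros((n, width), dtype=np.uint8)
    full, rem = divmod(k, n)
    if mode == "keep_padding":
        cols = range(n_seg - 1, n_seg - 1 - full, -1)
        rem_col = n_seg - 1 - full
    else:
        cols = range(full)
        rem_col = full
    for j in cols:
        data[:, j] = 1
    if rem:
        data[:rem, rem_col] = 1
    if mode == "keep_padding":
        return replace(matrix, data=data, positions=None)
    return replace(
        matrix, data=data, n_seg=width, positions=None, padding_obscured=True
    )


def apply_level(
    matrix: HaplotypeMatrix, level: PermutationLevel, seed: int = 0
) -> HaplotypeMatrix:
    """Dispatch to the operation for ``level``; ORIGINAL is the identity.

    ``seed`` is ignored by the deterministic levels (ORIGINAL and the two
    groupings).
    """
    level = PermutationLevel(level)
    if level is PermutationLevel.ORIGINAL:
        return matrix.copy()
    if level is PermutationLevel.COLS:
        return permute_columns(matrix, seed)
    if level is PermutationLevel.COLS_WITHIN:
        return permute_within_columns(matrix, seed)
    if level is PermutationLevel.ALL_ENTRIES:
        return permute_all_entries(matrix, seed)
    if level is PermutationLevel.GROUP_KEEP_PAD:
        return group_alleles(matrix, "keep_padding")
    if level is PermutationLevel.GROUP_OBSCURE_PAD:
        return group_alleles(matrix, "obscure_padding")
    raise ValueError(f"unknown permutation level {level!r}")


def apply_to_dataset(
    dataset: LabeledDataset, level: PermutationLevel, base_seed: int
) -> LabeledDataset:
    """Permute every matrix of a dataset at one level; labels untouched.

    Matrix ``i`` is permuted with the per-matrix seed derived from
    ``(base_seed, i)``, so the whole transformed dataset is reproducible
    from ``base_seed`` alone.
    """
    matrices = [
        apply_level(m, level, child_seed(base_seed, i))
        for i, m in enumerate(dataset.matrices)
    ]
    meta = dict(dataset.meta)
    meta.update(permutation_level=PermutationLevel(level).value, permutation_seed=int(base_seed))
    return LabeledDataset(
        matrices=matrices,
        labels=list(dataset.labels),
        label_names=list(dataset.label_names),
        task=dataset.task,
        meta=meta,
    )
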