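"""Extract padded haplotype-matrix windows from phased VCF.

One matrix row per haplotype (two per diploid sample, sample-major,
allele 0 then allele 1); one column per biallelic SNP passing filters, in
coordinate order.  Regions are 0-based half-open; VCF POS (1-based) is
converted on the fly.  Multiallelic sites and indels are skipped with a
logged warning; unphased or missing genotypes are hard errors, because
silently imputing them would corrupt haplotype structure.
"""

from __future__ import annotations

import logging
from typing import Union

import numpy as np
from cyvcf2 import VCF

from .matrix import HaplotypeMatrix, pad_to_width

__all__ = ["from_vcf_window"]

logger = logging.getLogger(__name__)


def from_vcf_window(
    vcf_path: Union[str, "VCF"],
    contig: str,
    start: int,
    end: int,
    max_sites: int,
    coding: str = "alternate",
    ancestral_tag: str = "AA",
) -> HaplotypeMatrix:
    """Build a haplotype matrix from phased genotypes in [start, end).

    Parameters
    ----------
    vcf_path
        Path to a VCF file (plain text or bgzipped), or an open
        :class:`cyvcf2.VCF`.  Records are scanned sequentially, so no
        tabix index is required.
    contig, start, end
        Region to extract, 0-based half-open on ``contig``.
    max_sites
        Target width; the window is truncated to the first ``max_sites``
        sites and zero-padded up to ``max_sites`` otherwise.
    coding
        ``alternate``: ALT coded 1.  ``minor``: the less frequent allele
        in the window coded 1 (ties at 1/2 keep ALT as 1).  ``derived``:
        the non-ancestral allele coded 1, requiring the ancestral-allele
        INFO tag (``ancestral_tag``, default "AA") on every record.
    """
    if max_sites < 1:
        raise ValueError("max_sites must be positive")
    if end <= start:
        raise ValueError("region must be non-empty (end > start)")
    if coding not in ("alternate", "minor", "derived"):
        raise ValueError(f"unknown coding {coding!r}")
    vcf = VCF(vcf_path) if not isinstance(vcf_path, VCF) else vcf_path
    n_hap = 2 * len(vcf.samples)
    columns: list[np.ndarray] = []
    positions: list[int] = []
    for rec in vcf:
        if rec.CHROM != contig:
            continue
        pos0 = rec.POS - 1
        if pos0 < start or pos0 >= end:
            continue
        if len(rec.ALT) != 1 or not rec.is_snp:
            logger.warning(
                "skipping non-biallelic-SNP record %s:%d (%s>%s)",
                rec.CHROM, rec.POS, rec.REF, ",".join(rec.ALT) or ".",
            )
            continue
        col = np.empty(n_hap, dtype=np.uint8)
        for s, gt in enumerate(rec.genotypes):
            a0, a1, phased = gt[0], gt[1], gt[-1]
            if a0 < 0 or a1 < 0:
                raise ValueError(
                    f"missing genotype at {rec.CHROM}:{rec.POS} sample {vcf.samples[s]}"
                )
            if not phased and a0 != a1:
                raise ValueError(
                    f"unphased genotype at {rec.CHROM}:{rec.POS} sample {vcf.samples[s]}"
                )
            col[2 * s] = a0
            col[2 * s + 1] = a1
        if coding == "derived":
            aa = rec.INFO.get(ancestral_tag)
            if aa is None:
                raise ValueError(
                    f"derived coding requested but INFO/{ancestral_tag} missing "
                    f"at {rec.CHROM}:{rec.POS}"
                )
            aa = str(aa).upper()
            if aa == rec.ALT[0].upper():
                col = 1 - col  # ancestral is ALT: derived allele is REF
            elif aa != rec.REF.upper():
                logger.warning(
                    "skipping %s:%d: ancestral allele %r matches neither REF nor ALT",
                    rec.CHROM, rec.POS, aa,
                )
                continue
        columns.append(col)
        positions.append(pos0)
        if len(columns) >= max_sites:
            break
    if not columns:
        data = np.zeros((n_hap, max_sites), dtype=np.uint8)
        return HaplotypeMatrix(
            data=data, n_seg=0, positions=np.empty(0, dtype=np.int64),
            allele_coding=coding,
        )
    data = np.column_stack(columns)
    if coding == "minor":
        freqs = data.mean(axis=0)
        flip = freqs > 0.5
        data[:, flip] = 1 - data[:, flip]
    matrix = HaplotypeMatrix(
        data=data,
        n_seg=data.shape[1],
        positions=np.asarray(positions, dtype=np.int64),
        allele_coding=coding,
    )
    return pad_to_width(matrix, max_sites)
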