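"""Padded binary haplotype matrices and their plain-text serialization.

A haplotype matrix encodes phased genetic variation for a sample of
haplotypes: rows are haplotypes, columns are segregating sites ordered by
genomic position, and entries are 0 (reference/major/ancestral allele) or 1
(alternate/minor/derived allele).  Because fixed-input-size predictors
require matrices of a common width, matrices carry trailing all-zero
*padding* columns; the number of genuine data columns is recorded
explicitly in ``n_seg`` rather than inferred from trailing zeros, since
permutations can legitimately produce all-zero data columns.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import IO, Iterable, Optional

import numpy as np

__all__ = [
    "HaplotypeMatrix",
    "MatrixParseError",
    "validate",
    "pad_to_width",
    "read_matrix_text",
    "write_matrix_text",
]

_CODINGS = ("derived", "minor", "alternate")


class MatrixParseError(ValueError):
    """Raised when a text-dialect stream cannot be parsed.

    Carries the 1-based line number of the first offending line.
    """

    def __init__(self, message: str, line: Optional[int] = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


@dataclass
class HaplotypeMatrix:
    """Binary haplotype matrix with an explicit padding boundary.

    Parameters
    ----------
    data
        ``(n_hap, width)`` array of 0/1 entries (stored as ``uint8``).
    n_seg
        Number of non-padding columns; columns ``>= n_seg`` are all zero.
    positions
        Optional sorted genomic coordinates, one per non-padding column.
    allele_coding
        Which allele the 1s encode: ``"derived"``, ``"minor"`` or
        ``"alternate"``.
    padding_obscured
        Set only by the most drastic allele grouping, which erases the
        padding boundary; implies ``n_seg == width``.
    """

    data: np.ndarray
    n_seg: int
    positions: Optional[np.ndarray] = None
    allele_coding: str = "derived"
    padding_obscured: bool = False

    def __post_init__(self) -> None:
        self.data = np.ascontiguousarray(self.data, dtype=np.uint8)
        if self.data.ndim != 2:
            raise ValueError("data must be a 2-D array")
        self.n_seg = int(self.n_seg)
        if self.positions is not None:
            self.positions = np.asarray(self.positions)

    @property
    def n_hap(self) -> int:
        return self.data.shape[0]

    @property
    def width(self) -> int:
        return self.data.shape[1]

    @property
    def region(self) -> np.ndarray:
        """View of the non-padding columns ``[0, n_seg)``."""
        return self.data[:, : self.n_seg]

    def copy(self) -> "HaplotypeMatrix":
        return replace(
            self,
            data=self.data.copy(),
            positions=None if self.positions is None else self.positions.copy(),
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, HaplotypeMatrix):
            return NotImplemented
        if self.positions is None or other.positions is None:
            pos_eq = self.positions is None and other.positions is None
        else:
            pos_eq = np.array_equal(self.positions, other.positions)
        return (
            np.array_equal(self.data, other.data)
            and self.n_seg == other.n_seg
            and pos_eq
            and self.allele_coding == other.allele_coding
            and self.padding_obscured == other.padding_obscured
        )


def validate(matrix: HaplotypeMatrix) -> list[str]:
    """Check the type invariants; return a list of violations (empty = pass).

    Violations are reported, never raised, and each names the first
    offending index.
    """
    out: list[str] = []
    data = matrix.data
    bad = np.argwhere(data > 1)
    if bad.size:
        r, c = bad[0]
        out.append(f"non-binary entry at row {r}, column {c}")
    if not 0 <= matrix.n_seg <= matrix.width:
        out.append(f"n_seg={matrix.n_seg} outside [0, width={matrix.width}]")
    else:
        pad = data[:, matrix.n_seg :]
        nz = np.argwhere(pad != 0)
        if nz.size and not matrix.padding_obscured:
            r, c = nz[0]
            out.append(f"non-zero entry in padding column {int(c) + matrix.n_seg}")
    if matrix.padding_obscured and matrix.n_seg != matrix.width:
        out.append("padding_obscured set but n_seg != width")
    if matrix.positions is not None:
        if len(matrix.positions) != matrix.n_seg:
            out.append(
                f"positions has {len(matrix.positions)} entries, expected n_seg={matrix.n_seg}"
            )
        elif len(matrix.positions) > 1:
            diffs = np.diff(matrix.positions)
            if (diffs < 0).any():
                i = int(np.argmax(diffs < 0))
                out.append(f"positions not sorted at index {i + 1}")
    if matrix.allele_coding not in _CODINGS:
        out.append(f"unknown allele_coding {matrix.allele_coding!r}")
    return out


def pad_to_width(matrix: HaplotypeMatrix, width: int) -> HaplotypeMatrix:
    """Append zero columns so the matrix reaches ``width`` total columns.

    Truncation is not supported: ``width`` must be at least ``n_seg``.
    """
    width = int(width)
    if width < matrix.n_seg:
        raise ValueError(
            f"cannot pad to width {width} < n_seg {matrix.n_seg}: truncation not supported"
        )
    out = np.zeros((matrix.n_hap, width), dtype=np.uint8)
    out[:, : matrix.n_seg] = matrix.region
    return replace(matrix, data=out)


# --- plain-text dialect -------------------------------------------------
#
# Header line:   #hapmatrix n_hap=<int> width=<int> n_seg=<int> coding=<word>
#                (an extra "obscured=1" records padding_obscured)
# Optional line: #positions <space-separated ints>
# Then n_hap rows of exactly `width` characters from {0,1}, no separators.


def write_matrix_text(matrix: HaplotypeMatrix, stream: IO[str]) -> None:
    header = (
        f"#hapmatrix n_hap={matrix.n_hap} width={matrix.width} "
        f"n_seg={matrix.n_seg} coding={matrix.allele_coding}"
    )
    if matrix.padding_obscured:
        header += " obscured=1"
    stream.write(header + "\n")
    if matrix.positions is not None:
        stream.write("#positions " + " ".join(str(int(p)) for p in matrix.positions) + "\n")
    for row in matrix.data:
        stream.write("".join("1" if v else "0" for v in row) + "\n")


def read_matrix_text(stream: IO[str]) -> HaplotypeMatrix:
    lines = stream.read().splitlines()
    if not lines or not lines[0].startswith("#hapmatrix"):
        raise MatrixParseError("missing '#hapmatrix' header", line=1)
    fields = {}
    for tok in lines[0].split()[1:]:
        if "=" not in tok:
            raise MatrixParseError(f"malformed header token {tok!r}", line=1)
        k, v = tok.split("=", 1)
        fields[k] = v
    try:
        n_hap = int(fields["n_hap"])
        width = int(fields["width"])
        n_seg = int(fields["n_seg"])
        coding = fields["coding"]
    except (KeyError, ValueError) as exc:
        raise MatrixParseError(f"bad header: {exc}", line=1) from None
    if coding not in _CODINGS:
        raise MatrixParseError(f"unknown coding {coding!r}", line=1)
    obscured = fields.get("obscured", "0") == "1"

    idx = 1
    positions = None
    if idx < len(lines) and lines[idx].startswith("#positions"):
        toks = lines[idx].split()[1:]
        try:
            positions = np.array([int(t) for t in toks], dtype=np.int64)
        except ValueError:
            raise MatrixParseError("non-integer position", line=idx + 1) from None
        idx += 1

    rows = lines[idx:]
    if len(rows) != n_hap:
        raise MatrixParseError(
            f"expected {n_hap} matrix rows, found {len(rows)}", line=idx + 1
        )
    data = np.empty((n_hap, width), dtype=np.uint8)
    for i, row in enumerate(rows):
        lineno = idx + 1 + i
        if len(row) != width:
            raise MatrixParseError(
                f"row has {len(row)} characters, expected {width}", line=lineno
            )
        arr = np.frombuffer(row.encode("ascii", "replace"), dtype=np.uint8) - ord("0")
        if not np.isin(arr, (0, 1)).all():
            j = int(np.argmax(~np.isin(arr, (0, 1))))
            raise MatrixParseError(f"non-binary character at column {j}", line=lineno)
        data[i] = arr

    matrix = HaplotypeMatrix(
        data=data,
        n_seg=n_seg,
        positions=positions,
        allele_coding=coding,
        padding_obscured=obscured,
    )
    problems = validate(matrix)
    if problems:
        raise MatrixParseError("invalid matrix: " + "; ".join(problems))
    return matrix
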