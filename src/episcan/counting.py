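"""Contingency-table construction for 1-4-SNV genotype combinations.

Three interchangeable counting paths build the same 3^m x 2 table of
genotype-combination counts per cohort:

* :func:`count_1vector` — the fast path.  Each SNV is one byte vector
  (2-bit genotype per sample); tuple slot j is pre-shifted by 2j bits,
  the m vectors are OR-ed into a single combined byte per sample, and a
  256-bin byte histogram is mapped onto contingency rows.  Per-test
  cost is independent of the order m.
* :func:`count_3vector` — the classical reference path: three one-bit
  indicator vectors per SNV (one per genotype), AND-ed across the tuple
  and popcounted, at 3^m AND/popcount passes per test.
* :func:`count_naive` — direct per-sample grouping; the test oracle.

Row index r of an m-tuple encodes genotypes g_1..g_m (g_j for tuple
slot j) little-endian in base 3: r = sum_j g_j * 3^(j-1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .genotype_io import (
    CASE,
    CONTROL,
    EncodedCohort,
    GenotypeMatrix,
    PhenotypeVector,
)

MAX_ORDER = 4  # an 8-bit byte holds at most four 2-bit genotypes

#: powers of 3 for row indexing, slot j weighted 3**j
_POW3 = np.array([1, 3, 9, 27], dtype=np.int64)


class CountingError(ValueError):
    """Invalid tuple or corrupt encoded data."""


@dataclass(frozen=True)
class ContingencyTable:
    """3^m x 2 genotype-combination counts; column 0 = case, 1 = control."""

    m: int
    counts: np.ndarray  # (3**m, 2) int64

    def __post_init__(self) -> None:
        c = np.asarray(self.counts, dtype=np.int64)
        if c.shape != (3 ** self.m, 2):
            raise CountingError(
                f"order-{self.m} table must be {3 ** self.m} x 2, got {c.shape}"
            )
        if (c < 0).any():
            raise CountingError("negative cell count")
        object.__setattr__(self, "counts", c)

    @property
    def n(self) -> int:
        return int(self.counts.sum())

    @property
    def case_counts(self) -> np.ndarray:
        return self.counts[:, 0]

    @property
    def control_counts(self) -> np.ndarray:
        return self.counts[:, 1]

    def cell(self, genotypes: tuple[int, ...]) -> tuple[int, int]:
        """(case, control) counts for an explicit genotype combination."""
        if len(genotypes) != self.m:
            raise CountingError(f"expected {self.m} genotypes")
        row = int(np.dot(genotypes, _POW3[: self.m]))
        return int(self.counts[row, 0]), int(self.counts[row, 1])

    def to_tsv(self, snv_ids: tuple[str, ...] | None = None) -> str:
        """Debug dump: one row per genotype combination, case and control."""
        labels = {0: "0/0", 1: "0/1", 2: "1/1"}
        names = snv_ids or tuple(f"SNV{j + 1}" for j in range(self.m))
        lines = ["\t".join([*names, "Case", "Control"])]
        for row in range(3 ** self.m):
            g = decode_row(row, self.m)
            lines.append(
                "\t".join(
                    [*(labels[x] for x in g),
                     str(int(self.counts[row, 0])),
                     str(int(self.counts[row, 1]))]
                )
            )
        return "\n".join(lines) + "\n"


def decode_row(row: int, m: int) -> tuple[int, ...]:
    """Inverse of the base-3 row encoding: row -> (g_1, ..., g_m)."""
    g = []
    for _ in range(m):
        g.append(row % 3)
        row //= 3
    return tuple(g)


def byte_to_row(byte_value: int, m: int) -> int:
    """Map a combined-genotype byte onto its contingency-table row.

    Tuple slot j (1-based) occupies bits 2(j-1)..2j-1 of the byte.
    Each 2-bit field must hold 0, 1 or 2 and fields above slot m must
    be zero.
    """
    if not 1 <= m <= MAX_ORDER:
        raise CountingError(f"order must be 1..{MAX_ORDER}, got {m}")
    if not 0 <= byte_value <= 255:
        raise CountingError(f"byte value out of range: {byte_value}")
    row = 0
    for j in range(4):
        g = (byte_value >> (2 * j)) & 0b11
        if j >= m:
            if g:
                raise CountingError(
                    f"invalid combined genotype byte {byte_value:#010b}: "
                    f"nonzero field above position {m}"
                )
        elif g == 0b11:
            raise CountingError(
                f"invalid combined genotype byte {byte_value:#010b}: "
                f"field {j + 1} is 0b11"
            )
        else:
            row += g * int(_POW3[j])
    return row


def _row_map(m: int) -> tuple[np.ndarray, np.ndarray]:
    """(valid byte values, their rows) for order m, both length 3^m."""
    bytes_, rows = [], []
    for b in range(256):
        try:
            rows.append(byte_to_row(b, m))
        except CountingError:
            continue
        bytes_.append(b)
    return np.array(bytes_, dtype=np.intp), np.array(rows, dtype=np.intp)


_ROW_MAPS = {m: _row_map(m) for m in range(1, MAX_ORDER + 1)}


def _check_tuple(snv_tuple: tuple[int, ...], n_snvs: int) -> int:
    m = len(snv_tuple)
    if not 1 <= m <= MAX_ORDER:
        raise CountingError(
            f"tuple order must be 1..{MAX_ORDER} (a byte holds at most "
            f"{MAX_ORDER} two-bit genotypes), got {m}"
        )
    if len(set(snv_tuple)) != m:
        raise CountingError(f"duplicate SNV in tuple {snv_tuple}")
    if any(not 0 <= i < n_snvs for i in snv_tuple):
        raise CountingError(f"SNV index out of range in tuple {snv_tuple}")
    return m


def combine_bytes(cohort: EncodedCohort, snv_tuple: tuple[int, ...]) -> np.ndarray:
    """OR the tuple's pre-shifted byte vectors into one byte per sample."""
    combined = cohort.shifted(0)[snv_tuple[0]]
    for slot, snv in enumerate(snv_tuple[1:], start=1):
        combined = combined | cohort.shifted(slot)[snv]
    return combined


def _histogram_column(combined: np.ndarray, m: int) -> np.ndarray:
    hist = np.bincount(combined, minlength=256)
    valid, rows = _ROW_MAPS[m]
    column = np.zeros(3 ** m, dtype=np.int64)
    column[rows] = hist[valid]
    if column.sum() != combined.size:
        bad = np.setdiff1d(np.nonzero(hist)[0], valid)
        raise CountingError(
            f"corrupt encoded data: invalid combined byte values {bad.tolist()}"
        )
    return column


def count_1vector(
    case: EncodedCohort, control: EncodedCohort, snv_tuple: tuple[int, ...]
) -> ContingencyTable:
    """Build the contingency table via the combined-byte histogram.

    Per cohort: OR the m pre-shifted byte vectors, histogram the 256
    possible byte values, and map the 3^m valid genotype-combination
    patterns onto rows.  Any count in an invalid pattern raises.
    """
    m = _check_tuple(snv_tuple, case.n_snvs)
    if case.cohort != CASE or control.cohort != CONTROL:
        raise CountingError("arguments must be (case cohort, control cohort)")
    counts = np.column_stack(
        [_histogram_column(combine_bytes(c, snv_tuple), m) for c in (case, control)]
    )
    return ContingencyTable(m=m, counts=counts)


def count_3vector(
    matrix: GenotypeMatrix,
    phenotype: PhenotypeVector,
    snv_tuple: tuple[int, ...],
) -> ContingencyTable:
    """Reference path: per-genotype one-bit indicator vectors.

    Each SNV contributes three bit-vectors (one per genotype, one bit
    per sample, packed 8 samples per byte word).  For every genotype
    combination the m indicators are AND-ed and the set bits counted.
    """
    m = _check_tuple(snv_tuple, matrix.n_snvs)
    phenotype.require_both_cohorts()
    counts = np.zeros((3 ** m, 2), dtype=np.int64)
    for col, mask in ((0, phenotype.case_mask), (1, ~phenotype.case_mask)):
        geno = matrix.genotypes[mask]  # (s, n_snvs)
        # indicators[i][g]: packed bits, sample j set iff genotype == g
        indicators = [
            [np.packbits(geno[:, snv] == g) for g in range(3)]
            for snv in snv_tuple
        ]
        for row in range(3 ** m):
            combo = decode_row(row, m)
            r = indicators[0][combo[0]]
            for j in range(1, m):
                r = r & indicators[j][combo[j]]
            counts[row, col] = int(np.bitwise_count(r).sum())
    return ContingencyTable(m=m, counts=counts)


def count_naive(
    matrix: GenotypeMatrix,
    phenotype: PhenotypeVector,
    snv_tuple: tuple[int, ...],
) -> ContingencyTable:
    """Oracle path: compute each sample's row index and tally directly."""
    m = _check_tuple(snv_tuple, matrix.n_snvs)
    phenotype.require_both_cohorts()
    rows = rows_per_sample(matrix, snv_tuple)
    counts = np.zeros((3 ** m, 2), dtype=np.int64)
    for col, mask in ((0, phenotype.case_mask), (1, ~phenotype.case_mask)):
        counts[:, col] = np.bincount(rows[mask], minlength=3 ** m)
    return ContingencyTable(m=m, counts=counts)


def rows_per_sample(
    matrix: GenotypeMatrix, snv_tuple: tuple[int, ...]
) -> np.ndarray:
    """Row index of every sample for the given tuple (base-3 encoding)."""
    m = _check_tuple(snv_tuple, matrix.n_snvs)
    geno = matrix.genotypes[:, list(snv_tuple)].astype(np.int64)
    return geno @ _POW3[:m]
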