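"""Genotype/phenotype input-output and bitwise cohort encoding.

Case/control genotype data for a set of bi-allelic SNVs is held as a
samples x SNVs matrix of genotype codes:

    0 = homozygous reference (0/0)
    1 = heterozygous          (0/1)
    2 = homozygous alternate  (1/1)

Two on-disk representations are supported: a plain genotype table
(TSV/CSV, samples as rows) and a bi-allelic VCF with a separate
sample->phenotype file.

For counting, each cohort (cases, controls) is encoded separately: one
byte per sample per SNV holding the 2-bit genotype, plus pre-shifted
copies at 2, 4 and 6 bits.  Shifting is precomputed once so that an
m-SNV combination is formed by OR-ing m byte vectors with no per-test
shift work.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field
from pathlib import Path
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: byte shift applied to tuple slot j (0-based): slot j occupies bits 2j..2j+1
SHIFT_LEVELS = (0, 2, 4, 6)

CASE = "case"
CONTROL = "control"


class GenotypeError(ValueError):
    """Invalid genotype data (bad code, missing value, malformed file)."""


@dataclass(frozen=True)
class GenotypeMatrix:
    """Samples x SNVs matrix of genotype codes in {0, 1, 2}."""

    snv_ids: tuple[str, ...]
    genotypes: np.ndarray  # (n_samples, n_snvs) uint8
    sample_ids: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        g = np.asarray(self.genotypes, dtype=np.uint8)
        if g.ndim != 2:
            raise GenotypeError("genotypes must be a 2-D samples x SNVs array")
        if g.shape[1] != len(self.snv_ids):
            raise GenotypeError(
                f"{len(self.snv_ids)} SNV ids but {g.shape[1]} genotype columns"
            )
        if len(set(self.snv_ids)) != len(self.snv_ids):
            raise GenotypeError("duplicate SNV ids")
        if any(not s for s in self.snv_ids):
            raise GenotypeError("unnamed SNV column")
        if g.size and g.max() > 2:
            bad = np.argwhere(g > 2)[0]
            raise GenotypeError(
                f"invalid genotype code {int(g[tuple(bad)])} at sample row "
                f"{int(bad[0])}, SNV '{self.snv_ids[int(bad[1])]}' "
                "(codes must be 0, 1 or 2)"
            )
        object.__setattr__(self, "genotypes", g)

    @property
    def n_samples(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_snvs(self) -> int:
        return self.genotypes.shape[1]

    def snv_index(self, snv_id: str) -> int:
        return self.snv_ids.index(snv_id)


@dataclass(frozen=True)
class PhenotypeVector:
    """Case/control labels per sample; 1 = case, 0 = control."""

    labels: np.ndarray  # (n_samples,) uint8 in {0, 1}

    def __post_init__(self) -> None:
        lab = np.asarray(self.labels, dtype=np.uint8)
        if lab.ndim != 1:
            raise GenotypeError("phenotype labels must be 1-D")
        if lab.size and lab.max() > 1:
            raise GenotypeError("phenotype labels must be 0 (control) or 1 (case)")
        object.__setattr__(self, "labels", lab)

    @property
    def n_samples(self) -> int:
        return self.labels.size

    @property
    def n_cases(self) -> int:
        return int(self.labels.sum())

    @property
    def n_controls(self) -> int:
        return self.n_samples - self.n_cases

    @property
    def case_mask(self) -> np.ndarray:
        return self.labels == 1

    def require_both_cohorts(self) -> None:
        if self.n_cases == 0 or self.n_controls == 0:
            raise GenotypeError("analysis requires non-empty case and control cohorts")


@dataclass(frozen=True)
class EncodedCohort:
    """Per-cohort bitwise genotype encoding.

    ``vectors[k]`` is an (n_snvs, s) uint8 array where entry (i, j) is
    sample j's genotype code at SNV i left-shifted by ``SHIFT_LEVELS[k]``
    bits.  Sample order inside a cohort preserves the input order.
    """

    cohort: str  # "case" or "control"
    vectors: np.ndarray = field(repr=False)  # (4, n_snvs, s) uint8

    @property
    def s(self) -> int:
        """Cohort size (number of samples)."""
        return self.vectors.shape[2]

    @property
    def n_snvs(self) -> int:
        return self.vectors.shape[1]

    def shifted(self, slot: int) -> np.ndarray:
        """Byte vectors pre-shifted for tuple slot ``slot`` (0-based)."""
        return self.vectors[slot]


def encode_cohorts(
    matrix: GenotypeMatrix, phenotype: PhenotypeVector
) -> tuple[EncodedCohort, EncodedCohort]:
    """Split samples into case/control cohorts and encode each bitwise.

    Returns ``(cases, controls)``.  At shift level k every byte equals
    ``genotype_code << 2k``; unused high bits are zero.
    """
    if phenotype.n_samples != matrix.n_samples:
        raise GenotypeError(
            f"phenotype has {phenotype.n_samples} samples, matrix has "
            f"{matrix.n_samples}"
        )
    phenotype.require_both_cohorts()
    out = []
    for cohort, mask in ((CASE, phenotype.case_mask), (CONTROL, ~phenotype.case_mask)):
        base = matrix.genotypes[mask].T  # (n_snvs, s), input sample order
        vectors = np.stack([base << k for k in SHIFT_LEVELS]).astype(np.uint8)
        out.append(EncodedCohort(cohort=cohort, vectors=vectors))
    return out[0], out[1]


def decode_cohorts(
    case: EncodedCohort, control: EncodedCohort, phenotype: PhenotypeVector
) -> np.ndarray:
    """Reassemble the samples x SNVs genotype matrix from shift-0 bytes."""
    g = np.empty((phenotype.n_samples, case.n_snvs), dtype=np.uint8)
    g[phenotype.case_mask] = case.shifted(0).T
    g[~phenotype.case_mask] = control.shifted(0).T
    return g


# ---------------------------------------------------------------------------
# genotype table (TSV/CSV)
# ---------------------------------------------------------------------------

PHENOTYPE_COLUMN = "phenotype"
SAMPLE_COLUMN = "sample_id"


def read_genotype_table(
    path: str | Path,
    sep: str | None = None,
    drop_missing_samples: bool = False,
) -> tuple[GenotypeMatrix, PhenotypeVector]:
    """Read a genotype table: rows are samples, columns are
    ``sample_id``, ``phenotype`` (1 = case, 0 = control) and one column
    per SNV holding codes in {0, 1, 2}.

    ``sep`` defaults to tab for .tsv/.txt and comma for .csv.
    Missing genotype cells are a hard error unless
    ``drop_missing_samples`` is set, in which case affected sample rows
    are removed (count logged).
    """
    path = Path(path)
    if sep is None:
        sep = "," if path.suffix.lower() == ".csv" else "\t"
    df = pd.read_csv(path, sep=sep, dtype=str)
    df.columns = [str(c) for c in df.columns]
    if any(c.startswith("Unnamed") or not c.strip() for c in df.columns):
        raise GenotypeError("unnamed SNV column in header")
    if PHENOTYPE_COLUMN not in df.columns:
        raise GenotypeError(f"missing required column '{PHENOTYPE_COLUMN}'")
    sample_ids: tuple[str, ...] | None = None
    if SAMPLE_COLUMN in df.columns:
        sample_ids = tuple(df.pop(SAMPLE_COLUMN).astype(str))
    pheno_raw = df.pop(PHENOTYPE_COLUMN)
    snv_ids = tuple(df.columns)

    missing = df.isna().any(axis=1)
    if missing.any():
        if not drop_missing_samples:
            row = int(np.argmax(missing.to_numpy()))
            col = df.columns[int(np.argmax(df.iloc[row].isna().to_numpy()))]
            raise GenotypeError(
                f"missing genotype at sample row {row}, SNV '{col}' "
                "(pass drop_missing_samples=True to remove such samples)"
            )
        n_drop = int(missing.sum())
        logger.info("dropped %d samples with missing genotypes", n_drop)
        keep = ~missing
        df = df.loc[keep]
        pheno_raw = pheno_raw.loc[keep]
        if sample_ids is not None:
            sample_ids = tuple(s for s, k in zip(sample_ids, keep) if k)

    try:
        geno = df.to_numpy(dtype=np.int64)
    except ValueError as exc:
        raise GenotypeError(f"non-numeric genotype value: {exc}") from exc
    bad = (geno < 0) | (geno > 2)
    if bad.any():
        r, c = np.argwhere(bad)[0]
        raise GenotypeError(
            f"invalid genotype code {geno[r, c]} at sample row {int(r)}, "
            f"SNV '{snv_ids[int(c)]}'"
        )
    try:
        pheno = pheno_raw.to_numpy(dtype=np.int64)
    except ValueError as exc:
        raise GenotypeError(f"non-numeric phenotype value: {exc}") from exc
    if ((pheno != 0) & (pheno != 1)).any():
        raise GenotypeError("phenotype values must be 0 (control) or 1 (case)")

    matrix = GenotypeMatrix(
        snv_ids=snv_ids, genotypes=geno.astype(np.uint8), sample_ids=sample_ids
    )
    phenotype = PhenotypeVector(labels=pheno.astype(np.uint8))
    logger.info(
        "read %s: %d samples, %d SNVs, %d cases, %d controls",
        path.name, matrix.n_samples, matrix.n_snvs,
        phenotype.n_cases, phenotype.n_controls,
    )
    return matrix, phenotype


def write_genotype_table(
    path: str | Path,
    matrix: GenotypeMatrix,
    phenotype: PhenotypeVector,
    sep: str | None = None,
) -> None:
    """Write the genotype-table format read by :func:`read_genotype_table`."""
    path = Path(path)
    if sep is None:
        sep = "," if path.suffix.lower() == ".csv" else "\t"
    sample_ids = matrix.sample_ids or tuple(
        f"S{i}" for i in range(matrix.n_samples)
    )
    df = pd.DataFrame(matrix.genotypes, columns=list(matrix.snv_ids))
    df.insert(0, PHENOTYPE_COLUMN, phenotype.labels)
    df.insert(0, SAMPLE_COLUMN, list(sample_ids))
    df.to_csv(path, sep=sep, index=False)


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def read_phenotype_file(path: str | Path) -> dict[str, int]:
    """Read a two-column (sample, phenotype) file; 1 = case, 0 = control."""
    mapping: dict[str, int] = {}
    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "rt") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 2:
                raise GenotypeError(
                    f"phenotype file line {lineno}: expected 2 columns, got "
                    f"{len(parts)}"
                )
            sample, value = parts
            if sample in (SAMPLE_COLUMN, "sample") and value in (
                PHENOTYPE_COLUMN, "status",
            ):
                continue  # header row
            if value not in ("0", "1"):
                raise GenotypeError(
                    f"phenotype file line {lineno}: value must be 0 or 1"
                )
            mapping[sample] = int(value)
    if not mapping:
        raise GenotypeError("phenotype file is empty")
    return mapping


def read_vcf(
    path: str | Path,
    phenotype_path: str | Path,
    drop_missing_samples: bool = False,
) -> tuple[GenotypeMatrix, PhenotypeVector]:
    """Read bi-allelic SNVs from a VCF plus a sample->phenotype file.

    GT 0/0 -> 0, 0/1 or 1/0 -> 1, 1/1 -> 2; phased separators are
    treated identically (the method is genotype-based, not
    haplotype-based).  Multi-allelic records are a hard error: split
    them first (e.g. ``bcftools norm -m-``).  SNV ids default to
    ``CHROM:POS:REF:ALT`` when the ID field is '.'.
    """
    from cyvcf2 import VCF

    pheno_map = read_phenotype_file(phenotype_path)
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    absent = [s for s in samples if s not in pheno_map]
    if absent:
        raise GenotypeError(
            f"samples in VCF but not in phenotype file: {absent[:5]}"
        )

    snv_ids: list[str] = []
    columns: list[np.ndarray] = []
    missing_any = np.zeros(len(samples), dtype=bool)
    for record in vcf:
        if len(record.ALT) != 1:
            raise GenotypeError(
                f"multi-allelic record at {record.CHROM}:{record.POS} "
                "(ALT = " + ",".join(record.ALT) + "); normalize to "
                "bi-allelic records first, e.g. with 'bcftools norm -m-'"
            )
        rid = record.ID
        if rid is None or rid == ".":
            rid = f"{record.CHROM}:{record.POS}:{record.REF}:{record.ALT[0]}"
        # gt_types: 0=hom-ref, 1=het, 2=unknown, 3=hom-alt
        gt = record.gt_types.copy()
        miss = gt == 2
        if miss.any():
            if not drop_missing_samples:
                j = int(np.argmax(miss))
                raise GenotypeError(
                    f"missing genotype for sample '{samples[j]}' at "
                    f"{record.CHROM}:{record.POS} (pass "
                    "drop_missing_samples=True to remove such samples)"
                )
            missing_any |= miss
        gt[gt == 3] = 2
        snv_ids.append(rid)
        columns.append(gt.astype(np.int16))
    if not snv_ids:
        raise GenotypeError(f"no variant records in {path}")

    geno = np.stack(columns, axis=1)
    keep = ~missing_any
    if missing_any.any():
        logger.info("dropped %d samples with missing genotypes",
                    int(missing_any.sum()))
    geno = geno[keep]
    kept_samples = [s for s, k in zip(samples, keep) if k]
    labels = np.array([pheno_map[s] for s in kept_samples], dtype=np.uint8)
    matrix = GenotypeMatrix(
        snv_ids=tuple(snv_ids),
        genotypes=geno.astype(np.uint8),
        sample_ids=tuple(kept_samples),
    )
    phenotype = PhenotypeVector(labels=labels)
    logger.info(
        "read %s: %d samples, %d SNVs, %d cases, %d controls",
        Path(path).name, matrix.n_samples, matrix.n_snvs,
        phenotype.n_cases, phenotype.n_controls,
    )
    return matrix, phenotype
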