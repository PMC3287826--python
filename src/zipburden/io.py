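"""Genotype, annotation, and phenotype input/output.

Genotypes are held as a dense subject x SNP matrix of counted-allele
dosages in {0, 1, 2}, with -1 marking missing calls.  The "counted"
allele is whichever allele the dosage counts copies of (the ALT allele
for VCF input); minor-allele orientation is decided later, per analysis
subset, because the identity of the minor allele can flip between
population groups.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MISSING = -1

FUNCTION_CLASSES = ("synonymous", "nonsynonymous")


class GenotypeParseError(ValueError):
    """Raised when a genotype file cannot be parsed or validated."""


class ValidationError(ValueError):
    """Raised when an input table violates a structural invariant."""


@dataclass
class GenotypeMatrix:
    """Subject x SNP matrix of counted-allele dosages.

    Parameters
    ----------
    subjects
        Unique subject identifiers, one per row of ``calls``.
    snps
        Unique SNP identifiers, one per column of ``calls``.
    calls
        Integer matrix with entries in {0, 1, 2} or :data:`MISSING` (-1).
    counted_allele
        Per-SNP label of the allele whose copies the dosage counts.
    other_allele
        Per-SNP label of the complementary allele.
    """

    subjects: list[str]
    snps: list[str]
    calls: np.ndarray
    counted_allele: list[str] = field(default_factory=list)
    other_allele: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if not self.counted_allele:
            self.counted_allele = ["A1"] * len(self.snps)
        if not self.other_allele:
            self.other_allele = ["A0"] * len(self.snps)
        self.validate()
        self._snp_index = {s: i for i, s in enumerate(self.snps)}
        self._subject_index = {s: i for i, s in enumerate(self.subjects)}

    def validate(self) -> None:
        n, m = self.calls.shape
        if n != len(self.subjects) or m != len(self.snps):
            raise ValidationError(
                f"calls shape {self.calls.shape} does not match "
                f"{len(self.subjects)} subjects x {len(self.snps)} SNPs"
            )
        if len(set(self.subjects)) != len(self.subjects):
            raise ValidationError("duplicate subject IDs")
        if len(set(self.snps)) != len(self.snps):
            raise ValidationError("duplicate SNP IDs")
        bad = ~np.isin(self.calls, (0, 1, 2, MISSING))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValidationError(
                f"call {self.calls[i, j]} for subject {self.subjects[i]} at "
                f"{self.snps[j]} is not in {{0,1,2}} or missing"
            )

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    def snp_index(self, snp: str) -> int:
        try:
            return self._snp_index[snp]
        except KeyError:
            raise KeyError(f"unknown SNP ID: {snp}") from None

    def subject_indices(self, subjects: Sequence[str] | None) -> np.ndarray:
        """Row indices for a subject subset (None = all, in stored order)."""
        if subjects is None:
            return np.arange(self.n_subjects)
        try:
            return np.array([self._subject_index[s] for s in subjects])
        except KeyError as exc:
            raise KeyError(f"unknown subject ID: {exc.args[0]}") from None


@dataclass
class GeneMap:
    """SNP -> (gene, function class) assignment.

    Every SNP belongs to exactly one gene; function class is either
    "synonymous" or "nonsynonymous" (stored lower-case).
    """

    entries: dict[str, tuple[str, str]]

    def __post_init__(self) -> None:
        for snp, (gene, func) in self.entries.items():
            if func not in FUNCTION_CLASSES:
                raise ValidationError(
                    f"SNP {snp}: function class {func!r} not in {FUNCTION_CLASSES}"
                )
        genes: dict[str, list[str]] = {}
        for snp, (gene, _) in self.entries.items():
            genes.setdefault(gene, []).append(snp)
        self._gene_snps = genes

    @property
    def genes(self) -> list[str]:
        return sorted(self._gene_snps)

    def snps_for_gene(self, gene: str) -> list[str]:
        try:
            return list(self._gene_snps[gene])
        except KeyError:
            raise KeyError(f"unknown gene: {gene}") from None

    def function_of(self, snp: str) -> str:
        return self.entries[snp][1]

    def n_snps(self, gene: str) -> int:
        return len(self._gene_snps[gene])

    def __len__(self) -> int:
        return len(self.entries)


@dataclass
class MafRecord:
    """Minor-allele frequency of one SNP within one analysis subset."""

    snp: str
    minor_allele: str
    maf: float
    n_called: int
    subset: str = "all"

    def __post_init__(self) -> None:
        if not 0.0 <= self.maf <= 0.5:
            raise ValidationError(f"MAF {self.maf} outside [0, 0.5] for {self.snp}")


PHENOTYPE_COLUMNS = ["subject", "replicate", "affected", "Q1", "Q2", "Q4",
                     "age", "sex", "smoke"]


def read_phenotypes(path: str | Path) -> pd.DataFrame:
    """Read a long-format phenotype/covariate table.

    Columns: subject, replicate, affected (0/1), Q1, Q2, Q4, age, sex (0/1),
    smoke (0/1).  One row per (subject, replicate); (subject, replicate)
    pairs must be unique.
    """
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in PHENOTYPE_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"phenotype table missing columns: {missing}")
    if df.duplicated(["subject", "replicate"]).any():
        raise ValidationError("duplicate (subject, replicate) pairs")
    bad_aff = ~df["affected"].isin((0, 1))
    if bad_aff.any():
        raise ValidationError("affected must be 0/1")
    df["subject"] = df["subject"].astype(str)
    return df


def write_phenotypes(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_gene_map(path: str | Path) -> GeneMap:
    """Read a 3-column TSV (snp, gene, function) into a :class:`GeneMap`.

    Function labels are case-insensitive and must be Synonymous or
    Nonsynonymous.  A SNP listed under two genes is an error; an empty
    file yields an empty map with a warning.
    """
    df = pd.read_csv(path, sep="\t", header=0,
                     names=["snp", "gene", "function"], dtype=str,
                     skip_blank_lines=True)
    if df.empty:
        warnings.warn(f"gene map {path} is empty", stacklevel=2)
        logger.warning("gene map %s is empty", path)
        return GeneMap(entries={})
    dup = df["snp"].duplicated()
    if dup.any():
        snp = df.loc[dup, "snp"].iloc[0]
        rows = df[df["snp"] == snp]
        if rows["gene"].nunique() > 1:
            raise ValidationError(
                f"SNP {snp} assigned to multiple genes: {sorted(rows['gene'])}"
            )
        raise ValidationError(f"duplicate gene-map row for SNP {snp}")
    entries = {}
    for snp, gene, func in df.itertuples(index=False):
        f = str(func).strip().lower()
        if f not in FUNCTION_CLASSES:
            raise ValidationError(
                f"SNP {snp}: function class {func!r} not recognised "
                f"(expected Synonymous or Nonsynonymous)"
            )
        entries[str(snp)] = (str(gene), f)
    return GeneMap(entries=entries)


def write_gene_map(gene_map: GeneMap, path: str | Path) -> None:
    rows = [(snp, gene, func.capitalize())
            for snp, (gene, func) in sorted(gene_map.entries.items())]
    pd.DataFrame(rows, columns=["snp", "gene", "function"]).to_csv(
        path, sep="\t", index=False)


def read_genotype_matrix(path: str | Path, format: str = "tsv") -> GenotypeMatrix:
    """Read genotypes from TSV or VCF.

    TSV dialect: header row of SNP IDs, first column ``subject``, cells in
    {0, 1, 2} or NA.  VCF: biallelic sites only; GT converted to ALT-allele
    dosage; any missing GT becomes a missing call.
    """
    if format == "tsv":
        return _read_genotype_tsv(path)
    if format == "vcf":
        return _read_genotype_vcf(path)
    raise ValueError(f"unknown genotype format: {format!r}")


def _read_genotype_tsv(path: str | Path) -> GenotypeMatrix:
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise GenotypeParseError(f"cannot parse {path}: {exc}") from exc
    snps = [str(c) for c in df.columns]
    subjects = [str(s) for s in df.index]
    calls = np.full(df.shape, MISSING, dtype=np.int8)
    values = df.to_numpy()
    for j in range(values.shape[1]):
        for i in range(values.shape[0]):
            cell = values[i, j]
            if cell is None or (isinstance(cell, float) and np.isnan(cell)):
                continue
            cell = str(cell).strip()
            if cell in ("", "NA", "nan", "."):
                continue
            try:
                d = int(cell)
            except ValueError:
                raise GenotypeParseError(
                    f"{path}: non-integer call {cell!r} at line {i + 2}, "
                    f"SNP {snps[j]}") from None
            if d not in (0, 1, 2):
                raise ValidationError(
                    f"{path}: call {d} out of range at line {i + 2}, SNP {snps[j]}")
            calls[i, j] = d
    return GenotypeMatrix(subjects=subjects, snps=snps, calls=calls)


def _read_genotype_vcf(path: str | Path) -> GenotypeMatrix:
    try:
        from cyvcf2 import VCF
    except ImportError:
        return _read_genotype_vcf_text(path)
    vcf = VCF(str(path))
    subjects = list(vcf.samples)
    snps: list[str] = []
    counted: list[str] = []
    other: list[str] = []
    columns: list[np.ndarray] = []
    for var in vcf:
        if len(var.ALT) != 1:
            raise ValidationError(
                f"multi-allelic site at {var.CHROM}:{var.POS} "
                f"({var.REF}->{var.ALT}); only biallelic SNPs are supported")
        snp_id = var.ID if var.ID not in (None, ".") else f"{var.CHROM}:{var.POS}"
        snps.append(snp_id)
        counted.append(var.ALT[0])
        other.append(var.REF)
        gts = var.genotype.array()  # rows: (allele1, allele2, phased)
        dose = np.where((gts[:, 0] < 0) | (gts[:, 1] < 0), MISSING,
                        gts[:, 0] + gts[:, 1]).astype(np.int8)
        columns.append(dose)
    if len(set(snps)) != len(snps):
        raise ValidationError("duplicate SNP IDs in VCF")
    calls = np.column_stack(columns) if columns else np.empty((len(subjects), 0), np.int8)
    return GenotypeMatrix(subjects=subjects, snps=snps, calls=calls,
                          counted_allele=counted, other_allele=other)


def _read_genotype_vcf_text(path: str | Path) -> GenotypeMatrix:
    """Minimal plain-text VCF reader (GT field only) used when cyvcf2 is absent."""
    subjects: list[str] = []
    snps, counted, other, columns = [], [], [], []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if line.startswith("##") or not line:
                continue
            if line.startswith("#CHROM"):
                subjects = line.split("\t")[9:]
                continue
            fields = line.split("\t")
            if len(fields) < 10:
                raise GenotypeParseError(f"{path}: truncated record at line {lineno}")
            chrom, pos, vid, ref, alt = fields[0], fields[1], fields[2], fields[3], fields[4]
            if "," in alt:
                raise ValidationError(
                    f"multi-allelic site at {chrom}:{pos}; only biallelic SNPs supported")
            fmt = fields[8].split(":")
            try:
                gt_idx = fmt.index("GT")
            except ValueError:
                raise GenotypeParseError(
                    f"{path}: no GT field at line {lineno}") from None
            dose = np.empty(len(fields) - 9, dtype=np.int8)
            for k, sample in enumerate(fields[9:]):
                gt = sample.split(":")[gt_idx].replace("|", "/")
                alleles = gt.split("/")
                if "." in alleles:
                    dose[k] = MISSING
                else:
                    dose[k] = sum(int(a) for a in alleles)
            snps.append(vid if vid != "." else f"{chrom}:{pos}")
            counted.append(alt)
            other.append(ref)
            columns.append(dose)
    if len(set(snps)) != len(snps):
        raise ValidationError("duplicate SNP IDs in VCF")
    calls = np.column_stack(columns) if columns else np.empty((len(subjects), 0), np.int8)
    return GenotypeMatrix(subjects=subjects, snps=snps, calls=calls,
                          counted_allele=counted, other_allele=other)


def write_genotype_tsv(geno: GenotypeMatrix, path: str | Path) -> None:
    """Write the dosage matrix as TSV (missing -> NA); inverse of the TSV reader."""
    df = pd.DataFrame(geno.calls, index=pd.Index(geno.subjects, name="subject"),
                      columns=geno.snps)
    df = df.astype(object).where(geno.calls != MISSING, "NA")
    df.to_csv(path, sep="\t")


def counted_allele_freqs(geno: GenotypeMatrix,
                         subset: Sequence[str] | np.ndarray | None = None
                         ) -> tuple[np.ndarray, np.ndarray]:
    """Frequency of the counted allele per SNP over non-missing calls.

    Returns (freqs, n_called); freq is NaN for SNPs with no calls.
    ``subset`` may be subject IDs or precomputed row indices.
    """
    if subset is not None and np.issubdtype(np.asarray(subset).dtype, np.integer):
        rows = np.asarray(subset)
    else:
        rows = geno.subject_indices(subset)
    calls = geno.calls[rows]
    observed = calls != MISSING
    n_called = observed.sum(axis=0)
    allele_counts = np.where(observed, calls, 0).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        freqs = np.where(n_called > 0, allele_counts / (2.0 * n_called), np.nan)
    return freqs, n_called


def compute_minor_allele_freq(geno: GenotypeMatrix, snp: str,
                              subset: Sequence[str] | None = None,
                              subset_label: str = "all") -> MafRecord:
    """Minor-allele frequency of ``snp`` within a subject subset.

    The minor allele is the less-common allele *within the subset*; a tie
    at 0.5 is broken toward the counted allele.  Missing calls are
    excluded from the denominator.
    """
    j = geno.snp_index(snp)
    rows = geno.subject_indices(subset)
    if rows.size == 0:
        raise ValueError("subject subset is empty")
    col = geno.calls[rows, j]
    observed = col != MISSING
    n_called = int(observed.sum())
    if n_called == 0:
        raise ValueError(f"all calls missing for SNP {snp} in subset {subset_label}")
    f_counted = float(col[observed].sum()) / (2.0 * n_called)
    if f_counted <= 0.5:
        minor, maf = geno.counted_allele[j], f_counted
    else:
        minor, maf = geno.other_allele[j], 1.0 - f_counted
    return MafRecord(snp=snp, minor_allele=minor, maf=maf,
                     n_called=n_called, subset=subset_label)
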