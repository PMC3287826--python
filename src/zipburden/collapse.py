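"""Rare-variant collapsing: carrier indicators summed within genes.

For each SNP of a gene, a subject is a carrier (indicator 1) when they
hold at least one copy of that SNP's minor allele; the per-gene count
for a subject is the number of the gene's SNPs at which they carry.
Minor alleles are oriented within the analysis subset, so the same SNP
can contribute differently in a pooled scan versus a per-group scan.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io import MISSING, GeneMap, GenotypeMatrix

logger = logging.getLogger(__name__)


class EmptyGeneError(ValueError):
    """No SNPs left for a gene after filtering; the gene is not testable."""


@dataclass
class CollapsedCounts:
    """Per-subject rare-variant counts for one gene."""

    gene: str
    subjects: list[str]
    counts: np.ndarray
    n_snps_used: int
    function_filter: str = "all"
    maf_ceiling: float | None = None
    snps_used: list[str] = field(default_factory=list)
    missing_calls: int = 0
    coding: str = "indicator"

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        bound = self.n_snps_used * (2 if self.coding == "dosage" else 1)
        if (self.counts < 0).any() or (self.counts > bound).any():
            raise ValueError(
                f"{self.gene}: counts must lie in [0, {bound}]")


def variant_indicator(dosage: int | np.ndarray) -> int | np.ndarray:
    """Presence indicator: 1 if at least one minor-allele copy, else 0.

    ``dosage`` is expressed as copies of the minor allele (0, 1, 2, or
    :data:`MISSING`).  Missing calls count as non-carriers.
    """
    d = np.asarray(dosage)
    out = ((d == 1) | (d == 2)).astype(np.int64)
    return int(out) if np.isscalar(dosage) or d.ndim == 0 else out


def _minor_oriented_dosage(calls: np.ndarray, counted_freqs: np.ndarray) -> np.ndarray:
    """Re-express dosages as minor-allele copies within the active subset.

    Where the counted allele is the major allele (freq > 0.5) the dosage
    flips d -> 2 - d; a tie at 0.5 keeps the counted orientation.
    Missing stays missing.
    """
    flip = counted_freqs > 0.5
    oriented = np.where(flip[None, :], 2 - calls, calls)
    oriented[calls == MISSING] = MISSING
    return oriented


def collapse_gene(geno: GenotypeMatrix, gene: str, gene_map: GeneMap,
                  subset: list[str] | None = None,
                  function_filter: str = "all",
                  maf_ceiling: float | None = None,
                  dosage_coding: bool = False) -> CollapsedCounts:
    """Collapse one gene's SNPs into per-subject carrier counts.

    Parameters
    ----------
    subset
        Subject IDs defining the analysis sample (None = all subjects).
        Minor alleles and MAFs are recomputed within this subset.
    function_filter
        "all" or "nonsynonymous".
    maf_ceiling
        Keep only SNPs whose within-subset MAF is <= this value
        (None = no ceiling; every minor allele is collapsed).
    dosage_coding
        If True, sum minor-allele copies instead of presence indicators
        (sensitivity analysis; not the default method).

    Raises
    ------
    EmptyGeneError
        If no SNP of the gene passes the filters.
    """
    if function_filter not in ("all", "nonsynonymous"):
        raise ValueError(f"unknown function filter: {function_filter!r}")
    snps = gene_map.snps_for_gene(gene)
    if function_filter == "nonsynonymous":
        snps = [s for s in snps if gene_map.function_of(s) == "nonsynonymous"]
    snps = [s for s in snps if s in geno._snp_index]
    if not snps:
        raise EmptyGeneError(f"{gene}: no SNPs pass filter {function_filter!r}")

    rows = geno.subject_indices(subset)
    if rows.size == 0:
        raise ValueError("subject subset is empty")
    cols = np.array([geno.snp_index(s) for s in snps])
    calls = geno.calls[np.ix_(rows, cols)]

    observed = calls != MISSING
    n_called = observed.sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        f = np.where(n_called > 0,
                     np.where(observed, calls, 0).sum(axis=0) / (2.0 * n_called),
                     np.nan)
    if np.isnan(f).any():
        keep = ~np.isnan(f)
        calls, f = calls[:, keep], f[keep]
        snps = [s for s, k in zip(snps, keep) if k]
    if maf_ceiling is not None:
        maf = np.minimum(f, 1.0 - f)
        keep = maf <= maf_ceiling
        calls, f = calls[:, keep], f[keep]
        snps = [s for s, k in zip(snps, keep) if k]
    if not snps:
        raise EmptyGeneError(f"{gene}: no SNPs pass MAF ceiling {maf_ceiling}")

    oriented = _minor_oriented_dosage(calls, f)
    if dosage_coding:
        per_snp = np.where(oriented == MISSING, 0, oriented).astype(np.int64)
    else:
        per_snp = variant_indicator(oriented)
    counts = per_snp.sum(axis=1)
    subjects = [geno.subjects[i] for i in rows]
    return CollapsedCounts(
        gene=gene, subjects=subjects, counts=counts, n_snps_used=len(snps),
        function_filter=function_filter, maf_ceiling=maf_ceiling,
        snps_used=snps, missing_calls=int((calls == MISSING).sum()),
        coding="dosage" if dosage_coding else "indicator")


def collapse_all(geno: GenotypeMatrix, gene_map: GeneMap,
                 subset: list[str] | None = None,
                 function_filter: str = "all",
                 maf_ceiling: float | None = None,
                 dosage_coding: bool = False) -> dict[str, CollapsedCounts]:
    """Collapse every gene; genes with no passing SNPs are skipped (logged).

    Returns a dict keyed by gene in lexicographic order, so the number of
    entries is the number of genes actually testable under the filter.
    """
    out: dict[str, CollapsedCounts] = {}
    for gene in gene_map.genes:
        try:
            out[gene] = collapse_gene(geno, gene, gene_map, subset,
                                      function_filter, maf_ceiling,
                                      dosage_coding)
        except EmptyGeneError as exc:
            logger.info("skipping gene: %s", exc)
    return out


def write_counts_tsv(counts: dict[str, CollapsedCounts], path: str | Path) -> None:
    """Write collapsed counts (rows = subjects, columns = genes) with the
    filter settings embedded as header comments."""
    if not counts:
        raise ValueError("no collapsed counts to write")
    first = next(iter(counts.values()))
    df = pd.DataFrame(
        {gene: cc.counts for gene, cc in counts.items()},
        index=pd.Index(first.subjects, name="subject"),
    )
    with open(path, "w") as fh:
        fh.write(f"# function_filter={first.function_filter}\t"
                 f"maf_ceiling={first.maf_ceiling}\n")
        df.to_csv(fh, sep="\t")
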