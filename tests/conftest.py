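import numpy as np
import pandas as pd
import pytest

from zipburden.io import GeneMap, GenotypeMatrix


@pytest.fixture
def tiny_geno():
    """4 subjects x 5 SNPs, two genes, one missing call."""
    calls = np.array([
        [0, 1, 2, 0, 0],
        [1, 0, 0, 0, 2],
        [2, 0, 1, 0, 0],
        [0, 0, 0, -1, 1],
    ], dtype=np.int8)
    return GenotypeMatrix(
        subjects=["S1", "S2", "S3", "S4"],
        snps=["C1S1", "C1S2", "C1S3", "C2S1", "C2S2"],
        calls=calls,
        counted_allele=["A", "C", "G", "T", "A"],
        other_allele=["G", "T", "A", "C", "G"],
    )


@pytest.fixture
def tiny_map():
    return GeneMap(entries={
        "C1S1": ("GENEA", "nonsynonymous"),
        "C1S2": ("GENEA", "synonymous"),
        "C1S3": ("GENEA", "nonsynonymous"),
        "C2S1": ("GENEB", "synonymous"),
        "C2S2": ("GENEB", "synonymous"),
    })


@pytest.fixture
def tiny_phen():
    rng = np.random.default_rng(42)
    n = 4
    return pd.DataFrame({
        "subject": ["S1", "S2", "S3", "S4"],
        "replicate": 0,
        "affected": [1, 0, 1, 0],
        "Q1": rng.normal(size=n),
        "Q2": rng.normal(size=n),
        "Q4": rng.normal(size=n),
        "age": [40.0, 55.0, 62.0, 38.0],
        "sex": [0, 1, 0, 1],
        "smoke": [1, 0, 0, 0],
    })


def brute_force_collapse(geno, gene, gene_map, subset=None,
                         function_filter="all", maf_ceiling=None):
    """Independent double-loop recount of per-gene carrier counts.

    Deliberately naive: per SNP, tally the counted allele over the
    subset, decide the minor allele (ties toward the counted allele),
    then walk every (subject, SNP) pair counting carriers of at least
    one minor-allele copy.  Missing calls never count.
    """
    subjects = subset if subset is not None else list(geno.subjects)
    snps = []
    for snp in gene_map.snps_for_gene(gene):
        if snp not in geno.snps:
            continue
        if function_filter == "nonsynonymous" and \
                gene_map.function_of(snp) != "nonsynonymous":
            continue
        snps.append(snp)
    counts = {s: 0 for s in subjects}
    used = 0
    for snp in snps:
        j = geno.snps.index(snp)
        alleles = 0
        called = 0
        for s in subjects:
            i = geno.subjects.index(s)
            d = int(geno.calls[i, j])
            if d >= 0:
                alleles += d
                called += 1
        if called == 0:
            continue
        f = alleles / (2.0 * called)
        maf = min(f, 1.0 - f)
        if maf_ceiling is not None and maf > maf_ceiling:
            continue
        minor_is_counted = f <= 0.5
        used += 1
        for s in subjects:
            i = geno.subjects.index(s)
            d = int(geno.calls[i, j])
            if d < 0:
                continue
            minor_copies = d if minor_is_counted else 2 - d
            if minor_copies >= 1:
                counts[s] += 1
    return np.array([counts[s] for s in subjects]), used
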