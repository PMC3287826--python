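"""Synthetic mini-exome generator for end-to-end verification.

Emulates the structure of a multi-population exome-panel study: fixed
rare-variant genotypes drawn under Hardy-Weinberg equilibrium within
each population (with population-divergent allele frequencies), SNPs
grouped into genes with synonymous/nonsynonymous labels, per-subject
covariates, and many phenotype replicates drawn over the fixed
genotypes — a binary disease status from a liability threshold and
quantitative traits (Q1, Q2, Q4) from a linear model on the collapsed
causal-gene counts.

Defaults mirror the study conditions this package targets: 692 subjects
in three ancestry groups (215 / 321 / 156), ~7.6 SNPs per gene, allele
frequencies skewed toward rarity (Beta(0.2, 5) truncated to (0, 0.5]),
200 phenotype replicates, 30% disease prevalence.

The phenotype model is a transparent liability/linear construction on
collapsed counts; it makes no attempt to reconstruct any particular
benchmark's undisclosed generating model.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .collapse import collapse_gene
from .io import GeneMap, GenotypeMatrix

__all__ = ["SimulationDesign", "simulate_genotypes", "simulate_phenotypes",
           "simulate_zip_counts", "child_seed", "effect_for_power",
           "designed_power"]


def child_seed(master: int, *tags) -> int:
    """Deterministic child seed < 2**31 from a master seed and tags.

    Stable hashing keeps component streams independent of each other
    and of the order in which they are requested.
    """
    key = repr((int(master),) + tuple(tags)).encode()
    return int.from_bytes(hashlib.sha256(key).digest()[:4], "big") % (2**31)


@dataclass
class SimulationDesign:
    """Study design for the synthetic generator.

    ``causal_genes`` maps trait name ("disease", "Q1", "Q2", "Q4") to
    {gene: effect}; effects act per collapsed-count unit on the
    liability scale (disease) or the trait scale (quantitative).
    A gene index (int) may be used in place of a name before genes
    exist; it resolves to the generated gene ID.
    """

    pop_sizes: tuple[int, ...] = (215, 321, 156)
    n_genes: int = 100
    mean_snps_per_gene: float = 7.6
    nonsyn_fraction: float = 0.67
    maf_beta: tuple[float, float] = (0.2, 5.0)
    divergence_sd: float = 1.0
    causal_genes: dict[str, dict] = field(default_factory=dict)
    covariate_effects: dict[str, float] = field(
        default_factory=lambda: {"age": 0.02, "sex": 0.5, "smoke": 0.5})
    noise_sd: float = 1.0
    prevalence: float = 0.30
    n_replicates: int = 200
    seed: int = 0
    # explicit per-population counted-allele frequencies (n_pops x n_snps),
    # overriding the Beta draw; requires fixed_snps_per_gene summing to n_snps
    fixed_pop_freq: np.ndarray | None = None
    fixed_snps_per_gene: list[int] | None = None

    def __post_init__(self) -> None:
        if any(s < 1 for s in self.pop_sizes):
            raise ValueError("population sizes must be >= 1")
        if not 0 < self.prevalence < 1:
            raise ValueError("prevalence must be in (0, 1)")
        for trait, genes in self.causal_genes.items():
            for g, eff in genes.items():
                if not np.isfinite(eff):
                    raise ValueError(f"non-finite effect for {trait}/{g}")

    @property
    def n_subjects(self) -> int:
        return int(sum(self.pop_sizes))


def gene_id(i: int) -> str:
    return f"GENE{i:04d}"


def simulate_genotypes(design: SimulationDesign
                       ) -> tuple[GenotypeMatrix, GeneMap, dict]:
    """Draw fixed genotypes and a gene map from the design.

    Per SNP, a base minor-allele frequency is drawn from the rare-skewed
    Beta prior; each population's frequency is a logit-scale Gaussian
    perturbation of it (divergence), so with enough divergence the
    counted allele can be minor in one group and major in another.
    Genotypes are Hardy-Weinberg draws within each population.

    Returns (genotypes, gene map, truth) where truth records the
    per-SNP per-population frequencies and population labels.
    """
    rng = np.random.default_rng(child_seed(design.seed, "genotypes"))
    n_pops = len(design.pop_sizes)
    if design.fixed_pop_freq is not None:
        if design.fixed_snps_per_gene is None:
            raise ValueError("fixed_pop_freq requires fixed_snps_per_gene")
        freq = np.atleast_2d(np.asarray(design.fixed_pop_freq, dtype=float))
        if freq.shape[0] != n_pops:
            raise ValueError(f"fixed_pop_freq has {freq.shape[0]} rows for "
                             f"{n_pops} populations")
        if sum(design.fixed_snps_per_gene) != freq.shape[1]:
            raise ValueError("fixed_snps_per_gene must sum to the SNP count")
        snps_per_gene = np.asarray(design.fixed_snps_per_gene)
    else:
        snps_per_gene = 1 + rng.poisson(
            max(design.mean_snps_per_gene - 1.0, 0.0), size=design.n_genes)
    n_genes = len(snps_per_gene)
    snp_ids, genes, functions = [], [], []
    for g in range(n_genes):
        chrom = g % 22 + 1
        for k in range(snps_per_gene[g]):
            snp_ids.append(f"C{chrom}S{g * 1000 + k}")
            genes.append(gene_id(g))
            functions.append("nonsynonymous"
                             if rng.random() < design.nonsyn_fraction
                             else "synonymous")
    m = len(snp_ids)
    if design.fixed_pop_freq is not None:
        pop_freq = np.clip(freq, 0.0, 1.0)
        base = pop_freq.mean(axis=0)
    else:
        a, b = design.maf_beta
        base = np.clip(rng.beta(a, b, size=m), 1e-4, 0.5)
        logit = np.log(base / (1.0 - base))
        pop_logit = logit[None, :] + rng.normal(
            0.0, design.divergence_sd, size=(n_pops, m))
        pop_freq = 1.0 / (1.0 + np.exp(-pop_logit))
        pop_freq = np.clip(pop_freq, 1e-6, 1.0 - 1e-6)

    blocks, pop_labels = [], []
    for p, size in enumerate(design.pop_sizes):
        blocks.append(rng.binomial(2, pop_freq[p], size=(size, m)))
        pop_labels.extend([f"POP{p}"] * size)
    calls = np.vstack(blocks).astype(np.int8)
    subjects = [f"S{i:04d}" for i in range(design.n_subjects)]
    geno = GenotypeMatrix(subjects=subjects, snps=snp_ids, calls=calls)
    gmap = GeneMap(entries={s: (g, f)
                            for s, g, f in zip(snp_ids, genes, functions)})
    truth = {
        "pop_labels": dict(zip(subjects, pop_labels)),
        "pop_freq": pop_freq,
        "base_freq": base,
        "snps_per_gene": snps_per_gene.tolist(),
    }
    return geno, gmap, truth


def _covariates(design: SimulationDesign, subjects: list[str]) -> pd.DataFrame:
    """Per-subject covariates, fixed across replicates."""
    rng = np.random.default_rng(child_seed(design.seed, "covariates"))
    n = len(subjects)
    return pd.DataFrame({
        "subject": subjects,
        "age": np.clip(rng.normal(50.0, 10.0, n), 18.0, 90.0).round(1),
        "sex": rng.integers(0, 2, n),
        "smoke": (rng.random(n) < 0.3).astype(int),
    })


def _resolve_gene(g, design: SimulationDesign) -> str:
    return gene_id(g) if isinstance(g, (int, np.integer)) else str(g)


def _genetic_score(geno: GenotypeMatrix, gene_map: GeneMap,
                   effects: dict, design: SimulationDesign) -> np.ndarray:
    score = np.zeros(geno.n_subjects)
    for g, eff in effects.items():
        gene = _resolve_gene(g, design)
        cc = collapse_gene(geno, gene, gene_map)
        score += float(eff) * cc.counts
    return score


def simulate_phenotypes(geno: GenotypeMatrix, gene_map: GeneMap,
                        design: SimulationDesign, replicate: int
                        ) -> pd.DataFrame:
    """Draw one phenotype replicate over fixed genotypes.

    Quantitative traits: intercept + sum(effect x collapsed causal-gene
    count) + covariate effects + Gaussian noise.  Disease status: the
    same construction on a liability scale with standard-normal noise,
    thresholded at the within-replicate quantile that yields the
    designed prevalence.  Covariates are drawn once per subject and
    shared across replicates; the noise stream is keyed by
    (master seed, replicate).
    """
    if not 0 <= replicate < design.n_replicates:
        raise ValueError(
            f"replicate {replicate} outside [0, {design.n_replicates})")
    n = geno.n_subjects
    n_aff = int(round(design.prevalence * n))
    if n_aff < 1 or n_aff >= n:
        raise ValueError(
            f"prevalence {design.prevalence} unreachable with N = {n}")
    cov = _covariates(design, geno.subjects)
    ce = design.covariate_effects
    cov_term = (ce.get("age", 0.0) * (cov["age"].to_numpy() - 50.0)
                + ce.get("sex", 0.0) * cov["sex"].to_numpy()
                + ce.get("smoke", 0.0) * cov["smoke"].to_numpy())
    rng = np.random.default_rng(child_seed(design.seed, "phenotype", replicate))
    out = cov.copy()
    out.insert(1, "replicate", replicate)

    for trait in ("Q1", "Q2", "Q4"):
        gscore = _genetic_score(geno, gene_map,
                                design.causal_genes.get(trait, {}), design)
        out[trait] = (gscore + cov_term
                      + rng.normal(0.0, design.noise_sd, n)).round(6)
    liability = (_genetic_score(geno, gene_map,
                                design.causal_genes.get("disease", {}), design)
                 + cov_term + rng.normal(0.0, 1.0, n))
    threshold = np.sort(liability)[n - n_aff - 1]
    out["affected"] = (liability > threshold).astype(int)
    return out[["subject", "replicate", "affected", "Q1", "Q2", "Q4",
                "age", "sex", "smoke"]]


def simulate_all_replicates(geno: GenotypeMatrix, gene_map: GeneMap,
                            design: SimulationDesign) -> pd.DataFrame:
    """Long-format phenotype table over all replicates."""
    return pd.concat(
        [simulate_phenotypes(geno, gene_map, design, r)
         for r in range(design.n_replicates)],
        ignore_index=True)


def simulate_zip_counts(X_zero: np.ndarray, X_mean: np.ndarray,
                        gamma: np.ndarray, beta: np.ndarray,
                        seed: int = 0) -> np.ndarray:
    """Draw counts from the zero-inflated Poisson model itself.

    Per subject: a structural zero with probability
    p_i = logistic(X_zero gamma), otherwise Poisson(exp(X_mean beta)).
    """
    X_zero = np.atleast_2d(np.asarray(X_zero, float))
    X_mean = np.atleast_2d(np.asarray(X_mean, float))
    gamma = np.asarray(gamma, float)
    beta = np.asarray(beta, float)
    if gamma.shape[0] != X_zero.shape[1] or beta.shape[0] != X_mean.shape[1]:
        raise ValueError("coefficient lengths do not match design columns")
    rng = np.random.default_rng(seed)
    p = 1.0 / (1.0 + np.exp(-(X_zero @ gamma)))
    mu = np.exp(X_mean @ beta)
    structural = rng.random(X_zero.shape[0]) < p
    counts = rng.poisson(mu)
    counts[structural] = 0
    return counts


def designed_power(effect: float, n: int, count_mean: float, count_var: float,
                   noise_sd: float, alpha: float = 0.05) -> float:
    """Asymptotic power of the Wald test for a quantitative-trait effect.

    For trait Q = effect x T + noise constructed on collapsed counts T
    (mean ``count_mean``, variance ``count_var`` per subject), the Wald
    z of the trait coefficient in the log-mean component is
    asymptotically Normal with

        mean     = effect * count_var * sqrt(n) / sqrt(var(Q) * count_mean)
        variance = count_var / count_mean

    (the variance ratio corrects for the binomial underdispersion of
    carrier counts relative to the Poisson working model).
    """
    var_q = effect**2 * count_var + noise_sd**2
    delta = effect * count_var * np.sqrt(n) / np.sqrt(var_q * count_mean)
    sd_z = np.sqrt(count_var / count_mean)
    crit = stats.norm.isf(alpha / 2.0)
    return float(stats.norm.sf((crit - delta) / sd_z)
                 + stats.norm.cdf((-crit - delta) / sd_z))


def effect_for_power(power: float, n: int, count_mean: float, count_var: float,
                     noise_sd: float = 1.0, alpha: float = 0.05) -> float:
    """Quantitative-trait effect size giving the target asymptotic power."""
    if not 0 < power < 1:
        raise ValueError("power must be in (0, 1)")
    f = lambda b: designed_power(b, n, count_mean, count_var, noise_sd, alpha) - power
    return float(optimize.brentq(f, 1e-6, 50.0))


def carrier_moments(mafs: np.ndarray) -> tuple[float, float]:
    """Mean and variance per subject of the collapsed carrier count for a
    gene with the given per-SNP minor-allele frequencies, under HWE."""
    q = 1.0 - (1.0 - np.asarray(mafs, float)) ** 2
    return float(q.sum()), float((q * (1.0 - q)).sum())


def write_truth(design: SimulationDesign, truth: dict, path: str | Path) -> None:
    """Serialize the design and generated truth (causal genes, effects,
    seeds, population labels) to JSON."""
    payload = {
        "pop_sizes": list(design.pop_sizes),
        "n_genes": design.n_genes,
        "causal_genes": {t: {_resolve_gene(g, design): e
                             for g, e in genes.items()}
                         for t, genes in design.causal_genes.items()},
        "prevalence": design.prevalence,
        "noise_sd": design.noise_sd,
        "n_replicates": design.n_replicates,
        "seed": design.seed,
        "pop_labels": truth.get("pop_labels", {}),
    }
    Path(path).write_text(json.dumps(payload, indent=2))
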