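# zipburden

Gene-based rare-variant association testing by **collapsing carrier
indicators** into per-gene counts and modelling those counts with a
**zero-inflated Poisson (ZIP) regression**, with ancestry adjustment via
genotype principal components and replicate-based power evaluation.

## Who this is for

Statistical geneticists analysing exome-panel data in which individual
rare variants are too infrequent to test one at a time. Instead of m×n
single-SNP tests, the scan runs one count-regression test per gene,
which both reduces the multiple-testing burden and concentrates the
mutational signal.

## The model

For subject *i* and a gene with *n_j* SNPs, define the carrier
indicator V_ijk = 1 if subject *i* holds at least one copy of the minor
allele of SNP *k* (minor allele determined **within the analysis
subset**, because allele frequencies — and hence minor-allele identity —
can flip between ancestry groups). The per-gene count is

    T_i = Σ_k V_ijk .

Because most subjects carry no rare variant in most genes, the counts
carry excess zeros; they are modelled as a zero-inflated Poisson

    P(T_i = 0) = p_i + (1 − p_i) e^(−μ_i)
    P(T_i = t) = (1 − p_i) e^(−μ_i) μ_i^t / t! ,   t ≥ 1

with canonical links

    logit(p_i) = γ0 + γ1 X_i + γ2 Z_1i + γ3 Z_2i + γ4 Z_3i + Σ_p γ_{4+p} PCS_ip
    log(μ_i)   = β0 + β1 X_i + β2 Z_1i + β3 Z_2i + β4 Z_3i + Σ_p β_{4+p} PCS_ip

where X_i is affection status (or a quantitative trait substituted in
its place), Z_1i..Z_3i are age, sex and smoking status, and PCS_ip are
the top genotype eigenvectors. Association is the Wald test of
**β1 = 0** in the log-mean component (a 2-df likelihood-ratio
alternative that also drops the γ1 term is available). Genome-wide
significance uses Bonferroni: α/m over the m genes actually tested
(0.05/3205 = 1.56 × 10⁻⁵ at the scale of a 3,205-gene exome panel).

Fitting is joint maximum likelihood (BFGS with analytic gradient,
Poisson warm start); standard errors come from the observed information.
Degenerate genes fall down an explicit ladder (full ZIP → intercept-only
zero component → plain Poisson → no test) — see `docs/methods.md`.

## Worked example

```python
from zipburden import (ScanConfig, SimulationDesign, compute_eigenvectors,
                       run_scan, simulate_genotypes, simulate_phenotypes)
from zipburden.pipeline import results_frame

design = SimulationDesign(n_genes=40, n_replicates=1, seed=21,
                          causal_genes={"Q1": {"GENE0005": 0.5}})
geno, gene_map, _ = simulate_genotypes(design)
eig = compute_eigenvectors(geno, 10)
phen = simulate_phenotypes(geno, gene_map, design, replicate=0)
results, meta = run_scan(geno, gene_map, phen,
                         ScanConfig(trait="Q1", n_pcs=10, maf_ceiling=0.05),
                         eig)
print(results_frame(results).dropna(subset=["p"]).sort_values("p").head(3))
```

prints (692 subjects in three ancestry groups, 37 genes testable under
the rare-variant filter, Bonferroni threshold 0.05/37 = 1.35 × 10⁻³):

```
    gene   n     beta1       se            p significant_bonferroni
GENE0005 692  0.448784 0.086605 2.195369e-07                   True
GENE0004 692 -0.255973 0.083778 2.247821e-03                  False
GENE0016 692  0.245711 0.105584 1.995639e-02                  False
```

The planted causal gene (true effect 0.5 trait units per carrier count)
heads the table with an estimate within one SE of truth and clears the
Bonferroni threshold; the remaining genes are null and scatter
accordingly. The scripts in `examples/` walk through each capability —
simulation, collapsing and minor-allele flips, ZIP fitting,
population-structure handling, the scan, and replicate power.

A thin CLI mirrors the library (`zipburden simulate | pca | collapse |
scan | power`); run `zipburden --help`.

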