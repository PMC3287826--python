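"""Generate a synthetic stratified rare-variant study and write it to disk.

Three ancestry groups (215 / 321 / 156 subjects), gene-grouped SNPs with
rare-skewed, population-divergent allele frequencies, and phenotype
replicates over fixed genotypes.
"""

from pathlib import Path

from zipburden import SimulationDesign, simulate_genotypes
from zipburden.io import write_gene_map, write_genotype_tsv, write_phenotypes
from zipburden.simulate import simulate_all_replicates, write_truth

design = SimulationDesign(n_genes=25, n_replicates=5, seed=42,
                          causal_genes={"Q1": {"GENE0003": 0.5}})
geno, gene_map, truth = simulate_genotypes(design)
phen = simulate_all_replicates(geno, gene_map, design)

out = Path("example_study")
out.mkdir(exist_ok=True)
write_genotype_tsv(geno, out / "genotypes.tsv")
write_gene_map(gene_map, out / "genemap.tsv")
write_phenotypes(phen, out / "phenotypes.tsv")
write_truth(design, truth, out / "truth.json")

print(f"subjects: {geno.n_subjects}  SNPs: {geno.n_snps}  "
      f"genes: {len(gene_map.genes)}")
print(f"phenotype rows: {len(phen)} ({design.n_replicates} replicates)")
print(f"affected per replicate: {phen.groupby('replicate')['affected'].sum().tolist()}")
# ~30% of subjects are affected in every replicate (the designed
# prevalence); genotypes are identical across replicates by construction.
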