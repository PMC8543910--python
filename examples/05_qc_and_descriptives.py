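"""Quality control and descriptive statistics on a cohort directory.

Applies the SNP filters (MAF >= 5%, missingness <= 10%) and the microbiome
filters (>= 10,000 reads per sample; ASVs present in >= 3 samples carrying
>= 0.001% of total counts), aggregates ASVs to genus, and prints per-trait
mean, SD and coefficient of variation.
"""

from microbiability import (
    SimulationConfig,
    aggregate_to_genus,
    describe_traits,
    filter_microbiome,
    simulate_cohort,
    snp_qc,
)

cfg = SimulationConfig(
    n_individuals=150,
    n_snps=800,
    maf_range=(0.01, 0.5),      # some SNPs will fail the MAF filter
    genotype_missing_rate=0.02,
    n_asvs=200,
    n_genera=25,
    library_size_range=(8_000, 40_000),  # some samples will fail depth
    n_traits=3,
    seed=2,
)
cohort = simulate_cohort(cfg)

g = snp_qc(cohort.genotypes)
print("SNP QC:", g.metadata["qc_report"])

m = filter_microbiome(cohort.microbiome)
print("microbiome filter:", m.metadata["filter_report"])

genus = aggregate_to_genus(m)
print(f"genus table: {genus.n_samples} samples x {genus.n_features} genera")

print("\ntrait descriptives (CV = SD/mean):")
print(describe_traits(cohort.phenotypes).round(3).to_string())
# removal counts are reported per criterion; a SNP failing both MAF and
# missingness appears under both counters
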