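"""Published reference values for the chickpea ICC 4958 v2.0 draft assembly.

These numbers describe the real assembly and its raw data (NCBI BioProject
PRJNA78951). They are *inputs and defaults*, never outputs: quantities such
as the scaffold count, genome-wide GC, the real kb/cM rates or the pooled
SNP counts cannot be re-derived without the original reads and map, so the
synthetic generator merely adopts them as realistic defaults and the test
suite treats them as fixed metadata.
"""

from __future__ import annotations

# Table of pseudomolecule lengths (bp), one per linkage group.
PSEUDOMOLECULE_LENGTHS_BP: dict[str, int] = {
    "Ca_LG_1": 39_901_017,
    "Ca_LG_2": 33_233_457,
    "Ca_LG_3": 42_267_542,
    "Ca_LG_4": 54_992_815,
    "Ca_LG_5": 45_819_701,
    "Ca_LG_6": 54_841_389,
    "Ca_LG_7": 45_279_478,
    "Ca_LG_8": 17_664_089,
}

TOTAL_ASSEMBLY_BP = 510_879_539
ANCHORED_BP = sum(PSEUDOMOLECULE_LENGTHS_BP.values())  # 333,999,488

# Reference values that are NOT re-derivable at desk scale (they depend on
# the unreleased raw data); kept for context and as synthetic defaults.
REFERENCE_ASSEMBLY = {
    "n_scaffolds": 38_513,
    "min_scaffold_bp": 1_000,
    "max_scaffold_bp": 54_992_815,
    "gc_content_pct": 27.95,
    "n50_length_bp": 39_901_017,
    "n50_index": 6,
}

REFERENCE_ANNOTATION = {
    "n_genes": 30_257,
    "n_mrnas": 30_686,
    "total_gene_length_bp": 91_806_333,
    "total_cds_length_bp": 35_503_303,
    "avg_gene_length_bp": 3_034,
    "avg_cds_length_bp": 1_173,
    "avg_exon_length_bp": 253,
    "avg_intron_length_bp": 432,
    "avg_exons_per_gene": 5.1,
    "cds_gc_pct": 41.60,
}

# Recombination landscape (kb/cM) and gene densities (genes/100 kb) of the
# euchromatic arms vs the pericentromeric cores; synthetic defaults.
EUCHROMATIN_KB_PER_CM = 193.0
PERICENTROMERE_KB_PER_CM = 1691.0
EUCHROMATIN_GENES_PER_100KB = 8.63
PERICENTROMERE_GENES_PER_100KB = 5.57

# Pooled-group SNP mining on 39 desi and 53 kabuli genotypes.
REFERENCE_SNPS = {
    "desi": {"n_snps": 2150, "mean_density_kb": 141.9, "n_genes": 715},
    "kabuli": {"n_snps": 2199, "mean_density_kb": 138.7, "n_genes": 757},
}

# Molecular clock used for divergence dating: synonymous substitutions per
# synonymous site per year.
SYNONYMOUS_RATE_PER_YEAR = 6.1e-9
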