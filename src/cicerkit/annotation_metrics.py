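"""Gene-model filtering and annotation summary statistics.

The gene-model filter removes models with a short total coding sequence
(<150 bases) or a high ambiguity content (>=10% N in the CDS). Summary
averages divide by the number of genes (not mRNAs), intron statistics
exclude single-exon genes, and printed-precision rounding is
half-away-from-zero unless truncation is requested.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

from .io_core import GeneModel, SequenceRecord

logger = logging.getLogger(__name__)

MIN_CDS_LENGTH = 150
MAX_CDS_N_FRACTION = 0.10


@dataclass
class AnnotationSummary:
    n_genes: int
    n_mrnas: int
    total_gene_len: int
    total_cds_len: int
    avg_gene_len: int
    avg_cds_len: int
    avg_exon_len: int
    avg_intron_len: int
    avg_exons_per_gene: float
    cds_gc_fraction: float | None
    genes_per_100kb: float


def round_half_away(x: float) -> int:
    """Round to nearest integer, halves away from zero."""
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def average_length(total: int, count: int) -> int:
    if count <= 0:
        raise ValueError("count must be positive")
    return round_half_away(total / count)


def gene_density_per_100kb(n_genes: int, genome_length: int, places: int = 1) -> float:
    if genome_length <= 0:
        raise ValueError("genome_length must be positive")
    scale = 10 ** places
    return round_half_away(n_genes / genome_length * 1e5 * scale) / scale


def cds_residues(model: GeneModel, genome: dict[str, SequenceRecord]) -> str:
    """Concatenated CDS residues (plus-strand; composition is strand-free)."""
    rec = genome[model.seq_id]
    return "".join(rec.residues[s - 1 : e] for s, e in model.cds)


def filter_gene_models(
    models: list[GeneModel],
    genome: dict[str, SequenceRecord],
    min_cds_len: int = MIN_CDS_LENGTH,
    max_n_fraction: float = MAX_CDS_N_FRACTION,
) -> tuple[list[GeneModel], list[GeneModel]]:
    """Partition models into (kept, removed).

    Removed iff total CDS length < ``min_cds_len`` (a CDS of exactly 150
    bases is kept) or the CDS N fraction >= ``max_n_fraction`` (exactly 10%
    is removed). A gene with no CDS intervals counts as CDS length 0.
    """
    kept: list[GeneModel] = []
    removed: list[GeneModel] = []
    for m in models:
        if not m.cds:
            logger.warning("gene %s has no CDS; treated as length 0", m.gene_id)
            removed.append(m)
            continue
        seq = cds_residues(m, genome)
        n_frac = seq.count("N") / len(seq)
        if len(seq) < min_cds_len or n_frac >= max_n_fraction:
            removed.append(m)
        else:
            kept.append(m)
    return kept, removed


def summarize_annotation(
    models: list[GeneModel],
    genome_length: int,
    genome: dict[str, SequenceRecord] | None = None,
) -> AnnotationSummary:
    if not models:
        raise ValueError("no gene models to summarize")
    if genome_length <= 0:
        raise ValueError("genome_length must be positive")
    n_genes = len(models)
    n_mrnas = sum(max(1, len(m.mrna_ids)) for m in models)
    total_gene = sum(m.span_length for m in models)
    total_cds = sum(m.cds_length for m in models)
    exon_lens = [e - s + 1 for m in models for s, e in m.exons]
    intron_lens = [e - s + 1 for m in models for s, e in m.introns()]
    cds_gc = None
    if genome is not None:
        g = c = acgt = 0
        for m in models:
            seq = cds_residues(m, genome)
            g += seq.count("G")
            c += seq.count("C")
            acgt += len(seq) - seq.count("N")
        cds_gc = (g + c) / acgt if acgt else None
    return AnnotationSummary(
        n_genes=n_genes,
        n_mrnas=n_mrnas,
        total_gene_len=total_gene,
        total_cds_len=total_cds,
        avg_gene_len=average_length(total_gene, n_genes),
        avg_cds_len=average_length(total_cds, n_genes),
        avg_exon_len=average_length(sum(exon_lens), len(exon_lens)),
        # single-exon genes contribute no introns and are excluded here
        avg_intron_len=(
            average_length(sum(intron_lens), len(intron_lens))
            if intron_lens
            else 0
        ),
        avg_exons_per_gene=round(len(exon_lens) / n_genes, 1),
        cds_gc_fraction=cds_gc,
        genes_per_100kb=gene_density_per_100kb(n_genes, genome_length),
    )


def ratio_report(
    numerator: int,
    denominator: int,
    label: str = "",
    places: int = 2,
    truncate: bool = False,
) -> float:
    """Percentage ``100 * numerator / denominator`` at printed precision."""
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    if numerator > denominator:
        raise ValueError(f"{label or 'ratio'}: numerator exceeds denominator")
    pct = 100 * numerator / denominator
    scale = 10 ** places
    if truncate:
        value = math.floor(pct * scale) / scale
    else:
        value = round_half_away(pct * scale) / scale
    if label:
        logger.info("%s: %d/%d = %s%%", label, numerator, denominator, value)
    return value


def expression_support(
    models: list[GeneModel], evidence_gene_ids: set[str]
) -> float:
    """Fraction of models whose gene_id appears in the expression evidence."""
    if not models:
        return 0.0
    supported = sum(1 for m in models if m.gene_id in evidence_gene_ids)
    return supported / len(models)


def noncoding_summary(
    loci_by_class: dict[str, list[tuple[int, int]]]
) -> dict[str, tuple[int, int, int | None]]:
    """Per-class (count, total span, mean span) for noncoding loci.

    Loci are 1-based inclusive intervals; a class with zero loci reports a
    missing mean.
    """
    out = {}
    for cls, loci in loci_by_class.items():
        total = sum(e - s + 1 for s, e in loci)
        mean = average_length(total, len(loci)) if loci else None
        out[cls] = (len(loci), total, mean)
    return out
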