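"""Orphan / species-specific / conserved gene classification from hit tables,
plus transcriptome-coverage and cross-assembly comparison tiers.

Significance thresholds are strict inequalities throughout: a hit is
significant only when its e-value is strictly below the cutoff, and coverage
tiers require identity/coverage strictly above their bounds.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass

from .io_core import HitRecord

EVALUE_CUTOFF = 1e-5


@dataclass
class GeneClassification:
    gene_id: str
    category: str  # "orphan" | "species_specific" | "conserved"
    supporting_db_count: int


def classify(
    gene_ids: list[str],
    hits: list[HitRecord],
    self_species: str,
    evalue_cutoff: float = EVALUE_CUTOFF,
) -> list[GeneClassification]:
    """Classify each gene from its similarity hits.

    orphan: no hit with e-value < cutoff to any database;
    species_specific: all significant hits are to ``self_species`` subjects
    (at least one exists); conserved: a significant hit to another species.
    """
    sig: dict[str, list[HitRecord]] = defaultdict(list)
    known = set(gene_ids)
    for h in hits:
        if h.query_id not in known:
            raise KeyError(f"hit references unknown gene {h.query_id!r}")
        if h.evalue < evalue_cutoff:
            sig[h.query_id].append(h)
    out = []
    for g in gene_ids:
        hs = sig.get(g, [])
        dbs = {h.subject_db for h in hs}
        if not hs:
            category = "orphan"
        elif all(h.subject_species == self_species for h in hs):
            category = "species_specific"
        else:
            category = "conserved"
        out.append(GeneClassification(g, category, len(dbs)))
    return out


def transcript_coverage(
    alignments: list[HitRecord],
    min_identity: float = 90.0,
    min_coverage: float = 80.0,
) -> float:
    """Fraction of distinct queries with an alignment at more than
    ``min_identity`` % identity and more than ``min_coverage`` % coverage."""
    queries = {a.query_id for a in alignments}
    if not queries:
        return 0.0
    covered = {
        a.query_id
        for a in alignments
        if a.identity_pct > min_identity and a.query_coverage_pct > min_coverage
    }
    return len(covered) / len(queries)


TIER_DEFS = [
    ("cov>90_id>95", 90.0, 95.0),
    ("cov>50_id>95", 50.0, 95.0),
]


def cross_assembly_tiers(hits: list[HitRecord]) -> dict[str, int]:
    """Tiered per-query counts for a cross-assembly CDS comparison.

    Queries with multiple hits keep the lowest-evalue hit (ties broken by
    highest identity). Tiers nest: identical <= cov>90_id>95 <= cov>50_id>95
    <= any_significant.
    """
    best: dict[str, HitRecord] = {}
    for h in hits:
        cur = best.get(h.query_id)
        if cur is None or (h.evalue, -h.identity_pct) < (
            cur.evalue, -cur.identity_pct
        ):
            best[h.query_id] = h
    counts = {"any_significant": len(best), "identical": 0}
    for name, _, _ in TIER_DEFS:
        counts[name] = 0
    for h in best.values():
        for name, cov, ident in TIER_DEFS:
            if h.query_coverage_pct > cov and h.identity_pct > ident:
                counts[name] += 1
        if h.identity_pct == 100.0 and h.query_coverage_pct == 100.0:
            counts["identical"] += 1
    return counts
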