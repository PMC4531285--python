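"""Pooled-group SNP mining from per-site allele depth tables.

A pooled group of genotypes yields a SNP call at a site when a single,
unique non-reference allele is observed and it is supported by at least
three reads. Calls are made per group independently; densities and genic
assignment summarize the resulting sets.
"""

from __future__ import annotations

import logging
from collections import Counter, defaultdict
from dataclasses import dataclass

from .genome_topography import WindowTrack, make_windows, window_density
from .io_core import AlleleCountSite, GeneModel

logger = logging.getLogger(__name__)

MIN_ALT_READS = 3


@dataclass
class SnpCall:
    seq_id: str
    pos: int
    ref_base: str
    alt_base: str
    depth: int
    group_id: str


def call_snps(
    sites: list[AlleleCountSite],
    min_alt_reads: int = MIN_ALT_READS,
    strict_unique: bool = True,
) -> list[SnpCall]:
    """Apply the unique-allele depth filter.

    A site is called iff exactly one non-reference base is observed (at any
    depth, under the strict reading of "unique") and that base has depth >=
    ``min_alt_reads`` ("at least three" keeps depth 3). With
    ``strict_unique=False`` a second alt is tolerated as long as it stays
    below ``min_alt_reads``.
    """
    calls = []
    for s in sites:
        alts = {
            b: d
            for b, d in s.depth_by_base.items()
            if b != s.ref_base and d > 0
        }
        if strict_unique:
            candidates = alts if len(alts) == 1 else {}
        else:
            deep = {b: d for b, d in alts.items() if d >= min_alt_reads}
            candidates = deep if len(deep) == 1 else {}
        for b, d in candidates.items():
            if d >= min_alt_reads:
                calls.append(SnpCall(s.seq_id, s.pos, s.ref_base, b, d, s.group_id))
    return calls


def group_polymorphism(
    sites: list[AlleleCountSite],
    min_alt_reads: int = MIN_ALT_READS,
    strict_unique: bool = True,
) -> tuple[dict[str, list[SnpCall]], int]:
    """Per-group SNP call sets plus the combined (group-keyed) count."""
    by_group: dict[str, list[AlleleCountSite]] = defaultdict(list)
    for s in sites:
        by_group[s.group_id].append(s)
    calls = {
        g: call_snps(ss, min_alt_reads, strict_unique)
        for g, ss in sorted(by_group.items())
    }
    combined = sum(len(c) for c in calls.values())
    return calls, combined


def snp_density(
    calls: list[SnpCall],
    genome_length: int,
    window_bp: int = 1_000_000,
    step_bp: int = 1_000_000,
    seq_lengths: dict[str, int] | None = None,
) -> tuple[float | None, dict[str, WindowTrack]]:
    """Mean kb of genome per SNP, plus windowed per-sequence SNP counts.

    The genome span defaults to the anchored pseudomolecule length of the
    analysis (SNPs are mapped to pseudomolecules); window tracks are built
    for every seq_id present in ``seq_lengths`` (or in the calls, using the
    maximum call position as a lower bound on length).
    """
    if genome_length <= 0:
        raise ValueError("genome_length must be positive")
    mean_kb = genome_length / len(calls) / 1000 if calls else None
    if mean_kb is None:
        logger.warning("snp_density: zero calls, mean density missing")
    per_seq: dict[str, list[tuple[int, int]]] = defaultdict(list)
    for c in calls:
        per_seq[c.seq_id].append((c.pos, c.pos))
    if seq_lengths is None:
        seq_lengths = {
            sid: max(p for p, _ in pts) for sid, pts in per_seq.items()
        }
    tracks = {}
    for sid, length in seq_lengths.items():
        windows = make_windows(length, window_bp, step_bp)
        tracks[sid] = window_density(
            per_seq.get(sid, []), windows, "count", seq_id=sid
        )
    return mean_kb, tracks


def assign_snps_to_genes(
    calls: list[SnpCall], models: list[GeneModel]
) -> tuple[Counter, int]:
    """Per-gene SNP counts (genic iff pos within the gene span, bounds
    inclusive) and the number of genes hit by at least one SNP."""
    by_seq: dict[str, list[GeneModel]] = defaultdict(list)
    for m in models:
        by_seq[m.seq_id].append(m)
    counts: Counter = Counter()
    for c in calls:
        for m in by_seq.get(c.seq_id, ()):
            if m.span[0] <= c.pos <= m.span[1]:
                counts[m.gene_id] += 1
    return counts, len(counts)
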