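"""Synthetic inputs with the statistical structure the analysis assumes.

The generator emulates the study design end to end: a multi-linkage-group
genome whose pericentromeric cores are repeat-rich, gene-poor and
recombination-suppressed while the arms are the opposite; a genetic-marker
map with monotone cM; a tissue expression matrix with planted specific and
preferential genes; similarity-hit tables with planted orphan and
species-specific genes; CDS pairs diverged to target Ks values; and pooled
per-site allele depths with planted SNPs and designed negative site
classes. Every planted item is recorded in a :class:`TruthSet` so each
downstream stage can be tested for exact recovery.

Defaults mirror the reference chickpea landscape: 193 vs 1691 kb/cM and
8.63 vs 5.57 genes/100 kb for euchromatic arms vs pericentromeric cores.
All randomness flows from one integer-seeded generator, so a fixed seed
reproduces byte-identical outputs.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import metadata
from .divergence_dating import (
    CODON_TO_AA,
    SENSE_CODONS,
    proportion_synonymous,
)
from .io_core import (
    AlleleCountSite,
    ExpressionMatrix,
    GeneModel,
    HitRecord,
    MarkerRecord,
    RepeatFeature,
    SequenceRecord,
    revcomp,
)

_BASE_BYTES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class GenomeSimConfig:
    """Layout of the simulated genome.

    Rates are kb per cM, densities genes per 100 kb, fractions the portion
    of a region covered by repeats. The core must be repeat-richer and
    recombination-poorer than the arms (that is what makes it a
    pericentromere).
    """

    n_linkage_groups: int = 2
    arm_length_bp: int = 3_000_000
    core_length_bp: int = 3_000_000
    gene_density_arm: float = metadata.EUCHROMATIN_GENES_PER_100KB
    gene_density_core: float = metadata.PERICENTROMERE_GENES_PER_100KB
    repeat_fraction_arm: float = 0.20
    repeat_fraction_core: float = 0.80
    recomb_rate_arm: float = metadata.EUCHROMATIN_KB_PER_CM
    recomb_rate_core: float = metadata.PERICENTROMERE_KB_PER_CM
    marker_spacing_cm: float = 0.5
    n_scaffolds_per_lg: int = 1
    flip_every: int = 0  # reverse-orient every k-th scaffold (0 = none)
    n_unanchored: int = 0
    unanchored_gene_density: float = 3.73
    gc_fraction: float = 0.28
    seed: int = 0

    def __post_init__(self) -> None:
        if self.repeat_fraction_core <= self.repeat_fraction_arm:
            raise ValueError("core must be repeat-richer than the arms")
        if self.recomb_rate_core <= self.recomb_rate_arm:
            raise ValueError("core kb/cM must exceed arm kb/cM")
        for d in (self.gene_density_arm, self.gene_density_core):
            if 1e5 / d < _MIN_GENE_SLOT_BP:
                raise ValueError(
                    f"gene density {d}/100kb implies overlapping genes "
                    f"(slot below {_MIN_GENE_SLOT_BP} bp)"
                )


@dataclass
class TruthSet:
    """Ground truth of everything the generator planted."""

    cores: dict[str, tuple[int, int]] = field(default_factory=dict)
    scaffold_order: dict[str, list[tuple[str, str]]] = field(default_factory=dict)
    unanchored: list[str] = field(default_factory=list)
    specific: dict[str, list[str]] = field(default_factory=dict)
    preferential: dict[str, list[str]] = field(default_factory=dict)
    orphan: set[str] = field(default_factory=set)
    species_specific: set[str] = field(default_factory=set)
    ks_targets: dict[tuple[str, str], float] = field(default_factory=dict)
    snp_sites: dict[str, set] = field(default_factory=dict)
    snp_negatives: dict[str, set] = field(default_factory=dict)

    def merge(self, other: "TruthSet") -> "TruthSet":
        for name in (
            "cores", "scaffold_order", "specific", "preferential",
            "ks_targets", "snp_sites", "snp_negatives",
        ):
            getattr(self, name).update(getattr(other, name))
        self.unanchored.extend(other.unanchored)
        self.orphan |= other.orphan
        self.species_specific |= other.species_specific
        return self

    def write_json(self, path: str | Path) -> None:
        payload = {
            "cores": {k: list(v) for k, v in self.cores.items()},
            "scaffold_order": {
                k: [list(t) for t in v] for k, v in self.scaffold_order.items()
            },
            "unanchored": self.unanchored,
            "specific": self.specific,
            "preferential": self.preferential,
            "orphan": sorted(self.orphan),
            "species_specific": sorted(self.species_specific),
            "ks_targets": {
                f"{a}|{b}": ks for (a, b), ks in self.ks_targets.items()
            },
            "snp_sites": {
                g: sorted(list(t) for t in s) for g, s in self.snp_sites.items()
            },
            "snp_negatives": {
                g: sorted(list(t) for t in s)
                for g, s in self.snp_negatives.items()
            },
        }
        Path(path).write_text(json.dumps(payload, indent=1))


_MIN_GENE_SLOT_BP = 7_000  # densest packable gene slot given max gene span
_REPEAT_BLOCK_BP = 5_000
_REPEAT_CLASSES = ("LTR/Gypsy", "LTR/Copia", "DNA/MuDR")


def _random_sequence(rng: np.random.Generator, length: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    codes = np.searchsorted(np.cumsum(p), rng.random(length), side="right")
    return _BASE_BYTES[codes].tobytes().decode("ascii")


def _make_gene(
    rng: np.random.Generator, gene_id: str, seq_id: str, slot_start: int,
    slot_len: int,
) -> GeneModel:
    n_ex = int(rng.integers(2, 7))
    exon_lens = rng.integers(120, 401, n_ex)
    intron_lens = rng.integers(200, 701, n_ex - 1)
    span_len = int(exon_lens.sum() + intron_lens.sum())
    offset = int(rng.integers(0, max(1, slot_len - span_len)))
    start = slot_start + offset
    exons = []
    pos = start
    for i, el in enumerate(exon_lens):
        exons.append((pos, pos + int(el) - 1))
        if i < n_ex - 1:
            pos += int(el) + int(intron_lens[i])
        else:
            pos += int(el)
    strand = "+" if rng.random() < 0.5 else "-"
    return GeneModel(
        gene_id=gene_id,
        seq_id=seq_id,
        strand=strand,
        span=(start, exons[-1][1]),
        exons=exons,
        cds=list(exons),
        mrna_ids=[f"{gene_id}.1"],
    )


def _place_genes(
    rng: np.random.Generator, seq_id: str, region: tuple[int, int],
    density: float, prefix: str, counter: list[int],
) -> list[GeneModel]:
    start, end = region
    length = end - start + 1
    n = int(round(density * length / 1e5))
    if n == 0:
        return []
    slot = length / n
    genes = []
    for k in range(n):
        counter[0] += 1
        gid = f"{prefix}g{counter[0]:05d}"
        genes.append(
            _make_gene(rng, gid, seq_id, start + int(k * slot), int(slot))
        )
    return genes


def _place_repeats(
    rng: np.random.Generator, seq_id: str, region: tuple[int, int],
    fraction: float,
) -> list[RepeatFeature]:
    start, end = region
    length = end - start + 1
    n_blocks = int(length * fraction / _REPEAT_BLOCK_BP)
    if n_blocks == 0:
        return []
    period = length / n_blocks
    out = []
    for k in range(n_blocks):
        jitter = int(rng.integers(0, max(1, int(period - _REPEAT_BLOCK_BP))))
        s = start + int(k * period) + jitter
        e = min(s + _REPEAT_BLOCK_BP - 1, end)
        out.append(
            RepeatFeature(seq_id, (s, e), _REPEAT_CLASSES[k % len(_REPEAT_CLASSES)])
        )
    return out


def simulate_genome(
    config: GenomeSimConfig,
) -> tuple[
    list[SequenceRecord],
    list[GeneModel],
    list[RepeatFeature],
    list[MarkerRecord],
    TruthSet,
]:
    """Simulate scaffolds, gene/repeat annotation, a marker map and truth.

    Each linkage group is arm + core + arm. Genes are placed one per density
    slot (uniformly within the slot), repeats as blocks covering the
    configured fraction, and markers walk along the group at
    ``marker_spacing_cm`` with the physical step set by the regional kb/cM
    (2% jitter). Optionally each group is cut into scaffolds at inter-gene
    gaps, some reverse-oriented, so the anchoring stage has real work to do.
    """
    rng = np.random.default_rng(config.seed)
    truth = TruthSet()
    marker_token = int(rng.integers(0, 2**31))

    records: list[SequenceRecord] = []
    genes: list[GeneModel] = []
    repeats: list[RepeatFeature] = []
    markers: list[MarkerRecord] = []
    counter = [0]
    scaffold_counter = [0]

    for lg_i in range(config.n_linkage_groups):
        lg = f"LG{lg_i + 1}"
        arm, core = config.arm_length_bp, config.core_length_bp
        L = 2 * arm + core
        regions = [
            ((1, arm), "arm"),
            ((arm + 1, arm + core), "core"),
            ((arm + core + 1, L), "arm"),
        ]
        truth.cores[lg] = (arm + 1, arm + core)

        lg_genes: list[GeneModel] = []
        lg_repeats: list[RepeatFeature] = []
        for (iv, kind) in regions:
            dens = (
                config.gene_density_arm if kind == "arm"
                else config.gene_density_core
            )
            frac = (
                config.repeat_fraction_arm if kind == "arm"
                else config.repeat_fraction_core
            )
            lg_genes += _place_genes(rng, lg, iv, dens, lg, counter)
            lg_repeats += _place_repeats(rng, lg, iv, frac)

        lg_markers: list[MarkerRecord] = []
        bp = int(rng.integers(1_000, 20_001))
        cm = 0.0
        j = 0
        while bp <= L:
            j += 1
            lg_markers.append(
                MarkerRecord(
                    f"M{marker_token:x}_{lg}_{j:04d}", lg, round(cm, 4), lg, bp
                )
            )
            in_core = arm < bp <= arm + core
            rate = config.recomb_rate_core if in_core else config.recomb_rate_arm
            step = config.marker_spacing_cm * rate * 1000
            bp += int(step * (1 + rng.uniform(-0.02, 0.02)))
            cm += config.marker_spacing_cm

        lg_seq = _random_sequence(rng, L, config.gc_fraction)
        pieces = _cut_linkage_group(
            rng, config, lg, lg_seq, lg_genes, lg_repeats, lg_markers,
            scaffold_counter,
        )
        truth.scaffold_order[lg] = [(sid, ori) for sid, ori, *_ in pieces]
        for sid, ori, seq, gs, rs, ms in pieces:
            records.append(SequenceRecord(sid, seq))
            genes += gs
            repeats += rs
            markers += ms

    for u in range(config.n_unanchored):
        scaffold_counter[0] += 1
        sid = f"scaffold_{scaffold_counter[0]:04d}"
        length = int(rng.integers(200_000, 800_001))
        records.append(
            SequenceRecord(sid, _random_sequence(rng, length, config.gc_fraction))
        )
        genes += _place_genes(
            rng, sid, (1, length), config.unanchored_gene_density, f"un{u}",
            counter,
        )
        repeats += _place_repeats(
            rng, sid, (1, length), config.repeat_fraction_arm
        )
        truth.unanchored.append(sid)

    order = rng.permutation(len(records))
    records = [records[i] for i in order]
    return records, genes, repeats, markers, truth


def _cut_linkage_group(
    rng, config, lg, lg_seq, lg_genes, lg_repeats, lg_markers, scaffold_counter
):
    """Cut a linkage group into scaffolds at inter-gene gaps; remap
    coordinates to scaffold-local and reverse-orient flagged scaffolds."""
    L = len(lg_seq)
    n = config.n_scaffolds_per_lg
    cuts = [0]
    if n > 1:
        spans = sorted(g.span for g in lg_genes)
        gap_mids = [
            (a[1] + b[0]) // 2
            for a, b in zip(spans, spans[1:])
            if b[0] - a[1] > 2
        ]
        for j in range(1, n):
            target = j * L // n
            mid = min(gap_mids, key=lambda m: abs(m - target))
            if mid > cuts[-1]:
                cuts.append(mid)
    cuts.append(L)

    pieces = []
    for idx in range(len(cuts) - 1):
        a, b = cuts[idx] + 1, cuts[idx + 1]
        scaffold_counter[0] += 1
        sid = f"scaffold_{scaffold_counter[0]:04d}"
        plen = b - a + 1
        seq = lg_seq[a - 1 : b]
        gs = [g for g in lg_genes if a <= g.span[0] and g.span[1] <= b]
        rs = [
            RepeatFeature(
                sid,
                (max(r.interval[0], a) - a + 1, min(r.interval[1], b) - a + 1),
                r.repeat_class,
            )
            for r in lg_repeats
            if r.interval[1] >= a and r.interval[0] <= b
        ]
        ms = [m for m in lg_markers if a <= m.bp <= b]
        flip = (
            config.flip_every > 0
            and (idx % config.flip_every) == config.flip_every - 1
            and len(ms) >= 2
        )
        ori = "-" if flip else "+"
        if flip:
            seq = revcomp(seq)

        def local(pos: int) -> int:
            rel = pos - a + 1
            return plen - rel + 1 if flip else rel

        def local_iv(iv: tuple[int, int]) -> tuple[int, int]:
            x, y = local(iv[0]), local(iv[1])
            return (min(x, y), max(x, y))

        gs = [
            GeneModel(
                gene_id=g.gene_id,
                seq_id=sid,
                strand=(
                    g.strand if not flip else ("-" if g.strand == "+" else "+")
                ),
                span=local_iv(g.span),
                exons=sorted(local_iv(e) for e in g.exons),
                cds=sorted(local_iv(c) for c in g.cds),
                mrna_ids=g.mrna_ids,
            )
            for g in gs
        ]
        rs = [
            RepeatFeature(sid, local_iv(r.interval), r.repeat_class) for r in rs
        ]
        ms = [
            MarkerRecord(m.marker_id, m.linkage_group, m.cm, sid, local(m.bp))
            for m in ms
        ]
        pieces.append((sid, ori, seq, gs, rs, ms))
    return pieces


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------


def simulate_expression(
    gene_ids: list[str],
    tissue_ids: list[str],
    n_specific_per_tissue: int = 5,
    n_preferential_per_tissue: int = 5,
    base_mean: float = 100.0,
    margin: float = 4.0,
    dispersion: float = 0.3,
    seed: int = 0,
) -> tuple[ExpressionMatrix, TruthSet]:
    """Counts with planted tissue-specific and tissue-preferential genes.

    Background counts are negative-binomial around ``base_mean``
    (``dispersion`` is the NB overdispersion, var = mu + dispersion*mu^2).
    Specific genes are zero everywhere but one tissue; preferential genes
    get at least ``margin``-fold RPM head-room (default 4, safely above the
    3-fold call threshold) over every other tissue.
    """
    if len(tissue_ids) < 2:
        raise ValueError("need at least 2 tissues")
    n_planted = (n_specific_per_tissue + n_preferential_per_tissue) * len(
        tissue_ids
    )
    if n_planted > len(gene_ids):
        raise ValueError("more planted genes than genes available")
    rng = np.random.default_rng(seed)
    G, T = len(gene_ids), len(tissue_ids)
    libs = rng.integers(800_000, 1_200_001, T)

    nb_n = 1.0 / dispersion
    mu = base_mean * libs / 1e6
    p = nb_n / (nb_n + mu)
    counts = rng.negative_binomial(nb_n, p[None, :], size=(G, T))

    planted_idx = rng.choice(G, size=n_planted, replace=False)
    spec_idx = planted_idx[: n_specific_per_tissue * T]
    pref_idx = planted_idx[n_specific_per_tissue * T :]
    truth = TruthSet(
        specific={t: [] for t in tissue_ids},
        preferential={t: [] for t in tissue_ids},
    )
    for k, gi in enumerate(spec_idx):
        t = k % T
        counts[gi, :] = 0
        counts[gi, t] = max(1, int(rng.poisson(base_mean * 3)))
        truth.specific[tissue_ids[t]].append(gene_ids[gi])
    for k, gi in enumerate(pref_idx):
        t = k % T
        others = np.delete(np.arange(T), t)
        if counts[gi, others].max() == 0:
            counts[gi, others[0]] = int(base_mean)
        other_rpm = (counts[gi, others] / libs[others] * 1e6).max()
        counts[gi, t] = int(math.ceil(margin * other_rpm * libs[t] / 1e6)) + 1
        truth.preferential[tissue_ids[t]].append(gene_ids[gi])

    matrix = ExpressionMatrix(list(gene_ids), list(tissue_ids), counts, libs)
    return matrix, truth


# ---------------------------------------------------------------------------
# CDS pairs at target Ks
# ---------------------------------------------------------------------------


def _synonymous_variants(codon: str) -> list[str]:
    aa = CODON_TO_AA[codon]
    out = []
    for pos in range(3):
        for b in "ACGT":
            if b == codon[pos]:
                continue
            mut = codon[:pos] + b + codon[pos + 1 :]
            if CODON_TO_AA.get(mut) == aa:
                out.append(mut)
    return out


def _jc_ks(ps: float) -> float:
    return -0.75 * math.log(1 - (4 / 3) * ps)


def simulate_cds_pairs(
    n_pairs: int,
    codons_per_gene: int,
    target_ks_values: list[float],
    seed: int = 0,
    tolerance: float = 0.10,
) -> tuple[list[tuple[SequenceRecord, SequenceRecord]], TruthSet]:
    """CDS pairs whose NG86 Ks estimate hits each target within ±10%.

    An ancestral gene of sense codons is copied and synonymous substitutions
    are applied one at a time, re-estimating Ks with the package's own
    estimator after each (a rejection loop, so generator and estimator
    cannot drift apart). Targets the sequence length cannot resolve raise
    an error advising longer genes.
    """
    if any(t < 0 or t > 1.0 for t in target_ks_values):
        raise ValueError("target Ks values must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    truth = TruthSet()
    pairs = []
    for i in range(n_pairs):
        target = target_ks_values[i % len(target_ks_values)]
        ida, idb = f"pair{i + 1:04d}_a", f"pair{i + 1:04d}_b"
        anc = [SENSE_CODONS[j] for j in rng.integers(0, len(SENSE_CODONS), codons_per_gene)]
        derived = list(anc)
        if target > 0:
            seq_a = "".join(anc)
            ps1, s_sites, _ = proportion_synonymous(seq_a, seq_a)
            step_ks = _jc_ks(1.0 / s_sites)
            if step_ks > (1 + tolerance) * target:
                raise ValueError(
                    f"target Ks {target} unreachable at {codons_per_gene} "
                    f"codons (one substitution already gives {step_ks:.2e}); "
                    "use longer genes"
                )
            needed = max(1, int(math.ceil(target * s_sites)))
            max_attempts = 10 * needed + 100
            attempts = 0
            ks = 0.0
            while not (1 - tolerance) * target <= ks <= (1 + tolerance) * target:
                attempts += 1
                if attempts > max_attempts:
                    raise ValueError(
                        f"could not reach Ks {target} within "
                        f"{max_attempts} attempts; use longer genes"
                    )
                j = int(rng.integers(0, codons_per_gene))
                if derived[j] != anc[j]:
                    continue
                variants = _synonymous_variants(derived[j])
                if not variants:
                    continue
                derived[j] = variants[int(rng.integers(0, len(variants)))]
                ps, _, _ = proportion_synonymous(seq_a, "".join(derived))
                ks = _jc_ks(ps)
                if ks > (1 + tolerance) * target:
                    raise ValueError(
                        f"overshot target Ks {target} (got {ks:.2e}); "
                        "use longer genes"
                    )
        pairs.append(
            (
                SequenceRecord(ida, "".join(anc)),
                SequenceRecord(idb, "".join(derived)),
            )
        )
        truth.ks_targets[(ida, idb)] = target
    return pairs, truth


# ---------------------------------------------------------------------------
# similarity hits
# ---------------------------------------------------------------------------

_FOREIGN = [
    ("nr", "Medicago truncatula"),
    ("nr", "Glycine max"),
    ("tair10", "Arabidopsis thaliana"),
    ("swissprot", "Phaseolus vulgaris"),
]


def simulate_hits(
    gene_ids: list[str],
    n_orphan: int,
    n_species_specific: int,
    self_species: str = "Cicer arietinum",
    seed: int = 0,
) -> tuple[list[HitRecord], TruthSet]:
    """Hit tables with planted orphan and species-specific genes.

    Orphans get either no hit at all or only hits at or above the 1e-5
    significance cutoff (including some at exactly 1e-5, which the strict
    "<" must reject); species-specific genes hit only ``self_species``
    subjects; everything else hits at least one foreign species.
    """
    if n_orphan + n_species_specific > len(gene_ids):
        raise ValueError("more planted genes than genes available")
    rng = np.random.default_rng(seed)
    chosen = rng.choice(len(gene_ids), n_orphan + n_species_specific, replace=False)
    orphan = {gene_ids[i] for i in chosen[:n_orphan]}
    specific = {gene_ids[i] for i in chosen[n_orphan:]}
    hits: list[HitRecord] = []

    def pct() -> float:
        return float(np.round(rng.uniform(60, 100), 2))

    for k, g in enumerate(sorted(orphan)):
        if k % 2 == 0:
            continue  # no hit at all
        evalue = 1e-5 if k % 4 == 1 else float(rng.uniform(1e-5, 1e-2))
        db, sp = _FOREIGN[int(rng.integers(0, len(_FOREIGN)))]
        hits.append(HitRecord(g, f"sub_{g}", db, sp, evalue, pct(), pct()))
    for g in sorted(specific):
        for _ in range(int(rng.integers(1, 3))):
            hits.append(
                HitRecord(
                    g, f"ca_{g}", "chickpea_db", self_species,
                    10.0 ** -float(rng.uniform(8, 40)), pct(), pct(),
                )
            )
    for g in gene_ids:
        if g in orphan or g in specific:
            continue
        n_hits = int(rng.integers(1, 4))
        for h in range(n_hits):
            db, sp = _FOREIGN[int(rng.integers(0, len(_FOREIGN)))]
            hits.append(
                HitRecord(
                    g, f"sub_{g}_{h}", db, sp,
                    10.0 ** -float(rng.uniform(6, 50)), pct(), pct(),
                )
            )
    truth = TruthSet(orphan=orphan, species_specific=specific)
    return hits, truth


# ---------------------------------------------------------------------------
# pooled allele counts
# ---------------------------------------------------------------------------


def simulate_allele_counts(
    genome: list[SequenceRecord],
    n_snps_per_group: int = 50,
    depth_range: tuple[int, int] = (5, 30),
    groups: tuple[str, ...] = ("desi", "kabuli"),
    n_negatives_per_class: int = 8,
    seed: int = 0,
) -> tuple[list[AlleleCountSite], TruthSet]:
    """Per-site allele depths with planted SNPs and designed negatives.

    Positives carry exactly one non-reference base at depth >= 3 (the first
    per group sits exactly at 3, pinning the boundary). Negatives come in
    three classes the depth filter must reject: an alt at depth 2, two
    distinct alts, and reference-only sites.
    """
    if depth_range[0] < 1:
        raise ValueError("depth_range lower bound must be >= 1")
    rng = np.random.default_rng(seed)
    lengths = np.array([len(r) for r in genome], dtype=float)
    weights = lengths / lengths.sum()
    used: set[tuple[str, int, str]] = set()

    def draw_site(group: str) -> tuple[str, int, str]:
        while True:
            i = int(rng.choice(len(genome), p=weights))
            pos = int(rng.integers(1, len(genome[i]) + 1))
            ref = genome[i].residues[pos - 1]
            key = (genome[i].id, pos, group)
            if ref in "ACGT" and key not in used:
                used.add(key)
                return genome[i].id, pos, ref

    def ref_depth() -> int:
        return int(rng.integers(depth_range[0], depth_range[1] + 1))

    sites: list[AlleleCountSite] = []
    truth = TruthSet(
        snp_sites={g: set() for g in groups},
        snp_negatives={g: set() for g in groups},
    )
    for group in groups:
        for k in range(n_snps_per_group):
            sid, pos, ref = draw_site(group)
            alt = rng.choice([b for b in "ACGT" if b != ref])
            alt_depth = 3 if k == 0 else int(
                rng.integers(3, max(4, depth_range[1]) + 1)
            )
            depths = {ref: ref_depth(), alt: alt_depth}
            sites.append(AlleleCountSite(sid, pos, ref, group, depths))
            truth.snp_sites[group].add((sid, pos, str(alt)))
        for _ in range(n_negatives_per_class):
            # (a) single alt below the depth floor
            sid, pos, ref = draw_site(group)
            alt = rng.choice([b for b in "ACGT" if b != ref])
            sites.append(
                AlleleCountSite(sid, pos, ref, group, {ref: ref_depth(), alt: 2})
            )
            truth.snp_negatives[group].add((sid, pos))
            # (b) two distinct alt bases, both deep
            sid, pos, ref = draw_site(group)
            alts = rng.choice(
                [b for b in "ACGT" if b != ref], size=2, replace=False
            )
            sites.append(
                AlleleCountSite(
                    sid, pos, ref, group,
                    {
                        ref: ref_depth(),
                        str(alts[0]): int(rng.integers(3, 10)),
                        str(alts[1]): int(rng.integers(3, 10)),
                    },
                )
            )
            truth.snp_negatives[group].add((sid, pos))
            # (c) reference-only
            sid, pos, ref = draw_site(group)
            sites.append(AlleleCountSite(sid, pos, ref, group, {ref: ref_depth()}))
            truth.snp_negatives[group].add((sid, pos))
    return sites, truth
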