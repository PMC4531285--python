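"""Shared domain types and readers/writers for the formats used by every stage.

All internal coordinates are 1-based inclusive (the GFF3 convention); the BED
writer is the only 0-based surface. Readers are total on well-formed files and
raise :class:`FormatError` otherwise — there are no partial silent results.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import gffutils
import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

logger = logging.getLogger(__name__)

ALPHABET = set("ACGTN")
# IUPAC nucleotide ambiguity codes other than N; collapsed to N on read
# because downstream statistics recognize only N as ambiguity.
_IUPAC_AMBIGUOUS = "RYSWKMBDHVU"
_AMBIG_TABLE = str.maketrans(_IUPAC_AMBIGUOUS, "N" * len(_IUPAC_AMBIGUOUS))

GAP_LENGTH = 100  # N padding between scaffolds in a pseudomolecule


class FormatError(ValueError):
    """A structurally invalid input file or record."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class SequenceRecord:
    """A named scaffold / pseudomolecule / CDS sequence over {A,C,G,T,N}."""

    id: str
    residues: str

    def __post_init__(self) -> None:
        if not self.id:
            raise FormatError("sequence record with empty id")
        if not self.residues:
            raise FormatError(f"sequence {self.id!r} has no residues")

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class GeneModel:
    """A gene with exon and CDS intervals on a scaffold (1-based inclusive)."""

    gene_id: str
    seq_id: str
    strand: str
    span: tuple[int, int]
    exons: list[tuple[int, int]]
    cds: list[tuple[int, int]]
    mrna_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise FormatError(f"gene {self.gene_id}: strand must be + or -")
        if not self.exons:
            raise FormatError(f"gene {self.gene_id}: at least one exon required")
        self.exons = sorted(self.exons)
        for (s, e) in self.exons + self.cds + [self.span]:
            if s > e or s < 1:
                raise FormatError(
                    f"gene {self.gene_id}: invalid interval {s}..{e}"
                )
        for (s, e) in self.exons:
            if s < self.span[0] or e > self.span[1]:
                raise FormatError(f"gene {self.gene_id}: exon outside span")
        for i in range(1, len(self.exons)):
            if self.exons[i][0] <= self.exons[i - 1][1]:
                raise FormatError(f"gene {self.gene_id}: overlapping exons")
        for (s, e) in self.cds:
            if s < self.span[0] or e > self.span[1]:
                raise FormatError(
                    f"gene {self.gene_id}: CDS {s}..{e} outside gene span"
                )

    @property
    def span_length(self) -> int:
        return self.span[1] - self.span[0] + 1

    @property
    def cds_length(self) -> int:
        return sum(e - s + 1 for s, e in self.cds)

    @property
    def midpoint(self) -> int:
        return (self.span[0] + self.span[1]) // 2

    def introns(self) -> list[tuple[int, int]]:
        """Gaps between consecutive exons."""
        out = []
        for (a, b) in zip(self.exons, self.exons[1:]):
            if b[0] - a[1] > 1:
                out.append((a[1] + 1, b[0] - 1))
        return out


@dataclass
class RepeatFeature:
    seq_id: str
    interval: tuple[int, int]
    repeat_class: str = "unknown"

    def __post_init__(self) -> None:
        if self.interval[0] > self.interval[1]:
            raise FormatError(
                f"repeat on {self.seq_id}: invalid interval {self.interval}"
            )


@dataclass
class MarkerRecord:
    """Genetic-map entry tying a scaffold coordinate to (linkage group, cM)."""

    marker_id: str
    linkage_group: str
    cm: float
    seq_id: str
    bp: int

    def __post_init__(self) -> None:
        if self.cm < 0:
            raise FormatError(f"marker {self.marker_id}: negative cM {self.cm}")
        if self.bp < 1:
            raise FormatError(f"marker {self.marker_id}: bp must be >= 1")


@dataclass
class ExpressionMatrix:
    """Gene x tissue unique-read counts plus per-tissue library sizes."""

    gene_ids: list[str]
    tissue_ids: list[str]
    counts: np.ndarray  # shape (n_genes, n_tissues), non-negative ints
    library_sizes: np.ndarray  # shape (n_tissues,), positive ints

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        self.library_sizes = np.asarray(self.library_sizes, dtype=np.int64)
        if self.counts.shape != (len(self.gene_ids), len(self.tissue_ids)):
            raise FormatError("expression matrix dimensions inconsistent")
        if (self.counts < 0).any():
            raise FormatError("negative read counts")
        if (self.library_sizes <= 0).any():
            raise FormatError("library sizes must be positive")
        if (self.counts > self.library_sizes[None, :]).any():
            raise FormatError("count exceeds library size")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts, index=self.gene_ids, columns=self.tissue_ids
        )


@dataclass
class HitRecord:
    """One similarity-search hit (tabular BLAST dialect)."""

    query_id: str
    subject_id: str
    subject_db: str
    subject_species: str
    evalue: float
    identity_pct: float
    query_coverage_pct: float

    def __post_init__(self) -> None:
        if self.evalue < 0:
            raise FormatError(f"hit {self.query_id}: negative e-value")
        for v in (self.identity_pct, self.query_coverage_pct):
            if not 0 <= v <= 100:
                raise FormatError(f"hit {self.query_id}: percentage out of range")


@dataclass
class AlleleCountSite:
    """Per-site, per-group read depth of each observed base."""

    seq_id: str
    pos: int
    ref_base: str
    group_id: str
    depth_by_base: dict[str, int]

    def __post_init__(self) -> None:
        if self.ref_base not in "ACGT":
            raise FormatError(f"site {self.seq_id}:{self.pos}: bad ref base")
        if any(d < 0 for d in self.depth_by_base.values()):
            raise FormatError(f"site {self.seq_id}:{self.pos}: negative depth")


@dataclass
class KsRecord:
    """Synonymous substitutions per synonymous site for an unordered pair."""

    gene_a: str
    gene_b: str
    ks: float

    def __post_init__(self) -> None:
        if self.ks < 0:
            raise FormatError("Ks must be non-negative")


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------


def normalize_residues(raw: str, seq_id: str = "?") -> str:
    """Uppercase and collapse IUPAC ambiguity codes (other than N) to N."""
    up = raw.upper()
    cleaned = up.translate(_AMBIG_TABLE)
    n_converted = sum(1 for a, b in zip(up, cleaned) if a != b)
    if n_converted:
        logger.warning(
            "sequence %s: converted %d IUPAC ambiguity bases to N",
            seq_id,
            n_converted,
        )
    bad = set(cleaned) - ALPHABET
    if bad:
        raise FormatError(
            f"sequence {seq_id}: characters outside A/C/G/T/N: {sorted(bad)}"
        )
    return cleaned


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise FormatError(f"duplicate sequence id {rec.id!r} in {path}")
        seen.add(rec.id)
        records.append(SequenceRecord(rec.id, normalize_residues(str(rec.seq), rec.id)))
    if not records:
        raise FormatError(f"no FASTA records in {path}")
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path) -> None:
    bio = (
        _BioSeqRecord(Seq(r.residues), id=r.id, description="") for r in records
    )
    SeqIO.write(bio, str(path), "fasta")


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------

DEFAULT_REPEAT_TYPES = ("repeat_region", "dispersed_repeat")


def _merge_intervals(ivals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    if not ivals:
        return []
    ivals = sorted(ivals)
    out = [ivals[0]]
    for s, e in ivals[1:]:
        if s <= out[-1][1] + 1:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


def read_gff3(
    path: str | Path,
    repeat_types: Sequence[str] = DEFAULT_REPEAT_TYPES,
) -> tuple[list[GeneModel], list[RepeatFeature]]:
    """Parse genes (gene/mRNA/exon/CDS linked by ID/Parent) and repeats.

    Exon/CDS intervals of alternative isoforms are merged per gene. Genes
    without exon children get a single exon equal to the span, with a
    warning. A CDS outside its gene span is an error naming the gene.
    """
    db = gffutils.create_db(
        str(path), ":memory:", keep_order=True, merge_strategy="create_unique"
    )
    genes: list[GeneModel] = []
    for g in db.features_of_type("gene"):
        if g.start > g.end:
            raise FormatError(f"gene {g.id}: start > end ({g.start}..{g.end})")
        exons = []
        cds = []
        mrna_ids = [m.id for m in db.children(g, featuretype="mRNA")]
        for f in db.children(g, featuretype=("exon", "CDS")):
            if f.start > f.end:
                raise FormatError(
                    f"gene {g.id}: {f.featuretype} with start > end "
                    f"({f.start}..{f.end})"
                )
            if f.featuretype == "exon":
                exons.append((f.start, f.end))
            else:
                if f.start < g.start or f.end > g.end:
                    raise FormatError(
                        f"gene {g.id}: CDS {f.start}..{f.end} outside gene span"
                    )
                cds.append((f.start, f.end))
        if not exons:
            logger.warning("gene %s has no exons; using span as single exon", g.id)
            exons = [(g.start, g.end)]
        genes.append(
            GeneModel(
                gene_id=g.id,
                seq_id=g.seqid,
                strand=g.strand if g.strand in "+-" else "+",
                span=(g.start, g.end),
                exons=_merge_intervals(exons),
                cds=_merge_intervals(cds),
                mrna_ids=mrna_ids,
            )
        )
    repeats: list[RepeatFeature] = []
    for rt in repeat_types:
        for f in db.features_of_type(rt):
            cls = f.attributes.get("repeat_class", [None])[0] or rt
            repeats.append(RepeatFeature(f.seqid, (f.start, f.end), cls))
    return genes, repeats


def write_gff3(
    genes: Iterable[GeneModel],
    repeats: Iterable[RepeatFeature],
    path: str | Path,
) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            fh.write(
                "\t".join(
                    [
                        g.seq_id, "cicerkit", "gene", str(g.span[0]),
                        str(g.span[1]), ".", g.strand, ".", f"ID={g.gene_id}",
                    ]
                )
                + "\n"
            )
            mrna = g.mrna_ids[0] if g.mrna_ids else f"{g.gene_id}.1"
            fh.write(
                "\t".join(
                    [
                        g.seq_id, "cicerkit", "mRNA", str(g.span[0]),
                        str(g.span[1]), ".", g.strand, ".",
                        f"ID={mrna};Parent={g.gene_id}",
                    ]
                )
                + "\n"
            )
            for i, (s, e) in enumerate(g.exons, 1):
                fh.write(
                    "\t".join(
                        [
                            g.seq_id, "cicerkit", "exon", str(s), str(e), ".",
                            g.strand, ".", f"ID={mrna}.exon{i};Parent={mrna}",
                        ]
                    )
                    + "\n"
                )
            for i, (s, e) in enumerate(g.cds, 1):
                fh.write(
                    "\t".join(
                        [
                            g.seq_id, "cicerkit", "CDS", str(s), str(e), ".",
                            g.strand, "0", f"ID={mrna}.cds;Parent={mrna}",
                        ]
                    )
                    + "\n"
                )
        for j, r in enumerate(repeats, 1):
            fh.write(
                "\t".join(
                    [
                        r.seq_id, "cicerkit", "repeat_region",
                        str(r.interval[0]), str(r.interval[1]), ".", "+", ".",
                        f"ID=repeat{j};repeat_class={r.repeat_class}",
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# marker map (5-column TSV dialect of our own)
# ---------------------------------------------------------------------------

MARKER_COLUMNS = ["marker_id", "linkage_group", "cm", "seq_id", "bp"]


def read_marker_map(path: str | Path) -> list[MarkerRecord]:
    df = pd.read_csv(path, sep="\t", dtype={"linkage_group": str, "seq_id": str})
    missing = [c for c in MARKER_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"marker map missing column(s): {missing}")
    if df["marker_id"].duplicated().any():
        dup = df.loc[df["marker_id"].duplicated(), "marker_id"].iloc[0]
        raise FormatError(f"duplicate marker id {dup!r}")
    records = [
        MarkerRecord(
            str(r.marker_id), str(r.linkage_group), float(r.cm), str(r.seq_id),
            int(r.bp),
        )
        for r in df.itertuples()
    ]
    records.sort(key=lambda m: (m.linkage_group, m.cm, m.marker_id))
    return records


def write_marker_map(markers: Iterable[MarkerRecord], path: str | Path) -> None:
    rows = [
        (m.marker_id, m.linkage_group, m.cm, m.seq_id, m.bp) for m in markers
    ]
    pd.DataFrame(rows, columns=MARKER_COLUMNS).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# AGP v2.1 / BED / TSV
# ---------------------------------------------------------------------------


@dataclass
class AgpRow:
    """One line of an AGP v2.1 file (W = scaffold component, U = gap)."""

    object_id: str
    object_beg: int
    object_end: int
    part_number: int
    kind: str  # "W" or "U"
    component_id: str = ""  # W only
    component_beg: int = 0
    component_end: int = 0
    orientation: str = "+"
    gap_length: int = GAP_LENGTH


def write_agp(plan: Sequence[AgpRow], path: str | Path) -> None:
    prev_end: dict[str, int] = {}
    with open(path, "w") as fh:
        fh.write("##agp-version\t2.1\n")
        for row in plan:
            expected = prev_end.get(row.object_id, 0) + 1
            if row.object_beg != expected:
                raise FormatError(
                    f"AGP components for {row.object_id} overlap or leave a "
                    f"hole at {row.object_beg} (expected {expected})"
                )
            prev_end[row.object_id] = row.object_end
            if row.kind == "W":
                fields = [
                    row.object_id, row.object_beg, row.object_end,
                    row.part_number, "W", row.component_id, row.component_beg,
                    row.component_end, row.orientation,
                ]
            elif row.kind == "U":
                fields = [
                    row.object_id, row.object_beg, row.object_end,
                    row.part_number, "U", row.gap_length, "scaffold", "yes",
                    "map",
                ]
            else:
                raise FormatError(f"unsupported AGP component type {row.kind!r}")
            fh.write("\t".join(str(f) for f in fields) + "\n")


def read_agp(path: str | Path) -> list[AgpRow]:
    rows: list[AgpRow] = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            p = line.rstrip("\n").split("\t")
            if p[4] == "W":
                rows.append(
                    AgpRow(
                        p[0], int(p[1]), int(p[2]), int(p[3]), "W", p[5],
                        int(p[6]), int(p[7]), p[8],
                    )
                )
            elif p[4] == "U":
                rows.append(
                    AgpRow(
                        p[0], int(p[1]), int(p[2]), int(p[3]), "U",
                        gap_length=int(p[5]),
                    )
                )
            else:
                raise FormatError(f"unsupported AGP component type {p[4]!r}")
    return rows


def write_bed(
    intervals: Iterable[tuple], path: str | Path
) -> None:
    """Write 1-based inclusive internal intervals as 0-based half-open BED.

    Each interval is (seq_id, start, end) or (seq_id, start, end, name).
    """
    with open(path, "w") as fh:
        for iv in intervals:
            seq_id, start, end = iv[0], iv[1], iv[2]
            if start < 1 or end < start:
                raise FormatError(f"invalid interval {iv}")
            fields = [seq_id, str(start - 1), str(end)]
            if len(iv) > 3:
                fields.append(str(iv[3]))
            fh.write("\t".join(fields) + "\n")


def write_tsv(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# expression counts / hits / allele counts tables
# ---------------------------------------------------------------------------


def read_expression(
    counts_path: str | Path, libsizes_path: str | Path
) -> ExpressionMatrix:
    """Counts TSV: first column gene_id, remaining columns tissues.
    Library-size TSV: columns tissue_id, library_size."""
    counts = pd.read_csv(counts_path, sep="\t", index_col=0)
    libs = pd.read_csv(libsizes_path, sep="\t", index_col=0)["library_size"]
    missing = [t for t in counts.columns if t not in libs.index]
    if missing:
        raise FormatError(f"library sizes missing for tissue(s): {missing}")
    return ExpressionMatrix(
        gene_ids=[str(g) for g in counts.index],
        tissue_ids=[str(t) for t in counts.columns],
        counts=counts.to_numpy(),
        library_sizes=libs.loc[counts.columns].to_numpy(),
    )


def write_expression(
    matrix: ExpressionMatrix, counts_path: str | Path, libsizes_path: str | Path
) -> None:
    matrix.to_frame().rename_axis("gene_id").to_csv(counts_path, sep="\t")
    pd.DataFrame(
        {"tissue_id": matrix.tissue_ids, "library_size": matrix.library_sizes}
    ).to_csv(libsizes_path, sep="\t", index=False)


HIT_COLUMNS = ["qseqid", "sseqid", "db", "species", "evalue", "pident", "qcovs"]


def read_hits(path: str | Path) -> list[HitRecord]:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in HIT_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"hits table missing column(s): {missing}")
    return [
        HitRecord(
            str(r.qseqid), str(r.sseqid), str(r.db), str(r.species),
            float(r.evalue), float(r.pident), float(r.qcovs),
        )
        for r in df.itertuples()
    ]


def write_hits(hits: Iterable[HitRecord], path: str | Path) -> None:
    rows = [
        (
            h.query_id, h.subject_id, h.subject_db, h.subject_species,
            h.evalue, h.identity_pct, h.query_coverage_pct,
        )
        for h in hits
    ]
    pd.DataFrame(rows, columns=HIT_COLUMNS).to_csv(path, sep="\t", index=False)


ALLELE_COLUMNS = [
    "seq_id", "pos", "ref_base", "group_id",
    "depth_A", "depth_C", "depth_G", "depth_T",
]


def read_allele_counts(path: str | Path) -> list[AlleleCountSite]:
    df = pd.read_csv(path, sep="\t", dtype={"seq_id": str, "group_id": str})
    missing = [c for c in ALLELE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"allele table missing column(s): {missing}")
    return [
        AlleleCountSite(
            str(r.seq_id), int(r.pos), str(r.ref_base), str(r.group_id),
            {
                "A": int(r.depth_A), "C": int(r.depth_C),
                "G": int(r.depth_G), "T": int(r.depth_T),
            },
        )
        for r in df.itertuples()
    ]


def write_allele_counts(
    sites: Iterable[AlleleCountSite], path: str | Path
) -> None:
    rows = [
        (
            s.seq_id, s.pos, s.ref_base, s.group_id,
            s.depth_by_base.get("A", 0), s.depth_by_base.get("C", 0),
            s.depth_by_base.get("G", 0), s.depth_by_base.get("T", 0),
        )
        for s in sites
    ]
    pd.DataFrame(rows, columns=ALLELE_COLUMNS).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# misc
# ---------------------------------------------------------------------------


def load_config(path: str | Path) -> dict:
    """YAML config naming input paths and parameters."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise FormatError(f"config {path} must be a YAML mapping")
    return cfg


_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(residues: str) -> str:
    return residues.translate(_COMPLEMENT)[::-1]


def natural_key(label: str) -> tuple:
    """Sort key that orders LG2 before LG10."""
    return tuple(
        int(t) if t.isdigit() else t for t in re.split(r"(\d+)", label)
    )
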