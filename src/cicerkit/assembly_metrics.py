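"""Assembly-level statistics and marker-map-driven pseudomolecule construction.

Covers scaffold length filtering, N50 length/index, base composition, and the
anchoring of scaffolds to linkage groups by genetic-map markers (majority
vote for assignment, mean marker cM for order, sign of the Spearman
correlation between bp and cM for orientation).
"""

from __future__ import annotations

import logging
from collections import Counter, defaultdict
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .io_core import (
    GAP_LENGTH,
    AgpRow,
    FormatError,
    MarkerRecord,
    SequenceRecord,
    natural_key,
    revcomp,
)

logger = logging.getLogger(__name__)


@dataclass
class AssemblySummary:
    total_size_bp: int
    n_scaffolds: int
    min_len: int
    max_len: int
    mean_len: float
    n50_length_bp: int
    n50_index: int
    gc_fraction: float | None  # None when no unambiguous base exists
    n_fraction: float


def filter_short(
    records: list[SequenceRecord], min_len: int
) -> list[SequenceRecord]:
    """Drop scaffolds shorter than ``min_len`` (a scaffold of exactly
    ``min_len`` survives: "less than" removes only the strictly shorter)."""
    if min_len < 0:
        raise ValueError("min_len must be >= 0")
    kept = [r for r in records if len(r) >= min_len]
    logger.info(
        "filter_short: removed %d of %d scaffolds (< %d bp)",
        len(records) - len(kept), len(records), min_len,
    )
    return kept


def n50(lengths: list[int]) -> tuple[int, int]:
    """(N50 length, N50 index): the smallest scaffold of the fewest set
    representing at least half the assembled bases, and that set's size."""
    if not lengths:
        raise ValueError("n50 of empty length list")
    if any(l <= 0 for l in lengths):
        raise ValueError("lengths must be positive")
    srt = sorted(lengths, reverse=True)
    half = sum(srt) / 2
    acc = 0
    for k, length in enumerate(srt, 1):
        acc += length
        if acc >= half:
            return length, k
    raise AssertionError("unreachable")


def composition(records: list[SequenceRecord]) -> AssemblySummary:
    """Pooled base composition and size statistics.

    GC is computed over unambiguous bases only: (G+C)/(A+C+G+T). A set of
    all-N sequences has undefined GC, reported as None.
    """
    if not records:
        raise ValueError("composition of empty record set")
    counts = Counter()
    lengths = []
    for r in records:
        lengths.append(len(r))
        for base in "ACGTN":
            counts[base] += r.residues.count(base)
    total = sum(lengths)
    acgt = counts["A"] + counts["C"] + counts["G"] + counts["T"]
    gc = (counts["G"] + counts["C"]) / acgt if acgt else None
    length_n50, idx = n50(lengths)
    return AssemblySummary(
        total_size_bp=total,
        n_scaffolds=len(records),
        min_len=min(lengths),
        max_len=max(lengths),
        mean_len=total / len(records),
        n50_length_bp=length_n50,
        n50_index=idx,
        gc_fraction=gc,
        n_fraction=counts["N"] / total,
    )


def anchor_scaffolds(
    records: list[SequenceRecord],
    markers: list[MarkerRecord],
    gap_length: int = GAP_LENGTH,
) -> tuple[list[SequenceRecord], list[AgpRow], list[SequenceRecord]]:
    """Build pseudomolecules from scaffolds using a genetic marker map.

    Assignment: each scaffold goes to the linkage group holding the majority
    of its markers (tie: lowest-numbered group, with a warning). Order within
    a group: ascending mean marker cM. Orientation: sign of the Spearman
    correlation between marker bp and cM ('+' when fewer than 2 markers or
    the correlation is undefined). Scaffolds are joined with ``gap_length``
    Ns recorded as AGP U gaps; marker-less scaffolds are returned unanchored.
    """
    by_id = {r.id: r for r in records}
    per_scaffold: dict[str, list[MarkerRecord]] = defaultdict(list)
    for m in markers:
        rec = by_id.get(m.seq_id)
        if rec is None:
            logger.warning(
                "marker %s references unknown scaffold %s; skipped",
                m.marker_id, m.seq_id,
            )
            continue
        if m.bp > len(rec):
            raise FormatError(
                f"marker {m.marker_id} at bp {m.bp} beyond scaffold "
                f"{m.seq_id} length {len(rec)}"
            )
        per_scaffold[m.seq_id].append(m)

    assignments: dict[str, list[tuple[float, str, str]]] = defaultdict(list)
    for sid, ms in per_scaffold.items():
        votes = Counter(m.linkage_group for m in ms)
        top = max(votes.values())
        winners = sorted(
            (lg for lg, v in votes.items() if v == top), key=natural_key
        )
        if len(winners) > 1:
            logger.warning(
                "scaffold %s: marker tie between %s; assigned to %s",
                sid, winners, winners[0],
            )
        lg = winners[0]
        lg_markers = [m for m in ms if m.linkage_group == lg]
        mean_cm = float(np.mean([m.cm for m in lg_markers]))
        orientation = _orientation(sid, lg_markers)
        assignments[lg].append((mean_cm, sid, orientation))

    pseudomolecules: list[SequenceRecord] = []
    plan: list[AgpRow] = []
    for lg in sorted(assignments, key=natural_key):
        ordered = sorted(assignments[lg], key=lambda t: (t[0], t[1]))
        obj_id = f"pseudo_{lg}"
        pieces = []
        pos = 0
        part = 0
        for i, (_, sid, orientation) in enumerate(ordered):
            if i > 0:
                part += 1
                plan.append(
                    AgpRow(
                        obj_id, pos + 1, pos + gap_length, part, "U",
                        gap_length=gap_length,
                    )
                )
                pieces.append("N" * gap_length)
                pos += gap_length
            seq = by_id[sid].residues
            if orientation == "-":
                seq = revcomp(seq)
            part += 1
            plan.append(
                AgpRow(
                    obj_id, pos + 1, pos + len(seq), part, "W", sid, 1,
                    len(seq), orientation,
                )
            )
            pieces.append(seq)
            pos += len(seq)
        pseudomolecules.append(SequenceRecord(obj_id, "".join(pieces)))

    unanchored = [r for r in records if r.id not in per_scaffold]
    return pseudomolecules, plan, unanchored


def _orientation(sid: str, ms: list[MarkerRecord]) -> str:
    if len(ms) < 2:
        logger.warning("scaffold %s: <2 markers, orientation defaults to +", sid)
        return "+"
    bp = [m.bp for m in ms]
    cm = [m.cm for m in ms]
    rho = stats.spearmanr(bp, cm).statistic
    if np.isnan(rho):
        logger.warning(
            "scaffold %s: orientation undefined (constant ranks), using +", sid
        )
        return "+"
    return "-" if rho < 0 else "+"


def anchored_fraction(plan: list[AgpRow], total_size: int) -> float:
    """Fraction of assembled bases placed in pseudomolecules.

    Gap Ns are excluded from the numerator (only W components count), so
    with everything anchored the fraction is exactly 1.0 relative to the
    scaffold total.
    """
    anchored = sum(
        row.component_end - row.component_beg + 1
        for row in plan
        if row.kind == "W"
    )
    return anchored / total_size
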