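"""Pairwise Ks by the Nei-Gojobori (1986) counting method, Ks-distribution
mode finding, and molecular-clock divergence dating T = Ks/(2r).

NG86 counts synonymous (S) and nonsynonymous (N) *sites* per codon as the
fraction of the three possible single-nucleotide changes at each position
that preserve the amino acid, and synonymous/nonsynonymous *differences*
between two codons by averaging over all minimal mutational pathways
(pathways passing through stop codons are excluded). The proportion of
synonymous differences pS = Sd/S is corrected for multiple hits with the
Jukes-Cantor formula Ks = -(3/4) ln(1 - (4/3) pS), which saturates at
pS >= 3/4.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from Bio.Data import CodonTable

from .io_core import KsRecord, SequenceRecord

_TABLE = CodonTable.unambiguous_dna_by_id[1]
STOP_CODONS = set(_TABLE.stop_codons)
CODON_TO_AA = dict(_TABLE.forward_table)
SENSE_CODONS = sorted(CODON_TO_AA)
_BASES = "ACGT"


class KsSaturationError(ValueError):
    """pS >= 3/4: the Jukes-Cantor correction is undefined (saturation)."""


@lru_cache(maxsize=None)
def synonymous_sites(codon: str) -> float:
    """NG86 synonymous site count of one codon (0..3)."""
    aa = CODON_TO_AA.get(codon)
    if aa is None:
        raise ValueError(f"stop or invalid codon {codon!r}")
    s = 0.0
    for pos in range(3):
        syn = 0
        for b in _BASES:
            if b == codon[pos]:
                continue
            mut = codon[:pos] + b + codon[pos + 1 :]
            if CODON_TO_AA.get(mut) == aa:
                syn += 1
        s += syn / 3
    return s


@lru_cache(maxsize=None)
def pathway_differences(c1: str, c2: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) differences between two codons, averaged
    with equal weight over all minimal mutational pathways that avoid stop
    codons."""
    if c1 == c2:
        return 0.0, 0.0
    positions = [i for i in range(3) if c1[i] != c2[i]]
    path_sd = []
    path_nd = []
    for order in itertools.permutations(positions):
        cur = c1
        sd = nd = 0
        valid = True
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
            if nxt in STOP_CODONS:
                valid = False
                break
            if CODON_TO_AA[cur] == CODON_TO_AA[nxt]:
                sd += 1
            else:
                nd += 1
            cur = nxt
        if valid:
            path_sd.append(sd)
            path_nd.append(nd)
    if not path_sd:
        # every pathway passes through a stop: count all changes nonsyn
        return 0.0, float(len(positions))
    return float(np.mean(path_sd)), float(np.mean(path_nd))


def _codons(seq: str, name: str) -> list[str]:
    if len(seq) % 3:
        raise ValueError(f"{name}: length {len(seq)} not divisible by 3")
    codons = [seq[i : i + 3] for i in range(0, len(seq), 3)]
    for i, c in enumerate(codons):
        if c in STOP_CODONS:
            raise ValueError(f"{name}: internal stop codon {c} at codon {i + 1}")
        if c not in CODON_TO_AA:
            raise ValueError(f"{name}: invalid codon {c!r} at codon {i + 1}")
    return codons


def proportion_synonymous(seq_a: str, seq_b: str) -> tuple[float, float, float]:
    """(pS, S, Sd) for two aligned gap-free coding sequences."""
    if len(seq_a) != len(seq_b):
        raise ValueError("sequences differ in length")
    ca = _codons(seq_a, "sequence a")
    cb = _codons(seq_b, "sequence b")
    s_a = sum(synonymous_sites(c) for c in ca)
    s_b = sum(synonymous_sites(c) for c in cb)
    s_sites = (s_a + s_b) / 2
    sd = sum(pathway_differences(x, y)[0] for x, y in zip(ca, cb) if x != y)
    if s_sites == 0:
        raise ValueError("no synonymous sites in sequences")
    return sd / s_sites, s_sites, sd


def ks_ng86(cds_a: SequenceRecord, cds_b: SequenceRecord) -> KsRecord:
    """Nei-Gojobori Ks with Jukes-Cantor correction for an aligned CDS pair."""
    ps, _, _ = proportion_synonymous(cds_a.residues, cds_b.residues)
    if ps >= 0.75:
        raise KsSaturationError(
            f"{cds_a.id}/{cds_b.id}: pS = {ps:.3f} >= 3/4, Ks saturated"
        )
    ks = -0.75 * math.log(1 - (4 / 3) * ps)
    return KsRecord(cds_a.id, cds_b.id, ks)


def ks_peak(
    ks_values: list[float],
    bin_width: float = 0.0005,
    min_mass: float = 0.05,
) -> list[float]:
    """Modal Ks values of a distribution.

    Histogram at ``bin_width`` starting at 0; modes are bins that strictly
    exceed both neighbours (edge bins compare against an implicit 0) and
    carry at least ``min_mass`` of the total mass. Returned as bin
    midpoints, largest mass first.
    """
    values = np.asarray(ks_values, dtype=float)
    if len(values) < 10:
        raise ValueError("need at least 10 Ks values")
    n_bins = int(np.floor(values.max() / bin_width)) + 1
    edges = np.arange(n_bins + 1) * bin_width
    counts, _ = np.histogram(values, bins=edges)
    padded = np.concatenate([[0], counts, [0]])
    modes = []
    for i in range(len(counts)):
        c = padded[i + 1]
        if c > padded[i] and c > padded[i + 2] and c >= min_mass * len(values):
            modes.append((c, (edges[i] + edges[i + 1]) / 2))
    modes.sort(key=lambda t: -t[0])
    return [m for _, m in modes]


@dataclass
class DatingParams:
    """Molecular clock: synonymous substitutions per site per year."""

    r: float = 6.1e-9

    def __post_init__(self) -> None:
        if self.r <= 0:
            raise ValueError("rate r must be positive")


def divergence_time(ks: float, params: DatingParams | None = None) -> float:
    """Years since divergence under T = Ks / (2 r)."""
    if ks < 0:
        raise ValueError("Ks must be non-negative")
    params = params or DatingParams()
    return ks / (2 * params.r)


def format_years_thousand(years: float) -> int:
    """Nearest thousand years (e.g. 8196.7 -> 8000)."""
    return int(round(years / 1000) * 1000)


def format_million_years(years: float) -> float:
    """Million years at 2 decimals (e.g. 163934 -> 0.16)."""
    return round(years / 1e6, 2)
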