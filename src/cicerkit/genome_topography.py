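"""Sliding-window genome tracks, recombination rate, pericentromere calls.

Tracks use a 1 Mb window advanced every 200 kb by default. The
pericentromeric core of a chromosome is the region that is simultaneously
repeat-rich, gene-poor and recombination-suppressed; it is delineated by
thresholding smoothed window tracks at the midpoint of their interquartile
range and taking the longest contiguous run of flagged windows.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .io_core import GeneModel, MarkerRecord, RepeatFeature

logger = logging.getLogger(__name__)

WINDOW_BP = 1_000_000
STEP_BP = 200_000


@dataclass
class WindowTrack:
    seq_id: str
    windows: list[tuple[int, int, float]]  # (start, end, value)
    window_bp: int
    step_bp: int

    def values(self) -> np.ndarray:
        return np.array([w[2] for w in self.windows], dtype=float)

    def starts(self) -> np.ndarray:
        return np.array([w[0] for w in self.windows], dtype=int)

    def centers(self) -> np.ndarray:
        return np.array([(w[0] + w[1]) // 2 for w in self.windows], dtype=int)


@dataclass
class PericentromereParams:
    smooth_windows: int = 3  # centered moving-mean width (windows)
    bridge_windows: int = 2  # unflagged gaps bridged within a run
    min_contrast: float = 0.25  # relative IQR below which no core is called
    trim_steps: int = 1  # steps trimmed per side before measuring rates


@dataclass
class PericentromereCall:
    linkage_group: str
    core: tuple[int, int] | None
    arm_recomb_kb_per_cm: float | None
    core_recomb_kb_per_cm: float | None
    arm_gene_density: float | None  # genes per 100 kb
    core_gene_density: float | None


def make_windows(
    seq_length: int, window_bp: int = WINDOW_BP, step_bp: int = STEP_BP
) -> list[tuple[int, int]]:
    """Sliding windows starting at 1, 1+step, ...; clipped to the sequence."""
    if seq_length < 1:
        raise ValueError("seq_length must be >= 1")
    if not 1 <= step_bp <= window_bp:
        raise ValueError("require window_bp >= step_bp >= 1")
    windows = []
    start = 1
    while start <= seq_length:
        windows.append((start, min(start + window_bp - 1, seq_length)))
        start += step_bp
    return windows


def window_density(
    features: list[tuple[int, int]],
    windows: list[tuple[int, int]],
    mode: str,
    seq_id: str = "",
    window_bp: int | None = None,
    step_bp: int | None = None,
) -> WindowTrack:
    """Per-window feature density.

    mode="count": number of features whose midpoint lies in the window.
    mode="covered_fraction": overlapping bp / window length.
    """
    if mode not in {"count", "covered_fraction"}:
        raise ValueError(f"unknown mode {mode!r}")
    if window_bp is None:
        window_bp = max((e - s + 1 for s, e in windows), default=WINDOW_BP)
    if step_bp is None:
        step_bp = (
            windows[1][0] - windows[0][0] if len(windows) > 1 else window_bp
        )
    vals = []
    if mode == "count":
        mids = np.sort(np.array([(s + e) // 2 for s, e in features], dtype=int))
        for ws, we in windows:
            vals.append(
                float(
                    np.searchsorted(mids, we, "right")
                    - np.searchsorted(mids, ws, "left")
                )
            )
    else:
        ivs = sorted(features)
        starts = np.array([s for s, _ in ivs], dtype=int)
        ends = np.array([e for _, e in ivs], dtype=int)
        for ws, we in windows:
            ov = np.minimum(ends, we) - np.maximum(starts, ws) + 1
            vals.append(float(ov[ov > 0].sum()) / (we - ws + 1))
    return WindowTrack(
        seq_id,
        [(s, e, v) for (s, e), v in zip(windows, vals)],
        window_bp,
        step_bp,
    )


def gene_intervals(
    models: list[GeneModel], seq_id: str
) -> list[tuple[int, int]]:
    return [m.span for m in models if m.seq_id == seq_id]


def repeat_intervals(
    repeats: list[RepeatFeature], seq_id: str
) -> list[tuple[int, int]]:
    return [r.interval for r in repeats if r.seq_id == seq_id]


def recomb_rate(
    markers: list[MarkerRecord], interval: tuple[int, int]
) -> float | None:
    """kb of physical span per cM of genetic span between the outermost
    markers inside the interval; None (with a warning) when fewer than two
    markers fall inside or the genetic span is zero."""
    inside = sorted(
        (m for m in markers if interval[0] <= m.bp <= interval[1]),
        key=lambda m: m.bp,
    )
    if len(inside) < 2:
        logger.warning("recomb_rate: <2 markers in %s", interval)
        return None
    bp_span = inside[-1].bp - inside[0].bp
    cm_span = abs(inside[-1].cm - inside[0].cm)
    if cm_span == 0:
        logger.warning("recomb_rate: zero genetic span in %s", interval)
        return None
    return (bp_span / 1000) / cm_span


def region_gene_density(
    models: list[GeneModel], interval: tuple[int, int]
) -> float:
    """Genes (by midpoint) per 100 kb of the interval."""
    length = interval[1] - interval[0] + 1
    if length <= 0:
        raise ValueError("zero-length interval")
    n = sum(1 for m in models if interval[0] <= m.midpoint <= interval[1])
    return n / length * 1e5


def marey_cm(markers: list[MarkerRecord]):
    """Monotone piecewise-linear genetic position (cM) as a function of bp.

    Returns a vectorized callable; NaN outside the span of the marker map.
    """
    srt = sorted(markers, key=lambda m: m.bp)
    bp = np.array([m.bp for m in srt], dtype=float)
    cm = np.maximum.accumulate(np.array([m.cm for m in srt], dtype=float))

    def f(x):
        x = np.asarray(x, dtype=float)
        y = np.interp(x, bp, cm)
        y = np.where((x < bp[0]) | (x > bp[-1]), np.nan, y)
        return y

    return f


def windowed_genetic_length(
    markers: list[MarkerRecord], windows: list[tuple[int, int]], seq_id: str = ""
) -> WindowTrack:
    """cM spanned by each window under the Marey interpolation (NaN outside
    the marker span). Low values mean recombination suppression."""
    if len(markers) < 2:
        raise ValueError("need >=2 markers for a Marey map")
    f = marey_cm(markers)
    starts = np.array([s for s, _ in windows], dtype=float)
    ends = np.array([e for _, e in windows], dtype=float)
    span = f(ends) - f(starts)
    wb = max(e - s + 1 for s, e in windows)
    sb = windows[1][0] - windows[0][0] if len(windows) > 1 else wb
    return WindowTrack(
        seq_id,
        [(int(s), int(e), float(v)) for s, e, v in zip(starts, ends, span)],
        wb,
        sb,
    )


def _smooth(values: np.ndarray, width: int) -> np.ndarray:
    if width <= 1:
        return values.astype(float)
    half = width // 2
    out = np.empty(len(values), dtype=float)
    for i in range(len(values)):
        seg = values[max(0, i - half) : i + half + 1]
        out[i] = np.nanmean(seg) if np.isfinite(seg).any() else np.nan
    return out


def _midpoint_threshold(values: np.ndarray, min_contrast: float):
    """(threshold, has_contrast): midpoint of the interquartile range, and
    whether the track shows enough arm/core contrast to segment at all."""
    finite = values[np.isfinite(values)]
    if len(finite) == 0:
        return np.nan, False
    p25, p75 = np.percentile(finite, [25, 75])
    mid = (p25 + p75) / 2
    contrast = (p75 - p25) > min_contrast * max(abs(mid), 1e-12)
    return mid, contrast


def _longest_run(flags: np.ndarray, bridge: int) -> tuple[int, int] | None:
    """Longest contiguous flagged run after bridging gaps <= ``bridge``."""
    idx = np.flatnonzero(flags)
    if len(idx) == 0:
        return None
    runs = []
    start = prev = idx[0]
    for i in idx[1:]:
        if i - prev <= bridge + 1:
            prev = i
        else:
            runs.append((start, prev))
            start = prev = i
    runs.append((start, prev))
    return max(runs, key=lambda r: r[1] - r[0])


def call_pericentromere(
    gene_track: WindowTrack,
    repeat_track: WindowTrack,
    markers: list[MarkerRecord],
    params: PericentromereParams | None = None,
) -> PericentromereCall:
    """Delineate the pericentromeric core of one chromosome.

    A window is flagged when, after centered smoothing, its repeat coverage
    is above, and both its gene count and its genetic length (cM spanned,
    from a monotone Marey interpolation of the marker map) are below, the
    midpoint of the track's interquartile range. The core is the longest
    contiguous flagged run (gaps up to ``bridge_windows`` bridged), reported
    from the center of its first to the center of its last window — the
    transition point where a window half-overlaps the core. If any track
    lacks arm/core contrast (relative IQR below ``min_contrast``) no core is
    called. Per-region recombination and gene density are measured on the
    core trimmed by ``trim_steps`` window steps per side, so that genetic
    distance accumulated in leaked arm sequence does not distort the core
    rate.
    """
    params = params or PericentromereParams()
    lg = gene_track.seq_id or repeat_track.seq_id
    n = len(gene_track.windows)
    if n != len(repeat_track.windows):
        raise ValueError("gene and repeat tracks must share the window grid")
    windows = [(s, e) for s, e, _ in gene_track.windows]
    chrom_len = windows[-1][1]

    cm_track = windowed_genetic_length(markers, windows, lg)
    genes = _smooth(gene_track.values(), params.smooth_windows)
    cov = _smooth(repeat_track.values(), params.smooth_windows)
    cm = _smooth(cm_track.values(), params.smooth_windows)

    thr_gene, ok_gene = _midpoint_threshold(genes, params.min_contrast)
    thr_cov, ok_cov = _midpoint_threshold(cov, params.min_contrast)
    thr_cm, ok_cm = _midpoint_threshold(cm, params.min_contrast)

    empty = PericentromereCall(lg, None, None, None, None, None)
    if not (ok_gene and ok_cov and ok_cm):
        logger.warning(
            "%s: no arm/core contrast in one or more tracks; empty core", lg
        )
        return empty

    with np.errstate(invalid="ignore"):
        flags = (cov > thr_cov) & (genes < thr_gene) & (cm < thr_cm)
    flags &= np.isfinite(cm)
    run = _longest_run(flags, params.bridge_windows)
    if run is None:
        logger.warning("%s: no window met all pericentromere criteria", lg)
        return empty

    centers = gene_track.centers()
    core = (max(1, int(centers[run[0]])), min(chrom_len, int(centers[run[1]])))

    trim = params.trim_steps * gene_track.step_bp
    inner = (core[0] + trim, core[1] - trim)
    if inner[0] >= inner[1]:
        inner = core
    core_rate = recomb_rate(markers, inner)
    arm_ivals = []
    if core[0] - trim > 1:
        arm_ivals.append((1, core[0] - trim))
    if core[1] + trim < chrom_len:
        arm_ivals.append((core[1] + trim, chrom_len))
    arm_rates = [r for r in (recomb_rate(markers, iv) for iv in arm_ivals) if r]
    arm_rate = float(np.mean(arm_rates)) if arm_rates else None

    core_density = _track_density(gene_track, inner)
    arm_density_vals = [
        d for d in (_track_density(gene_track, iv) for iv in arm_ivals)
        if d is not None
    ]
    arm_density = float(np.mean(arm_density_vals)) if arm_density_vals else None
    return PericentromereCall(
        linkage_group=lg,
        core=core,
        arm_recomb_kb_per_cm=arm_rate,
        core_recomb_kb_per_cm=core_rate,
        arm_gene_density=arm_density,
        core_gene_density=core_density,
    )


def _track_density(track: WindowTrack, interval: tuple[int, int]) -> float | None:
    """Mean gene count per 100 kb over windows fully inside the interval."""
    vals = [
        v / (e - s + 1) * 1e5
        for s, e, v in track.windows
        if s >= interval[0] and e <= interval[1]
    ]
    return float(np.mean(vals)) if vals else None
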