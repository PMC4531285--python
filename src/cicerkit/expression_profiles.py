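"""RPM normalization and tissue-specificity / tissue-preference calls.

RPM = uniquely mapped reads per million total reads. A gene is
tissue-specific when it has nonzero RPM in exactly one tissue, and
tissue-preferential in a tissue when its RPM there is at least ``fold``
times (default 3, inclusive) its RPM in every other tissue. Specific genes
are therefore always also preferential.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_core import ExpressionMatrix


@dataclass
class ExpressionCall:
    gene_id: str
    call: str  # "specific" | "preferential" | "none"
    tissue: str | None = None
    fold_margin: float | None = None  # None when all other tissues are zero


def rpm(matrix: ExpressionMatrix) -> pd.DataFrame:
    """counts / library_size * 1e6, as a gene x tissue DataFrame."""
    zero = np.flatnonzero(matrix.library_sizes == 0)
    if len(zero):
        raise ValueError(
            f"zero library size for tissue {matrix.tissue_ids[zero[0]]!r}"
        )
    values = matrix.counts / matrix.library_sizes[None, :] * 1e6
    return pd.DataFrame(values, index=matrix.gene_ids, columns=matrix.tissue_ids)


def fold_normalize(values) -> np.ndarray | pd.DataFrame:
    """Divide by the maximum so the highest value per gene becomes 1.

    Accepts a 1-D row or a gene x tissue DataFrame (row-wise). All-zero rows
    stay all-zero.
    """
    if isinstance(values, pd.DataFrame):
        mx = values.max(axis=1).replace(0, 1)
        return values.div(mx, axis=0)
    row = np.asarray(values, dtype=float)
    if (row < 0).any():
        raise ValueError("fold_normalize requires non-negative values")
    mx = row.max()
    return row / mx if mx > 0 else row


def tissue_specific(matrix: ExpressionMatrix) -> list[ExpressionCall]:
    """Genes with nonzero RPM in exactly one tissue."""
    if len(matrix.tissue_ids) < 2:
        raise ValueError("need at least 2 tissues")
    table = rpm(matrix)
    nz = (table.to_numpy() > 0).sum(axis=1)
    calls = []
    for i in np.flatnonzero(nz == 1):
        t = int(np.argmax(table.iloc[i].to_numpy()))
        calls.append(
            ExpressionCall(
                gene_id=matrix.gene_ids[i],
                call="specific",
                tissue=matrix.tissue_ids[t],
                fold_margin=None,
            )
        )
    return calls


def tissue_preferential(
    matrix: ExpressionMatrix, fold: float = 3.0
) -> list[ExpressionCall]:
    """Genes whose RPM in one tissue is >= fold x RPM in every other tissue.

    "At least" makes the boundary inclusive: (9, 3, 3, 3) qualifies at
    fold 3. Comparisons against zero tissues are satisfied; the fold margin
    is reported as None when every other tissue is zero (the gene is then
    also tissue-specific).
    """
    if fold <= 1:
        raise ValueError("fold must be > 1")
    table = rpm(matrix).to_numpy()
    calls = []
    for i, gene_id in enumerate(matrix.gene_ids):
        row = table[i]
        t = int(np.argmax(row))
        top = row[t]
        if top <= 0:
            continue
        others = np.delete(row, t)
        if np.all(top >= fold * others):
            max_other = others.max()
            calls.append(
                ExpressionCall(
                    gene_id=gene_id,
                    call="preferential",
                    tissue=matrix.tissue_ids[t],
                    fold_margin=float(top / max_other) if max_other > 0 else None,
                )
            )
    return calls


def paralog_divergence(
    pairs: list[tuple[str, str]],
    matrix: ExpressionMatrix,
    fold: float = 3.0,
) -> pd.DataFrame:
    """Per-pair expression divergence of paralogous genes.

    A pair is flagged diverged when the two RPM values differ by >= ``fold``
    in either direction in at least one tissue (zero vs positive counts as
    divergence; zero vs zero does not). The Pearson correlation of the RPM
    profiles is reported alongside but does not enter the flag.
    """
    table = rpm(matrix)
    index = {g: i for i, g in enumerate(matrix.gene_ids)}
    rows = []
    for a, b in pairs:
        for g in (a, b):
            if g not in index:
                raise KeyError(f"gene {g!r} not in expression matrix")
        ra = table.iloc[index[a]].to_numpy()
        rb = table.iloc[index[b]].to_numpy()
        diverged = False
        fold_diffs = []
        for x, y in zip(ra, rb):
            lo, hi = min(x, y), max(x, y)
            if hi == 0:
                fold_diffs.append(1.0)
                continue
            ratio = np.inf if lo == 0 else hi / lo
            fold_diffs.append(float(ratio))
            if ratio >= fold:
                diverged = True
        if np.std(ra) > 0 and np.std(rb) > 0:
            r = float(np.corrcoef(ra, rb)[0, 1])
        else:
            r = np.nan
        rows.append(
            {
                "gene_a": a,
                "gene_b": b,
                **{
                    f"fold_diff_{t}": d
                    for t, d in zip(matrix.tissue_ids, fold_diffs)
                },
                "pearson_r": r,
                "diverged": diverged,
            }
        )
    return pd.DataFrame(rows)
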