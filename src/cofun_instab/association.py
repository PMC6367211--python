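"""Rank genes by association between expression and genomic instability.

Per gene, a rank correlation (Spearman by default, Pearson behind a
switch) is computed between the gene's expression vector and the
per-sample instability score, Fisher-transformed into a standardized
z statistic, and genes are densely ranked by descending z.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .io_formats import ExpressionMatrix, InstabilityScores

logger = logging.getLogger(__name__)

ASSOCIATION_COLUMNS = ["gene_id", "rho", "z", "rank", "degenerate"]


def _align(expr: ExpressionMatrix, inst: InstabilityScores):
    """Intersect samples by ID, preserving the expression matrix order."""
    score_by_id = dict(zip(inst.sample_ids, inst.score))
    shared = [s for s in expr.sample_ids if s in score_by_id]
    if len(shared) < 3:
        raise ValueError(
            f"only {len(shared)} shared samples between expression matrix "
            "and instability scores; need at least 3"
        )
    cols = [expr.sample_ids.index(s) for s in shared]
    values = expr.values[:, cols]
    score = np.array([score_by_id[s] for s in shared], dtype=np.float64)
    if np.all(score == score[0]):
        raise ValueError("instability scores constant over shared samples")
    return values, score, shared


def _rowwise_corr(values: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Pearson correlation of every row of ``values`` with ``y``.

    Rows with zero variance get coefficient 0 and are flagged.
    """
    xc = values - values.mean(axis=1, keepdims=True)
    yc = y - y.mean()
    sx = np.sqrt((xc * xc).sum(axis=1))
    sy = np.sqrt(yc @ yc)
    degenerate = sx == 0.0
    denom = np.where(degenerate, 1.0, sx * sy)
    rho = (xc @ yc) / denom
    rho[degenerate] = 0.0
    return np.clip(rho, -1.0, 1.0), degenerate


def associate(
    expr: ExpressionMatrix,
    inst: InstabilityScores,
    method: str = "spearman",
) -> pd.DataFrame:
    """Transcriptome-wide association of expression with instability.

    Returns a DataFrame with columns ``gene_id, rho, z, rank, degenerate``:
    ``rho`` is the per-gene correlation with the instability score over
    the shared samples, ``z = atanh(rho) * sqrt(m - 3)`` (Fisher
    transform, m shared samples), and ``rank`` a dense 1..G rank by
    descending z with (rho, gene_id) tie-breaking.  Genes with constant
    expression are retained with rho = z = 0 and flagged degenerate.
    """
    if method not in ("spearman", "pearson"):
        raise ValueError(f"unknown correlation method {method!r}")
    values, score, shared = _align(expr, inst)
    m = len(shared)
    if method == "spearman":
        values = rankdata(values, axis=1)
        score = rankdata(score)
    rho, degenerate = _rowwise_corr(values, score)
    with np.errstate(divide="ignore"):
        z = np.arctanh(rho) * np.sqrt(m - 3) if m > 3 else np.zeros_like(rho)
    z[degenerate] = 0.0
    n_deg = int(degenerate.sum())
    if n_deg:
        logger.warning("%d genes with constant expression flagged degenerate", n_deg)

    table = pd.DataFrame(
        {
            "gene_id": expr.gene_ids,
            "rho": rho,
            "z": z,
            "degenerate": degenerate,
        }
    )
    order = table.sort_values(
        ["z", "rho", "gene_id"],
        ascending=[False, False, True],
        kind="mergesort",
    ).index
    rank = np.empty(len(table), dtype=np.int64)
    rank[order] = np.arange(1, len(table) + 1)
    table["rank"] = rank
    table.attrs["n_shared_samples"] = m
    table.attrs["method"] = method
    return table[ASSOCIATION_COLUMNS]


def select_top(
    table: pd.DataFrame, n: int = 250, direction: str = "positive"
) -> list[str]:
    """Top-``n`` genes by descending z (``direction='positive'``) or
    ascending z (``'negative'``); boundary ties broken by higher rho then
    lexicographic gene ID."""
    if n <= 0:
        raise ValueError("n must be positive")
    if n > len(table):
        raise ValueError(f"n={n} exceeds gene count {len(table)}")
    if direction not in ("positive", "negative"):
        raise ValueError(f"unknown direction {direction!r}")
    asc = direction == "negative"
    ordered = table.sort_values(
        ["z", "rho", "gene_id"],
        ascending=[asc, asc, True],
        kind="mergesort",
    )
    return list(ordered["gene_id"].iloc[:n])


def write_association_tsv(table: pd.DataFrame, path) -> None:
    from .io_formats import _FLOAT_FMT, _header_line

    with open(path, "w", encoding="utf-8") as fh:
        fh.write(
            _header_line(
                artifact="association",
                method=table.attrs.get("method", "spearman"),
                n_shared_samples=table.attrs.get("n_shared_samples", "?"),
                z="atanh(rho)*sqrt(m-3)",
            )
            + "\n"
        )
        fh.write("\t".join(ASSOCIATION_COLUMNS) + "\n")
        for row in table.itertuples(index=False):
            fh.write(
                f"{row.gene_id}\t{_FLOAT_FMT.format(row.rho)}\t"
                f"{_FLOAT_FMT.format(row.z)}\t{row.rank}\t{int(row.degenerate)}\n"
            )


def read_association_tsv(path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t", comment="#", dtype={"gene_id": str},
                        float_precision="round_trip")
    if list(table.columns) != ASSOCIATION_COLUMNS:
        raise ValueError(f"expected columns {ASSOCIATION_COLUMNS}")
    table["degenerate"] = table["degenerate"].astype(bool)
    return table
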