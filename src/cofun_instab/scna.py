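"""Focal vs whole-chromosome copy-number aberration counting per cell.

Deviations are called against the per-bin modal state of a control
population.  Within each chromosome, maximal runs of contiguous
deviating bins (split where the deviation changes sign) are events: a
uniform-direction run covering at least ``whole_chrom_fraction`` of the
chromosome's bins is one whole-chromosome event, every other run is one
focal event.  Deviation magnitude is ignored for counting.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import kruskal, norm, rankdata

from .io_formats import CNProfileSet

logger = logging.getLogger(__name__)

DEFAULT_WHOLE_CHROM_FRACTION = 0.9

COUNT_METRICS = ("n_focal", "n_whole_chromosome", "total")


@dataclass
class ModalProfile:
    """Per-bin modal copy-number state across control cells."""

    chroms: np.ndarray
    starts: np.ndarray
    ends: np.ndarray
    modal_state: np.ndarray  # int64 per bin

    def __post_init__(self) -> None:
        self.modal_state = np.asarray(self.modal_state, dtype=np.int64)
        if self.modal_state.shape != (len(self.chroms),):
            raise ValueError("modal_state must have one entry per bin")
        if (self.modal_state < 0).any():
            raise ValueError("negative modal state")


@dataclass
class Aberration:
    """One deviation event of a single cell."""

    chrom: str
    start_bin: int  # index within the chromosome's bins
    end_bin: int  # exclusive
    kind: str  # 'focal' | 'whole_chromosome'
    direction: int  # +1 gain, -1 loss


@dataclass
class GroupComparison:
    """Per-condition summaries plus omnibus and pairwise rank tests."""

    metric: str
    group_stats: pd.DataFrame  # condition, n, median, q1, q3
    kw_statistic: float
    kw_pvalue: float
    pairwise: pd.DataFrame  # condition_a, condition_b, z, p_raw, p_adj
    excluded: list[str]


def _same_grid(profiles: CNProfileSet, modal: ModalProfile) -> None:
    if (
        len(modal.chroms) != profiles.n_bins
        or not np.array_equal(modal.chroms, profiles.chroms)
        or not np.array_equal(modal.starts, profiles.starts)
        or not np.array_equal(modal.ends, profiles.ends)
    ):
        raise ValueError("bin grids of profiles and modal profile differ")


def modal_profile(profiles: CNProfileSet, control_condition: str) -> ModalProfile:
    """Per-bin mode of copy-number state across control cells.

    Ties are broken toward the state nearest the genome-wide control
    median, then toward the lower state.
    """
    ctrl = profiles.cells_of(control_condition)
    if len(ctrl) == 0:
        raise ValueError(f"no cells with control condition {control_condition!r}")
    if len(ctrl) < 3:
        raise ValueError(
            f"need >= 3 control cells, got {len(ctrl)} for {control_condition!r}"
        )
    states = profiles.states[ctrl]
    genome_median = float(np.median(states))
    modal = np.empty(profiles.n_bins, dtype=np.int64)
    n_tied = 0
    for j in range(profiles.n_bins):
        col = states[:, j]
        vals, counts = np.unique(col, return_counts=True)
        tied = vals[counts == counts.max()]
        if len(tied) > 1:
            n_tied += 1
        # nearest to genome-wide median, then lower state
        modal[j] = min(tied, key=lambda s: (abs(s - genome_median), s))
    if n_tied:
        logger.info(
            "modal state ties at %d bins broken toward genome-wide median %.1f "
            "then lower state", n_tied, genome_median,
        )
    return ModalProfile(
        profiles.chroms.copy(), profiles.starts.copy(), profiles.ends.copy(), modal
    )


def classify_deviations(
    cell_states: np.ndarray,
    modal: ModalProfile,
    whole_chrom_fraction: float = DEFAULT_WHOLE_CHROM_FRACTION,
) -> list[Aberration]:
    """Classify one cell's deviations from the modal profile into events.

    Runs of contiguous deviating bins are found per chromosome and split
    where the deviation direction (sign of state - modal) changes; a
    uniform-direction run covering >= ``whole_chrom_fraction`` of the
    chromosome's bins is a whole-chromosome event, otherwise focal.
    """
    cell_states = np.asarray(cell_states)
    if cell_states.shape != modal.modal_state.shape:
        raise ValueError("cell state vector does not match modal bin grid")
    if not (0.0 < whole_chrom_fraction <= 1.0):
        raise ValueError("whole_chrom_fraction must be in (0, 1]")
    events: list[Aberration] = []
    delta = cell_states.astype(np.int64) - modal.modal_state
    for chrom in dict.fromkeys(modal.chroms):
        idx = np.flatnonzero(modal.chroms == chrom)
        d = delta[idx]
        sign = np.sign(d)
        n = len(d)
        j = 0
        while j < n:
            if sign[j] == 0:
                j += 1
                continue
            k = j
            while k < n and sign[k] == sign[j]:
                k += 1
            length = k - j
            kind = (
                "whole_chromosome"
                if length >= whole_chrom_fraction * n
                else "focal"
            )
            events.append(Aberration(str(chrom), j, k, kind, int(sign[j])))
            j = k
    return events


def count_aberrations(
    profiles: CNProfileSet,
    modal: ModalProfile,
    whole_chrom_fraction: float = DEFAULT_WHOLE_CHROM_FRACTION,
) -> pd.DataFrame:
    """Per-cell focal and whole-chromosome event counts.

    Returns a DataFrame with columns ``cell_id, condition, n_focal,
    n_whole_chromosome`` (one row per input cell, input order).
    """
    _same_grid(profiles, modal)
    rows = []
    for i, (cell, cond) in enumerate(zip(profiles.cell_ids, profiles.conditions)):
        events = classify_deviations(
            profiles.states[i], modal, whole_chrom_fraction
        )
        n_focal = sum(1 for e in events if e.kind == "focal")
        n_whole = sum(1 for e in events if e.kind == "whole_chromosome")
        rows.append((cell, cond, n_focal, n_whole))
    return pd.DataFrame(
        rows, columns=["cell_id", "condition", "n_focal", "n_whole_chromosome"]
    )


def _dunn_pairwise(
    groups: list[np.ndarray], names: list[str], adjust: str
) -> pd.DataFrame:
    """Dunn's post-hoc z tests on pooled ranks with tie correction."""
    pooled = np.concatenate(groups)
    n_total = len(pooled)
    ranks = rankdata(pooled)
    # tie correction term: sum(t^3 - t) / (12 (N - 1))
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(((counts**3 - counts).sum()) / (12.0 * (n_total - 1)))
    mean_ranks = []
    offset = 0
    for g in groups:
        mean_ranks.append(float(ranks[offset : offset + len(g)].mean()))
        offset += len(g)
    base_var = n_total * (n_total + 1) / 12.0 - tie_term
    n_pairs = len(groups) * (len(groups) - 1) // 2
    rows = []
    for a in range(len(groups)):
        for b in range(a + 1, len(groups)):
            se = np.sqrt(base_var * (1.0 / len(groups[a]) + 1.0 / len(groups[b])))
            z = (mean_ranks[a] - mean_ranks[b]) / se if se > 0 else 0.0
            p_raw = float(2.0 * norm.sf(abs(z)))
            if adjust == "bonferroni":
                p_adj = min(1.0, p_raw * n_pairs)
            elif adjust == "none":
                p_adj = p_raw
            else:
                raise ValueError(f"unknown adjustment {adjust!r}")
            rows.append((names[a], names[b], float(z), p_raw, p_adj))
    return pd.DataFrame(
        rows, columns=["condition_a", "condition_b", "z", "p_raw", "p_adj"]
    )


def compare_groups(
    counts: pd.DataFrame,
    metric: str = "n_focal",
    adjust: str = "bonferroni",
    min_cells: int = 3,
) -> GroupComparison:
    """Kruskal-Wallis omnibus test across conditions with Dunn post hocs.

    ``metric`` is one of ``n_focal``, ``n_whole_chromosome`` or
    ``total`` (their sum).  Conditions with fewer than ``min_cells``
    cells are excluded with a warning; fewer than 2 remaining is a hard
    error.  Medians and interquartile ranges are reported per condition.
    """
    if metric not in COUNT_METRICS:
        raise ValueError(f"unknown metric {metric!r}; choose from {COUNT_METRICS}")
    df = counts.copy()
    if metric == "total":
        df["total"] = df["n_focal"] + df["n_whole_chromosome"]
    sizes = df.groupby("condition", sort=False).size()
    excluded = [c for c, n in sizes.items() if n < min_cells]
    if excluded:
        warnings.warn(
            f"conditions excluded with < {min_cells} cells: {excluded}",
            stacklevel=2,
        )
        df = df[~df["condition"].isin(excluded)]
    names = list(dict.fromkeys(df["condition"]))
    if len(names) < 2:
        raise ValueError("need >= 2 conditions with enough cells to compare")
    groups = [
        df.loc[df["condition"] == c, metric].to_numpy(dtype=np.float64)
        for c in names
    ]

    stats_rows = []
    for name, g in zip(names, groups):
        q1, med, q3 = np.percentile(g, [25, 50, 75])
        stats_rows.append((name, len(g), float(med), float(q1), float(q3)))
    group_stats = pd.DataFrame(
        stats_rows, columns=["condition", "n", "median", "q1", "q3"]
    )

    pooled = np.concatenate(groups)
    if np.all(pooled == pooled[0]):
        kw_stat, kw_p = 0.0, 1.0
    else:
        kw_stat, kw_p = kruskal(*groups)
    pairwise = _dunn_pairwise(groups, names, adjust)
    return GroupComparison(
        metric=metric,
        group_stats=group_stats,
        kw_statistic=float(kw_stat),
        kw_pvalue=float(kw_p),
        pairwise=pairwise,
        excluded=excluded,
    )


def write_counts_tsv(counts: pd.DataFrame, path) -> None:
    from .io_formats import _header_line

    with open(path, "w", encoding="utf-8") as fh:
        fh.write(_header_line(artifact="aberration_counts") + "\n")
        counts.to_csv(fh, sep="\t", index=False)


def comparison_to_dict(cmp: GroupComparison) -> dict:
    """JSON-serializable view of a GroupComparison."""
    return {
        "metric": cmp.metric,
        "kruskal_wallis": {"statistic": cmp.kw_statistic, "pvalue": cmp.kw_pvalue},
        "groups": cmp.group_stats.to_dict(orient="records"),
        "pairwise": cmp.pairwise.to_dict(orient="records"),
        "excluded_conditions": cmp.excluded,
    }
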