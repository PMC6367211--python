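"""Readers and writers for every on-disk artifact of the pipeline.

All downstream modules consume only the domain types defined here:
:class:`ExpressionMatrix`, :class:`InstabilityScores`,
:class:`GeneSetCollection` and :class:`CNProfileSet`.

Conventions
-----------
* All files are UTF-8, tab-delimited, '.' decimal.
* Genomic coordinates are 0-based half-open (BED convention) everywhere.
  Some upstream copy-number callers emit 1-based starts; pass
  ``one_based=True`` to :func:`read_cn_calls` to shift starts by -1.
* Gene identifiers are matched exactly (case-sensitive); no aliasing.
* Every writer emits a leading ``#`` header line recording the tool
  version and the parameters used; every reader skips ``#`` lines.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence, TYPE_CHECKING

import numpy as np
import pandas as pd

from . import __version__

if TYPE_CHECKING:  # pragma: no cover
    from .cofunctionality import CoFunctionalityNetwork

logger = logging.getLogger(__name__)

_MISSING_TOKENS = {"", "NA", "NaN", "nan", "NAN", "N/A", "null", "None"}

#: printf format that round-trips IEEE-754 doubles exactly
_FLOAT_FMT = "{:.17g}"


def _header_line(**params) -> str:
    items = " ".join(f"{k}={v}" for k, v in params.items())
    return f"# cofun-instab v{__version__} {items}".rstrip()


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class ExpressionMatrix:
    """Genes x samples real-valued (residual) expression.

    Invariants: unique gene and sample IDs, no missing values,
    at least 3 samples.
    """

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray  # float64, shape (genes, samples)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("duplicate gene IDs")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample IDs")
        if len(self.sample_ids) < 3:
            raise ValueError(
                f"need at least 3 samples, got {len(self.sample_ids)}"
            )
        if np.isnan(self.values).any():
            raise ValueError("missing values in expression matrix")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def gene_index(self) -> dict[str, int]:
        return {g: i for i, g in enumerate(self.gene_ids)}


@dataclass
class InstabilityScores:
    """Per-sample degree of genomic instability (SCNA burden proxy)."""

    sample_ids: list[str]
    score: np.ndarray  # float64, shape (samples,)

    def __post_init__(self) -> None:
        self.score = np.asarray(self.score, dtype=np.float64)
        if self.score.shape != (len(self.sample_ids),):
            raise ValueError("score length does not match sample_ids")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample IDs")
        if np.isnan(self.score).any():
            raise ValueError("missing instability scores")
        if len(self.sample_ids) > 0 and np.all(self.score == self.score[0]):
            raise ValueError("instability scores are all equal")


@dataclass
class GeneSetCollection:
    """Named gene sets (GMT semantics): name, description, member genes."""

    set_names: list[str]
    descriptions: list[str]
    members: list[frozenset[str]]

    def __post_init__(self) -> None:
        if not (len(self.set_names) == len(self.descriptions) == len(self.members)):
            raise ValueError("set_names, descriptions and members must align")
        if len(set(self.set_names)) != len(self.set_names):
            raise ValueError("duplicate gene-set names")
        for name, mem in zip(self.set_names, self.members):
            if len(mem) == 0:
                raise ValueError(f"gene set {name!r} is empty")
        self.members = [frozenset(m) for m in self.members]

    def __len__(self) -> int:
        return len(self.set_names)

    def restrict(
        self,
        universe: Sequence[str],
        min_set_size: int = 5,
        max_set_fraction: float = 0.5,
    ) -> "GeneSetCollection":
        """Intersect each set with ``universe`` and drop degenerate sets.

        Sets smaller than ``min_set_size`` after intersection, or covering
        at least ``max_set_fraction`` of the universe, are dropped (logged).
        """
        uni = set(universe)
        max_size = max_set_fraction * len(uni)
        names, descs, mems = [], [], []
        n_small = n_large = 0
        for name, desc, mem in zip(self.set_names, self.descriptions, self.members):
            inter = frozenset(mem & uni)
            if len(inter) < min_set_size:
                n_small += 1
                continue
            if len(inter) >= max_size:
                n_large += 1
                continue
            names.append(name)
            descs.append(desc)
            mems.append(inter)
        if n_small or n_large:
            logger.warning(
                "dropped %d gene sets below min_set_size=%d and %d covering "
                ">= %.0f%% of the %d-gene universe",
                n_small, min_set_size, n_large, 100 * max_set_fraction, len(uni),
            )
        return GeneSetCollection(names, descs, mems)


@dataclass
class CNProfileSet:
    """Cells x genomic bins integer copy-number states.

    The bin grid (``chroms``/``starts``/``ends``) is shared by all cells;
    coordinates are 0-based half-open, bins sorted and non-overlapping
    within each chromosome, and every chromosome has at least 2 bins.
    """

    cell_ids: list[str]
    conditions: list[str]  # one label per cell
    chroms: np.ndarray  # object/str, shape (bins,)
    starts: np.ndarray  # int64
    ends: np.ndarray  # int64
    states: np.ndarray  # int64, shape (cells, bins)

    def __post_init__(self) -> None:
        self.chroms = np.asarray(self.chroms, dtype=object)
        self.starts = np.asarray(self.starts, dtype=np.int64)
        self.ends = np.asarray(self.ends, dtype=np.int64)
        states = np.asarray(self.states)
        if not np.issubdtype(states.dtype, np.integer):
            raise ValueError("copy-number states must be integers")
        self.states = states.astype(np.int64)
        n_bins = len(self.chroms)
        if not (len(self.starts) == len(self.ends) == n_bins):
            raise ValueError("bin coordinate arrays must align")
        if self.states.shape != (len(self.cell_ids), n_bins):
            raise ValueError(
                f"states shape {self.states.shape} does not match "
                f"{len(self.cell_ids)} cells x {n_bins} bins"
            )
        if len(self.conditions) != len(self.cell_ids):
            raise ValueError("one condition label per cell required")
        if len(set(self.cell_ids)) != len(self.cell_ids):
            raise ValueError("duplicate cell IDs")
        if (self.states < 0).any():
            raise ValueError("negative copy-number state")
        if np.any(self.ends <= self.starts):
            raise ValueError("bin end must exceed bin start (0-based half-open)")
        # per-chromosome: sorted, non-overlapping, >= 2 bins
        for chrom in self.chrom_order():
            idx = np.flatnonzero(self.chroms == chrom)
            if len(idx) < 2:
                raise ValueError(f"chromosome {chrom!r} has fewer than 2 bins")
            s, e = self.starts[idx], self.ends[idx]
            if np.any(np.diff(s) <= 0):
                raise ValueError(f"bins not sorted within chromosome {chrom!r}")
            if np.any(s[1:] < e[:-1]):
                raise ValueError(f"overlapping bins on chromosome {chrom!r}")

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    @property
    def n_bins(self) -> int:
        return len(self.chroms)

    def chrom_order(self) -> list[str]:
        """Chromosome labels in first-appearance order along the grid."""
        seen: dict[str, None] = {}
        for c in self.chroms:
            seen.setdefault(c, None)
        return list(seen)

    def chrom_bin_indices(self, chrom: str) -> np.ndarray:
        return np.flatnonzero(self.chroms == chrom)

    def cells_of(self, condition: str) -> np.ndarray:
        return np.flatnonzero(np.asarray(self.conditions, dtype=object) == condition)


# ---------------------------------------------------------------------------
# Expression / instability readers & writers
# ---------------------------------------------------------------------------


def read_expression_tsv(path, samples_in_rows: bool = False) -> ExpressionMatrix:
    """Read a gene x sample expression TSV.

    The file has a header row of sample IDs and a first column of gene IDs
    (transposed if ``samples_in_rows``).  Duplicate gene IDs collapse to
    the row with the highest variance (logged); rows with any missing
    value are dropped (logged); an unparseable numeric cell is a hard
    error naming its row and column.
    """
    raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str, comment="#")
    if samples_in_rows:
        raw = raw.T
    gene_ids = [str(g) for g in raw.index]
    sample_ids = [str(s) for s in raw.columns]

    values = np.empty(raw.shape, dtype=np.float64)
    for j, col in enumerate(raw.columns):
        col_raw = raw[col].fillna("").str.strip()
        missing = col_raw.isin(_MISSING_TOKENS)
        # pd.to_numeric is not correctly rounded; numpy's parser is
        try:
            parsed = col_raw.where(~missing, "nan").to_numpy(dtype=np.float64)
        except ValueError:
            for gene, cell, miss in zip(raw.index, col_raw, missing):
                if miss:
                    continue
                try:
                    float(cell)
                except ValueError:
                    raise ValueError(
                        f"unparseable numeric value {cell!r} at gene {gene!r}, "
                        f"sample {col!r} in {path}"
                    ) from None
            raise
        values[:, j] = parsed

    if len(sample_ids) < 3:
        raise ValueError(f"need at least 3 samples, got {len(sample_ids)}")

    # collapse duplicate gene rows to the highest-variance row
    order: dict[str, int] = {}
    dupes = 0
    for i, g in enumerate(gene_ids):
        if g in order:
            dupes += 1
            old = order[g]
            if np.nanvar(values[i]) > np.nanvar(values[old]):
                order[g] = i
        else:
            order[g] = i
    if dupes:
        logger.warning("collapsed %d duplicate gene rows (kept highest variance)", dupes)
    keep = sorted(order.values())
    gene_ids = [gene_ids[i] for i in keep]
    values = values[keep]

    # drop gene rows with missing values (no imputation)
    complete = ~np.isnan(values).any(axis=1)
    if not complete.all():
        logger.warning(
            "dropped %d gene rows with missing values", int((~complete).sum())
        )
    return ExpressionMatrix(
        [g for g, ok in zip(gene_ids, complete) if ok],
        sample_ids,
        values[complete],
    )


def write_expression_tsv(expr: ExpressionMatrix, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(_header_line(artifact="expression") + "\n")
        fh.write("gene_id\t" + "\t".join(expr.sample_ids) + "\n")
        for g, row in zip(expr.gene_ids, expr.values):
            fh.write(g + "\t" + "\t".join(_FLOAT_FMT.format(v) for v in row) + "\n")


def read_instability_tsv(path) -> InstabilityScores:
    """Read a two-column TSV of sample_id, instability score."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype={0: str}, float_precision="round_trip")
    if df.shape[1] < 2:
        raise ValueError(f"expected >= 2 columns (sample_id, score) in {path}")
    sample_ids = [str(s) for s in df.iloc[:, 0]]
    score = pd.to_numeric(df.iloc[:, 1], errors="raise").to_numpy(dtype=np.float64)
    return InstabilityScores(sample_ids, score)


def write_instability_tsv(inst: InstabilityScores, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(_header_line(artifact="instability_scores") + "\n")
        fh.write("sample_id\tscore\n")
        for s, v in zip(inst.sample_ids, inst.score):
            fh.write(f"{s}\t{_FLOAT_FMT.format(v)}\n")


# ---------------------------------------------------------------------------
# GMT gene sets
# ---------------------------------------------------------------------------


def read_gmt(path) -> GeneSetCollection:
    """Read a GMT file: name TAB description TAB member genes.

    Duplicate member genes within a set are deduplicated; duplicate set
    names are a hard error; a line with fewer than 3 fields is a hard
    error naming the line number.
    """
    names: list[str] = []
    descs: list[str] = []
    members: list[frozenset[str]] = []
    seen: set[str] = set()
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"GMT line {lineno} has {len(fields)} fields (need >= 3)"
                )
            name, desc = fields[0], fields[1]
            if name in seen:
                raise ValueError(f"duplicate gene-set name {name!r} at line {lineno}")
            seen.add(name)
            genes = frozenset(g for g in fields[2:] if g)
            names.append(name)
            descs.append(desc)
            members.append(genes)
    return GeneSetCollection(names, descs, members)


def write_gmt(sets: GeneSetCollection, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for name, desc, mem in zip(sets.set_names, sets.descriptions, sets.members):
            fh.write("\t".join([name, desc, *sorted(mem)]) + "\n")


# ---------------------------------------------------------------------------
# Copy-number state calls (BED-like)
# ---------------------------------------------------------------------------

_CN_COLUMNS = ["chrom", "start", "end", "cell_id", "condition", "state"]


def read_cn_calls(path, one_based: bool = False) -> CNProfileSet:
    """Read per-cell, per-bin copy-number state calls.

    BED-like TSV columns: chromosome, start, end, cell_id, condition,
    integer state; coordinates 0-based half-open (``one_based=True``
    shifts starts by -1 for callers emitting 1-based starts).  All cells
    must share an identical bin grid; non-integer states are hard errors.
    """
    df = pd.read_csv(
        path, sep="\t", comment="#", header=None, names=_CN_COLUMNS,
        dtype={"chrom": str, "cell_id": str, "condition": str, "state": str},
    )
    if df.empty:
        raise ValueError(f"no copy-number calls in {path}")
    state_str = df["state"].str.strip()
    bad = ~state_str.str.fullmatch(r"[+-]?\d+")
    if bad.any():
        i = int(np.flatnonzero(bad.to_numpy())[0])
        raise ValueError(
            f"non-integer copy-number state {state_str.iloc[i]!r} "
            f"(data row {i + 1}) in {path}"
        )
    df["state"] = state_str.astype(np.int64)
    df["start"] = df["start"].astype(np.int64)
    df["end"] = df["end"].astype(np.int64)
    if one_based:
        df["start"] -= 1

    # condition must be unique per cell
    cond_per_cell = df.groupby("cell_id", sort=False)["condition"].nunique()
    if (cond_per_cell > 1).any():
        cell = cond_per_cell.index[cond_per_cell > 1][0]
        raise ValueError(f"cell {cell!r} carries conflicting condition labels")

    # canonical grid: chromosomes in first-appearance order, starts sorted
    chrom_order = list(dict.fromkeys(df["chrom"]))
    chrom_rank = {c: i for i, c in enumerate(chrom_order)}
    grid = (
        df[["chrom", "start", "end"]]
        .drop_duplicates()
        .assign(_cr=lambda d: d["chrom"].map(chrom_rank))
        .sort_values(["_cr", "start"], kind="mergesort")
        .drop(columns="_cr")
        .reset_index(drop=True)
    )
    n_bins = len(grid)
    bin_key = {
        (c, s, e): i
        for i, (c, s, e) in enumerate(zip(grid["chrom"], grid["start"], grid["end"]))
    }

    cell_ids = list(dict.fromkeys(df["cell_id"]))
    conditions = [
        str(df.loc[df["cell_id"] == c, "condition"].iloc[0]) for c in cell_ids
    ]
    cell_rank = {c: i for i, c in enumerate(cell_ids)}
    states = np.full((len(cell_ids), n_bins), -1, dtype=np.int64)
    rows = df["cell_id"].map(cell_rank).to_numpy()
    cols = [bin_key[(c, s, e)] for c, s, e in zip(df["chrom"], df["start"], df["end"])]
    if len(set(zip(rows, cols))) != len(df):
        raise ValueError("duplicate (cell, bin) entries")
    states[rows, cols] = df["state"].to_numpy()
    missing = states < 0
    if missing.any():
        cell = cell_ids[int(np.flatnonzero(missing.any(axis=1))[0])]
        raise ValueError(
            f"bin grids differ across cells (cell {cell!r} lacks "
            f"{int(missing.sum(axis=1).max())} bins)"
        )
    return CNProfileSet(
        cell_ids,
        conditions,
        grid["chrom"].to_numpy(dtype=object),
        grid["start"].to_numpy(dtype=np.int64),
        grid["end"].to_numpy(dtype=np.int64),
        states,
    )


def write_cn_calls(profiles: CNProfileSet, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(_header_line(artifact="cn_calls", coordinates="0-based-half-open") + "\n")
        for i, (cell, cond) in enumerate(zip(profiles.cell_ids, profiles.conditions)):
            for j in range(profiles.n_bins):
                fh.write(
                    f"{profiles.chroms[j]}\t{profiles.starts[j]}\t{profiles.ends[j]}"
                    f"\t{cell}\t{cond}\t{profiles.states[i, j]}\n"
                )


# ---------------------------------------------------------------------------
# Network edge list
# ---------------------------------------------------------------------------


def write_network_edgelist(net: "CoFunctionalityNetwork", path) -> None:
    """Write a thresholded network as a TSV edge list.

    Columns gene_a, gene_b, weight (full precision); only edges above the
    network threshold; deterministic lexicographic ordering.
    """
    rows = []
    for i, j in net.edges:
        a, b = net.gene_ids[i], net.gene_ids[j]
        if b < a:
            a, b = b, a
        rows.append((a, b, net.weights[i, j]))
    rows.sort(key=lambda r: (r[0], r[1]))
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(_header_line(artifact="cofunctionality_edges", tau=net.tau) + "\n")
        fh.write("gene_a\tgene_b\tweight\n")
        for a, b, w in rows:
            fh.write(f"{a}\t{b}\t{_FLOAT_FMT.format(w)}\n")


def read_network_edgelist(path) -> pd.DataFrame:
    """Read a network edge list back as a DataFrame (gene_a, gene_b, weight)."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"gene_a": str, "gene_b": str},
                     float_precision="round_trip")
    expected = ["gene_a", "gene_b", "weight"]
    if list(df.columns) != expected:
        raise ValueError(f"expected columns {expected}, got {list(df.columns)}")
    return df


# ---------------------------------------------------------------------------
# Small helpers used by the CLI / pipeline
# ---------------------------------------------------------------------------


def read_gene_list(path) -> list[str]:
    """One gene ID per line; '#' lines skipped; order preserved."""
    genes: list[str] = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                genes.append(line)
    return genes


def write_gene_list(genes: Iterable[str], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(_header_line(artifact="gene_list") + "\n")
        for g in genes:
            fh.write(g + "\n")
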