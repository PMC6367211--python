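"""Co-functionality network construction and cluster extraction.

The discovery route: a gene co-regulation matrix (pairwise Spearman of
expression profiles, or a precomputed symmetric matrix) is scored
against a gene-set database to give each query gene a *functional
likelihood vector* — one Spearman coefficient per gene set, measuring
how much the gene's co-regulation profile tracks the set's membership.
Correlating likelihood vectors between genes yields the
*co-functionality* weight matrix; thresholding it and taking connected
components yields gene clusters.

Notes on operationalization
---------------------------
* likelihood(g, S) is the Spearman correlation between g's co-regulation
  vector over all background genes except g and the 0/1 membership
  indicator of S over those genes (g excluded from the indicator too, to
  avoid a trivial self-correlation).
* The background universe is all genes of the co-regulation matrix, not
  just the query genes, so likelihoods are not dominated by the
  selection of the query list.
* Co-functionality correlation defaults to Pearson (likelihood vectors
  are already comparable-scale coefficients); Spearman is switchable.
* Edges require weight strictly greater than the threshold tau
  (default 0.5); clusters are connected components, not cliques.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .io_formats import ExpressionMatrix, GeneSetCollection

logger = logging.getLogger(__name__)

CORRELATION_FLAVORS = ("pearson", "spearman")

_SYM_TOL = 1e-12


def check_correlation_flavor(flavor: str) -> str:
    """Validate a correlation-flavor config value (default 'pearson')."""
    if flavor not in CORRELATION_FLAVORS:
        raise ValueError(
            f"unknown correlation flavor {flavor!r}; choose from {CORRELATION_FLAVORS}"
        )
    return flavor


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class CoRegulationMatrix:
    """Symmetric gene x gene co-regulation coefficients, diagonal 1."""

    gene_ids: list[str]
    values: np.ndarray  # float64 (G, G)
    degenerate: np.ndarray = None  # bool (G,), constant-expression genes

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        g = len(self.gene_ids)
        if self.values.shape != (g, g):
            raise ValueError("co-regulation matrix must be square over gene_ids")
        if len(set(self.gene_ids)) != g:
            raise ValueError("duplicate gene IDs")
        if np.abs(self.values - self.values.T).max(initial=0.0) > _SYM_TOL:
            raise ValueError("co-regulation matrix not symmetric")
        if not np.allclose(np.diag(self.values), 1.0, atol=0):
            raise ValueError("co-regulation diagonal must be exactly 1")
        if np.abs(self.values).max(initial=0.0) > 1.0:
            raise ValueError("co-regulation values outside [-1, 1]")
        if self.degenerate is None:
            self.degenerate = np.zeros(g, dtype=bool)

    def gene_index(self) -> dict[str, int]:
        return {g: i for i, g in enumerate(self.gene_ids)}


@dataclass
class FunctionalLikelihoodMatrix:
    """Query genes x gene sets Spearman coefficients."""

    gene_ids: list[str]
    set_names: list[str]
    values: np.ndarray  # float64 (Q, n)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != (len(self.gene_ids), len(self.set_names)):
            raise ValueError("likelihood matrix shape mismatch")
        if np.abs(self.values).max(initial=0.0) > 1.0 + 1e-12:
            raise ValueError("likelihood coefficients outside [-1, 1]")


@dataclass
class CoFunctionalityNetwork:
    """Thresholded weighted gene graph; edges are pairs with weight > tau."""

    gene_ids: list[str]
    weights: np.ndarray  # float64 (Q, Q), symmetric
    tau: float
    edges: list[tuple[int, int]] = field(init=False)

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=np.float64)
        q = len(self.gene_ids)
        if self.weights.shape != (q, q):
            raise ValueError("weight matrix must be square over gene_ids")
        if np.abs(self.weights - self.weights.T).max(initial=0.0) > _SYM_TOL:
            raise ValueError("weight matrix not symmetric")
        if not (-1.0 < self.tau <= 1.0):
            raise ValueError(f"tau must be in (-1, 1], got {self.tau}")
        iu, ju = np.triu_indices(q, k=1)
        keep = self.weights[iu, ju] > self.tau
        self.edges = list(zip(iu[keep].tolist(), ju[keep].tolist()))

    @property
    def n_edges(self) -> int:
        return len(self.edges)


@dataclass
class GeneCluster:
    """A connected component of the thresholded co-functionality network."""

    members: list[str]  # sorted gene IDs
    mean_weight: float  # mean weight over all member pairs

    @property
    def size(self) -> int:
        return len(self.members)


# ---------------------------------------------------------------------------
# Correlation helpers
# ---------------------------------------------------------------------------


def _rowwise_corr_matrix(rows: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """All-pairs Pearson correlation of the rows of ``rows``.

    Constant rows get 0 against every partner (flagged), diagonal exactly
    1, result clipped to [-1, 1] and exactly symmetric.
    """
    sd = rows.std(axis=1)
    degenerate = sd == 0.0
    centered = rows - rows.mean(axis=1, keepdims=True)
    norms = np.sqrt((centered * centered).sum(axis=1))
    safe = np.where(degenerate, 1.0, norms)
    unit = centered / safe[:, None]
    corr = unit @ unit.T
    corr[degenerate, :] = 0.0
    corr[:, degenerate] = 0.0
    corr = np.clip((corr + corr.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(corr, 1.0)
    return corr, degenerate


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------


def build_coregulation(
    expr: ExpressionMatrix, method: str = "spearman"
) -> CoRegulationMatrix:
    """Pairwise co-regulation of gene expression profiles.

    Spearman by default.  Genes with constant expression get coefficient
    0 against all partners and are flagged.
    """
    check_correlation_flavor(method)
    rows = expr.values
    if method == "spearman":
        rows = rankdata(rows, axis=1)
    corr, degenerate = _rowwise_corr_matrix(rows)
    if degenerate.any():
        logger.warning(
            "%d constant genes set to 0 co-regulation", int(degenerate.sum())
        )
    return CoRegulationMatrix(list(expr.gene_ids), corr, degenerate)


def load_coregulation(path) -> CoRegulationMatrix:
    """Load a precomputed symmetric co-regulation matrix TSV.

    Header row and first column are gene IDs (must agree in order).
    """
    df = pd.read_csv(path, sep="\t", comment="#", index_col=0, float_precision="round_trip")
    genes = [str(g) for g in df.index]
    if [str(c) for c in df.columns] != genes:
        raise ValueError("co-regulation matrix rows and columns must match")
    return CoRegulationMatrix(genes, df.to_numpy(dtype=np.float64))


def write_coregulation(coreg: CoRegulationMatrix, path) -> None:
    from .io_formats import _FLOAT_FMT, _header_line

    with open(path, "w", encoding="utf-8") as fh:
        fh.write(_header_line(artifact="coregulation") + "\n")
        fh.write("gene_id\t" + "\t".join(coreg.gene_ids) + "\n")
        for g, row in zip(coreg.gene_ids, coreg.values):
            fh.write(g + "\t" + "\t".join(_FLOAT_FMT.format(v) for v in row) + "\n")


def functional_likelihood(
    coreg: CoRegulationMatrix,
    sets: GeneSetCollection,
    query_genes: list[str],
    min_set_size: int = 5,
    max_set_fraction: float = 0.5,
) -> FunctionalLikelihoodMatrix:
    """Score each query gene against every gene set.

    likelihood(g, S) = Spearman correlation between g's co-regulation
    vector over all background genes except g and the 0/1 membership
    indicator of S over those same genes.  Sets with a constant
    indicator after intersection with the background universe are
    dropped with a warning; if all sets are dropped this is a hard
    error.

    Uses the identity Spearman(x, binary y) = Pearson(rank(x), y):
    for a binary vector, ranks are an affine function of the values,
    and Pearson is affine-invariant.
    """
    index = coreg.gene_index()
    missing = [g for g in query_genes if g not in index]
    if missing:
        raise ValueError(
            f"{len(missing)} query genes absent from co-regulation matrix "
            f"(first: {missing[0]!r})"
        )
    universe = coreg.gene_ids
    retained = sets.restrict(universe, min_set_size, max_set_fraction)
    if len(retained) == 0:
        raise ValueError("all gene sets dropped by size filters")

    g_total = len(universe)
    n_sets = len(retained)
    indicator = np.zeros((g_total, n_sets), dtype=np.float64)
    for k, mem in enumerate(retained.members):
        idx = [index[g] for g in mem]  # restrict() guarantees membership
        indicator[idx, k] = 1.0

    values = np.zeros((len(query_genes), n_sets), dtype=np.float64)
    n_bg = g_total - 1
    n_const = 0
    for qi, g in enumerate(query_genes):
        gi = index[g]
        mask = np.ones(g_total, dtype=bool)
        mask[gi] = False
        x = coreg.values[gi, mask]
        rx = rankdata(x)
        rxc = rx - rx.mean()
        ssx = rxc @ rxc
        sub = indicator[mask]
        m = sub.sum(axis=0)
        ssy = m - m * m / n_bg
        const = (ssy == 0.0) | (ssx == 0.0)
        denom = np.where(const, 1.0, np.sqrt(ssx * ssy))
        row = (rxc @ sub) / denom
        row[const] = 0.0
        n_const += int(const.sum())
        values[qi] = np.clip(row, -1.0, 1.0)
    if n_const:
        logger.warning(
            "%d (gene, set) pairs had a constant vector; coefficient set to 0",
            n_const,
        )
    return FunctionalLikelihoodMatrix(
        list(query_genes), list(retained.set_names), values
    )


def cofunctionality_matrix(
    fl: FunctionalLikelihoodMatrix, flavor: str = "pearson"
) -> np.ndarray:
    """Correlate functional-likelihood vectors between genes.

    Returns the symmetric co-functionality weight matrix (diagonal 1).
    A gene with a constant likelihood vector gets weight 0 everywhere.
    """
    check_correlation_flavor(flavor)
    if len(fl.set_names) < 3:
        raise ValueError(
            f"need >= 3 retained gene sets, got {len(fl.set_names)}"
        )
    rows = fl.values
    if flavor == "spearman":
        rows = rankdata(rows, axis=1)
    weights, degenerate = _rowwise_corr_matrix(rows)
    if degenerate.any():
        logger.warning(
            "%d genes with constant likelihood vectors set to 0 co-functionality",
            int(degenerate.sum()),
        )
    return weights


def threshold_network(
    gene_ids: list[str], weights: np.ndarray, tau: float = 0.5
) -> CoFunctionalityNetwork:
    """Build the network with edges where weight > tau (strict)."""
    return CoFunctionalityNetwork(list(gene_ids), weights, float(tau))


def extract_clusters(
    net: CoFunctionalityNetwork, min_cluster_size: int = 2
) -> list[GeneCluster]:
    """Connected components of the thresholded network, largest first.

    Components smaller than ``min_cluster_size`` (default 2, i.e.
    singletons) are excluded.  Size ties are ordered by mean
    intra-cluster weight descending, then by lexicographically smallest
    member.
    """
    graph = nx.Graph()
    graph.add_nodes_from(range(len(net.gene_ids)))
    graph.add_edges_from(net.edges)
    clusters = []
    for comp in nx.connected_components(graph):
        if len(comp) < min_cluster_size:
            continue
        idx = np.fromiter(comp, dtype=np.int64)
        sub = net.weights[np.ix_(idx, idx)]
        iu, ju = np.triu_indices(len(idx), k=1)
        mean_w = float(sub[iu, ju].mean())
        members = sorted(net.gene_ids[i] for i in idx)
        clusters.append(GeneCluster(members, mean_w))
    clusters.sort(key=lambda c: (-c.size, -c.mean_weight, c.members[0]))
    return clusters


def write_clusters_tsv(clusters: list[GeneCluster], path) -> None:
    from .io_formats import _FLOAT_FMT, _header_line

    with open(path, "w", encoding="utf-8") as fh:
        fh.write(_header_line(artifact="clusters") + "\n")
        fh.write("cluster_rank\tsize\tmean_weight\tmembers\n")
        for rank, cl in enumerate(clusters, start=1):
            fh.write(
                f"{rank}\t{cl.size}\t{_FLOAT_FMT.format(cl.mean_weight)}\t"
                + ",".join(cl.members)
                + "\n"
            )
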