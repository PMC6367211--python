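"""End-to-end orchestration: discovery and SCNA-count runs.

Each run is driven by a :class:`RunConfig` (JSON on disk; unknown keys
are hard errors), executes its stages in order, writes every artifact
under the output directory, and finishes with a ``manifest.json``
listing each written file with its SHA-256 checksum plus the config
echo — reruns with identical config and seed are byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

from . import __version__
from .association import associate, select_top, write_association_tsv
from .cofunctionality import (
    build_coregulation,
    check_correlation_flavor,
    cofunctionality_matrix,
    extract_clusters,
    functional_likelihood,
    threshold_network,
    write_clusters_tsv,
)
from .io_formats import (
    read_cn_calls,
    read_expression_tsv,
    read_gmt,
    read_instability_tsv,
    write_cn_calls,
    write_expression_tsv,
    write_gene_list,
    write_gmt,
    write_instability_tsv,
    write_network_edgelist,
)
from .scna import (
    comparison_to_dict,
    compare_groups,
    count_aberrations,
    modal_profile,
    write_counts_tsv,
)
from .simulate import (
    CNSimConfig,
    ExpressionSimConfig,
    simulate_cn_profiles,
    simulate_expression,
)

logger = logging.getLogger(__name__)

DISCOVERY_STAGES = ("simulate", "associate", "cofun")
SCNA_STAGES = ("simulate", "counts", "compare")


def _from_dict(cls, data: dict, where: str):
    """Build a dataclass from a dict, rejecting unknown keys."""
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown {where} config keys: {sorted(unknown)}")
    kwargs = dict(data)
    for f in dataclasses.fields(cls):
        # JSON has no tuples; coerce list-typed values back
        if f.name in kwargs and isinstance(kwargs[f.name], list):
            kwargs[f.name] = tuple(kwargs[f.name])
    return cls(**kwargs)


@dataclass
class RunConfig:
    """Single config object for both pipelines.

    Defaults reproduce the anchored settings: ``top_n=250``,
    ``tau=0.5``, whole-chromosome fraction 0.9.
    """

    seed: int = 0
    outdir: str = "run_out"
    # discovery stages/parameters
    discovery_stages: tuple[str, ...] = DISCOVERY_STAGES
    top_n: int = 250
    tau: float = 0.5
    assoc_method: str = "spearman"
    coreg_method: str = "spearman"
    cofun_flavor: str = "pearson"
    min_set_size: int = 5
    max_set_fraction: float = 0.5
    min_cluster_size: int = 2
    expression_sim: dict = field(default_factory=dict)
    # optional paths to real inputs (used when 'simulate' stage is off)
    expr_path: str | None = None
    scores_path: str | None = None
    gmt_path: str | None = None
    # scna stages/parameters
    scna_stages: tuple[str, ...] = SCNA_STAGES
    whole_chrom_fraction: float = 0.9
    control_condition: str = "CTRL"
    metric: str = "n_focal"
    dunn_adjust: str = "bonferroni"
    cn_sim: dict = field(default_factory=dict)
    calls_path: str | None = None

    def __post_init__(self) -> None:
        check_correlation_flavor(self.cofun_flavor)
        for st in self.discovery_stages:
            if st not in DISCOVERY_STAGES:
                raise ValueError(f"unknown discovery stage {st!r}")
        for st in self.scna_stages:
            if st not in SCNA_STAGES:
                raise ValueError(f"unknown scna stage {st!r}")

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            data = json.load(fh)
        return _from_dict(cls, data, "run")

    def expression_sim_config(self) -> ExpressionSimConfig:
        cfg = _from_dict(ExpressionSimConfig, self.expression_sim, "expression_sim")
        cfg.seed = self.seed
        return cfg

    def cn_sim_config(self) -> CNSimConfig:
        data = dict(self.cn_sim)
        if "conditions" in data:
            data["conditions"] = {
                k: tuple(v) for k, v in data["conditions"].items()
            }
        cfg = _from_dict(CNSimConfig, data, "cn_sim")
        cfg.seed = self.seed
        return cfg

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_manifest(outdir: Path, files: list[Path], config: RunConfig) -> Path:
    manifest = {
        "tool": f"cofun-instab v{__version__}",
        "config": config.to_dict(),
        "files": {f.name: _sha256(f) for f in sorted(files)},
    }
    path = outdir / "manifest.json"
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return path


# ---------------------------------------------------------------------------
# Discovery pipeline
# ---------------------------------------------------------------------------


def discover(
    expr,
    scores,
    sets,
    top_n: int = 250,
    tau: float = 0.5,
    assoc_method: str = "spearman",
    coreg_method: str = "spearman",
    cofun_flavor: str = "pearson",
    min_set_size: int = 5,
    max_set_fraction: float = 0.5,
    min_cluster_size: int = 2,
):
    """In-memory discovery: association -> top-N -> co-functionality
    network -> clusters.  Returns (assoc table, top genes, network,
    clusters)."""
    assoc = associate(expr, scores, method=assoc_method)
    top = select_top(assoc, n=top_n)
    coreg = build_coregulation(expr, method=coreg_method)
    fl = functional_likelihood(
        coreg, sets, top, min_set_size=min_set_size,
        max_set_fraction=max_set_fraction,
    )
    weights = cofunctionality_matrix(fl, flavor=cofun_flavor)
    net = threshold_network(fl.gene_ids, weights, tau=tau)
    clusters = extract_clusters(net, min_cluster_size=min_cluster_size)
    return assoc, top, net, clusters


def run_discovery(config: RunConfig) -> dict:
    """Execute the discovery pipeline per config; write artifacts and a
    checksum manifest.  Returns a dict of in-memory results."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    results: dict = {}
    stages = config.discovery_stages

    expr = scores = sets = None
    if "simulate" in stages:
        logger.info("stage simulate: expression (seed=%d)", config.seed)
        sim_cfg = config.expression_sim_config()
        expr, scores, sets, truth = simulate_expression(sim_cfg)
        results["truth"] = truth
        for name, writer, obj in [
            ("expression.tsv", write_expression_tsv, expr),
            ("instability.tsv", write_instability_tsv, scores),
            ("gene_sets.gmt", write_gmt, sets),
        ]:
            writer(obj, outdir / name)
            written.append(outdir / name)
        with open(outdir / "truth.json", "w", encoding="utf-8") as fh:
            json.dump(truth, fh, indent=2, sort_keys=True)
            fh.write("\n")
        written.append(outdir / "truth.json")
    elif "associate" in stages or "cofun" in stages:
        if not (config.expr_path and config.scores_path and config.gmt_path):
            raise ValueError(
                "without the simulate stage, expr_path, scores_path and "
                "gmt_path must be provided"
            )
        expr = read_expression_tsv(config.expr_path)
        scores = read_instability_tsv(config.scores_path)
        sets = read_gmt(config.gmt_path)

    if "associate" in stages:
        logger.info(
            "stage associate: method=%s top_n=%d", config.assoc_method, config.top_n
        )
        assoc = associate(expr, scores, method=config.assoc_method)
        top = select_top(assoc, n=config.top_n)
        results["association"] = assoc
        results["top_genes"] = top
        write_association_tsv(assoc, outdir / "association.tsv")
        write_gene_list(top, outdir / "top_genes.txt")
        written += [outdir / "association.tsv", outdir / "top_genes.txt"]

    if "cofun" in stages:
        if "associate" not in stages:
            raise ValueError("cofun stage requires the associate stage")
        logger.info(
            "stage cofun: coreg=%s flavor=%s tau=%.3g",
            config.coreg_method, config.cofun_flavor, config.tau,
        )
        coreg = build_coregulation(expr, method=config.coreg_method)
        fl = functional_likelihood(
            coreg, sets, results["top_genes"],
            min_set_size=config.min_set_size,
            max_set_fraction=config.max_set_fraction,
        )
        weights = cofunctionality_matrix(fl, flavor=config.cofun_flavor)
        net = threshold_network(fl.gene_ids, weights, tau=config.tau)
        clusters = extract_clusters(net, min_cluster_size=config.min_cluster_size)
        results["network"] = net
        results["clusters"] = clusters
        write_network_edgelist(net, outdir / "network_edges.tsv")
        write_clusters_tsv(clusters, outdir / "clusters.tsv")
        written += [outdir / "network_edges.tsv", outdir / "clusters.tsv"]

    results["manifest_path"] = _write_manifest(outdir, written, config)
    return results


# ---------------------------------------------------------------------------
# SCNA-count pipeline
# ---------------------------------------------------------------------------


def run_scna(config: RunConfig) -> dict:
    """Execute the SCNA counting pipeline per config; write artifacts and
    a checksum manifest.  Returns a dict of in-memory results."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    results: dict = {}
    stages = config.scna_stages

    profiles = None
    if "simulate" in stages:
        logger.info("stage simulate: cn profiles (seed=%d)", config.seed)
        sim_cfg = config.cn_sim_config()
        profiles, truth = simulate_cn_profiles(sim_cfg)
        results["truth"] = truth
        write_cn_calls(profiles, outdir / "cn_calls.tsv")
        written.append(outdir / "cn_calls.tsv")
        with open(outdir / "cn_truth.json", "w", encoding="utf-8") as fh:
            json.dump(truth, fh, indent=2, sort_keys=True)
            fh.write("\n")
        written.append(outdir / "cn_truth.json")
    elif "counts" in stages or "compare" in stages:
        if not config.calls_path:
            raise ValueError("without the simulate stage, calls_path must be provided")
        profiles = read_cn_calls(config.calls_path)

    if "counts" in stages:
        logger.info(
            "stage counts: control=%s frac=%.3g",
            config.control_condition, config.whole_chrom_fraction,
        )
        modal = modal_profile(profiles, config.control_condition)
        counts = count_aberrations(
            profiles, modal, whole_chrom_fraction=config.whole_chrom_fraction
        )
        results["counts"] = counts
        write_counts_tsv(counts, outdir / "counts.tsv")
        written.append(outdir / "counts.tsv")

    if "compare" in stages:
        if "counts" not in stages:
            raise ValueError("compare stage requires the counts stage")
        logger.info("stage compare: metric=%s", config.metric)
        cmp = compare_groups(
            results["counts"], metric=config.metric, adjust=config.dunn_adjust
        )
        results["comparison"] = cmp
        with open(outdir / "stats.json", "w", encoding="utf-8") as fh:
            json.dump(comparison_to_dict(cmp), fh, indent=2, sort_keys=True)
            fh.write("\n")
        written.append(outdir / "stats.json")

    results["manifest_path"] = _write_manifest(outdir, written, config)
    return results
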