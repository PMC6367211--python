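"""Synthetic inputs with known ground truth.

Two generators:

* :func:`simulate_expression` — an expression matrix whose
  instability-driver genes respond to the per-sample count of planted
  copy-number alterations (the instability score), with a planted
  co-functional gene module that shares a latent expression factor and
  is co-annotated across several gene sets.
* :func:`simulate_cn_profiles` — single-cell integer copy-number
  profiles on a diploid background with planted focal segments and
  whole-chromosome aneuploidies plus optional per-bin miscall noise.

All randomness flows from one seed through named substreams, so adding
a draw to one generator never perturbs another.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, asdict

import numpy as np

from .io_formats import (
    CNProfileSet,
    ExpressionMatrix,
    GeneSetCollection,
    InstabilityScores,
)


def substream(seed: int, name: str) -> np.random.Generator:
    """Independent, platform-stable RNG stream derived from (seed, name)."""
    return np.random.default_rng([int(seed), zlib.crc32(name.encode("utf-8"))])


# ---------------------------------------------------------------------------
# Expression + gene sets
# ---------------------------------------------------------------------------


@dataclass
class ExpressionSimConfig:
    """Parameters of the expression / instability / gene-set generator.

    ``dosage_effect_size`` is the mean expression shift per planted
    alteration; the instability score of a sample is its alteration
    count.  Defaults are tuned so that the full discovery pipeline
    (top 250 by association, co-functionality threshold 0.5) recovers
    the planted 11-gene module.
    """

    n_genes: int = 2000
    n_samples: int = 300
    n_instability_driver_genes: int = 100
    planted_module_size: int = 11
    n_gene_sets: int = 500
    n_coannotation_sets: int = 20
    dosage_effect_size: float = 0.03
    noise_sd: float = 1.0
    module_latent_sd: float = 0.85
    alteration_rate_range: tuple[float, float] = (1.0, 30.0)
    # large sets dilute the co-annotation signal leaking into non-module
    # driver genes; below ~40 the network bridges module and drivers
    set_size_range: tuple[int, int] = (60, 200)
    seed: int = 0

    def validate(self) -> None:
        if self.planted_module_size > self.n_genes:
            raise ValueError("planted module larger than gene universe")
        if self.planted_module_size > self.n_instability_driver_genes:
            raise ValueError("planted module must fit inside the driver genes")
        if self.n_instability_driver_genes > self.n_genes:
            raise ValueError("more driver genes than genes")
        if self.n_coannotation_sets > self.n_gene_sets:
            raise ValueError("more co-annotation sets than gene sets")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not (0 <= self.module_latent_sd <= self.noise_sd):
            raise ValueError(
                "module_latent_sd must be in [0, noise_sd]: the latent factor "
                "replaces part of the module genes' noise budget"
            )
        if self.n_samples < 3:
            raise ValueError("need >= 3 samples")
        lo, hi = self.set_size_range
        if not (0 < lo <= hi):
            raise ValueError("invalid set_size_range")


def simulate_expression(
    cfg: ExpressionSimConfig,
) -> tuple[ExpressionMatrix, InstabilityScores, GeneSetCollection, dict]:
    """Generate expression, instability scores, gene sets and truth.

    Per sample, an alteration count is drawn Poisson with a mean that
    varies across samples; driver genes shift by
    ``dosage_effect_size`` per alteration on top of Gaussian noise; the
    planted module (a subset of the drivers) additionally shares a
    latent factor and is co-annotated in ``n_coannotation_sets`` gene
    sets; the remaining sets are random draws with log-uniform sizes.
    The instability score is the alteration count.  Fully reproducible
    from ``cfg.seed``.
    """
    cfg.validate()
    rng_alt = substream(cfg.seed, "alterations")
    rng_noise = substream(cfg.seed, "noise")
    rng_latent = substream(cfg.seed, "latent")
    rng_sets = substream(cfg.seed, "sets")
    rng_genes = substream(cfg.seed, "gene_choice")

    gene_ids = [f"G{i:05d}" for i in range(cfg.n_genes)]
    sample_ids = [f"S{i:04d}" for i in range(cfg.n_samples)]

    lo, hi = cfg.alteration_rate_range
    lam = rng_alt.uniform(lo, hi, size=cfg.n_samples)
    k = rng_alt.poisson(lam).astype(np.float64)  # alteration count per sample
    if np.all(k == k[0]):  # vanishingly unlikely; keep scores non-constant
        k[0] += 1.0

    drivers = np.sort(
        rng_genes.choice(cfg.n_genes, cfg.n_instability_driver_genes, replace=False)
    )
    module = drivers[: cfg.planted_module_size]

    values = rng_noise.normal(0.0, cfg.noise_sd, size=(cfg.n_genes, cfg.n_samples))
    values[drivers] += cfg.dosage_effect_size * k[None, :]
    # the module's latent factor replaces part of its noise budget so the
    # total variance (and thus the instability-association rank profile)
    # of module genes matches the other driver genes
    latent = rng_latent.normal(0.0, 1.0, size=cfg.n_samples)
    indep_sd = float(np.sqrt(cfg.noise_sd**2 - cfg.module_latent_sd**2))
    noise_scale = indep_sd / cfg.noise_sd if cfg.noise_sd > 0 else 0.0
    values[module] = (
        cfg.dosage_effect_size * k[None, :]
        + noise_scale * (values[module] - cfg.dosage_effect_size * k[None, :])
        + cfg.module_latent_sd * latent[None, :]
    )

    # gene sets: log-uniform sizes; the first n_coannotation_sets jointly
    # annotate the planted module
    names, descs, members = [], [], []
    slo, shi = cfg.set_size_range
    module_genes = [gene_ids[i] for i in module]
    for s in range(cfg.n_gene_sets):
        size = int(round(np.exp(rng_sets.uniform(np.log(slo), np.log(shi)))))
        size = min(max(size, slo), shi)
        name = f"SET{s:04d}"
        if s < cfg.n_coannotation_sets:
            size = max(size, cfg.planted_module_size + 1)
            pool = np.setdiff1d(np.arange(cfg.n_genes), module)
            fill = rng_sets.choice(
                pool, size - cfg.planted_module_size, replace=False
            )
            mem = frozenset(module_genes) | {gene_ids[i] for i in fill}
            desc = "coannotation"
        else:
            idx = rng_sets.choice(cfg.n_genes, size, replace=False)
            mem = frozenset(gene_ids[i] for i in idx)
            desc = "random"
        names.append(name)
        descs.append(desc)
        members.append(mem)

    truth = {
        "driver_genes": [gene_ids[i] for i in drivers],
        "module_genes": module_genes,
        "coannotation_sets": names[: cfg.n_coannotation_sets],
        "seed": cfg.seed,
        "config": asdict(cfg),
    }
    return (
        ExpressionMatrix(gene_ids, sample_ids, values),
        InstabilityScores(sample_ids, k),
        GeneSetCollection(names, descs, members),
        truth,
    )


# ---------------------------------------------------------------------------
# Single-cell copy-number profiles
# ---------------------------------------------------------------------------


@dataclass
class CNSimConfig:
    """Parameters of the single-cell copy-number profile generator.

    ``conditions`` maps condition label -> (focal_rate,
    whole_chrom_rate), the expected numbers of planted focal and
    whole-chromosome events per cell.  The control condition defaults
    to rate (0, 0).  Cells are G1-like: integer states on a diploid
    (state 2) background.
    """

    n_cells_per_condition: int = 48
    conditions: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "CTRL": (0.0, 0.0),
            "DOX": (4.0, 0.3),
            "ALISERTIB": (2.0, 2.5),
            "DOX_ALISERTIB": (3.0, 0.8),
        }
    )
    control_condition: str = "CTRL"
    n_chromosomes: int = 22
    bins_per_chromosome: int = 50
    bin_width: int = 1_000_000
    focal_length_range: tuple[int, int] = (2, 20)
    whole_chrom_fraction: float = 0.9  # used only to validate focal lengths
    miscall_rate: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_cells_per_condition < 1:
            raise ValueError("need >= 1 cell per condition")
        if self.control_condition not in self.conditions:
            raise ValueError(
                f"control condition {self.control_condition!r} not in conditions"
            )
        for name, (fr, wr) in self.conditions.items():
            if fr < 0 or wr < 0:
                raise ValueError(f"negative event rate for condition {name!r}")
        if not (0.0 <= self.miscall_rate <= 0.2):
            raise ValueError("miscall_rate must be in [0, 0.2]")
        lo, hi = self.focal_length_range
        if lo < 1:
            raise ValueError("focal length must be >= 1 bin")
        if hi >= self.whole_chrom_fraction * self.bins_per_chromosome:
            raise ValueError(
                "max focal length must stay below "
                "whole_chrom_fraction * bins_per_chromosome"
            )
        if self.bins_per_chromosome < 2:
            raise ValueError("need >= 2 bins per chromosome")


def _place_focal(
    rng: np.random.Generator,
    free_chroms: list[int],
    occupied: dict[int, list[tuple[int, int]]],
    cfg: CNSimConfig,
) -> tuple[int, int, int] | None:
    """Pick (chrom, start, length) for a focal event, avoiding overlap or
    adjacency with existing events (so planted events never merge into a
    single deviation run)."""
    lo, hi = cfg.focal_length_range
    for _ in range(200):
        chrom = int(rng.choice(free_chroms))
        length = int(rng.integers(lo, hi + 1))
        start = int(rng.integers(0, cfg.bins_per_chromosome - length + 1))
        clash = any(
            start <= e and s <= start + length  # 1-bin margin on both sides
            for s, e in occupied.get(chrom, [])
        )
        if not clash:
            occupied.setdefault(chrom, []).append((start, start + length))
            return chrom, start, length
    return None


def simulate_cn_profiles(cfg: CNSimConfig) -> tuple[CNProfileSet, dict]:
    """Generate per-cell copy-number states with planted events.

    Whole-chromosome events shift every bin of a chromosome by +/-1;
    focal events shift a contiguous run of bins by +/-1; planted events
    never overlap or touch, and chromosomes carrying a whole-chromosome
    event receive no focal events, so zero-noise event counts equal the
    planted truth exactly.  Miscalls flip single bins by +/-1
    independently at ``miscall_rate``.  The truth record lists every
    planted event per cell.
    """
    cfg.validate()
    rng_events = substream(cfg.seed, "cn_events")
    rng_noise = substream(cfg.seed, "cn_miscalls")

    n_bins = cfg.n_chromosomes * cfg.bins_per_chromosome
    chroms = np.repeat(
        [f"chr{c + 1}" for c in range(cfg.n_chromosomes)], cfg.bins_per_chromosome
    ).astype(object)
    starts = np.tile(
        np.arange(cfg.bins_per_chromosome, dtype=np.int64) * cfg.bin_width,
        cfg.n_chromosomes,
    )
    ends = starts + cfg.bin_width

    cell_ids: list[str] = []
    conditions: list[str] = []
    states = []
    truth_events: dict[str, list[dict]] = {}

    for cond, (focal_rate, whole_rate) in cfg.conditions.items():
        for c in range(cfg.n_cells_per_condition):
            cell = f"{cond}_cell{c:03d}"
            cell_ids.append(cell)
            conditions.append(cond)
            st = np.full(n_bins, 2, dtype=np.int64)
            events: list[dict] = []

            n_whole = int(rng_events.poisson(whole_rate))
            n_whole = min(n_whole, cfg.n_chromosomes)
            whole_chroms = rng_events.choice(
                cfg.n_chromosomes, n_whole, replace=False
            )
            for ch in sorted(int(x) for x in whole_chroms):
                sign = 1 if rng_events.random() < 0.5 else -1
                lo = ch * cfg.bins_per_chromosome
                st[lo : lo + cfg.bins_per_chromosome] += sign
                events.append(
                    {
                        "type": "whole_chromosome",
                        "chrom": f"chr{ch + 1}",
                        "start_bin": 0,
                        "end_bin": cfg.bins_per_chromosome,
                        "sign": sign,
                    }
                )

            free = [
                ch
                for ch in range(cfg.n_chromosomes)
                if ch not in set(int(x) for x in whole_chroms)
            ]
            n_focal = int(rng_events.poisson(focal_rate))
            occupied: dict[int, list[tuple[int, int]]] = {}
            for _ in range(n_focal):
                if not free:
                    break
                placed = _place_focal(rng_events, free, occupied, cfg)
                if placed is None:
                    continue  # no room left; truth reflects what was planted
                ch, start, length = placed
                sign = 1 if rng_events.random() < 0.5 else -1
                lo = ch * cfg.bins_per_chromosome + start
                st[lo : lo + length] += sign
                events.append(
                    {
                        "type": "focal",
                        "chrom": f"chr{ch + 1}",
                        "start_bin": start,
                        "end_bin": start + length,
                        "sign": sign,
                    }
                )

            truth_events[cell] = events
            states.append(st)

    states = np.vstack(states)
    if cfg.miscall_rate > 0:
        flips = rng_noise.random(states.shape) < cfg.miscall_rate
        delta = rng_noise.choice([-1, 1], size=states.shape)
        states = np.where(flips, states + delta, states)
        np.maximum(states, 0, out=states)

    truth = {
        "events": truth_events,
        "config": {
            **asdict(cfg),
            "conditions": {k: list(v) for k, v in cfg.conditions.items()},
        },
        "seed": cfg.seed,
    }
    profiles = CNProfileSet(cell_ids, conditions, chroms, starts, ends, states)
    return profiles, truth


def planted_counts(truth: dict) -> dict[str, tuple[int, int]]:
    """Per-cell (n_focal, n_whole_chromosome) from a CN truth record."""
    out = {}
    for cell, events in truth["events"].items():
        nf = sum(1 for e in events if e["type"] == "focal")
        nw = sum(1 for e in events if e["type"] == "whole_chromosome")
        out[cell] = (nf, nw)
    return out
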