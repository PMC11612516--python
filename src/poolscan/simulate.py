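"""Synthetic Pool-Seq data with known ground truth.

The generator emulates the study design the pipeline targets: 12 farmed and
8 natural-origin (wild) pools of 11-25 diploid individuals each, sequenced as
two technical replicates, with allele frequencies differentiated by genetic
drift and, at a planted minority of loci, by a domestication-like shift of
the farmed group's mean frequency.

The drift model is the Balding-Nichols Beta parameterisation: a population
with drift intensity ``c`` (interpretable as its FST to the common ancestor)
has allele frequency ``Beta(p0*(1-c)/c, (1-p0)*(1-c)/c)`` around the
ancestral frequency ``p0``.  Read counts are produced by two-stage sampling:
first 2N allele copies are drawn binomially per pool (finite-pool variance),
then reads are drawn binomially from the realised copy frequency at a
Poisson-distributed depth per technical replicate.  Everything is
deterministic given the seed.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .annotation import FeatureCatalog
from .io import BASES

__all__ = ["SimConfig", "simulate_counts", "simulate_annotation",
           "simulate_interactome"]


@dataclasses.dataclass(frozen=True)
class SimConfig:
    """Study-design and generative parameters for the synthetic dataset.

    Defaults mirror the emulated study: 12 farmed + 8 wild pools of 11-25
    diploid individuals, drift intensity ~0.10 for farmed populations (small
    effective size under domestication) and ~0.02 for wild ones, mean read
    depth 60 split over two technical replicates, 24 linkage groups.
    """

    n_farmed: int = 12
    n_wild: int = 8
    #: individuals per pool (diploid).  An int applies to every pool; a
    #: sequence gives one size per pool (farmed pools first); None spreads
    #: sizes evenly over the study's 11-25 range.
    pool_sizes: int | Sequence[int] | None = None
    n_sites: int = 5000
    n_selected: int = 50
    #: (alpha, beta) of the ancestral allele-frequency distribution,
    #: truncated to [0.05, 0.95]
    ancestral_beta: tuple[float, float] = (1.0, 1.0)
    drift_wild: float = 0.02
    drift_farmed: float = 0.10
    #: mean farmed-group allele-frequency displacement at selected loci
    selection_shift: float = 0.45
    mean_depth: float = 60.0
    #: fraction of mean_depth assigned to each of the 2 technical replicates
    replicate_fraction: float = 0.5
    n_lg: int = 24
    lg_length: int = 1_000_000
    seed: int = 0

    def __post_init__(self):
        if self.n_farmed < 1 or self.n_wild < 1:
            raise ValueError("need at least one pool per group")
        if not (0.0 < self.drift_wild < 1.0 and 0.0 < self.drift_farmed < 1.0):
            raise ValueError("drift intensities must lie in (0, 1)")
        if not (0.0 <= self.selection_shift <= 1.0):
            raise ValueError("selection_shift must lie in [0, 1]")
        if self.n_selected > self.n_sites:
            raise ValueError("n_selected cannot exceed n_sites")
        if not (0.0 < self.replicate_fraction <= 1.0):
            raise ValueError("replicate_fraction must lie in (0, 1]")
        a, b = self.ancestral_beta
        if a <= 0 or b <= 0:
            raise ValueError("ancestral_beta shape parameters must be positive")
        if np.any(np.asarray(self.resolved_pool_sizes()) < 1):
            raise ValueError("pool sizes must be >= 1")
        if self.n_lg < 1:
            raise ValueError("need at least one linkage group")
        if self.mean_depth <= 0:
            raise ValueError("mean_depth must be positive")

    @property
    def n_pools(self) -> int:
        return self.n_farmed + self.n_wild

    @property
    def populations(self) -> list[str]:
        farmed = [f"farm{i + 1:02d}" for i in range(self.n_farmed)]
        wild = [f"wild{i + 1:02d}" for i in range(self.n_wild)]
        return farmed + wild

    def design(self) -> dict[str, str]:
        """Population → group labelling (farmed | wild)."""
        return {p: ("farmed" if p.startswith("farm") else "wild")
                for p in self.populations}

    def resolved_pool_sizes(self) -> np.ndarray:
        if self.pool_sizes is None:
            farmed = np.linspace(11, 25, self.n_farmed).round()
            wild = np.linspace(11, 25, self.n_wild).round()
            return np.concatenate([farmed, wild]).astype(int)
        if np.isscalar(self.pool_sizes):
            return np.full(self.n_pools, int(self.pool_sizes))
        sizes = np.asarray(self.pool_sizes, dtype=int)
        if sizes.shape != (self.n_pools,):
            raise ValueError("pool_sizes must have one entry per pool")
        return sizes

    def drift(self) -> np.ndarray:
        return np.array([self.drift_farmed] * self.n_farmed
                        + [self.drift_wild] * self.n_wild)


def _truncated_beta(rng: np.random.Generator, a: float, b: float,
                    size: int, lo: float = 0.05, hi: float = 0.95) -> np.ndarray:
    """Beta(a, b) draws rejection-sampled into [lo, hi]."""
    x = rng.beta(a, b, size)
    bad = (x < lo) | (x > hi)
    while bad.any():
        x[bad] = rng.beta(a, b, int(bad.sum()))
        bad = (x < lo) | (x > hi)
    return x


def _site_positions(cfg: SimConfig, rng: np.random.Generator):
    """Distinct sorted 1-based positions spread over the linkage groups."""
    per_lg = np.full(cfg.n_lg, cfg.n_sites // cfg.n_lg)
    per_lg[: cfg.n_sites % cfg.n_lg] += 1
    lgs, positions = [], []
    for i, n in enumerate(per_lg):
        if n == 0:
            continue
        pos = np.sort(rng.choice(cfg.lg_length, size=n, replace=False)) + 1
        lgs.append(np.full(n, i))
        positions.append(pos)
    lg_idx = np.concatenate(lgs)
    pos = np.concatenate(positions)
    names = np.array([f"LG{i + 1:02d}" for i in range(cfg.n_lg)])
    return names[lg_idx], pos


def simulate_counts(cfg: SimConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate pooled read counts and the matching ground-truth table.

    Returns ``(counts, truth)``: a long-format count table with one row per
    (site, population, technical replicate) and A/C/G/T read counts, and a
    per-site truth table flagging the selected loci with the true group
    allele-frequency means.
    """
    rng = np.random.default_rng(cfg.seed)
    L, J = cfg.n_sites, cfg.n_pools
    lg, pos = _site_positions(cfg, rng)

    a, b = cfg.ancestral_beta
    p0 = _truncated_beta(rng, a, b, L)

    selected = np.zeros(L, dtype=bool)
    if cfg.n_selected:
        selected[rng.choice(L, size=cfg.n_selected, replace=False)] = True
    sign = rng.choice([-1.0, 1.0], size=L)  # shift direction, fixed per locus

    p_farmed = p0.copy()
    shift = np.clip(p0 + sign * cfg.selection_shift, 0.01, 0.99)
    p_farmed[selected] = shift[selected]
    p_wild = p0

    # per-population mean frequencies (J, L)
    means = np.empty((J, L))
    means[: cfg.n_farmed] = p_farmed
    means[cfg.n_farmed:] = p_wild

    c = cfg.drift()[:, None]
    pop_freq = rng.beta(means * (1.0 - c) / c, (1.0 - means) * (1.0 - c) / c)

    copies = 2 * cfg.resolved_pool_sizes()[:, None]       # 2N allele copies
    k = rng.binomial(copies, pop_freq)
    copy_freq = k / copies

    ref_idx = rng.integers(0, 4, size=L)
    alt_idx = (ref_idx + rng.integers(1, 4, size=L)) % 4  # any base but ref
    base_arr = np.array(BASES)

    frames = []
    pops = np.array(cfg.populations)
    for rep in (1, 2):
        depth = rng.poisson(cfg.mean_depth * cfg.replicate_fraction, size=(J, L))
        alt_reads = rng.binomial(depth, copy_freq)
        ref_reads = depth - alt_reads
        counts = np.zeros((J, L, 4), dtype=np.int64)
        rows = np.arange(L)
        counts[:, rows, ref_idx] = ref_reads
        counts[:, rows, alt_idx] += alt_reads
        frame = pd.DataFrame({
            "lg": np.tile(lg, J),
            "pos": np.tile(pos, J),
            "ref": np.tile(base_arr[ref_idx], J),
            "population": np.repeat(pops, L),
            "replicate": rep,
            "A": counts[:, :, 0].ravel(),
            "C": counts[:, :, 1].ravel(),
            "G": counts[:, :, 2].ravel(),
            "T": counts[:, :, 3].ravel(),
        })
        frames.append(frame)
    counts_df = pd.concat(frames, ignore_index=True)
    counts_df = counts_df.sort_values(
        ["lg", "pos", "population", "replicate"], ignore_index=True)

    truth = pd.DataFrame({
        "lg": lg,
        "pos": pos,
        "ref": base_arr[ref_idx],
        "alt": base_arr[alt_idx],
        "selected": selected,
        "p_ancestral": p0,
        "p_farmed": np.where(selected, p_farmed, p0),
        "p_wild": p_wild,
    }).sort_values(["lg", "pos"], ignore_index=True)
    return counts_df, truth


def simulate_annotation(cfg: SimConfig, genes_per_lg: int = 30,
                        cpg_per_lg: int = 8) -> FeatureCatalog:
    """Toy genome annotation: non-overlapping genes plus CpG islands.

    Each linkage group is divided into ``genes_per_lg`` equal slots and one
    gene of random length (2-15 kbp) is placed at a random offset inside each
    slot, which guarantees sorted, non-overlapping gene features.  CpG
    islands (0.3-2 kbp) are interspersed anywhere on the linkage group and
    may overlap genes, as they do in real annotations.
    """
    rng = np.random.default_rng(cfg.seed + 1)
    records = []
    slot = cfg.lg_length // genes_per_lg
    for i in range(cfg.n_lg):
        lg = f"LG{i + 1:02d}"
        for g in range(genes_per_lg):
            length = int(rng.integers(2_000, min(15_000, slot - 1)))
            offset = int(rng.integers(0, slot - length))
            start = g * slot + offset + 1
            records.append((f"gene_{lg}_{g + 1:04d}", "gene", lg,
                            start, start + length - 1))
        for c in range(cpg_per_lg):
            length = int(rng.integers(300, 2_000))
            start = int(rng.integers(1, cfg.lg_length - length))
            records.append((f"cpg_{lg}_{c + 1:04d}", "CpG_island", lg,
                            start, start + length - 1))
    df = pd.DataFrame(records, columns=["id", "type", "lg", "start", "end"])
    return FeatureCatalog(df)


def simulate_interactome(genes: int | Sequence[str],
                         planted_module: Sequence[str],
                         p_within: float = 0.95,
                         p_background: float = 0.005,
                         seed: int = 0) -> nx.Graph:
    """Random interactome with a planted high-confidence module.

    The planted module is a clique whose edges carry coupling probabilities
    in [p_within, 1], so they survive the pipeline's 0.90 probability filter;
    background edges (Erdos-Renyi density ``p_background``) carry
    probabilities in [0.5, 0.90) and are all removed by that filter.  The
    full gene universe is recorded on the graph for enrichment backgrounds.
    """
    if p_within < 0.90:
        raise ValueError("p_within must be >= 0.90 so planted edges survive "
                         "the coupling-probability filter")
    if np.isscalar(genes):
        universe = [f"g{i + 1:05d}" for i in range(int(genes))]
    else:
        universe = list(genes)
    module = list(dict.fromkeys(planted_module))
    missing = set(module) - set(universe)
    if missing:
        raise ValueError(f"planted module not contained in gene universe: "
                         f"{sorted(missing)[:5]}")
    rng = np.random.default_rng(seed)
    g = nx.Graph(universe=tuple(sorted(universe)))
    g.add_nodes_from(universe)
    for i, u in enumerate(module):
        for v in module[i + 1:]:
            g.add_edge(u, v, probability=float(rng.uniform(p_within, 1.0)))
    if p_background > 0:
        n = len(universe)
        iu, ju = np.triu_indices(n, k=1)
        mask = rng.random(iu.size) < p_background
        probs = rng.uniform(0.5, 0.8999, size=int(mask.sum()))
        arr = np.array(universe)
        for u, v, p in zip(arr[iu[mask]], arr[ju[mask]], probs):
            if not g.has_edge(u, v):
                g.add_edge(u, v, probability=float(p))
    return g
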