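"""Gene-set construction: ranked-list truncation, eligibility pools, and
reproducible random gene-set sampling for the empirical null.

The empirical null asks how often a *random* gene-set of the same size as
the hypothesis set yields a burden p-value at least as extreme. Random sets
are drawn from an eligibility pool: genes with at least one sufficiently
specific functional annotation (a GO term of bounded size) that are not in
any of the hypothesis sets under test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .types import GeneSet, RankedGeneList

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class NullSamplerConfig:
    n_sets: int = 10_000
    set_size: int = 1_000
    go_term_max_size: int = 500
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_sets < 1:
            raise ValueError("n_sets must be >= 1")
        if self.set_size < 1:
            raise ValueError("set_size must be >= 1")


def top_k(
    ranked: RankedGeneList,
    k: int,
    exclusions: Sequence[GeneSet] = (),
) -> GeneSet:
    """Genes with rank <= k, minus any excluded symbols.

    Exclusions are applied after truncation, so the returned set may hold
    fewer than k symbols; the number removed is logged.
    """
    if not 1 <= k <= len(ranked):
        raise ValueError(f"k={k} out of range 1..{len(ranked)}")
    excluded = set().union(*(gs.genes for gs in exclusions)) if exclusions else set()
    selected = {g for g, r in ranked.entries if r <= k}
    removed = selected & excluded
    if removed:
        logger.info("top_%d: excluded %d overlapping genes", k, len(removed))
    return GeneSet(name=f"top_{k}", genes=frozenset(selected - removed))


def eligible_pool(
    gene_go_table: Mapping[str, Iterable[tuple[str, int]]],
    excluded: Sequence[GeneSet],
    cfg: NullSamplerConfig = NullSamplerConfig(),
) -> frozenset[str]:
    """Genes with >=1 GO term of size <= go_term_max_size, outside all
    excluded sets. Term sizes are taken as given (no ontology traversal)."""
    excluded_genes = set().union(*(gs.genes for gs in excluded)) if excluded else set()
    pool = set()
    for gene, terms in gene_go_table.items():
        if gene in excluded_genes:
            continue
        for _term, size in terms:
            if size <= 0:
                raise ValueError(f"gene {gene}: non-positive GO term size {size}")
            if size <= cfg.go_term_max_size:
                pool.add(gene)
                break
    if not pool:
        raise ValueError("eligible pool is empty")
    logger.info("eligible pool: %d genes", len(pool))
    return frozenset(pool)


def sample_random_sets(
    pool: Iterable[str],
    cfg: NullSamplerConfig,
) -> list[GeneSet]:
    """Draw cfg.n_sets random gene-sets of cfg.set_size without replacement
    within each set, independently across sets, reproducibly from cfg.seed."""
    pool_sorted = np.asarray(sorted(set(pool)), dtype=object)
    if len(pool_sorted) < cfg.set_size:
        raise ValueError(
            f"pool of {len(pool_sorted)} genes is smaller than set_size {cfg.set_size}"
        )
    rng = np.random.default_rng(cfg.seed)
    sets = []
    for i in range(cfg.n_sets):
        draw = rng.choice(pool_sorted, size=cfg.set_size, replace=False)
        sets.append(GeneSet(name=f"random_{i:05d}", genes=frozenset(draw.tolist())))
    return sets


def sample_random_index_matrix(
    pool_size: int,
    cfg: NullSamplerConfig,
) -> np.ndarray:
    """Vectorized variant of :func:`sample_random_sets` returning an
    (n_sets, set_size) integer index matrix into the sorted pool.

    Used on the gene-level count-matrix fast path where gene identities are
    columns; the same uniform without-replacement law applies.
    """
    if pool_size < cfg.set_size:
        raise ValueError("pool smaller than set_size")
    rng = np.random.default_rng(cfg.seed)
    # argpartition of uniform keys == uniform sample without replacement
    keys = rng.random((cfg.n_sets, pool_size))
    return np.argpartition(keys, cfg.set_size - 1, axis=1)[:, : cfg.set_size]
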