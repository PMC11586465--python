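"""Permutation enrichment-ratio (ER) statistics over gene lists.

The ER quantifies whether the genes a PLS list shares with an external
gene set (a disease list, a cell-type marker set) carry systematically
higher weights than chance: with k intersection genes,

    ER = (observed median weight - mean of null medians) / SD of null medians

where each null median is the median weight of k genes drawn without
replacement from the modeled-gene universe. Significance is the one-sided
upper-tail permutation p-value (enrichment = higher median weight), with
+1 smoothing. The null pool is the full universe of genes with PLS
weights by default; sampling within the thresholded list itself is
available for comparison but cannot produce large ER values.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .stats import bh_fdr

__all__ = [
    "GeneSet",
    "EnrichmentResult",
    "CELL_CLASSES",
    "enrichment_ratio",
    "gene_list_battery",
    "celltype_enrichment",
    "gene_list_overlap",
]

CELL_CLASSES = (
    "astrocytes",
    "endothelial",
    "excitatory neurons",
    "inhibitory neurons",
    "microglia",
    "oligodendrocytes",
    "OPCs",
)


@dataclass(frozen=True)
class GeneSet:
    """A named set of unique gene identifiers, optionally directional."""

    name: str
    genes: tuple[str, ...]
    direction: str = "none"
    description: str = ""

    def __post_init__(self) -> None:
        genes = tuple(self.genes)
        if not genes:
            raise ValueError("gene set must be non-empty")
        if len(set(genes)) != len(genes):
            raise ValueError("gene set members must be unique")
        if self.direction not in ("up", "down", "none"):
            raise ValueError("direction must be 'up', 'down' or 'none'")
        object.__setattr__(self, "genes", genes)


@dataclass
class EnrichmentResult:
    set_name: str
    list_name: str
    n_intersection: int
    observed_median_weight: float
    er: float
    p_perm: float
    q: float = np.nan

    @property
    def empty(self) -> bool:
        return self.n_intersection == 0

    def to_dict(self) -> dict:
        return {
            "set_name": self.set_name,
            "list_name": self.list_name,
            "n_intersection": self.n_intersection,
            "observed_median_weight": self.observed_median_weight,
            "er": self.er,
            "p_perm": self.p_perm,
            "q": self.q,
        }


def _null_medians(
    pool: np.ndarray, k: int, n_perm: int, rng: np.random.Generator, chunk: int = 2000
) -> np.ndarray:
    """Medians of k-subsets drawn without replacement from pool, n_perm times."""
    out = np.empty(n_perm)
    done = 0
    while done < n_perm:
        b = min(chunk, n_perm - done)
        keys = rng.random((b, pool.size))
        idx = np.argpartition(keys, k - 1, axis=1)[:, :k]
        out[done : done + b] = np.median(pool[idx], axis=1)
        done += b
    return out


def enrichment_ratio(
    weights: pd.Series,
    universe_weights: pd.Series,
    gene_set: GeneSet,
    n_perm: int = 10_000,
    seed: int = 0,
    null_pool: str = "universe",
    list_name: str = "",
) -> EnrichmentResult:
    """ER of one gene set against one PLS gene list.

    ``weights`` maps the genes of the PLS list to their PLS weights;
    ``universe_weights`` maps every modeled gene (the permutation pool).
    An empty intersection yields a flagged result (NaN ER), not an error.
    """
    if not set(weights.index).issubset(set(universe_weights.index)):
        raise ValueError("PLS list genes must be contained in the universe")
    inter = [g for g in weights.index if g in set(gene_set.genes)]
    if not inter:
        return EnrichmentResult(gene_set.name, list_name, 0, np.nan, np.nan, np.nan)
    observed = float(np.median(weights.loc[inter].to_numpy(float)))
    k = len(inter)
    if null_pool == "universe":
        pool = universe_weights.to_numpy(float)
    elif null_pool == "list":
        pool = weights.to_numpy(float)
    else:
        raise ValueError("null_pool must be 'universe' or 'list'")
    rng = np.random.default_rng(seed)
    null = _null_medians(pool, k, n_perm, rng)
    sd = null.std(ddof=1)
    er = (observed - null.mean()) / sd if sd > 0 else np.nan
    p = (1.0 + np.count_nonzero(null >= observed)) / (n_perm + 1.0)
    return EnrichmentResult(gene_set.name, list_name, k, observed, float(er), float(p))


def gene_list_battery(
    pls, gene_sets: list[GeneSet], n_perm: int = 10_000, seed: int = 0
) -> list[EnrichmentResult]:
    """ER of every gene set against both PLS lists, BH-FDR over the battery.

    The FDR family is the sets within one PLS list (a battery of one set
    therefore has q = p for each list).
    """
    if not gene_sets:
        raise ValueError("need at least one gene set")
    universe = pls.weights()
    rng = np.random.default_rng(seed)
    results = []
    for list_name in ("PLS+", "PLS-"):
        per_list = []
        for gs in gene_sets:
            sub_seed = int(rng.integers(0, 2**31 - 1))
            per_list.append(
                enrichment_ratio(
                    pls.weights(list_name), universe, gs, n_perm, sub_seed, list_name=list_name
                )
            )
        _attach_q(per_list)
        results.extend(per_list)
    return results


def celltype_enrichment(
    pls, class_table: pd.Series | dict, n_perm: int = 10_000, seed: int = 0, which: str = "PLS+"
) -> list[EnrichmentResult]:
    """ER per canonical brain cell class for one PLS list (PLS+ by default)."""
    table = pd.Series(class_table)
    unknown = sorted(set(table.unique()) - set(CELL_CLASSES))
    if unknown:
        raise ValueError(f"unknown cell classes: {unknown}")
    universe = pls.weights()
    rng = np.random.default_rng(seed)
    results = []
    for cls in CELL_CLASSES:
        genes = tuple(table.index[table == cls])
        if not genes:
            results.append(EnrichmentResult(cls, which, 0, np.nan, np.nan, np.nan))
            continue
        gs = GeneSet(name=cls, genes=genes)
        sub_seed = int(rng.integers(0, 2**31 - 1))
        results.append(
            enrichment_ratio(pls.weights(which), universe, gs, n_perm, sub_seed, list_name=which)
        )
    _attach_q(results)
    return results


def _attach_q(results: list[EnrichmentResult]) -> None:
    valid = [r for r in results if not r.empty]
    if not valid:
        return
    qs = bh_fdr(np.array([r.p_perm for r in valid]))
    for r, q in zip(valid, qs):
        r.q = float(q)


def gene_list_overlap(list_a, list_b) -> tuple[float, float, float]:
    """Containment in both directions and Jaccard index of two gene lists."""
    a, b = set(list_a), set(list_b)
    if not a or not b:
        raise ValueError("gene lists must be non-empty")
    inter = len(a & b)
    return inter / len(a), inter / len(b), inter / len(a | b)
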