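"""Marker-set construction and preranked gene set enrichment analysis.

Marker sets are built by a specificity score against reference cell-type
profiles: score(gene, type) = log2(mean_in_type + eps) - log2(max mean over
other types + eps).  Enrichment uses the classic weighted Kolmogorov-
Smirnov running sum on a signed-statistic-ranked gene list, with a
gene-permutation null (random same-size sets), sign-stratified NES
normalization and an add-one Monte-Carlo p-value.
"""

from __future__ import annotations

import warnings
import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .de import bh_adjust

__all__ = [
    "GeneSet",
    "RankedList",
    "EnrichmentResult",
    "build_marker_sets",
    "gsea_preranked",
    "gsea_collection",
]


@dataclass(frozen=True)
class GeneSet:
    name: str
    members: frozenset[str]
    description: str = ""

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"gene set {self.name!r} is empty")


@dataclass
class RankedList:
    """Genes ordered by a signed statistic, descending; ties break by gene id."""

    genes: np.ndarray
    stats: np.ndarray

    @classmethod
    def from_series(cls, s: pd.Series) -> "RankedList":
        if s.index.has_duplicates:
            raise ValueError("ranked list has duplicate gene ids")
        order = sorted(range(len(s)), key=lambda i: (-s.iloc[i], s.index[i]))
        return cls(
            genes=np.asarray(s.index[order], dtype=object),
            stats=s.to_numpy(dtype=float)[order],
        )

    def __len__(self) -> int:
        return len(self.genes)


@dataclass
class EnrichmentResult:
    set_name: str
    es: float
    nes: float
    p: float
    adjp: float
    n_hits: int
    leading_edge: tuple[str, ...] = ()
    dropped_members: tuple[str, ...] = ()


def build_marker_sets(
    profiles: pd.DataFrame, k: int = 100, *, eps: float = 1.0
) -> dict[str, GeneSet]:
    """Top-k most type-specific genes per cell type.

    Specificity of a gene for a type is the log2 ratio of its mean in that
    type to its maximum mean across the other types (both offset by
    ``eps``).  Ties are broken by gene id ascending, which makes the
    selection deterministic.
    """
    if profiles.shape[1] < 2:
        raise ValueError("need >= 2 cell types")
    if k > profiles.shape[0]:
        raise ValueError(f"k={k} exceeds the {profiles.shape[0]} available genes")
    vals = profiles.to_numpy(dtype=float)
    sets: dict[str, GeneSet] = {}
    for j, ct in enumerate(profiles.columns):
        others = np.delete(vals, j, axis=1).max(axis=1)
        score = np.log2(vals[:, j] + eps) - np.log2(others + eps)
        ranking = pd.DataFrame({"score": score, "gene": profiles.index})
        ranking = ranking.sort_values(["score", "gene"], ascending=[False, True])
        top = ranking["gene"].head(k)
        sets[str(ct)] = GeneSet(name=str(ct), members=frozenset(top), description=f"top-{k} specific")
    return sets


def _es_from_hits(hit_pos: np.ndarray, hit_w: np.ndarray, n_total: int) -> tuple[float, int]:
    """Enrichment score from sorted 0-based hit positions and their weights.

    The running sum gains w_i / sum(w) at each hit and loses 1/(N - Nh) per
    miss; the ES is the extremum of largest absolute value (positive wins a
    tie).  Returns (ES, position index of the extremum).
    """
    k = hit_pos.size
    n_miss = n_total - k
    cum_hit = np.cumsum(hit_w) / hit_w.sum()
    miss_before = (hit_pos - np.arange(k)) / n_miss
    at_hit = cum_hit - miss_before            # running sum right after each hit
    before_hit = np.concatenate([[0.0], cum_hit[:-1]]) - miss_before
    i_max = int(np.argmax(at_hit))
    i_min = int(np.argmin(before_hit))
    es_pos = float(at_hit[i_max])
    es_neg = float(before_hit[i_min])
    if max(es_pos, 0.0) >= max(-es_neg, 0.0):
        return es_pos, i_max
    return es_neg, i_min


def gsea_preranked(
    ranked: RankedList,
    gene_set: GeneSet,
    *,
    weight: float = 1.0,
    n_perm: int = 10_000,
    rng: np.random.Generator | int | None = 0,
) -> EnrichmentResult:
    """Classic preranked GSEA for one set.

    Hit increments are |r_i|^weight normalized over hits; misses decrement
    uniformly.  The null is ``n_perm`` random same-size gene sets; NES is
    ES divided by the mean |null ES| of matching sign, and p is the add-one
    fraction of same-sign nulls at least as extreme.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    n = len(ranked)
    in_set = np.isin(ranked.genes, list(gene_set.members))
    dropped = tuple(sorted(gene_set.members - set(ranked.genes)))
    n_hits = int(in_set.sum())
    if n_hits == 0:
        warnings.warn(f"gene set {gene_set.name!r} has no members in the ranked list; skipped")
        return EnrichmentResult(gene_set.name, np.nan, np.nan, np.nan, np.nan, 0, (), dropped)
    if n_hits == n:
        raise ValueError("gene set covers the entire ranked list")

    w_all = np.abs(ranked.stats) ** weight
    hit_pos = np.flatnonzero(in_set)
    es, i_ext = _es_from_hits(hit_pos, w_all[hit_pos], n)

    null = np.empty(n_perm)
    for b in range(n_perm):
        pos = np.sort(rng.choice(n, size=n_hits, replace=False))
        null[b], _ = _es_from_hits(pos, w_all[pos], n)

    same_sign = null >= 0 if es >= 0 else null < 0
    n_sign = int(same_sign.sum())
    if n_sign == 0:
        p = 1.0
        nes = np.nan
    else:
        p = (1.0 + np.sum(np.abs(null[same_sign]) >= abs(es))) / (1.0 + n_sign)
        denom = float(np.mean(np.abs(null[same_sign])))
        nes = es / denom if denom > 0 else np.nan

    if es >= 0:
        leading = tuple(ranked.genes[hit_pos[: i_ext + 1]])
    else:
        leading = tuple(ranked.genes[hit_pos[i_ext:]][::-1])
    return EnrichmentResult(gene_set.name, float(es), float(nes), float(p), float(p), n_hits, leading, dropped)


def gsea_collection(
    ranked: RankedList,
    gene_sets: dict[str, GeneSet] | list[GeneSet],
    *,
    weight: float = 1.0,
    n_perm: int = 10_000,
    rng_seed: int = 0,
) -> pd.DataFrame:
    """GSEA over a collection of sets with BH correction across the family.

    Each set gets an independent substream of the seed, so results per set
    do not depend on collection order.  Returns a frame indexed by set name
    with es, nes, p, adjp, n_hits and the leading edge.
    """
    if isinstance(gene_sets, dict):
        gene_sets = list(gene_sets.values())
    if not gene_sets:
        raise ValueError("need >= 1 gene set")
    results = []
    for gs in gene_sets:
        name_key = zlib.crc32(gs.name.encode("utf-8"))
        rng = np.random.default_rng(np.random.SeedSequence([rng_seed, 211, name_key]))
        results.append(gsea_preranked(ranked, gs, weight=weight, n_perm=n_perm, rng=rng))
    usable = [r for r in results if r.n_hits > 0]
    if usable:
        adj = bh_adjust([r.p for r in usable])
        for r, a in zip(usable, adj):
            r.adjp = float(a)
    return pd.DataFrame(
        {
            "es": [r.es for r in results],
            "nes": [r.nes for r in results],
            "p": [r.p for r in results],
            "adjp": [r.adjp for r in results],
            "n_hits": [r.n_hits for r in results],
            "leading_edge": [";".join(r.leading_edge) for r in results],
        },
        index=[r.set_name for r in results],
    )
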