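"""Preranked gene-set enrichment (weighted Kolmogorov–Smirnov running sum).

Given a gene list ranked by a real-valued score (here, median marker
co-expression) and a collection of gene sets, walk the list from top to
bottom keeping a running sum: at a set member ("hit") add
``|score|^p / sum_hits |score|^p``; at a non-member subtract
``1 / (N - N_hits)``. The enrichment score (ES) is the signed deviation of
the running sum with the largest magnitude, so |ES| <= 1, with ES = 1 when
every member precedes every non-member. ``p`` is the weight exponent
(default 1, the standard "weighted" scheme; ``p = 0`` gives the classic
unweighted KS statistic).

Significance uses a gene-tag permutation null: ES of uniformly random gene
subsets of the same size. NES divides ES by the mean magnitude of same-sign
null ES values; the FDR q-value is the signed-NES ratio statistic (fraction
of pooled null NES at least as extreme over fraction of observed NES at
least as extreme, per sign, clamped to [0, 1] and made monotone in |NES|).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import GeneSetCollection, read_gmt, read_rnk

__all__ = [
    "RankedList",
    "EnrichmentScore",
    "EnrichmentResult",
    "enrichment_score",
    "permutation_null",
    "normalize_and_fdr",
    "preranked_gsea",
]

logger = logging.getLogger("tmetargets.enrichment")

DEFAULT_N_PERM = 1000
DEFAULT_WEIGHT = 1.0
DEFAULT_MIN_SIZE = 15
DEFAULT_MAX_SIZE = 500


@dataclass
class RankedList:
    """Descending (gene, score) ranking — the RNK contents."""

    genes: np.ndarray
    scores: np.ndarray

    def __post_init__(self) -> None:
        self.genes = np.asarray(self.genes, dtype=object)
        self.scores = np.asarray(self.scores, dtype=float)
        if self.genes.shape != self.scores.shape or self.genes.ndim != 1:
            raise ValueError("genes and scores must be equal-length 1-D arrays")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("ranked list contains duplicate genes")
        if np.any(np.diff(self.scores) > 0):
            raise ValueError("scores must be in descending order")

    def __len__(self) -> int:
        return len(self.genes)

    @classmethod
    def from_series(cls, series: pd.Series) -> "RankedList":
        order = sorted(series.index, key=lambda g: (-series[g], g))
        return cls(np.array(order, dtype=object), series.loc[order].to_numpy())

    @classmethod
    def from_rnk(cls, path: str | Path) -> "RankedList":
        return cls.from_series(read_rnk(path))


@dataclass(frozen=True)
class EnrichmentScore:
    es: float
    peak_index: int  # 0-based position in the ranked list where |running sum| peaks
    n_hits: int


@dataclass(frozen=True)
class EnrichmentResult:
    name: str
    size: int
    es: float
    nes: float
    pval: float
    fdr_q: float
    degenerate_null: bool = False


def _hit_weights(scores: np.ndarray, hit_mask: np.ndarray, p: float) -> np.ndarray:
    w = np.abs(scores[hit_mask]) ** p
    total = w.sum()
    if total == 0:  # all hit scores are exactly 0: fall back to equal weights
        return np.full(hit_mask.sum(), 1.0 / hit_mask.sum())
    return w / total


def _running_sum(scores: np.ndarray, hit_mask: np.ndarray, p: float) -> np.ndarray:
    n = len(scores)
    n_hits = int(hit_mask.sum())
    steps = np.empty(n)
    if n_hits == n:
        steps[:] = 0.0
    else:
        steps[:] = -1.0 / (n - n_hits)
    steps[hit_mask] = _hit_weights(scores, hit_mask, p)
    return np.cumsum(steps)


def _es_from_running(running: np.ndarray) -> tuple[float, int]:
    i_max = int(np.argmax(running))
    i_min = int(np.argmin(running))
    # cumulative float error can push the sum marginally past +/-1
    pos = float(np.clip(running[i_max], -1.0, 1.0))
    neg = float(np.clip(running[i_min], -1.0, 1.0))
    # sign ties (|pos| == |neg|, including the all-zero case) resolve positive
    if pos >= -neg:
        return pos, i_max
    return neg, i_min


def enrichment_score(
    ranked: RankedList, gene_set: Sequence[str], weight_exponent: float = DEFAULT_WEIGHT
) -> EnrichmentScore:
    """Weighted running-sum enrichment score of one gene set.

    Only members present in the ranked universe contribute; an empty
    intersection raises ``ValueError``. ``weight_exponent >= 0`` required.
    """
    if weight_exponent < 0:
        raise ValueError("weight_exponent must be >= 0")
    members = set(gene_set)
    hit_mask = np.fromiter((g in members for g in ranked.genes), bool, len(ranked))
    n_hits = int(hit_mask.sum())
    if n_hits == 0:
        raise ValueError("gene set has no member in the ranked list")
    running = _running_sum(ranked.scores, hit_mask, weight_exponent)
    es, peak = _es_from_running(running)
    return EnrichmentScore(es=es, peak_index=peak, n_hits=n_hits)


def permutation_null(
    ranked: RankedList,
    set_size: int,
    n_perm: int,
    weight_exponent: float = DEFAULT_WEIGHT,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """ES null sample: uniformly random gene subsets of ``set_size``.

    Seeded and reproducible; the null depends on the ranked scores and the
    set size only, so it is shared between equal-size sets.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    n = len(ranked)
    if not 1 <= set_size <= n:
        raise ValueError(f"set_size must be in [1, {n}]")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    out = np.empty(n_perm)
    hit_mask = np.zeros(n, dtype=bool)
    for i in range(n_perm):
        idx = rng.choice(n, size=set_size, replace=False)
        hit_mask[:] = False
        hit_mask[idx] = True
        running = _running_sum(ranked.scores, hit_mask, weight_exponent)
        out[i], _ = _es_from_running(running)
    return out


def _normalize(es: float | np.ndarray, pos_mean: float, neg_mean: float):
    """NES = ES / mean |same-sign null ES| (0 stays 0)."""
    arr = np.asarray(es, dtype=float)
    out = np.zeros_like(arr)
    if pos_mean > 0:
        out = np.where(arr > 0, arr / pos_mean, out)
    if neg_mean > 0:
        out = np.where(arr < 0, arr / neg_mean, out)
    return out if out.ndim else float(out)


def normalize_and_fdr(
    observed: Mapping[str, EnrichmentScore],
    nulls: Mapping[str, np.ndarray],
) -> list[EnrichmentResult]:
    """NES, nominal p and FDR q from per-set permutation nulls.

    Nominal p is the fraction of same-sign null ES at least as extreme as
    the observed ES, floored at ``1 / (n_perm + 1)``; a null with no
    same-sign values is degenerate and flagged. The q-value compares the
    pooled distribution of normalised null ES against the observed NES
    values per sign and is made monotone non-increasing in |NES|.
    """
    names = list(observed)
    es = np.array([observed[n].es for n in names])
    nes = np.empty_like(es)
    pvals = np.empty_like(es)
    degenerate = np.zeros(len(names), dtype=bool)
    pooled_null_nes: list[np.ndarray] = []

    for i, name in enumerate(names):
        null = np.asarray(nulls[name], dtype=float)
        n_perm = len(null)
        pos = null[null > 0]
        neg = -null[null < 0]
        pos_mean = pos.mean() if len(pos) else 0.0
        neg_mean = neg.mean() if len(neg) else 0.0
        nes[i] = _normalize(es[i], pos_mean, neg_mean)
        pooled_null_nes.append(_normalize(null, pos_mean, neg_mean))

        floor = 1.0 / (n_perm + 1)
        if es[i] > 0:
            same = pos
        elif es[i] < 0:
            same = neg
        else:
            same = np.abs(null)
        if len(same) == 0:
            pvals[i] = floor
            degenerate[i] = True
        else:
            pvals[i] = max(float((same >= abs(es[i])).mean()), floor)
        pvals[i] = min(pvals[i], 1.0)

    pool = np.concatenate(pooled_null_nes) if pooled_null_nes else np.empty(0)
    qvals = np.empty_like(es)
    for sign in (1, -1):
        side = nes > 0 if sign == 1 else nes < 0
        if sign == 1:
            side = side | (nes == 0)  # zero-NES sets live on the positive side
        idx = np.where(side)[0]
        if len(idx) == 0:
            continue
        pool_side = pool[pool > 0] if sign == 1 else pool[pool < 0]
        obs_side = nes[idx]
        for k in idx:
            v = nes[k]
            if len(pool_side) == 0:
                num = 0.0
            elif sign == 1:
                num = float((pool_side >= v).mean())
            else:
                num = float((pool_side <= v).mean())
            den = float((obs_side >= v).mean() if sign == 1 else (obs_side <= v).mean())
            qvals[k] = min(1.0, num / den) if den > 0 else 1.0
        # monotone: a more extreme NES never gets a larger q than a less extreme one
        order = idx[np.argsort(-sign * nes[idx])]  # most extreme first
        qvals[order] = np.minimum.accumulate(qvals[order][::-1])[::-1]

    return [
        EnrichmentResult(
            name=name,
            size=observed[name].n_hits,
            es=float(es[i]),
            nes=float(nes[i]),
            pval=float(pvals[i]),
            fdr_q=float(qvals[i]),
            degenerate_null=bool(degenerate[i]),
        )
        for i, name in enumerate(names)
    ]


def preranked_gsea(
    ranked: RankedList | str | Path,
    gene_sets: GeneSetCollection | str | Path,
    n_perm: int = DEFAULT_N_PERM,
    weight_exponent: float = DEFAULT_WEIGHT,
    seed: int = 0,
    min_size: int = DEFAULT_MIN_SIZE,
    max_size: int = DEFAULT_MAX_SIZE,
) -> list[EnrichmentResult]:
    """Full preranked enrichment: RNK + GMT -> results sorted by NES descending.

    Sets are restricted to the ranked universe; sets whose restricted size
    falls outside [min_size, max_size] are dropped (logged). Nulls are shared
    between equal-size sets and seeded per size, so results do not depend on
    the order of GMT lines. Raises ``ValueError`` if no set survives.
    """
    if not isinstance(ranked, RankedList):
        ranked = RankedList.from_rnk(ranked)
    if not isinstance(gene_sets, GeneSetCollection):
        gene_sets = read_gmt(gene_sets)

    universe = set(ranked.genes)
    observed: dict[str, EnrichmentScore] = {}
    sizes: dict[str, int] = {}
    n_dropped = 0
    for s in gene_sets:
        members = [g for g in s.genes if g in universe]
        if not min_size <= len(members) <= max_size:
            n_dropped += 1
            continue
        observed[s.name] = enrichment_score(ranked, members, weight_exponent)
        sizes[s.name] = len(members)
    if n_dropped:
        logger.info("dropped %d gene set(s) outside size bounds [%d, %d]",
                    n_dropped, min_size, max_size)
    if not observed:
        raise ValueError("no gene set survives universe restriction and size bounds")

    null_by_size: dict[int, np.ndarray] = {}
    for size in sorted(set(sizes.values())):
        rng = np.random.default_rng(np.random.SeedSequence((seed, size)))
        null_by_size[size] = permutation_null(
            ranked, size, n_perm, weight_exponent, seed=rng
        )
    nulls = {name: null_by_size[size] for name, size in sizes.items()}
    results = normalize_and_fdr(observed, nulls)
    return sorted(results, key=lambda r: (-r.nes, r.name))


def results_to_frame(results: Sequence[EnrichmentResult]) -> pd.DataFrame:
    """Tabulate results (name, size, ES, NES, p, q) in the given order."""
    return pd.DataFrame(
        {
            "name": [r.name for r in results],
            "size": [r.size for r in results],
            "es": [r.es for r in results],
            "nes": [r.nes for r in results],
            "pval": [r.pval for r in results],
            "fdr_q": [r.fdr_q for r in results],
        }
    )
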