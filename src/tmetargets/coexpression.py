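"""Per-cancer-type marker co-expression profiles and median-based ranking.

The screen treats bulk-tumor mRNA expression of a pan T-cell marker (CD3E by
default) as a proxy for T-cell infiltration, computes the Pearson
product-moment correlation of every gene with the marker separately within
each cancer-type cohort (pairwise-complete over samples measured for both
genes), summarises each gene by the median correlation across cancer types,
and ranks genes by that median. Signed correlations are stored and ranked
throughout; absolute values enter only the complementarity scores.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io import ExpressionMatrix

__all__ = [
    "CorrelationProfile",
    "RankedGeneTable",
    "pearson_correlation",
    "marker_correlation_profile",
    "median_across_types",
    "rank_genes",
]

#: Cells with fewer pairwise-complete samples than this are reported missing.
DEFAULT_MIN_SAMPLES = 10


@dataclass
class CorrelationProfile:
    """Gene x cancer-type Pearson correlations with one marker gene.

    ``correlations``: DataFrame (genes x types), values in [-1, 1] or NaN.
    ``n_used``: same shape, number of pairwise-complete samples per cell.
    With marker CD3E this holds rho_TC; with PDCD1, rho_TP; with CTLA4,
    rho_TA.
    """

    marker: str
    correlations: pd.DataFrame
    n_used: pd.DataFrame

    @property
    def genes(self) -> list[str]:
        return list(self.correlations.index)

    @property
    def cancer_types(self) -> list[str]:
        return list(self.correlations.columns)


@dataclass
class RankedGeneTable:
    """Genes ranked by descending median marker correlation.

    ``table`` is indexed by gene symbol with a ``median`` column, a ``rank``
    column (1 = largest median; ties broken by ascending symbol; genes with
    no observable median get NaN rank and sort last) and, when built from a
    profile, one column per cancer type.
    """

    marker: str
    table: pd.DataFrame

    @property
    def medians(self) -> pd.Series:
        return self.table["median"]

    @property
    def ranks(self) -> pd.Series:
        return self.table["rank"]


def pearson_correlation(x: Sequence[float], y: Sequence[float]) -> float:
    """Pairwise-complete Pearson product-moment correlation.

    Restricted to indices where both vectors are non-missing. Returns NaN
    when fewer than two complete pairs remain or either restricted vector
    has zero variance. Raises ``ValueError`` on length mismatch.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    mask = np.isfinite(x) & np.isfinite(y)
    if mask.sum() < 2:
        return float("nan")
    xs, ys = x[mask], y[mask]
    if np.ptp(xs) == 0 or np.ptp(ys) == 0:
        return float("nan")
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(xs, ys)[0, 1]
    if np.isnan(r):  # nonzero range but vanishing variance (subnormal values)
        return float("nan")
    return float(np.clip(r, -1.0, 1.0))


def _profile_one_cohort(
    matrix: ExpressionMatrix, marker: str, genes: Sequence[str]
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised pairwise-complete correlation of every gene vs the marker.

    Returns (correlations, n_used) aligned to ``genes``; genes absent from
    the cohort yield NaN / 0.
    """
    m = matrix.data.loc[marker].to_numpy(dtype=float)
    present = [g for g in genes if g in matrix.data.index]
    X = matrix.data.loc[present].to_numpy(dtype=float)

    valid = np.isfinite(X) & np.isfinite(m)[None, :]
    n = valid.sum(axis=1).astype(float)
    Xv = np.where(valid, X, 0.0)
    Mv = np.where(valid, m[None, :], 0.0)
    sx = Xv.sum(axis=1)
    sm = Mv.sum(axis=1)
    sxx = (Xv * Xv).sum(axis=1)
    smm = (Mv * Mv).sum(axis=1)
    sxm = (Xv * Mv).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        cov = sxm - sx * sm / np.where(n > 0, n, np.nan)
        var_x = sxx - sx * sx / np.where(n > 0, n, np.nan)
        var_m = smm - sm * sm / np.where(n > 0, n, np.nan)
        r = cov / np.sqrt(var_x * var_m)
    bad = (n < 2) | ~(var_x > 0) | ~(var_m > 0)
    r = np.where(bad, np.nan, np.clip(r, -1.0, 1.0))

    lookup = dict(zip(present, range(len(present))))
    out_r = np.full(len(genes), np.nan)
    out_n = np.zeros(len(genes))
    for i, g in enumerate(genes):
        j = lookup.get(g)
        if j is not None:
            out_r[i] = r[j]
            out_n[i] = n[j]
    return out_r, out_n


def marker_correlation_profile(
    cohorts: Mapping[str, ExpressionMatrix] | Iterable[ExpressionMatrix],
    marker: str,
    gene_universe: Sequence[str] | None = None,
    min_samples: int = DEFAULT_MIN_SAMPLES,
    excluded_types: Sequence[str] = (),
) -> CorrelationProfile:
    """Correlate every gene with ``marker`` within each cancer-type cohort.

    Parameters
    ----------
    cohorts
        Mapping of cancer-type label to :class:`ExpressionMatrix`, or an
        iterable of matrices (labelled by their ``cancer_type``).
    marker
        Anchor gene symbol; must be present in every non-excluded cohort.
    gene_universe
        Ordered gene symbols to profile. Defaults to the sorted union of
        genes across the non-excluded cohorts.
    min_samples
        Cells with fewer pairwise-complete samples are set missing.
    excluded_types
        Cohort labels dropped before profiling (e.g. thymoma, whose tumors
        derive from the organ where T cells mature and distort the
        infiltration signal).
    """
    if isinstance(cohorts, Mapping):
        by_type = dict(cohorts)
    else:
        by_type = {}
        for m in cohorts:
            if m.cancer_type in by_type:
                raise ValueError(f"duplicate cancer-type label {m.cancer_type!r}")
            by_type[m.cancer_type] = m
    excluded = set(excluded_types)
    by_type = {t: m for t, m in by_type.items() if t not in excluded}
    if not by_type:
        raise ValueError("no cohorts remain after exclusion")

    for label, matrix in by_type.items():
        if marker not in matrix.data.index:
            raise ValueError(f"marker {marker!r} absent from cohort {label!r}")

    if gene_universe is None:
        universe: list[str] = sorted(set().union(*(m.data.index for m in by_type.values())))
    else:
        universe = list(gene_universe)
        if not universe:
            raise ValueError("gene_universe is empty")
        if len(universe) != len(set(universe)):
            raise ValueError("gene_universe contains duplicates")

    labels = sorted(by_type)
    corr = np.empty((len(universe), len(labels)))
    used = np.empty_like(corr)
    for j, label in enumerate(labels):
        r, n = _profile_one_cohort(by_type[label], marker, universe)
        r = np.where(n < min_samples, np.nan, r)
        corr[:, j] = r
        used[:, j] = n
    return CorrelationProfile(
        marker=marker,
        correlations=pd.DataFrame(corr, index=universe, columns=labels),
        n_used=pd.DataFrame(used, index=universe, columns=labels),
    )


def median_across_types(profile: CorrelationProfile) -> pd.Series:
    """Per-gene median correlation over non-missing cancer types.

    Even counts average the two central values; a gene missing in every type
    yields NaN.
    """
    return profile.correlations.median(axis=1, skipna=True)


def _rank_series(values: pd.Series) -> pd.Series:
    """Dense 1..k ranks, descending by value, ties by ascending symbol; NaN last."""
    present = values.dropna()
    order = sorted(present.index, key=lambda g: (-present[g], g))
    ranks = pd.Series(np.nan, index=values.index, dtype=float)
    for i, g in enumerate(order, start=1):
        ranks[g] = i
    return ranks


def rank_genes(
    medians: pd.Series,
    profile: CorrelationProfile | None = None,
    marker: str = "",
) -> RankedGeneTable:
    """Rank genes by descending median correlation (rank 1 = largest).

    Ties are broken by ascending gene symbol; genes with missing medians are
    placed last with missing rank. Raises ``ValueError`` if every median is
    missing.
    """
    if medians.dropna().empty:
        raise ValueError("no gene has a non-missing median")
    ranks = _rank_series(medians)
    order = sorted(
        medians.index,
        key=lambda g: (np.isnan(ranks[g]), ranks[g] if not np.isnan(ranks[g]) else 0, g),
    )
    table = pd.DataFrame({"median": medians, "rank": ranks}).loc[order]
    if profile is not None:
        table = profile.correlations.loc[order].join(table)
        marker = marker or profile.marker
    return RankedGeneTable(marker=marker, table=table)
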