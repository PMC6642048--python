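"""Checkpoint-complementarity scoring of candidate immunotherapy targets.

A good complementary target tracks T-cell abundance (high |rho_TC|, the
absolute correlation with the pan T-cell marker) while overlapping little in
expression with an already-targeted checkpoint (low |rho_TP| for PD-1, low
|rho_TA| for CTLA-4):

    PDCD1 complementarity:  |rho_TC| * (|rho_TC| - |rho_TP|)
    joint complementarity:  |rho_TC| * min(|rho_TC| - |rho_TP|,
                                           |rho_TC| - |rho_TA|)

Scores are computed per cancer type from that type's correlations and then
summarised by the median across types (not computed once from median
correlations — the two orders differ). Both scores lie in [-1, 1]; the joint
score reduces to the PDCD1 score when |rho_TA| <= |rho_TP|.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .coexpression import CorrelationProfile, _rank_series

__all__ = [
    "ComplementarityTable",
    "pdcd1_complementarity",
    "joint_complementarity",
    "complementarity_table",
    "filter_positive_scores",
]


def _check_correlation(value, name: str):
    arr = np.asarray(value, dtype=float)
    with np.errstate(invalid="ignore"):
        bad = np.abs(arr) > 1.0
    if np.any(bad & np.isfinite(arr)):
        raise ValueError(f"{name} outside [-1, 1]")
    return arr


def pdcd1_complementarity(rho_tc, rho_tp):
    """|rho_TC| * (|rho_TC| - |rho_TP|); NaN if either input is missing.

    Accepts scalars or arrays; inputs outside [-1, 1] raise ``ValueError``.
    """
    tc = np.abs(_check_correlation(rho_tc, "rho_tc"))
    tp = np.abs(_check_correlation(rho_tp, "rho_tp"))
    out = tc * (tc - tp)
    if out.ndim == 0:
        return float(out)
    return out


def joint_complementarity(rho_tc, rho_tp, rho_ta):
    """|rho_TC| * min(|rho_TC| - |rho_TP|, |rho_TC| - |rho_TA|).

    NaN if any input is missing; scalars or arrays; inputs outside [-1, 1]
    raise ``ValueError``.
    """
    tc = np.abs(_check_correlation(rho_tc, "rho_tc"))
    tp = np.abs(_check_correlation(rho_tp, "rho_tp"))
    ta = np.abs(_check_correlation(rho_ta, "rho_ta"))
    out = tc * np.minimum(tc - tp, tc - ta)
    if out.ndim == 0:
        return float(out)
    return out


@dataclass
class ComplementarityTable:
    """Per-gene complementarity scores, medians and dual ranking.

    ``table`` is indexed by gene, ordered by score rank, with one score
    column per cancer type plus ``median_score``, ``score_rank``,
    ``median_rho_tc`` and ``rho_tc_rank`` (the side-by-side "CS" and marker
    co-expression ranks).
    """

    score_kind: str
    table: pd.DataFrame

    @property
    def median_scores(self) -> pd.Series:
        return self.table["median_score"]


def complementarity_table(
    profile_tc: CorrelationProfile,
    profile_tp: CorrelationProfile,
    profile_ta: CorrelationProfile | None = None,
    score_kind: str = "pdcd1",
) -> ComplementarityTable:
    """Score every gene per cancer type, median across types, rank descending.

    ``profile_tc`` anchors the gene universe; the checkpoint profiles must
    cover the same cancer types (``ValueError`` listing the difference
    otherwise). A (gene, type) cell missing in any required profile yields a
    missing score for that cell, excluded from the gene's median.
    """
    if score_kind not in ("pdcd1", "joint"):
        raise ValueError(f"unknown score_kind {score_kind!r}")
    if score_kind == "joint" and profile_ta is None:
        raise ValueError("joint score requires a CTLA4 correlation profile")

    profiles = [profile_tc, profile_tp] + ([profile_ta] if profile_ta is not None else [])
    base = set(profile_tc.cancer_types)
    for prof in profiles[1:]:
        other = set(prof.cancer_types)
        if other != base:
            diff = sorted(base.symmetric_difference(other))
            raise ValueError(
                f"cancer-type sets differ between profiles (markers "
                f"{profile_tc.marker!r} vs {prof.marker!r}): {diff}"
            )

    genes = profile_tc.correlations.index
    types = profile_tc.correlations.columns
    tc = profile_tc.correlations
    tp = profile_tp.correlations.reindex(index=genes, columns=types)
    if score_kind == "pdcd1":
        scores = pd.DataFrame(
            pdcd1_complementarity(tc.to_numpy(), tp.to_numpy()),
            index=genes,
            columns=types,
        )
    else:
        ta = profile_ta.correlations.reindex(index=genes, columns=types)
        scores = pd.DataFrame(
            joint_complementarity(tc.to_numpy(), tp.to_numpy(), ta.to_numpy()),
            index=genes,
            columns=types,
        )

    median_score = scores.median(axis=1, skipna=True)
    median_tc = tc.median(axis=1, skipna=True)
    score_rank = _rank_series(median_score)
    tc_rank = _rank_series(median_tc)
    table = scores.copy()
    table["median_score"] = median_score
    table["score_rank"] = score_rank
    table["median_rho_tc"] = median_tc
    table["rho_tc_rank"] = tc_rank
    order = sorted(
        table.index,
        key=lambda g: (
            np.isnan(score_rank[g]),
            score_rank[g] if not np.isnan(score_rank[g]) else 0,
            g,
        ),
    )
    return ComplementarityTable(score_kind=score_kind, table=table.loc[order])


def filter_positive_scores(table: ComplementarityTable) -> ComplementarityTable:
    """Reporting view retaining genes with median score > 0, order preserved."""
    keep = table.table["median_score"] > 0
    return ComplementarityTable(score_kind=table.score_kind, table=table.table[keep])
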