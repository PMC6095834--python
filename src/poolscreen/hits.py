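"""Gene-level aggregation and four-criterion lethal-hit calling.

A gene is called a lethal hit in a cell line when (1) at least one of its
hairpins is significantly depleted (p below ``p_max``) with a fold change
below ``fc_hairpin_max``, (2) the geometric mean fold change of all its
retained hairpins is below ``geomean_max``, and (3) the gene ranks within
the top ``rank_max`` by second-best hairpin rank — the RIGER-style statistic
that guards against single off-target hairpins by requiring at least two
functional hairpins.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ParameterError


@dataclass(frozen=True)
class HitCriteria:
    """Thresholds of the four-criterion hit definition (all configurable)."""

    p_max: float = 0.1
    fc_hairpin_max: float = 0.3
    geomean_max: float = 0.8
    rank_max: int = 100
    #: if True, the p-criterion uses the gene-level minimum p instead of
    #: requiring p and fold change on the same hairpin
    gene_level_p: bool = False

    def __post_init__(self) -> None:
        if min(self.p_max, self.fc_hairpin_max, self.geomean_max) <= 0:
            raise ParameterError("thresholds must be > 0")
        if self.rank_max < 1:
            raise ParameterError("rank_max must be >= 1")


def gene_aggregate(
    results: pd.DataFrame, criteria: HitCriteria | None = None
) -> pd.DataFrame:
    """Aggregate retained hairpin results per gene.

    ``results`` is a per-hairpin frame with columns gene, fc, log2fc,
    p_value, retained (as produced by
    :func:`poolscreen.depletion.hairpin_depletion_table`).  Genes with zero
    retained hairpins are omitted.  Returns a frame indexed by gene with
    n_hairpins, min_fc, geom_mean_fc, max_fc, best_depleted_p (minimum p
    among hairpins below the fold-change threshold; NaN if none) and the
    significant-depletion indicator used by the hit call.
    """
    if results.empty:
        raise ParameterError("empty results table")
    if criteria is None:
        criteria = HitCriteria()
    kept = results[results["retained"]]

    def summarize(g: pd.DataFrame) -> pd.Series:
        fc = g["fc"].to_numpy()
        depleted = g["fc"] < criteria.fc_hairpin_max
        best_p = g.loc[depleted, "p_value"].min() if depleted.any() else np.nan
        if criteria.gene_level_p:
            sig = depleted.any() and (g["p_value"] < criteria.p_max).any()
        else:
            sig = bool(
                (depleted & (g["p_value"] < criteria.p_max)).any()
            )
        return pd.Series(
            {
                "n_hairpins": len(g),
                "min_fc": fc.min(),
                "geom_mean_fc": float(np.exp(np.mean(np.log(fc)))),
                "max_fc": fc.max(),
                "best_depleted_p": best_p,
                "has_significant_depletion": sig,
            }
        )

    out = kept.groupby("gene", sort=True)[["fc", "p_value"]].apply(summarize)
    out["n_hairpins"] = out["n_hairpins"].astype(int)
    return out


def second_best_ranking(
    results: pd.DataFrame, summaries: pd.DataFrame
) -> pd.DataFrame:
    """Fill in second-best hairpin ranks and the derived gene ranking.

    Retained hairpins are ranked 1..H ascending by log2 fold change (most
    depleted first; ties broken by smaller p, then hairpin id).  Each gene's
    score is the rank of its second-most-depleted hairpin; genes with fewer
    than two retained hairpins receive the sentinel worst rank H + 1.
    Genes are then ordered ascending by that score (ties by best hairpin
    rank, then gene symbol) to give ``gene_rank``.
    """
    kept = results[results["retained"]].copy()
    order = kept.assign(_hp=kept.index).sort_values(
        ["log2fc", "p_value", "_hp"], kind="mergesort"
    )
    ranks = pd.Series(np.arange(1, len(order) + 1), index=order.index)
    sentinel = len(order) + 1

    out = summaries.copy()
    second_best = pd.Series(sentinel, index=out.index, dtype=int)
    best = pd.Series(sentinel, index=out.index, dtype=int)
    for gene, g in kept.groupby("gene"):
        r = np.sort(ranks[g.index].to_numpy())
        best[gene] = int(r[0])
        second_best[gene] = int(r[1]) if len(r) >= 2 else sentinel
    out["second_best_rank"] = second_best
    out["best_rank"] = best

    gene_order = out.assign(_g=out.index).sort_values(
        ["second_best_rank", "best_rank", "_g"], kind="mergesort"
    )
    out["gene_rank"] = pd.Series(
        np.arange(1, len(out) + 1), index=gene_order.index
    )
    return out


def call_hits(
    summaries: pd.DataFrame, criteria: HitCriteria | None = None
) -> pd.DataFrame:
    """Apply the four-criterion hit definition and return the hit list.

    Adds the boolean criterion flags and ``is_hit`` (their conjunction,
    additionally requiring >= 2 retained hairpins) to the summaries and
    returns the hits sorted by gene rank.
    """
    if criteria is None:
        criteria = HitCriteria()
    s = summaries
    s["crit_significant_p"] = s["has_significant_depletion"].astype(bool)
    s["crit_fc"] = s["min_fc"] < criteria.fc_hairpin_max
    s["crit_geomean"] = s["geom_mean_fc"] < criteria.geomean_max
    s["crit_rank"] = s["gene_rank"] <= criteria.rank_max
    s["is_hit"] = (
        s["crit_significant_p"]
        & s["crit_fc"]
        & s["crit_geomean"]
        & s["crit_rank"]
        & (s["n_hairpins"] >= 2)
    )
    return s[s["is_hit"]].sort_values("gene_rank")


def score_line(
    results: pd.DataFrame, criteria: HitCriteria | None = None
) -> pd.DataFrame:
    """Convenience: aggregate, rank and flag one line's hairpin results.

    Returns the full gene summary table (hits and non-hits) with all
    criterion flags; filter on ``is_hit`` for the hit list.
    """
    if criteria is None:
        criteria = HitCriteria()
    summaries = gene_aggregate(results, criteria)
    summaries = second_best_ranking(results, summaries)
    call_hits(summaries, criteria)
    return summaries.sort_values("gene_rank")
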