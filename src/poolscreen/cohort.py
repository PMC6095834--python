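"""Cross-cell-line analysis: common vs genotype-specific lethality,
drug-sensitivity classification, exact association tests and the
two-group sample-size calculation.

The central object is the hit matrix — a boolean gene x cell-line table of
per-line lethal-hit calls with a genotype label (wildtype/mutant) per line.
Genotype specificity of a gene is summarised by the difference in hit
fractions between mutant and wildtype lines, with a two-sided Fisher exact
test on the underlying 2x2 table.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ParameterError, ValidationError

GENOTYPES = ("wildtype", "mutant")


@dataclass
class HitMatrix:
    """Boolean gene x cell-line hit calls plus per-line genotype labels."""

    matrix: pd.DataFrame
    genotypes: pd.Series
    gene_ranks: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        missing = self.matrix.columns.difference(self.genotypes.index).tolist()
        if missing:
            raise ValidationError(f"lines without genotype label: {missing}")
        self.genotypes = self.genotypes.loc[self.matrix.columns]
        bad = set(self.genotypes) - set(GENOTYPES)
        if bad:
            raise ValidationError(f"unknown genotypes {sorted(bad)}")

    @property
    def lines(self) -> list[str]:
        return list(self.matrix.columns)

    def lines_of(self, genotype: str) -> list[str]:
        return self.genotypes.index[self.genotypes == genotype].tolist()


def build_hit_matrix(
    hits_per_line: Mapping[str, Sequence[str] | pd.DataFrame],
    genotypes: pd.Series,
) -> HitMatrix:
    """Assemble per-line hit lists into a gene x line boolean matrix.

    Values of ``hits_per_line`` may be plain gene lists or per-line gene
    summary frames (indexed by gene, with ``is_hit`` and ``gene_rank``
    columns); in the latter case gene ranks are carried along for
    rank-aware downstream ordering.  Genes absent from a line's list are
    False for that line.
    """
    gene_lists: dict[str, list[str]] = {}
    ranks: dict[str, pd.Series] = {}
    for line, hits in hits_per_line.items():
        if line not in genotypes.index:
            raise ValidationError(f"line {line!r} has no genotype label")
        if isinstance(hits, pd.DataFrame):
            gene_lists[line] = hits.index[hits["is_hit"]].tolist()
            ranks[line] = hits["gene_rank"]
        else:
            gene_lists[line] = list(hits)
    all_genes = sorted(set().union(*gene_lists.values())) if gene_lists else []
    matrix = pd.DataFrame(False, index=all_genes, columns=list(gene_lists))
    for line, genes in gene_lists.items():
        matrix.loc[genes, line] = True
    rank_frame = (
        pd.DataFrame({ln: r.reindex(all_genes) for ln, r in ranks.items()})
        if ranks
        else None
    )
    return HitMatrix(matrix, genotypes.loc[list(gene_lists)], rank_frame)


def common_lethals(hm: HitMatrix, min_fraction: float = 1.0) -> pd.DataFrame:
    """Genes hit in at least ``min_fraction`` of all lines, ranked.

    Ordered by descending hit fraction, then (when per-line gene ranks are
    available) ascending mean gene rank, then gene symbol.
    """
    frac = hm.matrix.mean(axis=1)
    out = pd.DataFrame({"hit_fraction": frac, "n_hit": hm.matrix.sum(axis=1)})
    if hm.gene_ranks is not None:
        out["mean_gene_rank"] = hm.gene_ranks.mean(axis=1)
    else:
        out["mean_gene_rank"] = np.nan
    out = out[out["hit_fraction"] >= min_fraction]
    out = out.assign(_g=out.index).sort_values(
        ["hit_fraction", "mean_gene_rank", "_g"],
        ascending=[False, True, True],
        kind="mergesort",
        na_position="last",
    ).drop(columns="_g")
    return out


def fisher_exact_2x2(table: Sequence[Sequence[int]] | np.ndarray) -> float:
    """Two-sided Fisher exact p-value for a 2x2 contingency table.

    Uses the minimum-likelihood rule: the p-value sums the hypergeometric
    probabilities of every table with the same margins that is no more
    probable than the observed one.  Degenerate tables (an empty margin)
    return 1.
    """
    arr = np.asarray(table)
    if arr.shape != (2, 2):
        raise ParameterError("table must be 2x2")
    if np.any(arr < 0) or np.any(arr != np.floor(arr)):
        raise ParameterError("cells must be non-negative integers")
    arr = arr.astype(np.int64)
    if arr.sum(axis=0).min() == 0 or arr.sum(axis=1).min() == 0:
        return 1.0
    return float(stats.fisher_exact(arr, alternative="two-sided")[1])


def genotype_specific(hm: HitMatrix) -> pd.DataFrame:
    """Rank genes by preferential lethality in mutant lines.

    For each gene the hit counts among mutant and wildtype lines give a
    specificity score (difference of hit fractions, in [-1, 1]) and a
    two-sided Fisher exact p-value on the 2x2 genotype x hit table.
    Ranked by descending score, ties by ascending p, then gene symbol.
    """
    mut = hm.lines_of("mutant")
    wt = hm.lines_of("wildtype")
    if not mut or not wt:
        raise ValidationError("both genotypes must be present")
    n_mut, n_wt = len(mut), len(wt)
    rows = []
    for gene in hm.matrix.index:
        h_mut = int(hm.matrix.loc[gene, mut].sum())
        h_wt = int(hm.matrix.loc[gene, wt].sum())
        score = h_mut / n_mut - h_wt / n_wt
        p = fisher_exact_2x2(
            [[h_mut, n_mut - h_mut], [h_wt, n_wt - h_wt]]
        )
        rows.append((gene, h_mut, h_wt, n_mut, n_wt, score, p))
    out = pd.DataFrame(
        rows,
        columns=["gene", "n_hit_mut", "n_hit_wt", "n_mut", "n_wt",
                 "specificity_score", "fisher_p"],
    ).set_index("gene")
    return out.assign(_g=out.index).sort_values(
        ["specificity_score", "fisher_p", "_g"],
        ascending=[False, True, True],
        kind="mergesort",
    ).drop(columns="_g")


# ---------------------------------------------------------------------------
# Drug-sensitivity classification


def relative_growth(
    dose_response: pd.DataFrame, line: str, dose: float, drug: str | None = None
) -> float:
    """Mean signal at ``dose`` over mean signal at dose 0 for one line.

    Replicates are averaged per dose before the ratio is taken (the
    convention for normalizing a stained-plate mean to its untreated
    control).  ``dose_response`` needs columns cell_line, dose, signal
    (and optionally drug, replicate).
    """
    sub = dose_response[dose_response["cell_line"] == line]
    if drug is not None and "drug" in sub.columns:
        sub = sub[sub["drug"] == drug]
    at = sub.loc[sub["dose"] == dose, "signal"]
    ref = sub.loc[sub["dose"] == 0, "signal"]
    if at.empty or ref.empty:
        raise ParameterError(
            f"line {line!r}: missing dose {dose} or untreated control"
        )
    return float(at.mean() / ref.mean())


def classify_sensitivity(
    dose_response: pd.DataFrame,
    reference_dose: float = 250.0,
    cutoff: float = 0.5,
    drug: str | None = None,
) -> pd.DataFrame:
    """Call each line sensitive iff relative growth at the reference dose
    is strictly below the cutoff (default: below 0.5 at 250 nM)."""
    lines = dose_response["cell_line"].unique()
    rows = []
    for line in lines:
        rg = relative_growth(dose_response, line, reference_dose, drug)
        rows.append((line, rg, rg < cutoff))
    return pd.DataFrame(
        rows, columns=["cell_line", "relative_growth", "sensitive"]
    ).set_index("cell_line").assign(cutoff=cutoff, reference_dose=reference_dose)


def sensitivity_association(
    calls: pd.DataFrame, genotypes: pd.Series
) -> tuple[np.ndarray, float]:
    """2x2 table [[wt_sensitive, wt_resistant], [mut_sensitive,
    mut_resistant]] and its two-sided Fisher exact p-value."""
    sens = calls["sensitive"]
    geno = genotypes.loc[calls.index]
    table = np.array(
        [
            [int(sens[geno == "wildtype"].sum()),
             int((~sens[geno == "wildtype"]).sum())],
            [int(sens[geno == "mutant"].sum()),
             int((~sens[geno == "mutant"]).sum())],
        ]
    )
    return table, fisher_exact_2x2(table)


# ---------------------------------------------------------------------------
# Study-design power calculation


def sample_size_two_group(
    alpha: float = 0.05,
    power: float = 0.8,
    effect: float = 0.5,
    cv: float = 0.25,
) -> int:
    """Per-group sample size for a two-group comparison of means.

    Normal-approximation formula with the standard deviation expressed as a
    coefficient of variation of the control mean and the effect as a
    relative reduction:

        n = ceil( 2 * (z_{1-alpha/2} + z_{power})^2 * (cv / effect)^2 )

    With alpha 0.05, power 0.8, a 50% reduction and CV 25% this gives 4
    per group.
    """
    if not 0 < alpha < 1 or not 0 < power < 1:
        raise ParameterError("alpha and power must be in (0, 1)")
    if not 0 < effect < 1:
        raise ParameterError("effect must be a relative reduction in (0, 1)")
    if cv <= 0:
        raise ParameterError("cv must be > 0")
    z_a = stats.norm.ppf(1 - alpha / 2)
    z_b = stats.norm.ppf(power)
    n = 2 * (z_a + z_b) ** 2 * (cv / effect) ** 2
    return max(1, math.ceil(n))
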