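"""Normalization and per-hairpin T1-vs-T0 differential abundance testing.

This module re-implements the classic negative-binomial screen analysis:
median-of-ratios size factors, method-of-moments dispersion estimation with
a fitted mean-dispersion curve, and a conditional exact test on the summed
counts of the two timepoints.  Per-hairpin fold changes are computed on
normalized means with a small pseudocount; hairpins too lowly represented
at T0 to show depletion are dropped.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from .errors import DispersionError, NormalizationError, ParameterError
from .screen_io import CountTable, HairpinLibrary

#: conditioned sums above this are tested with a normal approximation
ENUMERATION_MAX = 5000


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors.

    For each hairpin *i* with strictly positive counts in every sample, the
    ratio of the count in sample *j* to the hairpin's geometric mean across
    samples is formed; the size factor of sample *j* is the median of these
    ratios.  Invariant under row permutation, equivariant under column
    scaling.
    """
    arr = counts.to_numpy(dtype=float)
    positive = np.all(arr > 0, axis=1)
    if not positive.any():
        raise NormalizationError(
            "no hairpin has strictly positive counts in all samples"
        )
    logs = np.log(arr[positive])
    log_geomean = logs.mean(axis=1, keepdims=True)
    s = np.exp(np.median(logs - log_geomean, axis=0))
    return pd.Series(s, index=counts.columns, name="size_factor")


@dataclass
class DispersionFit:
    """Per-hairpin NB dispersions with a fitted mean-dispersion curve.

    ``alpha_raw`` are method-of-moments estimates (floored at 0), the curve
    is ``alpha_fit(mu) = a0 + a1 / mu``, and ``alpha`` is the per-hairpin
    maximum of raw and fitted value — a conservative sharing rule.
    """

    mu: pd.Series
    alpha_raw: pd.Series
    a0: float
    a1: float
    alpha: pd.Series

    def fitted(self, mu: np.ndarray | float) -> np.ndarray | float:
        return np.maximum(self.a0 + self.a1 / np.asarray(mu, dtype=float), 0.0)


def _robust_curve_fit(mu: np.ndarray, alpha_raw: np.ndarray) -> tuple[float, float]:
    """Fit alpha = a0 + a1/mu robustly (soft-L1 loss, non-negative params)."""
    x = 1.0 / mu

    def resid(theta):
        return alpha_raw - (theta[0] + theta[1] * x)

    scale = np.median(np.abs(alpha_raw - np.median(alpha_raw))) or 0.01
    start = np.array([max(np.median(alpha_raw), 1e-8), 1.0])
    sol = optimize.least_squares(
        resid, start, bounds=([0.0, 0.0], [np.inf, np.inf]),
        loss="soft_l1", f_scale=float(scale),
    )
    return float(sol.x[0]), float(sol.x[1])


def estimate_dispersions(
    counts: pd.DataFrame,
    factors: pd.Series,
    condition: pd.Series,
    *,
    blind: bool = False,
) -> DispersionFit:
    """Method-of-moments dispersion estimation with curve sharing.

    Per condition with >= 2 replicates, the variance of normalized counts
    across replicates is decomposed into shot noise (``mu * mean(1/s_j)``)
    and excess variance ``alpha * mu^2``; raw estimates are pooled across
    conditions weighted by degrees of freedom and floored at zero.  A
    robust fit of ``a0 + a1/mu`` shares information across hairpins; the
    final dispersion is the maximum of raw and fitted value.

    With ``blind=True`` all samples are treated as one replicate group —
    required when a condition has a single replicate (conservative: real
    signal inflates the estimate).
    """
    factors = factors.loc[counts.columns]
    condition = condition.loc[counts.columns]
    groups = (
        {"all": list(counts.columns)}
        if blind
        else {c: condition.index[condition == c].tolist()
              for c in condition.unique()}
    )
    usable = {c: cols for c, cols in groups.items() if len(cols) >= 2}
    if not usable:
        raise DispersionError(
            "every condition has a single replicate; pass blind=True to pool "
            "all samples (conservative)"
        )
    if not blind and len(usable) < len(groups):
        raise DispersionError(
            "a condition has a single replicate; pass blind=True to pool"
        )

    norm = counts / factors
    mu_all = norm.mean(axis=1)

    num = pd.Series(0.0, index=counts.index)
    den = 0.0
    for cols in usable.values():
        sub = norm[cols]
        mu_c = sub.mean(axis=1)
        w_c = sub.var(axis=1, ddof=1)
        z_c = mu_c * float((1.0 / factors[cols]).mean())
        with np.errstate(divide="ignore", invalid="ignore"):
            alpha_c = (w_c - z_c) / mu_c**2
        alpha_c = alpha_c.replace([np.inf, -np.inf], np.nan).fillna(0.0)
        df = len(cols) - 1
        num += df * alpha_c.clip(lower=0.0)
        den += df
    alpha_raw = num / den

    ok = mu_all > 0
    if ok.sum() < 2:
        a0, a1 = float(alpha_raw.max()), 0.0
    else:
        a0, a1 = _robust_curve_fit(
            mu_all[ok].to_numpy(), alpha_raw[ok].to_numpy()
        )
    fitted = pd.Series(0.0, index=counts.index)
    fitted[ok] = np.maximum(a0 + a1 / mu_all[ok], 0.0)
    alpha = np.maximum(alpha_raw, fitted)
    return DispersionFit(mu=mu_all, alpha_raw=alpha_raw, a0=a0, a1=a1,
                         alpha=alpha)


# ---------------------------------------------------------------------------
# Conditional exact test


def _nb_logpmf(k: np.ndarray, mean: float, var: float) -> np.ndarray:
    """log PMF of an NB (or Poisson when var <= mean) with given moments."""
    k = np.asarray(k)
    if var <= mean or mean == 0:
        return stats.poisson.logpmf(k, mean)
    p = mean / var
    r = mean * mean / (var - mean)
    return stats.nbinom.logpmf(k, r, p)


def nb_exact_test(
    k_t0: np.ndarray,
    k_t1: np.ndarray,
    factors_t0: np.ndarray,
    factors_t1: np.ndarray,
    alpha: float,
    *,
    enumeration_max: int = ENUMERATION_MAX,
) -> float:
    """Two-sided conditional NB test of differential abundance.

    The replicate counts of each condition are summed; conditioning on the
    grand total ``K``, the p-value is the probability mass of all splits
    ``(a, K - a)`` no more likely than the observed one, divided by the
    total conditional mass.  Each condition's sum is modelled as NB with
    mean ``q0 * sum(s_j)`` and variance ``q0 * sum(s_j) +
    alpha * q0^2 * sum(s_j^2)``, where ``q0`` is the pooled mean of
    normalized counts.

    For ``K`` beyond ``enumeration_max`` the conditional distribution is
    replaced by its normal approximation (continuity-corrected, two-sided).
    Returns a p-value in (0, 1]; a grand total of zero is degenerate and
    returns 1.
    """
    if alpha < 0:
        raise ParameterError("alpha must be >= 0")
    k_t0 = np.asarray(k_t0, dtype=float)
    k_t1 = np.asarray(k_t1, dtype=float)
    s0 = np.asarray(factors_t0, dtype=float)
    s1 = np.asarray(factors_t1, dtype=float)
    if np.any(s0 <= 0) or np.any(s1 <= 0):
        raise ParameterError("size factors must be positive")

    ka, kb = float(k_t0.sum()), float(k_t1.sum())
    total = int(round(ka + kb))
    if total == 0:
        return 1.0

    q0 = float((np.concatenate([k_t0 / s0, k_t1 / s1])).mean())
    sa, sb = float(s0.sum()), float(s1.sum())
    mu_a, mu_b = q0 * sa, q0 * sb
    var_a = mu_a + alpha * q0 * q0 * float((s0 * s0).sum())
    var_b = mu_b + alpha * q0 * q0 * float((s1 * s1).sum())

    if total > enumeration_max:
        # normal approximation to the conditional law of the T0 sum
        w = var_a / (var_a + var_b)
        m = mu_a + (total - mu_a - mu_b) * w
        sd = np.sqrt(var_a * var_b / (var_a + var_b))
        lo = stats.norm.cdf((ka + 0.5 - m) / sd)
        hi = stats.norm.sf((ka - 0.5 - m) / sd)
        return float(min(1.0, 2.0 * min(lo, hi)))

    a = np.arange(total + 1)
    logp = _nb_logpmf(a, mu_a, var_a) + _nb_logpmf(total - a, mu_b, var_b)
    log_obs = logp[int(round(ka))]
    log_den = special.logsumexp(logp)
    qualify = logp <= log_obs + 1e-7
    log_num = special.logsumexp(logp[qualify])
    return float(min(1.0, np.exp(log_num - log_den)))


# ---------------------------------------------------------------------------
# Per-line hairpin depletion tables


def hairpin_depletion_table(
    table: CountTable,
    line: str,
    library: HairpinLibrary | None = None,
    *,
    abundance_floor: float = 30.0,
    pseudocount: float = 0.5,
    enumeration_max: int = ENUMERATION_MAX,
) -> pd.DataFrame:
    """Per-hairpin depletion results (fold change and p-value) for one line.

    Size factors and dispersions are estimated from the line's own T0/T1
    samples.  Hairpins whose normalized T0 mean falls below
    ``abundance_floor`` are dropped (``retained = False``) — a hairpin that
    is not represented at T0 cannot show depletion.  Fold change is
    ``(mean_T1_norm + c) / (mean_T0_norm + c)`` with pseudocount ``c``;
    the exact test uses raw counts only.

    Returns a DataFrame indexed by hairpin_id with columns gene (if a
    library is given), mean_T0_norm, mean_T1_norm, fc, log2fc, p_value,
    retained.
    """
    t0 = table.samples_for(line, "T0")
    t1 = table.samples_for(line, "T1")
    if not t0 or not t1:
        raise KeyError(f"cell line {line!r} not present with both timepoints")
    cols = t0 + t1
    counts = table.counts[cols]
    factors = size_factors(counts)
    condition = table.samples.loc[cols, "timepoint"]
    disp = estimate_dispersions(counts, factors, condition)

    norm = counts / factors
    mean_t0 = norm[t0].mean(axis=1)
    mean_t1 = norm[t1].mean(axis=1)
    retained = mean_t0 >= abundance_floor

    fc = (mean_t1 + pseudocount) / (mean_t0 + pseudocount)
    log2fc = np.log2(fc)

    k0 = counts[t0].to_numpy()
    k1 = counts[t1].to_numpy()
    s0 = factors[t0].to_numpy()
    s1 = factors[t1].to_numpy()
    pvals = np.ones(len(counts))
    alpha_arr = disp.alpha.to_numpy()
    idx_retained = np.flatnonzero(retained.to_numpy())
    for i in idx_retained:
        pvals[i] = nb_exact_test(
            k0[i], k1[i], s0, s1, float(alpha_arr[i]),
            enumeration_max=enumeration_max,
        )

    out = pd.DataFrame(
        {
            "mean_T0_norm": mean_t0,
            "mean_T1_norm": mean_t1,
            "fc": fc,
            "log2fc": log2fc,
            "p_value": pvals,
            "alpha": disp.alpha,
            "retained": retained,
        },
        index=counts.index,
    )
    if library is not None:
        out.insert(0, "gene", library.gene_of().reindex(out.index))
    return out


def write_depletion_table(results: pd.DataFrame, path) -> None:
    results.to_csv(path, sep="\t", index_label="hairpin_id")
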