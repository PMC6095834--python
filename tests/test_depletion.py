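"""Normalization, dispersion estimation, and the conditional NB exact test."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import poolscreen as ps
from poolscreen.depletion import estimate_dispersions, nb_exact_test, size_factors
from poolscreen.errors import DispersionError, NormalizationError
from oracles import brute_force_nb_p as brute_force_p


# ---------------------------------------------------------------------------
# Size factors


def test_size_factors_identical_columns_are_equal():
    df = pd.DataFrame({"a": [5, 10, 20], "b": [5, 10, 20], "c": [5, 10, 20]})
    s = size_factors(df)
    assert np.allclose(s, s.iloc[0])


def test_size_factors_scale_equivariance():
    rng = np.random.default_rng(0)
    df = pd.DataFrame(rng.integers(1, 1000, size=(50, 3)),
                      columns=["a", "b", "c"])
    df["b"] = 2 * df["a"]
    s = size_factors(df)
    assert s["b"] / s["a"] == pytest.approx(2.0)


def test_size_factors_match_hand_calculation():
    # rows: ratios to the row geometric mean, column-wise medians by hand
    df = pd.DataFrame(
        {
            "s1": [100, 40, 10, 30],
            "s2": [200, 80, 20, 90],
            "s3": [50, 20, 5, 30],
        }
    )
    # rows 1-3 have geometric means 100, 40, 10 -> ratios (1, 2, 0.5);
    # row 4 geomean = (30*90*30)^(1/3) = 43.2675 -> (0.6934, 2.0801, 0.6934);
    # medians: s1 -> 1, s2 -> 2, s3 -> 0.5
    s = size_factors(df)
    assert np.allclose(s, [1.0, 2.0, 0.5])


def test_size_factors_row_permutation_invariant():
    rng = np.random.default_rng(1)
    df = pd.DataFrame(rng.integers(1, 500, size=(30, 4)))
    s1 = size_factors(df)
    s2 = size_factors(df.sample(frac=1, random_state=2))
    assert np.allclose(s1, s2)


def test_size_factors_require_an_all_positive_row():
    df = pd.DataFrame({"a": [0, 5], "b": [3, 0]})
    with pytest.raises(NormalizationError):
        size_factors(df)


# ---------------------------------------------------------------------------
# Dispersion estimation


def _simulate_counts(mu, alpha, n_samples, rng):
    if alpha > 0:
        lam = mu[:, None] * rng.gamma(1 / alpha, alpha, (len(mu), n_samples))
    else:
        lam = np.repeat(mu[:, None], n_samples, axis=1)
    return pd.DataFrame(rng.poisson(lam), columns=[f"s{j}" for j in range(n_samples)])


def test_poisson_counts_give_near_zero_dispersion():
    rng = np.random.default_rng(3)
    df = _simulate_counts(np.full(200, 1000.0), 0.0, 6, rng)
    factors = size_factors(df)
    cond = pd.Series(["T0"] * 3 + ["T1"] * 3, index=df.columns)
    fit = estimate_dispersions(df, factors, cond)
    assert fit.alpha.median() <= 0.05


def test_planted_quadratic_dispersion_recovered():
    """Counts with variance mu + 0.1 mu^2 yield a fitted intercept a0 in
    [0.05, 0.2] over 500 hairpins."""
    rng = np.random.default_rng(4)
    mu = rng.uniform(100, 2000, 500)
    df = _simulate_counts(mu, 0.1, 6, rng)
    factors = size_factors(df)
    cond = pd.Series(["T0"] * 3 + ["T1"] * 3, index=df.columns)
    fit = estimate_dispersions(df, factors, cond)
    assert 0.05 <= fit.a0 <= 0.2


def test_final_alpha_is_max_of_raw_and_fitted():
    rng = np.random.default_rng(5)
    df = _simulate_counts(np.full(100, 500.0), 0.05, 6, rng)
    factors = size_factors(df)
    cond = pd.Series(["T0"] * 3 + ["T1"] * 3, index=df.columns)
    fit = estimate_dispersions(df, factors, cond)
    below = fit.alpha_raw < fit.fitted(fit.mu)
    assert below.any()
    assert np.allclose(fit.alpha[below], fit.fitted(fit.mu[below]))
    assert np.allclose(
        fit.alpha, np.maximum(fit.alpha_raw, fit.fitted(fit.mu))
    )


def test_single_replicate_demands_blind_mode():
    df = pd.DataFrame({"a": [10, 20], "b": [12, 18], "c": [11, 21]})
    factors = size_factors(df)
    cond = pd.Series(["T0", "T0", "T1"], index=df.columns)
    with pytest.raises(DispersionError, match="blind"):
        estimate_dispersions(df, factors, cond)
    fit = estimate_dispersions(df, factors, cond, blind=True)
    assert (fit.alpha >= 0).all()


# ---------------------------------------------------------------------------
# Conditional NB exact test




def test_balanced_counts_give_p_one():
    assert nb_exact_test([3, 3], [3, 3], [1, 1], [1, 1], 0.1) == 1.0


def test_small_case_matches_direct_enumeration():
    p = nb_exact_test([6, 0], [0, 0], [1, 1], [1, 1], 0.1)
    assert p == pytest.approx(
        brute_force_p([6, 0], [0, 0], [1, 1], [1, 1], 0.1), abs=1e-12
    )
    assert 0 < p < 1


def test_p_increases_with_dispersion():
    ps_ = [nb_exact_test([50, 60], [10, 8], [1, 1], [1, 1], a)
           for a in (0.01, 0.1, 1.0, 10.0)]
    assert np.all(np.diff(ps_) > 0)


def test_zero_total_is_degenerate():
    assert nb_exact_test([0, 0], [0, 0], [1, 1], [1, 1], 0.1) == 1.0


@settings(max_examples=60, deadline=None, derandomize=True)
@given(st.data())
def test_exact_test_equals_enumeration_for_random_parameters(data):
    """Oracle equivalence on randomized draws with conditioned sums <= 200."""
    n = data.draw(st.integers(2, 3))
    k0 = data.draw(st.lists(st.integers(0, 50), min_size=n, max_size=n))
    k1 = data.draw(st.lists(st.integers(0, 50), min_size=n, max_size=n))
    s0 = data.draw(st.lists(st.floats(0.5, 2.0), min_size=n, max_size=n))
    s1 = data.draw(st.lists(st.floats(0.5, 2.0), min_size=n, max_size=n))
    alpha = data.draw(st.floats(0.0, 1.0))
    if sum(k0) + sum(k1) == 0:
        return
    p = nb_exact_test(k0, k1, s0, s1, alpha)
    assert p == pytest.approx(brute_force_p(k0, k1, s0, s1, alpha), rel=1e-9)
    assert 0 < p <= 1


def test_normal_approximation_close_to_enumeration_at_switch():
    """Just above the enumeration cutoff the normal approximation agrees
    with full enumeration to within a small relative error on log p."""
    rng = np.random.default_rng(6)
    for _ in range(5):
        k0 = rng.integers(400, 900, 3)
        k1 = rng.integers(100, 700, 3)
        exact = nb_exact_test(k0, k1, [1] * 3, [1] * 3, 0.05,
                              enumeration_max=10**6)
        approx = nb_exact_test(k0, k1, [1] * 3, [1] * 3, 0.05,
                               enumeration_max=1)
        if exact < 0.99:
            assert np.log10(approx) == pytest.approx(np.log10(exact), abs=0.3)


# ---------------------------------------------------------------------------
# Per-line depletion tables


def test_identical_timepoints_give_unit_fold_change():
    rng = np.random.default_rng(7)
    base = rng.integers(500, 2000, 50)
    counts = pd.DataFrame(
        {f"A_{tp}_r{r}": base for tp in ("T0", "T1") for r in (1, 2, 3)}
    )
    counts.index = [f"hp{i}" for i in range(50)]
    samples = pd.DataFrame(
        [(f"A_{tp}_r{r}", "A", tp, r) for tp in ("T0", "T1") for r in (1, 2, 3)],
        columns=["sample_id", "cell_line", "timepoint", "replicate"],
    ).set_index("sample_id")
    table = ps.CountTable(counts, samples)
    res = ps.hairpin_depletion_table(table, "A")
    assert np.allclose(res["fc"], 1.0)
    assert np.allclose(res["log2fc"], 0.0)


def test_pseudocount_bounds_zero_t1_fold_change(small_screen):
    """A hairpin absent at T1 gets fc = (0 + c) / (mean_T0 + c)."""
    _, library, _, table, _ = small_screen
    line = "WT01"
    t1 = table.samples_for(line, "T1")
    counts = table.counts.copy()
    counts.loc[counts.index[0], t1] = 0
    table2 = ps.CountTable(counts, table.samples)
    res = ps.hairpin_depletion_table(table2, line, library)
    hp = counts.index[0]
    expected = 0.5 / (res.loc[hp, "mean_T0_norm"] + 0.5)
    assert res.loc[hp, "fc"] == pytest.approx(expected)


def test_abundance_floor_drops_rare_hairpins(small_screen):
    _, library, _, table, _ = small_screen
    counts = table.counts.copy()
    t0 = table.samples_for("WT01", "T0")
    counts.loc[counts.index[1], t0] = 2
    table2 = ps.CountTable(counts, table.samples)
    res = ps.hairpin_depletion_table(table2, "WT01", library,
                                     abundance_floor=30.0)
    assert not res.loc[counts.index[1], "retained"]
    assert res.loc[counts.index[1], "p_value"] == 1.0


def test_planted_depletion_estimated_within_band():
    """All five hairpins of a gene planted at FC 0.25 report fc in
    [0.15, 0.4] at coverage 1000."""
    design = ps.cohort_design(n_wildtype=1, n_mutant=1, n_genes=50, seed=19)
    library = ps.simulate_library(design)
    effects = ps.EffectModel(common_lethals={"G0011": [0.25] * 5},
                             off_target_rate=0.0)
    table, _ = ps.simulate_screen(library, design, effects)
    res = ps.hairpin_depletion_table(table, "MUT01", library)
    fcs = res.loc[res["gene"] == "G0011", "fc"]
    assert fcs.between(0.15, 0.4).all()


def test_unknown_line_raises(small_screen):
    table = small_screen[3]
    with pytest.raises(KeyError):
        ps.hairpin_depletion_table(table, "NOPE")


def test_column_scaling_absorbed_by_size_factors(small_screen):
    """Doubling one sample's column leaves normalized means and fold
    changes unchanged up to the pseudocount (the median-of-ratios
    reference rescales all samples by 2^(1/m)); p-values move only
    marginally (the exact test conditions on raw sums)."""
    _, library, _, table, _ = small_screen
    res1 = ps.hairpin_depletion_table(table, "WT01", library)
    counts = table.counts.copy()
    col = table.samples_for("WT01", "T0")[0]
    counts[col] = counts[col] * 2
    res2 = ps.hairpin_depletion_table(
        ps.CountTable(counts, table.samples), "WT01", library
    )
    assert np.allclose(res1["fc"], res2["fc"], rtol=1e-2)
    assert np.allclose(
        res1["mean_T0_norm"] * 2 ** (1 / 6), res2["mean_T0_norm"]
    )
    dlogp = np.abs(np.log10(res1["p_value"]) - np.log10(res2["p_value"]))
    assert np.median(dlogp) < 0.15


def test_null_pvalues_not_anticonservative():
    """On a no-effect screen the p-value ECDF never exceeds uniform by more
    than 0.1 (conservative-or-calibrated)."""
    design = ps.cohort_design(n_wildtype=1, n_mutant=1, n_genes=100, seed=23)
    library = ps.simulate_library(design)
    table, _ = ps.simulate_screen(library, design,
                                  ps.EffectModel(off_target_rate=0.0))
    res = ps.hairpin_depletion_table(table, "WT01", library)
    p = np.sort(res.loc[res["retained"], "p_value"].to_numpy())
    ecdf = np.arange(1, len(p) + 1) / len(p)
    assert np.max(ecdf - p) <= 0.1
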