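import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from genovmap.copy_stats import (
    copy_matrix,
    dunn_flag,
    kruskal_wallis,
    normality_check,
    retention,
)
from genovmap.synthetic_data import simulate_copy_matrix


# -- matrix construction --------------------------------------------------------


def test_copy_matrix_includes_zero_cells(small_table):
    mat = copy_matrix(small_table, ["A", "B", "C"])
    assert list(mat.loc["OG1"]) == [2, 1, 1]
    assert list(mat.loc["OG4"]) == [0, 0, 1]


def test_copy_matrix_unknown_species(small_table):
    with pytest.raises(KeyError, match="Zz"):
        copy_matrix(small_table, ["A", "Zz"])


def test_copy_matrix_row_sums_equal_table_totals(small_table):
    mat = copy_matrix(small_table, small_table.species)
    for og in small_table.orthogroup_ids:
        total = sum(len(small_table.groups[og][sp])
                    for sp in small_table.species)
        assert mat.loc[og].sum() == total


def test_grand_mean_is_total_over_cells(small_table):
    mat = copy_matrix(small_table, small_table.species)
    _, _, _, grand = kruskal_wallis(mat)
    assert grand == pytest.approx(mat.to_numpy().sum() / mat.size)


# -- retention -------------------------------------------------------------------


def test_retention_75_of_99_boundary():
    row75 = [1] * 75 + [0] * 24
    row74 = [1] * 74 + [0] * 25
    mat = pd.DataFrame([row75, row74], index=["hi", "lo"])
    out = retention(mat, threshold=0.75)
    assert out.loc["hi", "fraction"] == pytest.approx(75 / 99)
    assert bool(out.loc["hi", "retained"])
    assert not bool(out.loc["lo", "retained"])


def test_retention_matches_bruteforce_recount():
    rng = np.random.default_rng(21)
    mat = pd.DataFrame(rng.integers(0, 4, size=(30, 17)))
    out = retention(mat, threshold=0.6)
    for i in range(30):
        present = sum(1 for v in mat.iloc[i] if v >= 1)
        assert out.iloc[i]["fraction"] == pytest.approx(present / 17)
        assert bool(out.iloc[i]["retained"]) == (present / 17 >= 0.6)


def test_retention_threshold_validation():
    mat = pd.DataFrame([[1, 0]])
    for bad in (0.0, 1.5, -0.1):
        with pytest.raises(ValueError):
            retention(mat, threshold=bad)


# -- normality check --------------------------------------------------------------


def test_skewed_counts_reject_normality():
    """Right-skewed copy-count draws are firmly non-normal."""
    for seed in range(10):
        rng = np.random.default_rng(seed)
        x = 1 + rng.poisson(0.16, size=5000)
        a2, p, reject, skew = normality_check(pd.DataFrame([x]))
        assert reject and skew > 1.0


def test_normal_draws_reject_at_alpha_rate():
    rejections = sum(
        normality_check(
            pd.DataFrame([np.random.default_rng(s).normal(size=500)]))[2]
        for s in range(200))
    assert 0.01 <= rejections / 200 <= 0.10


def test_constant_vector_is_automatic_reject():
    a2, p, reject, skew = normality_check(pd.DataFrame([[2.0] * 20]))
    assert reject and p == 0.0 and math.isinf(a2)


def test_too_few_observations_is_error():
    with pytest.raises(ValueError, match="8"):
        normality_check(pd.DataFrame([[1.0, 2.0, 3.0]]))


# -- Kruskal–Wallis ----------------------------------------------------------------


def test_identical_groups_give_h_zero_p_one():
    mat = pd.DataFrame([[1, 2, 3], [1, 2, 3]], index=["a", "b"])
    h, df, p, _ = kruskal_wallis(mat)
    assert h == pytest.approx(0.0, abs=1e-12)
    assert df == 1 and p == pytest.approx(1.0)


def test_kw_matches_bruteforce_rank_statistic_with_ties():
    """Tie-corrected H recomputed from first principles on a tie-heavy
    fixture."""
    mat = pd.DataFrame([[1, 1, 2, 2, 3],
                        [2, 2, 2, 3, 3],
                        [1, 1, 1, 1, 2]], index=["a", "b", "c"])
    h, df, p, _ = kruskal_wallis(mat)

    flat = mat.to_numpy().ravel().astype(float)
    n = flat.size
    # manual average ranks
    order = np.argsort(flat, kind="stable")
    ranks = np.empty(n)
    i = 0
    srt = flat[order]
    while i < n:
        j = i
        while j < n and srt[j] == srt[i]:
            j += 1
        ranks[order[i:j]] = (i + j + 1) / 2.0
        i = j
    rank_mat = ranks.reshape(mat.shape)
    h_raw = (12.0 / (n * (n + 1))
             * sum(row.sum() ** 2 / len(row) for row in rank_mat)
             - 3 * (n + 1))
    _, counts = np.unique(flat, return_counts=True)
    tie = 1 - np.sum(counts ** 3 - counts) / (n ** 3 - n)
    h_expected = h_raw / tie
    assert h == pytest.approx(h_expected, abs=1e-10)
    assert df == 2
    assert p == pytest.approx(stats.chi2.sf(h_expected, 2))


def test_kw_invariant_under_monotone_transform():
    mat = simulate_copy_matrix(20, 30, seed=5)
    h1, *_ = kruskal_wallis(mat)
    h2, *_ = kruskal_wallis(mat ** 3 + 7)
    assert h1 == pytest.approx(h2, abs=1e-10)


def test_kw_needs_two_groups():
    with pytest.raises(ValueError):
        kruskal_wallis(pd.DataFrame([[1, 2, 3]]))


# -- Dunn cascade ------------------------------------------------------------------


def _manual_one_vs_rest_z(mat: pd.DataFrame, row: str) -> float:
    """Independent Dunn z computation: manual ranking and the rank-variance
    formula, no shared code with the implementation."""
    flat = mat.to_numpy().ravel().astype(float)
    n = flat.size
    srt_idx = np.argsort(flat, kind="stable")
    ranks = np.empty(n)
    i = 0
    srt = flat[srt_idx]
    while i < n:
        j = i
        while j < n and srt[j] == srt[i]:
            j += 1
        ranks[srt_idx[i:j]] = (i + j + 1) / 2.0
        i = j
    rank_mat = pd.DataFrame(ranks.reshape(mat.shape), index=mat.index)
    n_i = mat.shape[1]
    n_rest = n - n_i
    mean_i = rank_mat.loc[row].mean()
    mean_rest = (ranks.sum() - rank_mat.loc[row].sum()) / n_rest
    vals, counts = np.unique(flat, return_counts=True)
    s2 = n * (n + 1) / 12.0 - np.sum(counts ** 3 - counts) / (12.0 * (n - 1))
    return (mean_i - mean_rest) / math.sqrt(s2 * (1 / n_i + 1 / n_rest))


def test_dunn_z_matches_independent_implementation():
    mat = simulate_copy_matrix(12, 25, seed=8, expanded={2: 2.5})
    rep = dunn_flag(mat, require_kw=False)
    for og in mat.index:
        assert rep.dunn.loc[og, "z"] == pytest.approx(
            _manual_one_vs_rest_z(mat, og), abs=1e-8)


def test_dunn_all_identical_no_flags():
    mat = pd.DataFrame(np.ones((10, 20), dtype=int))
    rep = dunn_flag(mat)
    assert rep.flagged == []
    assert rep.kw_p == pytest.approx(1.0)


def test_dunn_flags_planted_expansion_one_sided():
    mat = simulate_copy_matrix(50, 99, seed=30, expanded={7: 3.0})
    rep = dunn_flag(mat)
    assert rep.flagged == ["OG00007"]
    assert rep.kw_df == 49
    # adjusted p never below raw p
    assert (rep.dunn["p_adj"] >= rep.dunn["p"] - 1e-15).all()


def test_dunn_flags_invariant_to_row_and_column_order():
    mat = simulate_copy_matrix(30, 40, seed=31, expanded={4: 3.0})
    rng = np.random.default_rng(0)
    shuffled = mat.iloc[rng.permutation(30), rng.permutation(40)]
    assert dunn_flag(mat).flagged == dunn_flag(shuffled).flagged


def test_dunn_requires_significant_kw_by_default():
    mat = pd.DataFrame(np.ones((10, 30), dtype=int))
    mat.iloc[0, 0] = 2  # negligible deviation: KW not significant
    rep = dunn_flag(mat)
    assert rep.kw_p >= 0.05 and rep.flagged == []


def test_dunn_all_pairs_scheme_flags_same_planted_outlier():
    mat = simulate_copy_matrix(15, 60, seed=32, expanded={3: 3.0})
    rep = dunn_flag(mat, scheme="all_pairs")
    assert "OG00003" in rep.flagged


def test_dunn_adjustment_methods_and_validation():
    mat = simulate_copy_matrix(20, 50, seed=33, expanded={1: 3.0})
    for method in ("bh", "bonferroni", "holm", "none"):
        rep = dunn_flag(mat, adjust=method)
        assert "OG00001" in rep.flagged
    with pytest.raises(ValueError):
        dunn_flag(mat, adjust="fdr_by")
    with pytest.raises(ValueError):
        dunn_flag(mat, alpha=1.5)
    with pytest.raises(ValueError):
        dunn_flag(mat - 5)  # negative counts
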