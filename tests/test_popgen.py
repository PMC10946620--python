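"""Diversity, differentiation and outlier statistics."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ecoparallel import popgen
from tests.conftest import toy_allele_table


# ---------------------------------------------------------------------------
# brute-force oracle on a toy alignment
# ---------------------------------------------------------------------------

def brute_force_stats(alignment: np.ndarray):
    """Pairwise-difference pi, S and Tajima's D computed from first principles.

    alignment: (n_seqs, n_sites) 0/1 matrix.  Returns (pi_total, S, D) using
    the textbook constants, coded independently of the package.
    """
    n, L = alignment.shape
    pi_total = 0.0
    npairs = 0
    for i in range(n):
        for j in range(i + 1, n):
            pi_total += np.sum(alignment[i] != alignment[j])
            npairs += 1
    pi_total /= npairs
    derived = alignment.sum(axis=0)
    S = int(np.sum((derived > 0) & (derived < n)))
    a1 = sum(1.0 / i for i in range(1, n))
    a2 = sum(1.0 / i**2 for i in range(1, n))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n * n + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1 * a1 + a2)
    D = (pi_total - S / a1) / math.sqrt(e1 * S + e2 * S * (S - 1)) if S else float("nan")
    return pi_total, S, D


def alignment_to_table(alignment, pop="P"):
    n, L = alignment.shape
    derived = alignment.sum(axis=0)
    rows = [("c1", s + 1, "g1", pop, int(min(d, n - d)), n) for s, d in enumerate(derived)]
    return toy_allele_table(rows)


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_diversity_and_tajima_match_brute_force(seed):
    rng = np.random.default_rng(seed)
    n, L = 8, 20
    alignment = (rng.random((n, L)) < rng.uniform(0.05, 0.5, size=L)).astype(int)
    pi_total, S, D = brute_force_stats(alignment)
    table = alignment_to_table(alignment)
    win = popgen.diversity_windows(table, "P", window_size=50_000, step=50_000)
    row = win.iloc[0]
    assert row["covered_sites"] == L
    assert row["pi"] * L == pytest.approx(pi_total, rel=1e-12)
    a1 = sum(1.0 / i for i in range(1, n))
    assert row["theta_w"] * L == pytest.approx(S / a1, rel=1e-12)
    if S:
        assert row["tajimas_d"] == pytest.approx(D, rel=1e-9)
        assert popgen.tajimas_d(S, pi_total, n) == pytest.approx(D, rel=1e-12)


def test_tajimas_d_zero_at_equilibrium_and_undefined_at_zero_S():
    n = 10
    a1 = sum(1.0 / i for i in range(1, n))
    S = 16
    assert popgen.tajimas_d(S, S / a1, n) == pytest.approx(0.0, abs=1e-12)
    assert math.isnan(popgen.tajimas_d(0, 0.0, n))


def test_window_diversity_hand_example():
    # two haplotypes differing at 1 of 10 covered sites: pi = theta_w = 0.1
    rows = [("c1", p, "g1", "P", 1 if p == 5 else 0, 2) for p in range(1, 11)]
    win = popgen.diversity_windows(toy_allele_table(rows), "P")
    row = win.iloc[0]
    assert row["pi"] == pytest.approx(0.1)
    assert row["theta_w"] == pytest.approx(0.1)


def test_empty_window_flagged_not_zero():
    rows = [("c1", 60_001, "g1", "P", 1, 4)]
    win = popgen.diversity_windows(toy_allele_table(rows), "P")
    first = win.iloc[0]
    assert not first["defined"] and math.isnan(first["pi"])


# ---------------------------------------------------------------------------
# folding from allele tables
# ---------------------------------------------------------------------------

def test_fold_sfs_classes_and_conservation():
    rows = [("c1", 1, "g", "P", 7, 10), ("c1", 2, "g", "P", 3, 10),
            ("c1", 3, "g", "P", 0, 10)]
    sfs = popgen.fold_sfs(toy_allele_table(rows), "P")
    assert sfs.counts[3] == 2  # c=7 of n=10 folds to class 3
    assert sfs.counts[0] == 1
    assert sfs.n_sites == 3


def test_fold_sfs_heterogeneous_n_reported():
    rows = [("c1", 1, "g", "P", 1, 10), ("c1", 2, "g", "P", 1, 8)]
    with pytest.raises(ValueError, match="heterogeneous"):
        popgen.fold_sfs(toy_allele_table(rows), "P")


def test_fold_jsfs_transposes_with_populations():
    rng = np.random.default_rng(3)
    rows = []
    for p in range(1, 40):
        c1, c2 = rng.integers(0, 3), rng.integers(0, 3)
        rows += [("c1", p, "g", "A", int(c1), 2), ("c1", p, "g", "B", int(c2), 2)]
    tbl = toy_allele_table(rows)
    ab = popgen.fold_jsfs(tbl, "A", "B")
    ba = popgen.fold_jsfs(tbl, "B", "A")
    assert ab.n_sites == ba.n_sites == 39
    i = np.arange(3)[:, None]
    j = np.arange(3)[None, :]
    off_tie = (i + j) != 2
    assert np.allclose(ab.matrix.T[off_tie], ba.matrix[off_tie])


# ---------------------------------------------------------------------------
# FST
# ---------------------------------------------------------------------------

def test_fst_single_site_hand_arithmetic():
    # p1=0.2, p2=0.8, n1=n2=10: alpha=0.324444, den=0.68, FST=0.477124
    rows = [("c1", 1, "g1", "A", 2, 10), ("c1", 1, "g1", "B", 8, 10)]
    tbl = popgen.fst_gene(toy_allele_table(rows), "A", "B")
    assert tbl.loc["g1", "alpha_sum"] == pytest.approx(0.3244444444, rel=1e-9)
    assert tbl.loc["g1", "den_sum"] == pytest.approx(0.68)
    assert tbl.loc["g1", "fst"] == pytest.approx(0.4771241830, rel=1e-9)


def test_fst_limits():
    rows = [("c1", 1, "g1", "A", 100, 100), ("c1", 1, "g1", "B", 0, 100)]
    tbl = popgen.fst_gene(toy_allele_table(rows), "A", "B")
    assert tbl.loc["g1", "fst"] == pytest.approx(1.0, abs=0.02)
    rows = [("c1", 1, "g1", "A", 50, 1000), ("c1", 1, "g1", "B", 50, 1000)]
    tbl = popgen.fst_gene(toy_allele_table(rows), "A", "B")
    assert abs(tbl.loc["g1", "fst"]) < 0.05


def test_fst_is_ratio_of_averages_not_average_of_ratios():
    rows = [
        ("c1", 1, "g1", "A", 1, 10), ("c1", 1, "g1", "B", 9, 10),
        ("c1", 2, "g1", "A", 5, 10), ("c1", 2, "g1", "B", 5, 10),
    ]
    tbl = popgen.fst_gene(toy_allele_table(rows), "A", "B")
    a1, d1 = popgen._bhatia_terms(0.1, 0.9, 10, 10)
    a2, d2 = popgen._bhatia_terms(0.5, 0.5, 10, 10)
    ratio_of_avg = (a1 + a2) / (d1 + d2)
    avg_of_ratios = 0.5 * (a1 / d1 + a2 / d2)
    assert ratio_of_avg != pytest.approx(avg_of_ratios)
    assert tbl.loc["g1", "fst"] == pytest.approx(ratio_of_avg, rel=1e-12)


def test_weighted_fst_consistent_with_sitewise_accumulation():
    rng = np.random.default_rng(4)
    rows = []
    for p in range(1, 200):
        c1, c2 = rng.integers(0, 4), rng.integers(0, 4)
        rows += [("c1", p, "g1", "A", int(c1), 6), ("c1", p, "g1", "B", int(c2), 6)]
    tbl = toy_allele_table(rows)
    jsfs = popgen.fold_jsfs(tbl, "A", "B")
    gene = popgen.fst_gene(tbl, "A", "B")
    assert popgen.weighted_fst(jsfs) == pytest.approx(
        gene.loc["g1", "fst"], rel=1e-9
    )


def test_gene_interval_assignment_bed_half_open():
    intervals = pd.DataFrame(
        {"chrom": ["c1", "c1"], "start": [0, 10], "end": [10, 20],
         "gene_id": ["gA", "gB"]}
    )
    rows = [("c1", 10, None, "A", 1, 4), ("c1", 10, None, "B", 2, 4),
            ("c1", 11, None, "A", 2, 4), ("c1", 11, None, "B", 0, 4)]
    tbl = toy_allele_table(rows).drop(columns=["gene_id"])
    out = popgen.fst_gene(tbl, "A", "B", gene_intervals=intervals)
    # 1-based position 10 = 0-based 9 -> gA; position 11 -> gB
    assert set(out.index) == {"gA", "gB"}
    assert out.loc["gA", "n_sites"] == 1 and out.loc["gB", "n_sites"] == 1


# ---------------------------------------------------------------------------
# outliers and permutation test
# ---------------------------------------------------------------------------

def random_fst_table(G, seed=0):
    rng = np.random.default_rng(seed)
    return pd.DataFrame(
        {"fst": rng.beta(0.5, 3, size=G), "alpha_sum": 1.0, "den_sum": 1.0,
         "n_sites": 10},
        index=[f"g{i:05d}" for i in range(G)],
    )


@settings(derandomize=True, max_examples=25, deadline=None)
@given(G=st.integers(20, 5000), alpha=st.sampled_from([0.01, 0.05, 0.1]),
       seed=st.integers(0, 1000))
def test_outlier_count_law(G, alpha, seed):
    tbl = popgen.top_fraction_outliers(random_fst_table(G, seed), alpha=alpha)
    assert int(tbl["outlier"].sum()) == math.ceil(alpha * G)


def test_outlier_tiny_and_undefined_handling():
    tbl = random_fst_table(10)
    flagged = popgen.top_fraction_outliers(tbl, alpha=0.05)
    assert flagged["outlier"].sum() == 1
    tbl.loc[:, "fst"] = np.nan
    with pytest.raises(ValueError):
        popgen.top_fraction_outliers(tbl)


def test_permutation_p_one_when_deg_is_everything():
    tbl = random_fst_table(50)
    res = popgen.deg_fst_permutation(tbl, list(tbl.index), n_perm=99, seed=0)
    assert res["p_value"] == pytest.approx(1.0)


def test_permutation_detects_seeded_top_decile():
    tbl = random_fst_table(500, seed=5)
    top = tbl.sort_values("fst", ascending=False).head(30).index
    res = popgen.deg_fst_permutation(tbl, top, n_perm=499, seed=1)
    assert res["p_value"] < 0.01


def test_permutation_deterministic_and_validates_input():
    tbl = random_fst_table(100)
    a = popgen.deg_fst_permutation(tbl, list(tbl.index[:10]), n_perm=99, seed=7)
    b = popgen.deg_fst_permutation(tbl, list(tbl.index[:10]), n_perm=99, seed=7)
    assert a["p_value"] == b["p_value"]
    with pytest.raises(ValueError):
        popgen.deg_fst_permutation(tbl, [], n_perm=10, seed=0)
    with pytest.raises(ValueError):
        popgen.deg_fst_permutation(tbl, ["not_a_gene"], n_perm=10, seed=0)


# ---------------------------------------------------------------------------
# PCA plumbing
# ---------------------------------------------------------------------------

def make_pca_table(freqs, n=10):
    rows = []
    for pop, fvec in freqs.items():
        for s, f in enumerate(fvec):
            rows.append(("c1", s + 1, "g", pop, int(round(f * n)), n))
    return toy_allele_table(rows)


def test_pca_separates_fixed_differences():
    tbl = make_pca_table({"A": [1, 1, 0, 0], "B": [0, 0, 1, 1], "C": [1, 1, 0, 0]})
    coords, ratio = popgen.allele_freq_pca(tbl)
    assert ratio.sum() <= 1.0 + 1e-12
    # identical populations coincide; the divergent one is far on PC1
    assert coords.loc["A", "PC1"] == pytest.approx(coords.loc["C", "PC1"], abs=1e-9)
    assert abs(coords.loc["B", "PC1"] - coords.loc["A", "PC1"]) > 1.0


def test_pca_degenerate_rank_reported():
    tbl = make_pca_table({"A": [0.5, 0.5], "B": [0.5, 0.5]})
    with pytest.raises(ValueError, match="degenerate"):
        popgen.allele_freq_pca(tbl)
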