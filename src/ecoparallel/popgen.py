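"""Diversity and differentiation summaries from per-site allele counts.

The allele-count table is a tidy DataFrame with columns ``chrom``, ``pos``
(1-based), optional ``gene_id``, ``pop``, ``minor_count`` and ``n`` (sampled
haploids).  Counts must refer to the same allele across populations at a
site (e.g. the globally minor allele); the folding operations handle the
remaining ambiguity.

Differentiation uses the Hudson-class FST estimator of Bhatia et al. (2013):
per site a numerator alpha = (p1-p2)^2 - p1(1-p1)/(n1-1) - p2(1-p2)/(n2-1)
and denominator p1(1-p2) + p2(1-p1); gene- or genome-level FST is the ratio
of the summed numerator to the summed denominator (ratio of averages), never
the average of per-site ratios.
"""

from __future__ import annotations

import math
from typing import Iterable

import numpy as np
import pandas as pd

from .sfs import FoldedSFS, JointFoldedSFS, fold_joint_matrix

__all__ = [
    "fold_sfs",
    "fold_jsfs",
    "diversity_windows",
    "tajimas_d",
    "fst_gene",
    "weighted_fst",
    "top_fraction_outliers",
    "deg_fst_permutation",
    "allele_freq_pca",
]

REQUIRED_COLS = ("chrom", "pos", "pop", "minor_count", "n")


def _check_table(df: pd.DataFrame) -> None:
    missing = [c for c in REQUIRED_COLS if c not in df.columns]
    if missing:
        raise ValueError(f"allele-count table missing columns {missing}")


def _uniform_n(sub: pd.DataFrame, pop: str) -> int:
    ns = sub["n"].unique()
    if len(ns) != 1:
        bad = sub.loc[sub["n"] != ns[0], ["chrom", "pos"]].head(20)
        raise ValueError(
            f"heterogeneous sample size in population {pop!r}: {sorted(ns)}; "
            f"first offending sites:\n{bad}"
        )
    n = int(ns[0])
    if n < 2:
        raise ValueError(f"population {pop!r}: need n >= 2")
    return n


def fold_sfs(allele_counts: pd.DataFrame, population: str) -> FoldedSFS:
    """Fold per-site counts of one population into a minor-allele SFS."""
    _check_table(allele_counts)
    sub = allele_counts[allele_counts["pop"] == population]
    if sub.empty:
        raise ValueError(f"no sites for population {population!r}")
    n = _uniform_n(sub, population)
    c = sub["minor_count"].to_numpy()
    if np.any((c < 0) | (c > n)):
        raise ValueError("minor_count outside [0, n]")
    folded = np.minimum(c, n - c)
    counts = np.bincount(folded, minlength=n // 2 + 1).astype(float)
    return FoldedSFS(counts, n=n, pop=population)


def fold_jsfs(allele_counts: pd.DataFrame, pop1: str, pop2: str) -> JointFoldedSFS:
    """Joint folded SFS of two populations (sites present in both)."""
    _check_table(allele_counts)
    sub1 = allele_counts[allele_counts["pop"] == pop1]
    sub2 = allele_counts[allele_counts["pop"] == pop2]
    if sub1.empty or sub2.empty:
        raise ValueError("empty population in jSFS request")
    n1 = _uniform_n(sub1, pop1)
    n2 = _uniform_n(sub2, pop2)
    merged = sub1.merge(sub2, on=["chrom", "pos"], suffixes=("_1", "_2"))
    mat = np.zeros((n1 + 1, n2 + 1))
    np.add.at(
        mat,
        (merged["minor_count_1"].to_numpy(), merged["minor_count_2"].to_numpy()),
        1.0,
    )
    return JointFoldedSFS(fold_joint_matrix(mat), n1=n1, n2=n2, pops=(pop1, pop2))


def tajimas_d(S: float, pi_total: float, n: int) -> float:
    """Tajima's D from segregating sites and total pairwise diversity.

    ``pi_total`` is the sum over sites of per-site pairwise diversity (not
    divided by covered length).  Returns NaN when S = 0 (undefined).
    """
    if S <= 0:
        return float("nan")
    i = np.arange(1, n)
    a1 = float(np.sum(1.0 / i))
    a2 = float(np.sum(1.0 / i**2))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    var = e1 * S + e2 * S * (S - 1)
    if var <= 0:  # n = 2 has zero variance; D undefined
        return float("nan")
    return float((pi_total - S / a1) / math.sqrt(var))


def diversity_windows(
    allele_counts: pd.DataFrame,
    population: str,
    window_size: int = 50_000,
    step: int = 10_000,
    covered: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Sliding-window pi, Watterson's theta and Tajima's D for one population.

    Windows are half-open [start, start + window_size) advancing by ``step``.
    Per-window estimates are divided by the covered-site count; by default
    every row of the table (variant or invariant, i.e. minor_count = 0)
    counts as covered, or pass ``covered`` with columns (chrom, start,
    covered_sites).  Windows with no coverage are flagged undefined (NaN),
    not zero.
    """
    _check_table(allele_counts)
    sub = allele_counts[allele_counts["pop"] == population]
    if sub.empty:
        raise ValueError(f"no sites for population {population!r}")
    n = _uniform_n(sub, population)
    a_n = float(np.sum(1.0 / np.arange(1, n)))
    cov_lookup = None
    if covered is not None:
        cov_lookup = {
            (r.chrom, int(r.start)): float(r.covered_sites)
            for r in covered.itertuples()
        }
    rows = []
    for chrom, grp in sub.groupby("chrom", sort=True):
        pos = grp["pos"].to_numpy()
        cnt = grp["minor_count"].to_numpy()
        fold = np.minimum(cnt, n - cnt)
        p = fold / n
        persite_pi = 2.0 * p * (1 - p) * n / (n - 1)
        last = int(pos.max())
        start = 0
        while start <= last:
            end = start + window_size
            in_win = (pos >= start + 1) & (pos <= end)  # 1-based positions
            n_cov = (
                cov_lookup.get((chrom, start), 0.0)
                if cov_lookup is not None
                else float(in_win.sum())
            )
            S = float((fold[in_win] > 0).sum())
            pi_tot = float(persite_pi[in_win].sum())
            if n_cov > 0:
                pi = pi_tot / n_cov
                theta_w = S / (a_n * n_cov)
                d = tajimas_d(S, pi_tot, n)
                defined = True
            else:
                pi = theta_w = d = float("nan")
                defined = False
            rows.append(
                dict(chrom=chrom, start=start, end=end, pi=pi, theta_w=theta_w,
                     tajimas_d=d, S=S, covered_sites=n_cov, defined=defined)
            )
            start += step
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# FST
# ---------------------------------------------------------------------------

def _bhatia_terms(p1, p2, n1, n2):
    alpha = (
        (p1 - p2) ** 2
        - p1 * (1 - p1) / (n1 - 1)
        - p2 * (1 - p2) / (n2 - 1)
    )
    den = p1 * (1 - p2) + p2 * (1 - p1)
    return alpha, den


def _assign_genes(df: pd.DataFrame, intervals: pd.DataFrame) -> pd.Series:
    """Map 1-based positions onto BED intervals (0-based half-open)."""
    gene = pd.Series(pd.NA, index=df.index, dtype="object")
    for chrom, grp in intervals.groupby("chrom"):
        sel = df["chrom"] == chrom
        if not sel.any():
            continue
        pos0 = df.loc[sel, "pos"].to_numpy() - 1  # to 0-based
        starts = grp["start"].to_numpy()
        ends = grp["end"].to_numpy()
        names = grp["gene_id"].to_numpy()
        order = np.argsort(starts)
        starts, ends, names = starts[order], ends[order], names[order]
        idx = np.searchsorted(starts, pos0, side="right") - 1
        ok = (idx >= 0) & (pos0 < ends[np.clip(idx, 0, None)])
        vals = np.where(ok, names[np.clip(idx, 0, None)], None)
        gene.loc[sel] = vals
    return gene


def fst_gene(
    allele_counts: pd.DataFrame,
    pop1: str,
    pop2: str,
    gene_intervals: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Per-gene ratio-of-averages Hudson/Bhatia FST between two populations.

    Genes come from the ``gene_id`` column or from ``gene_intervals``
    (BED-style: chrom, start, end, gene_id; 0-based half-open).  Returns a
    DataFrame indexed by gene with alpha_sum, den_sum, fst (NaN when the
    summed denominator is zero) and n_sites.
    """
    _check_table(allele_counts)
    sub1 = allele_counts[allele_counts["pop"] == pop1]
    sub2 = allele_counts[allele_counts["pop"] == pop2]
    n1 = _uniform_n(sub1, pop1)
    n2 = _uniform_n(sub2, pop2)
    cols = ["chrom", "pos", "minor_count"] + (
        ["gene_id"] if "gene_id" in allele_counts.columns else []
    )
    merged = sub1[cols].merge(
        sub2[["chrom", "pos", "minor_count"]],
        on=["chrom", "pos"],
        suffixes=("_1", "_2"),
    )
    if gene_intervals is not None:
        merged["gene_id"] = _assign_genes(merged, gene_intervals)
    if "gene_id" not in merged.columns:
        raise ValueError("no gene_id column and no gene_intervals given")
    merged = merged.dropna(subset=["gene_id"])
    p1 = merged["minor_count_1"].to_numpy() / n1
    p2 = merged["minor_count_2"].to_numpy() / n2
    alpha, den = _bhatia_terms(p1, p2, n1, n2)
    out = (
        pd.DataFrame(
            {"gene_id": merged["gene_id"], "alpha": alpha, "den": den}
        )
        .groupby("gene_id")
        .agg(alpha_sum=("alpha", "sum"), den_sum=("den", "sum"),
             n_sites=("alpha", "size"))
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        out["fst"] = np.where(out["den_sum"] > 0,
                              out["alpha_sum"] / out["den_sum"], np.nan)
    return out


def weighted_fst(jsfs: JointFoldedSFS) -> float:
    """Genome-wide Bhatia FST accumulated over all jSFS cells (ratio of sums)."""
    if jsfs.n_sites <= 0:
        raise ValueError("empty spectrum")
    n1, n2 = jsfs.n1, jsfs.n2
    i = np.arange(n1 + 1)[:, None] / n1
    j = np.arange(n2 + 1)[None, :] / n2
    alpha, den = _bhatia_terms(i, j, n1, n2)
    w = jsfs.matrix
    den_sum = float((w * den).sum())
    if den_sum <= 0:
        return float("nan")
    return float((w * alpha).sum() / den_sum)


def top_fraction_outliers(fst_table: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Flag the top-alpha fraction of genes by FST.

    Exactly ceil(alpha * G) genes are flagged among the G genes with defined
    FST; boundary ties break deterministically by gene id.
    """
    if not (0 < alpha < 1):
        raise ValueError("alpha must be in (0, 1)")
    out = fst_table.copy()
    defined = out["fst"].notna()
    G = int(defined.sum())
    if G == 0:
        raise ValueError("no genes with defined FST")
    n_flag = math.ceil(alpha * G)
    # deterministic order: descending fst, ascending gene id on boundary ties
    ranked = out[defined].reset_index()
    idcol = ranked.columns[0]
    ranked = ranked.sort_values(
        ["fst", idcol], ascending=[False, True], kind="mergesort"
    )
    flagged = set(ranked.head(n_flag)[idcol])
    out["outlier"] = [g in flagged for g in out.index]
    return out


def deg_fst_permutation(
    fst_table: pd.DataFrame,
    deg_set: Iterable,
    n_perm: int = 1000,
    seed: int = 0,
) -> dict:
    """Permutation test: mean FST of a gene set vs same-size random sets.

    Two-sided p with add-one correction; returns the observed mean, the null
    means and the p-value.
    """
    defined = fst_table["fst"].dropna()
    deg = sorted(set(deg_set))
    if not deg:
        raise ValueError("deg_set is empty")
    missing = [g for g in deg if g not in defined.index]
    if missing:
        raise ValueError(f"deg_set genes without defined FST: {missing[:10]}")
    values = defined.to_numpy()
    obs = float(defined.loc[deg].mean())
    rng = np.random.default_rng(seed)
    k = len(deg)
    null = np.array([
        values[rng.choice(len(values), size=k, replace=False)].mean()
        for _ in range(n_perm)
    ])
    center = null.mean()
    p = (1.0 + np.sum(np.abs(null - center) >= abs(obs - center))) / (1.0 + n_perm)
    return {"statistic": obs, "null": null, "p_value": float(p)}


def allele_freq_pca(allele_counts: pd.DataFrame) -> tuple[pd.DataFrame, np.ndarray]:
    """PCA of the centered population-by-site allele-frequency matrix.

    Plumbing for structure checks: populations (or individuals coded as
    populations) are observations, per-site minor-allele frequencies are
    variables.  Signs are fixed so each component's largest loading is
    positive.  Returns (coordinates, explained variance ratios).
    """
    _check_table(allele_counts)
    freq = allele_counts.assign(p=allele_counts["minor_count"] / allele_counts["n"])
    wide = freq.pivot_table(index="pop", columns=["chrom", "pos"], values="p")
    wide = wide.dropna(axis=1)
    if wide.shape[0] < 2:
        raise ValueError("need at least two populations/samples")
    X = wide.to_numpy(dtype=float)
    X = X - X.mean(axis=0, keepdims=True)
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    if np.allclose(s, 0):
        raise ValueError("degenerate rank: no variance across populations")
    # deterministic sign: largest-magnitude loading of each PC positive
    for k in range(len(s)):
        jmax = np.argmax(np.abs(Vt[k]))
        if Vt[k, jmax] < 0:
            Vt[k] *= -1
            U[:, k] *= -1
    coords = U * s
    var = s**2
    ratio = var / var.sum() if var.sum() > 0 else var
    cols = [f"PC{k + 1}" for k in range(coords.shape[1])]
    return pd.DataFrame(coords, index=wide.index, columns=cols), ratio
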