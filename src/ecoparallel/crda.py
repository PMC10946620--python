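"""Conditioned (partial) redundancy analysis of expression on ecotype.

Multivariate counterpart of the per-gene tests: after partialling out the
ecotype-pair (locality) structure, how much of the remaining expression
variance is explained by the single ecotype axis?  The procedure follows
the classical two-step RDA: (1) center the gene matrix; (2) residualize
both the response and the ecotype indicator on the pair indicator matrix
(the Condition term); (3) regress the residualized response on the
residualized ecotype variable; (4) the SVD of the fitted values yields one
constrained axis whose gene loadings are the cRDA scores.  Total inertia
decomposes exactly into conditioned + constrained + unconstrained parts.

Outliers are genes whose score lies beyond 2 (and 2.6) standard deviations
of the score distribution; significance of the constrained fraction is a
permutation ANOVA with ecotype labels permuted within pair blocks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import permutations

import numpy as np
import pandas as pd

__all__ = ["CRDAResult", "crda_fit", "crda_outliers", "crda_anova"]


@dataclass
class CRDAResult:
    fraction_conditioned: float
    fraction_constrained: float
    fraction_unconstrained: float
    fraction_constrained_of_residual: float  # constrained / (total - conditioned)
    gene_scores: pd.Series
    gene_z: pd.Series
    sample_constrained: pd.Series
    sample_unconstrained: pd.Series
    pseudo_F: float
    total_inertia: float

    def __post_init__(self) -> None:
        s = (self.fraction_conditioned + self.fraction_constrained
             + self.fraction_unconstrained)
        if abs(s - 1.0) > 1e-9:
            raise ValueError(f"inertia fractions sum to {s}, expected 1")


def _design(labels: pd.Series) -> np.ndarray:
    cats = sorted(labels.unique())
    return np.stack([(labels == c).to_numpy(float) for c in cats], axis=1)


def _residualize(M: np.ndarray, Z: np.ndarray) -> np.ndarray:
    """Project out the column space of Z (least squares, rank-safe)."""
    coef, *_ = np.linalg.lstsq(Z, M, rcond=None)
    return M - Z @ coef


def crda_fit(
    cpm_matrix: pd.DataFrame,
    ecotype: pd.Series,
    pair: pd.Series,
) -> CRDAResult:
    """Fit the ecotype-constrained, pair-conditioned RDA.

    ``cpm_matrix`` is genes x samples (same orientation as the count
    matrix); ``ecotype`` and ``pair`` are indexed by sample.  Requires at
    least two samples per pair x ecotype cell and an ecotype contrast not
    collinear with pair.
    """
    samples = list(cpm_matrix.columns)
    ecotype = ecotype.loc[samples]
    pair = pair.loc[samples]
    cell_counts = pd.crosstab(pair, ecotype)
    if (cell_counts < 2).to_numpy().any():
        raise ValueError("need >= 2 samples per pair x ecotype cell")
    Y = cpm_matrix.to_numpy(dtype=float).T  # samples x genes
    Y = Y - Y.mean(axis=0, keepdims=True)
    total = float(np.sum(Y**2))
    if total <= 0:
        raise ValueError("zero total inertia")

    Z = _design(pair.astype(str))
    x = (ecotype == "M").to_numpy(float)[:, None]
    Y_res = _residualize(Y, Z)
    x_res = _residualize(x, Z)
    xx = float(np.sum(x_res**2))
    if xx < 1e-12:
        raise ValueError("ecotype is collinear with pair after conditioning")

    beta = (x_res.T @ Y_res) / xx
    Y_fit = x_res @ beta
    ss_cond = total - float(np.sum(Y_res**2))
    ss_con = float(np.sum(Y_fit**2))
    ss_uncon = float(np.sum((Y_res - Y_fit) ** 2))

    # single constrained axis from the rank-1 fitted matrix
    U, s, Vt = np.linalg.svd(Y_fit, full_matrices=False)
    loadings = Vt[0]
    jmax = int(np.argmax(np.abs(loadings)))
    sign = 1.0 if loadings[jmax] >= 0 else -1.0
    scores = pd.Series(sign * loadings * s[0], index=cpm_matrix.index,
                       name="crda_score")
    samp_con = pd.Series(sign * U[:, 0] * s[0], index=samples,
                         name="constrained_axis")
    resid = Y_res - Y_fit
    Ur, sr, _ = np.linalg.svd(resid, full_matrices=False)
    samp_uncon = pd.Series(Ur[:, 0] * sr[0], index=samples, name="pc1_residual")

    sd = float(scores.std(ddof=1))
    z = (scores - float(scores.mean())) / sd if sd > 0 else scores * np.nan

    q = 1  # one constrained axis
    df_resid = Y.shape[0] - Z.shape[1] - q
    pseudo_f = (ss_con / q) / (ss_uncon / df_resid) if df_resid > 0 else float("nan")
    denom_resid = total - ss_cond
    return CRDAResult(
        fraction_conditioned=ss_cond / total,
        fraction_constrained=ss_con / total,
        fraction_unconstrained=ss_uncon / total,
        fraction_constrained_of_residual=(
            ss_con / denom_resid if denom_resid > 0 else float("nan")
        ),
        gene_scores=scores,
        gene_z=z,
        sample_constrained=samp_con,
        sample_unconstrained=samp_uncon,
        pseudo_F=pseudo_f,
        total_inertia=total,
    )


def crda_outliers(
    result: CRDAResult, thresholds: tuple[float, float] = (2.0, 2.6)
) -> dict[float, list]:
    """Genes beyond each |z| threshold; nested sets, degenerate scores flagged."""
    if result.gene_z.isna().all():
        raise ValueError("degenerate scores: zero variance, no outliers defined")
    out = {}
    for thr in sorted(thresholds):
        sel = result.gene_z.abs() > thr
        out[thr] = sorted(result.gene_z.index[sel])
    return out


def crda_anova(
    cpm_matrix: pd.DataFrame,
    ecotype: pd.Series,
    pair: pd.Series,
    n_perm: int = 1000,
    seed: int = 0,
) -> dict:
    """Permutation ANOVA of the constrained fraction.

    The null permutes ecotype labels within pair blocks (pairs are the
    nuisance; the design is balanced).  When fewer distinct within-block
    arrangements than ``n_perm`` exist they are enumerated exactly (with a
    warning).  Add-one correction on the p-value.
    """
    import warnings

    samples = list(cpm_matrix.columns)
    ecotype = ecotype.loc[samples].astype(str)
    pair = pair.loc[samples].astype(str)
    obs = crda_fit(cpm_matrix, ecotype, pair)

    blocks = {p: np.where((pair == p).to_numpy())[0] for p in sorted(pair.unique())}
    n_arr = 1
    for idx in blocks.values():
        k = int((ecotype.iloc[idx] == "M").sum())
        n_arr *= math.comb(len(idx), k)
    rng = np.random.default_rng(seed)
    eco_arr = ecotype.to_numpy().copy()

    def stat_of(labels: np.ndarray) -> float:
        res = crda_fit(cpm_matrix, pd.Series(labels, index=samples), pair)
        return res.pseudo_F

    null = []
    if n_arr - 1 < n_perm:
        warnings.warn(
            f"only {n_arr} distinct within-block arrangements; enumerating exactly"
        )
        per_block = []
        for p, idx in blocks.items():
            labs = eco_arr[idx]
            opts = sorted(set(permutations(labs)))
            per_block.append((idx, opts))

        def recurse(i: int, labels: np.ndarray):
            if i == len(per_block):
                if not np.array_equal(labels, eco_arr):
                    null.append(stat_of(labels))
                return
            idx, opts = per_block[i]
            for opt in opts:
                lab2 = labels.copy()
                lab2[idx] = opt
                recurse(i + 1, lab2)

        recurse(0, eco_arr.copy())
    else:
        for _ in range(n_perm):
            labels = eco_arr.copy()
            for idx in blocks.values():
                labels[idx] = labels[idx][rng.permutation(len(idx))]
            null.append(stat_of(labels))
    null = np.asarray(null)
    p = (1.0 + np.sum(null >= obs.pseudo_F)) / (1.0 + len(null))
    return {"pseudo_F": obs.pseudo_F, "p_value": float(p), "null": null,
            "n_perm_used": len(null)}
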