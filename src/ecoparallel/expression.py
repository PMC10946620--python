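"""Negative-binomial differential expression for the paired-ecotype design.

A gene x sample integer count matrix with a sample sheet (ecotype pair,
ecotype) is filtered by mean counts-per-million, normalized with trimmed
mean of M-values (TMM) factors, and modelled per gene as negative binomial
with one mean per pair x ecotype cell (log link, effective library size
offsets).  Gene-wise dispersions are estimated by Cox-Reid adjusted profile
likelihood on a grid and moderated toward the all-gene average curve with a
fixed prior weight.  Each pair's ecotype contrast is tested by a likelihood
ratio test (chi-square, 1 df) comparing the full cell-mean model to the
model with that pair's two cells merged; Benjamini-Hochberg adjustment is
applied across genes within each pair.

This is a self-contained re-implementation of the standard count-based DE
workflow; the contract is statistical calibration (type-I error and FDR
control) and power on negative-binomial data, not numerical equivalence to
any particular published fitter.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln
from scipy.stats import chi2
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ExpressionExperiment",
    "DEResult",
    "filter_cpm",
    "tmm_factors",
    "fit_test",
    "bh_adjust",
    "deg_sets",
]


@dataclass
class ExpressionExperiment:
    """Counts (genes x samples) plus the sample sheet (sample, pair, ecotype)."""

    counts: pd.DataFrame
    samples: pd.DataFrame  # index = sample id, columns pair, ecotype
    tmm: pd.Series | None = None

    def __post_init__(self) -> None:
        if not set(self.counts.columns) == set(self.samples.index):
            raise ValueError("counts columns and sample sheet do not match")
        self.samples = self.samples.loc[list(self.counts.columns)]
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("negative counts")
        ecos = set(self.samples["ecotype"].unique())
        if not ecos <= {"A", "M"}:
            raise ValueError(f"ecotype labels must be A/M, got {ecos}")
        if (self.lib_size <= 0).any():
            bad = self.lib_size[self.lib_size <= 0].index.tolist()
            raise ValueError(f"all-zero samples: {bad}")

    @property
    def lib_size(self) -> pd.Series:
        return self.counts.sum(axis=0)

    @property
    def effective_lib_size(self) -> pd.Series:
        t = self.tmm if self.tmm is not None else pd.Series(1.0, index=self.counts.columns)
        return self.lib_size * t

    def cpm(self, use_tmm: bool = True) -> pd.DataFrame:
        size = self.effective_lib_size if use_tmm else self.lib_size
        return self.counts / size * 1e6

    def cells(self) -> pd.Series:
        """Pair x ecotype cell label per sample."""
        return self.samples["pair"].astype(str) + ":" + self.samples["ecotype"]


def filter_cpm(experiment: ExpressionExperiment, threshold: float = 1.0) -> ExpressionExperiment:
    """Keep genes with mean cpm strictly above ``threshold``.

    cpm is computed on raw library sizes (pre-TMM), mean taken across all
    samples, matching the usual low-count trimming step.
    """
    mean_cpm = experiment.cpm(use_tmm=False).mean(axis=1)
    keep = mean_cpm > threshold
    if not keep.any():
        raise ValueError("cpm filter removed every gene")
    return ExpressionExperiment(
        experiment.counts.loc[keep], experiment.samples.copy(), experiment.tmm
    )


def tmm_factors(
    experiment: ExpressionExperiment,
    trim_m: float = 0.30,
    trim_a: float = 0.05,
) -> pd.Series:
    """Weighted trimmed-mean-of-M-values normalization factors.

    The reference sample is the one whose upper-quartile cpm is closest to
    the mean upper-quartile.  For each sample, M (log2 fold) and A (log2
    abundance) values on genes positive in both sample and reference are
    two-sided trimmed (30% on M, 5% on A); the factor is 2 to the
    inverse-asymptotic-variance weighted mean of the kept M values, and
    factors are rescaled to geometric mean 1.
    """
    Y = experiment.counts.to_numpy(dtype=float)
    libs = experiment.lib_size.to_numpy(dtype=float)
    frac = Y / libs
    with np.errstate(invalid="ignore"):
        uq = np.array([
            np.quantile(frac[:, s][Y[:, s] > 0], 0.75) if (Y[:, s] > 0).any() else 0.0
            for s in range(Y.shape[1])
        ])
    ref = int(np.argmin(np.abs(uq - uq.mean())))
    factors = np.ones(Y.shape[1])
    for s in range(Y.shape[1]):
        if s == ref:
            continue
        both = (Y[:, s] > 0) & (Y[:, ref] > 0)
        if not both.any():
            continue
        ys, yr = Y[both, s], Y[both, ref]
        ns, nr = libs[s], libs[ref]
        M = np.log2((ys / ns) / (yr / nr))
        A = 0.5 * np.log2((ys / ns) * (yr / nr))
        lo_m, hi_m = np.quantile(M, [trim_m, 1 - trim_m])
        lo_a, hi_a = np.quantile(A, [trim_a, 1 - trim_a])
        keep = (M >= lo_m) & (M <= hi_m) & (A >= lo_a) & (A <= hi_a)
        if not keep.any():
            continue
        w = 1.0 / ((ns - ys[keep]) / (ns * ys[keep]) + (nr - yr[keep]) / (nr * yr[keep]))
        factors[s] = 2 ** (np.sum(w * M[keep]) / np.sum(w))
    factors = factors / np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=experiment.counts.columns, name="tmm")


# ---------------------------------------------------------------------------
# NB cell-mean fitting
# ---------------------------------------------------------------------------

def _fit_cell(Y: np.ndarray, e: np.ndarray, r: np.ndarray, n_iter: int = 40):
    """MLE of a single NB cell mean per gene with fixed dispersion.

    Y: (G, S_c) counts of the cell's samples; e: (S_c,) effective sizes;
    r: (G,) NB size parameter (1/dispersion).  The model is mu_gs = q_g *
    e_s.  Returns (q, loglik, fisher_info) per gene, where the information
    is with respect to log q.  Cells with zero total count get q = 0 and
    zero log-likelihood contribution.
    """
    tot = Y.sum(axis=1)
    q = np.maximum(tot, 0.5) / e.sum()
    b = np.log(q)
    converged = np.zeros(len(b), dtype=bool)
    for _ in range(n_iter):
        mu = np.exp(b)[:, None] * e[None, :]
        grad = np.sum(Y - (Y + r[:, None]) * mu / (mu + r[:, None]), axis=1)
        info = np.sum((r[:, None] * mu * (Y + r[:, None])) / (mu + r[:, None]) ** 2, axis=1)
        step = grad / np.maximum(info, 1e-10)
        step = np.clip(step, -3.0, 3.0)
        b = b + step
        newly = np.abs(step) < 1e-10
        converged |= newly
        if converged.all():
            break
    q = np.exp(b)
    zero = tot == 0
    q[zero] = 0.0
    mu = q[:, None] * e[None, :]
    with np.errstate(divide="ignore", invalid="ignore"):
        term = np.where(Y > 0, Y * np.log(np.maximum(mu, 1e-300)), 0.0)
        ll = np.sum(
            gammaln(Y + r[:, None]) - gammaln(r[:, None])
            + r[:, None] * np.log(r[:, None])
            + term
            - (Y + r[:, None]) * np.log(mu + r[:, None]),
            axis=1,
        )
    info = np.sum((r[:, None] * mu) / (mu + r[:, None]), axis=1)
    ll[zero] = 0.0
    return q, ll, info, ~converged & ~zero


def _apl(Y, e_by_cell, cell_cols, phi):
    """Cox-Reid adjusted profile log-likelihood at a common dispersion."""
    G = Y.shape[0]
    r = np.full(G, 1.0 / max(phi, 1e-12))
    apl = np.zeros(G)
    for cols, e in zip(cell_cols, e_by_cell):
        _, ll, info, _ = _fit_cell(Y[:, cols], e, r)
        apl += ll - 0.5 * np.log(np.maximum(info, 1e-8))
    return apl


@dataclass
class DEResult:
    """Per-gene, per-pair test results plus fitted quantities."""

    table: pd.DataFrame  # columns: gene, pair, logFC, stat, p, fdr, direction
    dispersion: pd.Series
    cell_means: pd.DataFrame
    background: list = field(default_factory=list)

    def significant(self, fdr: float = 0.05) -> pd.DataFrame:
        return self.table[self.table["fdr"] < fdr]


def estimate_dispersion(
    experiment: ExpressionExperiment,
    prior_df: float = 40.0,
    grid: np.ndarray | None = None,
) -> pd.Series:
    """Grid APL dispersion per gene, moderated toward the all-gene curve.

    The moderation weight is prior_df / residual_df, i.e. a fixed prior
    worth ``prior_df`` residual degrees of freedom.
    """
    Y = experiment.counts.to_numpy(dtype=float)
    e_all = experiment.effective_lib_size.to_numpy(dtype=float)
    cells = experiment.cells()
    labels = sorted(cells.unique())
    cell_cols = [np.where((cells == c).to_numpy())[0] for c in labels]
    e_by_cell = [e_all[cols] for cols in cell_cols]
    if grid is None:
        grid = np.logspace(-4, 1, 24)
    apl = np.stack([_apl(Y, e_by_cell, cell_cols, phi) for phi in grid], axis=1)
    common = apl.mean(axis=0)
    d_res = Y.shape[1] - len(labels)
    if d_res <= 0:
        raise ValueError("design leaves no residual degrees of freedom")
    prior_n = prior_df / d_res
    obj = apl + prior_n * common[None, :]
    phi_hat = grid[np.argmax(obj, axis=1)]
    return pd.Series(phi_hat, index=experiment.counts.index, name="dispersion")


def fit_test(
    experiment: ExpressionExperiment,
    prior_df: float = 40.0,
    dispersion: pd.Series | None = None,
) -> DEResult:
    """Fit the pair x ecotype NB cell-mean model and LRT each pair's contrast.

    Requires >= 2 replicates in every pair x ecotype cell.  The reduced model
    for pair p merges that pair's A and M cells; because cells are fitted
    independently the LRT statistic only involves the three fits of those
    samples.  logFC is log2 of the fitted M vs A cell means with an offset of
    half a count per (mean) library.
    """
    if experiment.tmm is None:
        experiment = ExpressionExperiment(
            experiment.counts, experiment.samples, tmm_factors(experiment)
        )
    cells = experiment.cells()
    counts_per_cell = cells.value_counts()
    if (counts_per_cell < 2).any():
        bad = counts_per_cell[counts_per_cell < 2].index.tolist()
        raise ValueError(f"cells with < 2 replicates: {bad}")
    Y = experiment.counts.to_numpy(dtype=float)
    genes = experiment.counts.index
    e_all = experiment.effective_lib_size.to_numpy(dtype=float)
    if dispersion is None:
        dispersion = estimate_dispersion(experiment, prior_df=prior_df)
    r = 1.0 / np.maximum(dispersion.to_numpy(dtype=float), 1e-12)

    labels = sorted(cells.unique())
    cell_cols = {c: np.where((cells == c).to_numpy())[0] for c in labels}
    q = {}
    ll = {}
    flagged = np.zeros(Y.shape[0], dtype=bool)
    for c in labels:
        cols = cell_cols[c]
        q[c], ll[c], _, bad = _fit_cell(Y[:, cols], e_all[cols], r)
        flagged |= bad

    pairs = sorted(experiment.samples["pair"].astype(str).unique())
    offset = 0.5 / float(np.mean(e_all))
    rows = []
    for pair in pairs:
        ca, cm = f"{pair}:A", f"{pair}:M"
        if ca not in cell_cols or cm not in cell_cols:
            raise ValueError(f"pair {pair} lacks one of the ecotypes")
        cols = np.concatenate([cell_cols[ca], cell_cols[cm]])
        _, ll_merged, _, bad = _fit_cell(Y[:, cols], e_all[cols], r)
        stat = np.maximum(2.0 * (ll[ca] + ll[cm] - ll_merged), 0.0)
        p = chi2.sf(stat, df=1)
        logfc = np.log2((q[cm] + offset) / (q[ca] + offset))
        p = np.where(flagged | bad, np.nan, p)
        fdr = bh_adjust(p)
        rows.append(pd.DataFrame({
            "gene": genes, "pair": pair, "logFC": logfc, "stat": stat,
            "p": p, "fdr": fdr, "direction": np.sign(logfc),
        }))
    table = pd.concat(rows, ignore_index=True)
    cell_means = pd.DataFrame(q, index=genes)
    return DEResult(table=table, dispersion=dispersion, cell_means=cell_means,
                    background=list(genes))


def bh_adjust(p: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment; NaN p-values propagate."""
    p = np.asarray(p, dtype=float)
    out = np.full_like(p, np.nan)
    ok = np.isfinite(p)
    if ok.any():
        if ((p[ok] < 0) | (p[ok] > 1)).any():
            raise ValueError("p-values outside [0, 1]")
        out[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return out


def deg_sets(de_result: DEResult, fdr: float = 0.05):
    """Per-pair directional DEG sets over the filtered-gene background.

    Returns a GeneSetCollection with 8 sets named ``pair<p>_over_in_M`` /
    ``pair<p>_under_in_M`` (logFC sign gives the direction of the montane
    relative to the alpine ecotype).
    """
    from .parallelism import GeneSetCollection

    sets = {}
    for pair, grp in de_result.table.groupby("pair", sort=True):
        sig = grp[grp["fdr"] < fdr]
        sets[f"pair{pair}_over_in_M"] = set(sig.loc[sig["logFC"] > 0, "gene"])
        sets[f"pair{pair}_under_in_M"] = set(sig.loc[sig["logFC"] < 0, "gene"])
    return GeneSetCollection(background=list(de_result.background), sets=sets)
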