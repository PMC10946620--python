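"""Synthetic data with the replicated-ecotype study structure.

Two generators make every analysis stage testable without external data:

* ``gen_expression`` — negative-binomial RNA-seq counts for the 4 ecotype
  pairs x 2 ecotypes x 3 replicates common-garden design, with a
  controllable fraction of genes differentially expressed per pair and a
  controllable fraction of those shared (same genes, consistent direction)
  across all pairs — the genetic-redundancy dial.  A truth table records
  each gene's DE status, pairs and direction.

* ``gen_genetic`` — per-site allele counts for four demes drawn from a
  demographic model via the structured-coalescent simulator, optionally
  pushed through depth-based binomial read resampling to emulate noisy
  low-coverage counts, plus folded joint SFS files for all six deme pairs.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import demography
from .demography import DemographicModel, jsfs_set_from_configs, simulate_genealogies
from .expression import ExpressionExperiment
from .sfs import write_jsfs_obs

__all__ = [
    "ExpressionScenario",
    "GeneticScenario",
    "gen_expression",
    "gen_genetic",
    "study_model",
]


@dataclass
class ExpressionScenario:
    """Study-design parameters for the expression generator.

    Defaults emulate the published design at desk scale: 4 ecotype pairs,
    3 replicates per ecotype, ~5% of genes DE per pair with only 2% of those
    shared across all pairs (the observed near-absence of shared DEGs), a
    log2 fold-change magnitude around 2 (clear but not extreme effects),
    NB dispersion 0.1 (typical for outbred plant RNA-seq) and ~2M-read
    libraries.
    """

    n_genes: int = 2_000
    pairs: tuple = ("1", "3", "4", "5")
    reps: int = 3
    frac_de: float = 0.05
    frac_shared: float = 0.02
    logfc_mean: float = 2.0
    logfc_sd: float = 0.5
    dispersion: float = 0.1
    lib_size_mean: float = 2e6
    lib_size_sigma: float = 0.15  # sdlog of the lognormal library sizes
    baseline_sigma: float = 1.5  # sdlog of relative gene abundances
    n_categories: int = 0  # synthetic annotation categories (0 = none)
    enriched_category_frac: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.frac_de <= 1 and 0 <= self.frac_shared <= 1):
            raise ValueError("frac_de and frac_shared must lie in [0, 1]")
        n_de = round(self.frac_de * self.n_genes)
        n_shared = round(self.frac_shared * n_de)
        n_private_total = len(self.pairs) * (n_de - n_shared)
        if n_shared + n_private_total > self.n_genes:
            raise ValueError(
                "infeasible scenario: private DE genes across pairs exceed the "
                "gene universe"
            )


def gen_expression(scenario: ExpressionScenario):
    """Simulate counts + sample sheet + truth table (+ optional annotation).

    Returns (experiment, truth, annotation).  Truth columns: gene, pair,
    is_de, logfc (signed log2 fold of M relative to A; 0 when not DE).
    Shared DE genes are DE in all pairs with a consistent direction.
    """
    rng = np.random.default_rng(scenario.seed)
    G = scenario.n_genes
    genes = [f"g{i:05d}" for i in range(G)]
    n_de = round(scenario.frac_de * G)
    n_shared = round(scenario.frac_shared * n_de)
    n_private = n_de - n_shared

    perm = rng.permutation(G)
    shared = perm[:n_shared]
    cursor = n_shared
    private = {}
    for p in scenario.pairs:
        private[p] = perm[cursor:cursor + n_private]
        cursor += n_private

    # signed log2 fold changes
    lfc = np.zeros((G, len(scenario.pairs)))
    shared_sign = rng.choice([-1.0, 1.0], size=n_shared)
    shared_mag = rng.normal(scenario.logfc_mean, scenario.logfc_sd, size=n_shared)
    for j, p in enumerate(scenario.pairs):
        lfc[shared, j] = shared_sign * np.abs(shared_mag)
        sign = rng.choice([-1.0, 1.0], size=n_private)
        mag = rng.normal(scenario.logfc_mean, scenario.logfc_sd, size=n_private)
        lfc[private[p], j] = sign * np.abs(mag)

    # sample sheet
    rows = []
    for p in scenario.pairs:
        for eco in ("A", "M"):
            for r in range(scenario.reps):
                rows.append({"sample": f"{eco}{p}_{r + 1}", "pair": p,
                             "ecotype": eco})
    sheet = pd.DataFrame(rows).set_index("sample")

    base = rng.lognormal(mean=0.0, sigma=scenario.baseline_sigma, size=G)
    base = base / base.sum()
    libs = rng.lognormal(np.log(scenario.lib_size_mean),
                         scenario.lib_size_sigma, size=len(sheet))
    counts = np.empty((G, len(sheet)), dtype=np.int64)
    r_nb = 1.0 / scenario.dispersion
    for s, (sample, meta) in enumerate(sheet.iterrows()):
        j = scenario.pairs.index(meta["pair"])
        shift = 0.5 * lfc[:, j] if meta["ecotype"] == "M" else -0.5 * lfc[:, j]
        mu = base * libs[s] * 2.0 ** shift
        counts[:, s] = rng.negative_binomial(r_nb, r_nb / (r_nb + mu))
    experiment = ExpressionExperiment(
        pd.DataFrame(counts, index=genes, columns=sheet.index), sheet
    )

    truth = pd.DataFrame(
        [
            {"gene": genes[g], "pair": p, "is_de": lfc[g, j] != 0,
             "logfc": lfc[g, j]}
            for j, p in enumerate(scenario.pairs)
            for g in range(G)
        ]
    )

    annotation = None
    if scenario.n_categories > 0:
        cat_of = rng.integers(scenario.n_categories, size=G)
        # plant one enriched category: bias it toward DE genes
        de_any = np.unique(np.concatenate([shared] + list(private.values())))
        take = rng.choice(
            de_any,
            size=max(1, int(scenario.enriched_category_frac * len(de_any))),
            replace=False,
        ) if len(de_any) else np.array([], dtype=int)
        cat_of[take] = 0
        annotation = pd.DataFrame(
            {"gene_id": genes, "category_id": [f"cat{c:03d}" for c in cat_of]}
        )
    return experiment, truth, annotation


@dataclass
class GeneticScenario:
    """Demographic model plus sequencing-style noise knobs."""

    model: DemographicModel
    n_loci: int = 5_000
    locus_length: float = 1_000.0
    mean_depth: float = 0.0  # per-haploid read depth; 0 disables resampling
    error_rate: float = 0.0
    seed: int = 0


def study_model(
    topology: str = "two_origins",
    mode: str = "SI",
    sample_size: int = 6,
    m_within: float = 5e-6,
    m_between: float = 5e-7,
) -> DemographicModel:
    """A four-deme model in the middle of the search priors.

    Alpine demes larger than montane (20,000 vs 3,000 diploids), splits at
    50,000 / 15,000 / 8,000 generations, mutation rate 1e-8.  IM migration
    defaults are low (4Nm well below 1, within-locality ten-fold higher than
    between), matching the very low rates the system's demographic analyses
    support.
    """
    params = dict(
        Ne=[20_000, 3_000, 20_000, 3_000],
        T1=50_000, T2=15_000, T3=8_000, mu=1e-8,
        sample_sizes=[sample_size] * 4,
    )
    if mode == "IM":
        params["m_within"] = m_within
        params["m_between"] = m_between
    return demography.build_model(topology, mode, params)


def gen_genetic(scenario: GeneticScenario, out_dir: str | Path | None = None):
    """Simulate allele counts for the four demes (+ optional .obs files).

    Returns (allele_counts, jsfs_dict, sim).  Counts are of the globally
    minor allele; with ``mean_depth`` > 0 each population's count is
    re-estimated from binomially resampled reads with the given error rate
    (sites with zero reads in a population are dropped for that population).
    """
    model = scenario.model
    sim = simulate_genealogies(
        model, scenario.n_loci, scenario.seed, scenario.locus_length
    )
    n_per = sim.n_per
    configs = sim.configs.copy()
    n_tot = int(n_per.sum())
    # globally minor allele orientation
    derived_tot = configs.sum(axis=1)
    flip = derived_tot > n_tot / 2
    configs[flip] = n_per[None, :] - configs[flip]

    rng = np.random.default_rng(scenario.seed + 1)
    # a stable site address shared by all populations: position = rank within locus
    chrom = np.array([f"locus{l}" for l in sim.locus])
    pos = np.empty(len(sim.locus), dtype=np.int64)
    for l in np.unique(sim.locus):
        sel = sim.locus == l
        pos[sel] = np.arange(1, sel.sum() + 1)
    rows = []
    for d, name in enumerate(sim.deme_names):
        c = configs[:, d].astype(float)
        n = int(n_per[d])
        keep = np.ones(len(c), dtype=bool)
        if scenario.mean_depth > 0:
            p = c / n
            p_err = p * (1 - scenario.error_rate) + (1 - p) * scenario.error_rate
            reads = rng.poisson(scenario.mean_depth * n, size=len(c))
            keep = reads > 0
            alt = rng.binomial(np.maximum(reads, 1), p_err)
            c = np.round(n * alt / np.maximum(reads, 1))
        rows.append(pd.DataFrame({
            "chrom": chrom[keep],
            "pos": pos[keep],
            "gene_id": chrom[keep],
            "pop": name,
            "minor_count": c[keep].astype(int),
            "n": n,
        }))
    table = pd.concat(rows, ignore_index=True)

    jsfs = jsfs_set_from_configs(configs, n_per, sim.deme_names)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for (a, b), spec in jsfs.items():
            write_jsfs_obs(spec, out_dir / f"jsfs_{a}_{b}.obs")
        table.to_csv(out_dir / "allele_counts.tsv", sep="\t", index=False)
    return table, jsfs, sim
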