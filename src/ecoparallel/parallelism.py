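"""Repeatability of gene usage across replicated divergence events.

Given per-replicate gene sets (e.g. DEGs per ecotype pair, FST outliers per
pair) over an explicit background universe, this module quantifies how much
more the sets overlap than expected if each replicate drew its genes
uniformly at random: Jaccard indices, exact hypergeometric overlap tests
(pairwise and k-way), the standardized C-hypergeometric repeatability score
of Yeaman et al. (2018), sharing partitions, and flat Fisher category
enrichment with direction z-scores.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from fractions import Fraction
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .expression import bh_adjust

__all__ = [
    "GeneSetCollection",
    "jaccard",
    "hypergeom_overlap",
    "multiset_exact_test",
    "c_hyper",
    "c_hyper_global",
    "sharing_partition",
    "category_enrichment",
    "overlap_report",
]


@dataclass
class GeneSetCollection:
    """Named gene sets over an explicit background universe."""

    background: Sequence
    sets: Mapping[str, set]

    def __post_init__(self) -> None:
        self.background = list(dict.fromkeys(self.background))
        bg = set(self.background)
        self.sets = {name: set(s) for name, s in self.sets.items()}
        for name, s in self.sets.items():
            stray = s - bg
            if stray:
                raise ValueError(
                    f"set {name!r} contains genes outside the background: "
                    f"{sorted(stray)[:5]}"
                )

    @property
    def N(self) -> int:
        return len(self.background)

    def sizes(self) -> dict[str, int]:
        return {name: len(s) for name, s in self.sets.items()}


def jaccard(set_a: Iterable, set_b: Iterable) -> float:
    """|A n B| / |A u B|; 0 when both sets are empty."""
    a, b = set(set_a), set(set_b)
    union = a | b
    if not union:
        return 0.0
    return len(a & b) / len(union)


def hypergeom_overlap(x: int, n1: int, n2: int, N: int) -> float:
    """Upper-tail overlap probability P(X >= x) for two uniform random sets."""
    if not (0 <= x <= min(n1, n2) <= N):
        raise ValueError(f"infeasible overlap: x={x}, n1={n1}, n2={n2}, N={N}")
    if x == 0:
        return 1.0
    return float(hypergeom.sf(x - 1, N, n1, n2))


def _multiset_pmf_exact(x: int, sizes: Sequence[int], N: int) -> Fraction:
    """P(k-way intersection = x) for independent uniform fixed-size subsets.

    Inclusion-exclusion over the elements forced into (or kept out of) the
    intersection, computed in exact integer arithmetic: the alternating sum
    is catastrophically cancellation-prone in floating point.
    """
    nmin = min(sizes)
    total = Fraction(0)
    denom = 1
    for n in sizes:
        denom *= math.comb(N, n)
    for i in range(0, nmin - x + 1):
        prod = 1
        for n in sizes:
            prod *= math.comb(N - x - i, n - x - i)
        term = math.comb(N - x, i) * prod
        total += Fraction((-1) ** i * term)
    return Fraction(math.comb(N, x)) * total / denom


def multiset_exact_test(
    collection: GeneSetCollection | None,
    set_names: Sequence[str] | None = None,
    *,
    sizes: Sequence[int] | None = None,
    N: int | None = None,
    x_obs: int | None = None,
) -> float:
    """Exact P(k-way intersection >= x_obs) under independent uniform sets.

    Call either with a collection and k set names (x_obs computed from the
    sets) or with explicit ``sizes``, ``N`` and ``x_obs``.  Reduces to the
    hypergeometric upper tail at k = 2.
    """
    if collection is not None:
        if set_names is None or len(set_names) < 2:
            raise ValueError("need at least 2 set names")
        chosen = [collection.sets[s] for s in set_names]
        sizes = [len(s) for s in chosen]
        N = collection.N
        x_obs = len(set.intersection(*chosen))
    if sizes is None or N is None or x_obs is None:
        raise ValueError("explicit sizes, N and x_obs required")
    if len(sizes) < 2:
        raise ValueError("need at least 2 sets")
    nmin = min(sizes)
    if not (0 <= x_obs <= nmin <= N):
        raise ValueError("infeasible intersection size")
    if x_obs == 0:
        return 1.0
    # sum the shorter side of the distribution
    if x_obs <= nmin - x_obs + 1:
        head = Fraction(0)
        for t in range(0, x_obs):
            head += _multiset_pmf_exact(t, sizes, N)
        return float(1 - head)
    tail = Fraction(0)
    for t in range(x_obs, nmin + 1):
        tail += _multiset_pmf_exact(t, sizes, N)
    return float(tail)


def c_hyper(x: int, n1: int, n2: int, N: int) -> float:
    """Standardized overlap excess (x - E) / sigma under the hypergeometric null.

    E = n1*n2/N and sigma^2 = n1*n2*(N-n1)*(N-n2) / (N^2 * (N-1)).
    """
    if not (0 <= x <= min(n1, n2) <= N):
        raise ValueError("infeasible overlap")
    E = n1 * n2 / N
    var = n1 * n2 * (N - n1) * (N - n2) / (N**2 * (N - 1))
    if var <= 0:
        raise ValueError(
            f"degenerate sets (n1={n1}, n2={n2}, N={N}): zero overlap variance"
        )
    return (x - E) / math.sqrt(var)


def c_hyper_global(
    collection: GeneSetCollection,
    n_perm: int = 1000,
    seed: int = 0,
    set_names: Sequence[str] | None = None,
) -> dict:
    """Permutation-standardized multi-replicate repeatability score.

    Statistic: number of genes present in >= 2 of the chosen sets.  The null
    redraws each set uniformly at random from the background at its observed
    size; the score is (observed - null mean) / null sd.
    """
    names = list(set_names) if set_names is not None else sorted(collection.sets)
    if len(names) < 3:
        raise ValueError("global repeatability score needs >= 3 sets")
    chosen = [collection.sets[s] for s in names]
    sizes = [len(s) for s in chosen]

    def n_reused(list_of_sets) -> int:
        counts: dict = {}
        for s in list_of_sets:
            for g in s:
                counts[g] = counts.get(g, 0) + 1
        return sum(1 for v in counts.values() if v >= 2)

    obs = n_reused(chosen)
    rng = np.random.default_rng(seed)
    bg = np.asarray(collection.background, dtype=object)
    null = np.empty(n_perm)
    for i in range(n_perm):
        rand_sets = [
            set(bg[rng.choice(len(bg), size=sz, replace=False)]) for sz in sizes
        ]
        null[i] = n_reused(rand_sets)
    sd = null.std()
    if sd == 0:
        raise ValueError("degenerate null: zero variance of reuse counts")
    return {
        "observed": obs,
        "null_mean": float(null.mean()),
        "null_sd": float(sd),
        "score": float((obs - null.mean()) / sd),
    }


def sharing_partition(collection: GeneSetCollection,
                      set_names: Sequence[str] | None = None) -> dict:
    """Counts of genes in exactly / at least 2, 3, ... sets.

    Also reports, per set, how many of its genes are shared with at least
    one other set.
    """
    names = list(set_names) if set_names is not None else sorted(collection.sets)
    chosen = {nm: collection.sets[nm] for nm in names}
    membership: dict = {}
    for nm, s in chosen.items():
        for g in s:
            membership.setdefault(g, set()).add(nm)
    k = len(names)
    exactly = {j: 0 for j in range(2, k + 1)}
    for g, mem in membership.items():
        if len(mem) >= 2:
            exactly[len(mem)] += 1
    at_least = {
        j: sum(v for jj, v in exactly.items() if jj >= j) for j in exactly
    }
    shared_per_set = {
        nm: sum(1 for g in s if len(membership[g]) >= 2) for nm, s in chosen.items()
    }
    return {"exactly": exactly, "at_least": at_least,
            "shared_with_any": shared_per_set}


def overlap_report(
    collection: GeneSetCollection,
    n_perm: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Pairwise Jaccard, overlap, expectation, hypergeometric p and C-score."""
    N = collection.N
    rows = []
    for a, b in itertools.combinations(sorted(collection.sets), 2):
        sa, sb = collection.sets[a], collection.sets[b]
        x = len(sa & sb)
        n1, n2 = len(sa), len(sb)
        rows.append({
            "set1": a, "set2": b, "n1": n1, "n2": n2, "overlap": x,
            "expected": n1 * n2 / N,
            "jaccard": jaccard(sa, sb),
            "hypergeom_p": hypergeom_overlap(x, n1, n2, N) if min(n1, n2) else 1.0,
            "c_hyper": (
                c_hyper(x, n1, n2, N)
                if 0 < n1 < N and 0 < n2 < N
                else float("nan")
            ),
        })
    return pd.DataFrame(rows)


def category_enrichment(
    gene_set: Iterable,
    background: Sequence,
    annotation: pd.DataFrame,
    logfc: Mapping | pd.Series | None = None,
) -> pd.DataFrame:
    """Flat one-sided Fisher enrichment of categories with direction z-scores.

    ``annotation`` has columns (gene_id, category_id); categories with no
    annotated background gene are dropped with a warning.  The z-score is
    (n_up - n_down) / sqrt(n_up + n_down) over the set members of the
    category, using the sign of their log fold-change (NaN when no member or
    no logfc given).  BH adjustment across categories.
    """
    import warnings

    bg = set(background)
    gs = set(gene_set)
    stray = gs - bg
    if stray:
        raise ValueError(f"gene_set outside background: {sorted(stray)[:5]}")
    ann = annotation[annotation["gene_id"].isin(bg)]
    dropped = set(annotation["category_id"]) - set(ann["category_id"])
    if dropped:
        warnings.warn(
            f"{len(dropped)} categories have no annotated background gene; dropped"
        )
    N, n = len(bg), len(gs)
    rows = []
    for cat, grp in ann.groupby("category_id", sort=True):
        genes_in_cat = set(grp["gene_id"])
        K = len(genes_in_cat)
        members = gs & genes_in_cat
        x = len(members)
        p = float(hypergeom.sf(x - 1, N, K, n)) if x > 0 else 1.0
        z = float("nan")
        if logfc is not None and x > 0:
            signs = np.sign([logfc[g] for g in members])
            n_up = int(np.sum(signs > 0))
            n_down = int(np.sum(signs < 0))
            if n_up + n_down > 0:
                z = (n_up - n_down) / math.sqrt(n_up + n_down)
        rows.append({
            "category": cat, "annotated_background": K, "annotated_set": x,
            "p": p, "z": z,
        })
    out = pd.DataFrame(rows)
    if not out.empty:
        out["fdr"] = bh_adjust(out["p"].to_numpy())
    return out
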