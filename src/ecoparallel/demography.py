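"""Four-deme demographic models and composite-likelihood model selection.

Two replicate ecotype pairs (an alpine and a montane population at each of
two localities) give four demes.  Two rooted histories are contrasted:

* ``two_origins`` — the ecotypes arose independently at each locality: the
  alpine and montane deme of locality 1 merge (backward in time) at T2, those
  of locality 2 at T3, and the two locality ancestors merge at T1.
* ``one_origin`` — each ecotype arose once: the two alpine demes merge at T2,
  the two montane demes at T3, and the ecotype ancestors merge at T1.

Each topology is evaluated under strict isolation (SI, no gene flow) and
isolation-with-migration (IM, continuous backward migration).  T1 is always
the oldest event; both T2 > T3 and T3 > T2 are representable.

Inference uses the folded joint SFS of all six deme pairs as summary
statistics.  The expected spectra are Monte-Carlo estimates from the
structured coalescent (branch lengths by joint allele configuration), and
the fit criterion is the multinomial composite log-likelihood over
polymorphic cells — monomorphic mass is excluded, which also removes the
mutation rate from the objective (only relative spectra matter).  Model
comparison uses AIC in natural-log units; a saturated-model bound
(``max_obs_lhood``) gives the fit gap ΔL.
"""

from __future__ import annotations

import hashlib
import itertools
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.optimize import minimize

from ._coalescent import decode_configs, sim_branch_lengths, sim_sites
from .sfs import JointFoldedSFS, fold_joint_matrix

__all__ = [
    "DemeConfig",
    "DemographicModel",
    "PriorBox",
    "FitResult",
    "build_model",
    "simulate_genealogies",
    "expected_jsfs",
    "expected_jsfs_all",
    "composite_loglik",
    "max_obs_lhood",
    "fit_model",
    "model_select",
    "jsfs_set_from_configs",
    "simulate_single_deme",
    "simulate_single_deme_sites",
]

TOPOLOGIES = ("one_origin", "two_origins")
MODES = ("SI", "IM")
DEFAULT_DEME_NAMES = ("A1", "M1", "A3", "M3")

# deme index convention: 0=A1, 1=M1 (locality one), 2=A3, 3=M3 (locality two);
# alpine demes are even indices, montane odd.
_ALPINE = (0, 2)
_WITHIN_LOCALITY = {(0, 1), (1, 0), (2, 3), (3, 2)}


@dataclass
class DemeConfig:
    """One sampled population: diploid Ne and an even haploid sample size."""

    name: str
    Ne: float
    sample_size: int

    def __post_init__(self) -> None:
        if self.Ne <= 0:
            raise ValueError(f"deme {self.name}: Ne must be > 0, got {self.Ne}")
        if self.sample_size < 2 or self.sample_size % 2 != 0:
            raise ValueError(
                f"deme {self.name}: sample_size must be even and >= 2, "
                f"got {self.sample_size}"
            )


@dataclass
class DemographicModel:
    topology: str
    mode: str
    demes: Sequence[DemeConfig]
    T1: float
    T2: float
    T3: float
    mu: float
    migration: np.ndarray = field(default_factory=lambda: np.zeros((4, 4)))
    ancestral_Ne: Mapping[str, float] | None = None  # keys: split2, split3, root

    def __post_init__(self) -> None:
        if self.topology not in TOPOLOGIES:
            raise ValueError(f"unknown topology {self.topology!r}")
        if self.mode not in MODES:
            raise ValueError(f"unknown mode {self.mode!r}")
        if len(self.demes) != 4:
            raise ValueError("exactly 4 demes required")
        if not (self.T1 > max(self.T2, self.T3)):
            raise ValueError(
                f"T1 ({self.T1}) must pre-date T2 ({self.T2}) and T3 ({self.T3})"
            )
        for t in (self.T1, self.T2, self.T3):
            if t <= 0:
                raise ValueError("split times must be positive")
        if self.mu < 0:
            raise ValueError("mutation rate must be >= 0")
        self.migration = np.asarray(self.migration, dtype=float)
        if self.migration.shape != (4, 4):
            raise ValueError("migration matrix must be 4x4")
        if np.any(self.migration < 0):
            raise ValueError("migration rates must be >= 0")
        np.fill_diagonal(self.migration, 0.0)
        if self.mode == "SI" and np.any(self.migration > 0):
            raise ValueError("SI mode requires a zero migration matrix")

    @property
    def deme_names(self) -> tuple[str, ...]:
        return tuple(d.name for d in self.demes)

    def merge_schedule(self) -> list[tuple[float, int, int, float]]:
        """(time, source deme, destination deme, ancestral Ne) sorted by time.

        Backward in time the source deme's lineages move into the destination;
        ancestral sizes default to the sum of the merging demes' current sizes
        (option ``ancestral_Ne`` frees them).
        """
        if self.topology == "two_origins":
            pairs = [("split2", 1, 0, self.T2), ("split3", 3, 2, self.T3)]
            root = ("root", 2, 0, self.T1)
        else:  # one_origin: ecotype-wise merges
            pairs = [("split2", 2, 0, self.T2), ("split3", 3, 1, self.T3)]
            root = ("root", 1, 0, self.T1)
        anc = dict(self.ancestral_Ne or {})
        size = {i: float(d.Ne) for i, d in enumerate(self.demes)}
        events = []
        for key, src, dst, t in sorted(pairs, key=lambda e: e[3]) + [root]:
            ne = float(anc.get(key, size[src] + size[dst]))
            events.append((t, src, dst, ne))
            size[dst] = ne
            size[src] = 0.0
        events.sort(key=lambda e: e[0])
        return events

    def arrays(self):
        """Low-level arrays for the compiled simulator."""
        n_per = np.array([d.sample_size for d in self.demes], dtype=np.int64)
        ne = np.array([d.Ne for d in self.demes], dtype=float)
        sched = self.merge_schedule()
        mtimes = np.array([e[0] for e in sched], dtype=float)
        msrc = np.array([e[1] for e in sched], dtype=np.int64)
        mdst = np.array([e[2] for e in sched], dtype=np.int64)
        mne = np.array([e[3] for e in sched], dtype=float)
        return n_per, ne, np.ascontiguousarray(self.migration), mtimes, msrc, mdst, mne


@dataclass
class PriorBox:
    """Per-parameter search bounds (lo, hi).

    Defaults: mutation rate 1e-10..1e-8 per site per generation, alpine Ne
    50..50,000 and montane Ne 50..5,000 diploids, split times 1,000..100,000
    generations, migration 1e-9..2 per lineage per generation.
    """

    mu: tuple[float, float] = (1e-10, 1e-8)
    ne_alpine: tuple[float, float] = (50.0, 50_000.0)
    ne_montane: tuple[float, float] = (50.0, 5_000.0)
    t: tuple[float, float] = (1_000.0, 100_000.0)
    m: tuple[float, float] = (1e-9, 2.0)

    def __post_init__(self) -> None:
        for name in ("mu", "ne_alpine", "ne_montane", "t", "m"):
            lo, hi = getattr(self, name)
            if not (0 < lo <= hi):
                raise ValueError(f"prior {name}: need 0 < lo <= hi, got {lo}, {hi}")


def build_model(
    topology: str,
    mode: str,
    params: Mapping,
    priors: PriorBox | None = None,
) -> DemographicModel:
    """Validate a parameter mapping into a DemographicModel.

    ``params`` keys: Ne (4 floats), sample_sizes (4 even ints), T1, T2, T3,
    mu, and for IM either ``migration`` (4x4) or ``m_within``/``m_between``
    (within- vs between-locality backward rates).
    """
    names = tuple(params.get("names", DEFAULT_DEME_NAMES))
    ne = [float(x) for x in params["Ne"]]
    ss = [int(x) for x in params.get("sample_sizes", (6, 6, 6, 6))]
    demes = [DemeConfig(nm, n, s) for nm, n, s in zip(names, ne, ss)]
    mig = np.zeros((4, 4))
    if mode == "IM":
        if "migration" in params:
            mig = np.asarray(params["migration"], dtype=float)
        else:
            mw = float(params.get("m_within", 0.0))
            mb = float(params.get("m_between", 0.0))
            for i in range(4):
                for j in range(4):
                    if i == j:
                        continue
                    mig[i, j] = mw if (i, j) in _WITHIN_LOCALITY else mb
    model = DemographicModel(
        topology=topology,
        mode=mode,
        demes=demes,
        T1=float(params["T1"]),
        T2=float(params["T2"]),
        T3=float(params["T3"]),
        mu=float(params["mu"]),
        migration=mig,
        ancestral_Ne=params.get("ancestral_Ne"),
    )
    if priors is not None:
        for i, d in enumerate(model.demes):
            lo, hi = priors.ne_alpine if i in _ALPINE else priors.ne_montane
            if not (lo <= d.Ne <= hi):
                raise ValueError(f"Ne of {d.name} outside prior [{lo}, {hi}]")
        if not (priors.mu[0] <= model.mu <= priors.mu[1]):
            raise ValueError("mu outside prior")
        if not (priors.t[0] <= model.T1 <= priors.t[1]):
            raise ValueError("T1 outside prior")
    return model


# ---------------------------------------------------------------------------
# simulation
# ---------------------------------------------------------------------------

@dataclass
class SimulatedLoci:
    """Infinite-sites output: per-site derived-allele configurations."""

    configs: np.ndarray  # (S, 4) derived counts per deme
    locus: np.ndarray  # (S,) locus index per site
    tmrca: np.ndarray  # (n_loci,) genealogy heights, generations
    n_per: np.ndarray  # haploid sample sizes
    deme_names: tuple[str, ...]


def simulate_genealogies(
    model: DemographicModel,
    n_loci: int,
    seed: int,
    locus_length: float = 1_000.0,
) -> SimulatedLoci:
    """Simulate genealogies and drop infinite-sites mutations.

    Mutations arrive on branches at rate mu * locus_length per generation.
    """
    if n_loci < 1:
        raise ValueError("n_loci must be >= 1")
    n_per, ne, mig, mtimes, msrc, mdst, mne = model.arrays()
    mu_locus = model.mu * locus_length
    # generous initial capacity: E[S] ~ mu_locus * E[total length]; retry on overflow
    cap = max(1000, int(4 * mu_locus * 8 * ne.sum() * n_loci) + 1000)
    while True:
        codes, locus, ns, heights = sim_sites(
            n_per, ne, mig, mtimes, msrc, mdst, mne, n_loci, mu_locus,
            seed % 2**31, cap,
        )
        if ns >= 0:
            break
        cap *= 4
    configs = decode_configs(codes[:ns], n_per)
    return SimulatedLoci(configs, locus[:ns].copy(), heights, n_per,
                         model.deme_names)


def simulate_single_deme(Ne: float, n: int, n_loci: int, seed: int,
                         mu: float = 0.0, locus_length: float = 1.0):
    """Single panmictic deme: returns (tmrca, config branch-length spectrum).

    The spectrum is the accumulated branch length subtending i samples,
    i = 1..n-1 — proportional to the expected unfolded SFS.
    """
    n_per = np.array([n, 0, 0, 0], dtype=np.int64)
    ne = np.array([Ne, 1.0, 1.0, 1.0])
    mig = np.zeros((4, 4))
    no_ev = np.empty(0, dtype=float)
    no_i = np.empty(0, dtype=np.int64)
    cfg, heights = sim_branch_lengths(
        n_per, ne, mig, no_ev, no_i, no_i, no_ev, n_loci, seed % 2**31
    )
    # config code for i copies in deme 0 is i * stride0, stride0 = 1 here
    # (other dims are width 1), so cfg[i] is the branch length subtending i.
    return heights, cfg[1:n]


def simulate_single_deme_sites(Ne: float, n: int, n_loci: int, mu_locus: float,
                               seed: int) -> np.ndarray:
    """Panmictic infinite-sites data: derived counts (1..n-1) per site.

    ``mu_locus`` is the per-generation mutation rate of a whole locus.
    """
    n_per = np.array([n, 0, 0, 0], dtype=np.int64)
    ne = np.array([Ne, 1.0, 1.0, 1.0])
    mig = np.zeros((4, 4))
    no_ev = np.empty(0, dtype=float)
    no_i = np.empty(0, dtype=np.int64)
    cap = max(1000, int(8 * mu_locus * 4 * Ne * math.log(n) * n_loci) + 1000)
    while True:
        codes, _, ns, _ = sim_sites(n_per, ne, mig, no_ev, no_i, no_i, no_ev,
                                    n_loci, mu_locus, seed % 2**31, cap)
        if ns >= 0:
            break
        cap *= 4
    return codes[:ns].copy()  # code == derived count in the single deme


def _pair_matrices(cfg: np.ndarray, n_per: np.ndarray) -> dict:
    """Project flat config lengths onto all six unfolded pairwise matrices."""
    codes = np.nonzero(cfg)[0]
    lengths = cfg[codes]
    configs = decode_configs(codes, n_per)
    out = {}
    for a, b in itertools.combinations(range(4), 2):
        mat = np.zeros((n_per[a] + 1, n_per[b] + 1))
        np.add.at(mat, (configs[:, a], configs[:, b]), lengths)
        out[(a, b)] = mat
    return out


def expected_jsfs_all(
    model: DemographicModel, n_sims: int, seed: int,
    max_events_per_tree: int = 1_000_000,
) -> dict[tuple[str, str], JointFoldedSFS]:
    """Expected folded jSFS (normalized over polymorphic cells) for all pairs.

    ``max_events_per_tree`` bounds the simulation effort per genealogy;
    parameter regimes that exceed it (extreme migration) are reported as
    infeasible via FloatingPointError.
    """
    if n_sims < 1:
        raise ValueError("n_sims must be >= 1")
    n_per, ne, mig, mtimes, msrc, mdst, mne = model.arrays()
    cfg, heights = sim_branch_lengths(
        n_per, ne, mig, mtimes, msrc, mdst, mne, n_sims, seed % 2**31,
        max_events_per_tree,
    )
    if heights[0] < 0:
        raise FloatingPointError(
            "per-tree event budget exceeded (migration regime too intense "
            "to simulate at this effort)"
        )
    names = model.deme_names
    out = {}
    for (a, b), mat in _pair_matrices(cfg, n_per).items():
        folded = fold_joint_matrix(mat)
        folded[0, 0] = 0.0
        tot = folded.sum()
        if tot <= 0:
            raise FloatingPointError(
                f"no polymorphic mass for pair {names[a]}-{names[b]}"
            )
        out[(names[a], names[b])] = JointFoldedSFS(
            folded / tot, n1=int(n_per[a]), n2=int(n_per[b]),
            pops=(names[a], names[b]),
        )
    return out


def expected_jsfs(
    model: DemographicModel,
    pop_pair: tuple[str, str],
    n_sims: int,
    seed: int,
) -> JointFoldedSFS:
    """Expected folded jSFS for one deme pair, normalized to sum 1."""
    if n_sims < 1000:
        raise ValueError("n_sims must be >= 1000 for a usable expectation")
    all_pairs = expected_jsfs_all(model, n_sims, seed)
    for key, val in all_pairs.items():
        if key == tuple(pop_pair) or key == tuple(reversed(pop_pair)):
            return val if key == tuple(pop_pair) else val.transpose()
    raise KeyError(f"pair {pop_pair} not in model demes {model.deme_names}")


def jsfs_set_from_configs(
    configs: np.ndarray, n_per: np.ndarray, names: Sequence[str]
) -> dict[tuple[str, str], JointFoldedSFS]:
    """Observed folded jSFS counts for all six pairs from per-site configs."""
    out = {}
    for a, b in itertools.combinations(range(4), 2):
        mat = np.zeros((n_per[a] + 1, n_per[b] + 1))
        np.add.at(mat, (configs[:, a], configs[:, b]), 1.0)
        folded = fold_joint_matrix(mat)
        folded[0, 0] = 0.0  # sites monomorphic within the pair carry no signal
        out[(names[a], names[b])] = JointFoldedSFS(
            folded, n1=int(n_per[a]), n2=int(n_per[b]), pops=(names[a], names[b])
        )
    return out


# ---------------------------------------------------------------------------
# composite likelihood and model selection
# ---------------------------------------------------------------------------

def _as_pairs(obs) -> list[JointFoldedSFS]:
    if isinstance(obs, Mapping):
        return [obs[k] for k in sorted(obs)]
    if isinstance(obs, JointFoldedSFS):
        return [obs]
    return list(obs)


def composite_loglik(obs, expected, floor: float = 1e-8) -> float:
    """Multinomial composite log-likelihood over polymorphic jSFS cells.

    lnCL = sum over pairs and cells of m_cell * ln(p_cell) with expected cell
    probabilities renormalized over polymorphic cells and floored at ``floor``
    (unvisited Monte-Carlo cells would otherwise contribute -inf).
    """
    obs_l, exp_l = _as_pairs(obs), _as_pairs(expected)
    if len(obs_l) != len(exp_l):
        raise ValueError("observed and expected spectra sets differ in length")
    ll = 0.0
    for o, e in zip(obs_l, exp_l):
        if o.matrix.shape != e.matrix.shape:
            raise ValueError(
                f"dimension mismatch: obs {o.matrix.shape} vs expected "
                f"{e.matrix.shape}"
            )
        mask = o.polymorphic_mask()
        m = o.matrix[mask]
        p = e.matrix[mask]
        tot = p.sum()
        if tot > 0:
            p = p / tot
        p = np.maximum(p, floor)
        ll += float(np.sum(m * np.log(p)))
    return ll


def max_obs_lhood(obs) -> float:
    """Saturated-model bound: observed proportions plugged in as probabilities."""
    obs_l = _as_pairs(obs)
    ll = 0.0
    any_mass = False
    for o in obs_l:
        mask = o.polymorphic_mask()
        m = o.matrix[mask]
        tot = m.sum()
        if tot <= 0:
            continue
        any_mass = True
        nz = m > 0
        ll += float(np.sum(m[nz] * np.log(m[nz] / tot)))
    if not any_mass:
        raise ValueError("empty spectrum: no polymorphic sites observed")
    return ll


@dataclass
class FitResult:
    model_id: str
    topology: str
    mode: str
    params: dict
    lnCL_est: float
    lnCL_obs: float
    k: int
    n_sims: int
    seed: int
    restarts: list = field(default_factory=list)
    obs_key: str = ""

    def __post_init__(self) -> None:
        if self.lnCL_est > self.lnCL_obs + 1e-9:
            raise ValueError("lnCL_est exceeds the saturated-model bound")

    @property
    def AIC(self) -> float:
        return 2 * self.k - 2 * self.lnCL_est

    @property
    def delta_L(self) -> float:
        return self.lnCL_obs - self.lnCL_est

    @property
    def log10CL_est(self) -> float:
        return self.lnCL_est / math.log(10)

    @property
    def log10CL_obs(self) -> float:
        return self.lnCL_obs / math.log(10)


def _obs_key(obs) -> str:
    h = hashlib.sha1()
    for o in _as_pairs(obs):
        h.update(np.ascontiguousarray(o.matrix).tobytes())
    return h.hexdigest()


def _infer_sample_sizes(obs: Mapping, names: Sequence[str]) -> dict[str, int]:
    sizes: dict[str, int] = {}
    for (a, b), jsfs in obs.items():
        for nm, n in ((a, jsfs.n1), (b, jsfs.n2)):
            if sizes.setdefault(nm, n) != n:
                raise ValueError(f"inconsistent sample size for deme {nm}")
    missing = [nm for nm in names if nm not in sizes]
    if missing:
        raise ValueError(f"no observed spectra mention demes {missing}")
    return sizes


def fit_model(
    obs: Mapping[tuple[str, str], JointFoldedSFS],
    topology: str,
    mode: str,
    priors: PriorBox | None = None,
    n_restarts: int = 3,
    n_sims: int = 2_000,
    seed: int = 0,
    maxiter: int = 120,
    deme_names: Sequence[str] = DEFAULT_DEME_NAMES,
    max_events_per_tree: int = 4_000,
    max_split_fraction: float = 0.98,
) -> FitResult:
    """Multi-start bounded Nelder-Mead fit of one model class.

    Search space (log10 where noted): per-deme Ne (log10), T1 (log10) and the
    split-time fractions u2, u3 in (0, 1) with T2 = u2*T1, T3 = u3*T1 (T1 is
    oldest by construction), plus for IM the within- and between-locality
    backward migration rates (log10).  The mutation rate does not enter the
    polymorphic-cell likelihood and is held at the geometric midpoint of its
    prior.  Common random numbers (one simulation seed per fit) keep the
    Monte-Carlo objective deterministic for the optimizer.
    ``max_split_fraction`` caps u2 and u3, restricting the search to
    histories whose recent splits are clearly separated from the root; it
    applies symmetrically to every model class being compared.
    """
    if n_restarts < 1:
        raise ValueError("n_restarts must be >= 1")
    priors = priors or PriorBox()
    rng = np.random.default_rng(seed)
    crn_seed = int(rng.integers(2**31 - 1))
    sizes = _infer_sample_sizes(obs, deme_names)
    sample_sizes = [sizes[nm] for nm in deme_names]
    mu_fixed = math.sqrt(priors.mu[0] * priors.mu[1])
    floor = 1.0 / (10.0 * n_sims)
    obs_sorted = {k: obs[k] for k in sorted(obs)}
    lnCL_obs = max_obs_lhood(obs_sorted)

    u_hi = float(max_split_fraction)
    lo = [math.log10(priors.ne_alpine[0]), math.log10(priors.ne_montane[0]),
          math.log10(priors.ne_alpine[0]), math.log10(priors.ne_montane[0]),
          math.log10(priors.t[0]), 0.02, 0.02]
    hi = [math.log10(priors.ne_alpine[1]), math.log10(priors.ne_montane[1]),
          math.log10(priors.ne_alpine[1]), math.log10(priors.ne_montane[1]),
          math.log10(priors.t[1]), u_hi, u_hi]
    if mode == "IM":
        lo += [math.log10(priors.m[0])] * 2
        hi += [math.log10(priors.m[1])] * 2
    lo_a, hi_a = np.array(lo), np.array(hi)
    k = len(lo_a)

    def unpack(x: np.ndarray) -> dict:
        xc = np.minimum(np.maximum(x, lo_a), hi_a)
        p = {
            "Ne": [10 ** xc[0], 10 ** xc[1], 10 ** xc[2], 10 ** xc[3]],
            "T1": 10 ** xc[4],
            "sample_sizes": sample_sizes,
            "mu": mu_fixed,
            "names": tuple(deme_names),
        }
        p["T2"] = xc[5] * p["T1"]
        p["T3"] = xc[6] * p["T1"]
        if mode == "IM":
            p["m_within"] = 10 ** xc[7]
            p["m_between"] = 10 ** xc[8]
        return p

    def objective(x: np.ndarray) -> float:
        penalty = float(np.sum(np.maximum(x - hi_a, 0) ** 2)
                        + np.sum(np.maximum(lo_a - x, 0) ** 2))
        params = unpack(x)
        model = build_model(topology, mode, params)
        try:
            exp_all = expected_jsfs_all(
                model, n_sims, crn_seed, max_events_per_tree=max_events_per_tree
            )
        except FloatingPointError:
            # unsimulatable regime (extreme migration) or degenerate spectrum
            return 1e12
        exp_sorted = {key: exp_all[key] for key in sorted(exp_all)}
        ll = composite_loglik(obs_sorted, exp_sorted, floor=floor)
        if not np.isfinite(ll):
            raise FloatingPointError(
                f"non-finite composite likelihood at parameters {params}"
            )
        return -ll + 100.0 * penalty

    nm_opts = {"xatol": 1e-3, "fatol": 1e-3, "adaptive": True}
    restarts = []
    best = None
    for r in range(n_restarts):
        # draw a feasible start (reject unsimulatable migration regimes)
        x0 = rng.uniform(lo_a, hi_a)
        if mode == "IM":
            # warm start: optimize the no-migration subspace first, then
            # free the two migration rates from a low initial value
            pin = np.array([lo_a[7], lo_a[8]])

            def obj_nomig(x7):
                return objective(np.concatenate([x7, pin]))

            res0 = minimize(obj_nomig, x0[:7], method="Nelder-Mead",
                            options={"maxiter": maxiter, **nm_opts})
            x0 = np.concatenate([res0.x, [-6.0, -6.5]])
        else:
            for _ in range(30):
                if objective(x0) < 1e11:
                    break
                x0 = rng.uniform(lo_a, hi_a)
        res = minimize(objective, x0, method="Nelder-Mead",
                       options={"maxiter": maxiter, **nm_opts})
        ll_est = -float(res.fun)
        rec = {"restart": r, "x0": x0.tolist(), "x": res.x.tolist(),
               "lnCL_est": ll_est, "n_iter": int(res.nit)}
        restarts.append(rec)
        if best is None or ll_est > best[0]:
            best = (ll_est, res.x)

    ll_best, x_best = best
    ll_best = min(ll_best, lnCL_obs)  # Monte-Carlo noise guard on the bound
    params_best = unpack(np.asarray(x_best))
    return FitResult(
        model_id=f"{topology}_{mode}",
        topology=topology,
        mode=mode,
        params=params_best,
        lnCL_est=ll_best,
        lnCL_obs=lnCL_obs,
        k=k,
        n_sims=n_sims,
        seed=seed,
        restarts=restarts,
        obs_key=_obs_key(obs_sorted),
    )


def model_select(fits: Iterable[FitResult]):
    """Rank fitted models by AIC; ΔAIC relative to the best, ΔL per model."""
    import pandas as pd

    fits = list(fits)
    if len(fits) < 2:
        raise ValueError("model selection needs at least two fits")
    keys = {f.obs_key for f in fits}
    if len(keys) > 1:
        raise ValueError("fits were computed on different observed data")
    best_aic = min(f.AIC for f in fits)
    rows = [
        {
            "model": f.model_id,
            "k": f.k,
            "lnCL_est": f.lnCL_est,
            "lnCL_obs": f.lnCL_obs,
            "log10CL_est": f.log10CL_est,
            "delta_L": f.delta_L,
            "AIC": f.AIC,
            "delta_AIC": f.AIC - best_aic,
        }
        for f in fits
    ]
    return pd.DataFrame(rows).sort_values("delta_AIC").reset_index(drop=True)
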