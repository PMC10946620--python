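"""Structured coalescent, expected spectra and composite-likelihood fitting."""

import math

import msprime
import numpy as np
import pytest

from ecoparallel import demography
from ecoparallel.demography import (
    DemeConfig,
    DemographicModel,
    FitResult,
    PriorBox,
    build_model,
    composite_loglik,
    expected_jsfs,
    expected_jsfs_all,
    fit_model,
    jsfs_set_from_configs,
    max_obs_lhood,
    model_select,
    simulate_genealogies,
    simulate_single_deme,
)
from ecoparallel.sfs import JointFoldedSFS, fold_joint_matrix


def base_params(**over):
    p = dict(Ne=[20_000, 3_000, 20_000, 3_000], T1=50_000, T2=15_000, T3=8_000,
             mu=1e-8, sample_sizes=[6, 6, 6, 6])
    p.update(over)
    return p


# ---------------------------------------------------------------------------
# model construction and validation
# ---------------------------------------------------------------------------

def test_build_valid_two_origins_si():
    m = build_model("two_origins", "SI", base_params(T1=50_000, T2=20_000, T3=10_000))
    sched = m.merge_schedule()
    # locality merges: M1(1)->A1(0) and M3(3)->A3(2), then root
    assert {(s, d) for _, s, d, _ in sched[:2]} == {(1, 0), (3, 2)}
    assert sched[-1][0] == 50_000
    # ancestral sizes tied to daughter sums by default
    assert sched[0][3] == pytest.approx(23_000)


def test_one_origin_merges_ecotypes():
    m = build_model("one_origin", "IM", base_params(m_within=1e-5, m_between=1e-6))
    sched = m.merge_schedule()
    assert {(s, d) for _, s, d, _ in sched[:2]} == {(2, 0), (3, 1)}
    # IM fills the migration matrix with the within/between structure
    assert m.migration[0, 1] == pytest.approx(1e-5)
    assert m.migration[0, 2] == pytest.approx(1e-6)


def test_validation_errors():
    with pytest.raises(ValueError, match="migration"):
        DemographicModel("one_origin", "IM",
                         [DemeConfig(n, 100, 4) for n in "abcd"],
                         T1=5000, T2=100, T3=100, mu=1e-8,
                         migration=np.full((4, 4), -1.0))
    with pytest.raises(ValueError, match="pre-date"):
        build_model("two_origins", "SI", base_params(T1=1000, T2=20_000))
    with pytest.raises(ValueError, match="even"):
        build_model("two_origins", "SI", base_params(sample_sizes=[5, 6, 6, 6]))
    with pytest.raises(ValueError, match="zero migration"):
        DemographicModel("one_origin", "SI",
                         [DemeConfig(n, 100, 4) for n in "abcd"],
                         T1=5000, T2=100, T3=100, mu=1e-8,
                         migration=np.full((4, 4), 0.1))
    with pytest.raises(ValueError):
        DemeConfig("x", -5, 4)
    # both split orders representable
    build_model("two_origins", "SI", base_params(T2=8_000, T3=15_000))


# ---------------------------------------------------------------------------
# coalescent correctness
# ---------------------------------------------------------------------------

def test_single_deme_tmrca_matches_2ne():
    Ne, n_loci = 1_000, 5_000
    heights, _ = simulate_single_deme(Ne, 2, n_loci, seed=1)
    se = heights.std() / math.sqrt(n_loci)
    assert abs(heights.mean() - 2 * Ne) <= 3 * se


def test_panmictic_branch_spectrum_proportional_to_1_over_i():
    _, spectrum = simulate_single_deme(1_000, 10, 8_000, seed=2)
    expected = 1.0 / np.arange(1, 10)
    ratio = spectrum / spectrum.sum()
    expected = expected / expected.sum()
    assert np.max(np.abs(ratio - expected)) < 0.01


def test_pairwise_diversity_matches_theta():
    # mean within-deme pairwise diversity per site ~ 4 Ne mu
    model = build_model(
        "two_origins", "SI",
        base_params(Ne=[5_000] * 4, T1=200_000, T2=100_000, T3=90_000,
                    sample_sizes=[2, 2, 2, 2], mu=1e-7),
    )
    sim = simulate_genealogies(model, 4_000, seed=3, locus_length=100)
    # deme 0, n=2: heterozygous sites have exactly one derived copy
    het = np.sum(sim.configs[:, 0] == 1)
    pi = het / (4_000 * 100)
    theta = 4 * 5_000 * 1e-7
    assert pi == pytest.approx(theta, rel=0.1)


def test_strict_isolation_tmrca_exceeds_root_time():
    model = build_model("two_origins", "SI", base_params(Ne=[500] * 4))
    sim = simulate_genealogies(model, 300, seed=4)
    assert np.all(sim.tmrca > 50_000)


def test_expected_jsfs_symmetric_pair_transposition():
    model = build_model(
        "two_origins", "SI", base_params(Ne=[5_000, 5_000, 5_000, 5_000])
    )
    n_per, ne, mig, mtimes, msrc, mdst, mne = model.arrays()
    from ecoparallel._coalescent import sim_branch_lengths
    cfg, _ = sim_branch_lengths(n_per, ne, mig, mtimes, msrc, mdst, mne, 20_000, 5)
    mats = demography._pair_matrices(cfg, n_per)
    B = mats[(0, 1)]  # A1-M1, exchangeable demes under equal sizes
    B = B / B.sum()
    assert np.max(np.abs(B - B.T)) < 0.01


def test_near_zero_split_times_recover_panmictic_marginal():
    model = build_model(
        "two_origins", "SI",
        base_params(Ne=[5_000] * 4, T1=20, T2=10, T3=10,
                    ancestral_Ne={"split2": 5_000, "split3": 5_000, "root": 5_000}),
    )
    n_per, ne, mig, mtimes, msrc, mdst, mne = model.arrays()
    from ecoparallel._coalescent import sim_branch_lengths
    cfg, _ = sim_branch_lengths(n_per, ne, mig, mtimes, msrc, mdst, mne, 20_000, 6)
    mats = demography._pair_matrices(cfg, n_per)
    marginal = mats[(0, 1)].sum(axis=1)[1:6]  # deme-0 classes 1..5
    expected = 1.0 / np.arange(1, 6)
    np.testing.assert_allclose(
        marginal / marginal.sum(), expected / expected.sum(), atol=0.01
    )


def test_topologies_produce_distinct_between_locality_spectra():
    params = base_params()
    two = build_model("two_origins", "SI", params)
    one = build_model("one_origin", "SI", params)
    j2 = expected_jsfs(two, ("A1", "A3"), n_sims=20_000, seed=7)
    j1 = expected_jsfs(one, ("A1", "A3"), n_sims=20_000, seed=7)
    tv_between = 0.5 * np.abs(j2.matrix - j1.matrix).sum()
    # Monte-Carlo noise scale: same model, different seeds
    j2b = expected_jsfs(two, ("A1", "A3"), n_sims=20_000, seed=8)
    tv_noise = 0.5 * np.abs(j2.matrix - j2b.matrix).sum()
    assert tv_between > 5 * tv_noise


# ---------------------------------------------------------------------------
# independent coalescent oracle (msprime)
# ---------------------------------------------------------------------------

def msprime_folded_jsfs(model, pair, num_reps, seed):
    """Expected folded jSFS for a deme pair from msprime branch statistics."""
    dem = msprime.Demography()
    sizes = {d.name: d.Ne for d in model.demes}
    for d in model.demes:
        dem.add_population(name=d.name, initial_size=d.Ne)
    sched = model.merge_schedule()
    names = list(model.deme_names)
    anc_names = []
    cur = {i: names[i] for i in range(4)}
    for k, (t, src, dst, ne) in enumerate(sched):
        anc = f"ANC{k}"
        dem.add_population(name=anc, initial_size=ne)
        dem.add_population_split(time=t, derived=[cur[src], cur[dst]], ancestral=anc)
        cur[dst] = anc
        anc_names.append(anc)
    for i in range(4):
        for j in range(4):
            if i != j and model.migration[i, j] > 0:
                dem.set_migration_rate(source=names[i], dest=names[j],
                                       rate=model.migration[i, j])
    dem.sort_events()
    # diploid Ne convention: n haploid lineages = n/2 diploid individuals
    samples = {d.name: d.sample_size // 2 for d in model.demes}
    reps = msprime.sim_ancestry(
        samples=samples, demography=dem, ploidy=2,
        num_replicates=num_reps, random_seed=seed,
    )
    ia, ib = names.index(pair[0]), names.index(pair[1])
    na = model.demes[ia].sample_size
    nb = model.demes[ib].sample_size
    afs = np.zeros((na + 1, nb + 1))
    offs = np.cumsum([0] + [d.sample_size for d in model.demes])
    set_a = list(range(offs[ia], offs[ia + 1]))
    set_b = list(range(offs[ib], offs[ib + 1]))
    for ts in reps:
        afs += ts.allele_frequency_spectrum(
            sample_sets=[set_a, set_b], mode="branch", polarised=True,
            span_normalise=False,
        )
    folded = fold_joint_matrix(afs)
    folded[0, 0] = 0.0
    return folded / folded.sum()


def tv(a, b):
    return 0.5 * float(np.abs(a - b).sum())


def test_expected_jsfs_agrees_with_msprime_oracle_im():
    # IM pair: migration between the two demes of locality one
    model = build_model(
        "two_origins", "IM",
        base_params(Ne=[8_000, 3_000, 8_000, 3_000], m_within=2e-5, m_between=0.0),
    )
    oracle = msprime_folded_jsfs(model, ("A1", "M1"), num_reps=30_000, seed=10)
    mine_small = expected_jsfs(model, ("A1", "M1"), n_sims=1_500, seed=11).matrix
    mine_big = expected_jsfs(model, ("A1", "M1"), n_sims=40_000, seed=11).matrix
    assert tv(mine_big, oracle) < 0.02
    # Monte-Carlo error shrinks with the number of simulated genealogies
    assert tv(mine_big, oracle) < tv(mine_small, oracle)


# ---------------------------------------------------------------------------
# composite likelihood
# ---------------------------------------------------------------------------

def two_cell_obs(c1, c2):
    mat = np.zeros((3, 3))
    mat[0, 1] = c1
    mat[1, 0] = c2
    return JointFoldedSFS(mat, 2, 2)


def test_composite_loglik_hand_value():
    obs = two_cell_obs(3, 1)
    exp = JointFoldedSFS(np.zeros((3, 3)), 2, 2)
    exp.matrix[0, 1] = 0.5
    exp.matrix[1, 0] = 0.5
    assert composite_loglik([obs], [exp]) == pytest.approx(4 * math.log(0.5))


def test_max_obs_lhood_hand_value_and_invariance():
    obs = two_cell_obs(3, 1)
    expected = 3 * math.log(0.75) + 1 * math.log(0.25)
    assert max_obs_lhood([obs]) == pytest.approx(expected)
    assert max_obs_lhood([two_cell_obs(1, 3)]) == pytest.approx(expected)
    # all mass in one cell -> 0
    assert max_obs_lhood([two_cell_obs(5, 0)]) == pytest.approx(0.0)
    with pytest.raises(ValueError, match="empty"):
        max_obs_lhood([JointFoldedSFS(np.zeros((3, 3)), 2, 2)])


def test_saturated_model_attains_the_bound_and_gibbs_inequality():
    rng = np.random.default_rng(12)
    mat = np.zeros((4, 4))
    mat[0, 1], mat[1, 0], mat[1, 1], mat[2, 0] = rng.integers(1, 30, 4)
    obs = JointFoldedSFS(mat, 3, 3)
    sat = JointFoldedSFS(mat / mat.sum(), 3, 3)
    bound = max_obs_lhood([obs])
    assert composite_loglik([obs], [sat], floor=1e-300) == pytest.approx(bound)
    for _ in range(10):
        q = np.zeros((4, 4))
        q[0, 1], q[1, 0], q[1, 1], q[2, 0] = rng.dirichlet(np.ones(4))
        other = JointFoldedSFS(q, 3, 3)
        assert composite_loglik([obs], [other], floor=1e-300) <= bound + 1e-9


def test_dimension_mismatch_rejected():
    with pytest.raises(ValueError, match="mismatch"):
        composite_loglik([two_cell_obs(1, 1)],
                         [JointFoldedSFS(np.zeros((4, 4)), 3, 3)])


# ---------------------------------------------------------------------------
# fitting and model selection
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def observed_two_origins():
    truth = build_model("two_origins", "SI", base_params())
    sim = simulate_genealogies(truth, 4_000, seed=20, locus_length=100)
    return jsfs_set_from_configs(sim.configs, sim.n_per, sim.deme_names)


def test_fit_is_deterministic_under_seed(observed_two_origins):
    kw = dict(n_restarts=1, n_sims=500, seed=5, maxiter=25)
    f1 = fit_model(observed_two_origins, "two_origins", "SI", **kw)
    f2 = fit_model(observed_two_origins, "two_origins", "SI", **kw)
    assert f1.lnCL_est == f2.lnCL_est
    assert f1.params["T1"] == f2.params["T1"]
    assert f1.lnCL_est <= f1.lnCL_obs
    assert f1.AIC == pytest.approx(2 * f1.k - 2 * f1.lnCL_est)


def test_point_priors_pin_parameters(observed_two_origins):
    pri = PriorBox(mu=(1e-9, 1e-9), ne_alpine=(9_000, 9_000),
                   ne_montane=(2_000, 2_000), t=(30_000, 30_000), m=(1e-5, 1e-5))
    fit = fit_model(observed_two_origins, "two_origins", "IM", priors=pri,
                    n_restarts=1, n_sims=300, seed=1, maxiter=10)
    assert fit.params["Ne"][0] == pytest.approx(9_000)
    assert fit.params["Ne"][1] == pytest.approx(2_000)
    assert fit.params["T1"] == pytest.approx(30_000)
    assert fit.params["m_within"] == pytest.approx(1e-5)


def test_true_topology_preferred(observed_two_origins):
    kw = dict(n_restarts=2, n_sims=1_500, seed=9, maxiter=80)
    f2 = fit_model(observed_two_origins, "two_origins", "SI", **kw)
    f1 = fit_model(observed_two_origins, "one_origin", "SI", **kw)
    sel = model_select([f1, f2])
    assert sel.iloc[0]["model"] == "two_origins_SI"
    assert sel.iloc[1]["delta_AIC"] > 0
    assert (sel["delta_L"] >= 0).all()


def test_model_select_laws(observed_two_origins):
    def mk(lnCL, k, key="same"):
        return FitResult("m", "two_origins", "SI", {}, lnCL, -5.0, k, 100, 0,
                         obs_key=key)

    sel = model_select([mk(-10.0, 7), mk(-10.0, 7)])
    assert np.allclose(sel["delta_AIC"], 0.0)
    sel = model_select([mk(-10.0, 7), mk(-10.0, 8)])
    assert sorted(sel["delta_AIC"]) == [0.0, 2.0]
    with pytest.raises(ValueError, match="different observed data"):
        model_select([mk(-10.0, 7), mk(-10.0, 7, key="other")])
    with pytest.raises(ValueError, match="at least two"):
        model_select([mk(-10.0, 7)])


def test_restart_log_records_every_start(observed_two_origins):
    fit = fit_model(observed_two_origins, "two_origins", "SI",
                    n_restarts=3, n_sims=300, seed=2, maxiter=10)
    assert len(fit.restarts) == 3
    assert fit.lnCL_est == pytest.approx(max(r["lnCL_est"] for r in fit.restarts))
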