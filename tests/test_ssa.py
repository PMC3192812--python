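"""Simulation engine: staging, exclusion, conservation, determinism."""

import numpy as np
import pytest

import splicekin as sk
from splicekin.geometry import ValidationError

TIMES = np.arange(0.0, 901.0, 30.0)


def test_initial_state_only_initiation_enabled(network_I):
    st = sk.initial_state(network_I)
    st.gene_active = True
    st.burst_budget = 3
    assert set(sk.propensities(st)) == {"initiation"}
    assert sk.propensities(st)["initiation"] == network_I.rates.k_init


def test_elongation_vs_transition_propensity_ratio(network_I):
    """A post-track Pol II past the branchsite with splicing active has two
    moves, hop : transition = eta : 1."""
    st = sk.initial_state(network_I)
    st.gene_active = st.splicing_active = True
    st.occupancy[19] = 1  # section 20, downstream empty
    a = sk.propensities(st)
    assert a["hop[20]"] / a["co_transition[20]"] == pytest.approx(
        network_I.rates.eta)


def test_exclusion_blocks_hop(network_I):
    st = sk.initial_state(network_I)
    st.gene_active = True
    st.occupancy[19] = 1
    st.occupancy[20] = 2  # co- and post-track copies share capacity
    assert "hop[20]" not in sk.propensities(st)
    # the blocked polymerase may still transition tracks in place
    st.splicing_active = True
    assert "co_transition[20]" in sk.propensities(st)


def test_splicing_never_activates_when_k_on_zero():
    net = sk.build_pathway(sk.PathwayVariant.from_name("I"),
                           rates=sk.RateSet(k_on=0.0))
    traj = sk.simulate(net, TIMES, seed=3)
    for name in ("U-lariat-exon2", "P-lariat-exon2", "U-mRNA", "P-mRNA",
                 "lariat"):
        assert np.all(traj.pools[:, net.pool_index[name]] == 0)
    # only pre-mRNA forms appear
    pre = [net.pool_index[n] for n in ("U-pre-mRNA", "P-pre-mRNA")]
    assert traj.pools[-1, pre].sum() > 0


def test_ss5_only_pre_mrna_species():
    net = sk.build_pathway(sk.PathwayVariant.from_name("I", mutant="ss5"))
    traj = sk.simulate(net, TIMES, seed=11, debug=True)
    for i, pool in enumerate(net.pools):
        if pool.species in ("lariat-exon2", "mRNA", "lariat"):
            assert np.all(traj.pools[:, i] == 0), pool.name


def test_conservation_audit(network_I, traj_I):
    """Initiations = exits + in-flight; exits = sum of released pools."""
    inflight = traj_I.apc + (traj_I.occupancy != 0).sum(axis=1)
    init = traj_I.cumulative[:, 0]
    post_exits = traj_I.cumulative[:, 2]
    co_exits = traj_I.cumulative[:, 3]
    assert np.all(init == inflight + post_exits + co_exits)
    assert np.all(post_exits + co_exits <= init)
    # every released transcript is in exactly one pool (the excised lariat
    # is a by-product of step two, not a transcript)
    transcript_pools = [i for i, p in enumerate(network_I.pools)
                        if p.species != "lariat"]
    assert np.all(post_exits + co_exits
                  == traj_I.pools[:, transcript_pools].sum(axis=1))
    lariat = traj_I.pools[:, network_I.pool_index["lariat"]]
    assert np.all(lariat <= post_exits + co_exits)


def test_feedback_counter_monotone(traj_I):
    assert np.all(np.diff(traj_I.y, axis=0) >= 0)
    assert np.all(traj_I.y >= 1)


def test_determinism_and_single_run_mean(network_I):
    t1 = sk.simulate(network_I, TIMES, seed=42)
    t2 = sk.simulate(network_I, TIMES, seed=42)
    assert np.array_equal(t1.pools, t2.pools)
    assert np.array_equal(t1.occupancy, t2.occupancy)

    e1 = sk.ensemble_mean(network_I, TIMES, n_runs=1, base_seed=42)
    assert np.array_equal(e1.mean_pools, t1.pools.astype(float))
    e2 = sk.ensemble_mean(network_I, TIMES, n_runs=5, base_seed=9)
    e3 = sk.ensemble_mean(network_I, TIMES, n_runs=5, base_seed=9)
    assert np.array_equal(e2.mean_pools, e3.mean_pools)


def test_staged_activation_timing(traj_I, network_I):
    """Nothing happens before t_act; the burst is capped at n_burst before
    splicing activation."""
    before = traj_I.sample_times < network_I.rates.t_act
    assert np.all(traj_I.cumulative[before, 0] == 0)
    splicing_off = traj_I.flags[:, 1] == 0
    assert np.all(traj_I.cumulative[splicing_off, 0]
                  <= network_I.rates.n_burst)


def test_exponential_decay_of_isolated_pool():
    """With only a first-order sink enabled, the ensemble mean decays as
    exp(-k t) within Monte-Carlo error."""
    rates = sk.RateSet(k_init=0.0, k_elong=0.001, eta=1.0, k_on=0.0, c1=0.0,
                       c2=0.0, k1_post=0.0, k2_post=0.0, k2_co=0.0, ks=0.0,
                       ke=0.0, d_ppre=0.01, d_plar=0.0, d_mrna=0.0,
                       t_act=0.0, n_burst=0)
    net = sk.build_pathway(sk.PathwayVariant.from_name("VIII"), rates=rates)
    times = np.arange(0.0, 201.0, 50.0)
    n0, n_runs = 400, 100
    ens = sk.ensemble_mean(net, times, n_runs=n_runs, base_seed=5,
                           initial_counts={"P-pre-mRNA": n0},
                           start_active=True, start_splicing=True)
    j = net.pool_index["P-pre-mRNA"]
    expected = n0 * np.exp(-0.01 * times)
    se = np.sqrt(n0 * np.exp(-0.01 * times)
                 * (1 - np.exp(-0.01 * times)) / n_runs)
    assert np.all(np.abs(ens.mean_pools[:, j] - expected) <= 4 * se + 1e-9)


@pytest.mark.parametrize("eta", [0.5, 2.0, 11.39, 30.0])
def test_single_walker_matches_closed_form(eta):
    n = 40_000
    frac = sk.single_pol_exit_fraction(eta=eta, n_walkers=n, seed=123)
    p = sk.p_post(eta, 25)
    se = np.sqrt(p * (1 - p) / n)
    assert abs(frac - p) <= 3 * se


def test_single_walker_invariant_to_elongation_rate():
    f1 = sk.single_pol_exit_fraction(k_elong=1.0, n_walkers=50_000, seed=7)
    f2 = sk.single_pol_exit_fraction(k_elong=10.0, n_walkers=50_000, seed=8)
    p = sk.p_post(11.39, 25)
    se = np.sqrt(p * (1 - p) / 50_000)
    assert abs(f1 - f2) <= 4 * se


def test_single_walker_vanishing_eta():
    assert sk.single_pol_exit_fraction(eta=1e-6, n_walkers=2_000, seed=1) == 0.0


def test_kernel_agrees_with_reference_stepper(network_I):
    """The fast kernel and the pure-Python reference stepper agree on the
    final mature-mRNA mean within Monte-Carlo error."""
    times = np.array([0.0, 450.0, 900.0])
    n = 60
    ref = np.zeros(network_I.n_pools)
    for s in range(n):
        ref += sk.simulate_reference(network_I, times, seed=10_000 + s)[-1]
    ref /= n
    ens = sk.ensemble_mean(network_I, times, n_runs=n, base_seed=20_000)
    j = network_I.pool_index["P-mRNA"]
    se = np.sqrt(2 * ens.var_pools[-1, j] / n)
    assert abs(ref[j] - ens.mean_pools[-1, j]) <= 4 * se


def test_invalid_inputs_rejected(network_I):
    with pytest.raises(ValidationError):
        sk.simulate(network_I, np.array([]))
    with pytest.raises(ValidationError):
        sk.simulate(network_I, np.array([0.0, 0.0]))
    with pytest.raises(ValidationError):
        sk.ensemble_mean(network_I, TIMES, n_runs=0)
    with pytest.raises(ValidationError):
        sk.simulate(network_I, TIMES, initial_counts={"nope": 1})
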