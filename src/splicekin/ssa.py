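"""Exact stochastic simulation of a pathway network.

`simulate` and `ensemble_mean` run the fast event-loop kernel; `SimState` and
`step` form a small, readable pure-Python reference stepper used for unit
tests and as an independent cross-check of the kernel.

The activation schedule is staged: the gene activates deterministically at
``t_act`` (doxycycline induction delay), which enables a burst of at most
``n_burst`` initiations; splicing activation follows after an exponential
waiting time at rate ``k_on``, enabling the splicing reactions, the
co-transcriptional transition and unlimited initiation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from ._kernel import run_kernel
from .geometry import GeneGeometry, ValidationError
from .pathway import ReactionNetwork

EMPTY, POST, CO = 0, 1, 2


@dataclass
class Trajectory:
    """A single sampled SSA path."""

    sample_times: np.ndarray
    pools: np.ndarray  # (n_samples, n_pools) molecule counts
    occupancy: np.ndarray  # (n_samples, n_sections) codes 0/1/2
    apc: np.ndarray  # (n_samples,) 0/1
    y: np.ndarray  # (n_samples, n_y) feedback counters
    cumulative: np.ndarray  # (n_samples, 5): init, co-trans, post/co exits, burst
    flags: np.ndarray  # (n_samples, 2): gene_active, splicing_active
    seed: int
    network: ReactionNetwork

    @property
    def occ_post(self) -> np.ndarray:
        return (self.occupancy == POST).astype(np.int64)

    @property
    def occ_co(self) -> np.ndarray:
        return (self.occupancy == CO).astype(np.int64)


@dataclass
class EnsembleSummary:
    """Per-species population means over independent runs (copies/cell)."""

    sample_times: np.ndarray
    mean_pools: np.ndarray
    var_pools: np.ndarray
    mean_occ_post: np.ndarray  # mean post-track polymerases per section
    mean_occ_co: np.ndarray
    n_runs: int
    base_seed: int
    network: ReactionNetwork


def _default_sample_times(horizon: float = 900.0, dt: float = 30.0) -> np.ndarray:
    return np.arange(0.0, horizon + 0.5 * dt, dt)


def simulate(network: ReactionNetwork,
             sample_times: Optional[np.ndarray] = None,
             seed: int = 0,
             initial_counts: Optional[dict[str, int]] = None,
             start_active: bool = False,
             start_splicing: bool = False,
             debug: bool = False) -> Trajectory:
    """Run one SSA realisation and snapshot the state at ``sample_times``.

    ``initial_counts`` preloads released-molecule pools at t=0 (useful for
    isolating sub-processes); by default all counts are zero and the gene is
    inactive until ``t_act``.
    """
    if sample_times is None:
        sample_times = _default_sample_times()
    sample_times = np.asarray(sample_times, dtype=np.float64)
    if sample_times.size == 0 or np.any(np.diff(sample_times) <= 0):
        raise ValidationError("sample_times must be non-empty, strictly increasing")
    if sample_times[0] < 0:
        raise ValidationError("sample_times must be non-negative")

    c = network.compile()
    init = np.zeros(c.n_pools, np.int64)
    if initial_counts:
        for name, n in initial_counts.items():
            if name not in network.pool_index:
                raise ValidationError(f"unknown pool {name!r}")
            init[network.pool_index[name]] = int(n)

    out = run_kernel(np.uint32(seed & 0x7FFFFFFF), sample_times,
                     float(c.k_init), float(c.t_act), float(c.k_on),
                     int(c.n_burst),
                     int(c.n_sections), int(c.branch0), float(c.k_elong),
                     float(c.k_co), bool(c.single_elong), float(c.ks),
                     float(c.ke),
                     c.sub, c.prod1, c.prod2, c.rate, c.ydx, c.gated,
                     int(c.n_pools), int(c.n_y), int(c.exit_post),
                     int(c.exit_co),
                     init, bool(start_active), bool(start_splicing),
                     bool(debug))
    pools, occ, apc, y, cum, flags, status = out
    if status == 1:
        raise AssertionError("polymerase conservation violated in kernel")
    if status == 2:
        raise AssertionError("negative count or Y < 1 in kernel")
    return Trajectory(sample_times=sample_times, pools=pools, occupancy=occ,
                      apc=apc, y=y, cumulative=cum, flags=flags, seed=seed,
                      network=network)


def ensemble_mean(network: ReactionNetwork,
                  sample_times: Optional[np.ndarray] = None,
                  n_runs: int = 500,
                  base_seed: int = 0,
                  **sim_kwargs) -> EnsembleSummary:
    """Mean and variance over ``n_runs`` independent trajectories.

    Runs use seeds ``base_seed .. base_seed + n_runs - 1``; the summary is
    deterministic given ``(base_seed, n_runs, network, schedule)``.
    """
    if n_runs < 1:
        raise ValidationError("n_runs must be >= 1")
    if sample_times is None:
        sample_times = _default_sample_times()
    sample_times = np.asarray(sample_times, dtype=np.float64)

    s = sq = None
    occ_post_sum = occ_co_sum = None
    for r in range(n_runs):
        traj = simulate(network, sample_times, seed=base_seed + r, **sim_kwargs)
        p = traj.pools.astype(np.float64)
        if s is None:
            s = np.zeros_like(p)
            sq = np.zeros_like(p)
            occ_post_sum = np.zeros_like(traj.occupancy, dtype=np.float64)
            occ_co_sum = np.zeros_like(occ_post_sum)
        s += p
        sq += p * p
        occ_post_sum += traj.occupancy == POST
        occ_co_sum += traj.occupancy == CO
    mean = s / n_runs
    var = np.maximum(sq / n_runs - mean * mean, 0.0)
    return EnsembleSummary(sample_times=sample_times, mean_pools=mean,
                           var_pools=var, mean_occ_post=occ_post_sum / n_runs,
                           mean_occ_co=occ_co_sum / n_runs, n_runs=n_runs,
                           base_seed=base_seed, network=network)


def single_pol_exit_fraction(geometry: Optional[GeneGeometry] = None,
                             k_elong: float = 2.27,
                             eta: float = 11.39,
                             n_walkers: int = 100_000,
                             seed: int = 0) -> float:
    """Monte-Carlo twin of the closed-form exit probability.

    Simulates independent single polymerases (splicing active, no excluded
    volume) through the transition window: at each of the
    ``n_transition_sections`` sections, an exponential hop at ``k_elong``
    competes with an exponential transition at ``k_elong / eta``. Returns the
    fraction exiting without ever transitioning, i.e. the fraction of
    transcripts that splice post-transcriptionally.
    """
    if n_walkers < 1:
        raise ValidationError("n_walkers must be >= 1")
    if eta <= 0:
        raise ValidationError("eta must be > 0")
    geometry = geometry or GeneGeometry()
    n_choices = geometry.n_transition_sections
    rng = np.random.default_rng(seed)
    hop = rng.exponential(1.0 / k_elong, size=(n_walkers, n_choices))
    trans = rng.exponential(eta / k_elong, size=(n_walkers, n_choices))
    no_transition = np.all(hop < trans, axis=1)
    return float(np.mean(no_transition))


# ---------------------------------------------------------------------------
# Pure-Python reference stepper (spec-level state, used in tests and audits).
# ---------------------------------------------------------------------------

@dataclass
class SimState:
    """Explicit simulation state for the reference stepper."""

    network: ReactionNetwork
    t: float = 0.0
    gene_active: bool = False
    splicing_active: bool = False
    burst_budget: int = 0
    apc_occupied: bool = False
    occupancy: np.ndarray = None  # type: ignore[assignment]
    species_counts: dict = field(default_factory=dict)
    y_counters: dict = field(default_factory=dict)
    cumulative: dict = field(default_factory=lambda: dict(
        initiations=0, co_transitions=0, post_exits=0, co_exits=0))
    t_gene: float = np.inf
    t_splice: float = np.inf

    def __post_init__(self) -> None:
        if self.occupancy is None:
            self.occupancy = np.zeros(self.network.geometry.n_sections,
                                      np.int8)
        if not self.species_counts:
            self.species_counts = {p.name: 0 for p in self.network.pools}
        if not self.y_counters:
            self.y_counters = {r.name: 1 for r in
                               self.network.feedback_reactions}


def initial_state(network: ReactionNetwork) -> SimState:
    st = SimState(network=network)
    st.t_gene = network.rates.t_act
    return st


def _channels(state: SimState):
    """Enumerate (name, propensity, apply) for every enabled reaction."""
    net = state.network
    rs, geom, var = net.rates, net.geometry, net.variant
    S = geom.n_sections
    single = var.elongation_mech == "single"
    out = []

    def add(name, a, fn):
        if a > 0:
            out.append((name, a, fn))

    if (state.gene_active and not state.apc_occupied
            and (state.burst_budget > 0 or state.splicing_active)):
        def fire_init(st=state):
            st.apc_occupied = True
            st.cumulative["initiations"] += 1
            if not st.splicing_active:
                st.burst_budget -= 1
        add("initiation", rs.k_init, fire_init)

    if state.apc_occupied:
        if single:
            if state.splicing_active and var.has_co_track:
                def fire_ks(st=state):
                    st.apc_occupied = False
                    st.species_counts[net.exit_co_pool] += 1
                    st.cumulative["co_exits"] += 1
                add("apc_exit_co", rs.ks, fire_ks)

            def fire_ke(st=state):
                st.apc_occupied = False
                st.species_counts[net.exit_post_pool] += 1
                st.cumulative["post_exits"] += 1
            add("apc_exit_post", rs.ke, fire_ke)
        elif state.occupancy[0] == EMPTY:
            def fire_escape(st=state):
                st.apc_occupied = False
                st.occupancy[0] = POST
            add("promoter_escape", rs.k_elong, fire_escape)

    if not single:
        occ = state.occupancy
        for i in range(S):
            if occ[i] == EMPTY:
                continue
            if i == S - 1:
                def fire_exit(st=state, i=i):
                    if st.occupancy[i] == POST:
                        st.species_counts[net.exit_post_pool] += 1
                        st.cumulative["post_exits"] += 1
                    else:
                        st.species_counts[net.exit_co_pool] += 1
                        st.cumulative["co_exits"] += 1
                    st.occupancy[i] = EMPTY
                add(f"release[{i + 1}]", rs.k_elong, fire_exit)
            elif occ[i + 1] == EMPTY:
                def fire_hop(st=state, i=i):
                    st.occupancy[i + 1] = st.occupancy[i]
                    st.occupancy[i] = EMPTY
                add(f"hop[{i + 1}]", rs.k_elong, fire_hop)
        if state.splicing_active and var.has_co_track:
            k_co = rs.k_elong / rs.eta
            for i in range(geom.branch_section - 1, S):
                if occ[i] == POST:
                    def fire_co(st=state, i=i):
                        st.occupancy[i] = CO
                        st.cumulative["co_transitions"] += 1
                    add(f"co_transition[{i + 1}]", k_co, fire_co)

    for r in net.reactions:
        if r.gated and not state.splicing_active:
            continue
        n = state.species_counts[r.substrate]
        if n <= 0:
            continue
        a = r.rate * n
        if r.feedback:
            a *= state.y_counters[r.name]

        def fire_rxn(st=state, r=r):
            st.species_counts[r.substrate] -= 1
            for p in r.products:
                st.species_counts[p] += 1
            if r.feedback:
                st.y_counters[r.name] += 1
        add(r.name, a, fire_rxn)
    return out


def propensities(state: SimState) -> dict[str, float]:
    """Map of enabled reaction name -> propensity (reference stepper)."""
    return {name: a for name, a, _ in _channels(state)}


def step(state: SimState, rng: np.random.Generator):
    """Advance the reference stepper by one event.

    Returns ``(event_name, dt)``. Scheduled activation events (gene
    activation at ``t_act``; splicing activation after an exponential delay
    at ``k_on``) pre-empt reaction firings occurring after them. Returns
    ``(None, inf)`` when nothing can ever fire again.
    """
    chans = _channels(state)
    total = sum(a for _, a, _ in chans)
    t_react = state.t + rng.exponential(1.0 / total) if total > 0 else np.inf
    t_sched = min(state.t_gene, state.t_splice)

    if t_sched <= t_react:
        if t_sched == np.inf:
            return None, np.inf
        dt = t_sched - state.t
        state.t = t_sched
        if state.t_gene <= state.t_splice:
            state.t_gene = np.inf
            state.gene_active = True
            state.burst_budget = state.network.rates.n_burst
            k_on = state.network.rates.k_on
            if not state.splicing_active and k_on > 0:
                state.t_splice = state.t + rng.exponential(1.0 / k_on)
            return "gene_activation", dt
        state.t_splice = np.inf
        state.splicing_active = True
        return "splicing_activation", dt

    dt = t_react - state.t
    state.t = t_react
    u = rng.random() * total
    acc = 0.0
    for name, a, fire in chans:
        acc += a
        if u < acc:
            fire()
            return name, dt
    name, _, fire = chans[-1]
    fire()
    return name, dt


def simulate_reference(network: ReactionNetwork, sample_times: np.ndarray,
                       seed: int = 0) -> np.ndarray:
    """Drive the reference stepper, returning pool counts at sample times.

    Independent of the kernel; used as a cross-check on small problems.
    """
    sample_times = np.asarray(sample_times, dtype=np.float64)
    rng = np.random.default_rng(seed)
    st = initial_state(network)
    out = np.zeros((sample_times.size, network.n_pools), np.int64)
    si = 0
    while si < sample_times.size:
        before = {k: v for k, v in st.species_counts.items()}
        t_before = st.t
        name, dt = step(st, rng)
        t_event = t_before + dt if np.isfinite(dt) else np.inf
        while si < sample_times.size and sample_times[si] <= t_event:
            for j, p in enumerate(network.pools):
                out[si, j] = before[p.name] if sample_times[si] < t_event \
                    else st.species_counts[p.name]
            si += 1
        if name is None:
            break
    return out
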