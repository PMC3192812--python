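"""Event-loop kernel of the stochastic simulator.

A single function implements the Gillespie direct method over the polymerase
lattice plus the released-molecule chemistry. It is written in
numba-compatible Python and jitted when numba is importable; the identical
source runs uncompiled otherwise.

Channel layout (propensity vector `a`):
  0                      initiation (gene must be active, APC empty, and
                         either burst budget remaining or splicing active)
  1                      promoter escape APC -> section 1 (lattice), or the
                         APC -> U-lariat-exon2 exit (single-step elongation)
  2                      APC -> U-pre-mRNA exit (single-step elongation only)
  3 .. 3+S-1             hop/exit of the polymerase on section i
  3+S .. 3+2S-1          co-transcriptional transition on section i
  3+2S ..                chemistry reactions

Occupancy codes: 0 empty, 1 post track, 2 co track. A section holds one code,
so excluded volume is structural; hops only fire into empty sections.
"""

from __future__ import annotations

import numpy as np

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

    def njit(*args, **kwargs):
        if args and callable(args[0]):
            return args[0]

        def wrap(fn):
            return fn

        return wrap


@njit(cache=False)
def run_kernel(seed,
               sample_times,
               # schedule
               k_init, t_act, k_on, n_burst,
               # lattice
               n_sections, branch0, k_elong, k_co, single_elong, ks, ke,
               # chemistry
               sub, prod1, prod2, rate, ydx, gated, n_pools, n_y,
               exit_post, exit_co,
               # initial condition
               init_counts, start_active, start_splicing,
               debug):
    np.random.seed(seed)

    ns = sample_times.shape[0]
    nr = sub.shape[0]
    S = n_sections

    pools = init_counts.copy()
    occ = np.zeros(S, np.int8)
    y = np.ones(n_y, np.int64)
    apc = 0
    gene_active = start_active
    splicing_active = start_splicing
    burst = n_burst if gene_active else 0
    # cumulative: initiations, co-transitions, post exits, co exits
    cum = np.zeros(4, np.int64)

    INF = 1.0e30
    t_gene = INF if gene_active else t_act
    t_splice = INF
    if gene_active and not splicing_active:
        if k_on > 0.0:
            t_splice = -np.log(1.0 - np.random.random()) / k_on

    # outputs
    pools_out = np.zeros((ns, n_pools), np.int64)
    occ_out = np.zeros((ns, S), np.int8)
    apc_out = np.zeros(ns, np.int8)
    y_out = np.zeros((ns, n_y), np.int64)
    cum_out = np.zeros((ns, 5), np.int64)
    flags_out = np.zeros((ns, 2), np.int8)

    n_channels = 3 + 2 * S + nr
    a = np.zeros(n_channels, np.float64)
    off = 3 + 2 * S

    t = 0.0
    si = 0  # next sample index
    status = 0

    while si < ns:
        # --- propensities ---
        for i in range(n_channels):
            a[i] = 0.0
        if gene_active and apc == 0 and (burst > 0 or splicing_active):
            a[0] = k_init
        if apc == 1:
            if single_elong:
                if splicing_active and ks > 0.0:
                    a[1] = ks
                a[2] = ke
            else:
                if occ[0] == 0:
                    a[1] = k_elong
        if not single_elong:
            for i in range(S):
                if occ[i] != 0:
                    if i == S - 1 or occ[i + 1] == 0:
                        a[3 + i] = k_elong
            if splicing_active and k_co > 0.0:
                for i in range(branch0, S):
                    if occ[i] == 1:
                        a[3 + S + i] = k_co
        for j in range(nr):
            if gated[j] == 1 and not splicing_active:
                continue
            c = pools[sub[j]]
            if c > 0:
                r = rate[j] * c
                if ydx[j] >= 0:
                    r *= y[ydx[j]]
                a[off + j] = r

        total = 0.0
        for i in range(n_channels):
            total += a[i]

        if total > 0.0:
            t_react = t - np.log(1.0 - np.random.random()) / total
        else:
            t_react = INF

        t_sched = t_gene if t_gene < t_splice else t_splice
        t_next = t_react if t_react < t_sched else t_sched

        # record samples the process passes before the next event
        while si < ns and sample_times[si] <= t_next:
            for p in range(n_pools):
                pools_out[si, p] = pools[p]
            for i in range(S):
                occ_out[si, i] = occ[i]
            apc_out[si] = apc
            for q in range(n_y):
                y_out[si, q] = y[q]
            for q in range(4):
                cum_out[si, q] = cum[q]
            cum_out[si, 4] = burst
            flags_out[si, 0] = 1 if gene_active else 0
            flags_out[si, 1] = 1 if splicing_active else 0
            si += 1
        if si >= ns:
            break
        if t_next >= INF:
            # no reactions possible and nothing scheduled: remaining samples
            # were just recorded above, so only reachable if none remain
            break

        if t_sched <= t_react:
            # scheduled activation event
            t = t_sched
            if t_gene <= t_splice:
                gene_active = True
                burst = n_burst
                t_gene = INF
                if not splicing_active:
                    if k_on > 0.0:
                        t_splice = t - np.log(1.0 - np.random.random()) / k_on
            else:
                splicing_active = True
                t_splice = INF
            continue

        # reaction firing
        t = t_react
        u = np.random.random() * total
        acc = 0.0
        ch = -1
        for i in range(n_channels):
            acc += a[i]
            if u < acc:
                ch = i
                break
        if ch < 0:
            ch = n_channels - 1

        if ch == 0:
            apc = 1
            cum[0] += 1
            if not splicing_active:
                burst -= 1
        elif ch == 1:
            if single_elong:
                apc = 0
                pools[exit_co] += 1
                cum[3] += 1
            else:
                apc = 0
                occ[0] = 1
        elif ch == 2:
            apc = 0
            pools[exit_post] += 1
            cum[2] += 1
        elif ch < 3 + S:
            i = ch - 3
            if i == S - 1:
                if occ[i] == 1:
                    pools[exit_post] += 1
                    cum[2] += 1
                else:
                    pools[exit_co] += 1
                    cum[3] += 1
                occ[i] = 0
            else:
                occ[i + 1] = occ[i]
                occ[i] = 0
        elif ch < 3 + 2 * S:
            i = ch - 3 - S
            occ[i] = 2
            cum[1] += 1
        else:
            j = ch - off
            pools[sub[j]] -= 1
            if prod1[j] >= 0:
                pools[prod1[j]] += 1
            if prod2[j] >= 0:
                pools[prod2[j]] += 1
            if ydx[j] >= 0:
                y[ydx[j]] += 1

        if debug:
            # polymerase conservation: initiations = in flight + exits
            inflight = apc
            for i in range(S):
                if occ[i] != 0:
                    inflight += 1
            if cum[0] != inflight + cum[2] + cum[3]:
                status = 1
                break
            ok = True
            for p in range(n_pools):
                if pools[p] < 0:
                    ok = False
            for q in range(n_y):
                if y[q] < 1:
                    ok = False
            if not ok:
                status = 2
                break

    return pools_out, occ_out, apc_out, y_out, cum_out, flags_out, status
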