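# Methods

## Model overview

`splicekin` models a single inducible reporter gene per cell as a
continuous-time Markov jump process, simulated exactly with the Gillespie
direct method. The state comprises:

- a **DNA lattice** of 40 sections (~31 nt each, 1240 nt total), each
  holding at most one RNA polymerase II (excluded volume). A polymerase
  occupies its section on one of two tracks: the default **post** track,
  or the **co** track after the nascent transcript has completed splicing
  step one co-transcriptionally;
- an **active promoter complex (APC)** slot where a newly initiated
  polymerase resides before entering section 1;
- **released-molecule pools**: uncleaved (U) and polyadenylated (P) forms
  of pre-mRNA, lariat-exon2 and mRNA, the excised lariat by-product, and
  degradation sinks per transcript class;
- **feedback counters** `Y` (one per feedback-mechanism reaction),
  starting at 1 and incremented on each firing — a minimal model of a
  splicing machine whose efficiency grows with use.

### Staged induction

Induction is staged. The gene activates deterministically at `t_act`
(transcription-factor equilibration after drug addition). Activation
enables a burst of at most `n_burst` initiations. Splicing activation
follows after an exponential delay at rate `k_on`; it enables the splicing
reactions, the co-transcriptional transition, and sustained (unbounded)
initiation.

### Elongation and the co-transcriptional transition

A polymerase at section `i` hops to `i+1` at rate `k_elong` if that
section is empty (the last section's hop releases the transcript). On
sections 16–40 — the 25 sections at/past the intron branchsite — a
post-track polymerase may instead switch to the co track at rate
`k_elong / eta`, provided splicing is active. Because both competing
rates share `k_elong`, a lone polymerase exits unswitched with probability

    p_post(eta) = (eta / (eta + 1))^25,

the closed form implemented in `analytics.p_post` and validated by the
Monte-Carlo twin `ssa.single_pol_exit_fraction`. Post-track exits release
U-pre-mRNA; co-track exits release U-lariat-exon2.

### Released-molecule chemistry

Each candidate pathway (I–VIII) assigns one of three mechanisms to the
co-transcriptional step two, to the post-transcriptional steps one and
two, and one of two mechanisms to elongation:

- **F (feedback)**: single reaction with propensity `rate · substrate · Y`;
- **M (multistep)**: a chain of 5 identical-rate exponential stages
  (Erlang waiting time), propensity `rate · substrate` per stage;
- **S (single)**: one exponential step, propensity `rate · substrate`;
- elongation **M** is the 40-section lattice; elongation **S** replaces it
  by two competing single-step exits from the APC (co at `ks`, post at
  `ke`).

3′ end maturation (cleavage + polyadenylation + release) is always a
5-stage multistep converting U→P forms. Mutants are structural: `ss3`
removes both step-two routes (lariat-exon2 instead 3′-matures at `c2`);
`ss5` removes step one entirely (and with it the co track).

## Parameters

All first-order rates in 1/s; times in seconds; counts in copies/cell.

| name | default | units | role and rationale |
|---|---|---|---|
| `k_init` | 0.25 | 1/s | initiation rate (0.175 for `ss3`, 0.1 for `ss5`, reflecting mutant expression levels) |
| `t_act` | 400 | s | deterministic gene-activation delay after induction |
| `n_burst` | 8 | — | initiation burst cap before splicing activation |
| `k_on` | 0.03 | 1/s | splicing-activation rate (mean delay ~33 s; 0.015 for `ss3`) |
| `k_elong` | 2.27 | sections/s | elongation hop rate (~70 nt/s over 31-nt sections) |
| `eta` | 11.39 | — | elongation : transition odds per choice section (30 for `ss3`) |
| `c1` | 4.670909/35 | 1/s | per-stage 3′ maturation rate of pre-mRNA; the Erlang(5) median constant 4.670909 converts a 35 s maturation half-time into a per-stage rate |
| `c2` | 4.670909/49 | 1/s | per-stage 3′ maturation rate of mRNA (49 s half-time) |
| `k1_post` | 4.670909/34 | 1/s | per-stage post-transcriptional step-one rate (34 s half-time; 0 for `ss5`) |
| `k2_post` | 4.670909/36 | 1/s | per-stage post-transcriptional step-two rate (36 s half-time; 0 for `ss3`) |
| `k2_co` | 0.0063 | 1/s | co-transcriptional step-two feedback rate; first-event half-life ln2/k ≈ 110 s, reduced to ~5.5 s once Y reaches 20 (0 for `ss3`) |
| `ks`, `ke` | 0.4, 0.07 | 1/s | single-elongation exit rates (co and post routes) |
| `d_ppre`, `d_plar` | 0.002 | 1/s | degradation of polyadenylated intermediates |
| `d_mrna` | 0 | 1/s | mature mRNA is stable on the 900 s horizon |

Free-parameter counts for AIC are derived from the architecture (e.g. 9
for pathway I, 5 for `ss5`): base `{k_init, k_on, c1, c2}` plus the
elongation pair (`k_elong, eta` or `ke, ks`) plus whichever splicing
rates the variant retains.

## Observation model

Two primer pairs define two experiments on the same state:

- **expt1** (primer inside the transcription unit, section 35): total
  pre-mRNA (pools + post-track nascent transcripts past the primer),
  total lariat-exon2 (pools + co-track nascent), total mRNA.
- **expt2** (primer at the 3′ end, section 40): the U/P split of each
  species. Molecules inside a maturation chain count as uncleaved.

By construction expt1 mRNA equals expt2 U-mRNA + P-mRNA exactly; the
analogous pre-mRNA identity does **not** hold in general because nascent
gating differs between the primers.

## Synthetic data

The generator simulates a truth ensemble (default 500 runs) on a 0–900 s
grid with 60 s spacing, then draws replicates (default 3) per point as
`max(0, mean·(1 + 0.15·N) + 0.2·N)` with independent standard normals —
heteroscedastic multiplicative noise (CV 15%) plus an additive floor
(0.2 copies). This mimics error bars that grow with copy number, but it
is not a calibrated instrument model: real RT-qPCR error is log-scale
and correlated within replicates, amplification efficiency and
normalisation drift are not represented, and clipping at zero slightly
biases low-copy points upward.

## Fitting and model selection

The annealer minimises `E`, the RMSE over all series and time points
(replicates averaged first), either absolute or — recommended when series
span orders of magnitude — relative to the data value. Each objective
evaluation averages a reduced ensemble (default 100 runs) with **common
random numbers**: fixed per-fit seeds make the objective a deterministic
function of the parameters, so fits are exactly reproducible and the
Metropolis chain compares like with like. Proposals perturb every free
parameter by `N(0,1) · scale · (max − min)` with reflection at the
bounds; `scale` may be per-parameter (useful when sensitivities differ by
orders of magnitude), may shrink by `alpha` each stage
(`anneal_proposal`), and an optional uniform pre-search supplies the
"approximate fit" starting point the annealer expects. Worsenings are
accepted with probability `exp(−k(E′−E)/T)`, `k = 1/E0`, `T = T0·alpha^stage`.
The best-ever parameters are re-evaluated with a larger ensemble
(default 500 runs) and fresh seeds for the reported `E` and residuals.

Model scores are `AIC = n·ln(RSS/n) + 2k` pooled over series, normalised
to the best model for Akaike weights `exp(−Δ/2)/Σ`; a per-series AIC
matrix (column-normalised to min 0) localises where architectures
differ.

## Numerical choices and problem sizes

- Ensemble sizes are desk-scale choices: 500-run ensembles for headline
  time courses and data generation (Monte-Carlo error on a 60-copy mean
  ≈ 0.4 copies), 50–100-run ensembles inside annealing loops, 10⁵
  walkers for the exit-probability twin (binomial SE 0.1%), 10⁶ samples
  for the Erlang-median oracle (±1%).
- The SSA kernel recomputes all propensities after each event — simple
  and, at ~10³–10⁴ events per 900 s run (~1 ms jitted), fast enough that
  no dependency-graph optimisation is warranted.
- Erlang half-times use the inverse regularised incomplete gamma
  function; `erlang_half_time(1, k) = ln2/k` to machine precision. Note
  this is the *isolated-cohort* median (time for half of a batch to
  finish); under continuous inflow the observable "half of the standing
  pool turned over" differs.
- Seeds: every stochastic entry point takes an explicit seed; compound
  seeds are derived with `numpy.random.SeedSequence` and kept below 2³¹.

## Limitations

- One gene copy per cell; no cell-to-cell extrinsic variability, growth
  or dilution.
- Elongation is uniform across sections — no pausing, backtracking or
  termination failure.
- The feedback counter `Y` never resets or decays within a run.
- The noise model is a convenience, not an instrument calibration (see
  above); recovered-parameter uncertainties from synthetic data should
  be read as method checks, not biological error bars.
- Parameter recovery at desk scale resolves `eta` well, but `k_on` is
  weakly identified near the sampling interval (60 s vs a ~33 s mean
  delay): in roughly 2 of 10 seeded repetitions the best fit sits ~35–55%
  above the generating value because the noisy data genuinely prefer it.
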