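# splicekin

Stochastic modelling of coupled transcription, splicing and 3′ end
maturation for a budding-yeast reporter gene.

`splicekin` simulates an induced reporter gene as a chemical master
equation, with RNA polymerase II elongation resolved on a 40-section DNA
lattice with excluded volume (at most one polymerase per ~31-nt section).
Splicing can complete **co-transcriptionally** — the nascent transcript
switches to a dedicated track while the polymerase is still elongating —
or **post-transcriptionally**, after 3′ cleavage releases the transcript.
The package answers where splicing happens, how efficiently, and which
reaction architecture the data support.

## What's in the box

- **Pathway networks** — eight candidate architectures (I–VIII) combining
  feedback / multistep / single-step mechanisms for the two splicing
  steps with lattice or single-step elongation, plus 5′ and 3′
  splice-site mutants (`ss5`, `ss3`) as structural knockouts.
- **Exact SSA engine** — a Gillespie direct-method kernel (numba-jitted,
  with a pure-Python reference stepper for cross-checking) implementing
  staged induction: gene activation at `t_act`, an initiation burst, and
  exponential splicing activation at rate `k_on`.
- **Observation model** — converts raw molecular state to the nine
  RT-qPCR signals of two primer pairs, including nascent-transcript
  contributions past each primer.
- **Closed-form analytics** — the single-polymerase exit probability
  `p_post(eta) = (eta/(eta+1))^25`, first-order half-lives, and Erlang
  half-times for multistep maturation.
- **Fitting** — simulated annealing over ensemble-averaged simulations
  with common random numbers (deterministic objective given a seed),
  absolute or relative RMSE.
- **Model selection** — AIC (`n·ln(RSS/n) + 2k`) and Akaike weights,
  with a per-series score matrix and a ranked comparison table.
- **Synthetic data** — a generator with heteroscedastic multiplicative
  noise plus floor, and a parameter-recovery harness.
- **CLI** — `splicekin simulate | observe | synth | fit | compare |
  analytics`, each writing tidy CSV/JSON plus a provenance manifest.

## Worked example

Where does splicing happen for the wild-type reporter? The fitted ratio
constant `eta = 11.39` sets the per-section odds of elongating vs
switching to the co-transcriptional track across 25 choice points:

```python
>>> import splicekin as sk
>>> sk.p_post(11.39, 25)          # post-transcriptional fraction
0.12199...
>>> sk.single_pol_exit_fraction(eta=11.39, n_walkers=100_000, seed=1)
0.12245                           # Monte-Carlo twin of the closed form
```

so ~88% of transcripts start splicing while still attached to the
polymerase. Simulating the full induction time course
(`python examples/simulate_induction.py`) prints the staging hallmarks:

```
time-course hallmarks (population means, copies/cell):
  U-pre-mRNA peaks at 450 s (2.6 copies)
  P-pre-mRNA peaks at 480 s (1.9 copies) — 30 s later
  U-mRNA crosses 1 copy/cell at 480 s; final 10.5 copies
  P-mRNA crosses 1 copy/cell at 510 s; final 87.8 copies
  total mature mRNA at 900 s: 98.3 copies/cell
```

Fitting a noisy synthetic dataset recovers the generating parameter
(`python examples/synthesize_and_fit.py`):

```
dataset: 432 rows, truth eta = 11.39
recovered eta = 10.11 (11.2% off truth) in 12 s; final E = 0.154
implied post-transcriptional fraction: 9.5%
```

and ranking architectures by AIC picks the generating one decisively
(`python examples/model_comparison.py`):

```
pathway I: fitted eta = 11.060, E = 0.122
pathway VIII: fitted ks = 0.238, E = 2.557

model Co Po El  total_aic       weight
    I  F  M  M   0.000000 1.000000e+00
 VIII  S  S  S 315.769685 2.700748e-69
```

The other examples: `examples/exit_probability.py` (closed form vs
Monte-Carlo) and `examples/mutant_phenotypes.py` (ss3/ss5 knockouts).

## Documentation

`docs/methods.md` describes the model, every parameter with units and
defaults, the noise model and its limits, and the numerical conventions
(common random numbers, annealing schedule, ensemble sizes).
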