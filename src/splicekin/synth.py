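"""Synthetic nine-series RT-qPCR datasets with known ground truth.

Emulates the layout of the reporter induction experiments: two assay
experiments, nine species, three biological replicates, values in
copies/cell. The noise-free series is the ensemble mean of the pathway
model under the true parameters; replicates add heteroscedastic noise
(multiplicative with coefficient of variation ``noise_cv`` plus an additive
floor), mimicking error bars that grow with copy number. Values are clipped
at zero.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd

from .fitting import SAConfig, anneal, error_E
from .geometry import GeneGeometry, ValidationError
from .observe import observe
from .pathway import PathwayVariant, RateSet, build_pathway
from .ssa import ensemble_mean


def _default_times() -> np.ndarray:
    return np.arange(0.0, 901.0, 60.0)


@dataclass
class SynthSpec:
    """Ground truth and noise model for one synthetic dataset."""

    variant: PathwayVariant = field(
        default_factory=lambda: PathwayVariant.from_name("I"))
    geometry: GeneGeometry = field(default_factory=GeneGeometry)
    rates: RateSet = field(default_factory=RateSet)
    sample_times: np.ndarray = field(default_factory=_default_times)
    n_replicates: int = 3
    noise_cv: float = 0.15
    noise_floor: float = 0.2
    truth_ensemble_runs: int = 500
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_cv < 0 or self.noise_floor < 0:
            raise ValidationError("noise_cv and noise_floor must be >= 0")
        if self.n_replicates < 1:
            raise ValidationError("n_replicates must be >= 1")


def generate(spec: SynthSpec) -> tuple[pd.DataFrame, dict]:
    """Generate a noisy nine-series dataset and its ground-truth manifest."""
    ss = np.random.SeedSequence([int(spec.seed), 0x51])
    ens_seed, noise_seed = (int(x % (2 ** 31)) for x in ss.generate_state(2))
    net = build_pathway(spec.variant, spec.geometry, spec.rates)
    ens = ensemble_mean(net, spec.sample_times,
                        n_runs=spec.truth_ensemble_runs, base_seed=ens_seed)
    clean = observe(ens)

    rng = np.random.default_rng(noise_seed)
    frames = []
    for rep in range(spec.n_replicates):
        df = clean.copy()
        mult = 1.0 + spec.noise_cv * rng.standard_normal(len(df))
        add = spec.noise_floor * rng.standard_normal(len(df))
        df["value"] = np.maximum(0.0, df["value"] * mult + add)
        df["replicate"] = rep
        frames.append(df)
    data = pd.concat(frames, ignore_index=True)

    manifest = {
        "variant": dataclasses.asdict(spec.variant),
        "geometry": dataclasses.asdict(spec.geometry),
        "rates": dataclasses.asdict(spec.rates),
        "n_replicates": spec.n_replicates,
        "noise_cv": spec.noise_cv,
        "noise_floor": spec.noise_floor,
        "truth_ensemble_runs": spec.truth_ensemble_runs,
        "seed": spec.seed,
        "ensemble_seed": ens_seed,
        "noise_seed": noise_seed,
    }
    return data, manifest


def noise_free(spec: SynthSpec) -> pd.DataFrame:
    """The underlying noise-free ensemble-mean series of a spec."""
    ss = np.random.SeedSequence([int(spec.seed), 0x51])
    ens_seed = int(ss.generate_state(1)[0] % (2 ** 31))
    net = build_pathway(spec.variant, spec.geometry, spec.rates)
    ens = ensemble_mean(net, spec.sample_times,
                        n_runs=spec.truth_ensemble_runs, base_seed=ens_seed)
    return observe(ens)


def recovery_experiment(spec: SynthSpec, fit_params,
                        sa: SAConfig, n_repeats: int = 10,
                        initial: Optional[dict] = None) -> dict:
    """Generate data and refit, reporting recovered-vs-truth errors.

    Each repeat draws a fresh dataset and annealing seed. ``fit_params`` is
    the subset of rate parameters to optimise; all other rates are held at
    truth. With an empty subset, only the noise-floor error of the true
    parameters is reported.
    """
    truth = {name: getattr(spec.rates, name) for name in fit_params}
    repeats = []
    for rep in range(n_repeats):
        rep_spec = replace(spec, seed=spec.seed + 1000 * (rep + 1))
        data, _ = generate(rep_spec)
        if not fit_params:
            sim = noise_free(rep_spec)
            repeats.append({"E": error_E(sim, data)})
            continue
        start = dict(initial) if initial else {
            name: 0.5 * (sa.bounds[name][0] + sa.bounds[name][1])
            for name in fit_params}
        sa_rep = replace(sa, seed=sa.seed + rep)
        fit = anneal(spec.variant, spec.geometry, data, sa_rep, start,
                     base_rates=spec.rates)
        entry = {"E": fit.E, "params": {}}
        for name in fit_params:
            got = fit.params[name]
            entry["params"][name] = {
                "truth": truth[name],
                "fitted": got,
                "rel_err": abs(got - truth[name]) / abs(truth[name]),
            }
        repeats.append(entry)

    report = {"repeats": repeats, "fit_params": list(fit_params)}
    if fit_params and repeats:
        report["median_rel_err"] = {
            name: float(np.median([r["params"][name]["rel_err"]
                                   for r in repeats]))
            for name in fit_params}
        report["fitted_values"] = {
            name: [r["params"][name]["fitted"] for r in repeats]
            for name in fit_params}
    return report
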