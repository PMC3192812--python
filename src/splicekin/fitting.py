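"""Simulated-annealing parameter estimation against multi-series data.

The objective is the root-mean-square deviation E between the simulated and
observed nine-series time courses (replicates averaged first). Proposals add
a normal perturbation scaled by each parameter's allowed range and are
reflected at the bounds. Worsenings are accepted with probability
``exp(-k (E' - E) / T)`` under a geometric cooling schedule; the scale
constant k is set from the error E0 of the initial parameter set so a
worsening of size E0 at T0 = 1 is accepted with probability 1/e.

Every objective evaluation reuses the same ensemble seeds (common random
numbers), making the objective — and hence the whole fit — deterministic
given the configuration seed.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .geometry import GeneGeometry, ValidationError
from .observe import observe
from .pathway import (PathwayVariant, RateSet, build_pathway,
                      count_free_parameters, free_parameters)
from .ssa import ensemble_mean


@dataclass
class SAConfig:
    """Annealing schedule, proposal bounds and evaluation budget."""

    t0: float = 1.0
    alpha: float = 0.9
    iters_per_stage: int = 50
    n_stages: int = 40
    bounds: dict = field(default_factory=dict)  # name -> (min, max)
    proposal_scale: float = 0.1  # sigma as a fraction of each range
    anneal_proposal: bool = False  # shrink the proposal sigma by alpha each stage
    n_presearch: int = 0  # uniform samples scored before annealing; best is the start
    scale_rule: str = "inverse_e0"
    ensemble_runs_per_eval: int = 100
    final_ensemble_runs: int = 500
    relative_error: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValidationError("alpha must be in (0, 1)")
        if self.iters_per_stage < 1 or self.n_stages < 1:
            raise ValidationError("iters_per_stage and n_stages must be >= 1")
        for name, (lo, hi) in self.bounds.items():
            if not lo < hi:
                raise ValidationError(f"bounds[{name}]: min must be < max")


@dataclass
class FitResult:
    """Optimised parameters with error E and bookkeeping for the AIC."""

    model_id: str
    variant: PathwayVariant
    params: dict
    E: float
    n_points: int
    k_params: int
    per_series_rss: dict  # (experiment, species) -> (rss, n)
    trace: list
    seed: int

    def to_json(self, path) -> None:
        obj = {
            "model_id": self.model_id,
            "variant": dataclasses.asdict(self.variant),
            "params": self.params,
            "E": self.E,
            "n_points": self.n_points,
            "k_params": self.k_params,
            "per_series_rss": {f"{e}|{s}": [rss, n] for (e, s), (rss, n)
                               in self.per_series_rss.items()},
            "trace": self.trace,
            "seed": self.seed,
        }
        Path(path).write_text(json.dumps(obj, indent=2))

    @classmethod
    def from_json(cls, path) -> "FitResult":
        obj = json.loads(Path(path).read_text())
        per = {tuple(k.split("|")): tuple(v)
               for k, v in obj["per_series_rss"].items()}
        return cls(model_id=obj["model_id"],
                   variant=PathwayVariant(**obj["variant"]),
                   params=obj["params"], E=obj["E"],
                   n_points=obj["n_points"], k_params=obj["k_params"],
                   per_series_rss=per, trace=obj["trace"], seed=obj["seed"])


def _replicate_mean(df: pd.DataFrame) -> pd.DataFrame:
    return (df.groupby(["experiment", "species", "time_s"], as_index=False)
            ["value"].mean())


def _aligned_residuals(sim: pd.DataFrame, data: pd.DataFrame,
                       relative: bool = False) -> pd.DataFrame:
    s = _replicate_mean(sim).rename(columns={"value": "S"})
    d = _replicate_mean(data).rename(columns={"value": "D"})
    merged = d.merge(s, on=["experiment", "species", "time_s"], how="left")
    if merged["S"].isna().any():
        missing = merged[merged["S"].isna()][
            ["experiment", "species", "time_s"]].head(10)
        raise ValidationError(
            "simulation missing data keys:\n" + missing.to_string(index=False))
    merged["resid"] = merged["S"] - merged["D"]
    if relative:
        merged["resid"] /= np.maximum(np.abs(merged["D"]), 1.0)
    return merged


def error_E(sim: pd.DataFrame, data: pd.DataFrame,
            relative: bool = False) -> float:
    """Root-mean-square deviation over all n time points and d series."""
    merged = _aligned_residuals(sim, data, relative)
    return float(np.sqrt(np.mean(merged["resid"] ** 2)))


def per_series_rss(sim: pd.DataFrame, data: pd.DataFrame) -> dict:
    """Residual sum of squares and point count for each (experiment, species)."""
    merged = _aligned_residuals(sim, data)
    out = {}
    for (e, sp), grp in merged.groupby(["experiment", "species"]):
        out[(e, sp)] = (float(np.sum(grp["resid"] ** 2)), int(len(grp)))
    return out


def propose(params: dict, bounds: dict, scale,
            rng: np.random.Generator) -> dict:
    """Perturb each parameter by N(0,1)*scale*(max-min), reflected at bounds.

    ``scale`` is a fraction of each parameter's range: a single float, or a
    dict of per-parameter fractions for heterogeneous sensitivities.
    """
    new = {}
    for name, p in params.items():
        lo, hi = bounds[name]
        s = scale[name] if isinstance(scale, dict) else scale
        v = p + rng.standard_normal() * s * (hi - lo)
        # reflect until inside [lo, hi]
        width = hi - lo
        if width > 0:
            while v < lo or v > hi:
                if v < lo:
                    v = 2 * lo - v
                else:
                    v = 2 * hi - v
        new[name] = v
    return new


def _objective_factory(variant: PathwayVariant, geometry: GeneGeometry,
                       base_rates: RateSet, data: pd.DataFrame,
                       sample_times: np.ndarray, n_runs: int,
                       eval_seed: int, relative: bool):
    def objective(params: dict, runs: Optional[int] = None) -> tuple:
        rates = replace(base_rates, **params)
        net = build_pathway(variant, geometry, rates)
        ens = ensemble_mean(net, sample_times, n_runs=runs or n_runs,
                            base_seed=eval_seed)
        sim = observe(ens)
        return error_E(sim, data, relative), sim
    return objective


def anneal(variant: PathwayVariant, geometry: GeneGeometry,
           data: pd.DataFrame, sa: SAConfig, initial_params: dict,
           base_rates: Optional[RateSet] = None,
           model_id: Optional[str] = None) -> FitResult:
    """Fit the parameters named in ``initial_params`` to the data.

    Returns the best-ever parameter set; the reported E and per-series
    residuals come from a final re-evaluation with ``final_ensemble_runs``.
    """
    base_rates = base_rates or RateSet()
    for name, v in initial_params.items():
        if name not in sa.bounds:
            raise ValidationError(f"no bounds given for parameter {name!r}")
        lo, hi = sa.bounds[name]
        if not lo <= v <= hi:
            raise ValidationError(
                f"initial value of {name!r} ({v}) outside bounds [{lo}, {hi}]")

    times = np.sort(data["time_s"].unique()).astype(float)
    ss = np.random.SeedSequence([int(sa.seed), 0x5A])
    eval_seed, final_seed = (int(x % (2 ** 31)) for x in ss.generate_state(2))
    rng = np.random.default_rng(np.random.SeedSequence([int(sa.seed), 0xA5]))
    objective = _objective_factory(variant, geometry, base_rates, data, times,
                                   sa.ensemble_runs_per_eval, eval_seed,
                                   sa.relative_error)

    current = dict(initial_params)
    if sa.n_presearch > 0:
        # coarse uniform search over the bounds; the best point becomes the
        # "approximate fit" starting point the annealer expects
        names = list(initial_params)
        cands = [current] + [
            {n: rng.uniform(*sa.bounds[n]) for n in names}
            for _ in range(sa.n_presearch)]
        scored = [(objective(c)[0], c) for c in cands]
        current = min(scored, key=lambda t: t[0])[1]
    e_cur, _ = objective(current)
    if not math.isfinite(e_cur):
        raise ValidationError(
            "initial parameters give non-finite error; provide an "
            "approximate fit as the starting point")
    e0 = e_cur
    kscale = (1.0 / e0) if (sa.scale_rule == "inverse_e0" and e0 > 0) else 1.0

    best, e_best = dict(current), e_cur
    trace: list = [[e_cur, True]]
    for stage in range(sa.n_stages):
        T = sa.t0 * sa.alpha ** stage
        shrink = sa.alpha ** stage if sa.anneal_proposal else 1.0
        if isinstance(sa.proposal_scale, dict):
            scale = {n: s * shrink for n, s in sa.proposal_scale.items()}
        else:
            scale = sa.proposal_scale * shrink
        for _ in range(sa.iters_per_stage):
            cand = propose(current, sa.bounds, scale, rng)
            e_new, _ = objective(cand)
            if e_new <= e_cur:
                accept = True
            else:
                accept = (T > 0 and
                          rng.random() < math.exp(-kscale * (e_new - e_cur) / T))
            if accept:
                current, e_cur = cand, e_new
                if e_cur < e_best:
                    best, e_best = dict(current), e_cur
            trace.append([e_new, bool(accept)])

    # final evaluation at higher ensemble resolution, fresh seeds
    rates = replace(base_rates, **best)
    net = build_pathway(variant, geometry, rates)
    ens = ensemble_mean(net, times, n_runs=sa.final_ensemble_runs,
                        base_seed=final_seed)
    sim = observe(ens)
    rss = per_series_rss(sim, data)
    n_points = sum(n for _, n in rss.values())
    return FitResult(
        model_id=model_id or variant.name or "custom",
        variant=variant,
        params=best,
        E=error_E(sim, data, sa.relative_error),
        n_points=n_points,
        k_params=len(best),
        per_series_rss=rss,
        trace=trace,
        seed=sa.seed,
    )


def default_bounds(variant: PathwayVariant) -> dict:
    """Broad bounds for the full free-parameter set of a variant."""
    all_bounds = {
        "k_init": (0.01, 1.0), "k_elong": (0.5, 10.0), "eta": (1.0, 50.0),
        "k_on": (0.002, 0.2), "c1": (0.01, 1.0), "c2": (0.01, 1.0),
        "k1_post": (0.01, 1.0), "k2_post": (0.01, 1.0),
        "k2_co": (0.0005, 0.05), "ks": (0.01, 2.0), "ke": (0.01, 2.0),
    }
    return {name: all_bounds[name] for name in free_parameters(variant)}


__all__ = ["SAConfig", "FitResult", "error_E", "per_series_rss", "propose",
           "anneal", "default_bounds", "count_free_parameters"]
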