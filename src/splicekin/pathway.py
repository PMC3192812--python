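"""Pathway variants, rate sets and reaction-network construction.

The reporter RNA is processed along two routes. On the post-transcriptional
route, a transcript is released uncleaved (U-pre-mRNA), matures at its 3'
end into polyadenylated pre-mRNA (P-pre-mRNA), then undergoes splicing step
one (-> P-lariat-exon2) and step two (-> P-mRNA + excised lariat). On the
co-transcriptional route, the elongating polymerase switches track after the
branchsite (splicing step one happens on the nascent transcript); the
completed transcript is released as uncleaved lariat-exon2, undergoes step
two (-> U-mRNA + lariat) and finally matures at the 3' end into P-mRNA.

Each processing step can be realised as a single first-order reaction, as a
chain of identical-rate sub-steps (gamma-like kinetics), or — for the
splicing steps — as a positive-feedback reaction whose propensity grows with
a dedicated enzyme counter Y that starts at 1 and is incremented on every
firing. Eight named pathway variants (I..VIII) enumerate the mechanism
combinations; two splice-site mutants (ss3, ss5) modify the wild-type
topology.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from .geometry import GeneGeometry, ValidationError

FEEDBACK = "feedback"
MULTISTEP = "multistep"
SINGLE = "single"

#: Mechanism triples (co-transcriptional step 2, post-transcriptional steps,
#: elongation) for the eight named pathways.
PATHWAY_TABLE: dict[str, tuple[str, str, str]] = {
    "I": (FEEDBACK, MULTISTEP, MULTISTEP),
    "II": (FEEDBACK, MULTISTEP, SINGLE),
    "III": (FEEDBACK, FEEDBACK, MULTISTEP),
    "IV": (FEEDBACK, FEEDBACK, SINGLE),
    "V": (MULTISTEP, MULTISTEP, MULTISTEP),
    "VI": (MULTISTEP, MULTISTEP, SINGLE),
    "VII": (SINGLE, SINGLE, MULTISTEP),
    "VIII": (SINGLE, SINGLE, SINGLE),
}

# Canonical observable species names (U- = 3' uncleaved, P- = polyadenylated).
U_PRE = "U-pre-mRNA"
P_PRE = "P-pre-mRNA"
U_LAR = "U-lariat-exon2"
P_LAR = "P-lariat-exon2"
U_MRNA = "U-mRNA"
P_MRNA = "P-mRNA"
LARIAT = "lariat"


@dataclass(frozen=True)
class PathwayVariant:
    """Which mechanism each processing step uses."""

    co2_mech: str = FEEDBACK
    post_mech: str = MULTISTEP
    elongation_mech: str = MULTISTEP
    mutant: str = "none"  # none | ss3 | ss5
    n_substeps: int = 5
    allow_ulariat_polyadenylation: bool = False
    name: Optional[str] = None

    def __post_init__(self) -> None:
        if self.co2_mech not in (FEEDBACK, MULTISTEP, SINGLE):
            raise ValidationError(f"co2_mech: unknown mechanism {self.co2_mech!r}")
        if self.post_mech not in (FEEDBACK, MULTISTEP, SINGLE):
            raise ValidationError(f"post_mech: unknown mechanism {self.post_mech!r}")
        if self.elongation_mech not in (MULTISTEP, SINGLE):
            raise ValidationError(
                f"elongation_mech: unknown mechanism {self.elongation_mech!r}"
            )
        if self.mutant not in ("none", "ss3", "ss5"):
            raise ValidationError(f"mutant: unknown mutant {self.mutant!r}")
        if self.n_substeps < 1:
            raise ValidationError("n_substeps must be >= 1")

    @classmethod
    def from_name(cls, name: str, **overrides) -> "PathwayVariant":
        """Build one of the eight named pathways (I .. VIII)."""
        key = name.strip().upper()
        if key not in PATHWAY_TABLE:
            raise ValidationError(f"unknown pathway name {name!r}")
        co, po, el = PATHWAY_TABLE[key]
        return cls(co2_mech=co, post_mech=po, elongation_mech=el, name=key,
                   **overrides)

    @property
    def has_co_track(self) -> bool:
        return self.mutant != "ss5"


# Per-stage rates of the five-step processes are set so the Erlang(5) median
# completion times match the fitted half-times: 35 s (pre-mRNA 3' maturation),
# 49 s (mRNA 3' maturation), 34 s / 36 s (post splicing steps 1/2).
_ERLANG5_MEDIAN = 4.670909  # median of a unit-rate Erlang(5) waiting time


@dataclass(frozen=True)
class RateSet:
    """All kinetic constants and the activation schedule.

    Rates are per second; ``k2_co`` (and other feedback rates) are per
    molecule per second when the mechanism is feedback. ``eta`` is the
    dimensionless ratio constant: the co-transcriptional transition fires at
    ``k_elong / eta`` so the per-section odds of elongating vs switching are
    eta : 1.
    """

    k_init: float = 0.25
    k_elong: float = 2.27
    eta: float = 11.39
    k_on: float = 0.03
    c1: float = _ERLANG5_MEDIAN / 35.0
    c2: float = _ERLANG5_MEDIAN / 49.0
    k1_post: float = _ERLANG5_MEDIAN / 34.0
    k2_post: float = _ERLANG5_MEDIAN / 36.0
    k2_co: float = 0.0063
    ks: float = 0.4
    ke: float = 0.07
    d_ppre: float = 0.002
    d_plar: float = 0.002
    d_mrna: float = 0.0
    t_act: float = 400.0
    n_burst: int = 8

    def __post_init__(self) -> None:
        for name in ("k_init", "k_elong", "k_on", "c1", "c2", "k1_post",
                     "k2_post", "k2_co", "ks", "ke", "d_ppre", "d_plar",
                     "d_mrna", "t_act"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        if self.eta <= 0:
            raise ValidationError("eta must be > 0")
        if self.n_burst < 0:
            raise ValidationError("n_burst must be >= 0")

    def validate_for(self, variant: PathwayVariant) -> None:
        """Check mutant-specific rate constraints."""
        if variant.mutant == "ss3":
            if self.k2_co != 0:
                raise ValidationError("k2_co must be 0 in the ss3 mutant")
            if self.k2_post != 0:
                raise ValidationError("k2_post must be 0 in the ss3 mutant")
        if variant.mutant == "ss5":
            if self.k1_post != 0:
                raise ValidationError("k1_post must be 0 in the ss5 mutant")


def ribo1_rates(**overrides) -> RateSet:
    """Default wild-type reporter rates."""
    return replace(RateSet(), **overrides) if overrides else RateSet()


def ss3_rates(**overrides) -> RateSet:
    """3' splice-site mutant: step two abolished; lariat-exon2 matures at c2
    instead. Initiation at 70% of wild type, splicing activation twice as
    slow, and eta raised to 30 (co-transcriptional step one less likely)."""
    base = RateSet(k_init=0.175, eta=30.0, k_on=0.015, k2_co=0.0, k2_post=0.0)
    return replace(base, **overrides) if overrides else base


def ss5_rates(**overrides) -> RateSet:
    """5' splice-site mutant: no splicing at all; initiation at 40% of wild
    type. eta is ignored (the co track is unreachable)."""
    base = RateSet(k_init=0.1, k1_post=0.0, k2_post=0.0, k2_co=0.0)
    return replace(base, **overrides) if overrides else base


@dataclass(frozen=True)
class Pool:
    """A released-molecule pool with its observational classification."""

    name: str
    species: str  # pre-mRNA | lariat-exon2 | mRNA | lariat | degraded
    polyadenylated: Optional[bool]  # None for lariat / degraded


@dataclass(frozen=True)
class Reaction:
    """A first-order conversion between pools.

    Propensity is ``rate * count(substrate)``, multiplied by the reaction's
    dedicated Y counter when ``feedback`` is set (Y starts at 1 and is
    incremented on each firing). ``gated`` reactions have propensity 0 until
    the splicing-activation event has occurred.
    """

    name: str
    substrate: str
    products: tuple[str, ...]
    rate: float
    feedback: bool = False
    gated: bool = False


def feedback_reaction_spec(step: str, rate_constant: float,
                           substrate: str, products: tuple[str, ...],
                           gated: bool = True) -> Reaction:
    """Bimolecular positive-feedback reaction with a dedicated enzyme counter.

    The enzyme Y starts at copy number 1 and is incremented on every firing,
    so the per-substrate hazard grows linearly with the number of completed
    events: propensity = rate_constant * substrate_count * Y.
    """
    if rate_constant < 0:
        raise ValidationError(f"{step}: rate_constant must be >= 0")
    return Reaction(name=step, substrate=substrate, products=products,
                    rate=rate_constant, feedback=True, gated=gated)


@dataclass
class CompiledNetwork:
    """Flat-array form of a ReactionNetwork consumed by the SSA kernel."""

    sub: np.ndarray
    prod1: np.ndarray
    prod2: np.ndarray
    rate: np.ndarray
    ydx: np.ndarray
    gated: np.ndarray
    n_pools: int
    n_y: int
    n_sections: int
    branch0: int  # 0-based first transition section
    k_elong: float
    k_co: float  # 0 disables the co-transcriptional transition
    single_elong: bool
    ks: float  # APC -> U-lariat-exon2 (single-elongation co exit)
    ke: float  # APC -> U-pre-mRNA (single-elongation post exit)
    k_init: float
    t_act: float
    k_on: float
    n_burst: int
    exit_post: int
    exit_co: int


@dataclass
class ReactionNetwork:
    """Full reaction network for one pathway variant.

    The polymerase lattice (initiation, promoter escape, per-section hops,
    co-transcriptional transitions and release) is handled positionally by
    the simulation engine; the released-molecule chemistry is the explicit
    ``reactions`` list over ``pools``.
    """

    geometry: GeneGeometry
    variant: PathwayVariant
    rates: RateSet
    pools: list[Pool] = field(default_factory=list)
    reactions: list[Reaction] = field(default_factory=list)
    exit_post_pool: str = U_PRE
    exit_co_pool: str = U_LAR

    def __post_init__(self) -> None:
        self.pool_index = {p.name: i for i, p in enumerate(self.pools)}

    @property
    def n_pools(self) -> int:
        return len(self.pools)

    @property
    def feedback_reactions(self) -> list[Reaction]:
        return [r for r in self.reactions if r.feedback]

    def pools_by_class(self, species: str,
                       polyadenylated: Optional[bool] = None) -> list[int]:
        """Indices of pools of a given observational class."""
        out = []
        for i, p in enumerate(self.pools):
            if p.species != species:
                continue
            if polyadenylated is not None and p.polyadenylated != polyadenylated:
                continue
            out.append(i)
        return out

    def validate(self) -> None:
        names = set(self.pool_index)
        flags = {"gene_active", "splicing_active", "burst_budget_remaining"}
        del flags  # gating uses only splicing_active; others gate the lattice
        for r in self.reactions:
            if r.substrate not in names:
                raise ValidationError(f"{r.name}: unknown substrate {r.substrate!r}")
            for p in r.products:
                if p not in names:
                    raise ValidationError(f"{r.name}: unknown product {p!r}")
            if r.rate < 0:
                raise ValidationError(f"{r.name}: negative rate")

    def compile(self) -> CompiledNetwork:
        """Lower to the flat arrays used by the stochastic kernel."""
        rs, v, g = self.rates, self.variant, self.geometry
        nr = len(self.reactions)
        sub = np.empty(nr, np.int64)
        prod1 = np.full(nr, -1, np.int64)
        prod2 = np.full(nr, -1, np.int64)
        rate = np.empty(nr, np.float64)
        ydx = np.full(nr, -1, np.int64)
        gated = np.zeros(nr, np.uint8)
        n_y = 0
        for j, r in enumerate(self.reactions):
            sub[j] = self.pool_index[r.substrate]
            if len(r.products) > 0:
                prod1[j] = self.pool_index[r.products[0]]
            if len(r.products) > 1:
                prod2[j] = self.pool_index[r.products[1]]
            rate[j] = r.rate
            gated[j] = 1 if r.gated else 0
            if r.feedback:
                ydx[j] = n_y
                n_y += 1
        single = v.elongation_mech == SINGLE
        k_co = 0.0
        if not single and v.has_co_track:
            k_co = rs.k_elong / rs.eta
        return CompiledNetwork(
            sub=sub, prod1=prod1, prod2=prod2, rate=rate, ydx=ydx, gated=gated,
            n_pools=self.n_pools, n_y=max(n_y, 1),
            n_sections=g.n_sections, branch0=g.branch_section - 1,
            k_elong=rs.k_elong, k_co=k_co, single_elong=single,
            ks=rs.ks if (single and v.has_co_track) else 0.0,
            ke=rs.ke if single else 0.0,
            k_init=rs.k_init, t_act=rs.t_act, k_on=rs.k_on,
            n_burst=rs.n_burst,
            exit_post=self.pool_index[self.exit_post_pool],
            exit_co=self.pool_index[self.exit_co_pool],
        )


def _add_pool(net: ReactionNetwork, name: str, species: str,
              polyadenylated: Optional[bool]) -> None:
    net.pools.append(Pool(name, species, polyadenylated))
    net.pool_index[name] = len(net.pools) - 1


def _add_process(net: ReactionNetwork, name: str, substrate: str,
                 products: tuple[str, ...], mech: str, rate: float,
                 m: int, gated: bool) -> None:
    """Realise one processing step per its mechanism.

    For ``multistep`` the substrate pool is stage 1 of an m-stage chain of
    identical-rate conversions; the intermediate stages inherit the
    substrate's observational classification (the assays detect chemical
    species, not assembly states).
    """
    if mech == SINGLE:
        net.reactions.append(Reaction(name, substrate, products, rate,
                                      gated=gated))
    elif mech == FEEDBACK:
        net.reactions.append(feedback_reaction_spec(name, rate, substrate,
                                                    products, gated=gated))
    elif mech == MULTISTEP:
        base = net.pools[net.pool_index[substrate]]
        prev = substrate
        for k in range(1, m):
            stage = f"{name}~{k}"
            _add_pool(net, stage, base.species, base.polyadenylated)
            net.reactions.append(Reaction(f"{name}.{k}", prev, (stage,),
                                          rate, gated=gated))
            prev = stage
        net.reactions.append(Reaction(f"{name}.{m}", prev, products, rate,
                                      gated=gated))
    else:  # pragma: no cover - mechanisms validated upstream
        raise ValidationError(f"unknown mechanism {mech!r}")


def build_pathway(variant: PathwayVariant,
                  geometry: Optional[GeneGeometry] = None,
                  rates: Optional[RateSet] = None) -> ReactionNetwork:
    """Construct the full reaction network for a pathway variant.

    The returned network contains the released-molecule chemistry explicitly;
    initiation, elongation, co-transcriptional transitions and release are
    described by the geometry/rates and executed positionally by the engine.
    """
    geometry = geometry or GeneGeometry()
    if rates is None:
        rates = {"none": ribo1_rates, "ss3": ss3_rates, "ss5": ss5_rates}[
            variant.mutant]()
    rates.validate_for(variant)

    net = ReactionNetwork(geometry=geometry, variant=variant, rates=rates)
    # Canonical pools are always registered so every assay signal is defined
    # (unreachable pools simply stay at zero).
    _add_pool(net, U_PRE, "pre-mRNA", False)
    _add_pool(net, P_PRE, "pre-mRNA", True)
    _add_pool(net, U_LAR, "lariat-exon2", False)
    _add_pool(net, P_LAR, "lariat-exon2", True)
    _add_pool(net, U_MRNA, "mRNA", False)
    _add_pool(net, P_MRNA, "mRNA", True)
    _add_pool(net, LARIAT, "lariat", None)
    _add_pool(net, "deg:pre-mRNA", "degraded", None)
    _add_pool(net, "deg:lariat-exon2", "degraded", None)
    _add_pool(net, "deg:mRNA", "degraded", None)

    m = variant.n_substeps
    # 3' end maturation of uncleaved pre-mRNA (always multistep, ungated:
    # the initial burst of transcripts is cleaved and polyadenylated before
    # splicing activates).
    _add_process(net, "mat3p_pre", U_PRE, (P_PRE,), MULTISTEP, rates.c1, m,
                 gated=False)

    if variant.mutant != "ss5":
        # Post-transcriptional splicing step one.
        _add_process(net, "splice1", P_PRE, (P_LAR,), variant.post_mech,
                     rates.k1_post, m, gated=True)

    if variant.mutant == "none":
        # Post-transcriptional splicing step two.
        _add_process(net, "splice2", P_LAR, (P_MRNA, LARIAT),
                     variant.post_mech, rates.k2_post, m, gated=True)
        # Co-transcriptional splicing step two on the released transcript.
        _add_process(net, "co_splice2", U_LAR, (U_MRNA, LARIAT),
                     variant.co2_mech, rates.k2_co, m, gated=True)
        # 3' end maturation of uncleaved (co-spliced) mRNA.
        _add_process(net, "mat3p_mrna", U_MRNA, (P_MRNA,), MULTISTEP,
                     rates.c2, m, gated=False)
    elif variant.mutant == "ss3":
        # Step two is blocked: uncleaved lariat-exon2 instead completes the
        # multistep 3' cleavage process at rate c2.
        _add_process(net, "mat3p_lar", U_LAR, (P_LAR,), MULTISTEP, rates.c2,
                     m, gated=False)

    if variant.allow_ulariat_polyadenylation and variant.mutant == "none":
        # Optional slow 3' maturation of co-spliced lariat-exon2 (a
        # transition the data disfavour; off by default).
        net.reactions.append(Reaction("ulariat_polya", U_LAR, (P_LAR,),
                                      rates.c1, gated=False))

    # First-order degradation sinks on every pool of the degradable classes
    # (molecules midway through a multistep conversion can still degrade).
    for species, d, sink in (("pre-mRNA", rates.d_ppre, "deg:pre-mRNA"),
                             ("lariat-exon2", rates.d_plar, "deg:lariat-exon2"),
                             ("mRNA", rates.d_mrna, "deg:mRNA")):
        if d <= 0:
            continue
        for i in net.pools_by_class(species):
            net.reactions.append(Reaction(f"deg[{net.pools[i].name}]",
                                          net.pools[i].name, (sink,), d,
                                          gated=False))

    net.validate()
    return net


#: Parameters common to every variant that the fitter may optimise.
_BASE_FREE = ("k_init", "k_on", "c1", "c2")


def free_parameters(variant: PathwayVariant) -> tuple[str, ...]:
    """Names of the rate parameters optimised for a variant (AIC's k)."""
    params = list(_BASE_FREE)
    if variant.elongation_mech == MULTISTEP:
        params.append("k_elong")
        if variant.has_co_track:
            params.append("eta")
    else:
        params.append("ke")
        if variant.has_co_track:
            params.append("ks")
    if variant.mutant != "ss5":
        params.append("k1_post")
    if variant.mutant == "none":
        params.append("k2_post")
        if variant.has_co_track:
            params.append("k2_co")
    return tuple(params)


def count_free_parameters(variant: PathwayVariant) -> int:
    """Number of rate parameters the fitter optimises (k in the AIC)."""
    return len(free_parameters(variant))
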