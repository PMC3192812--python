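"""Network construction: pathway-table fidelity, mutants, free parameters."""

import numpy as np
import pytest

import splicekin as sk
from splicekin.geometry import ValidationError
from splicekin.pathway import FEEDBACK, MULTISTEP, SINGLE


def _mech_of(net, process):
    """Infer the realised mechanism of a named process from its reactions."""
    named = [r for r in net.reactions if r.name == process
             or r.name.startswith(process + ".")]
    if not named:
        return None
    if len(named) == 1:
        return FEEDBACK if named[0].feedback else SINGLE
    return MULTISTEP


@pytest.mark.parametrize("name,co,po,el", [
    (n, *mechs) for n, mechs in sk.PATHWAY_TABLE.items()])
def test_pathway_table_fidelity(name, co, po, el):
    """Each named pathway realises the mechanisms of its table row."""
    net = sk.build_pathway(sk.PathwayVariant.from_name(name))
    assert _mech_of(net, "co_splice2") == co
    assert _mech_of(net, "splice1") == po
    assert _mech_of(net, "splice2") == po
    assert net.compile().single_elong == (el == SINGLE)


def test_multistep_processes_have_five_stages(network_I):
    """Post splicing steps in pathway I are chains of 5 identical-rate stages."""
    for proc, rate in (("splice1", network_I.rates.k1_post),
                       ("splice2", network_I.rates.k2_post)):
        stages = [r for r in network_I.reactions
                  if r.name.startswith(proc + ".")]
        assert len(stages) == 5
        assert all(r.rate == rate for r in stages)
        assert not any(r.feedback for r in stages)


def test_single_elongation_network_structure():
    """Pathway VIII: one exit reaction per route from the APC, single-step
    splicing reactions."""
    net = sk.build_pathway(sk.PathwayVariant.from_name("VIII"))
    c = net.compile()
    assert c.single_elong
    assert c.ks == net.rates.ks and c.ke == net.rates.ke
    assert _mech_of(net, "splice1") == SINGLE
    assert _mech_of(net, "co_splice2") == SINGLE


def test_reachability_pathway_I(network_I):
    """P-mRNA is produced only by U-mRNA maturation and post step two."""
    producers = {r.name for r in network_I.reactions
                 if "P-mRNA" in r.products}
    assert producers == {"mat3p_mrna.5", "splice2.5"}
    u_mrna_producers = {r.name for r in network_I.reactions
                        if "U-mRNA" in r.products}
    assert u_mrna_producers == {"co_splice2"}


def test_ss5_mutant_has_no_splicing_routes():
    net = sk.build_pathway(sk.PathwayVariant.from_name("I", mutant="ss5"))
    assert _mech_of(net, "co_splice2") is None
    assert _mech_of(net, "splice1") is None
    assert net.compile().k_co == 0.0
    # the only conversion chemistry is pre-mRNA maturation (degradation
    # sinks exist for every class but the non-pre pools stay unreachable)
    for r in net.reactions:
        if r.name.startswith("deg["):
            continue
        sp = net.pools[net.pool_index[r.substrate]].species
        assert sp == "pre-mRNA"


def test_ss3_mutant_lariat_matures_instead_of_splicing():
    net = sk.build_pathway(sk.PathwayVariant.from_name("I", mutant="ss3"))
    assert _mech_of(net, "co_splice2") is None
    assert _mech_of(net, "splice2") is None
    stages = [r for r in net.reactions if r.name.startswith("mat3p_lar.")]
    assert len(stages) == 5
    assert all(r.rate == net.rates.c2 for r in stages)
    assert net.rates.eta == 30.0 and net.rates.k_init == 0.175


def test_mutant_rate_invariants_enforced():
    with pytest.raises(ValidationError, match="k2_co"):
        sk.build_pathway(sk.PathwayVariant.from_name("I", mutant="ss3"),
                         rates=sk.RateSet(k2_post=0.0))
    with pytest.raises(ValidationError, match="k1_post"):
        sk.build_pathway(sk.PathwayVariant.from_name("I", mutant="ss5"),
                         rates=sk.RateSet())


def test_geometry_invariants():
    with pytest.raises(ValidationError, match="n_sections"):
        sk.GeneGeometry(length_nt=1240, section_nt=31, n_sections=39)
    with pytest.raises(ValidationError, match="transition window"):
        sk.GeneGeometry(branch_section=17)
    with pytest.raises(ValidationError, match="branch_section"):
        sk.GeneGeometry(length_nt=62, section_nt=31, n_sections=2,
                        branch_section=1, n_transition_sections=2,
                        primer_section_expt1=2, primer_section_expt2=2)


def test_feedback_reaction_spec_propensity():
    """Feedback propensity is rate * substrate * Y, with Y starting at 1 and
    incrementing on each firing."""
    net = sk.build_pathway(sk.PathwayVariant.from_name("I"))
    st = sk.initial_state(net)
    st.gene_active = st.splicing_active = True
    st.species_counts["U-lariat-exon2"] = 1
    a = sk.propensities(st)
    assert a["co_splice2"] == pytest.approx(0.0063)

    # fire the feedback reaction 19 times: Y reaches 20, per-molecule hazard
    # is 20x the initial one (half-life 110 s -> 5.5 s)
    st.species_counts["U-lariat-exon2"] = 1000
    rng = np.random.default_rng(0)
    fired = 0
    while fired < 19:
        name, _ = sk.step(st, rng)
        if name == "co_splice2":
            fired += 1
    assert st.y_counters["co_splice2"] == 20
    n_sub = st.species_counts["U-lariat-exon2"]
    assert sk.propensities(st)["co_splice2"] == pytest.approx(
        0.0063 * n_sub * 20)

    # zero substrate -> channel disabled
    st.species_counts["U-lariat-exon2"] = 0
    assert "co_splice2" not in sk.propensities(st)


def test_count_free_parameters():
    v1 = sk.PathwayVariant.from_name("I")
    v8 = sk.PathwayVariant.from_name("VIII")
    assert sk.count_free_parameters(v8) <= sk.count_free_parameters(v1)
    # feedback and multistep mechanisms both carry one rate constant
    v3 = sk.PathwayVariant.from_name("III")
    assert sk.count_free_parameters(v3) == sk.count_free_parameters(v1)
    # ss5 drops eta, k1_post, k2_post, k2_co
    v5ss = sk.PathwayVariant.from_name("I", mutant="ss5")
    names = sk.free_parameters(v5ss)
    assert not {"eta", "k1_post", "k2_post", "k2_co"} & set(names)
    assert sk.count_free_parameters(v5ss) == sk.count_free_parameters(v1) - 4


def test_unknown_mechanism_rejected():
    with pytest.raises(ValidationError, match="co2_mech"):
        sk.PathwayVariant(co2_mech="bogus")
    with pytest.raises(ValidationError, match="pathway"):
        sk.PathwayVariant.from_name("IX")
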