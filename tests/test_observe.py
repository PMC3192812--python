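"""Observation model: primer gating, U/P partition, signal identities."""

import numpy as np
import pytest

import splicekin as sk
from splicekin.observe import AssayConfig
from splicekin.ssa import Trajectory


def _hand_trajectory(network, occupancy=None, pools=None):
    """Single-snapshot trajectory built by hand."""
    S = network.geometry.n_sections
    occ = np.zeros((1, S), np.int8)
    if occupancy:
        for sec, code in occupancy.items():  # 1-based sections
            occ[0, sec - 1] = code
    p = np.zeros((1, network.n_pools), np.int64)
    if pools:
        for name, n in pools.items():
            p[0, network.pool_index[name]] = n
    return Trajectory(sample_times=np.array([0.0]), pools=p, occupancy=occ,
                      apc=np.zeros(1, np.int8), y=np.ones((1, 1), np.int64),
                      cumulative=np.zeros((1, 5), np.int64),
                      flags=np.zeros((1, 2), np.int8), seed=0,
                      network=network)


def test_nascent_gating_upstream_of_primer(network_I):
    traj = _hand_trajectory(network_I, occupancy={10: 1})
    sig = sk.signals(traj, AssayConfig("expt1", 35))
    assert all(v[0] == 0 for v in sig.values())


def test_co_track_nascent_counts_as_lariat_exon2(network_I):
    """A co-track polymerase past the primer has completed step one on the
    nascent transcript: it is lariat-exon2, not pre-mRNA."""
    traj = _hand_trajectory(network_I, occupancy={38: 2})
    sig = sk.signals(traj, AssayConfig("expt1", 35))
    assert sig["lariat-exon2"][0] == 1
    assert sig["pre-mRNA"][0] == 0


def test_maturation_stage_is_uncleaved_until_final_step(network_I):
    before = _hand_trajectory(network_I, pools={"mat3p_mrna~2": 1})
    sig = sk.signals(before, AssayConfig("expt2", 40))
    assert sig["U-mRNA"][0] == 1 and sig["P-mRNA"][0] == 0
    after = _hand_trajectory(network_I, pools={"P-mRNA": 1})
    sig = sk.signals(after, AssayConfig("expt2", 40))
    assert sig["U-mRNA"][0] == 0 and sig["P-mRNA"][0] == 1


def test_monotone_gating(traj_I):
    """Moving a primer downstream never increases a nascent contribution."""
    prev = None
    for primer in (1, 10, 20, 30, 40):
        sig = sk.signals(traj_I, AssayConfig("expt1", primer))
        tot = sig["pre-mRNA"] + sig["lariat-exon2"]
        if prev is not None:
            assert np.all(tot <= prev + 1e-12)
        prev = tot


def test_partition_audit(traj_I, network_I):
    """expt2 U+P signals partition each species: released pools plus gated
    nascent contributions, audited against the raw state."""
    sig = sk.signals(traj_I, AssayConfig("expt2", 40))
    for species in ("pre-mRNA", "lariat-exon2", "mRNA"):
        pools = traj_I.pools[:, network_I.pools_by_class(species)].sum(axis=1)
        track = traj_I.occ_post if species == "pre-mRNA" else traj_I.occ_co
        nascent = track[:, 39:].sum(axis=1) if species != "mRNA" else 0
        u = sig[f"U-{species}" if species != "mRNA" else "U-mRNA"]
        p = sig[f"P-{species}" if species != "mRNA" else "P-mRNA"]
        assert np.allclose(u + p, pools + nascent)


def test_observe_nine_series_and_mrna_identity(ensemble_I):
    df = sk.observe(ensemble_I)
    assert set(df["experiment"]) == {"expt1", "expt2"}
    assert len(df.groupby(["experiment", "species"])) == 9
    piv1 = df[df.experiment == "expt1"].pivot(index="time_s",
                                              columns="species",
                                              values="value")
    piv2 = df[df.experiment == "expt2"].pivot(index="time_s",
                                              columns="species",
                                              values="value")
    # released mRNA has identical gating in both experiments
    assert np.allclose(piv1["mRNA"],
                       piv2["U-mRNA"] + piv2["P-mRNA"])
    # before gene activation every signal is zero
    assert piv1.loc[0.0].sum() == 0 and piv2.loc[0.0].sum() == 0


def test_uncleaved_mrna_rises_before_polyadenylated(ensemble_I):
    df = sk.observe(ensemble_I)
    piv = df[df.experiment == "expt2"].pivot(index="time_s",
                                             columns="species",
                                             values="value")
    t_u = piv.index[piv["U-mRNA"] > 1.0].min()
    t_p = piv.index[piv["P-mRNA"] > 1.0].min()
    assert t_u < t_p


def test_invalid_assay_rejected():
    with pytest.raises(sk.ValidationError):
        AssayConfig("expt3", 35)
    with pytest.raises(sk.ValidationError):
        AssayConfig("expt1", 0)
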