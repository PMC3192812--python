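"""RT-qPCR observation model.

Maps simulated state to the nine assay signals. Experiment 1 detects total
pre-mRNA, lariat-exon2 and mRNA via a cDNA primer in exon 2 (C1); nascent
transcripts count only once the polymerase has passed the primer section.
Experiment 2 separates 3' uncleaved (primer C2, downstream of the cleavage
sites) from polyadenylated (oligo-dT) forms of each species. A molecule
midway through 3' end maturation counts as uncleaved until the final
sub-step fires; cleavage and polyadenylation are not separated
observationally.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Union

import numpy as np
import pandas as pd

from .geometry import GeneGeometry, ValidationError
from .pathway import ReactionNetwork
from .ssa import EnsembleSummary, Trajectory, POST, CO

EXPT1_SPECIES = ("pre-mRNA", "lariat-exon2", "mRNA")
EXPT2_SPECIES = ("U-pre-mRNA", "P-pre-mRNA", "U-lariat-exon2",
                 "P-lariat-exon2", "U-mRNA", "P-mRNA")
ALL_SPECIES = EXPT1_SPECIES + EXPT2_SPECIES


@dataclass(frozen=True)
class AssayConfig:
    """One assay experiment: which primer gates nascent detection."""

    experiment: str  # 'expt1' | 'expt2'
    primer_section: int  # 1-based

    def __post_init__(self) -> None:
        if self.experiment not in ("expt1", "expt2"):
            raise ValidationError(f"unknown experiment {self.experiment!r}")
        if self.primer_section < 1:
            raise ValidationError("primer_section must be >= 1")


def default_assays(geometry: Optional[GeneGeometry] = None
                   ) -> tuple[AssayConfig, AssayConfig]:
    geometry = geometry or GeneGeometry()
    return (AssayConfig("expt1", geometry.primer_section_expt1),
            AssayConfig("expt2", geometry.primer_section_expt2))


def _pool_sums(network: ReactionNetwork, values: np.ndarray, species: str,
               polyadenylated: Optional[bool] = None) -> np.ndarray:
    idx = network.pools_by_class(species, polyadenylated)
    if not idx:
        return np.zeros(values.shape[:-1])
    return values[..., idx].sum(axis=-1)


def _nascent(occ_track: np.ndarray, assay: AssayConfig,
             geometry: GeneGeometry) -> np.ndarray:
    if assay.primer_section > geometry.n_sections:
        raise ValidationError("primer_section beyond the last section")
    return occ_track[..., assay.primer_section - 1:].sum(axis=-1)


def signals(source: Union[Trajectory, EnsembleSummary],
            assay: AssayConfig) -> dict[str, np.ndarray]:
    """Assay signals per reported species, on the source's sample grid.

    Post-track polymerases past the primer contribute to the pre-mRNA (expt1)
    or U-pre-mRNA (expt2) signal; co-track polymerases (step one of splicing
    already done on the nascent transcript) contribute to lariat-exon2 /
    U-lariat-exon2.
    """
    if isinstance(source, Trajectory):
        pools = source.pools.astype(np.float64)
        occ_post = (source.occupancy == POST).astype(np.float64)
        occ_co = (source.occupancy == CO).astype(np.float64)
    else:
        pools = source.mean_pools
        occ_post = source.mean_occ_post
        occ_co = source.mean_occ_co
    net = source.network
    geom = net.geometry
    nasc_post = _nascent(occ_post, assay, geom)
    nasc_co = _nascent(occ_co, assay, geom)

    if assay.experiment == "expt1":
        return {
            "pre-mRNA": _pool_sums(net, pools, "pre-mRNA") + nasc_post,
            "lariat-exon2": _pool_sums(net, pools, "lariat-exon2") + nasc_co,
            "mRNA": _pool_sums(net, pools, "mRNA"),
        }
    return {
        "U-pre-mRNA": _pool_sums(net, pools, "pre-mRNA", False) + nasc_post,
        "P-pre-mRNA": _pool_sums(net, pools, "pre-mRNA", True),
        "U-lariat-exon2": _pool_sums(net, pools, "lariat-exon2", False) + nasc_co,
        "P-lariat-exon2": _pool_sums(net, pools, "lariat-exon2", True),
        "U-mRNA": _pool_sums(net, pools, "mRNA", False),
        "P-mRNA": _pool_sums(net, pools, "mRNA", True),
    }


def observe(source: Union[Trajectory, EnsembleSummary],
            assays: Optional[tuple[AssayConfig, AssayConfig]] = None,
            replicate: int = 0) -> pd.DataFrame:
    """Emit the nine series as tidy time-series data (copies/cell).

    Columns: ``experiment, species, time_s, replicate, value``.
    """
    if assays is None:
        assays = default_assays(source.network.geometry)
    rows = []
    times = source.sample_times
    for assay in assays:
        for sp, vals in signals(source, assay).items():
            for t, v in zip(times, vals):
                rows.append((assay.experiment, sp, float(t), replicate,
                             float(v)))
    return pd.DataFrame(rows, columns=["experiment", "species", "time_s",
                                       "replicate", "value"])
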