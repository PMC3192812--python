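"""Lattice description of the reporter gene.

The gene is divided into equal sections of DNA, each roughly one Pol II
footprint (~30 nt), and each section can hold at most one polymerase.
Transcription is a sequence of section-to-section hops; from the branchsite
section onwards a polymerase may switch to the co-transcriptional splicing
track.
"""

from __future__ import annotations

import math
from dataclasses import dataclass


class ValidationError(ValueError):
    """Raised when a configuration violates a model invariant."""


@dataclass(frozen=True)
class GeneGeometry:
    """Sectioned lattice of the reporter gene.

    Parameters
    ----------
    length_nt:
        Gene length in nucleotides.
    section_nt:
        Nucleotides per DNA section (one Pol II footprint).
    n_sections:
        Number of sections; must equal ``ceil(length_nt / section_nt)``.
    branch_section:
        1-based index of the first section at which the transition to the
        co-transcriptional splicing track is possible (the branchsite).
    n_transition_sections:
        Number of sections where the transition choice exists; the window
        ``branch_section .. n_sections`` must contain exactly this many.
    primer_section_expt1, primer_section_expt2:
        1-based section indices of the cDNA primers gating nascent-transcript
        detection in the two assay experiments.
    """

    length_nt: int = 1240
    section_nt: int = 31
    n_sections: int = 40
    branch_section: int = 16
    n_transition_sections: int = 25
    primer_section_expt1: int = 35
    primer_section_expt2: int = 40

    def __post_init__(self) -> None:
        if self.n_sections != math.ceil(self.length_nt / self.section_nt):
            raise ValidationError(
                f"n_sections={self.n_sections} must equal "
                f"ceil(length_nt/section_nt)="
                f"{math.ceil(self.length_nt / self.section_nt)}"
            )
        if self.branch_section <= 1:
            raise ValidationError("branch_section must be > 1")
        window = self.n_sections - self.branch_section + 1
        if window != self.n_transition_sections:
            raise ValidationError(
                f"transition window {self.branch_section}..{self.n_sections} "
                f"has {window} sections, expected n_transition_sections="
                f"{self.n_transition_sections}"
            )
        for name in ("primer_section_expt1", "primer_section_expt2"):
            v = getattr(self, name)
            if not 1 <= v <= self.n_sections:
                raise ValidationError(f"{name}={v} outside 1..{self.n_sections}")
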