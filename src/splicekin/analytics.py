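"""Closed-form kinetic quantities.

* ``p_post`` — probability that a lone polymerase exits the gene without
  switching to the co-transcriptional splicing track, given the ratio
  constant eta and the number of choice points: at each transition-capable
  section, elongation (rate k_elong) competes with the transition
  (rate k_elong / eta), so the per-section odds of not switching are
  eta : 1 and the elongation rate cancels.
* ``half_life`` — ln(2)/k for a first-order reaction.
* ``erlang_half_time`` — median completion time of an m-stage chain of
  identical-rate exponential steps (the multistep processes), generalising
  the single-step half-life. The waiting time is Erlang (gamma with integer
  shape), so the median is computed from the inverse regularised incomplete
  gamma function.
"""

from __future__ import annotations

import math

from scipy.special import gammaincinv

from .geometry import ValidationError


def p_post(eta: float, n_choices: int = 25) -> float:
    """Probability of exiting on the post-transcriptional pathway.

    ``(eta / (eta + 1)) ** n_choices`` for a single polymerase facing
    ``n_choices`` independent elongate-vs-switch competitions.
    """
    if eta <= 0:
        raise ValidationError("eta must be > 0")
    if n_choices < 0:
        raise ValidationError("n_choices must be >= 0")
    return (eta / (eta + 1.0)) ** n_choices


def half_life(k: float) -> float:
    """Half-life ln(2)/k of a first-order reaction, in seconds."""
    if k <= 0:
        raise ValidationError("k must be > 0")
    return math.log(2.0) / k


def erlang_half_time(m: int, r: float) -> float:
    """Median of an Erlang(m, r) waiting time, in seconds.

    Scales as 1/r; ``erlang_half_time(1, k) == half_life(k)`` exactly.
    """
    if m < 1:
        raise ValidationError("m must be >= 1")
    if r <= 0:
        raise ValidationError("r must be > 0")
    return float(gammaincinv(m, 0.5)) / r
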