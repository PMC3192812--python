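"""AIC model scoring, Akaike weights and cross-pathway comparison.

Assuming normally distributed residuals, a model's score is
``AIC = n ln(RSS / n) + 2 k`` where k counts the parameters optimised for
that model. Weights are relative likelihoods ``exp(-Delta_i / 2)``
normalised over the compared models, where ``Delta_i`` is each model's AIC
minus the minimum. The per-series AIC matrix, with each column shifted to a
minimum of 0, supports heat-map style views of where each pathway fails.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .geometry import ValidationError
from .pathway import PATHWAY_TABLE


def aic(rss: float, n: int, k: int) -> float:
    """Akaike information criterion from residuals: n ln(rss/n) + 2k."""
    if rss <= 0:
        raise ValidationError("rss must be > 0 (perfect fit is degenerate)")
    if n < 1:
        raise ValidationError("n must be >= 1")
    if k < 0:
        raise ValidationError("k must be >= 0")
    return n * math.log(rss / n) + 2 * k


def akaike_weights(aics) -> np.ndarray:
    """Akaike weights w_i = exp(-Delta_i/2) / sum_j exp(-Delta_j/2)."""
    a = np.asarray(aics, dtype=float)
    if a.size == 0:
        raise ValidationError("empty AIC list")
    if not np.all(np.isfinite(a)):
        raise ValidationError("AIC values must be finite")
    delta = a - a.min()
    rel = np.exp(-delta / 2.0)
    return rel / rel.sum()


@dataclass
class ComparisonTable:
    """Cross-pathway AIC comparison."""

    model_ids: list
    total_aic: np.ndarray
    delta_vs_reference: np.ndarray  # total AIC minus the reference model's
    delta_vs_min: np.ndarray
    weights: np.ndarray
    series_keys: list  # (experiment, species)
    per_series_aic: np.ndarray  # model x series
    per_series_normalized: np.ndarray  # each column shifted to min 0

    def to_frame(self) -> pd.DataFrame:
        """Summary table mirroring the pathway-comparison layout."""
        rows = []
        for i, mid in enumerate(self.model_ids):
            co, po, el = PATHWAY_TABLE.get(mid, ("?", "?", "?"))
            rows.append({
                "model": mid,
                "Co": co[0].upper(), "Po": po[0].upper(), "El": el[0].upper(),
                "total_aic": self.delta_vs_reference[i],
                "weight": self.weights[i],
            })
        return pd.DataFrame(rows)


def compare(fits, reference: str = "I") -> ComparisonTable:
    """Build the comparison table from fitted models.

    Each fit must expose ``model_id``, ``k_params`` and ``per_series_rss``
    (mapping (experiment, species) -> (rss, n)), all evaluated against the
    same data. Total AIC pools the residuals over all series.
    """
    if not fits:
        raise ValidationError("no fits to compare")
    keys = sorted(fits[0].per_series_rss.keys())
    for f in fits[1:]:
        if sorted(f.per_series_rss.keys()) != keys:
            raise ValidationError(
                f"fit {f.model_id!r}: data keys differ from {fits[0].model_id!r}")

    model_ids = [f.model_id for f in fits]
    totals = []
    per_series = np.zeros((len(fits), len(keys)))
    for i, f in enumerate(fits):
        rss_tot = sum(r for r, _ in f.per_series_rss.values())
        n_tot = sum(n for _, n in f.per_series_rss.values())
        totals.append(aic(rss_tot, n_tot, f.k_params))
        for j, key in enumerate(keys):
            r, n = f.per_series_rss[key]
            per_series[i, j] = aic(r, n, f.k_params)
    totals = np.asarray(totals)
    if reference in model_ids:
        ref = totals[model_ids.index(reference)]
    else:
        ref = totals.min()
    return ComparisonTable(
        model_ids=model_ids,
        total_aic=totals,
        delta_vs_reference=totals - ref,
        delta_vs_min=totals - totals.min(),
        weights=akaike_weights(totals),
        series_keys=keys,
        per_series_aic=per_series,
        per_series_normalized=per_series - per_series.min(axis=0,
                                                          keepdims=True),
    )
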