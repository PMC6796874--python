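"""Trimmed-total-intensity normalization of two condition profiles.

High-abundance outliers (intensity above Q3 + L * (Q3 - Q1), L = 1.5 by
default) are excluded from the total intensity of *both* profiles, and each
profile is divided by its normalization factor = trimmed total / mean
trimmed total of the pair. Outlier proteins are only excluded from the
totals; they are still normalized and tested downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io_tables import ConditionPair


@dataclass
class NormalizationSummary:
    """Bookkeeping of one normalization: quartiles, outliers, factors.

    The two factors average to 1 by construction, so the trimmed totals of
    the normalized profiles are equal.
    """

    L: float
    q1: dict = field(default_factory=dict)
    q3: dict = field(default_factory=dict)
    outlier_ids: dict = field(default_factory=dict)
    trimmed_total: dict = field(default_factory=dict)
    factor: dict = field(default_factory=dict)


def detect_outliers(intensities, L: float = 1.5) -> np.ndarray:
    """Indices of values strictly greater than Q3 + L * (Q3 - Q1).

    Q1/Q3 are the 25th/75th percentiles under the linear-interpolation
    convention (numpy default). With zero spread nothing is flagged.
    """
    values = np.asarray(intensities, dtype=float)
    if values.size == 0:
        raise ValueError("cannot detect outliers in an empty collection")
    q1, q3 = np.percentile(values, [25.0, 75.0])
    threshold = q3 + L * (q3 - q1)
    return np.flatnonzero(values > threshold)


def normalize_pair(
    pair: ConditionPair, L: float = 1.5
) -> tuple[ConditionPair, NormalizationSummary]:
    """Normalize both condition profiles by their trimmed-total factors.

    A protein flagged as an outlier in *either* profile is excluded from
    both trimmed totals. Every intensity (outliers included) is divided by
    its profile's factor.
    """
    if len(pair) == 0:
        raise ValueError("cannot normalize an empty condition pair")
    summary = NormalizationSummary(L=L)
    out_union = np.zeros(len(pair), dtype=bool)
    for label, values in ((pair.label_a, pair.a), (pair.label_b, pair.b)):
        q1, q3 = np.percentile(values, [25.0, 75.0])
        idx = detect_outliers(values, L)
        summary.q1[label] = float(q1)
        summary.q3[label] = float(q3)
        summary.outlier_ids[label] = list(pair.ids[idx])
        out_union[idx] = True

    kept = ~out_union
    totals = {}
    for label, values in ((pair.label_a, pair.a), (pair.label_b, pair.b)):
        total = float(values[kept].sum())
        if total <= 0:
            raise ValueError(
                f"trimmed total of profile {label!r} is zero; every protein "
                "was flagged as an outlier"
            )
        totals[label] = total
        summary.trimmed_total[label] = total

    mean_total = (totals[pair.label_a] + totals[pair.label_b]) / 2.0
    factor_a = totals[pair.label_a] / mean_total
    factor_b = totals[pair.label_b] / mean_total
    summary.factor[pair.label_a] = factor_a
    summary.factor[pair.label_b] = factor_b

    normalized = ConditionPair(
        ids=pair.ids.copy(),
        a=pair.a / factor_a,
        b=pair.b / factor_b,
        label_a=pair.label_a,
        label_b=pair.label_b,
        n_dropped=pair.n_dropped,
    )
    return normalized, summary
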