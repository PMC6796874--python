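"""Per-protein significance from the fitted error model.

Each protein's null variance sigma_i^2 is the global variance function
evaluated at its own mean log2 intensity A_i. The two-tailed P-value is
the probability that N(0, sigma_i^2) exceeds |M_i|, and the Z-statistic is
M_i / sigma_i, putting changes on a common scale across intensity levels
and runs. The stringent mode adds sigma_mu^2 (the variance of the window
intercepts) to every protein's null variance, absorbing residual local
normalization bias; stringent P-values are never smaller than default
ones.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .error_model import VarianceModel, WindowConfig, build_error_model, compute_ma
from .io_tables import COMPARISON_COLUMNS, ConditionPair
from .normalization import NormalizationSummary, normalize_pair

#: Smallest P-value ever reported (keeps -log10 transforms finite).
P_FLOOR = np.finfo(float).tiny


def _check_sigma2(sigma2) -> np.ndarray:
    sigma2 = np.asarray(sigma2, dtype=float)
    if np.any(~(sigma2 > 0)):
        raise ValueError("sigma2 must be strictly positive")
    return sigma2


def protein_pvalue(m, sigma2) -> np.ndarray:
    """Two-tailed P-value of a log2 ratio under N(0, sigma2).

    P = 2 * (1 - Phi(|M| / sigma)); M = 0 gives P = 1. Values are floored
    at the smallest positive float instead of underflowing to 0.
    """
    sigma2 = _check_sigma2(sigma2)
    m = np.asarray(m, dtype=float)
    p = 2.0 * stats.norm.sf(np.abs(m) / np.sqrt(sigma2))
    return np.maximum(p, P_FLOOR)


def z_statistic(m, sigma2) -> np.ndarray:
    """Z = M / sigma; the sign of Z is the direction of the change."""
    sigma2 = _check_sigma2(sigma2)
    return np.asarray(m, dtype=float) / np.sqrt(sigma2)


def stringent_sigma2(a_values, model: VarianceModel) -> np.ndarray:
    """Null variance with the sigma_mu^2 inflation of the stringent mode."""
    return model.variance(a_values) + model.sigma_mu_sq


def bh_adjust(p) -> np.ndarray:
    """Benjamini--Hochberg step-up adjusted P-values (capped at 1)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p <= 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("P-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


@dataclass
class ComparisonResult:
    """One run's comparison: per-protein statistics plus the fitted model.

    ``table`` columns: protein_id, A, M, sigma2, Z, P, P_adj (the fixed
    output order).
    """

    table: pd.DataFrame
    model: VarianceModel
    normalization: NormalizationSummary | None = None
    run_id: str = ""
    stringent: bool = False


def compare_pair(
    pair: ConditionPair,
    cfg: WindowConfig | None = None,
    trim_l: float = 1.5,
    stringent: bool = False,
    normalize: bool = True,
    run_id: str = "",
) -> ComparisonResult:
    """Full single-run analysis of a two-condition comparison.

    Normalizes the pair (unless ``normalize=False``), computes MA points,
    fits the sliding-window error model, and assigns each protein its
    sigma2, Z, two-tailed P and BH-adjusted P. Rows come back in the
    input protein order.
    """
    cfg = cfg or WindowConfig()
    summary = None
    if normalize:
        pair, summary = normalize_pair(pair, L=trim_l)
    points = compute_ma(pair)
    sorted_points, model = build_error_model(points, cfg)

    a_vals = sorted_points["A"].to_numpy()
    m_vals = sorted_points["M"].to_numpy()
    sigma2 = stringent_sigma2(a_vals, model) if stringent else model.variance(a_vals)
    table = pd.DataFrame(
        {
            "protein_id": sorted_points["protein_id"],
            "A": a_vals,
            "M": m_vals,
            "sigma2": sigma2,
            "Z": z_statistic(m_vals, sigma2),
            "P": protein_pvalue(m_vals, sigma2),
        }
    )
    table["P_adj"] = bh_adjust(table["P"].to_numpy())
    # restore the caller's protein order
    table = (
        table.set_index("protein_id")
        .loc[pd.Index(pair.ids, name="protein_id")]
        .reset_index()[COMPARISON_COLUMNS]
    )
    return ComparisonResult(
        table=table,
        model=model,
        normalization=summary,
        run_id=run_id,
        stringent=stringent,
    )
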