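"""Combining per-run comparisons across biological replicates.

Each run contributes a per-protein P-value and Z-statistic. Three
integrated statistics are computed over the runs in which a protein is
detected: the best (smallest) P, the second-best P (the second-best rule
from shRNA screening: a protein must score in at least two replicates),
and the Stouffer-style average Z

    Zhat_i = sum_t Z_i^t / sqrt(k),

standard normal under the null, with its own two-tailed P. A permutation
scheme estimates the false discovery rate of thresholding the second-best
P or the average Z, and a consistency score compares detected change
directions against an external direction reference (e.g. translation
changes from ribosome profiling).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io_tables import INTEGRATION_COLUMNS
from .significance import bh_adjust

logger = logging.getLogger(__name__)

MIN_PERMUTATIONS = 10


@dataclass
class IntegrationResult:
    """Combined statistics across runs, one row per protein.

    ``table`` columns: protein_id, k, best_P, second_best_P, avg_Z,
    avg_Z_P, avg_Z_P_adj, fdr_second_best, fdr_avg_z. Proteins detected
    in a single run keep best_P and avg_Z but have no second-best P or
    permutation FDR (NaN, flagged by k == 1).
    """

    table: pd.DataFrame
    n_runs: int = 0
    fdr_curves: dict = field(default_factory=dict)


def _run_table(result) -> pd.DataFrame:
    table = getattr(result, "table", result)
    required = {"protein_id", "Z", "P"}
    if not required.issubset(table.columns):
        raise ValueError("each run needs protein_id, Z and P columns")
    return table


def rank_statistics(per_run_results: Sequence) -> IntegrationResult:
    """Best P, second-best P and average Z across runs.

    ``k`` counts the comparisons in which a protein is detected; the
    average Z is summed over exactly those runs and divided by sqrt(k).
    """
    if len(per_run_results) == 0:
        raise ValueError("at least one run is required")
    tables = [_run_table(r) for r in per_run_results]

    p_wide = pd.concat(
        [t.set_index("protein_id")["P"].rename(i) for i, t in enumerate(tables)],
        axis=1,
    )
    z_wide = pd.concat(
        [t.set_index("protein_id")["Z"].rename(i) for i, t in enumerate(tables)],
        axis=1,
    )
    k = p_wide.notna().sum(axis=1).to_numpy()
    p_values = p_wide.to_numpy(dtype=float)
    p_sorted = np.sort(np.where(np.isnan(p_values), np.inf, p_values), axis=1)
    best = p_sorted[:, 0]
    second = np.where(k >= 2, p_sorted[:, np.minimum(1, p_sorted.shape[1] - 1)], np.nan)
    avg_z = np.nansum(z_wide.to_numpy(dtype=float), axis=1) / np.sqrt(k)
    avg_z_p = avg_z_pvalue(avg_z)

    table = pd.DataFrame(
        {
            "protein_id": p_wide.index.to_numpy(dtype=object),
            "k": k,
            "best_P": best,
            "second_best_P": second,
            "avg_Z": avg_z,
            "avg_Z_P": avg_z_p,
            "avg_Z_P_adj": bh_adjust(avg_z_p),
            "fdr_second_best": np.nan,
            "fdr_avg_z": np.nan,
        }
    ).sort_values("protein_id", kind="stable", ignore_index=True)
    return IntegrationResult(table=table[INTEGRATION_COLUMNS], n_runs=len(tables))


def avg_z_pvalue(z_hat) -> np.ndarray:
    """Two-tailed standard-normal P for the average Z-statistic."""
    z_hat = np.asarray(z_hat, dtype=float)
    return np.maximum(2.0 * stats.norm.sf(np.abs(z_hat)), np.finfo(float).tiny)


def _second_best_null_p(second_best_p: np.ndarray, k: np.ndarray) -> np.ndarray:
    """P(2nd smallest of k uniforms <= s): the null P of a second-best P."""
    return stats.binom.sf(1, k, second_best_p)


@dataclass
class PermutationFDR:
    """Per-protein FDR estimates for one integrated statistic."""

    statistic: str
    per_protein: pd.Series
    curve: pd.DataFrame
    n_permutations: int
    n_excluded: int


def permutation_fdr(
    per_run_results: Sequence,
    statistic: str = "avg_z",
    n_permutations: int = 1000,
    seed: int | None = None,
    exclusion_alpha: float = 0.05,
) -> PermutationFDR:
    """Permutation estimate of the FDR of thresholding an integrated statistic.

    Null copies of the integrated statistic are built by, independently in
    each run, randomly reassigning the observed Z values across the
    proteins detected in that run and flipping each sign with probability
    1/2 (the null M-distribution is symmetric about 0, and the
    reassignment breaks the cross-run consistency that the integrated
    statistics reward). Proteins whose integrated statistic is
    BH-significant at ``exclusion_alpha`` are excluded from the null pool
    so that genuine signals do not contaminate it; under a global null
    almost nothing is excluded and the scheme reduces to a plain
    permutation. The FDR at threshold t is the mean permutation count
    exceeding t divided by the observed count, clipped to [0, 1] and made
    monotone in significance.
    """
    if statistic not in ("avg_z", "second_best_p"):
        raise ValueError("statistic must be 'avg_z' or 'second_best_p'")
    if len(per_run_results) < 2:
        raise ValueError("permutation FDR requires at least 2 runs")
    if n_permutations < MIN_PERMUTATIONS:
        raise ValueError(f"need at least {MIN_PERMUTATIONS} permutations")
    if seed is None:
        raise ValueError("a seed is required for the permutation FDR")
    rng = np.random.default_rng(seed)

    tables = [_run_table(r) for r in per_run_results]
    z_wide = pd.concat(
        [t.set_index("protein_id")["Z"].rename(i) for i, t in enumerate(tables)],
        axis=1,
    ).sort_index()
    z_matrix = z_wide.to_numpy(dtype=float)
    detected = ~np.isnan(z_matrix)
    k = detected.sum(axis=1)
    multi = k >= 2
    ids = z_wide.index.to_numpy(dtype=object)[multi]
    z_matrix = z_matrix[multi]
    detected = detected[multi]
    k = k[multi]
    m, n_runs = z_matrix.shape
    if m == 0:
        raise ValueError("no protein is detected in at least 2 runs")

    def integrated_score(z) -> np.ndarray:
        """Score increasing with significance."""
        if statistic == "avg_z":
            return np.abs(np.nansum(z, axis=1)) / np.sqrt(k)
        p = np.where(np.isnan(z), np.inf, protein_pvalue_matrix(z))
        return -np.sort(p, axis=1)[:, 1]

    def protein_pvalue_matrix(z):
        return 2.0 * stats.norm.sf(np.abs(z))

    s_obs = integrated_score(z_matrix)

    # exclusion of confident signals from the null pool
    if statistic == "avg_z":
        null_p = avg_z_pvalue(np.nansum(z_matrix, axis=1) / np.sqrt(k))
    else:
        null_p = _second_best_null_p(-s_obs, k)
        null_p = np.maximum(null_p, np.finfo(float).tiny)
    excluded = bh_adjust(null_p) < exclusion_alpha
    n_excluded = int(excluded.sum())
    if n_excluded:
        logger.info(
            "%d protein(s) excluded from the permutation null pool", n_excluded
        )
    pool_rows = ~excluded
    if not pool_rows.any():
        raise ValueError("every protein was excluded from the permutation pool")

    z_pool = z_matrix[pool_rows]
    det_pool = detected[pool_rows]
    k_pool = k[pool_rows]
    m_pool = z_pool.shape[0]

    null_scores = np.empty((n_permutations, m_pool))
    z_null = np.full_like(z_pool, np.nan)
    for b in range(n_permutations):
        z_null[:] = np.nan
        for t in range(n_runs):
            slots = np.flatnonzero(det_pool[:, t])
            values = z_pool[slots, t]
            signs = rng.integers(0, 2, size=slots.size) * 2 - 1
            z_null[slots[rng.permutation(slots.size)], t] = values * signs
        if statistic == "avg_z":
            null_scores[b] = np.abs(np.nansum(z_null, axis=1)) / np.sqrt(k_pool)
        else:
            p = np.where(np.isnan(z_null), np.inf, protein_pvalue_matrix(z_null))
            null_scores[b] = -np.sort(p, axis=1)[:, 1]

    null_flat = np.sort(null_scores.ravel())
    obs_sorted = np.sort(s_obs)
    # counts at each observed threshold (>= threshold)
    null_count = (null_flat.size - np.searchsorted(null_flat, s_obs, side="left")) / (
        float(n_permutations)
    )
    obs_count = len(s_obs) - np.searchsorted(obs_sorted, s_obs, side="left")
    raw = np.clip(null_count / obs_count, 0.0, 1.0)

    # monotone in significance: FDR at a stricter threshold never exceeds
    # the FDR at a looser one (suffix minimum over significance order)
    order = np.argsort(-s_obs, kind="stable")
    mono = np.minimum.accumulate(raw[order][::-1])[::-1]
    fdr = np.empty_like(raw)
    fdr[order] = mono

    per_protein = pd.Series(fdr, index=pd.Index(ids, name="protein_id"))
    curve = pd.DataFrame(
        {
            "score": s_obs[order],
            "observed_count": obs_count[order],
            "mean_null_count": null_count[order],
            "fdr": fdr[order],
        }
    )
    return PermutationFDR(
        statistic=statistic,
        per_protein=per_protein,
        curve=curve,
        n_permutations=n_permutations,
        n_excluded=n_excluded,
    )


def integrate(
    per_run_results: Sequence,
    n_permutations: int = 1000,
    seed: int | None = None,
    with_fdr: bool = True,
    exclusion_alpha: float = 0.05,
) -> IntegrationResult:
    """Rank statistics plus (optionally) permutation FDR columns."""
    result = rank_statistics(per_run_results)
    if with_fdr and len(per_run_results) >= 2:
        for statistic, column in (
            ("second_best_p", "fdr_second_best"),
            ("avg_z", "fdr_avg_z"),
        ):
            fdr = permutation_fdr(
                per_run_results,
                statistic=statistic,
                n_permutations=n_permutations,
                seed=seed,
                exclusion_alpha=exclusion_alpha,
            )
            result.table[column] = (
                result.table["protein_id"].map(fdr.per_protein).to_numpy()
            )
            result.fdr_curves[statistic] = fdr
    return result


def filter_reference_directions(
    log2_ratios: Mapping[str, float], threshold: float = 0.2
) -> dict[str, int]:
    """Direction reference from external log2 ratios.

    Entries with |ratio| <= threshold are dropped; the rest map to the
    sign (+1/-1) of their ratio.
    """
    if not threshold > 0:
        raise ValueError("threshold must be positive")
    return {
        key: (1 if ratio > 0 else -1)
        for key, ratio in log2_ratios.items()
        if abs(ratio) > threshold
    }


def consistency_score(
    dep_directions: Mapping[str, int], reference_directions: Mapping[str, int]
) -> float:
    """Fraction of detected changes whose direction matches the reference.

    Identifiers absent from the reference are excluded from both the
    numerator and the denominator; an empty overlap is an error.
    """
    for name, mapping in (
        ("dep", dep_directions),
        ("reference", reference_directions),
    ):
        bad = [k for k, v in mapping.items() if v not in (1, -1)]
        if bad:
            raise ValueError(f"{name} directions must be +1/-1; offending: {bad[:5]}")
    overlap = [k for k in dep_directions if k in reference_directions]
    if not overlap:
        raise ValueError("no overlap between detected proteins and the reference")
    consistent = sum(
        1 for k in overlap if dep_directions[k] == reference_directions[k]
    )
    return consistent / len(overlap)
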