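"""Intensity-dependent error model built by sliding-window QQ regression.

The comparison of two profiles is summarized as an MA plot: per protein a
log2 ratio M against a mean log2 intensity A. Under the null, M is assumed
to follow N(0, sigma^2) with sigma^2 a smooth function of A. The plot is
scanned by a sliding window of ``size`` proteins (step ``step``) along A;
within each window the ordered log2 ratios are regressed against standard
normal quantiles over the middle ``middle_fraction`` of ranks (the part of
the mixture dominated by unchanged proteins), giving a local scale
estimate sigma per window. A two-parameter exponential variance function

    sigma^2 = exp(theta1 + theta2 * A)

is then fitted across windows by nonlinear least squares and becomes the
global null variance used for every protein's test.

Quantile levels use the Michael--Schucany product formula for a subset
Omega of the ranks 1..N,

    p_i = (N - a + 1)/(N - 2a + 1) * prod_{j in Omega, j >= i} (j - a)/(j - a + 1),

which for the complete sample telescopes to (i - a)/(N - 2a + 1). The
window regression pairs each selected middle rank with its complete-window
level: this keeps the design symmetric and makes the fitted slope a
consistent estimate of sigma (the subset form of the product, intended for
right censoring, would skew the levels of a doubly trimmed middle).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from math import ceil

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .io_tables import ConditionPair

logger = logging.getLogger(__name__)

#: Smallest window the QQ regression accepts.
MIN_WINDOW = 20
#: Smallest number of middle ranks entering one regression.
MIN_SELECTED = 10
#: Abort when more than this fraction of windows is degenerate.
MAX_DEGENERATE_FRACTION = 0.2


@dataclass(frozen=True)
class WindowConfig:
    """Sliding-window and QQ-regression settings.

    size:
        Window size in proteins (default 400).
    step:
        Step size in proteins (default 100).
    middle_fraction:
        Fraction W of ordered ratios, symmetric about the median, used in
        each regression (default 0.5).
    a:
        Plotting-position constant in the Michael--Schucany formula
        (default 0.3175).
    """

    size: int = 400
    step: int = 100
    middle_fraction: float = 0.5
    a: float = 0.3175

    def __post_init__(self) -> None:
        if self.size < MIN_WINDOW:
            raise ValueError(f"window size must be >= {MIN_WINDOW}")
        if not 0 < self.step <= self.size:
            raise ValueError("step must satisfy 0 < step <= size")
        if not 0 < self.middle_fraction <= 1:
            raise ValueError("middle_fraction must be in (0, 1]")
        if not 0 <= self.a < 1:
            raise ValueError("plotting-position constant a must be in [0, 1)")
        if self.n_selected(self.size) < MIN_SELECTED:
            raise ValueError(
                f"middle_fraction selects fewer than {MIN_SELECTED} points"
            )

    def n_trim(self, n: int) -> int:
        """Number of ranks trimmed from each side of a window of n points."""
        return ceil(n * (1.0 - self.middle_fraction) / 2.0)

    def n_selected(self, n: int) -> int:
        return n - 2 * self.n_trim(n)


@dataclass
class WindowEstimate:
    """One window's local scale fit: M = mu + sigma * q over middle ranks.

    ``sigma**2`` is the window's variance estimate; ``mean_a`` is the mean
    A over the proteins selected for the regression. Degenerate windows
    (non-positive slope or zero spread) are flagged and excluded from the
    global fit.
    """

    index: int
    start: int
    stop: int
    mu: float
    sigma: float
    r_squared: float
    mean_a: float
    n_selected: int
    degenerate: bool = False
    member_ids: np.ndarray | None = None


@dataclass
class VarianceModel:
    """Global exponential variance function sigma^2 = exp(theta1 + theta2*A).

    ``sigma_mu_sq`` is the variance of the window intercepts mu, used only
    by the stringent testing mode to absorb residual local normalization
    bias. ``a_range`` is the span of window mean-A values the fit saw;
    outside it the exponential is extrapolated directly (it is globally
    defined) with a logged notice.
    """

    theta1: float
    theta2: float
    fit_r_squared: float
    sigma_mu_sq: float
    window_estimates: list[WindowEstimate] = field(default_factory=list)
    a_range: tuple[float, float] = (-np.inf, np.inf)

    def variance(self, a_values) -> np.ndarray:
        a_values = np.asarray(a_values, dtype=float)
        lo, hi = self.a_range
        n_out = int(np.sum((a_values < lo) | (a_values > hi)))
        if n_out:
            logger.info(
                "variance function extrapolated beyond fitted mean-A range "
                "[%.3g, %.3g] for %d protein(s)",
                lo,
                hi,
                n_out,
            )
        return np.exp(self.theta1 + self.theta2 * a_values)


def compute_ma(pair: ConditionPair) -> pd.DataFrame:
    """Per-protein (A, M): mean log2 intensity and log2 ratio.

    A = (log2 S1 + log2 S2)/2 and M = log2(S1/S2), with S1 the first
    (``label_a``) and S2 the second condition.
    """
    bad = ~((pair.a > 0) & (pair.b > 0))
    if bad.any():
        raise ValueError(
            "non-positive intensity for protein(s): "
            + ", ".join(map(str, pair.ids[bad][:5]))
        )
    log_a = np.log2(pair.a)
    log_b = np.log2(pair.b)
    return pd.DataFrame(
        {
            "protein_id": pair.ids,
            "A": (log_a + log_b) / 2.0,
            "M": log_a - log_b,
        }
    )


def sort_by_a(points: pd.DataFrame) -> pd.DataFrame:
    """Sort MA points ascending by A (ties broken by protein_id)."""
    order = np.lexsort((points["protein_id"].to_numpy(), points["A"].to_numpy()))
    return points.iloc[order].reset_index(drop=True)


def make_windows(n_points: int, cfg: WindowConfig) -> list[tuple[int, int]]:
    """Index ranges [k*step, k*step+size) over the A-sorted points.

    The final window is anchored to the right edge so every protein is
    covered by at least one window.
    """
    if n_points < cfg.size:
        raise ValueError(
            f"{n_points} proteins is fewer than the window size {cfg.size}; "
            "use a smaller window"
        )
    starts = list(range(0, n_points - cfg.size + 1, cfg.step))
    if starts[-1] != n_points - cfg.size:
        starts.append(n_points - cfg.size)
    return [(s, s + cfg.size) for s in starts]


def plotting_positions(
    n: int, omega, a: float = 0.3175
) -> tuple[np.ndarray, np.ndarray]:
    """Michael--Schucany plotting positions and normal quantiles.

    ``omega`` is an increasing subset of the ranks 1..n. Returns one
    (p, q) pair per member of omega, with q = Phi^-1(p). For the complete
    sample the product telescopes to p_i = (i - a)/(n - 2a + 1).
    """
    omega = np.asarray(omega, dtype=float)
    if omega.size == 0:
        raise ValueError("omega must be non-empty")
    if np.any(np.diff(omega) <= 0):
        raise ValueError("omega must be strictly increasing")
    if omega[0] < 1 or omega[-1] > n:
        raise ValueError("omega must be a subset of 1..n")
    if not 0 <= a < 1:
        raise ValueError("a must be in [0, 1)")
    terms = (omega - a) / (omega - a + 1.0)
    suffix = np.cumprod(terms[::-1])[::-1]
    p = (n - a + 1.0) / (n - 2.0 * a + 1.0) * suffix
    return p, stats.norm.ppf(p)


def qq_regression(
    m_values,
    cfg: WindowConfig,
    a_values=None,
    ids=None,
    window_index: int = 0,
    start: int = 0,
) -> WindowEstimate:
    """Estimate one window's (mu, sigma) by middle-W QQ regression.

    The window's M values are ordered (ties broken by protein id for
    reproducibility), the middle ``middle_fraction`` of ranks is selected
    symmetrically, and the selected ordered ratios are regressed by OLS on
    the complete-window normal quantiles at those ranks. The slope is the
    scale estimate; a non-positive slope or zero spread flags the window
    as degenerate.
    """
    m_values = np.asarray(m_values, dtype=float)
    n = m_values.size
    if n < MIN_WINDOW:
        raise ValueError(f"window of {n} points is below the minimum {MIN_WINDOW}")
    n_trim = cfg.n_trim(n)
    n_sel = n - 2 * n_trim
    if n_sel < MIN_SELECTED:
        raise ValueError(
            f"middle fraction selects {n_sel} points; minimum is {MIN_SELECTED}"
        )
    if ids is not None:
        order = np.lexsort((np.asarray(ids, dtype=object), m_values))
    else:
        order = np.argsort(m_values, kind="stable")
    m_sorted = m_values[order]
    ranks = np.arange(n_trim + 1, n - n_trim + 1)  # 1-based middle ranks
    _, q = plotting_positions(n, np.arange(1, n + 1), cfg.a)
    q_sel = q[ranks - 1]
    m_sel = m_sorted[ranks - 1]

    mean_a = float("nan")
    if a_values is not None:
        a_sorted = np.asarray(a_values, dtype=float)[order]
        mean_a = float(a_sorted[ranks - 1].mean())

    member_ids = None
    if ids is not None:
        member_ids = np.asarray(ids, dtype=object)[order][ranks - 1]

    if np.ptp(m_sel) == 0.0:
        return WindowEstimate(
            index=window_index,
            start=start,
            stop=start + n,
            mu=float(m_sel[0]),
            sigma=0.0,
            r_squared=0.0,
            mean_a=mean_a,
            n_selected=n_sel,
            degenerate=True,
            member_ids=member_ids,
        )

    fit = stats.linregress(q_sel, m_sel)
    sigma = float(fit.slope)
    degenerate = sigma <= 0.0
    if degenerate:
        logger.warning(
            "window %d: non-positive QQ slope %.3g; flagged degenerate",
            window_index,
            sigma,
        )
    return WindowEstimate(
        index=window_index,
        start=start,
        stop=start + n,
        mu=float(fit.intercept),
        sigma=sigma,
        r_squared=float(fit.rvalue**2),
        mean_a=mean_a,
        n_selected=n_sel,
        degenerate=degenerate,
        member_ids=member_ids,
    )


def fit_variance_function(estimates: list[WindowEstimate]) -> VarianceModel:
    """Fit sigma^2 = exp(theta1 + theta2 * mean_A) across windows.

    Window variance estimates carry multiplicative noise (their relative
    error is roughly constant across the 2-3 orders of magnitude sigma^2
    spans), so the nonlinear least squares minimizes *relative* residuals
    (y - psi)/psi -- equivalent to inverse-variance weighting -- and is
    initialized by the OLS of log(sigma^2) on mean_A, which nearly solves
    the problem already. An unweighted fit would be dominated by the few
    highest-variance (lowest-A) windows and give badly miscalibrated
    variances at high intensity. Degenerate windows are excluded; more
    than 20% degenerate aborts the run. ``sigma_mu_sq`` is the sample
    variance of mu across all windows.
    """
    if not estimates:
        raise ValueError("no window estimates to fit")
    usable = [e for e in estimates if not e.degenerate and e.sigma > 0]
    frac_degenerate = 1.0 - len(usable) / len(estimates)
    if frac_degenerate > MAX_DEGENERATE_FRACTION:
        raise ValueError(
            f"{frac_degenerate:.0%} of windows are degenerate; the variance "
            "fit would be driven by pathological windows"
        )
    if len(usable) < 2:
        raise ValueError("need at least 2 non-degenerate windows to fit")
    if frac_degenerate > 0:
        logger.warning(
            "%d degenerate window(s) excluded from the variance fit",
            len(estimates) - len(usable),
        )

    x = np.array([e.mean_a for e in usable])
    y = np.array([e.sigma**2 for e in usable])
    if np.any(~np.isfinite(x)):
        raise ValueError("window estimates lack mean_a values")

    # log-linear initializer
    slope, intercept = np.polyfit(x, np.log(y), 1)
    theta0 = np.array([intercept, slope])

    def residuals(theta):
        psi = np.exp(theta[0] + theta[1] * x)
        return (y - psi) / psi

    result = optimize.least_squares(residuals, theta0, method="lm", ftol=1e-10)
    if not result.success:
        raise RuntimeError(
            "variance-function fit did not converge "
            f"(initializer {theta0.tolist()}, residual {result.cost:.3g})"
        )
    theta1, theta2 = result.x
    fitted = np.exp(theta1 + theta2 * x)
    ss_res = float(np.sum((y - fitted) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r_squared = 1.0 if ss_tot == 0.0 else 1.0 - ss_res / ss_tot

    mus = np.array([e.mu for e in estimates if np.isfinite(e.mu)])
    sigma_mu_sq = float(np.var(mus, ddof=1)) if mus.size > 1 else 0.0

    return VarianceModel(
        theta1=float(theta1),
        theta2=float(theta2),
        fit_r_squared=float(r_squared),
        sigma_mu_sq=sigma_mu_sq,
        window_estimates=list(estimates),
        a_range=(float(x.min()), float(x.max())),
    )


def build_error_model(
    points: pd.DataFrame, cfg: WindowConfig | None = None
) -> tuple[pd.DataFrame, VarianceModel]:
    """Run the full sliding-window analysis on MA points.

    Returns the A-sorted points and the fitted global variance model.
    """
    cfg = cfg or WindowConfig()
    sorted_points = sort_by_a(points)
    a_arr = sorted_points["A"].to_numpy()
    m_arr = sorted_points["M"].to_numpy()
    id_arr = sorted_points["protein_id"].to_numpy(dtype=object)
    windows = make_windows(len(sorted_points), cfg)
    estimates = [
        qq_regression(
            m_arr[s:e],
            cfg,
            a_values=a_arr[s:e],
            ids=id_arr[s:e],
            window_index=i,
            start=s,
        )
        for i, (s, e) in enumerate(windows)
    ]
    model = fit_variance_function(estimates)
    return sorted_points, model


def rescaled_qq_summary(
    sorted_m,
    windows: list[tuple[int, int]],
    estimates: list[WindowEstimate],
    cfg: WindowConfig | None = None,
) -> pd.DataFrame:
    """Per-rank mean and SD of window-rescaled ordered log2 ratios.

    Each full-size, non-degenerate window's ordered M values are divided
    by that window's sigma; the mean and SD at every rank across windows
    are paired with the complete-sample normal quantiles, so the summary
    can be inspected against the line y = x (a diagnostic for the choice
    of the middle fraction W).
    """
    cfg = cfg or WindowConfig()
    sorted_m = np.asarray(sorted_m, dtype=float)
    rows = []
    for (s, e), est in zip(windows, estimates):
        if e - s != cfg.size:
            logger.warning(
                "window [%d, %d) is not full-size and is excluded from the "
                "rescaled-QQ summary",
                s,
                e,
            )
            continue
        if est.degenerate or est.sigma <= 0:
            logger.warning("degenerate window %d excluded from summary", est.index)
            continue
        rows.append(np.sort(sorted_m[s:e]) / est.sigma)
    if not rows:
        raise ValueError("no usable full-size windows for the rescaled summary")
    stacked = np.vstack(rows)
    _, q = plotting_positions(cfg.size, np.arange(1, cfg.size + 1), cfg.a)
    return pd.DataFrame(
        {
            "rank": np.arange(1, cfg.size + 1),
            "q": q,
            "mean": stacked.mean(axis=0),
            "sd": stacked.std(axis=0, ddof=1) if stacked.shape[0] > 1 else 0.0,
            "n_windows": stacked.shape[0],
        }
    )
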