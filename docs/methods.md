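# Methods

## Model and assumptions

`promap` compares two protein-level intensity profiles measured in the
same MS run. For protein *i* the mean log2 intensity is
A_i = (log2 S_i1 + log2 S_i2)/2 and the log2 ratio is
M_i = log2(S_i1/S_i2). The contribution of technical and systematic error
to M_i is modeled as N(0, sigma_i^2) with the variance an exponential
function of abundance,

    sigma^2 = Psi(theta, A) = exp(theta1 + theta2 * A),

so low-abundance proteins are allowed to be much noisier. The detected
proteins are treated as a mixture of differentially (DEP) and
non-differentially expressed proteins; all inference of Psi is restricted
to the center of the M distribution, where non-DEPs dominate. The method
assumes (i) intensities have been summarized to protein level upstream,
(ii) most proteins are unchanged (needed both by the normalization and by
the middle-W regression), and (iii) the null ratio distribution is
symmetric and approximately normal in its middle.

## Normalization

High-abundance outliers are flagged per profile as intensities strictly
above Q3 + L(Q3 - Q1) with L = 1.5 (`--trim-L`); quartiles use the linear
interpolation ("type 7") convention. A protein flagged in either profile
is excluded from the trimmed totals of both. Each profile is divided by
factor = trimmed total / mean trimmed total, which equalizes the trimmed
totals of the pair. Outlying proteins are only excluded from the totals;
they are still normalized and tested. Note the absolute output scale is
the mean trimmed total, so rescaling one input profile rescales both
normalized profiles by a common constant; every ratio M_i is invariant,
which is what the downstream model consumes.

## Sliding-window QQ regression

Proteins are sorted by A and scanned by windows of `size` N = 400
proteins with step 100; the final window is anchored to the right edge so
every protein is covered. Windows below 20 points, or whose middle
selection falls below 10 points, are rejected.

Within a window the M values are ordered (ties broken by protein id for
reproducibility) and the middle W = 50% of ranks
(ceil(N(1-W)/2)+1 ... N-ceil(N(1-W)/2)) are regressed by OLS on standard
normal quantiles q-hat = Phi^-1(p-hat), giving M = mu + sigma*q-hat; the
squared slope is the window's variance estimate and mean_A is the mean
abundance of the selected proteins.

Plotting positions use the Michael--Schucany product formula for a subset
Omega of ranks 1..N,

    p_i = (N-a+1)/(N-2a+1) * prod_{j in Omega, j >= i} (j-a)/(j-a+1),

with a = 0.3175 (`--qq-a`), the constant this position family was
designed around; for the complete sample it telescopes to
(i-a)/(N-2a+1). The window regression pairs the selected middle ranks
with their complete-window levels rather than re-deriving positions from
the trimmed subset: the product form encodes right censoring, so applying
it to a doubly trimmed middle yields strongly asymmetric levels (for the
middle half of 400 points, p in [0.34, 0.998]) under which the slope no
longer estimates sigma (numerically ~0.54 sigma) and the fit degrades
(R^2 ~ 0.93). With complete-window levels the slope is a consistent scale
estimate (Monte Carlo: 0.502 for sigma = 0.5) and the middle-rank
regressions are near-perfectly linear (R^2 ~ 0.996) under the null, which
is the behaviour the method's diagnostics are built on.

Degenerate windows (zero spread or non-positive slope) are flagged,
logged and excluded from the global fit; if more than 20% of windows are
degenerate the run aborts rather than fit a variance function to
pathological local estimates.

## Global variance function

Psi is fitted across windows by nonlinear least squares of the window
variance estimates on mean_A. Because the window estimates have
approximately constant *relative* error while sigma^2 spans two to three
orders of magnitude over the abundance range, the fit minimizes relative
residuals (y - Psi)/Psi — equivalent to inverse-variance weighting. An
unweighted variance-scale fit would be dominated by the few
lowest-abundance windows and produces badly miscalibrated Z statistics
(SDs ranging 0.94-1.14 across simulated datasets). The fit is initialized
at the OLS of log sigma^2 on mean_A, which nearly solves the problem, and
converges with ftol 1e-10 (Levenberg–Marquardt). The reported fit R^2 is
computed on the variance scale. Exactly two windows are interpolated
exactly; identical window variances give a flat function with R^2 = 1.

Each protein's null variance is Psi evaluated at its own A. Outside the
span of window mean_A values the exponential is extrapolated directly (it
is globally defined); the extrapolation is logged.

## Significance

P_i = 2(1 - Phi(|M_i|/sigma_i)), floored at the smallest positive double
so downstream -log10 transforms stay finite, and BH-adjusted within the
comparison. Z_i = M_i/sigma_i is standard normal under the null and is
the unit in which runs are integrated. The *stringent* mode
(`--stringent`) adds sigma_mu^2 — the sample variance (ddof 1) of the
window intercepts mu — to every protein's null variance, absorbing
residual local normalization bias; stringent P-values are never smaller
than default ones.

## Replicate integration

Across k runs each protein gets its best and second-best P (the latter
requires detection in at least two runs and trades sensitivity for
reproducibility), and the Stouffer combination
Z-hat = sum_t Z_i^t / sqrt(k) over the runs where it is detected, with a
two-tailed standard-normal P, BH-adjusted over the integrated protein
set. Proteins seen in a single run keep best_P and Z-hat (= that run's Z)
but no second-best P or FDR; they are flagged by k = 1, not dropped.

## Permutation FDR

The FDR of thresholding the second-best P or |Z-hat| is estimated by
permutation. Null copies are built by, independently within each run,
randomly reassigning the observed Z values across the proteins detected
in that run and flipping each sign with probability 1/2: the sign flip is
exact under the symmetric null, and the reassignment destroys the
cross-run consistency that both integrated statistics reward. (Sign flips
alone cannot serve here: they leave each |Z|, hence every per-run P and
the second-best P, unchanged.) Proteins whose integrated statistic is
already BH-significant at alpha = 0.05 — using the standard-normal P for
Z-hat and the order-statistic null P(2nd smallest of k uniforms <= s) for
the second-best P — are excluded from the permutation pool, so strong
genuine signals do not inflate the estimated null; under a global null
essentially nothing is excluded and the scheme reduces to a plain
permutation. The FDR at threshold t is mean null count / observed count,
clipped to [0, 1] and made monotone in significance by a suffix minimum
(q-value style). At the most extreme observed thresholds (observed count
of order 1) the ratio estimator is intrinsically noisy; estimates are
meaningful from a few dozen discoveries onward.

## Consistency score

Detected DEP directions (signs of change) can be compared against an
external direction reference, e.g. translation changes from ribosome
profiling. Reference entries with |log2 ratio| <= 0.2 are dropped; the
score is the fraction of overlapping proteins whose signs agree.
Magnitudes are never compared, and proteins absent from the reference are
excluded from both numerator and denominator.

## Synthetic data generator

The generator emulates the structure the model assumes: A uniform over
[10, 25] log2 units (a realistic reporter-ion dynamic range), null
M ~ N(0, exp(theta1 + theta2*A)) with default theta = (2.0, -0.4) (sigma
from ~0.37 at the faint end to ~0.018 at the bright end), an optional
spiked fraction of DEPs with a fixed log2-shift magnitude (default 1.5)
split evenly between up and down so the spikes do not bias the
normalization, and intensities back-solved as S1 = 2^(A+M/2),
S2 = 2^(A-M/2) (exactly invertible). Multi-run studies share abundances
and spike labels, draw independent noise per run, and can drop a random
per-run fraction of proteins to emulate partial detection. The
technical-replicate mode splits each condition into two channels whose
within-condition ratio follows the same variance function, so comparing
the two channels of one condition is an exact null comparison.

The generator does **not** emulate ratio compression, peptide-level
variation, intensity-dependent missingness, or heavy-tailed
contamination. Passing tests therefore demonstrate correctness and
calibration under the model's own assumptions — not robustness to every
artefact of real isobaric data.

## Test and script problem sizes

The statistical tests and `scripts/acceptance.py` use 5,000-protein
studies with three replicates, the default window settings and 1,000
permutations — large enough that window estimates, calibration fractions
and precision-recall areas are stable, while a full run of the suite
stays in the tens of seconds. Two sampling-noise facts are worth knowing
when reading test output: a single 400-point window's middle-half QQ
regression has P(R^2 < 0.99) of roughly 3%, so the minimum R^2 over ~47
overlapping windows dips below 0.99 for a substantial fraction of random
datasets; and theta1, being the log-variance extrapolated to A = 0 far
outside the observed abundance range, has a sampling SE of ~0.14 at this
study size, so its recovery is much looser than theta2's.

## Known limitations

- The exponential variance function is a parametric choice; data whose
  variance-abundance trend is not log-linear will be miscalibrated at the
  extremes (no kernel/spline smoothing is provided).
- The error model is built from the middle of the ratio distribution;
  if more than ~25% of proteins in some abundance stratum are truly
  changed in the same direction, the local scale estimate inflates.
- Permutation FDR requires at least two runs and at least ~tens of
  discoveries to be informative.
- Multi-profile (more than two conditions per run) comparison is out of
  scope, as are peptide-to-protein rollup and spectral processing.
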