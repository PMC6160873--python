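# Methods

`eegstates` characterizes how functional brain networks change over the
course of a task from multi-trial EEG.  Rather than assuming one static
network per condition, it models each trial as a sequence of *functional
states* — recurring directed-network patterns — and compares experimental
conditions through the statistics of transitions between those states.

## Pipeline

**1. Preprocessing.**  Each channel is z-scored within each trial
(sample standard deviation, n−1 denominator), then each (channel, sample)
cell is z-scored across the trials of a condition.  The first step
removes between-trial amplitude differences; the second removes the
evoked response (the cross-trial mean, i.e. the ERP) and cross-trial
variance differences, leaving only the induced, trial-varying activity
from which time-lagged dependencies are estimated.  The order is fixed:
within-trial before across-trial.  Constant series raise an error
instead of producing NaNs, because silent NaNs would corrupt the
regression stage.  Results are therefore orthogonal to ERP averaging and
to amplitude-topography (microstate) analyses.

**2. Windowed sparse-MVAR networks.**  An order-p MVAR model is fitted
to short non-overlapping windows (40 samples at 1 kHz for simulated
data; half the typical 80–100 ms functional-state lifetime, so that even
fast state changes are resolved).  Windows contain too few samples for
ordinary least squares with tens of channels, so each column of the
coefficient matrix is estimated by L1-penalized regression
(`‖y − Xα‖² + λ²Σ|αⱼ|`; note the squared-λ convention) and a few
consecutive trials are pooled per window: window w of each member trial
is demeaned per channel and lagged separately, then the lagged blocks
are stacked.  Design rows never span a trial boundary — a literal
concatenation would create p contaminated rows per boundary.

The lasso is solved by Majorization–Minimization: |α| is majorized by a
quadratic at the current iterate, so each step is a reweighted ridge
solve (weight guard 1e-8) and the objective is non-increasing.  Columns
stop when both the relative objective change and the coefficient change
fall below `tol` (default 1e-6), or when the nonzero support has been
stable for five sweeps.  A final active-set refinement then solves the
KKT stationarity system exactly on the detected support, dropping
coordinates whose sign flips and adding coordinates whose gradient
violates the KKT bound, so the returned solution matches an independent
coordinate-descent solver to machine precision.  Entries below 1e-6 are
reported as exact zeros.

λ is chosen by generalized cross-validation, `GCV = RSS/(L − df)²`, with
L the number of response rows and df the per-column count of nonzero
coefficients (the standard lasso df estimator; estimation is
column-wise, and per-window GCV sums the per-column scores).  A random
fraction of windows is scored over a 30-point log grid on [0.01, 100]
and the mean of the per-window winners is used.  The order p ∈ [1, 6] is
chosen on a second window sample by
`BIC = log σ + (log L − 1)·df/L` with σ the pooled mean squared residual
and df the mean per-column nonzero count; the modal order wins, ties to
the smaller order.

Each fitted window yields the nonnegative matrix
`W[i,j] = mean_k |a_ij(k)|` (the influence of channel j's past on
channel i's present, averaged over lags), vectorized without the
diagonal in row-major order.

**3. Functional states by correlation k-means.**  Features from both
conditions are pooled and clustered with k-means under the distance
1 − r (Pearson correlation), which compares network *patterns*
regardless of overall connection strength.  Rows are centered and scaled
to unit norm, after which 1 − r is half the squared Euclidean distance
and a cluster's cost is `n_c − ‖s_c‖` with `s_c` the member sum; batch
Lloyd sweeps (restarts vectorized into single large matrix products)
run to convergence and are followed by exact single-point refinement
moves.  Empty clusters are reseeded at the point farthest from their
centroid.  1,000 random restarts are used by default and the lowest-cost
solution wins; runs are deterministic given the seed.  A window whose
network is entirely empty (all coefficients shrunk to zero) carries no
pattern; in pipeline runs such features are embedded as neutral points
at distance 1 from every centroid rather than aborting (the strict
estimator API still rejects them).  k is a user choice scanned over 2–8
by the driver; automatic selection of k is out of scope.

**4. Markov modeling and the model-distance test.**  Each condition's
symbol matrix (grouped trials × windows, symbols 1..k) is summarized by
a Markov chain.  With the emission matrix pinned to identity, the EM
(Baum-Welch) fixed point is the closed-form counting MLE, which is what
is implemented (and cross-checked against an EM implementation in
tests): initial probabilities from first symbols, transition rows from
transition counts; never-visited states get a uniform row.  Conditions
are compared by the symmetrized Rabiner model distance — the per-symbol
log-likelihood advantage of each condition's model over the other's on
the *observed* sequences of the other condition, normalized by total
symbol count (T × trials) and averaged over both directions.  Zero
probabilities are floored at 2.2204e-16 before logs.  When both models
are MLEs of their own data the distance is ≤ 0, and more negative means
more distinguishable.  Significance comes from the lower tail of a
permutation null: trials are pooled and reassigned without replacement
to pseudo-conditions of the original sizes 1,000 times, the chains
re-estimated each time, and `p = (1 + #{null ≤ D_obs})/(1 + n_perm)`
(the add-one correction, so p is never 0).  Permutations reuse the fixed
clustering — only the Markov stage is recomputed — both because the
trial labels enter the pipeline only at that stage and because re-running
estimation and clustering per permutation would be prohibitive.

## Built-in simulation studies

**Estimator comparison.**  Order-1 MVAR processes over 32 sources with
sparse coefficient matrices (nonzero count = round(density·1024),
strengths uniform in [0.1, 0.2], all positive; the diagonal is
eligible) are generated at sample counts of {0.05, 0.1, 0.2, 0.5}×1024,
densities {0.05, 0.1, 0.2} and additive observation noise at SNR
{0.1, 1, 10, ∞} (SNR = signal sd / noise sd).  Each replication is
fitted with the penalized estimator (λ calibrated once per density by
GCV on an independent noiseless dataset with 10× as many samples as
parameters) and with OLS (λ = 0), scored by coefficient RMSE, and
compared by one-tailed paired sign tests per cell, per factor level and
overall.  At the largest sample ratio (0.5) the advantage of the
penalized fit is smallest — the calibrated penalty is relatively strong
there — and the sign-test statistic is closest to its bound.

**Pipeline validation.**  Two conditions share the design: 3 states per
condition with distinct sparse networks (10% density, strengths
[0.1, 0.5], stability enforced by rejection sampling with a down-scaling
fallback to spectral radius 0.95), a 25-state sequence per condition
drawn from the two built-in 3×3 transition matrices (uniform initial
state; the chains do not specify one) and replicated across all
trials, 40-sample MVAR blocks substituted per state occurrence
(independent across blocks and trials, 100-sample burn-in), projection
through a three-shell spherical head model to 32 electrodes, and white
sensor noise with sd = RMS(noiseless scalp data)/SNR.  Trials: 300 per
condition at full scale; the bundled validation runs use 100–150 per
condition to keep the studies desk-sized, which weakens but does not
qualitatively change the discrimination (Markov estimates then rest on
~800 transitions per condition instead of ~2400).

The head model solves the concentric-three-sphere dipole problem per
Legendre order by imposing potential and radial-current continuity at
the two interior interfaces and zero current at the scalp (5×5 linear
system per order, 60 orders by default; truncation error is ~1e-3
relative at these geometries).  Shell radii 0.88/0.92/1.0,
conductivities 0.33/0.0042/0.33.  Sources sit at radius 0.8 on the
upper hemisphere with radial orientation (the orientation is a design
choice: radial maximizes scalp visibility for superficial sources).
Electrodes are a 32-channel 10-20/10-10 montage constructed from the
standard arc proportions on the unit sphere (ring at 72° inclination,
midline arc, great-circle interpolation for intermediate rows).

**What the simulations do not emulate.**  Volume conduction is
spherical-homogeneous rather than realistic BEM/FEM; sensor noise is
white and uncorrelated (no 1/f, no artifacts); state blocks are
independent across boundaries (no continuity of source activity);
sources are radial point dipoles.  Passing validation on these data
shows the pipeline recovers condition differences through linear mixing
and noise, not that electrode-level networks equal source-level truth —
mis-allocation of states due to mixing distorts both the per-state
networks and the estimated transition probabilities even when
discrimination succeeds.

## Numerical and design choices

- Sample-sd (n−1) z-scoring throughout; the pipeline is scale-free past
  preprocessing, so the convention is immaterial beyond a constant.
- Window/group bookkeeping: windows per trial = ⌊n/width⌋, grouped
  trials per condition = ⌊d_c/group⌋; trailing samples and trials are
  dropped and logged.
- All randomness flows from one master seed through named substreams
  (smvar-sampling, clustering, permutation, simulators), so reports are
  byte-identical across reruns and scanning k does not perturb earlier
  stages.
- Model-distance normalization is per symbol (T × trials) so multi-trial
  data aggregate consistently with the per-trial definition.
- The permutation p-value uses the add-one correction; with 1,000
  permutations the smallest attainable p is 1/1001 ≈ 0.000999.
- Degenerate inputs (constant series, zero cross-trial variance,
  rank-deficient unpenalized designs) raise errors naming the offending
  index.

## Limitations

Networks live at the electrode level; no inverse projection is applied,
so state networks are mixtures of source networks.  Order-1 fits on
short windows have essentially no spectral resolution.  k must be chosen
by the user (the driver scans 2–8).  The permutation scheme tests
exchangeability of trials given the fixed symbolization; it does not
propagate clustering uncertainty.
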