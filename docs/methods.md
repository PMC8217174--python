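# Methods

## Scope and data model

`bgcausal` reconstructs directed, lagged dependence graphs from multichannel
BOLD ROI time series. The data model mirrors a block-design fMRI study of the
basal-ganglia motor circuit: eight regions (M1, S1, Put, GPe, STN, GPi, SN,
Tal), 20 subjects, a 1.6 s repetition time, and per subject four 100-volume
blocks alternating a motor task with rest. The pipeline starts at ROI series;
image-space steps (slice timing, motion correction, registration, ROI
delineation) are upstream contracts, not code. Subjects with excessive head
motion are assumed to have been excluded before export.

## Synthetic-data generator

Because no recordings ship with the package, a generator produces series with
the statistical structure the analysis assumes, plus the exact causal graph
that produced them. Each region follows an AR(1) innovation process,

    x_j(t) = a * x_j(t-1) + couplings + s * eps_j(t),

with autocorrelation `a = 0.4` (BOLD-like at a 1.6 s sampling interval),
innovation scale `s = 1` and Gaussian innovations (a unit-variance uniform
option exists for robustness checks). Planted couplings come in four kinds:

| kind                  | contribution to the target             | visible to |
|-----------------------|----------------------------------------|------------|
| linear (lag >= 1)     | `b * x_src(t-lag)`                     | PC, GPDC, CMIknn |
| linear (lag 0)        | shared latent innovation on both ends  | PC, GPDC, CMIknn |
| quadratic             | `b * x_src(t-lag)^2`                   | GPDC, CMIknn |
| threshold             | `b * sign(x_src(t-lag) - offset)`      | (has a linear component) |
| multiplicative noise  | `b * x_src(t-lag) * eta(t)`            | CMIknn (GPDC partially) |

Contemporaneous couplings are realized as shared latent innovations, not
instantaneous structural equations, so no cyclic ambiguity arises; the ground
truth records them undirected, matching how instantaneous dependence is
reported downstream. The linear part of every coupling set must have a
companion-matrix spectral radius below 1 or generation is refused with the
offending radius. Blocks discard a 300-sample burn-in, so the returned
segment is effectively stationary.

Per-block random streams derive from the master seed through a counter scheme
(`SeedSequence(master, spawn_key=(subject, condition, block))`): adding
subjects or blocks never reshuffles the streams of earlier ones.

Coupling strengths in the shipped presets are chosen for test power at the
default study size, not to mimic (unknown) physiological effect sizes. What
the generator does **not** emulate: hemodynamic response convolution, spatial
structure, realistic physiological noise spectra (the nuisance component is a
single shared AR(1) regressor). Passing tests therefore demonstrate that the
inference machinery recovers the process classes its statistics target — not
that it would behave identically on real BOLD data.

## Preprocessing

1. **Nuisance regression** — each region column is replaced by its OLS
   residual on `[intercept, nuisance]`, the nuisance being a shared reference
   series (in the emulated study: the mean white-matter/ventricle signal).
2. **High-pass filter** — 4th-order Butterworth at 0.009 Hz, applied
   forward-backward (`sosfiltfilt`) so no phase shift biases the lag
   estimates; applied per block, never across recording boundaries. The
   realized response removes DC exactly, attenuates 0.004 Hz by > 20 dB and
   passes 0.018 Hz (2x cutoff) within 1 dB.
3. **Per-subject normalization** — demeaning pooled over all of a subject's
   samples (both conditions), per region. Pooled, not per block: per-block
   mean differences are signal. No variance scaling by default (an option
   exists), since only the mean is normalized in the emulated protocol.
4. **Concatenation** — all subjects' blocks of one condition are joined in
   (subject, block) order into a single series (4,000 x 8 under defaults).
   The first and last 5 samples of each block are smoothed with a Gaussian
   moving average (window 5, sd 1 sample, kernel renormalized at the ends) to
   suppress spurious dependence from the artificial junctions; interior
   samples are untouched. Block start indices travel with the series so that
   permutation tests never shuffle across junctions.

Whether the 0.009 Hz filter should run per block or over a whole recording is
ambiguous for concatenated designs; per block is implemented, which is the
conservative choice (no leakage across recordings).

## Conditional-independence tests

All three statistics share one interface and one significance engine.

* **PC (partial correlation).** Pearson correlation of the OLS residuals of
  x and y on `[intercept, Z]`. Rank-deficient conditioning columns are
  dropped with a warning. A Student-t p-value is available as a cross-check
  flag but is never the primary path.
* **GPDC.** x and y are each regressed on Z by Gaussian-process regression
  (constant x RBF + white-noise kernel, inputs standardized, hyperparameters
  by marginal-likelihood optimization; training subsampled beyond
  `gp_max_train = 400` points); the statistic is the distance correlation of
  the residuals after an empirical-CDF transform to uniform marginals, as in
  the method's reference formulation. The rank transform matters: without it
  a few extreme residual pairs dominate the distance matrices, and the test
  acquires substantial power against noise-amplitude (multiplicative)
  coupling — which is exactly the dependence class meant to separate CMIknn
  from GPDC. With empty Z the regression is skipped. A numerically failed GP
  fit falls back to linear residualization and is flagged.
* **CMIknn.** Frenzel–Pompe / KSG k-nearest-neighbour estimate of
  I(x; y | Z) in nats, Chebyshev metric on per-column standardized data,
  `k = 10` by default. Exact duplicate points receive 1e-10 jitter (logged).
  The reported statistic is clipped at zero; the permutation comparison uses
  the raw value.

### Significance: block-shuffle permutation

BOLD series are autocorrelated, so i.i.d.-based p-values are invalid. The
null distribution is built by cutting x into contiguous blocks and permuting
them while y and Z stay fixed; p = (1 + #{|T_perm| >= |T_obs|}) / (n_perm+1).
The block length defaults to the smallest lag at which the mean absolute
autocorrelation of the tested series falls below 2/sqrt(n), clamped to
[1, n/20]; inside the discovery procedure it is resolved once per series from
all channels. Blocks never straddle concatenation boundaries. Testing is
two-sided; for the nonnegative GPDC/CMIknn statistics the two-sided rule
reduces to the upper tail. Default `n_perm = 500`; benchmark suites use
99–199 for speed (the smallest attainable p, 1/(n_perm+1), still reaches the
0.01 level).

Implementation notes: the PC permutation path residualizes the permuted x
against the fixed Z, vectorized over permutations — numerically identical to
recomputing the statistic per permutation. For GPDC the GP residuals are
computed once and the *residual* series is permuted: under the conditional
null the residuals are (block-)exchangeable, and a sample permutation only
permutes rows/columns of the centered distance matrix, so each permutation is
a matrix gather instead of an O(n^3) refit. For CMIknn with non-empty Z a
local permutation is the default: x values are swapped only among samples
with similar Z (nearest neighbours in Z, neighbourhood 5), preserving the
x–Z relation under the null; with empty Z the block shuffle is used.

All tests are pure functions of (data, options); per-link seeds derive from
the run seed and the region labels, so results are independent of evaluation
order, stable under column permutation, and safe to compute in parallel. An
optional on-disk cache keyed by a hash of (data, method, options) avoids
recomputing the expensive CMIknn results.

## Two-stage discovery (PCMCI)

**Stage 1 — parent selection.** For each region, all lagged candidates
(region, lag 1..tau_max) are screened by iterated partial-correlation tests,
conditioning on the q strongest surviving candidates for q = 0, 1, ... up to
`max_conds`; candidates with p > `pc_alpha` (default 0.2, deliberately loose)
are removed. Partial correlation is always used in this stage regardless of
the MCI statistic — it is orders of magnitude cheaper, and the stage only
needs an over-approximation of the parents (switchable in principle; the
selection statistic is a config seam). The selection stage caps its
permutation count at 99: decisions are made against the loose pc_alpha, where
that resolution is ample. ``pc_alpha_sensitivity`` reruns the procedure over
a grid of selection levels and tabulates how the recovered graph responds, so
the heuristic choice can be audited on the data at hand.

**Stage 2 — momentary conditional independence.** Every inter-region link
slot is tested: a lagged link (i, tau, j) conditions on parents(j) minus the
tested link plus parents(i) shifted by tau; a contemporaneous link conditions
on the lagged parents of both ends. Conditioning on both parent sets removes
indirect (chain) paths and common drivers. Each half of the conditioning set
is capped at `max_conds = 3` strongest parents (unbounded conditioning is
unstable for the nearest-neighbour statistic at realistic n). Links with
p <= alpha (default 0.01, two-sided) are retained. Lag-0 links are reported
undirected — at the sampling interval of the recording the driver of an
instantaneous dependence is unidentifiable — and no orientation phase is
attempted. Self-dependencies are used in conditioning but excluded from
reported graphs.

With tau_max = 2 and a 1.6 s repetition time, the maximum causal horizon is
3.2 s. For 8 regions the enumeration is 28 undirected lag-0 slots plus 56
directed slots per lag (140 tests per condition and method).

## Link taxonomy

* **Timing** from the lag: instantaneous / single-delayed / double-delayed.
* **Nature** by detection precedence: significant under PC → *linear*
  (regardless of the others); under GPDC but not PC → *non-linear*; only
  under CMIknn → *complex*. The classes partition the union of the three
  graphs. When PC and GPDC disagree at the margin, the rule table is followed
  strictly — PC significance alone implies linear.
* **Persistence** across conditions: significant (any method) in both →
  *permanent*; otherwise tagged with its single condition. An optional
  binomial screen against a Bernoulli(alpha x tests) null can additionally
  filter links by detection frequency; it is off by default because the
  simple significance rules already reproduce the taxonomy's definitions.

Reported statistic tables are normalized per method and condition by the
maximum absolute statistic, so the strongest link maps to +/-1, signs are
preserved, and magnitudes are comparable across methods. This is the only
reading under which a "0 to 1" normalization coexists with negative printed
entries.

The taxonomy is *operational*: a link's nature is defined by which statistics
detect it. The mapping from generative kinds to natures (linear → linear,
quadratic → non-linear, multiplicative noise → complex) holds sharply for
the first two — partial correlation has asymptotically zero power against a
pure even dependence, distance correlation has full power — but only
tendentially for the third: even with rank-transformed residuals the distance
correlation retains partial power against dependence carried by the noise
amplitude, so at strong couplings the regression statistic sometimes
co-detects a multiplicative link, which the precedence rules then label
non-linear. The benchmark suite therefore scores the multiplicative kind by
*relative detection rates* (CMIknn above both others) rather than by
exclusive detection, and the end-to-end fixture scores nature accuracy over
recovered links. One practical regime note: at strong quadratic couplings the
correlation statistic also over-rejects relative to its nominal level — the
permutation test correctly senses second-moment coupling even though the
population correlation is zero — so the differentiation benchmark plants the
quadratic coupling at strength 0.25, inside the regime where that leakage
stays at a few percent while the distance-correlation power is saturated.

## Benchmark problem sizes

The shipped benchmark runs (mirrored by the acceptance script) use: null
calibration and planted recovery at the study's own scale (8 channels,
n = 4,000, alpha = 0.01, 199 permutations, 30 replicate seeds); quadratic
differentiation at n = 1,000 over 100 seeds; multiplicative differentiation
at n = 2,000 over 40 seeds with 99 permutations; the classification fixture
on 6 regions at 800 samples per condition. These sizes keep a full benchmark
at desk scale while leaving every rate estimate's binomial error well inside
the margins being tested.

## Numerical choices and degenerate inputs

* OLS residualization via pseudo-inverse; rank-deficient Z columns dropped by
  pivoted QR with an eps-scaled tolerance.
* Distance correlation in its V-statistic form; zero distance variance maps
  to a statistic of 0.
* CMI counts use a strictly-inside radius (`nextafter` of the kth-neighbour
  distance); counts include the query point, supplying the +1 of the digamma
  arguments.
* p-values are never 0 by construction; statistics must be finite or the
  result is rejected.
* Unstable coupling sets, cutoffs at/above Nyquist, mismatched lengths,
  duplicate region labels, ragged or non-numeric table rows are all rejected
  with specific messages (and line numbers for tables).

## Known limitations

* Effective connectivity here is statistical, not interventional; the usual
  PCMCI preconditions (causal sufficiency, faithfulness, stationarity) are
  assumptions, and the generator satisfies them by construction — real
  recordings need not.
* The multiplicative-noise / "complex" boundary is power-dependent, as
  discussed above.
* The GP regression subsamples its training set beyond 400 points; for very
  rough conditional means this trades a little residualization fidelity for
  tractability.
* Only pairwise links are modelled; simultaneous multi-region interactions
  are out of scope.
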