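# Methods

This note documents the models, estimators and design choices behind
`gcherit`, in the order the pipeline applies them.

## Cohort model and kinship

Cohorts consist of monozygotic (MZ) twin pairs, dizygotic (DZ) twin
pairs, full-sibling sets and singletons. Under that structure the
expected-relatedness matrix `2*Phi` needs only three values — 1 (self and
MZ co-twins), 0.5 (DZ co-twins, full siblings), 0 (across families) — so
kinship is derived from group labels rather than parental genealogy.
Arbitrary multi-generation pedigrees, inbreeding and half-siblings are
out of scope. Households default to families (`hhid = famid`); the column
is exposed so users with real household data can override it.

The default synthetic composition is 62 MZ pairs, 25 DZ pairs, sibling
sets totalling 197 individuals (sets of 2 and 3) and 78 singletons — 449
individuals, the per-cohort size of large young-adult family imaging
samples. Ages are family-anchored at 29 +- 3.5 y (twins share age),
education 15 +- 1.8 y, sex balanced with MZ co-twins concordant,
handedness ~90% right.

## Discovery/replication split

Families are grouped by their composition signature; within each
signature class they are shuffled and dealt alternately to the two sides,
which makes the MZ/DZ/sibling/singleton counts of the halves identical by
construction. A greedy same-class swap pass then minimizes the worst
absolute standardized difference (pooled-SD denominator) of age,
education, sex and handedness; random restarts and, as a last resort,
exclusion of matched same-class family pairs bring the worst difference
under the tolerance (default 0.05). One family per odd-sized class is
excluded up front because it cannot be mirrored. The procedure is a
reproducible stand-in for interactive matching software; the exclusion
rule is a design choice, not a reconstruction of any particular tool.
Balance is reported with Welch's t for continuous covariates and
chi-square for categorical ones (the choice of tests is conventional).

## Synthetic ground truth

Per-connection coupling traits are drawn from
`N(0, h2 * 2*Phi + c2 * H + (1 - h2 - c2) * I)` blockwise per family,
independently across the `N(N-1)` directed connections (total variance
1). Each subject's neural dynamics are a VAR(1) with diagonal
autoregression 0.5; a designated sparse edge set (default ~15% of ordered
pairs, drawn once per configuration seed) carries coefficients
`base_coupling * (1 + trait)` with the trait clipped at -0.9 so edge
signs survive; the matrix is rescaled to spectral radius <= 0.95 when
needed. Heritable variation therefore enters the observable dynamics
monotonically through the couplings.

Neural innovations are **sparse positive bursts** (probability 0.02 per
sample, amplitude ~5, on a 0.5-SD Gaussian background). This choice is
load-bearing: for a strictly Gaussian process, blind deconvolution can
only ever recover the amplitude spectrum of the hemodynamic kernel — its
phase (the regional lag that confounds directed inference) is formally
unidentifiable. Heavy-tailed burst activity is both the physiological
picture behind point-process deconvolution methods and the condition
under which lag removal is possible at all. The neural simulation step
equals TR (no super-resolution); sessions share the subject's VAR and
HRFs but have independent innovations.

Observation: each node's neural series is convolved with a double-gamma
HRF (undershoot mode fixed at 16 s, ratio 1/6) whose **peak latency is
jittered per node and subject**, uniform on 4-7 s by default; white
observation noise (default SD 0.3 relative to unit signal) is added and
the series standardized. Physiological noise models, motion and spatial
ICA mixing are not emulated — passing tests show the statistical pipeline
is correct under its stated model, not that it is robust to artefacts
real rs-fMRI data contain.

## Blind HRF estimation and deconvolution

Pseudo-events are local maxima of the standardized series above a
threshold (default 1.0 SD), excluding one kernel length at the borders.
The default kernel family is **latency-adaptive**: for each candidate
peak latency `p` on a 2.5-10 s grid (step 0.1 s), sticks weighted by the
detected peak height are placed at `event - round(p/TR)` and the series
is regressed on a double-gamma kernel with peak `p`, sampled with a
fractional shift so its maximum aligns exactly with the detected events;
the candidate minimizing the pooled residual sum of squares over all of
a subject's sessions wins.

Why not the classic canonical-plus-derivatives basis? Because events are
detected *at the response peak*, the selected onset lag of a fixed-peak
basis is pinned to the basis' own peak latency and the fitted kernel
carries at most ~1 s of latency through its derivative terms; the
deconvolution then removes nearly the same phase from every node and the
inter-regional lag survives. Tying the candidate lag to the kernel's peak
latency restores identifiability: the winning candidate must explain the
causal rise and undershoot placement, which differ across latencies. The
canonical basis (3 regressors) and a ridge-smoothed FIR basis remain
available as options. Estimates from fewer than 5 events are flagged
low-confidence; an unusable fit falls back to the canonical kernel with a
flag.

Deconvolution is a regularized Wiener inversion
`N(w) = conj(H) B / (|H|^2 + lambda)` with `lambda = 0.1 max|H|^2` by
default, reflect-padding by one kernel length against wrap-around.
`lambda = 0` is rejected when the kernel spectrum has near-zero bins.
Estimated latency differences are attenuated relative to truth (roughly
half, in the simulation conditions above) because background events pull
all nodes toward a common waveform; the attenuation is common-mode, so
the *relative* correction that directed inference needs survives.

## State-space Granger causality

Each subject's sessions are de-meaned per session and pooled into one
VAR least-squares system with no regression row spanning a session
boundary; the residual covariance carries a degrees-of-freedom
correction. Order selection (default AIC over 1..p_max, evaluated on a
common sample) is available alongside fixed orders; the generating order
in the synthetic world is 1, but estimation may fit higher orders.

The fitted VAR(p) is rewritten in companion innovations form
(`C = [A_1 .. A_p]`, `K = [I; 0]`, `V = Sigma`). For each source the
reduced model deletes the source's observation row; its innovations
covariance solves the filtering discrete algebraic Riccati equation
(scipy's Schur-based solver, with a fixed-point Riccati iteration at
tolerance 1e-12 / 500 iterations as fallback), and

    F(source -> i | rest) = ln(V^R_ii / V_ii)

for all targets at once — one DARE per source, no refitting. The default
conditions on all remaining nodes; an unconditional bivariate mode
(sub-models observing {i} and {i, j}) is provided because the conditioning
set used by multivariate GC on large network sets is a genuine modelling
choice. F is nonnegative by theory; tiny negative values (numerical) are
clipped to zero and counted. Per-source DARE failures yield NaN rows and
are logged, never aborting a run. Matrix orientation is `[source,
target]` everywhere, including CSV output (stated in each file header).

Group aggregation is the entrywise NaN-skipping median across subjects,
with a report of connections at or above the 75th percentile of median
strength.

## Variance-component heritability

Preprocessing order: OLS residualization on [1, age, sex, handedness,
education] first, then a rank-based inverse normal transform of the
residuals (Blom constants (3/8, 1/4), mean ranks for ties). Residualizing
before the transform matches the convention of adjusting connectivity
values prior to heritability estimation.

The likelihood is evaluated blockwise per family (the covariance is
block-diagonal across families) after grouping families with identical
kinship/household block patterns: for each such structure the per-grid
inverse and log-determinant of the unit-variance block
`R(theta) = h2 K + c2 H + (1 - h2 - c2) I` are precomputed and each
trait contributes only its per-structure scatter matrix. The total
variance is profiled out analytically (`sigma_p^2 = q(theta)/n`), leaving
a 1-D (AE) or 2-D (ACE) search over variance shares: a 0.01 grid over the
simplex followed by 0.001 local refinement. The grid is capped at
`h2 + c2 <= 0.99` because MZ and household blocks are singular on the
simplex edge. Boundary solutions are admissible; a pedigree with no
related pairs makes `h2` unidentifiable and returns a flagged boundary
result. The grid-plus-refinement scheme is immune to the boundary local
optima that gradient methods hit in this bounded problem.

The null model constrains `sigma_g^2 = 0` (E, or CE for ACE) and is
fitted by the same machinery. The LRT statistic `2(LL_full - LL_null)` is
clipped at zero and referred to the 50:50 mixture of a point mass at zero
and chi-square with 1 df (the parameter sits on the boundary under the
null), so `Lambda = 0` gives p = 0.5. FDR control is Benjamini-Hochberg
(statsmodels) across all `N(N-1)` connections within each cohort
separately; connections whose fit fails are flagged and excluded from the
FDR family so sentinel p-values cannot contaminate the q-values.

Replication is the intersection of FDR-significant connections, with the
percentage defined as `100 * n_both / n_discovery`, rounded to the
nearest integer — the denominator convention that reproduces the
published 38% (58 of 152, AE) and 14% (8 of 56, ACE) rates. Mean-h2
confidence intervals reported alongside published estimates are not
reproduced (their definition is not stated).

## Determinism and problem sizes

The master seed is split into per-stage child seeds by mixing the stage
name's CRC32 into a `SeedSequence`, so stages are independently
reproducible; a rerun with the same configuration reproduces every result
file bit-for-bit. The configuration hash stamped into each output
excludes only the output directory.

The validation experiments run at desk scale, chosen to finish in minutes
on one CPU: 20 random systems for the GC oracle check; 20 seeds with
4 replicate records each for the consistency ratio (the replicate
averaging makes the measured ratio concentrate on the 1/sqrt(T) rate —
the theoretical value is 0.5, and the test bound of 0.65 is ~3 sigma
above it under this design); 50 seeds of 4 sessions x 1200 timepoints for
the directional rescue; 50 traits on the 449-individual cohort for
parameter recovery; 1000 null traits for LRT calibration; and a
120-subject, 10-network, 2x400 run for end-to-end determinism.

## Known limitations

- Kinship from group labels only; no genotype-based relatedness.
- The generator's burst-innovation neural model is a stand-in chosen for
  identifiability and physiological plausibility, not fitted to data; the
  directional-rescue rate (~0.9 at the default settings) degrades when
  events are rare, weak, or the background dominates.
- Estimated HRF latency differences are attenuated (common-mode bias
  removed, scale bias ~2x); the pipeline relies on relative, not
  absolute, latency correction.
- ML (not REML) variance components: slight downward bias in small
  cohorts; ACE h2/c2 separation rests entirely on the MZ vs DZ/sibling
  contrast and is noisy per trait at n = 449.
- The AE/ACE model assumes no dominance, no gene-environment interaction,
  and equal environments across zygosity groups.
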