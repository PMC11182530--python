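# Methods

## Model and procedure

The workflow treats a genus-level abundance table as observations of a
two-layer generative process and summarizes its dynamics as an energy
landscape over binary assemblage patterns.

**Assemblage model.** Each count unit ("occurrence") in sample n carries a
latent assemblage attribute i ~ Multinomial(θₙ) and a genus
f ~ Multinomial(φᵢ); θₙ ~ Dirichlet(β·1_I) and φᵢ ~ Dirichlet(α·1_F). The
fit uses scikit-learn's batch variational implementation. Two deliberate
asymmetries of the study design are preserved: φ is estimated only on each
participant's first retained sample (one sample per participant, so the
within-participant homogeneity of a time series does not bias the
compositions), and θ is then inferred for all retained samples with φ held
fixed (a transform, not a refit). The model archive stores the unnormalised
variational topic-word parameters alongside the normalised φ so that a
reloaded model transforms identically to the in-memory one.

**Occurrence states.** For each disease class and assemblage i, the
threshold is the order statistic of rank ⌈0.75·N⌉ of {θₙᵢ} within the class
(no interpolation), and σᵢⁿ = +1 iff θₙᵢ strictly exceeds it. This
estimator makes the activation fraction exactly ⌊N/4⌋/N when values are
distinct — 65/260 = 25 % at the study's per-class sample size — and is
invariant under any strictly increasing transform of a column. Ties at the
threshold are inactive (−1) by the strict inequality; an all-constant
column therefore binarizes to all −1. Thresholds are per-class by default;
pooling across classes exists behind a flag but changes the question being
asked and is off.

**Pairwise maximum-entropy fit.** With I ≤ 20 the 2^I patterns are
enumerated exactly, so moments, likelihood and its gradient are computed
without sampling. The likelihood of the exponential family is concave and
the update ε·(moment gap) is plain gradient ascent on the per-sample
log-likelihood; the fit starts at h = 0, g = 0 (the uniform model), keeps g
symmetric with zero diagonal by updating only the upper triangle and
mirroring, and stops when the largest absolute gap between empirical and
model moments (first and off-diagonal second) falls below `tol`.
Temperature is absorbed: kT ≡ 1, so h and g carry the energy scale.

**Landscape.** E(σ) is evaluated for every pattern; each pattern links to
its minimum-energy Hamming-1 neighbor when that energy is strictly lower
(ties among equally minimal strictly-lower neighbors go to the lowest
pattern id, making the construction deterministic), otherwise to itself. A
self-linked pattern is a local minimal pattern; equal-energy plateaus are
therefore all LMPs, which guarantees termination of every descent path.
Basins are computed by iterating the link map to its fixed point; their
sizes partition 2^I. At I = 9 a pattern has nine single-flip neighbors —
one per assemblage — and all nine are compared. The brute-force LMP finder
(`find_lmps_bruteforce`) re-derives neighbors by explicit bit flips and
serves as an independent oracle for the descent construction in the tests.

## Parameters that matter

| parameter | default | meaning / rationale |
|---|---|---|
| I | 9 | number of assemblages; fixed, not selected automatically — it keeps 2^I enumeration cheap while remaining interpretable |
| k | 10 | retained time points per participant; participants with fewer are dropped entirely |
| per_class | 26 | participants drawn per class for the balanced MaxEnt input (26×10 = 260 samples/class) |
| α, β | 1/I | symmetric Dirichlet priors of φ and θ (the common default of the underlying implementation); configurable |
| binarization quantile | 0.25 | upper-quartile activation rule |
| ε | 0.1 | gradient-ascent step; monotone non-decreasing log-likelihood observed for ε ≤ 0.2 on all test fixtures |
| tol | 1e-5 | maximum moment gap at convergence |
| max_iter | 50,000 | iteration cap; non-convergence returns the result with a warning rather than an error |
| count depth | 10,000 | reads per sample when converting relative abundances to the counts the assemblage model requires (half-even rounding with largest-remainder repair so rows sum exactly to depth) |

The balanced subset is drawn by seeded uniform sampling of participants
without replacement — any defensible selection rule would do, and a seeded
one makes runs reproducible; the seed is recorded in the output metadata
and the run manifest.

## Synthetic cohorts

`SyntheticCohortSpec` defaults emulate the study's structure: 65 CD, 38 UC
and 27 non-IBD participants with ten visits each, plus 20 short
participants (1–9 visits) so the first-k filter is exercised; F = 40
genera, I = 9 planted assemblages, θ-prior β = 0.5 (sparse enough to
reproduce the strong assemblage-abundance imbalance typical of real
profiles), depth 10,000. Samples are drawn independently within a
participant: the generator reproduces cohort sizes and compositional
statistics, **not** temporal autocorrelation, phylogenetic structure or
read-level noise. Passing tests on this generator therefore demonstrate
correctness of the selection arithmetic, the estimators and the landscape
construction — not that real IBD data would yield any particular LMP set.
The demo fixture uses depth 2,000 to keep files small; all fixtures are
generated programmatically.

`sample_boltzmann_patterns` draws iid patterns by exact enumeration +
categorical sampling, providing the ground-truth sampler for parameter
recovery tests (empirical moments converge to model moments at 1/√n).

## Numerical choices and degenerate inputs

- Pattern probabilities are normalized in log space (log-sum-exp), so
  arbitrarily large |h|, |g| cannot overflow.
- At I = 2, h = 0: ⟨σ₁σ₂⟩ = tanh(g₁₂); at g = 0: ⟨σᵢ⟩ = tanh(hᵢ). These
  closed forms are checked to 1e-10.
- The MLE need not exist when an empirical moment sits on the ±1 boundary
  (e.g. two assemblages perfectly co-activated in a small sample); the fit
  then runs to `max_iter` and reports `converged=False`. This is a property
  of the data, not a solver failure, and is why very small cohorts may
  converge slowly.
- Exported energy tables are written with 17 significant digits; re-reading
  them bit-exactly requires a correctly rounded parser (pandas
  `float_precision="round_trip"`).
- Kruskal–Wallis comparisons with zero variance in every group (all ties)
  report statistic 0 and p-value 1 instead of propagating the undefined tie
  correction. No multiplicity correction is applied to the per-assemblage
  p-values.
- Assemblage labels are arbitrary across seeds; reports order genera within
  an assemblage by descending weight with alphabetical tie-break, and
  planted-model tests match assemblages by minimum total-variation
  assignment before comparing.

## Problem sizes used in the tests

The suite exercises the full study-scale arithmetic (130 participants /
1300 samples / 780 balanced samples) with the synthetic generator, fits the
assemblage model at planted-recovery scale (200 samples × 500 reads, 2
assemblages) and the maximum-entropy model at the study's I = 9 with 260
samples per class; parameter recovery uses 50,000 exact-sampler draws at
I = 3, and the landscape oracle sweep covers 100 random energy tables over
I = 2..9. These sizes were chosen so each check is statistically decisive
for the property it tests.

## Known limitations

- Exact enumeration caps I at 20 by construction (and practically at ~16);
  the method is intended for small I — there is deliberately no
  pseudolikelihood or MCMC path for large I.
- LDA inference is variational; recovered φ is a point estimate and the
  planted-recovery tolerance (TV < 0.05 per row) reflects estimation error
  at the tested corpus size, not an exact identity.
- The landscape stops at LMPs and basins: no barrier heights,
  disconnectivity graphs or transition-rate dynamics.
- The upstream step — reads to genus table — is out of scope; inputs start
  at the genus level.
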