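# Methods

## Model

All analyses assume a homogeneous Kimura two-parameter (K2P) substitution
process.  The unit rate matrix assigns rate α to transitions (A↔G, C↔T) and
rate β to each transversion, normalized so α + 2β = 1 (one expected
substitution per site per unit time); a homogeneous sub-model is indexed by
the transition-transversion ratio R = α/2β ≥ ½, with α = R/(R+1) and
β = 1/(2(R+1)).  R = ½ is the Jukes-Cantor (JC) sub-model.  The exact
per-site substitution probabilities at separation time t are

    p_α(t) = ¼ (1 + e^{−4βt} − 2 e^{−2(α+β)t}),
    p_β(t) = ¼ (1 − e^{−4βt}),

where p_β is the probability of *each* of the two transversion targets.
Consequently the empirical estimate from an aligned pair of k sites divides
the transversion-difference count by 2k.  This per-target convention (rather
than the total transversion proportion Q = 2p_β) is used consistently so that
the Kimura and transversion-only distance formulas apply verbatim; it is the
single most common source of off-by-two errors when comparing against other
software.

Sites evolve i.i.d. (no rate variation), and the simulator draws the root
sequence uniformly.  Because the process is time-reversible with a uniform
stationary distribution, the joint law of the leaves does not depend on where
the root is placed; this is verified by a re-rooting test.  Sequences are
evolved edge-by-edge using the three-class closed form (keep / transition /
each transversion), vectorized over replicates; with the coding A=0, G=1,
C=2, T=3 the mutation classes are XOR masks, which keeps large replicate
batches cheap.

## Substitution-rate functions

An SR function maps (p̂_α, p̂_β) to a scalar distance.  Implemented: the
Kimura distance (additive for every R — it returns t exactly on model
probabilities), the JC distance (additive only at R = ½), the
transversion-only distance (βt up to the 1/(2(R+1)) scale), a fixed-R
maximum-likelihood time estimate (bounded scalar optimization of the
trinomial likelihood on t ∈ (10⁻⁸, 20], absolute tolerance ~10⁻¹⁰; the
maximizer depends only on the observed proportions, not on k), and a LogDet
distance, −¼ ln det of the row-normalized joint frequency matrix.  The LogDet
variant choice (row-normalized versus the symmetrized marginal-corrected
form) only shifts the distance by marginal terms and none of the package's
quantitative results depend on it.

In the time domain the JC distance under K2P(R) is

    Δ_JC(R, t) = 3t / (2(R+1)) − ¾ ln((1 + 2e^{−ρt})/3),   ρ = (2R−1)/(R+1),

with closed-form first three t-derivatives.  Its slope at t = 0 is exactly 1
and its curvature is negative for R > ½, with the global curvature minimum
−(3/16)ρ² at t = ln 2 / ρ.  Note that p_α(t) itself is *not* monotone in t
(it overshoots ¼ and relaxes back when transitions dominate early); the
monotone quantities are p_β, the total mismatch probability p_α + 2p_β, and
every implemented SR function as a function of t.

## Deviation from additivity

The deviation of Δ over [t₀, t₁] is inf over affine functions at+b (a > 0)
of max_t |Δ(t) − at − b| / a — the slope normalization expresses the bias in
time units so it can be compared with edge lengths.  When the deviation is
below half the minimal edge time of a tree whose inter-leaf times fall in
the interval, the induced dissimilarities are near-additive and robust
methods (four-point, NJ within Atteson's radius) recover the topology.

Numerics.  The implementation samples the curve on a 2001-point grid and
checks whether the residual to the linear interpolation keeps one sign; if so
(the concave/convex case, which covers the JC curve for every R > ½) it uses
the closed form — optimal slope A (the chord slope), intercept shifted by
half the maximal gap X, deviation X/(2A) — with the gap located by a local
bounded refinement around the grid argmax.  Otherwise a nested minimax runs:
for fixed slope the optimal intercept is the Chebyshev center of the
residuals, and the slope is minimized by bounded search over [A/10, 10A]
with a 400-point dense-scan fallback for non-unimodal objectives.  The
objective ψ(a)/a has a kink at its minimum in the concave case, so
brute-force validation grids must refine iteratively; the test suite's
independent oracle does exactly that and agrees to 10⁻⁴ relative on random
(R, interval) draws.  The interpolation-error bound (t₁−t₀)² F / (16A) with
F = max|Δ″| uses the closed-form second derivative for the JC curve
(endpoint or interior minimum at ln 2/ρ) and central differences otherwise.

## Noise model

Per-site pair differences are trinomial, so the delta method gives
first-order variances of the distance estimators.  For the Kimura distance,
with w = 1−2p_α−2p_β and v = 1−4p_β,

    Var(Δ_K2P) = [ (1/w)² p_α(1−p_α) + (1/w + 1/v)² p_β(1−2p_β)/2
                   − 2 (1/w)(1/w + 1/v) p_α p_β ] / k,

propagating the full multinomial covariance of (p̂_α, p̂_β).  For the JC
distance, which depends only on the binomial total p = p_α + 2p_β,

    Var(Δ_JC) = p(1−p) / ( k (1 − 4p/3)² ).

Both scale exactly as 1/k and are validated against Monte-Carlo standard
deviations to within 5% at k = 10⁴ over (R, t) ∈ {½,2,5,10}×{0.2,…,1.5}.
The noise of an affine surrogate a·t + b is a·σ(Δ_K2P): the surrogate tracks
the same time estimate, scaled.  The Monte-Carlo validator drops saturated
replicates rather than capping them (a cap would bias the spread) and
reports their count, warning above 10%.

## Quartets and the Fisher criterion

Two hard quartet prototypes with true split (12|34), internal edge t_i,
short/long external edges t_s ≤ t_l: type A ("Farris zone") puts both short
edges on one side — concavity of the SR function *widens* the four-point
margin; type B ("Felsenstein zone") mixes a short and a long edge on each
side — the pair time d₁₂ = d₃₄ = t_s + t_l sits near the middle of the
interpolation interval [d₁₃, d₂₄], so the margin shrinks by exactly twice
the chord gap at d₁₂ (≈ 2X, the maximal gap).  On exact distances the
four-point method flips to (13|24) precisely when the deviation exceeds
t_i/2, which the suite verifies by a grid scan.

The Fisher criterion for the competing sums uses exact expected distances
for the means and the sum of the two delta-method variances for each sum's
variance.  Covariance between sums sharing external edges is deliberately
ignored — the criterion is a separability heuristic, not an exact error
rate — and the sums are not normal; its value lies in *comparing* two SR
functions, where both approximations act symmetrically.  Because both noises
scale as 1/√k, FC crossings between two SR functions are invariant to the
sequence length used.

Monte-Carlo quartet accuracy simulates all replicates once and evaluates
every SR function on the same replicates (a paired design — the crossing of
two accuracy curves is located far more precisely than with independent
runs).  Saturated distances are capped at twice the largest finite distance
in the same replicate's matrix (5.0 if none), and exact ties among split
sums are broken uniformly at random with noise shared across SR functions.

## Trees, NJ and RF

Trees are dendropy objects; Newick round-trips preserve lengths to 10⁻¹².
Neighbor joining is implemented in-repo (classic Q-criterion with
Studier–Keppler updates, smallest row-major index tie-break) so its
contracts — determinism and invariance of the topology under affine
transforms aD + b of the input — are directly testable; it is cross-checked
against scikit-bio's NJ.  Negative branch lengths are kept, since evaluation
is topology-only.  Robinson-Foulds distances are symmetric differences of
canonical bipartition sets, normalized by 2(n−3); the implementation is
cross-checked against dendropy.  A fast path returns NJ bipartitions
directly from the merge record, skipping tree-object construction inside
replicated experiments.

## Experiment scales and defaults

The packaged study conditions are: quartet series with R = 5, t_i = 0.2,
t_l = 1.0, t_s swept over [0.2, 1.0] in 0.01 steps for deterministic FC
curves; 1,000 bp alignments with 20,000 replicates per point on a 0.025-step
coarse grid over t_s ∈ [0.2, 0.6] for the Monte-Carlo crossover (the
crossover sits inside this window; the full grid at these replicate counts
adds nothing to its location); and the semi-symmetric 7-taxon caterpillar
(t_ext = 5·t_int) at R = 2 and 500 bp, rescaled to diameters 0.1–2.0 in 0.1
steps with 4,000 replicates per scale.  Crossings of noisy difference curves
are located by a cubic least-squares fit (root nearest the raw sign change);
deterministic FC crossings use plain linear interpolation between grid
points.  Replicate counts are driver arguments and can be raised freely.

## What the simulations do and do not show

The generator emulates exactly the assumed model: homogeneous K2P, i.i.d.
sites, uniform base composition, no indels or alignment error.  Passing
tests therefore demonstrate the internal bias/noise trade-off — that a
misspecified but quieter distance can dominate the correctly specified one —
not robustness to rate heterogeneity, compositional bias, or non-homogeneous
processes.  The framework itself (deviation from additivity + delta-method
noise) extends to any homogeneous model with a tractable time
parameterization; only the K2P/JC instantiation is implemented here.

## Known limitations

* The fixed-R ML distance is scalar-optimized per pair; it is accurate but
  the slowest SR function in matrix computations.
* The Fisher criterion ignores correlations between split sums and is not
  calibrated as a probability; only its comparisons are meaningful.
* Saturation capping (2× largest finite entry) is a pragmatic policy; at
  extreme tree scales the transversion-only and LogDet distances saturate
  often and results there depend mildly on the cap.
* `consistency_check` is a sufficient-condition test: "not guaranteed" does
  not mean reconstruction fails, only that the near-additivity margin is
  exhausted.
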