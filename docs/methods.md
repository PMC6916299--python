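# Methods

## Model and notation

Each of K two-arm studies yields an effect estimate θ̂ᵢ with estimated
within-study variance v²ᵢ.  The random-effects model is
θ̂ᵢ ~ N(θᵢ, σᵢ²), θᵢ ~ N(θ, τ²).  For MD, θ̂ᵢ = x̄ᵢT − x̄ᵢC and
v²ᵢ = s²ᵢT/nᵢT + s²ᵢC/nᵢC, and v²ᵢ is independent of θ̂ᵢ.  For SMD the
estimator is Hedges's g, gᵢ = J(mᵢ)(x̄ᵢT − x̄ᵢC)/sᵢ with mᵢ = nᵢ − 2,
J(m) = Γ(m/2)/(√(m/2)Γ((m−1)/2)) computed on the log scale, and
v²ᵢ = 1/ñᵢ + (1 − (m−2)/(mJ²)) gᵢ², ñᵢ = nᵢTnᵢC/nᵢ.  Crucially, for SMD the
variance estimator is a deterministic function of gᵢ, which couples the
weights of Cochran's Q to the estimates.

All Q-based methods use Q(τ²) = Σ wᵢ(θ̂ᵢ − θ̂_w)², wᵢ = 1/(v²ᵢ + τ²);
Q(τ²) is continuous, strictly decreasing and convex in τ², which makes every
profile equation in the package a bracketed one-dimensional root-find
(bisection bracket grown geometrically from 4·max(v²ᵢ)·K, Brent solver,
tolerance 1e-10 on τ²).

## Corrected null moments of Q

The classical reference distribution χ²(K−1) for Q(0) assumes known v²ᵢ.
The package implements corrected moments for both measures.

**MD (Welch-type).**  Conditioning on the (independent) variance estimates
and expanding in their fluctuations gives

    κ₁ = E[Q]  = K − 1 + 2 Σ wᵢ²γᵢpᵢ²,
    κ₂ = Var[Q] = 2(K − 1) + 14 Σ wᵢ²γᵢpᵢ²,

with γᵢ = s⁴ᵢT/(n²ᵢT fᵢT) + s⁴ᵢC/(n²ᵢC fᵢC) (half the sampling variance of
v²ᵢ; fᵢⱼ = nᵢⱼ − 1) and pᵢ = 1 − wᵢ/W.  We re-derived both constants from
scratch (the derivation conditions on the weights, expands 1/W to second
order, and matches the one-way Welch ANOVA special case); a 200 000-draw
Monte-Carlo null simulation in the test suite guards the transcription.
The null distribution of Q is approximated by c·F(K−1, f₂) with (c, f₂)
solved in closed form from (κ₁, κ₂); when κ₂ is at or below the chi-square
relative variance no F solution with f₂ > 4 exists and the code falls back
to a chi-square with df = κ₁ (flagged).

From these: the WT estimator solves Q(τ²) = κ̂₁(τ²) (weights and pᵢ
re-evaluated at the candidate τ², outer fixed point, inner MP-type solve);
CDL is the DL closed form with K − 1 replaced by κ̂₁(0); the WT interval is
the Q-profile inversion against the c·F quantiles with (c, f₂) recomputed
along the profile.

**SMD (corrected moments for Hedges's g).**  Under homogeneity at a common
effect δ (plugged in as the inverse-variance weighted mean), gᵢ is an
exactly-scaled noncentral t variable and v²ᵢ = aᵢ + bᵢgᵢ².  We expand
Q(g₁,…,g_K) in a fourth-order Taylor series about the homogeneous point
δ·1 and take expectations with the *exact* central moments of the
noncentral-t distribution (computed from closed-form raw moments up to order
six).  The corrected mean keeps every expectation term of the quartic
polynomial; the corrected variance keeps
Var(Q₂) + 2Cov(Q₂,Q₃) + 2Cov(Q₂,Q₄) + Var(Q₃) of its homogeneous parts —
the complete O(1/n) family.  The derivative tensors of Q are evaluated by
batched central finite differences (step 0.02 on the g scale); the
moment-pattern sums are verified in the test suite against a brute-force
symbolic expansion of a generic quartic, and the tensors against symbolic
differentiation of Q itself.

Both corrections are negative for nontrivial δ — the g–v² coupling deflates
E[Q] and, strongly, Var[Q] — which explains two known phenomena: DL-type
estimators underestimate τ² for SMD, and intervals built from the corrected
distribution are markedly narrower than the Q-profile interval.  The point
estimator solves Q(τ²) = κ₁; the interval inverts the Q-profile against a
scaled chi-square matched to (κ₁, κ₂) (Satterthwaite: scale κ₂/2κ₁,
df 2κ₁²/κ₂).  We use the two-moment match rather than a one-moment
chi-square because a single-df chi-square cannot simultaneously reproduce
both tails of the corrected distribution; with (κ₁, κ₂) both deflated the
two tails move in opposite directions relative to χ²(K−1).

*Relation to published variants.*  The O(1/n) moment corrections for SMD
were originally derived by Kulinskaya, Dollinger and Bjørkestøl; their
printed expressions were not available to us, so the expansion here is an
independent derivation of the same order.  On the 24-study OCD example our
κ₁ is 21.36 where the published machinery evidently used ≈ 20.69
(reconstructed from their printed τ̂² and interval); the resulting point
estimate differs by about 6% (0.428 vs 0.454) and the interval upper limit
by about 10%.  Monte-Carlo experiments in the test suite confirm that our
(κ₁, κ₂) move the classical moments toward the true simulated moments of Q
and converge to them as study sizes grow; at very small n *any* O(1/n)
truncation is far from the truth (true Var[Q] ≈ 40 in the example against
2(K−1) = 46 classical and ≈ 17–26 corrected), which is inherent to the
method, not to this implementation.

For studies too small for an exact sixth moment of the noncentral t
(m ≤ 6), normal-theory surrogate moments are substituted with a warning.

## Standard estimators

DL and MP are textbook implementations; REML uses the Fisher-scoring fixed
point (max 200 iterations, relative tolerance 1e-10, truncation at zero,
DL start), with a grid-search oracle in the tests guarding against spurious
optima.  Jackson's generalized-method-of-moments estimator uses weights
aᵢ = 1/vᵢ (reciprocal standard error); its expectation equation is linear in
τ².  The profile-likelihood interval profiles the *restricted* likelihood by
default — this is the variant that pairs with the REML point estimate and
the one that reproduces the worked example's printed interval; the ordinary
profile likelihood is available by argument.  BJ and Jackson intervals
invert the exact distribution of the (generalized) Q under the model: a
positive linear combination Σ λⱼ(τ²)χ²₁ with λⱼ the nonzero eigenvalues of
the weighted centring form, evaluated with Ruben's mixture-of-chi-squares
series (absolute accuracy ≈ 1e-10 when converged) and Imhof's oscillatory
integral as fallback; the two paths are unit-tested against each other and
against Monte Carlo.

## Pooling

Inverse-variance pooling at a given τ² with normal critical values;
HKSJ with variance Σwᵢ(θ̂ᵢ−θ̂)²/((K−1)Σwᵢ) and t(K−1) critical values (no
"modified" variance floor); SSW with weights ñᵢ, variance
Σñᵢ²(v²ᵢ+τ̂²)/(Σñᵢ)² and t(K−1) critical values.  For SMD, inverse-variance
weights are correlated with the estimates, biasing the pooled effect toward
zero by 5–10% for δ ≥ 1 at n = 20 (reproduced in the tests); SSW removes
this by construction.  I² uses the Higgins–Thompson typical within-study
variance s² = (K−1)ΣW/((ΣW)² − ΣW²), W = 1/v²ᵢ — the originating literature
plots I² without defining s², so this choice is recorded here.

## Synthetic data

The generators draw from the model exactly: for MD, s²ᵢⱼ ~ σ²ᵢⱼχ²(nᵢⱼ−1)/(nᵢⱼ−1)
and yᵢ ~ N(μ, σ²ᵢT/nᵢT + σ²ᵢC/nᵢC + τ²); for SMD, δᵢ ~ N(δ, τ²) and gᵢ
directly from the scaled noncentral t with Hedges's variance formula.
Arm sizes follow nᵢT = ⌈(1−q)nᵢ⌉.  Defaults mirror the study conditions the
methods were evaluated under: K ∈ {5, 10, 30}, equal sizes n ∈
{20, 40, 100, 250} or the skewed unequal patterns (n̄ = 30: 12, 16, 18, 20, 84,
and analogues for 60, 100, 160, repeated for larger K), q ∈ {0.5, 0.75},
within-study variances (1,1), (1,2), (10,10), (10,20) for MD, δ ∈ {0…2} and
τ² up to 1 (MD) or 2.5 (SMD).  What the generators do *not* emulate:
non-normal subject-level data, unequal arm variances for SMD, correlation
between studies, publication selection.  Passing tests therefore certify
correctness under the model, not robustness to its violations.

Seeding: a master seed spawns SeedSequence substreams keyed by
(configuration, replicate), so results are invariant to chunking and any
single replicate can be regenerated alone.

Default replication counts are 2 000 per configuration (a `--full` flag
switches the CLI to 10 000); the test suite's stochastic checks use 2 000
replications with three-Monte-Carlo-SE allowances on top of published bands.

## Numerical choices and edge cases

* Truncation at zero keeps the untruncated value for bias studies.
* K = 1 is rejected; K = 2 runs with a loud warning.
* Both arm SDs zero (MD) or zero pooled SD (SMD) raise degenerate-input
  errors rather than producing v² = 0.
* Text reports print four decimals; CSV output keeps full precision.
* The finite-difference step for the SMD moment tensors (0.02) balances
  truncation against cancellation; the κ₂ pattern sums accumulate O(K³)
  terms and carry a numerical floor around 1% at extreme study sizes.

## Known limitations

* The SMD corrected moments are an independent derivation; worked-example
  agreement with the originally published variant is approximate (see
  above), and the discrepancy is documented rather than calibrated away.
* SSW on the worked example gives 1.0765 where the published table prints
  1.0950; the effective-sample-size weighted mean of the printed data is
  1.0765 under every weighting variant we tested, so the package reports it.
* The chi-square-mixture intervals (BJ, J) assume fixed weights under the
  model and inherit that approximation.
* No meta-regression, prediction intervals, or effect measures beyond
  MD/SMD (log response ratio, odds ratios etc. are out of scope).
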