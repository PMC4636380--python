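# Methods

This note records the model as implemented, the defaults and why they are
what they are, the numerical choices, and what the synthetic tests do and
do not establish about real regulatory sequences.

## Thermodynamic binding and fitness

A TF bound to an n-bp window has energy `E = Σ_j ξ[σ_j, j]` (additive
energy matrix, consensus entries zero).  Under the mismatch approximation
all non-consensus entries equal the specificity ε, so `E = εk` for a
window k mismatches from the consensus, and the equilibrium occupancy is
`π(k) = 1/(1 + exp(β(εk − μ)))`.  Defaults ε = 2 k_BT (the 1–3 k_BT range
measured for real TFs) and μ = 4 k_BT, which places the occupancy midpoint
at k = 2 for n = 7 so that sequence changes span the full expression
range.  β = 1 fixes the energy unit.  Strong/weak classes use the 2/3 and
1/3 occupancy thresholds; boundaries are strict (`k_strong` is the largest
k with π > 2/3), so every class labelled strong genuinely clears the
threshold.

Fitness is linear in expression: `f = s·π` for an isolated site and
`f = s·Σ_i π⁽ⁱ⁾` over all overlapping windows of a promoter (additive
activation, all sites equal sign and weight).  `s` is the selective
advantage of strongest over weakest binding; the chain dynamics depend on
the product Ns (population-scaled selection), and runs are parametrised by
Ns with N = 1000 by default, s = Ns/N.  Two alternative promoter maps are
provided for robustness analyses: `strongest` (max window occupancy) and
`synergistic_pair` (product of the two largest window occupancies, a toy
for cooperative displacement of nucleosomes).  A `power_law_gamma` option
replaces the thermodynamic tail beyond `k_strong` with
`π(k_strong)·(k − k_strong + 1)^(−γ)`; γ = ∞ gives a step landscape.  The
tail form was chosen to be continuous at the strong boundary and to
reduce to the step landscape in the limit.

### Cooperativity

Two TFs bound within `window` (default 3) bp interact with energy E_c.
The focal-site occupancy uses the two-site partition function with joint
Boltzmann weight `exp(−β(εk + εk_c + E_c − 2μ))`, so favorable (negative)
E_c increases joint binding and a strong partner acts as a local upward
shift of the chemical potential — numerically,
`π_coop(k, 0; E_c) ≈ π(k; μ − E_c)` once the partner is saturated.  (The
alternative sign convention, with E_c subtracted inside the weight, would
make favorable cooperativity *reduce* binding and contradicts the
chemical-potential-shift picture; we flag this as a deliberate convention
choice.)  Each window pairs with its lowest-k non-overlapping partner at
gap ≤ window bp, leftmost on ties; the focal-site marginal occupancy (not
the joint) enters fitness and strong-site counting.

## Mutation

Point mutations: rate u per bp per generation, uniform position, uniform
among the 3 alternative bases.  Class kernel: up `1 − k/n`, down `k/3n`,
stay `2k/3n`.

Indels: rate θu per bp (θ = 0 or 0.15; the literature range is 0.1–0.2),
lengths 1–2 bp with relative frequencies 0.45 : 0.18 renormalised to sum
to one (these are frequencies among all indel lengths in the source data;
the model restricts to 1–2 bp).  Insertions and deletions are equally
likely.  The sequence is anchored at its final position: an insertion
after position j pushes the first d bases off the distal end; a deletion
window ending at position j pulls d random background bases in at the
distal end.  Insertions are placed uniformly over the L within-sequence
gaps and deletions over the L possible end positions (windows reaching
past the distal end are truncated), so both event types randomise j ∈
{1..L} distal positions uniformly — the structure the analytic kernel
assumes.

The analytic class kernel composes `X ~ Binomial(i−1, k/n)` mismatches on
the preserved segment with `Y ~ Binomial(n−i+1, 3/4)` on the randomised
one, position i uniform.  For a site with *exactly* k mismatches the
preserved segment is hypergeometric, not binomial;
`indel_kernel(..., exact=True)` provides that exact composition.  The two
differ by up to ~0.075 per cell at n = 7 — a real approximation error of
the analytic form that Monte-Carlo validation at 10^5 events resolves
clearly (~50 binomial SE).  The explicit-edit simulator is validated
against the exact kernel; the analytic kernel is what enters the
combined mutation generator `U = n·u·(P_point + θ·P_indel)`, keeping the
chain consistent with the standard analytical treatment.

## Origin–fixation chain

`R[k'|k] = 2N·U[k'|k]·P_fix(N, Δf)` with Kimura's diffusion result
`P_fix = (1 − e^(−2Δf))/(1 − e^(−4NΔf))`.  All rates are reported in
units of u and times in 1/u.  Numerical care:

- Neutral limit by series for |4NΔf| < 1e−8; the scaled factor 2N·P_fix
  is evaluated directly so that s = 0 gives R = U bit-for-bit.
- Deep-deleterious entries are computed in log space (no overflow).
- The stationary distribution comes from the eigen-decomposition
  (eigenvalue nearest zero) with a normalised least-squares fallback;
  tiny negative round-off is clipped and the vector renormalised.
- The point-mutation-only closed form is `ψ_k ∝ exp(F + H)` with
  `H = log Binomial(n, 3/4) pmf` (mutational entropy) and
  `F = 2(2N−1)·f(k)`: the exact detailed-balance exponent for the chain
  as built, whose N ≫ 1 limit is the conventional 4N·f(k).  Using the
  exact exponent makes the eigenvector and the closed form agree to
  solver precision rather than to O(1/N).
- Closed-form (tridiagonal) hitting times use cumulative-stationary
  ratios evaluated through detailed-balance rate ratios in log space;
  the naive cumulative sums underflow for Ns ≳ 30.
- The exact hitting-time solver refuses to return times that overflow
  the floating-point range (e.g. loss under strong positive selection)
  instead of returning an ill-conditioned solve's garbage.
- The shortest-path approximation sums inverse forward rates along the
  monotone path: downhill-in-k rates for gain, uphill for loss (the loss
  sum must use the rates *into* higher classes; this follows from the
  strong-selection limit of the tridiagonal form).
- `expm` (scaling-and-squaring) propagates distributions; n ≤ 30 keeps
  this trivial.  KL divergences floor underflowed reference masses at
  the smallest positive normal float.

The strong-selection threshold `Ns* = (1/4)(n·log4 − ½·log(2πα(1−α)n))`,
linear part `n·log(2)/2`, is exposed together with a bisection solver for
the operational threshold (5% stationary mass outside the strong classes).

## Simulators

**Wright–Fisher.**  2N haplotypes of length L; per generation, mutation
(binomial event counts at rates u and θu per bp), then multinomial
resampling with weights `exp(f)` — genic selection without dominance,
equivalent to a haploid population of size 2N.  Selection weights `exp(f)`
rather than 1 + f differ at O(f²), negligible for s ≤ 0.5.  Gain/loss
events are scored when the frequency of target-class haplotypes exceeds
50% (a population-level analogue of the chain's state change; 90% is
available as an option).  Because the chain jumps at the *origination* of
a successful mutant while the population needs the sweep to reach
majority, WF first-passage times run ~10–15% above the chain prediction
at Nu = 0.01 — the expected half-sweep lag, within the 2-SEM band of a
200-replicate ensemble.

**Fixed-state sequence simulator.**  The origin–fixation jump process run
directly on an L-bp sequence: candidate mutations arise as a Poisson
process at rate 2N·L·u(1+θ) per generation and fix instantly with
probability P_fix computed from the full promoter fitness.  This is the
natural comparator for the promoter theory (no sweep lag, no
polymorphism) and is 10–50× faster; the WF engine covers the regimes
where the fixed-state assumption is in question.

Promoter runs use a *random* consensus drawn from the seeded generator:
a homopolymer consensus (the mismatch-mode placeholder default "A"·n)
self-overlaps, so selection rewards A-runs in which every 1-bp extension
creates an additional overlapping strong window, inflating counts ~5×.
Random n = 7 consensi have negligible self-overlap.  Strong-site counts
are raw (overlap-allowed) by default, since the additive fitness is
overlap-blind; a greedy left-to-right non-overlapping count is reported
alongside.  Trajectories record the population-mean strong-site count
(the continuous estimator of the chain expectation), plus the modal
sequence's raw and greedy counts.

## Promoter theory

`dz/dt = λ_gain(z_max − z) − λ_loss·z` with closed-form solution
relaxing to `B/A`.  Under strong positive selection λ_loss is ignored.
Two (rate, capacity) pairings bracket the dynamics: the presite-limited
rate with the overlap-allowed capacity `z_max = L − n + 1` (early epoch),
and the all-class rate with the packed capacity `⌊L/n⌋` (late epoch).
A per-class refinement — each non-strong window of class k converting
independently at rate `1/⟨t⟩_{S←k}` with capacity L − n + 1 — is used for
the ancient-site predictions, where the class composition matters.
The ancient-site background is the mixture
`Ψ = ψ(t′)/(L−n+1) + (L−n)·φ/(L−n+1)`, with ψ(t′) the neutrally decayed
class distribution of the old site (the same θ as the main run) and φ the
binomial background.  Note the per-class prediction is *not* monotone in
the ancient site's class at short decay times: a consensus relic has
mostly not yet left the strong class (its remnant is not "newly
evolved"), so the peak sits at the presite class.

Limits of the single-site heuristic, measurable with the simulators: it
ignores that all L − n + 1 positions stay active well past the early
epoch, and that in an anchored sequence every indel re-randomises *all*
windows distal to it (per-window churn ~(L − a)·θu instead of n·θu), so
from ~10^−2/u onwards simulated counts run ~30% above the all-class
curve.  Within t ≲ 5·10^−3/u theory and simulation agree inside the
sampling envelope.

## Synthetic data and what the tests show

All test inputs are generated: uniform random ACGT backgrounds (the
binomial mismatch model's own assumption), planted sites at exact
mismatch counts, neutrally decayed ancient sites, and Gaussian energy
matrices (mean ε, sd 0.5 k_BT, truncated at zero so the consensus stays
the energy minimum).  These fixtures reproduce the model's idealisations
— equiprobable bases, independent positions, a single TF species, no
strand structure, no GC bias or repeats, fixed alignment against an
anchored reference.  Passing tests therefore establish internal
consistency (simulators vs analytics vs closed forms) and the model's
qualitative claims, not calibration against genomic data: real promoters
have biased composition and repeat structure (which enrich presites), TFs
bind both strands, and indel accounting in real alignments is ambiguous
in ways the fixed-window model sidesteps.

Statistical tests are seeded and use pre-registered envelopes: 3–5
binomial SE for Monte-Carlo frequency comparisons, 2-SEM separations for
scenario contrasts at the replicate counts stated in the tests.  Problem
sizes (200-replicate ensembles, 10^5-event kernel validations, L = 30
promoters) were chosen to resolve the effects of interest on a single
CPU in minutes.

## Known limitations

- No recombination; the regulatory locus is fully linked.
- One TF species with one consensus; no TF-side evolution of length or
  specificity.
- The chemical potential is fixed, not solved self-consistently against
  genome-wide binding.
- Polymorphic-population theory beyond Kimura's formula (clonal
  interference etc.) is only probed empirically via the WF engine.
- The analytic indel kernel's binomial treatment of the preserved
  segment is an approximation (see above); the exact kernel is provided
  but the analytic one is kept in the rate matrix for consistency with
  the standard treatment.
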