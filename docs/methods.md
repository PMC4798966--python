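# Methods

This note documents the models, conventions and design choices behind
`mlsel`, in the order of the package modules.

## Price accounting (`mlsel.price`)

The identity π̄ΔP̄ = Cov(π, P) + Ave(πΔP) is an algebraic tautology, but
only under a consistent weighting convention. The package exposes two,
both exact:

- **uniform** (default): each group weighs 1/G; π is the absolute final
  group size; P̄ is the *unweighted mean* of group initial frequencies and
  P̄′ the pooled final frequency (total final cooperators over total final
  individuals). This reproduces the two-group worked example (0.5 weights,
  Cov = 8/3, Ave = −5/3) digit for digit. When initial group sizes are
  equal the unweighted mean equals the pooled initial frequency; when they
  are not, the unweighted mean is the convention under which the uniform
  identity remains exact.
- **initial_size**: groups weigh proportionally to initial size, π is
  replaced by the per-capita growth factor π/n, and both community
  frequencies are pooled counts. Use this when "community frequency" must
  mean pooled head counts for unequal groups.

Numerical conventions: an exact mode built on `fractions.Fraction` (the
identity residual is literally zero; used throughout the tests) and a float
mode for large simulations (residual < 1e-9). The covariance centers P at
P̄ by default; because π is centered at π̄ the choice of centering constant
is immaterial, and the `center` parameter exists so that invariance can be
asserted. A group that dies out (π = 0) contributes zero to the
expectation term — its final frequency is undefined — and its
(π − π̄)(P − P̄) term is kept, which keeps the identity exact under the
pooled definition of P̄′. A community whose every group dies has no defined
P̄′ and is rejected; simulation drivers report extinction instead of
calling the decomposition. Printed-precision output rounds half-even to
three significant figures (two below 0.1), matching the worked examples.

## Group-reproduction game (`mlsel.group_game`)

The interaction rule is deterministic: a cooperator sires one cooperator
and grants one extra offspring to each *other* member; a cheater sires two
cheaters. Closed form (c, d) → (c², d(2+c)); within any mixed group the
cooperator frequency strictly falls (the gap reduces to 2cd > 0), so all
pro-cooperation action must come from assortment. Three schemes supply it:
`random` (shuffle-and-chunk, i.e. multivariate hypergeometric), explicit
`fixed-counts`, and `perfect-segregation`. Individuals that do not fill a
complete group form a final smaller group, conserving individuals exactly.

Multi-generation runs pool all offspring globally each generation before
re-forming groups — the standard trait-group lifecycle; the single
generation of the worked example does not constrain this choice, so it is
documented rather than derived. Because the rule grows the population
roughly four-fold per generation, a `max_population` cap with
hypergeometric downsampling is available for long runs. The `cull_groups`
operator (remove groups below a cooperator-frequency threshold) carries a
dual annotation — PC at the community↔group level, PFF at the
group↔member level — reflecting that the same act of selective abortion
reads differently depending on the focal entity.

## Toxin–antitoxin model (`mlsel.toxin`)

Well-mixed episode rule: suicides = round(s·C) (round half-even, exact at
the worked values), kills = min(k·suicides, D). Deaths are exactly
suicides + kills and neither type can go negative. Cooperators gain in
frequency across an episode iff their frequency exceeds 1/(1+k) (cheater
relative loss k·s·C/D versus cooperator relative loss s); the threshold is
independent of s at zero growth cost. With a growth cost the trajectory
alternates deterministic exponential growth (cheater rate 1, cooperator
rate 1 − cost) to the density threshold K with episodes; the cost-adjusted
critical frequency is found by bisection on the one-cycle frequency map.
The magnitude of the cooperators' growth deficit is left free (default 0
in the worked examples, which do not constrain it).

The lattice variant is this package's own model design: sites on a torus
hold a cooperator, a cheater, or nothing; empty sites are colonized at a
rate proportional to the growth-rate-weighted occupied fraction of their
Moore neighborhood (colonization rate 0.3 per step); a cooperator whose
Chebyshev radius-2 neighborhood is ≥ 50% occupied lyses with probability
s = 0.1, and the released toxin kills cheaters within that radius —
*all* of them by default (`k=None`), modeling a lethal toxin halo; a
finite per-suicide kill count is available for matched comparisons with
the well-mixed rule. Suicides resolve sequentially in seeded random
order after a synchronous colonization step. Defaults (40×40 grid,
30% occupancy, 5% growth cost, 150 steps) were chosen as a regime where
the known qualitative contrast is visible within seconds of compute:
locally acting toxin lets a clustered 2% cooperator minority invade, while
destroying locality (whole-grid kill radius with finite k) recovers the
well-mixed threshold failure. No quantitative claims are made for the
lattice; tests assert directions and orderings only.

## Proportional tit-for-tat (`mlsel.games`)

The strategy: cooperate in round 1, then cooperate with probability equal
to the previous round's fraction of cooperating *partners* (self
excluded). Payoffs are a linear public good — each act costs c and pays
b/(n−1) to every partner — since the strategy definition itself fixes no
payoffs; defaults b=3, c=1 are arbitrary. The factorial experiment uses
b=2.4, c=1 with the {5,1}/{1,5} grouping of six-member groups: that
grouping has whole-group relatedness r = 1/3, so b < 3c guarantees that
one-shot assortment alone cannot pay for cooperation (Hamilton's rb > c
fails) and any pTFT advantage must come from repeated interactions acting
on the across-group variance. The tests assert that pTFT's mean payoff
exceeds the cheaters' only in the (rounds > 1) × (high variance) cell.

## Nested heteroplasmy simulator (`mlsel.mito`)

State is hierarchical: an organism holds germ cells; a cell holds
mitochondria; a mitochondrion holds functional/dysfunctional mtDNA counts
(stored as an (n, 2) integer array per cell for vectorization).
"Dysfunctional" is binary and there is no mutation by default, so h = 0
and h = 1 are absorbing; partition operators (cell division, germline
draws) conserve mtDNA copies exactly, and only replication and destruction
operators change them.

Operators and their oracles:

- **replicate_mtdna** — a weighted urn: copies are added one at a time
  with per-copy weight 1 (functional) vs 1 + δ (dysfunctional). Tested
  against the exact urn recursion over the count distribution.
- **divide_mitochondria** — each mitochondrion divides with probability
  `mito_fitness(functional_fraction)`; copies split binomially between
  daughters. Division alone conserves the cell's copy composition; the
  functional fraction rises through the two-type branching expectation
  (class i leaves 1 + p&#7522; daughters) once daughters regrow their copy
  number.
- **mitophagy** — destruction odds multiplied by
  1 + selectivity·(1 − functional fraction)·w (w = 1 by default);
  selectivity 0 is unbiased turnover. Tested against the survival-odds
  closed form.
- **asymmetric_inheritance** — a mitochondrion (functional ≡ functional
  fraction ≥ 1/2) reaches the favored daughter with probability
  0.5 + bias/2, else 0.5 − bias/2; bias 1 sorts deterministically.
- **apoptosis_filter** — cells die with probability `apoptosis_rule(h)`;
  tested against the importance-weighted survivor mean.
- **germline_transmission** — founder pools are hypergeometric draws of
  N_b copies (binomial optional for large pools; `selective_import`
  reweights draws toward functional copies when import selectivity is on).
  Across offspring, founder-h variance ≈ h(1−h)/N_b — the variance the
  downstream PFF filters feed on.

The per-generation lifecycle is a concrete schedule chosen here (the
mechanisms themselves do not impose one): per organism, fecundity
(Poisson with mean `organism_fecundity(h)`) → per-offspring bottleneck →
offspring germline development (zygote assembly, mtDNA amplification with
δ, mitochondrial division up to the per-cell capacity, germ-cell doubling
with asymmetric segregation up to the per-organism capacity) → mitophagy →
apoptosis. The offspring pool is capped by uniform subsampling. Per
generation the simulator emits the population mean h, the between-oocyte
founder variance, organism counts, and a Price decomposition treating
each parent as a group of mtDNAs (π = copies transmitted, P = functional
frequency), whose residual is checked to vanish.

Scale defaults — 8 mtDNAs per mitochondrion, 16 mitochondria per cell,
4 germ cells per organism, 20 organisms — are deliberate small-scale
choices so that paired-seed experiments (e.g. 100 pairs of 6-generation
runs for the filter-efficacy comparison) complete in about two minutes on
one CPU; they are scale parameters, not biological estimates, and all
mechanism tests are property-based (directions, orderings, conservation,
variance laws), not tied to these sizes.

## Randomness and reproducibility

One global seed expands into per-component streams via
`numpy.random.SeedSequence` with a CRC32-keyed spawn key per component
label (`mlsel.config.child_seed`), so toggling one mechanism does not
perturb another's stream. Every CLI run writes a manifest (model,
parameters, seed, per-mechanism {level, PC/PFF} annotations, output
paths) from which the run is reproducible bit-for-bit.

## What the synthetic conditions do and do not show

All inputs are generated by the models themselves; there is no external
data. Passing tests demonstrate internal consistency (exact identities,
conservation laws), agreement with closed-form and recursion oracles, and
the qualitative phenomena the framework predicts (variance-driven spread
of cooperation, threshold versus spatial rescue, the dual PFF
requirements, bottleneck-enabled purging). They do not calibrate any
mechanism against measured biological rates: the toxin lattice is a
stylized dispersal/halo model, the public-goods payoffs are conventional,
and the mitochondrial carrying capacities are orders of magnitude below
real copy numbers. Conclusions about real systems should rest on the
structure of the results (which mechanisms can act at which levels, and
what variance they require), not on the absolute numbers.

## Known limitations

- Binary types throughout (cooperator/cheater, functional/dysfunctional);
  no continuous quality, no mutation between types in the default models.
- Non-overlapping generations everywhere; no evolution of the strategies
  or rules themselves.
- The lattice model has no explicit toxin diffusion chemistry; killing is
  an instantaneous radius effect.
- The mitochondrial model omits biochemistry (ATP, membrane potential,
  ROS), paternal leakage, and disease-threshold phenomenology.
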