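# Methods

`tedkit` implements total-evidence tip dating: joint Bayesian inference of a
dated phylogeny from discrete morphological characters, partitioned DNA and
fossil tips with fixed ages, under explicit diversification-process priors.
This note records the models, the numerical choices, what the synthetic data
emulate, and the design decisions taken where the design was genuinely open.

## The model

### Dated trees

A tree is strictly binary and rooted, with node ages in Ma before present
(present = 0).  Extant tips sit at age exactly 0; fossils are *terminal*
tips at fixed positive ages — sampled-ancestor (zero-length-attachment)
placements are not modelled, and a simulated fossil with sampled descendants
on its own lineage cannot be represented (see "Synthetic data" below).
Fossil ages carry no uncertainty.  Hard monophyly constraints apply to the
fossil-pruned tree only: fossils attach anywhere.

### Tree priors

Three families of prior on dated trees are implemented, all conditioned on
the root age (scored by a separate root-age prior) and on each root child
leaving at least one sampled extant descendant:

* **Uniform**: given root age, topology and tip ages, the internal node ages
  are uniform over the feasible age polytope.  The normalizing volume is
  computed exactly by recursive piecewise-polynomial integration over the
  tree (knots at the fossil ages, ages rescaled by the root age for
  conditioning).
* **Birth–death (BD)** with extant sampling fraction ρ, in the
  (d, r) = (λ−μ, μ/λ) parameterization, using the standard ρ-sampled
  functions p0(t) and p1(t).
* **Fossilized birth–death (FBD)** adding Poissonian fossil recovery ψ,
  parameterized by the fossil-sampling probability f = ψ/(μ+ψ).  The density
  is the q-function product form (factor λ·q per internal node, ψ·p0/q per
  fossil tip, ρ per extant tip); at ψ = 0 it reduces to the BD form exactly.
  A **skyline** variant allows piecewise-constant (d, r, f) over fixed age
  intervals (default boundaries 70 and 55 Ma), with p0 and q propagated
  across boundaries by continuity.

Three tip-sampling modes are supported: *complete* (ρ = 1), *random*
(Bernoulli-ρ), and *diversified* — the n extant exemplars span every split
older than the cutoff x_cut, itself defined as the youngest sampled split.
Diversified sampling is implemented by inserting an interval boundary at
x_cut into the piecewise machinery: below the cutoff ψ is 0 and ρ-sampling
is replaced by survival to the present, so each sampled-tree tip contributes
the probability that its lineage survives and each unobserved side branch
the probability that it leaves nothing sampled.  The published literature
does not print this density in closed form; the forward simulator is
therefore the authoritative contract, and the density is validated against
simulation histograms (2–4 tips, Kolmogorov–Smirnov and total-variation
checks in the test suite).  Fossils younger than x_cut are inconsistent
with the construction and receive density 0 (−∞ log density).

The root age has a diffuse offset-exponential prior (default mean 164 Ma,
offset 64 Ma, i.e. rate 1/100); when fossils are present the effective lower
bound is the oldest fossil age, enforced as a hard reject without
renormalization (the truncation constant cancels in MCMC).

Hyperpriors on (d, r, f) come in named presets: `vague`
(d ~ Exp(10), r, f ~ Beta(1,1)), `low_extinction` (r ~ Beta(1,100)),
`high_fossil_sampling` (f ~ Beta(100,1)), `low_ext_high_fs` (both), and
`rapid_diversification` (d fixed at 0.1).  The informative presets raise the
price of ghost lineages — lineage-time unobserved in the fossil record —
and are the corrective lever for deep root attraction (DRA).  A note on
mechanism: pointwise in parameter space the single-tree ghost penalty is
governed by d and by ψ (at ψ = 0 the reconstructed-branch factor decays at
exactly rate d regardless of r), so the turnover prior acts through the
joint posterior on full datasets — by blocking high-turnover explanations
of deep roots — rather than through any per-tree monotonicity.  The
acceptance suite tests the posterior-level effect end to end.

### Character models

Morphology uses the Mk model: per character a k-state symmetric rate matrix
normalized to one expected change per unit effective length, with a shared
discrete-gamma (4 categories, mean-of-quantile-bin rates renormalized to
mean exactly 1) shape across all k-groups.  Matrices that contain only
variable characters trigger the ascertainment ("coding bias") correction:
per k-group, the likelihood is divided by (1 − P(constant)) per character,
with P(constant) computed by pruning the k constant patterns through the
same gamma mixture.  Missing states contribute partial likelihood 1; state
codes are matrix-specific.

DNA partitions (codon positions and UTR in the emulated design) each carry
a GTR + Γ(4) + invariable-sites model.  Exchangeabilities are fixed (no
reversible-jump averaging over exchangeability partitions) and stationary
frequencies are fixed at their empirical values; the gamma shape and the
invariable proportion are sampled.  The invariable class is a two-component
mixture applied to molecular partitions only.  Per-partition rate
multipliers (weights proportional to character counts, weighted mean
constrained to 1) have a scaled-Dirichlet prior with flat concentration.

Likelihoods use Felsenstein pruning with per-node rescaling of partial
likelihoods; patterns are compressed per partition/k-group and transition
matrices for all branches and rate categories are built in one vectorized
step per evaluation.  The pruning path is verified against exhaustive
state-enumeration oracles to 1e-8 and better.

### Clocks

Effective branch lengths (expected changes per character) come from a
strict clock, v_b = c·t_b, or the independent-gamma-rates (IGR, white
noise) relaxed clock, v_b ~ Gamma(shape t_b/ν, scale c·ν), so
E[v_b] = c·t_b and Var[v_b] = c²·ν·t_b: the branch-average rate's variance
shrinks as 1/t_b.  The clock rate c has a lognormal(−6.0, 0.5) prior on the
natural-log scale; its central (median) rate exp(−6) ≈ 0.25%
substitutions/site/Myr (the arithmetic mean would be exp(−6 + σ²/2) ≈
0.28%; the central-rate reading is adopted).  ν has an Exp(10) prior.
Morphological and molecular clocks may be linked (one set of effective
lengths) or unlinked (independent c, ν and lengths on the shared dated
tree).

## The sampler

Metropolis-coupled MCMC with incremental heating β_i = 1/(1 + 0.1·i)
(4 runs × 4 chains in the headline configuration; desk-scale tests use
fewer), sampling the cold chain every `sample_every` generations and
discarding 25% as burn-in.  Each generation attempts one *structural* move
(node-age slide; root slide; whole-tree age scale compensated by the clock
rate; joint clock-rate/branch-effect scale; narrow exchange; fossil-subtree
SPR; per-branch effect updates; site-model and partition-rate moves) and
one *cheap* hyperparameter move (d, r, f, c, ν), since the latter touch
only closed-form prior terms.  Weakly-identified coordinates additionally
use independence proposals from their own priors, which cancel in the
acceptance ratio and mix well when the data are uninformative.

The fossil SPR detaches a maximal fossil-only subtree and reattaches it to
a uniformly chosen feasible slot at a uniformly chosen feasible age; an
"above the root" slot with a shifted-exponential age proposal keeps the
move ergodic across root-adjacent attachments, and branch-set changes under
the IGR clock draw new branch effects from the prior with the proposal
densities absorbed into the Hastings ratio.  The two compensated scale
moves exist because the IGR prior at small ν binds ages, effects and the
clock rate into razor-thin ridges that single-coordinate moves traverse
extremely slowly.

The log posterior is held as named components with dirty-flag recomputation;
every `check_every` generations the cold chain's cache is compared against
a full recomputation at 1e-6 relative tolerance and any drift raises.
Prior-only ("induced prior") sampling forces the character log-likelihood
to zero while fossil ages, constraints and hyperpriors still act; its
correctness is tested against direct simulation and quadrature oracles.
Convergence diagnostics report per-parameter ESS and between-run
rank-normalized PSRF (via ArviZ) plus across-run clade-frequency standard
deviations, flagging PSRF > 1.05.

## Synthetic data

The generator emulates, at desk scale, a eutherian-like total-evidence
design: an FBD tree simulated forward (exact Gillespie from two root
lineages), diversified sampling of ~20 exemplars out of a much larger
standing diversity (realized ρ well under 5%), a handful of fossil tips,
variable-only morphology (rejection sampling until the requested number of
variable characters accumulate, matching the Mkv conditioning), partitioned
DNA under the IGR clock, and an injected block of convergent characters.
Default generating values: d = 0.08, r = 0.5, f = 0.4, root age 90 Ma,
clock rate exp(−6), ν = 0.05, 300 morphological characters (80% binary,
20% three-state), 2000 sites in four partitions.  f = 0.4 was chosen once
so that the expected number of retained fossil tips (~5–8) matches the
scaled design; the DRA scenario requires at least `min_fossils` retained
fossils and redraws otherwise.

Because fossils are terminal tips, a ψ-sample with sampled descendants on
its own lineage is unrepresentable.  The density oracles condition on such
events not occurring (`sa_policy="reject"`); the scenario generator instead
*drops* conflicting marks (`sa_policy="drop"`), emulating a fossil pool
thinned to finds that terminate their lineages.  This makes the generator's
fossil recovery slightly sparser than its nominal ψ, which biases f
estimates down but leaves ages, clock and d essentially calibrated (the
coverage experiment bears this out).

Convergent blocks share one simulated event history on an "ecotype" tree
whose clades are the (randomly drawn) ecological groups, with long group
stems and near-zero within-group branch lengths: every character in a block
is a shared derived state of the ecotype groups up to state relabelling.
This is the simplest generative mechanism producing the correlated-homoplasy
signature that misleads independence-assuming morphological models; it does
not emulate directional evolution, body-size-correlated rates, or partial
character correlation.

What passing tests do and do not show: the calibration and DRA experiments
demonstrate internal coherence (the sampler targets the stated posterior,
and the documented biases appear and are corrected under the stated
misspecifications).  Real morphological data violate Mk exchangeability and
character independence in richer ways than the injected blocks, so effect
sizes on real data may differ; the qualitative orderings are the claim.

## Desk-scale problem sizes

The reference analyses behind the acceptance script and tests use a
12-exemplar conflict scenario (~11 fossils, 160 morphological characters
including the convergent blocks, 600 sites) at 6000 generations per chain
with two pooled runs for the preset comparisons, companion conflict-free
scenarios for the tip-sampling misspecification checks, and a calibration
experiment of prior-drawn replicates (6 extant + ≥2 fossils, 24
morphological characters + 120 sites, two pooled runs of 4000 generations,
strict clock, topology fixed at truth).  Sizes were chosen so the entire
pipeline re-runs from scratch in minutes while leaving the statistical
checks (orderings, interval widths, coverage at binomial tolerance)
well-powered; topology is fixed at the generating tree in these experiments
because extant-topology mixing, not dating, would otherwise dominate the
run length.  The conflict-scenario comparisons pool two independent runs
per analysis cell because single-chain posterior medians at these lengths
still carry ~1–2 Myr of Monte Carlo noise, comparable to the hyperprior
effects being measured.  Full-size eutherian analyses (74 taxa, 41 k
characters, 10–30 M generations) are outside this package's scope.

## Known limitations

* No sampled ancestors; no fossil age uncertainty; no node calibrations.
* GTR exchangeabilities and stationary frequencies fixed during MCMC.
* Narrow exchange is the only extant-topology move, adequate for the tree
  sizes used here but slow for large unconstrained topology spaces.
* The diversified-sampling density treats x_cut as the youngest sampled
  split of the current state; datasets whose fossils are younger than the
  cutoff are rejected at input rather than modelled.
* The uniform-prior polytope volume is exact but scales poorly beyond a few
  hundred taxa (piecewise polynomial degree grows with tree size).
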