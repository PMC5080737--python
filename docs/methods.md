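# Methods

## Model structure

A host individual is a pair (GRN, receptor sequences).  The GRN is a real
matrix `W ∈ R^(N × N_TF)` with `N = N_TF + N_R` (defaults 5 + 5): row *i* is
the cis-regulatory region of gene *i*, and only transcription-factor (TF)
products regulate.  Rows 1..N_TF are TF genes, the rest receptor genes.
Expression is the discrete map `S(t+1) = Sig(W·S_TF(t))` with the steep
sigmoid `Sig(x) = 1/(1+e^(−100x))`; 0.5 is basal (unregulated) expression.
The phenotype is the binarized steady state (`on` iff expression > 0.5).
Each receptor gene owns a binary binding-site sequence of length `L`
(0 = polar, 1 = hydrophobic residue); a virus is one such sequence.  Binding
requires the percentage of positionwise matches to *strictly exceed*
`ε_seqM` (default 90 %).  Strictness matters: at `L = 10` and 90 % it forces
a perfect match, so an inclusive (`>=`) policy flag exists for sensitivity
analyses but is off by default, following the "exceeds the threshold"
convention.

## Steady-state criterion

The expression map is declared converged when the maximum absolute
elementwise change stays below `1e-4` for 10 consecutive updates, within 100
updates overall; non-converging genotypes are inviable.  These three
numbers are exposed in the configuration (`stability_tol`,
`stability_window`, `max_expression_steps`).  The initial state `S(0)` is a
random binary vector drawn once per founder and reused for all descendants
— phenotypes, and therefore selection, are defined relative to a common
input condition.

## Mutation model

One candidate GRN mutation event occurs per offspring matrix with
probability `μ = 0.1`: a uniform entry is chosen; zero entries become fresh
Normal(0,1) draws with probability `ρ` (addition), nonzero entries are
zeroed with probability `φ` (deletion) or redrawn otherwise (`δ = 1 − φ`,
modification).  With `ρ(1−c) = φc` the expected density drift is zero; the
defaults `ρ = 0.028, φ = 0.042` balance at the founder density `c = 0.4`,
and `GRNMutationRates.balanced()` solves the constraint for other
densities.  Host protein mutation is one Bernoulli(`μ_hp`) event per
offspring flipping a single uniformly chosen (receptor, site) pair — the
minimal reading of a rate quoted "per set of receptors"; an independent
per-site mode exists behind a flag.  Virus protein mutation is one
Bernoulli(`μ_vp = 0.1`) single-site flip per contact, applied to a *copy*
of the carried virus, so repeated contacts by the same infected host try
fresh variants.

## Burn-in and selection

The run starts from `M_init = 150` clones of a viable founder (exactly
`round(c·N·N_TF)` nonzero weights; receptor sequences independent and
mutually distinct — a homogeneous receptor set would make every receptor a
target of the same virus and the run degenerate).  For 500 steps the
population is replaced each generation by `M_init` accepted offspring of
uniformly drawn parents (sexual by default: each gene row, together with its
receptor sequence, comes from a random parent — free recombination).
Acceptance requires stable expression, at least `N_ER` expressed receptors,
a phenotype within Hamming distance 1 of the founder's, and a
Bernoulli(`e^(−D/σ)`) survival trial on the mean per-site L1 receptor
distance `D` from the founder (`σ = 0.1`).  Filters run cheap-to-expensive;
the order does not change the accepted distribution.  Stabilizing selection
is lifted when the viruses are introduced.

## Epidemic step

Each coevolution step applies, in order, with all event counts computed from
start-of-step `S, I, N` (synchronous with the difference-equation form):
births (`b·N(1−N/K)` viable candidates, each surviving with probability 1,
`(k_I+1)/2`, or `k_I` by parental infection status), contacts
(`(r/N)·S·I` uniform susceptible–infected pairs; a host infected mid-step
immediately leaves the susceptible pool), recoveries (`γ·I`, virus
dropped), then natural (`λ_N·S`, `λ_N·I`) and disease (`λ_D·I`) deaths
drawn without replacement from the post-recovery pools.  Continuous rate
terms become integer counts by stochastic rounding (floor + Bernoulli on
the fraction), which is unbiased; plain rounding is a config option.  The
per-step ledger records every count plus the emergent
`ξ = infections/contacts` (0 recorded when there were no contacts, and such
steps are excluded from steady-state averages) and `η = survivors/
candidates` (1 when there were no candidates).  A frozen-rate skeleton
(`simulate_frozen_sis`) replaces the genotype layer with fixed `ξ, η`; its
trajectory settles within a few percent of the closed-form steady state,
validating the discretization.

## Founder viruses and seeding

Founder viruses are copies of a random host's expressed receptor sequence,
passed once through the virus mutation operator.  Two founders by default;
the diverse-founder experiment instead builds three viruses per receptor
index (15 in total) so that every receptor starts targeted.  Each founder
virus is seeded by contacting random susceptibles (without the on-contact
mutation) until it binds one, capped at `10·M_init` attempts; a virus that
binds nobody simply fails to establish, which is a legitimate outcome of
the copy-then-mutate construction at strict thresholds.

## Measurement protocol

Targeting is measured at every 50th step: the receptors matched by the
hosts newly infected *at that step*.  The Gini coefficient (sorted-ascending
form) is applied to the mean per-receptor counts over these measurement
points; the multi-receptor frequency is the fraction of measurement points
whose newly infected hosts cover two or more distinct receptors.  Snapshot
sampling — rather than accumulating over whole 50-step windows — is
deliberate: it is what makes the statistic insensitive to the short initial
transient in which several founder strains coexist, and a window-union
variant remains available (`mode="window"`).  Resistance strategy is
tallied per step among hosts that survived a contact: those not expressing
the step's most-targeted receptor count as network-level (rewiring)
resistance, the rest as protein-level; ties among co-leading receptors
contribute their mean.  Runs whose mean population does not exceed
`M_init` are flagged and excluded from resistance-strategy aggregation.

The perturbation assays redraw every nonzero interaction 50 times
(modification-type only — the assay quantifies over *existing*
interactions): a perturbation counts as resistance only if the new
phenotype is stable, still expresses `N_ER` receptors (the escape must be
viable) and no longer binds the challenging virus; perturbations that break
convergence count as failures.  The protein-level assay flips each site of
a matched receptor independently at `μ_hp` — using the in-simulation rate
rather than a fixed single flip keeps the assay's difficulty scaled to `L`.
The multi-switch assay scores perturbations flipping the expression of more
than one gene; in the no-regulation null model (identity TF block, receptor
diagonal present with probability 0.7, mutations confined to that diagonal)
this is exactly zero, which the tests assert.  Assays are off by default in
`run_simulation` (they dominate runtime) and enabled with
`potential_assays=true`.

## Defaults and key parameters

All population and genotype parameters default to the standard condition
set: `L = 10`, `μ_hp = 0.01`, `μ_vp = 0.1`, `N_TF = N_R = 5`,
`ε_seqM = 90 %`, `k_I = 0.8`, `K = 1000`, `M_init = 150`, `b = 0.15`,
`λ_N = 0.09`, `λ_D = 0.06`, `γ = 0.2`, `r = 2`, `c = 0.4`, `μ = 0.1`,
`ρ = 0.028`, `φ = 0.042`, `σ = 0.1`, `a = 100`; burn-in 500 steps,
coevolution 500 steps, measurements every 50.  `N_ER` defaults to 1 (full
functional redundancy: any single expressed receptor sustains the host).
This choice was genuinely open — reference analyses exist for both
`N_ER = 1` and `3` — and was made on phenomenological grounds: with
`N_ER = 3`, founders typically express exactly three receptors, switching
any targeted receptor off is lethal, and regulatory escape is structurally
blocked, which contradicts the serial strain-extinction dynamics the model
is meant to exhibit.  Analyses that require `N_ER = 3` (e.g.
resistance-potential comparisons) set it explicitly.

## What the simulations do and do not show

All data are generated internally; there is no real sequence content.  The
binary hydrophobic/polar code, single-site mutations and positionwise
matching abstract away alignment, substitution biases and structure, so
agreement of the package's statistics with reference values supports the
*population-genetic logic* (specialization with binding complexity, the
balance of resistance levels), not any molecular detail.  Typical healthy
runs at high `L` end with the virus extinct; the steady-state
transmissibility is then undefined and reported as missing, never as zero.
Run-level outcomes are strongly bimodal (host victory vs population
collapse), so replicate means converge slowly; the acceptance script uses
20 replicates per condition (the reference design used 100) and reports the
number of included runs alongside each value.

## Numerical and degenerate-input conventions

The sigmoid is computed in its two stable branches (no overflow at any
weight magnitude).  Gini of an all-zero vector, Margalef of fewer than two
individuals, transmissibility of an all-zero-contact window, and rewiring
preference without resistance events are all `nan` (missing), never 0.
Modification redraws reject values exactly equal to zero or to the old
weight (probability-zero events, handled for formal compliance).  The RNG
is a single seed split into named sub-streams (burn-in / epidemic / assays),
so enabling the assays never perturbs the simulated trajectory, and
replicates use `SeedSequence`-derived child seeds below 2^31.

## Known limitations

No spatial structure, diploidy, coinfection, latency or immune memory; one
virus per infected host; no TF–DNA or protein–protein interaction sequence
model for the regulatory network itself.  The discretization resolves at
most one recovery/death event per host per step, and simultaneous-event
collisions are resolved by drawing deaths from post-recovery pools.  The
coevolution-phase length (500 steps) is a package choice exposed in the
configuration; statistics that accumulate over measurement points (Gini,
multi-receptor frequency) weight the early epidemic more heavily in shorter
phases.
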