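# Methods

This note documents the models and procedures `cogem` implements, the
parameters that matter, what the synthetic data emulate, and the design
choices made where the design was genuinely open. It states no empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## Constraint-based core

Models are `cobra.Model` objects; flux units are mmol·gDW⁻¹·h⁻¹. FBA
maximizes (or minimizes) the declared biomass reaction subject to
steady-state mass balance S·v = 0 and bounds lb ≤ v ≤ ub; FVA computes
per-reaction flux ranges, optionally with the objective held at a fraction
of its optimum; single-reaction deletion flags a reaction essential when
the post-knockout optimum falls below `essentiality_tolerance` (default
0.01) times the wild-type optimum. Numerical tolerances: steady-state
residual 1e-6, bound violation 1e-9 — common constraint-based practice.
I/O is SBML Level 3 + FBC v2 (subsystems serialized as SBML groups, with
group members sorted so files are byte-reproducible) and cobrapy's JSON
dialect, which keeps fixtures hand-writable.

GPR scoring follows the E-flux convention: AND = min, OR = max over
non-negative gene scores. A gene missing from the score map is treated as
*unmeasured*: it is dropped from OR alternatives and makes any AND
containing it unmeasured; a reaction whose GPR cannot be scored keeps its
original bounds. Rationale: absent annotations should not silently zero
reactions.

## Host contextualization

`aggregate_expression` takes the arithmetic per-gene mean TPM over samples
(duplicate gene rows are an error — isoform aggregation belongs upstream);
`filter_active_genes` applies the strict TPM > 1 call. The extraction step
is a deliberately simple greedy core extraction, not a MILP
reconstruction: reactions whose GPR evaluates inactive are removed
(GPR-less and protected reactions, including the objective, are always
kept), then removed reactions are restored one at a time in descending
reaction-expression order until the objective is feasible again. This
preserves the qualitative contract of expression-weighted extraction —
feasible output, expression-ranked retention — at desk scale. E-flux then
caps bounds at ±B·ŝ where ŝ is the reaction score normalized by the 95th
percentile of measured scores (clipped to 1; "absolute" max-normalization
is available) and B is the default bound magnitude (1000). Normalizing by
a high quantile rather than the maximum keeps one outlier gene from
flattening every other reaction's cap.

`compare_models` reports structural reductions, GPR coverage, paired FVA
spans on shared reactions with a Wilcoxon test, and essentiality
difference sets. Both the signed-rank (default) and rank-sum variants are
exposed because either can be argued for a paired span comparison;
all-tied spans return p = 1 rather than an error.

## Joint-model assembly

`merge_models` implements the multi-species architecture with three
compartment layers: per-member extracellular `[e]`, a shared lumen `[u]`,
and a host-only body-fluid layer `[b]`.

- Every member is id-tagged (reactions, metabolites, genes, compartments);
  tagging preserves internal references and the FBA optimum.
- `create_interspace` adds, for each of a member's n extracellular
  metabolites, one shared lumen metabolite and one reversible transport
  `met[e] ⇌ met[u]` with coefficients −1/+1, so the new stoichiometric
  columns over the `([e]; [u])` rows are exactly `[−I; I]`.
- Microbial boundary exchanges are removed at merge: a microbe's only
  environment access is the lumen. The host's boundary exchanges are
  re-homed onto `[b]` (transport `met[e] ⇌ met[b]` plus an exchange on
  `met[b]` carrying the original bounds), representing systemic
  circulation; no microbe touches `[b]`.
- Each lumen metabolite gets a boundary exchange with efflux open and
  influx closed by default: the host is the sole supplier. The influx
  bound is configurable (`lumen_influx`) for diet-like scenarios.
- Futile-cycle pruning: with every boundary exchange closed, any
  interspace reaction that can still carry flux (by FVA) sits on a
  net-zero circular transport loop; for each flagged lumen metabolite,
  microbial interspace reactions are made uptake-only and the host's
  secretion-only. A restriction that moves any member's biomass optimum by
  more than 1e-6 is reverted for that metabolite, so pruning never costs
  growth.

Co-metabolite identification certifies flux capability by FVA on the
joint model: a lumen metabolite is a *co-metabolite* when the host
interspace reaction can carry secretion flux and ≥1 microbial interspace
reaction can carry uptake flux; otherwise it is *host-specific* if the
host side can carry any flux, else *microbe-specific*. The three classes
partition the lumen.

The pipeline's default mode is host-single-strain: one pairwise joint
model per microbe rather than a single many-member model, which isolates
host-driven effects from inter-microbe competition. An all-member merge is
available but is not the default procedure.

## Flux sampling

`achr_sample` is a self-contained artificial-centering hit-and-run
sampler. Warm-up points are vertices obtained by minimizing and maximizing
each reaction (then random dense objectives, up to `n_warmup`, default
min(2·reactions, 2000)), solved with HiGHS through `scipy.optimize.linprog`.
The chain starts at the warm-up centroid; each step picks a random warm-up
point, walks along the direction from the running centre through it,
computes the feasible chord from the bounds alone (directions are
differences of steady-state points, hence lie in the null space of S) and
steps uniformly within the chord. The running centre is the incremental
mean of all points seen. Every `thinning`-th point is retained until
`n_samples` rows exist. The chain point is re-snapped onto the null space
every 50,000 steps to keep the steady-state residual at solver level.
Defaults follow standard flux-sampling practice for converged
distributions: n_samples = 10,000 with thinning 100; the synthetic-study
conditions scale this to n = 2000, thinning 10 (see below). Unbounded
polytopes are rejected with the offending reactions named, since uniform
sampling is undefined there; the warm-up phase is the burn-in (recorded in
the sample's provenance). Sampling is bit-for-bit reproducible given
(model, config, seed); per-stage seeds are derived from the global seed by
a keyed blake2 hash.

Sampling for the differential stage runs on the **member submodel**: the
strain's reactions, its interspace transports (ids and bounds exactly as
in the joint model, so restrictions carry over), and one lumen exchange
per touched metabolite whose influx is capped at the host's maximum
secretion flux (FVA on the joint model). This matches the procedure of
sampling individual bacterial models under joint-model supply, and it is
also what makes the statistics well-behaved at desk scale: the bacterial
polytope (~20–40 dimensions) mixes to ~1–3% chain-to-chain error on the
biomass mean at n = 2000 × thinning 10, whereas the full joint polytope
(~100+ dimensions, dominated by host flux dimensions that are irrelevant
to the strain) leaves ~25% noise at the same budget.

## Differential analysis

A restriction scenario sets lb = ub = 0 on the strain's interspace uptake
route for one co-metabolite — a binary loss-of-supply model, not a
concentration gradient. Per reaction, restricted vs unrestricted samples
are compared with the two-sample KS test (asymptotic two-sided p); BH-FDR
is applied across the scenario's reactions; the normalized flux change
FC = (S_R − S_U)/|S_R + S_U| of the mean fluxes is thresholded at
|FC| ≥ 0.82 (a 10:1 flux ratio gives FC = 9/11 ≈ 0.818); and a percentile
bootstrap 95% CI of the mean flux difference must exclude zero. A
reaction is *significant* only under the conjunction of all three
filters — the three criteria are order-independent as a conjunction.
Reactions absent from one condition are treated as constant-zero there.
Since the two conditions are sampled by independent chains, the
per-sample differences are paired after rank alignment (sorting both
margins), which leaves the mean difference untouched while coupling the
quantiles. FC edge cases: both means zero gives FC = 0; a vanishing
denominator with unequal means is replaced by ε = 1e-12 and the result
clipped to ±1e12, detectable via `flux_change_is_degenerate`.

Biomass effects are classified per (strain, co-metabolite): *blocked*
when the post-restriction mean biomass flux is below 1e-9; *reduced* when
the KS test is significant **and** the mean drops by at least
`min_relative_drop` (default 20%) of the pre-restriction mean; otherwise
*unchanged*. The effect-size guard plays for the biomass call the role
the FC threshold plays for ordinary reactions: two finite Markov chains
from the *same* polytope differ detectably by KS alone (autocorrelation
makes the test anti-conservative), and a pure significance rule would
misclassify null restrictions. Monte-Carlo noise on the biomass mean is
1–3% under the default sampling budget; planted partial dependencies drop
>90%, so the 20% guard sits well clear of both. Key co-metabolites are
those with ≥1 non-unchanged member, reported with their affected-member
lists and effect classes.

## Subsystem enrichment

With N background reactions, K in a subsystem, n significant, and k
significant in the subsystem, the point mass P(X = k) and the upper tail
P(X ≥ k) are computed via `scipy.stats.hypergeom` (log-space internally);
out-of-support arguments return 0 with a warning. The default enrichment
criterion is the upper tail — standard over-representation practice —
with the literal point-mass criterion available as `mode="point"`; both
probabilities are always reported, and BH-FDR is applied across
subsystems. The background N is the member model's full reaction count
including exchange and interspace reactions, configurable via
`exclude_subsystems` to drop transport classes. Unlabelled reactions pool
into an `unassigned` subsystem.

## Synthetic data

The generators emulate the *shape* of the real inputs, not their content:

- **Host**: cytosol + extracellular compartments; a diet carbon input
  routed through a linear core chain into biomass; biosynthesis and
  secretion routes for a panel of metabolites (default names echo common
  gut co-metabolites: glc, ac, succ, cl, fe2, fe3, zn2, so4, glyc,
  ribflv, thm, fol, ...); ≥60% GPR coverage from a configurable gene pool.
  Each biosynthesis route is capped at 50 mmol·gDW⁻¹·h⁻¹, far below the
  diet intake bound, so no global resource constraint couples unrelated
  pathways — this keeps a decoy's flux subspace exactly independent of
  the biomass subspace in the joint model, which is what "restriction of
  a decoy changes nothing" means distributionally.
- **Microbes**: glucose catabolism into an energy carrier feeding biomass;
  planted *hard auxotrophies* enter the biomass stoichiometry with no
  internal synthesis route (restriction ⇒ zero growth); *partial
  dependencies* feed biomass through a precursor that a low-capacity
  glucose bypass (0.3 mmol·gDW⁻¹·h⁻¹ vs uptake bounds of 10) can also
  supply (restriction ⇒ reduced growth); *decoys* are degraded to a
  secreted waste product (restriction ⇒ nothing). A three-step pathway
  consuming the first planted dependency carries the designated
  "planted-enriched" subsystem label, so restricting that metabolite
  silences a whole subsystem. Planted classes are verified at generation
  time by FBA under restriction, standalone and in the pairwise joint
  model.
- **Expression**: log-normal TPM with per-gene log-means ~N(log 30, 0.8)
  for active genes and ~N(log 0.05, 0.5) for inactive ones, multiplicative
  per-sample noise (σ = 0.3) — wide separation around the TPM = 1 calling
  threshold, so the planted active fraction is recovered up to boundary
  noise. Real expression data differ in every distributional detail;
  what passing tests show is that the *calling and contextualization
  machinery* behaves correctly, not that the noise model is realistic.
- **Standard community**: 5 microbes, 12-metabolite secretable panel,
  3 planted key co-metabolites (fe3 hard for two strains, fol hard for
  one, thm partial for two) and 2 decoys (ac, glyc) degraded by all. The
  carbon source is excluded from the restriction panel: it is the
  growth-limiting control substrate, and restricting it would trivially
  block every strain. Differential sampling runs at n = 2000, thinning
  10 — sized so the full 10-seed recovery study completes in minutes on
  one CPU while the per-scenario Monte-Carlo error stays at the few-
  percent level.
- **Enrichment fixture**: 200 abstract reactions over 8 subsystems with a
  60-reaction significant set drawn with 5× selection weight for the
  planted subsystem. Sizing is a design-time power choice: at these
  dimensions the planted subsystem receives ~19 of 60 hits against a null
  expectation of 7.5, which the upper-tail test detects essentially
  always, while the factor-1 null stays at the nominal false-positive
  rate.

Fixtures are deterministic functions of (seed, parameters) down to the
byte level of their saved files.

## Known limitations

- The greedy extraction is not a MILP reconstruction; it can restore more
  reactions than the minimal feasible set when expression ties are
  adverse.
- ACHR is an approximate uniform sampler (non-Markovian centring); the
  test suite checks its marginals only on polytopes with known closed
  forms and its validity (steady state, bounds) everywhere else.
- The KS test's independence assumption is only approximately met by
  thinned chains; the screening conjunction (effect-size threshold and
  bootstrap CI on top of the KS p) is what carries the error control in
  practice.
- Toy stoichiometry makes no biological-realism claims; panel names are
  mnemonic labels, not curated chemistry. Conclusions about real
  host–microbiome systems require real GEMs and expression data plugged
  into the same interfaces.
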