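# Methods

## Model and objective

`exprflux` predicts steady-state fluxes in a multi-tissue, diel
constraint-based metabolic model by weighted flux minimization:

```
min Σ_j c_j |v_j|   s.t.   S v = 0,   LB_j ≤ v_j ≤ UB_j,
                           v_biomass(tissue, phase) = fixed value
```

The model is assembled by replicating a single-tissue core network once
per (tissue, phase) pair — reaction ids are namespaced
`<core_id>__<tissue>__<phase>` so the mapping back to the core is
reversible without a lookup table — and wiring the copies with *linker*
reactions: inter-tissue transporters (phase-preserving) and diel
carry-overs (tissue-preserving, e.g. starch day→night). Linkers are
ordinary irreversible reactions declared in the build config, not
special cases, because the set of shared metabolites is a property of
the biological system being modeled, not of the algorithm. Whole-plant
exchange placement (which tissue takes up CO₂, photons, nutrients) is
likewise config-driven.

Two assumptions underlie the method: (i) low-total-flux maps are closer
to real flux distributions than arbitrary feasible maps, and (ii) a
reaction catalysed by genes that are highly expressed in tissue A and
poorly expressed in tissue B more likely carries flux in A.

## Penalty weights

For gene *i* with abundances E_i across tissues, the weight in tissue
*t* is `W_it = max(E_i)/E_it ≥ 1`; the gene's most-expressing tissue
gets exactly 1. Because the weight is a ratio within one gene's row,
any per-gene rescaling cancels — only relative abundance across tissues
matters, so TPM-like and IBAQ-like inputs behave identically, and the
two phases of a tissue share the same weight (tissue atlases have no
diel resolution).

Gene weights are folded through the reaction's GPR tree: OR nodes
(isozymes) take the arithmetic mean of their children, AND nodes
(complex subunits) take the maximum — the "worst" (most penalizing)
subunit limits the complex. Stoichiometric coefficients inside GPRs are
ignored. The grammar gives AND precedence over OR; an unparenthesized
mixed rule parses but logs a warning. A single scaling factor maps the
combined base weight w_R to the objective coefficient
`c_R = SF·(w_R − 1) + 1`, affine in SF with intercept 1, so SF = 0
recovers pFBA exactly and SF interpolates continuously toward full
expression weighting.

Parameters that matter, with defaults:

| parameter | default | meaning |
|---|---|---|
| SF | 1.0 | strength of the expression signal; 0 = pFBA. Errors typically plateau beyond ~0.1–1 |
| `w_max` | 1000 | cap for W_it when E_it = 0 but the gene is expressed elsewhere: strongly penalized, never forbidden (avoids infinities) |
| GPR-less policy | `unit` | reactions with no GPR (or no evidence) get c = 1; `tissue_median` instead assigns the median *base* weight of the GPR-weighted reactions in the reaction's home tissue, then applies SF — taking the median pre-scaling keeps SF = 0 ≡ pFBA under both policies |
| FVA objective tolerance | 1e-6 (relative) | slack defining the near-optimal face |
| fixed biomass flux | 0.01 per tissue and phase | arbitrary anchor; its unit mismatch with mmol-scale fluxes is absorbed by the normalization factor A |

Degenerate-input rules: a gene with an all-zero row carries no relative
evidence and is treated as *absent* (dropped from its GPR node, a node
with all-absent children is itself absent); a gene present in the model
but missing from the dataset is handled the same way. A reaction whose
genes are all absent falls back to the GPR-less policy. Linker
reactions inherit the policy of a declared home tissue (default: their
source tissue); whole-plant reactions always get 1.

## Optimization

The absolute value is linearized by splitting every reaction — exchanges
included, so their weights penalize magnitude symmetrically — into
nonnegative halves v = v⁺ − v⁻ sharing c_j, with half-bounds
`v⁺ ∈ [max(LB,0), max(UB,0)]`, `v⁻ ∈ [max(−UB,0), max(−LB,0)]`. The LP
is solved with scipy's HiGHS interface; `highs-ds` and `highs-ipm` are
exposed as alternative backends and agree to ≤1e-5 relative on the test
fixtures. Ratio constraints (v_a = r·v_b, used e.g. for
starch:sucrose synthesis or the RuBisCO vo/vc ratio) are materialized as
auxiliary balance rows via pseudo-metabolites rather than bound
manipulation, which is exact at any flux magnitude and makes scenario
application idempotent (deterministic row ids, overwritten on
re-application).

Alternate optima are the norm, not the exception: the reported point
solution is whichever vertex the solver returns (deterministic for a
fixed input ordering), and uncertainty is quantified by FVA —
per-reaction min/max net flux subject to
`Σ c_j|v_j| ≤ (1 + tol)·optimum`, with a tiny absolute slack floor so
the face stays nonempty when the optimum is near zero.

## Error evaluation against MFA

MFA studies report fluxes of lumped steps, so each measured flux v_m is
paired with a signed linear combination of model reactions. Model
fluxes are rescaled once by `A = measured net CO₂ uptake / model net CO₂
uptake` (computed from the incumbent optimum and held fixed during FVA
bounding — normalization is a single post-hoc rescaling, not a per-vertex
fit). The summary statistic is

```
error% = 100 · Σ_j |A·v_j^p − v_j^m| / Σ_j |v_j^m|
```

which is algebraically identical to the |v_m|-weighted mean of the
per-flux percent errors; weighting prevents tiny measured fluxes from
dominating. Deviations and measured fluxes enter in absolute value so
the error is nonnegative. Entries with v_m = 0 are flagged in the
per-flux table (no division) but still contribute their deviation to
the aggregate numerator.

FVA error bounds use interval arithmetic over the combo's component
ranges: the minimum takes the in-interval point nearest v_m, the maximum
the farthest endpoint. Component independence is assumed, which widens
the bounds (conservative) when combo reactions co-vary; the
nearest-point/farthest-endpoint rule is isolated in one function
(`evaluation.error_bounds`) so alternative aggregations can be swapped
in.

Physiology summaries — RuBisCO carboxylation / net CO₂ assimilation,
photorespiratory CO₂ loss %, cyclic/linear electron flow %, and %
of daytime leaf assimilation incorporated into biomass (via
per-reaction carbon counts) — are computed from editable named reaction
sets, because which model reactions constitute e.g. CEF vs LEF is a
property of the specific reconstruction. Daytime-only metrics are
expressed by listing daytime replicas in the set config. Zero
denominators flag the metric as undefined rather than raising.

## Synthetic data generator

`make_toy_plant` emulates the structure of the real use case at desk
scale: a leaf that fixes CO₂ with photon-driven ATP by day, sucrose
export to sink tissues in both phases, a starch day→night carry-over,
fixed biomass of 0.01 per tissue and phase, a starch:sucrose synthesis
ratio constraint consistent with the planted fluxes, and a biomass
precursor chain with parallel routes:

* **isozyme segments** (OR GPRs, default 2): two equal-cost routes whose
  genes are co-expressed in every tissue; the planted truth splits flux
  50/50. Every LP vertex pays the same irreducible error against this
  split, so the pFBA optimal face is nontrivial but no solution's score
  depends on arbitrary vertex selection.
* **resolved segments** (default 2): the true route in one seeded
  "carrier" tissue is two reactions long (AND-form complex GPRs), the
  alternative a single reaction (OR isozyme pair). Plain flux
  minimization always takes the short route and is deterministically
  wrong in the carrier tissue; the expression signal corrects it once
  SF·(w − 1) + 1 exceeds the long route's cost of 2, i.e. for SF above
  roughly 1/(w − 1) ≈ 0.1 — reproducing at fixture scale the observation
  that the benefit of weighting appears only for non-negligible scaling
  factors.

Expression values are drawn log-uniformly on [1, 1000]; genes of a
planted route are then set, in the tissues that carry it, to 10× their
row maximum. Applying the boost to the row maximum (rather than to the
tissue's own draw) guarantees the carrying tissue is the gene's peak
with at least a 10-fold margin, making truth recovery a property of the
construction instead of a draw-dependent event. Values are rounded to
3 decimals for platform-stable file output. The derived MFA comparison
measures the chain routes per tissue plus the major backbone fluxes —
including photon uptake and linear electron flow, so negative controls
that reroute ATP synthesis through the inefficient cyclic path are
penalized. By construction the planted map satisfies S·v = 0 and all
bounds, and scores 0 % error at A = 1 with zero noise;
`perturb_mfa` adds uniform multiplicative noise for robustness studies.

What the generator does **not** emulate: realistic transcript/protein
abundance distributions, transcriptional regulation, measurement
covariance between MFA fluxes, thermodynamic infeasibility of loops, or
genome-scale network size. Passing tests therefore demonstrate the
correctness and the qualitative behaviour of the algorithm (signal
recovery, control degradation, monotonicity), not its quantitative
accuracy on real plant data.

## Study sizes used in tests and the acceptance script

The shipped study conditions are a 3-tissue × 2-phase model (~130
replicated reactions, 40 MFA-paired fluxes), 20 generator seeds for the
recovery study, 20 permuted-weight negative controls per fixture, and
the scaling-factor grid {0, 0.01, 0.05, 0.1, 0.25, 0.5, 1, 2}. These
sizes exercise every code path while keeping a full pipeline run in
seconds on one CPU.

## Known limitations

* Interval-arithmetic error bounds over-cover when combo reactions
  co-vary on the optimal face.
* The point solution on a degenerate face is solver-determined; only
  the FVA bounds are solver-independent.
* GPR semantics are purely boolean (mean/max); enzyme abundance
  stoichiometry within complexes is ignored.
* The tissue-median GPR-less policy uses base weights pre-scaling; with
  extremely skewed weight distributions the median may be dominated by
  capped (w_max) values.
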