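# Methods

## Problem setting

A chemostat at dilution rate D holds any persisting strain at growth rate
v_growth = D. All strains — ancestor, producer, consumer — are modeled on
one stoichiometric network at steady state (S·v = 0, l ≤ v ≤ u). Strains
differ only in the boundary constraints imposed on them: which carbon they
may take up, what they must excrete, and how much. The package's central
quantity is the minimal number of internal reactions whose steady-state flux
must differ between two strains, used as a parsimony proxy for evolutionary
accessibility.

Sign convention: exchange flux < 0 is uptake, > 0 is secretion. Uptake caps
in configurations are stated as positive magnitudes and applied as negative
lower bounds. Reversibility lives solely in the bounds (lb < 0); reactions
are never duplicated at the model layer, and flux splitting happens only
inside the pFBA optimizer.

## Environments

`ChemostatEnvironment` encodes a minimal medium: all exchange uptake closed,
a configurable set of non-limiting inorganic exchanges opened at ±1000
mmol gDW⁻¹ h⁻¹ (the conventional "unbounded" magnitude of genome-scale
models), and the primary carbon exchange opened up to its cap (default 10
mmol gDW⁻¹ h⁻¹ for glucose). D defaults to 0.2 h⁻¹. Maintenance-type bounds
shipped with a model are left untouched; only carbon exchanges are
manipulated.

## Ancestral state

Parsimonious FBA: among flux vectors with v_growth = D (an equality, not
≥ D), minimize Σ|vᵢ|. Absolute values are realized by splitting each flux
into non-negative forward/reverse parts; the LP doubles in width but stays
sparse. The minimal total flux is the contract; individual fluxes of
degenerate alternate optima are advisory, and downstream code treats them
that way (distance objectives, not flux identities, are asserted).

## Distances

**ROOM.** One binary indicator per counted internal reaction; two linear
big-M rows per indicator with the big-M implied by the reaction's own
bounds, exactly as written in the README. Exchange and biomass reactions are
constrained but excluded from the objective: a strain that changes only its
boundary behavior at identical internal operation is at distance 0. The
MILP is solved to proven optimality (mip_rel_gap = 0); hitting a time limit
raises an error carrying the best bound rather than returning an unproven
incumbent. After the solve, indicators are rounded to {0,1} and the implied
constraints re-verified at 1e-6; at a true optimum every f = 1 reaction
moved by more than β (otherwise flipping it to 0 would improve the
objective), so the classified change count equals the objective.

**ROOM-het.** The reference a becomes a second flux-vector variable with its
own bound set. The coupling |eᵢ − aᵢ| ≤ β + Mᵢfᵢ uses
Mᵢ = uᵢᵉ − lᵢᵃ − β (and symmetrically for the other side), the tightest
valid big-M available from the two bound sets. With f ∈ {0,1} this is an
exact linearization of "fᵢ = 0 forces agreement within β". Because any
fixed ancestor satisfying the ancestor constraints is a feasible choice of
a, the ROOM-het optimum never exceeds the ROOM distance against such an
ancestor — a property the tests assert rather than assume.

**MoMA** (comparison method): minimize Σ(eᵢ−aᵢ)², a strictly convex QP
solved with SciPy's trust-constr on the sparse steady-state constraint; the
quadratic (standard) variant is implemented and labeled as such. Its change
count upper-bounds the ROOM distance by construction.

**β.** Default 0.001 mmol gDW⁻¹ h⁻¹; the classification threshold for
"active" flux uses the same magnitude. Distances are checked to be
non-increasing in β over {0.0002, 0.001, 0.005} and barely move across that
25-fold range on the bundled networks.

**Numerics.** HiGHS is asked for 1e-9 feasibility; every returned
distribution is re-checked at 1e-6 (|S·v| and bounds). The changed/unchanged
boundary |e−a| = β is evaluated with the same 1e-6 slack, so solutions
sitting exactly on the band edge are not spuriously counted. Alternate
optimal change-*sets* are expected; results flag the returned set as "one
optimal solution among possibly many", and only the distance is contractual.

## Strain construction

Producer: growth = D, excretion of the candidate metabolite fixed at
1 mmol gDW⁻¹ h⁻¹, glucose fixed (equality) at the minimal uptake compatible
with those two constraints, found by an LP maximizing the glucose exchange
flux. Consumer: growth = D, glucose uptake 0, candidate uptake fixed at its
minimal sufficient value — the same minimization applied symmetrically; a
variant fixes glucose at 1 mmol gDW⁻¹ h⁻¹ instead of 0. A metabolite that
cannot support growth as sole carbon source makes the consumer infeasible;
scans log and exclude it rather than aborting. Growth is an equality for
every role, consistent with the ancestral formulation.

Ranking: metabolites are ordered by total (producer + consumer) distance,
ascending; ties share the minimum rank (competition ranking — recorded in
the table attributes, since no convention is canonical). The glucose sweep
re-runs ROOM-het with the ancestor's glucose *capped* (not fixed) at each
grid value; the ancestral solution space grows monotonically along the grid,
so each distance is non-increasing — asserted, not assumed — and Spearman
rank correlations between consecutive grid points quantify ranking
stability.

## Gene mapping

Changed reactions map to genes through the GPR rules (union of leaf genes;
reactions without a rule are reported unmapped), then to operon and regulon
counts via user-supplied TSV tables — no public operon/regulon source is
bundled, so these are inputs. The expression-concordance rule (per reaction:
|e| vs |a| beyond β gives up/down; genes take the majority vote over their
reactions, ties and conflicts resolve to unchanged) is this package's own
explicit reconstruction; it is documented here precisely because it is a
design choice, not an imported convention. Per category, a two-sided Fisher
exact test on the 2×2 predicted-vs-observed table is used, with degenerate
tables reported as p = 1.

## Sequential emergence model

The consumer can only establish after the producer exists. The two-stage
model assumes per-generation establishment probabilities p = exp(−λ·d) for
each partner and sums two geometric waiting times; the closed form for
P(both by generation T) is checked against Monte-Carlo simulation in the
tests. λ defaults to ln(100)/57 ≈ 0.081, chosen once so that a producer at
the distance scale typical of genome-scale scans (~57 changed reactions)
establishes with probability ~1e-2 per generation; it is a free parameter,
and the module makes no claim to reproduce any particular published
functional form. On synthetic distance sets with genome-scale dispersion
(means/SD 57±15 and 62±17 reactions) the total distance and the model's
probability agree to |Spearman ρ| ≥ 0.9, which is the property the package
relies on when it uses the plain total as its ranking key.

## Synthetic networks and oracles

The bundled fixture is a deterministic 26-reaction, 17-metabolite
central-carbon caricature: glucose transport into a hexose pool, a lumped
glycolysis step, a TCA-like cycle with anaplerosis, a glyoxylate-like
shortcut and a gluconeogenic return, an overflow branch excreting an
acetate-like by-product (re-importable and assimilable, with CO2 released on
assimilation so the overflow branch is not a free bypass for the ancestor),
a second glycerol-like by-product off the pyruvate pool, a three-reaction
futile cycle, a biomass reaction drawing two precursors plus nitrogen, toy
GPR rules and operon/regulon tables. Growth at D = 0.2 requires 0.2 glucose;
the acetate-like producer/consumer distances are 3/8 and the glycerol-like
4/4. The random generator wraps a guaranteed-feasible backbone chain with
seeded extra reactions (a configurable fraction reversible), by-product
machinery, optional futile cycle, and Poisson-sized GPRs; a fixed seed gives
byte-identical output.

What the toys do not emulate: cofactor and energy balancing, elemental mass
balance, and genome-scale redundancy. Passing tests therefore demonstrate
the correctness of the optimization and bookkeeping machinery on exact
instances of the same problem class, not the biological accuracy of any
specific genome-scale prediction; genome-scale runs use the same code paths
but their numeric outcomes depend on the supplied model and metabolite
list.

`brute_force_min_change` is the independent oracle: it enumerates candidate
change-sets by increasing size and tests each with a feasibility LP (|eᵢ−aᵢ|
≤ β enforced outside the set; joint (a, e) variables for the heterogeneous
variant), sharing only the LP backend — not the MILP formulation — with the
optimizers it checks. It is exact up to its search limit and reports
exceedance rather than guessing. Problem sizes used in the default test and
acceptance runs: the fixture plus 10–20 random networks of ~10 internal
reactions with change-sets up to size 4, which exhaustively covers the
distances those problems actually have (except the acetate-like consumer at
distance 8, which is instead verified by MILP optimality plus the size-≤2
exceedance check). The Fisher-vs-hypergeometric comparison enumerates every
2×2 table with total n ≤ 18 and adds a seeded sample of 400 tables spanning
margins up to 50.

## Known limitations

* Changed-reaction identities (hence gene/operon/regulon counts and
  shared-reaction statistics) inherit MILP solution multiplicity; only
  distances are solver-independent.
* The consumer's secondary uptake is fixed at its minimized value by
  symmetry with the producer's glucose treatment; other conventions (e.g.
  capping instead of fixing) would change consumer distances.
* The expression-direction rule and the sequential-model functional form are
  explicit reconstructions (flagged in their modules' provenance).
* ROOM-het on genome-scale models is a large MILP; with the bundled
  open-source solver, full scans are hours-scale rather than minutes-scale.
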