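# crossfeed

Constraint-based prediction of how easily cross-feeding evolves in a
glucose-limited chemostat.

When an initially clonal *E. coli* population grows on glucose as the sole
carbon source, stable polymorphisms can emerge in which one strain (the
*producer*) excretes a secondary carbon source — acetate, glycerol, or in
principle dozens of other metabolites — and another strain (the *consumer*)
lives off it. `crossfeed` quantifies, on a genome-scale metabolic model, the
**minimal number of reactions that must change flux** for an ancestral strain
to give rise to the producer and the consumer of a candidate metabolite.
That count (the *metabolic distance*) is a parsimony proxy for how likely the
interaction is to evolve: fewer required changes, higher likelihood.

## The model

All strains share one stoichiometric network (S, an m×r matrix) at steady
state, S·v = 0 with per-reaction bounds l ≤ v ≤ u (fluxes in mmol gDW⁻¹ h⁻¹,
growth in h⁻¹). In a chemostat at dilution rate D the growth flux is pinned
at v_growth = D (default 0.2 h⁻¹).

* **Ancestral state** — parsimonious FBA:
  min Σᵢ|aᵢ| s.t. S·a = 0, l ≤ a ≤ u, a_growth = D.
* **Producer problem** — growth = D, excretion of the candidate metabolite
  fixed at 1 mmol gDW⁻¹ h⁻¹, glucose consumption fixed at the minimal amount
  compatible with both (found by an auxiliary LP).
* **Consumer problem** — growth = D, glucose consumption 0, uptake of the
  candidate metabolite fixed at its minimal sufficient value.
* **Distance (ROOM)** — a mixed-integer program with one binary fᵢ per
  internal reaction:

      min Σ fᵢ   s.t.  S·e = 0,  lᵢ ≤ eᵢ ≤ uᵢ,
                       eᵢ − fᵢ(uᵢ − (aᵢ+β)) ≤ aᵢ + β,
                       eᵢ − fᵢ(lᵢ − (aᵢ−β)) ≥ aᵢ − β,

  so fᵢ = 0 forces |eᵢ − aᵢ| ≤ β (β = 0.001 mmol gDW⁻¹ h⁻¹ by default) and
  the optimum counts the reactions that must change.
* **ROOM-het** — the same objective, but the ancestor flux vector *a* is a
  second variable with its own constraint set instead of a fixed reference;
  this models a phenotypically heterogeneous ancestral population and can
  only lower the distance.
* Downstream: changed reactions are classified as turned on / turned off /
  magnitude-only, mapped through gene–protein–reaction rules to gene, operon
  and regulon counts, metabolites are ranked by total (producer + consumer)
  distance, and a sweep of the ancestor's glucose allowance shows how excess
  consumption shrinks the distances. A two-stage geometric model relates
  distances to the probability that producer-then-consumer emergence
  completes within T generations.

Every optimizer is validated against an exhaustive change-set enumeration
oracle on bundled toy networks.

## Worked example

```python
import crossfeed as cf

model = cf.make_core_fixture()          # ~26-reaction central-carbon toy
env = cf.core_environment()             # glucose-limited chemostat, D = 0.2

print(cf.minimal_glucose(model, env))   # 0.2
ancestor = cf.ancestral_state(model, env)
print(-ancestor["EX_glc_e"])            # 0.2   (pFBA takes only the minimum)

results = cf.compute_distances(model, env, ["ac_e", "gol_e"], method="room",
                               ancestor=ancestor)
for r in results:
    print(r.metabolite, r.role, r.distance)
# ac_e  producer 3
# ac_e  consumer 8
# gol_e producer 4
# gol_e consumer 4
print(cf.rank_metabolites(results)[["metabolite", "total", "rank"]])
#   metabolite  total  rank
# 0      gol_e      8     1
# 1       ac_e     11     2
```

Reading: turning this toy ancestor into an acetate-like overflow producer
needs only 3 flux changes (more glucose in, overflow branch on, exporter on),
while the corresponding consumer must rewire 8 reactions (glucose transport
off, the import/assimilation route and gluconeogenic steps on). Summed over
both partners, the glycerol-like by-product (4 + 4) is the easier
cross-feeding interaction to evolve in this network — being cheap to produce
does not make a metabolite the overall front-runner.

The same API runs on a genome-scale model: load one with
`cf.load_model("iJO1366.json", "bigg_json")`, supply your candidate
metabolite list, and use the `crossfeed` command-line tool (`fixtures`,
`ancestor`, `scan`, `rank`, `sweep`, `report`) with a YAML config for batch
runs.

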