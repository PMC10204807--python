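# Methods

## The model class

`leafcbm` works with compartmentalized stoichiometric models of leaf
mesophyll metabolism under the standard steady-state assumption of flux
balance analysis (FBA): internal metabolite pools are constant, so fluxes
satisfy `S·v = 0` with bounds `LB ≤ v ≤ UB`, and the flux through a biomass
pseudo-reaction (draining precursors in measured mass proportions) is read
as the growth rate.  The objective is maximal biomass production; because
FBA optima are degenerate in individual fluxes, every reported solution is
*canonical*: among all optima, the vector minimizing Σ|v_j| (parsimonious
FBA, solved as a second LP with the objective fixed at its optimum to 1e-9
relative).  Feasibility tolerance is 1e-6, LPs are solved with GLPK through
COBRApy, and identical inputs give bit-identical outputs.

Two linear extensions carry the physiology:

* **Vc/Vo coupling.** RuBisCO appears as separate carboxylase (Vc) and
  oxygenase (Vo) reactions; the ambient operating point is imposed as the
  equality `v_c − r·v_o = 0` (default r = 3, swept 1…5 for the
  photorespiration experiment).  Operands must be irreversible so the
  equality through zero is sound; reversible operands are rejected.
* **Photon budget.** Photon uptake is bounded by `P_N / LUE`, the smallest
  photon supply consistent with the measured net photosynthesis `P_N` at the
  maximum light-use efficiency `LUE`.

## The packaged leaf model

The fixture is a hand-curated network of ~130 reactions over cytosol (c),
chloroplast (h), mitochondrion (m), peroxisome (x) and an external pool:
light reactions (linear + cyclic electron flow, lumped), the Calvin-Benson
cycle with a lumped regeneration segment, the complete photorespiratory
glycolate route (PGP → glycolate oxidase → transaminases → glycine
decarboxylase releasing CO2 + NH3 in the mitochondrion → glycerate return),
GS/GOGAT ammonia refixation in both cytosol and chloroplast (free NH3
export is closed), glycolysis/TCA/electron transport, cytosolic oxidative
pentose phosphate, starch and sucrose synthesis with a phloem export drain,
cell-wall (cellulose) and fatty-acid synthesis, nitrate/sulfate
assimilation, and the C4-module enzymes present in a C3 leaf: carbonic
anhydrase, PEPC (cytosol), PEPCK (cytosol), NADP-malic enzyme (chloroplast),
NAD-malic enzyme (mitochondrion), PPDK.  Shuttles are written as single
antiport reactions (malate/OAA between h/c, m/c and x/c; ATP/ADP between
m/c) so each shuttle flux is one well-defined number; net dicarboxylate and
OAA carriers provide anaplerotic transport.

Elemental formulas track C, N, P and S exactly for every species; hydrogen
and oxygen are not balanced because protons and some waters are omitted
from lumped redox steps.  Photons are massless.  Validation therefore
checks C/N/P/S balance on all non-exchange reactions, and the test suite
verifies closed carbon accounting (exchange carbon in = biomass carbon
drained + carbon exported) to 1e-6 in every scenario.

### Study conditions (defaults, overridable per `FixtureConfig`)

| parameter | default | meaning |
| --- | --- | --- |
| `net_photosynthesis` | 10 mmol CO2/gDW/day | measured net uptake; imposed as an equality on the CO2 exchange |
| `lue` | 0.05 mol CO2/mol photon | maximum light-use efficiency; photon cap = 200 |
| `maintenance_atp` | 7.5 mmol/gDW/day | fixed mitochondrial ATP demand (dark respiration) |
| `vc_vo_default` | 3 | ambient carboxylation/oxygenation ratio |
| `biomass_fractions` | carb 0.55 / protein 0.20 / fiber 0.17 / lipid 0.08 | mass fractions; converted to mmol of pool precursors per g via their formula weights |
| `malate_valve_capacity` | 0.5 mmol/gDW/day | cap on chloroplast NADP-MDH (light/thioredoxin modulation) |
| `co2_transfer_capacity` | 1.4 × P_N | ceiling on gas-phase CO2 diffusion into the stroma (finite mesophyll conductance) |

Biomass composition is a curator's placeholder for a measured leaf
composition, deliberately ordinary for a source leaf; the protein pool is a
seven-residue average (glu/gln/asp/ala/ser/gly/cys with 4.3 ATP per residue
for translation), the lipid pool is palmitate, fiber is cellulose glucan.

### Why the structure is the way it is

Several structural choices exist to make the drought physiology *possible*
in a linear program; they are the model's scientific content, not incidental:

* **Maintenance is mitochondrial and the chloroplast cannot export ATP
  directly** (no envelope ATP/ADP translocator; the mitochondrial
  translocator only exports).  A maintenance drain that photon-powered
  shuttles could feed would make "dark respiration" vanish from the model;
  every internal CO2 source would then scale proportionally with growth and
  stomatal closure would produce a strictly proportional response — no PEPC
  recycling, no retention above 50%.  With a mitochondrial demand, GDC
  redox plus a bounded malate valve cover part of it and the TCA cycle must
  supply the rest, giving the leaf a growth-independent respiratory CO2
  source.
* **The malate valve (NADP-MDH) has finite capacity** (0.5), reflecting its
  strict light/thioredoxin regulation, and **cytosolic GAPDH/PGK runs only
  gluconeogenically** in the lit leaf (the chloroplast exports PGA or triose
  directly).  Both close photon-powered bypasses around dark respiration.
* **Gas-phase CO2 delivery to the stroma is capacity-limited** (1.4 × P_N),
  i.e. mesophyll conductance is finite even with open stomata.  At normal
  operation the gas route is saturated, so part of the respiratory CO2
  recapture already runs through carbonic anhydrase → HCO3⁻ → PEPC →
  malate → malic enzyme; baseline PEPC is consequently ~9% of gross
  carboxylation, consistent with the high PEPC activity reported for
  cassava leaves.

### Scenario semantics

* **Normal.** Net CO2 uptake fixed at P_N (an equality: the measured rate is
  a datum, not a ceiling), photon cap 200, Vc/Vo = 3, canonical solution.
* **Photorespiration sweep.** The uptake equality is relaxed to a cap so
  simulated uptake can decline as the ratio falls; each ratio in 1…5 is a
  separate canonical solve and fold changes are taken against the ratio-3
  point.  Infeasible points are recorded and skipped.
* **Drought (fraction f).** Stomatal closure scales gas-phase transport:
  the uptake equality becomes f·P_N *and* the stroma-delivery cap becomes
  f × its baseline canonical flux.  The dissolved bicarbonate route is not
  gas-phase and is untouched — that asymmetry is precisely the mechanism
  under test, and without it (scaling the exchange alone) a biomass-
  maximizing LP has no reason ever to increase PEPC.
* **PEPC elevation (factor k).** PEPC's lower bound is set to k × its
  baseline canonical flux — a lower bound, not an equality, so the LP stays
  feasible while at least the stated activity is enforced.  For k > 1 the
  normal-condition stroma-delivery ceiling is lifted: the scenario's
  defining feature is an enlarged intracellular CO2 pool, i.e. a steeper
  gradient driving gas-phase diffusion, and carboxylation must be free to
  rise with the pool.  k = 1 is an exact no-op.

### Analyses

* **Flux-sum** Φ_i = ½·Σ_j |S_ij·v_j| with producer/consumer breakdowns; at
  steady state the producing and consuming halves each equal Φ (asserted to
  1e-6 for every internal species in every scenario).
* **CO2 pool** = the flux-sum of all compartmental CO2 species treated as
  one pool, judging each reaction by its *net* pool coefficient so
  inter-compartment diffusion does not inflate turnover; bicarbonate is a
  distinct species, so carbonic anhydrase appears as a pool consumer and
  PEPCK as a producer.  Attribution groups producers by pathway tag;
  atmospheric supply appears under `transport`.
* **Energy budgets** use metabolite role annotations (`atp`, `nadh`,
  `nadph` on the energized forms), not identifier spelling, and report
  per-compartment flux-sums plus the annotated shuttle reactions.
* **Concordance** maps reactions to genes via GPR rules; a reaction's
  expression direction is the sign of the mean log2FC over detected member
  genes, with |mean| ≤ 0.1 treated as unchanged (the band is configurable;
  per-gene rows are also emitted).  Agreement is computed over rows where
  both the predicted and the expression direction are ±1.

### The synthetic expression generator

`synth_expression` plants a known agreement probability p: each GPR gene of
a directionally-changed reaction receives a log2FC whose sign matches the
flux change with probability p, magnitude 0.1 + LogNormal(−0.35, 0.6)
(median ≈ 0.8, so signs are always classifiable); genes of unchanged
reactions get values inside the unchanged band.  Genes shared between
reactions are assigned once (first reaction in table order), so even p = 1
yields slightly less than full agreement when shared-gene reactions move in
opposite directions — a property of GPR-mediated comparison itself, not a
bug.  Generation is deterministic for a fixed seed; the test suite recovers
p ∈ {0.5, 0.8, 1.0} within the 95% binomial interval at n = 200.

## What passing tests do and do not show

The packaged model reproduces the *mechanistic sign structure* of the
drought response: growth monotone in CO2 supply and in Vc/Vo; glycolate-
route activation with PEPC suppression under severe photorespiration;
PEPC recycling rising severalfold with carboxylation retained above
proportional under stomatal closure; biomass falling and sucrose export
rising under forced PEPC, with PEPCK decarboxylation feeding an enlarged
CO2 pool.  Quantitatively, the relative growth loss at Vc/Vo = 1 (~65%) and
the carboxylation retention at half uptake (~71%) land close to values
reported for a measurement-constrained reconstruction three times this
size; other magnitudes (the PEPCK share of the CO2 pool, the biomass cost
of 10× PEPC, shuttle fold changes) depend strongly on network size, on the
absolute uptake constraint, and on which disposal routes exist, and are
reported rather than matched.  In particular the malate-valve shuttle sits
at its capacity bound in both normal and elevated-PEPC conditions here, so
its fold change is 1 by construction.  None of this certifies behavior of
real leaves; it certifies that the implementation computes what it claims
on a network whose structure encodes the intended physiology.

## Numerical choices and degenerate inputs

LP feasibility 1e-6; optimality fixing 1e-9 relative; fold-change epsilon
1e-9 with an inactive-flux threshold of 1e-6 and an unchanged band of 0.01
log2 units; flux-sum terms below 1e-9 are dropped from breakdowns.  Ratio
constraints with a zero-flux denominator force the numerator to zero (the
equality passes through the origin).  A drought fraction of 0 (or a closed
photon exchange) leaves the fixed maintenance demand unsatisfiable in
strict steady state — the model has no storage to draw down — so those
limits report infeasibility rather than a zero-growth solution; tests treat
either outcome as "no growth".  Blocked reactions in the fixture are the
phosphate exchange pair (no biomass component carries phosphorus) and the
plastid hexose-phosphate isomerases (the starch granule's only sink is its
own phosphorolysis); they are reported by `find_gaps`, which detects but
never fills gaps.

## File formats

The TSV dialect is a single UTF-8 file with `!`-prefixed sections
(`!model`, `!compartments`, `!metabolites`, `!reactions`, `!objective`),
tab-separated columns, equations like `pep_c + hco3_c -> oaa_c + pi_c`
(`<->` for reversible), and `key=value;key=value` annotation fields; floats
are serialized with full precision so a write/read/write cycle is
byte-identical.  SBML I/O is Level 3 with the FBC extension via COBRApy;
pathway tags map to subsystems and role annotations ride in notes.
Stoichiometry survives SBML round trips to 1e-9.
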