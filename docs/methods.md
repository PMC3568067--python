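# Methods

## Scope and model

`cardiocore` studies how the composition of the substrates available to a
cardiomyocyte — glucose, lactate, ketone bodies, acetate and six fatty acids —
affects the oxygen and substrate cost of meeting the cell's metabolic
targets. The machinery is standard constraint-based modelling: a
stoichiometric matrix N over a metabolic network, the steady-state assumption
N·v = 0, flux bounds, and linear programming. All fluxes are in
mmol·min⁻¹·(l cell)⁻¹; experimental per-cell rates are converted through the
volume of a single cardiomyocyte, modelled as a cylinder V = π/4·d²·l with
default d = 14 μm, l = 140 μm (V = 2.16e-11 l).

## The flux-minimization problem

For a fixed set of target fluxes (at minimum the ATPase drain, representing
contractile and maintenance ATP expenditure, default 21.6
mmol·min⁻¹·(l cell)⁻¹) and a substrate composition β on the unit simplex,
the solver computes

```
minimize    v_s + v_O2
subject to  N·v = 0
            v_min ≤ v ≤ v_max
            v_t = fixed target values        (equality)
            v_m = β_m · v_s  for each substrate m
```

where v_s = Σ_m v_m is the total substrate uptake over the declared uptake
set and v_O2 the oxygen uptake. The composition coupling reflects the
empirical observation that uptake rates of energy-delivering substrates
track their shares in the perfusion medium.

The LP is solved in two lexicographic stages. Stage 1 minimizes v_s + v_O2.
Stage 2 pins that optimum (equality within absolute slack 1e-7) and
minimizes Σ_j |v_j| over all reactions, with reversible fluxes split into
nonnegative forward/backward components. The tiebreak selects the sparsest
of the degenerate optimal distributions — the flux-minimization principle —
without changing v_s or v_O2, which stage 1 already determines. The order
(uptake first, total flux as tiebreak) is a design choice made explicit; a
`tiebreak=False` switch disables stage 2, which is also what the large
scans and the closed-form oracle tests use, since the quantities recorded
per composition are stage-1-determined.

Targets are equalities; minimum-rate demands (the basal NADPH requirement)
are ≥ bounds. Per-reaction bound overrides (`extra_bounds`) are applied
last, after target pins — this is what lets the alternate-optima
enumeration re-pin an individual flux, including a target flux.

Solver: HiGHS through `scipy.optimize.linprog`, primal/dual feasibility
tolerances 1e-9. Steady-state residuals max|N·v| of returned solutions are
asserted ≤ 1e-6 in the test suite.

## The core network generator

The generator emits a deliberately lumped network: per substrate, one
uptake exchange and one oxidation reaction
`substrate + o2_stoich·O2 + y·ADP → y·ATP + byproduct`, plus an ATPase
drain `ATP → ADP` and a secreted byproduct pool standing in for CO2/H2O.
Pathway resolution (glycolysis, TCA, β-oxidation) is intentionally absent:
the quantities of interest — uptake and oxygen rates per composition —
depend only on the per-mole yield ratios.

ATP yields: palmitate 120, stearate 136, oleate 134, alpha-linoleate 132,
EPA 142, DHA 156 (the standard per-mole totals for complete β-oxidation);
glucose 36 (glycerophosphate-shuttle convention), lactate 17, acetoacetate
22, acetate 9. With these values a 21.6 demand met by glucose alone costs
exactly v_s = 0.60 and v_O2 = 3.60, and by oleate alone v_O2 = 4.11.
Oxygen coefficients are the combustion stoichiometry of the molecular
formulas (glucose 6, palmitate 23, oleate 25.5, DHA 29, …). A known
inconsistency in published reference values: a lactate yield of 17
reproduces a sole-lactate uptake of 1.2706 (matching one published table at
1.2701) but not an alternative printed value of 1.17; we keep 17 and do not
chase the second figure.

Optional subsystems:

* **Glycogen** — a buffered store: synthesis `glucose + c·ATP → store`
  (default cost c = 2 ATP per glucosyl unit: hexokinase plus UDP-glucose
  activation) and capped degradation `store → glucose` (default cap 0.9
  mmol·min⁻¹·(l cell)⁻¹). The store metabolite is balanced by a free
  reversible exchange, so synthesis and degradation are independent fluxes
  — the only structure consistent with scan records showing degradation
  without concurrent synthesis and vice versa. Because store-derived
  glucose costs no uptake, the optimizer runs glycogenolysis up to its cap
  whenever glucose carbon is useful; this is a property of the lumped
  model, stated here so scan outputs are read correctly.
* **Phospholipid targets** — lumped assembly reactions for ceramide,
  cardiolipin, phosphatidylcholine, phosphatidylethanolamine and
  sphingomyelin, each consuming a fixed acyl recipe plus 5 ATP, with a
  pinned demand reaction per target. The recipes are *synthetic defaults*
  (the true acyl compositions of cardiac membrane lipids are not encoded
  here) chosen to preserve one structural fact: alpha-linoleate and DHA
  appear in every recipe and cannot be synthesized, so lipid targets are
  infeasible whenever either is absent from the supply. Non-essential
  fatty acids get lumped de-novo synthesis at a cost of (oxidation yield
  + 2) ATP — above their yield, so no free-energy cycle exists — and EPA is
  elongated from alpha-linoleate.
* **NADPH** — a two-step lumped branch glucose → G6P → 2 NADPH with a
  minimum-rate demand (default 1.42e-5 mmol·min⁻¹·(l cell)⁻¹, a basal
  cytosolic pentose-phosphate rate).

Default lipid-target demand fluxes (1e-3 to 5e-4) are likewise synthetic
small rates, user-overridable via `CoreOptions.target_fluxes`.

## Composition grids and scans

Compositions are enumerated on a regular simplex grid: all vectors
(a_1/k, …, a_ns/k) with nonnegative integers summing to k = 1/step, in
lexicographic order; the count is C(k + n_s − 1, n_s − 1). Four substrates
at step 0.01 give C(103, 3) = 176,851 points. For nine substrates the
default step is 0.05 — a full 0.01 nine-substrate grid would be
astronomically large, and published nine-substrate runs used a non-uniform
grid that is not recoverable; explicit composition lists are accepted for
exact replication of specific rows. Scans record (β, v_O2, v_s, v_GL,
v_GS, status) per composition, keep infeasible rows, checkpoint to TSV
every 1000 rows and resume from a partial checkpoint. Substrates outside
the scanned uptake set are closed during a scan (an unlisted substrate is
unavailable, not free).

## Efficiency index

Solutions are ranked by the TOPSIS closeness coefficient over "lower is
better" criteria (v_O2, v_s, optionally v_GL): with q⁺/q⁻ the column
minima/maxima, S⁺ and S⁻ the Euclidean distances of a row to them,
C⁺ = S⁻/(S⁺+S⁻). Distances use **raw units, no prior normalization** —
recomputing published index values from the printed criteria reproduces
them to 3–4 decimals only without normalization, so that is the default;
classic vector normalization sits behind a flag. One bundled-table row
(exclusive acetoacetate) recomputes to ≈0.280 against a printed 0.2791;
this is attributed to rounding of the printed inputs and documented rather
than resolved. Ideals are recomputed over whatever row set is scored, so
C⁺ values are specific to the simulation batch — scoring a subset changes
the indices. Degenerate rows (S⁺+S⁻ = 0) are defined as C⁺ = 1 with a
warning. No criterion weighting is applied.

## Alternate optima

Degeneracy of the optimal flux distribution is probed by re-pinning each
nonzero flux, one at a time, to 1.01× and 0.99× its original value and
re-solving. Solutions matching the original optimum within relative 1e-6
are retained as alternates; fluxes infeasible in both directions are
"dependent" (coupled to the targets). Zero fluxes are skipped — scaling
zero is no perturbation. Per-reaction sample variance is computed over the
original plus all retained alternates; variance ≤ 1e-10 counts as unique,
and uniqueness is cross-checked against the width of the flux range over
the optimal face. A one-way ANOVA (distributions as groups, reactions as
observations) summarizes overall similarity; degenerate cases are handled
explicitly (identical groups → F = 0; zero within-group variance with
distinct means → F capped at infinity, flagged).

## What the synthetic core network does and does not show

The generator reproduces yield-level energetics exactly, so uptake/oxygen
rates, their closed-form relation v_s = demand/Σβ_m·yield_m,
v_O2 = v_s·Σβ_m·o2_m, efficiency rankings of compositions, and essential
fatty-acid infeasibility are faithful. It does not resolve internal
pathways, compartmental transport, the carnitine shuttle or cofactor
stoichiometry; internal flux variability, glycogen kinetics and NADPH
branch rates on the core network are structural stand-ins, and passing
tests on them validate the algorithms, not organ-scale physiology. Results
on a full genome-scale cardiomyocyte reconstruction require supplying that
model via SBML.

## Numerical choices

* LP feasibility/optimality tolerance 1e-9; objective pinning slack 1e-7
  absolute (looser, to avoid numerical infeasibility of the pinned stage).
* Blocked-reaction tolerance 1e-6 on per-flux minima/maxima.
* Default flux cap ±1000 for otherwise unconstrained reactions.
* Composition sum tolerance 1e-9; β = 0 pins the uptake to exactly zero.
* Alternate-optima acceptance 1e-6 relative; uniqueness threshold 1e-10 on
  sample variance.
* Ties in efficiency ranking keep row order (stable sort).
* Problem sizes in the shipped tests are deliberately small (core network,
  ≤ 35-point scan grids, 1000 random compositions for the closed-form
  oracle); all are the package's own choice of representative sizes.

## Known limitations

* The SBML reader targets plain Level 2/3 plus FBC bounds; exotic
  constructs (kinetic laws, rules) are logged and ignored.
* The scanner is sequential by contract (deterministic output order);
  parallel execution is future work.
* Benefit criteria and criterion weights are deliberately unsupported in
  the efficiency index.
* No gap-filling: function-battery failures are reported, not repaired.
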