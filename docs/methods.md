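# Methods

## The ME formalism implemented here

A metabolism-and-expression (ME) model joins a stoichiometric metabolic
network to its own expression machinery. Three ingredients:

1. **Expression reactions.** Each modeled gene has a transcription reaction
   (NTPs in transcript composition → transcript + biomass-mRNA mass) and a
   translation reaction (pooled amino acids + ATP → protein +
   biomass-protein mass). The biomass-species coefficients equal the
   product molecular weight in kDa, so expression flux (mmol gDW⁻¹ day⁻¹)
   times coefficient is g gDW⁻¹ day⁻¹ of macromolecule. Enzyme complexes
   form from their subunits at stated copy numbers (L₈S₈ form I rubisco,
   L₂ form II, two-subunit nitrogenase complexes, α₂ββ′ω RNA polymerase, a
   ribosome from a lumped rRNA transcript plus 52 ribosomal proteins).
   Transcription and translation rates are *proxies* for mRNA and protein
   amounts, not inventories.

2. **Coupling.** A reaction with flux `v` catalyzed by enzyme `E`
   (turnover `k_cat`, day⁻¹) carries a usage term consuming
   `(mu/k_cat)·v` of `E`: the synthesis flux needed to balance growth
   dilution of the catalyst pool. Transcription couples to RNA polymerase,
   translation to the ribosome and (per-gene) to the transcript. mRNA is a
   diluted catalyst of translation, not a stoichiometric substrate, and
   has no separate degradation pathway. tRNA charging, translocation, DNA
   replication and post-translational modification are deliberately out of
   scope.

3. **Biomass dilution.** One reaction drains biomass components —
   small-molecule precursors, amino-acid pool, ribose-5-phosphate,
   growth-associated ATP, 0.55 g protein and 0.06 g RNA per gDW — at a
   flux pinned to `mu`. Bulk (non-catalytic) protein and RNA are produced
   by dedicated average-composition expression reactions, so the modeled
   catalysts are a small part of a realistic proteome mass.

Fixing `mu` instantiates all coupling coefficients and yields a pure LP
(steady state for every species, bounds, optional extra linear rows).
`max_growth` bisects `mu` over LP feasibility between 0 and twice an
analytic carbon-balance bound (default tolerance 1e-4 day⁻¹), with a
10-point guard scan for the monotone-feasibility assumption and a linear
scan fallback. Parsimonious FBA minimizes Σ|v| via variable splitting.
Reported solutions keep steady-state residuals below 1e-6 (typically
1e-12); alternate-optimum questions are answered with `flux_range`,
optionally restricted to near-parsimonious solutions. The LP backend is
HiGHS through `scipy.optimize.linprog`.

Macromolecule bookkeeping uses gram units for the biomass species, which
keeps all matrix coefficients within ~10 orders of magnitude; no further
rescaling proved necessary at this model size.

## Turnover numbers

`k_cat(enzyme) = 234,000 day⁻¹ × SASA(MW)/SASA(31.09 kDa)` with
`SASA = MW^(3/4)`; the anchor is the 283-residue, 31.09 kDa average
bacterial enzyme, so the identity `assign_kcat(31.09) = 234,000` is exact.
The SASA mean uses that generic enzyme, not the average over model
enzymes. Rubisco k_cats are per active site (3.7 s⁻¹ form I, 6.6 s⁻¹ form
II) and are multiplied by site count (8 and 2) for the complex-level
coupling, because the usage terms consume whole complexes; the
coexpression constraint's ratio uses the per-site values.
Temperature enters only as a qualitative Arrhenius multiplier
(`Ea` default 50 kJ mol⁻¹, reference 303.15 K); the temperature study
itself scans k_cat multipliers directly.

## The bespoke constraints

* **Rubisco coexpression.** Two-pass protocol: solve once without the
  constraint to obtain `mu_max` and the CO₂ production at that optimum,
  then add the linear row
  `v_I + r·Σv_CO2 {>=,==} r·(Σv_CO2,max/mu_max)·mu`, `r = k_cat,I/k_cat,II`.
  The CO₂-producing set (every reaction making cytosolic CO₂, exchange
  excluded) is emitted as a model annotation. The bracket can be negative
  at low growth; the default "relaxed" mode implements
  `v_I = max(0, bracket·r)` as the inequality pair `v_I ≥ 0`,
  `v_I ≥ bracket·r` (exact under the parsimonious objective, which drives
  `v_I` to the lower envelope); "strict" equality mode surfaces the
  infeasibility instead of clamping.
* **ATP caps.** The designated photophosphorylation ATP reaction gets an
  upper bound equal to the substrate's photosynthetic-yield cap (acetate
  54.0, succinate 45.7, butyrate 56.7, p-coumarate 85.4 mmol gDW⁻¹ day⁻¹),
  or `54.0 × phi_S/phi_ace` when yields are supplied. This anoxygenic organism has a single
  photosystem (so "PSI" and "PSII" labels name the same complex); the cap is applied to the ATP-production step.
* **Nitrogenases.** Three independent reactions; per N₂ at ATP cost `a`:
  `N2 + (a/2) fd_red + a ATP → 2 NH3 + (a/4 − 3) H2`. Defaults a = 16/24/40
  for Mo/V/Fe (8/12/20 reduced-ferredoxin electrons, obligatory H₂
  by-product); only the ordering Mo < V < Fe is externally constrained,
  the stoichiometries follow the standard literature pattern.

## What the toy network emulates

`rpalme.synth` builds a ~110-species, ~127-reaction photoheterotroph with
a growth-coupled expression layer, deterministic (byte-identical) under a
fixed seed. Design choices that shape its physiology, all free parameters
documented here:

* **Substrates** enter as neutral acids (acetate C₂H₄O₂, succinate C₄H₆O₄,
  butyrate C₄H₈O₂, p-coumarate C₉H₈O₃). Each has a lumped TCA-like full
  oxidation (→ CO₂ + NADH) and an assimilation that releases a quarter of
  its carbon as CO₂ alongside NADH (obligatory decarboxylation). The
  decarboxylation is what creates genuine redox stress on every substrate:
  without it, oxidation-plus-refixation exactly ties direct assimilation
  and the parsimonious objective never expresses rubisco.
* **Electron chain**: NADH feeds the quinone
  pool through an NADH dehydrogenase; the photosystem lifts quinol
  electrons to its primary acceptor using 1 photon per electron; from
  there they either return through the bc1 complex (2 pmf per pair; ATP
  synthase makes 1 ATP per 2 pmf) — the cyclic loop — or branch onto
  ferredoxin through the explicit **ETFD** reaction. Reduced ferredoxin is
  consumed only by the nitrogenases and by a ferredoxin:NAD⁺ reductase
  (FNR) return valve capped at 1.0 mmol gDW⁻¹ day⁻¹ (an enzyme-capacity
  stand-in). The cap matters: an unbounded return valve lets a pinned ETFD
  flux be short-circuited by a ferredoxin↔NAD cycle and erases the
  electron-partitioning behavior entirely.
* **CBB module**: a lumped carboxylation (CO₂ + 2 NADH + 3 ATP → 1/5
  ribulose-5P) duplicated for rubisco form I and II with distinct enzymes
  and k_cats; ribulose-5P ↔ precursor interconversion and the
  ribulose-5P → ribose-5P drain into biomass nucleotide precursors.
* **Redox sinks**: the gluconeogenic triose route runs through malate
  (OAA + NADH → malate → DHAP + CO₂), then DHAP + NADH → glycerol-3P
  (G3PDH), which either leaves as glycerol or continues into a lumped
  fatty-acid product (C₄H₈O₂ per unit, 5 e⁻ per carbon, secretable) — the
  fatty-acid-biosynthesis electron valve. A redox-neutral acetate
  overflow (2 precursors → acetate) vents excess carbon at precursor
  oxidation state, and a malate-dehydrogenase branch can also secrete
  succinate. These choices give the model one export more reduced per
  carbon than glycerol; without such a valve no lumped stoichiometry
  makes carbon fixation collapse at the growth plateau.
* **Carriers** use transferable-atom formulas (NADH = NAD + 2H, reduced
  ferredoxin = oxidized + H, quinol = quinone + 2H, ATP/ADP/Pi massless),
  so C/H/O balance is checkable for every metabolic reaction; expression
  reactions balance only by construction of the macromolecule bookkeeping
  and are excluded from the element check.
* **Genes** are seeded random coding sequences (ATG start, no internal
  stops, GC ≈ 0.65) with lengths loosely following the real operon
  products; sequences are cosmetic except that molecular weights (hence
  SASA-scaled k_cats and biomass coefficients) derive from them.
* **Biomass**: 10 precursor + 1 amino acid + 0.5 ribose-5P + 30 ATP +
  0.55 g protein + 0.06 g RNA per unit dilution flux. Nitrogen demand is
  ~6 mmol gDW⁻¹ per unit growth, all of it through N₂ fixation (ammonium
  can only be excreted), which prices nitrogen at the nitrogenase ATP
  cost and makes the triple-nitrogenase knockout lethal.

### What the toy reproduces, and where

With the ATP cap applied, growth saturates on all four substrates
(mu_max ≈ 0.39–0.75 day⁻¹, ordered by cap) and the slope-based classifier
labels contiguous SNL → Janusian → SPL regions. The full redox-balancing
trajectory — interior carbon-fixation peak, collapse at the plateau,
rising MDH/G3PDH sink fluxes — appears on **succinate** (the baseline
substrate), whose assimilation releases few enough electrons per carbon
(≤ the lipid valve's 5 e⁻/C) for the valve to take over disposal when ATP
becomes scarce. On butyrate (5 e⁻/C, equal to the valve) and p-coumarate
the toy keeps fixation high at the plateau; this is a known consequence
of its four-compound overflow repertoire, not of the framework. MDH rises
at the plateau because the valve's triose backbone routes through it; on
operating points where the valve is idle it stays at zero, so the sink
statement is tested as "each sink ≥ its value at the fixation peak and
the sum strictly rises".

The ETFD sweep holds growth and uptake constant in the **Mo-only mutant**
(the wild type is Mo-exclusive anyway, but the LP could otherwise burn
surplus electrons by mixing in Fe-nitrogenase at constant total N₂ flux)
at 85% of the operating point's maximal growth — off-solution pins need
slack to be feasible at all. The carbon-fixation axis spans
[0, 1.25 × the solution value] in 8 steps, anchored at the parsimonious
solution value. At the solution-level ETFD pin the
nitrogenase flux is first-order invariant (relative range ~4e-7 over the
feasible band); a second-order drift of order 1e-6 appears over wider
axes because pinned carbon fixation changes enzyme synthesis and hence
nitrogen demand — a real ME coupling, noted here rather than suppressed.
At 1.15× and 1.3× the solution level, nitrogenase flux declines with
pinned carbon fixation (Pearson r ≈ −0.99 and −0.74), floored by the
biomass nitrogen demand.

The temperature scan reduces the Mo-nitrogenase k_cat as an Arrhenius
cold proxy. Growth is insensitive down to ~1e-3 (the enzyme's protein
simply substitutes for bulk proteome mass), then collapses once
nitrogenase synthesis dominates the proteome; the V-only mutant first
outgrows the Mo-only mutant at a multiplier of ~3e-4. Raising the V-nase
k_cat arbitrarily never lifts the V-only mutant above the wild type,
because its higher ATP cost per N₂ binds first.

### What passing tests do *not* show

The toy is a caricature: lumped single-step pathways, one respiratory-
chain stoichiometry, four overflow products, pooled amino acids and NTPs,
and ~20 genes. Absolute growth rates, flux magnitudes and the crossover
multiplier are properties of these choices, not predictions for the real
organism, and are never compared against measured values; only the
reference arithmetic (oxidation states, accuracy percentages, growth-excess
percentages, caps, k_cat identities) and qualitative orderings are. The
fold-change validation runs on synthetic fixtures with injected ground
truth because the experimental direction tables are not distributed with
this package.

## Numerical choices

* LP: HiGHS (scipy), default feasibility tolerances; bisection tolerance
  1e-4 day⁻¹ (tests that only need curve shape use 1e-3 to stay fast);
  steady-state check 1e-6.
* Fold-change ties (ratio exactly 1) are classified "unchanged", excluded
  from the accuracy denominator and reported; zero baselines get a 1e-9
  pseudo-flux. Accuracy rounds half-up to integer percent (25/37 → 68).
* Region thresholds: SNL where the central-difference slope ≥ 0.9 × max
  slope, SPL where ≤ 0.05 × max; contiguity enforced structurally (SNL
  prefix, SPL suffix).
* OR-GPRs are realized as per-isozyme reaction copies at build time, so
  each LP column carries at most one enzyme usage term.
* Degenerate alternate optima are reported as the solver's vertex plus
  `flux_range`; the symmetric-isozyme case is explicitly handled that way.

## Known limitations

* Monotone feasibility in `mu` is assumed (guarded, with a scan
  fallback); exotic constraint sets could violate it.
* The SBML export covers only the metabolic + exchange subset; the
  expression layer and coupling terms have no SBML-core representation
  (flagged in the document notes).
* The biomass formula of the toy is arbitrary; its oxidation state is not
  asserted anywhere.
* `m_rr` and `f_rRNA` are carried as documented coupling parameters but
  the toy's lumped single-rRNA ribosome does not exercise the rRNA
  fraction; they are overridable for models that do.
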