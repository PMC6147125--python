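# Methods

## Thermodynamics of the four pathways

The free energy of each pathway is evaluated in the linearised Nernst
form ΔG(T) = ΔH° − R_B·T + R·T·ln Q with R = 8.3145×10⁻³ kJ mol⁻¹ K⁻¹.
ΔH° is the standard reaction enthalpy and R_B plays the role of the
standard reaction entropy, so ΔH° − R_B·T is the standard-state ΔG at
temperature T; both are treated as temperature-independent over the
295–320 K range of interest. The registry holds the four reactions per
mole of organic substrate (per CH₄ for hydrogenotrophic
methanogenesis) with (ΔH° [kJ mol⁻¹], R_B [kJ mol⁻¹ K⁻¹]):

| reaction | ΔH° | R_B |
|---|---|---|
| syntrophic acetate oxidation (SAO) | 270.6 | 0.723 |
| syntrophic propionate oxidation | 205.1 | 0.447 |
| acetoclastic methanogenesis | 17.7 | 0.314 |
| hydrogenotrophic methanogenesis (HM) | −252.9 | −0.41 |

These constants are validated in the test suite by recomputing ΔH° =
Σν·ΔH_f and ΔS° = Σν·S° from bundled CODATA/NIST formation data
(H₂O(l) as liquid, aqueous ions on the conventional H⁺ = 0 scale): SAO,
acetoclastic and hydrogenotrophic values agree within 0.1 kJ mol⁻¹ and
0.001 kJ mol⁻¹ K⁻¹. The propionate R_B is not exactly reproducible
from common formation tables and is used verbatim.

Quotients take gases in bar (standard state 1 bar; inputs in kPa are
multiplied by 0.01), solutes in mol L⁻¹ (standard state 1 M), [H⁺] =
10^(−pH), and water activity 1 (water omitted). Because the SAO and
HM quotients sum species-wise to the acetoclastic quotient, ΔG_SAO +
ΔG_HM − ΔG_AM reduces to (0.314 − 0.313)·T ≤ 0.32 kJ mol⁻¹ — an
internal identity the tests verify on random states.

Assumptions and deliberate omissions: activities equal concentrations
(no ionic-strength correction), no carbonate speciation, pH defaults
to 7.0 when not measured (it is a required, logged input — it enters
three of the four quotients), and undetectable measurements are
floored (defaults 10⁻⁶ bar for gases, 10⁻⁶ M for solutes) so ln Q
stays defined; flooring is logged. Feasibility is the strict test
ΔG < threshold with threshold 0 by default (−20 kJ mol⁻¹ selects the
biological energy quantum instead).

## Co-occurrence networks

Counts are aggregated to family (taxa without a family-level lineage
field are dropped), then families holding < 0.5 ‰ of all reads are
discarded (the boundary is inclusive: exactly 0.5 ‰ is retained).
Correlation uses all 15 samples of one temperature (3 replicates × 5
days) as independent columns of the per-sample relative-abundance
view; replicate-averaged (n = 5) and raw-count variants are available
as options since the source protocol does not pin this down. Spearman
ρ is the Pearson correlation of mid-ranks; p-values use the
t-approximation with n − 2 degrees of freedom (constant families are
recorded as ρ = 0, p = 1); the BH step-up correction is applied once
to the strict upper triangle (m = k(k−1)/2 hypotheses) and mirrored.

An edge requires 0.6 ≤ ρ ≤ 0.9 **and** q < 0.01; negative correlations
are never edged and isolated families stay in the graph with degree 0,
mirroring how non-clustering abundant families remain part of the
community description as singleton or small modules. The significance
test is strict (<); the source material uses both "< 0.01" and
"≤ 0.01", so the strict variant was chosen and is configurable.

Modularity is Newman's Q = Σ_c (e_cc − a_c²) on unweighted edges at
resolution 1. The default partitioner is deterministic greedy
agglomeration: merge the community pair with the largest ΔQ (ties
broken by lexicographically smallest label pair) down to a single
community, keep the best cut of the merge path, then polish with a
deterministic best-single-node-move pass. The polish step exists
because plain agglomeration can stop one move short of the optimum on
small graphs; with it, the greedy partition attains the exhaustive-
search optimum on ≥ 18/20 random ≤ 8-node graphs (tested). A seeded
igraph Louvain is available where the randomised heuristic is wanted;
published modularity scores obtained with randomised Gephi/Louvain
runs are therefore reproducible in distribution but not digit-exact,
and are not treated as fixed targets. Module ids are relabelled by
decreasing size so outputs (and GraphML bytes) are stable.

## Expression dynamics

Proportions are computed per sample and then averaged across the three
biological replicates; SE is the sample standard deviation (n − 1)
over √n. Pooling counts before dividing would weight replicates by
sequencing depth, which is wrong for biological replicates. Zero
denominators (empty pools, zero gene copies) yield missing values that
are logged and excluded from the mean rather than propagated as zeros.
Functional-pool composition tables pool groups below a configurable
0.5 % cutoff into "other" and always close to 1 per day.

## Synthetic data

The generator reproduces the *structure* of the incubation study — 2
temperatures × sampling days {5, 11, 16, 23, 30} × 3 replicates — not
any real sequence data.

**Chemistry.** Pools in mM (polymer P as carbon equivalents, acetate A,
propionate Pr, H₂, CH₄): first-order hydrolysis dP/dt = −k_h·P whose
carbon flux splits into acetate (fraction f_a), propionate (f_p) and a
CO₂ remainder, plus fermentation H₂ (f_h mol per mM C). Each pathway
rate is v_max·S/(K_m+S), multiplied by a logistic
population-establishment ramp 1/(1+exp(−(t−t_lag)/τ)) and by a
thermodynamic gate that zeroes the rate unless the pathway's own ΔG
(evaluated by the thermo module at the current state, CO₂ fixed at 0.2
bar, pH 7) is below ΔG_crit = 0. Stoichiometry: 4 H₂ per acetate
oxidised, 3 H₂ per propionate (plus 1 acetate), 4 H₂ → 1 CH₄, 1 CH₄
per acetate (acetoclastic). Carbon is conserved to machine precision
against an explicit CO₂ ledger (tested each run). Integration is
explicit Euler at Δt = 0.05 d for all pools except H₂, whose Monod
consumption is solved implicitly within each step (a per-step
quadratic): H₂ turnover is much faster than the step and the explicit
update oscillates between zero and the per-step production, which
would chatter the SAO feasibility gate through the detection floor.
Dissolved-gas pools are mapped to partial pressures by a fixed
headspace factor of 1.65 kPa mM⁻¹.

The logistic ramps are the model's stand-in for microbial growth: the
delayed onset of thermophilic acetate consumption reflects the time
needed for syntrophic populations to reach critical size, and a short
acetoclastic lag sets the mesophilic CH₄ onset. Without them a pure
Monod model consumes acetate from day 0 and cannot produce the
observed peaks.

Preset calibration targets are the published sampled-day anchors:
mesophilic acetate peak 8.4 mM (day 5) and day-30 CH₄ 48.5 kPa;
thermophilic acetate peak 17.7 mM (day 16) and day-30 CH₄ 26.0 kPa.
The frozen presets land within ~3 % of all four. One compromise is
intrinsic: with a single shared headspace factor, carbon bookkeeping
cannot simultaneously match the full thermophilic acetate decline
(17.7 → 4.6 mM) and a day-30 CH₄ of only 26 kPa, so the presets
prioritise the peak anchors and end the thermophilic acetate near
6.3 mM. The H₂ trace is calibrated qualitatively only (higher early
H₂ at 30 °C); the mesophilic residual H₂ settles in the window where
propionate oxidation is exergonic but acetate oxidation is not —
which is exactly the published feasibility contrast.

**Community.** Three planted modules of 8 families each — an early
fermenter guild (peak day 5), a mid-incubation syntroph guild (day 16)
and a late methanogen-associated guild (day 30). Latent abundance =
family base level (lognormal, σ = 0.3) × Gaussian activity bump ×
per-sample lognormal noise (σ = 0.2); compositions are normalised and
counts drawn multinomially at 50 000 reads per sample. Bump widths are
(16, 7.5, 16) days: the mid-incubation bump is flattest over the
5-day sampling grid and needs a narrower width for its families to
carry the same rank signal as the edge guilds; with these defaults the
network pipeline recovers the planted labels with ARI ≥ 0.9 in ≥ 98 %
of seeds (tested over 50). What this generator does **not** emulate:
real compositional count overdispersion, shared environmental drivers
beyond the module bump, phylogenetic correlation, or families
belonging to several guilds — so passing recovery tests demonstrates
the machinery, not field-data performance.

**Read pools.** Subset counts are drawn binomially from their parent
pool (bacterial/archaeal mRNA from total RNA, CAZyme transcripts from
the resulting mRNA), so containment invariants hold by construction.
Default temporal profiles follow the published ranges: flat low
expression at 30 °C, bimodal bacterial and late-surging archaeal
expression at 45 °C.

All stochastic outputs are reproducible from (scenario, seed); the
chemistry integration itself is deterministic, with optional lognormal
replicate measurement noise.

## Numerical and interface choices

* Problem sizes throughout tests and acceptance runs are the study's
  own (≤ 24 families × 15 samples; 600 integration steps), chosen to
  keep every check a desk-scale computation.
* Exit codes: 2 for validation/schema errors, 3 for numerical errors.
* GraphML is the primary network format (GEXF secondary for Gephi);
  node and edge order are sorted so byte-identical output is a tested
  determinism contract.
* Thresholds are applied with documented open/closed boundaries:
  prevalence ≥, ρ window inclusive, q strictly <, feasibility strictly <.

## Known limitations

* The kinetic model is a calibration device, not a mechanistic digester
  model: no biomass state variables, no pH feedback, fixed CO₂, binary
  thermodynamic gates (no Boltzmann-factor rate attenuation).
* Published network statistics that depend on unavailable raw reads
  (node counts, exact modularity indices) are out of reach by design;
  the pipeline reproduces the *method*, validated on planted structure.
* The Spearman p-value t-approximation is inaccurate for n < ~10 with
  heavy ties; an exact permutation option exists for small designs.
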