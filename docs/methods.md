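# Methods

## Formulation

The package builds a metabolism-and-expression (ME) model as a MILP with
five constraint families.

**Steady state.** One mass-balance equality per metabolite, as in FBA.
Metabolic reactions are split into nonnegative forward/backward fluxes
(mmol gDW⁻¹ h⁻¹); the net flux enters the balances. The biomass reaction is
not a flux variable: after surgery (below) its remaining drains enter each
metabolite balance as terms proportional to growth.

**Growth discretization.** Growth μ is exactly discrete:
μ = ū Σ_k δ_k 2⁻ᵏ with p = log₂N binary digits, so μ ranges over the N
values u·ū/N. Redundant one-hot bin indicators b_u are tied to the digits
by Σ b_u = 1 and Σ u·b_u = Σ 2^(p−k) δ_k; the digits linearize bilinear
products, the indicators select growth-dependent parameters. Each dilution
term μ·X uses p auxiliaries z_k with z_k ≤ X̄δ_k, z_k ≤ X,
z_k ≥ X − X̄(1−δ_k), z_k ≥ 0, where X̄ is a valid upper bound on the
concentration (its macromolecular class mass divided by the species MW, so
the big-M is as tight as the allocation data allows). At integer points the
linearization is exact; the only model error is the growth resolution ū/N.
Consequence of exact discreteness: a continuous optimum μ* is reported as
the largest encodable value below it, so the approximation error is at most
ū·2⁻ᵖ.

**Expression.** Each gene has a transcript species F_l (mmol gDW⁻¹) with
balance v_tr − k_deg F − μF = 0; transcription consumes NTPs per the
gene's nucleotide composition and is capped by the assigned share of its
RNA polymerase, Σ_l assigned + free = total, separately for the nuclear and
the mitochondrial polymerase. Translation consumes one charged tRNA per
amino acid (returned uncharged) and 2L GTP + 2L H₂O → 2L (GDP + Pi + H⁺)
for a peptide of length L, capped by the assigned ribosomes of the variants
serving the gene (two cytosolic compositions, A and B, and a mitochondrial
one; a peptide translated by either cytosolic variant sums their capacity).
Assigned ribosomes on a transcript are additionally capped by a polysome
loading bound (L_nt / 30 nt ribosomes per mRNA molecule), which is what
makes a transcription block silence translation — the knockout mechanism.
Enzymes assemble from peptide copies by complexation fluxes
(v_cplx − k_deg E − μE = 0); ribosomes additionally consume free rRNA
transcripts. Degradation fluxes, when rates are nonzero, recycle the
monomer composition (RNA decay recycles NTP equivalents at 2 ATP per
nucleotide re-phosphorylation).

**Catalysis.** Per catalyzed reaction and direction,
v ≤ Σ_j kcat_j E_j over isozymes. Missing turnover numbers default to the
*S. cerevisiae* median 70.9 s⁻¹ (stored internally in h⁻¹); transporter
enzymes get 10⁹ h⁻¹, preserving the gene–protein–reaction coupling without
a catalytic limit. kcat_bwd defaults to kcat_fwd. Reactions without a GPR
are uncatalyzed and unconstrained. The dummy species never catalyze.

**Allocation.** Protein and RNA drains are removed from the input biomass
reaction (their synthesis is now explicit) and replaced by total-mass
equalities: Σ MW_j E_j = P^m over all enzymes, machinery peptide mass and
free peptides; Σ MW_l F_l = R^m over mRNA, rRNA (free and
ribosome-incorporated), tRNA and the dummy mRNA; and
Σ_{non-dummy} MW_j E_j = φ·P^m with φ = 0.55 g/g. The machinery's mass is
split between the two ledgers: its peptide part counts as protein, its rRNA
part as RNA. The dummy protein (mean composition of the modeled peptides,
250 aa) absorbs the (1−φ) protein slack; the dummy mRNA absorbs RNA slack.
In constant-biomass (cb) mode P^m, R^m and the pool drains use the
reference fractions computed from the input biomass by f_k = Σ η_i MW_i;
in variable-biomass (vb) mode a growth-indexed composition table is
resampled onto the bin centers by piecewise-linear interpolation (clamped
outside its range, with a warning) and selected per bin through the
indicators. Pool classes (DNA, carbohydrate, lipid, ion) stay in the
biomass as drains of pooled metabolites with per-bin coefficients
η_i,ref · X_u,i/X_ref,i · μ_u; any residual table mass (rows summing below
1) would be routed to an "other" drain so the 1-gram accounting closes at
every bin — the bundled table rows sum to 1 exactly. The GAM hydrolysis
scales with μ in both modes, after subtracting the explicit
2 ATP-per-amino-acid polymerization cost (2·A_tot, where A_tot is the
summed amino-acid drain; a negative result clamps to 0 with a warning).
tRNA aminoacylation ATP is configurable and defaults to 0 — the explicit
translation energy is the 2 GTP/aa; charging energy is considered part of
maintenance. With a nonzero charging cost the model is strictly more
expensive than the FBA it was derived from, which is a modeling choice, not
an error; the default keeps the two layers energetically equivalent.

**Thermodynamics (TFA).** For every reaction whose participants all carry
formation energies and none is membrane-associated (transport and boundary
reactions are excluded wholesale), ΔG_r = ΔG′°_r + RT Σ η ln c with
ΔG′°_r = Σ η ΔG′°_f, RT = 2.479 kJ mol⁻¹, and ln-concentration variables
bounded by [10⁻⁸, 0.05] M (water and protons excluded from the sum). Two
binaries per covered reaction couple direction to sign:
FU + BU ≤ 1, ΔG_r ≤ −ε + M_G(1−FU), ΔG_r ≥ ε − M_G(1−BU),
v_fwd ≤ M_v FU, v_bwd ≤ M_v BU. The margin ε = 0.05 kJ mol⁻¹ enforces the
strict inequality that eliminates zero-ΔG loop fluxes; it must exceed
M_G times the solver's integrality tolerance or near-integral binaries leak
through the big-M (M_G = 5000 kJ mol⁻¹ brackets the attainable |ΔG_r| of
the bundled energies; M_v = 1000).

## Solving

Problems are backend-neutral (named variables, linear constraints,
insertion-ordered for reproducibility). Two open-source backends: HiGHS via
`scipy.optimize.milp` (default) and GLPK via optlang. HiGHS runs without
presolve and at 10⁻⁹ feasibility tolerances: the coefficient range
(10⁹ h⁻¹ transporter kcats against ~10⁻⁹ mmol gDW⁻¹ machinery
concentrations) made presolve prune true optima, and a default-tolerance
violation on a capacity row times a large kcat is a visible phantom flux.
Feasibility of returned optima is re-checked at 10⁻⁶ absolute.
Lexicographic cascades fix each stage's optimum within 10⁻⁶ relative
(absolute at zero) before optimizing the next; infeasibility names the
failing stage.

## Analyses

*Uptake scans* bound the substrate uptake flux and maximize growth;
expression-aware builds plateau, FBA stays linear. *Essentiality* blocks a
gene's transcription flux and calls the gene essential below 10% of the
wild-type optimum (threshold configurable; 0.1 is the common convention),
scored by the Matthews correlation coefficient — undefined margins return 0
with a warning. *Chemostat curves* snap each requested growth rate to the
nearest bin, then run: (1) minimal substrate uptake, (2) minimal total
flux (forward+backward sum) at fixed uptake, (3) minimal total non-dummy
enzyme concentration, (4) the Chebyshev center of the enzyme space — the
largest ball in the enzyme coordinates inscribed in the polytope left after
stages 1–3, inequality rows scaled by the Euclidean norm of their enzyme
coefficients, finite enzyme bounds included as rows, equality rows defining
the affine hull left untouched. After stage 3 pins the enzyme sum, the
radius is essentially zero and the center is simply a well-centered
representative solution, which is its purpose.

## The toy organism

The generator emits a fixed two-compartment topology; the seed only draws
gene sequences (so transcript compositions vary) and a ±5% kcat jitter.
Design calculations behind its defaults, all chosen at construction time:

* fermentation vs respiration: the respiratory chain is lumped into one
  slow complex (kcat 0.25 s⁻¹, ~211 g mmol⁻¹, 12.5 ATP/pyruvate + an NADH
  oxidase on the same enzyme) against fast cheap glycolysis/fermentation
  (50 / 300 s⁻¹, 2 ATP/glucose), so ATP per gram of enzyme differs ~50×
  between branches while ATP per glucose differs ~15× the other way —
  the proteome-limitation route to overflow;
* the RNA budget (reference R^m = 0.06 g gDW⁻¹, cytosolic rRNA 3500 nt)
  caps ribosome content and hence growth at ≈0.42–0.44 h⁻¹, below the
  encodable ceiling, so the scan plateau is a model property, not a grid
  artifact;
* peptide compositions are mean-field (L/4 per amino acid) and the biomass
  amino-acid drains are count-matched to them, making the metabolic and
  expression layers describe the same proteome — this is what lets the
  relaxed model (huge kcats, unbounded machinery, no degradation, φ = 1)
  reproduce the FBA optimum to within the grid resolution;
* essential/nonessential gene pairs are built in: sole-gene pathways
  (transport, amino-acid/NTP synthesis, pools, nuclear polymerase,
  cytosolic rRNA) against escape routes (glycolysis isozymes A/B, ribosome
  variants A/B, and a fermentation-only "petite" phenotype when any part of
  the mitochondrial system is lost).

What the toy does **not** emulate: genome scale (dozens of species, not
thousands), elemental/charge balance (only the 1-gram biomass accounting is
enforced), a real genetic code (amino-acid composition is decoupled from
codons), compartment-specific proton/water bookkeeping, condensation water
in polymer masses, and operon structure or stable-RNA splicing. Passing
tests therefore demonstrate the formulation's mechanics — budget coupling,
machinery capacity, directionality, discretization — not quantitative yeast
physiology.

## Problem sizes

The test suite and the acceptance script run the toy at N = 8–16 bins
(~450–500 variables, ≤40 binaries; solves in well under a second), N = 128
for the binary accounting (135 binaries) and N = 256 for the FBA-limit
check, where the grid error must drop below 1%. The full suite completes in
under a minute on one CPU.

## Known limitations

Growth being exactly discrete means reported optima are floor-quantized;
use more bins where that matters. Machinery assignment variables are
per-gene continuous shares, not integer ribosome counts. The φ split is an
equality, so the modeled proteome cannot shrink below φ·P^m at low growth —
enzymes are "parked" rather than freed, consistent with the allocation
formulation but not with regulated proteome reallocation. TFA covers only
aqueous, fully-annotated reactions; membrane energetics are out of scope.
Formation-energy estimation is an input, not a feature.
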