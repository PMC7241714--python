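# Methods

## Pocket geometry and pose triage

The triage operates entirely in the receptor coordinate frame: docking
programs emit poses in the frame of the receptor they docked against, and
the reference substrate position comes from the same frame, so no
superposition is ever applied. All distances are in Å.

**Anchor distances.** Four distances characterize a pose: the catalytic
lysine's Nζ (K331) to the ligand's proton-abstraction carbon, and the
Mg-oriented carboxylate oxygens to the glutamine amide nitrogen (Q329),
the histidine ε-nitrogen (H194) and the catalytic Mg²⁺. Because the two
carboxylate oxygens are chemically indistinguishable, each oxygen-based
distance is the minimum over both oxygens. For dicarboxylic ligands the
carboxylate whose carbon lies nearer the Mg²⁺ supplies the oxygens and
the abstraction carbon; the choice is recorded per pose.

**Pocket criterion.** A pose is inside the pocket when at least
`min_pass` (default 3) of the four distances are *strictly* below
`cutoff` (default 4 Å). Strictness matters at the boundary: the
crystallographic substrate itself measures (4.16, 3.08, 2.75, 2.2) and
passes 3 of 4 — the K331 distance sits just above the cutoff — which is
precisely why the rule demands three rather than four.

**Scaffold RMSD.** Poses are ranked by the positional RMSD of six atoms
common to all ligands studied: the Mg-oriented carboxyl carbon, its two
oxygens, and the three backbone carbons that follow. Scaffold membership
is declared per ligand in an explicit template (shipped for
3-methylaspartate, aspartate, β-lysine, lysine, β-glutamate,
3-aminobutanoate and 2-aminoadipate) rather than perceived from bonds —
this keeps the geometry free of any cheminformatics dependency and makes
the atom correspondence auditable. The RMSD is minimized over the pose's
and the reference's carboxylate choices and the oxygen swap within the
matched carboxylates (2×2×2 mappings at most); the unit tests check this
minimum against an independent exhaustive enumeration. The abstraction
carbon defaults to the first backbone carbon after the Mg-oriented
carboxyl carbon and can be overridden per template, since β-amino acids
shift the reactive carbon relative to the carboxylate numbering.

**Selection and statistics.** Among in-pocket poses the lowest scaffold
RMSD wins; ties break by better docking score, then lower pose id (real
pose sets essentially never tie; the rule exists for determinism). An
all-decoy set yields an explicit no-selection outcome rather than an
error. The percent-in-pocket statistic is the plain fraction of poses
passing the pocket criterion.

## Interaction fingerprints

Contacts between pocket residues and a ligand pose are classified into
four categories with precedence hydrogen_bond > ionic > hydrophobic >
proximal. Default thresholds: hydrogen bond ≤ 3.5 Å between N/O atoms
(with a D–H…A angle ≥ 120° required only when explicit hydrogens ride
the donor; distance-only otherwise); ionic ≤ 4.0 Å between oppositely
charged group atoms; hydrophobic ≤ 4.5 Å between apolar carbons;
proximal ≤ 5.0 Å for anything else. These thresholds are package
defaults exposed in `ContactRules`, chosen as round values in the ranges
contact-typing tools conventionally use; richer schemes distinguish an
order of magnitude more categories, and no bit-for-bit agreement with any
of them is claimed. Charges come from residue/atom-name lookup (no pKa
model); ligand atom classes (carboxylate oxygens, amino nitrogens,
apolar carbons) come from the same templates the triage uses. A
fingerprint is the *set* of (residue, category) pairs; comparison is set
algebra with the Jaccard index defined as 1.0 for two empty sets.
Water-mediated hydrogen bonds are out of scope: a residue that contacts
the ligand only through a bridging water appears as proximal at most.

## Kinetics

Velocity conversion follows Beer–Lambert, v = slope/(ε·l), with optional
division by the enzyme concentration (and by 60 s/min) into a turnover in
s⁻¹. Substrate and inhibitor concentrations are mM throughout.

Fits use Levenberg–Marquardt least squares (`scipy.optimize.curve_fit`),
unweighted, with initial guesses Km = median(S), kcat = 1.2·max(v) and,
for inhibition fits, Ki = the median positive inhibitor level. Standard
errors are Jacobian-based at the optimum; 95% limits are ±1.96·se. The
inhibition fits are *global*: one (kcat, Km, Ki) across all inhibitor
series, with the competitive law v = kcat·S/(Km(1+I/Ki)+S) and the
non-competitive law v = kcat·S/((1+I/Ki)(Km+S)). The competitive
equation is sometimes typeset ambiguously in the literature; the standard
form above is the dimensionally consistent reading and reproduces the
expected double-reciprocal pattern. Global R² is 1 − SSres/SStot pooled
over all points.

Model discrimination fits both inhibition laws plus an inhibitor-blind
Michaelis–Menten baseline and selects by smallest AICc
(n·ln(SSres/n) + 2k + 2k(k+1)/(n−k−1), k counting parameters plus the
residual variance). An inhibition model must beat the baseline by more
than 2 AICc units, otherwise "none" is declared; a fitted Ki more than
100× the largest probed inhibitor concentration is likewise reported as
a no-inhibition indication. The margin of 2 is the conventional
"substantial support" boundary for AIC differences; an automated rule is
needed where visual Lineweaver–Burk inspection would otherwise decide.

Lineweaver–Burk series are provided as a diagnostic, not a fitting
method: per inhibitor level a line is fitted to (1/S, 1/v), and a common
y-intercept across levels labels the set competitive-pattern, a common
x-intercept non-competitive-pattern (default relative-spread tolerance
1e-6, meaningful only for noiseless or averaged data). Non-positive
velocities cannot be reciprocated and are excluded with a warning.

Data expectations: ≥ 4 distinct substrate concentrations; inhibition
data must include the uninhibited series. With only I = 0 present the Ki
is structurally unidentifiable; the fit degrades to Michaelis–Menten and
is flagged rather than failed.

## Stability-scan post-processing

Replicate ΔΔG values (kcal/mol) per mutation are combined by arithmetic
mean (population SD reported); five runs is the expected protocol but any
count ≥ 1 is accepted. Classification is strict: destabilizing iff
mean > 1.6 kcal/mol — twice the 0.8 kcal/mol typical error of the
predictor — so a mean of exactly 1.6 is neutral (the boundary convention
is a package decision; the threshold's provenance does not fix it). An
optional third class, stabilizing (mean ≤ −1.6), is an annotation beyond
the two-class scheme and off by default. The predictor itself is never
executed; only its tables are consumed, which keeps the module
tool-agnostic.

## Synthetic data

Every generator is a pure function of its configuration including the
seed.

**Analytic pocket.** The reference ligand is laid out with realistic
bond geometry (C–C ≈ 1.5 Å, C–O ≈ 1.25 Å) and the four anchors are then
*placed by construction* at the reference distances, measured exactly as
the triage measures them: the Mg²⁺ on the carboxylate bisector
(equidistant from both oxygens at 2.2 Å), the Q329 and H194 nitrogens
2.08 Å-offset along each oxygen's normal at 3.08/2.75 Å, the K331 Nζ
perpendicular over the abstraction carbon at 4.16 Å. The fixture is a
synthetic stand-in for the crystal pocket, exact to machine precision by
construction; an extended variant adds an L384 side-chain carbon 4.0 Å
from the methyl group plus T360/C361 hydrogen-bond partners of the
distal carboxylate so fingerprints have non-anchor content.

**Pose clouds.** In-pocket poses are rigid perturbations of the
reference — rotation up to 8° about the scaffold centroid and isotropic
Gaussian translation with σ = 0.25 Å, jitter comparable to
within-cluster spread in docking output — and each draw is verified
against the pocket criterion and redrawn if the jitter pushed it out
(the generator's contract is poses that *are* in-pocket, so labels are
correct by construction; the redraw rate is small at the defaults).
Decoys are displaced 20 Å in random directions, beyond any geometry that
could pass the criterion, so labels are unambiguous. What this does not
emulate: real docking poses explore internal torsions and cluster
around multiple minima, so passing tests demonstrate the correctness of
the triage rules, not docking realism.

**Kinetic datasets.** v = model(S, I; θ)·(1+ε), ε ~ N(0, cv²) with
cv = 2% — multiplicative because initial-velocity error in plate readers
scales with signal. The default substrate grid (1.25, 2.5, 5, 7.5, 10,
15 mM, six levels, three replicates) spans the assay range of the
reference experiments with a conventional near-doubling layout.
Parameter defaults are the natural-substrate constants (kcat 17.6 s⁻¹,
Km 1.00 mM). Not emulated: substrate depletion, product inhibition,
instrument drift.

**ΔΔG tables.** True effects per mutation come from a declared
two-component mixture — neutral ~ N(0, 0.5²), destabilizing ~ N(3, 1²)
with planted fraction 0.3 — and each replicate adds N(0, 0.8²) run
noise. The mixture components deliberately overlap the 1.6 threshold a
little, so even a perfect classifier cannot reach 100% against the
component labels; the achievable accuracy at the defaults is ≈ 96–97%.

## Problem sizes and numerical choices

The verification suite runs the recovery studies at 25 seeds for the
kinetics regimes, 20 seeds × 5 positions for the ΔΔG accuracy, and 100
random pose pairs for the RMSD-oracle cross-check — sizes at which the
medians and rates are stable while the whole suite completes in seconds.
Fits cap Levenberg–Marquardt evaluations (1e4–2e4) and surface
non-convergence as a typed error with diagnostics rather than returning
garbage; negative parameters at an optimum are flagged invalid, not
clipped. PDB round-trips preserve coordinates to the fixed-width
3-decimal contract; equality tests on re-read geometry therefore use
5e-4 Å (or looser) tolerances.

## Known limitations

* The triage consumes poses as-is; it cannot rescue a docking run whose
  receptor frame differs from the reference's.
* Fingerprint categories are coarse by design: no π-stacking, halogen or
  carbonyl categories, no solvent, no pKa model.
* Only competitive and non-competitive inhibition are modelled; mixed
  and uncompetitive mechanisms, substrate inhibition and progress-curve
  analysis are out of scope.
* The percent-in-pocket figures reported for real re-docked ligand sets
  depend on the external docking program's pose ensemble and are not
  reproducible from synthetic data; the synthetic pose clouds validate
  the statistic, not those numbers.
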