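# malkit

Analysis toolkit for probing the substrate determinants of
**3-methylaspartate ammonia lyase (MAL, EC 4.3.1.2)** — the Mg²⁺-dependent
enzyme that deaminates (2S,3S)-3-methylaspartate to mesaconate and a
candidate scaffold for engineering the deamination of β-lysine on the
route from lysine to adipic acid.

It is written for computational enzymologists who combine docking,
contact analysis, steady-state kinetics and stability predictions when
asking whether a non-natural compound can bind and react in an enzyme's
catalytic pocket. Four stages are provided as a plain Python library,
each independently usable:

1. **Pose triage** (`malkit.triage`) — docking poses are kept or rejected
   by four anchor distances in the catalytic pocket: K331 Nζ to the
   proton-abstraction carbon C3, and the Mg-oriented carboxylate oxygens
   to the Q329 amide nitrogen, the H194 ε-nitrogen and the Mg²⁺ ion
   (4.16, 3.08, 2.75 and 2.2 Å for the crystallographic substrate). A
   pose is *inside the pocket* when ≥ 3 of the 4 distances are strictly
   below 4 Å, taking the shorter of the two carboxylate oxygens. Among
   in-pocket poses, the one with the lowest **positional scaffold RMSD**
   — over the six common atoms (carboxyl C, its two O, three following
   backbone C), minimized over carboxylate symmetry, with no
   superposition — is selected.
2. **Interaction fingerprints** (`malkit.fingerprint`) — receptor–ligand
   contacts classified into hydrogen-bond / ionic / hydrophobic /
   proximal categories per pocket residue, compared as sets (Jaccard).
3. **Enzyme kinetics** (`malkit.kinetics`) — Beer–Lambert rate
   conversion, Michaelis–Menten fits (v = kcat·S/(Km+S)), global
   competitive (v = kcat·S/(Km(1+I/Ki)+S)) and non-competitive
   (v = kcat·S/((1+I/Ki)(Km+S))) inhibition fits with AICc model
   discrimination, Lineweaver–Burk diagnostics, kcat/Km and fold-change
   arithmetic.
4. **Stability-scan post-processing** (`malkit.stability`) — replicate
   ΔΔG tables from a saturation-mutagenesis predictor are averaged and
   classified destabilizing (mean ΔΔG > 1.6 kcal/mol, twice the typical
   prediction error) vs neutral.

`malkit.synthetic` generates ground-truth inputs for every stage — an
analytic pocket whose reference pose reproduces the four anchor distances
exactly, labelled pose clouds, kinetic datasets under each rate law, and
replicate ΔΔG tables — so the whole pipeline is testable without
downloads or external docking runs.

## Worked example

`examples/03_inhibition_kinetics.py` simulates a competitive inhibitor at
the β-lysine regime (Ki 1.7 mM, kcat 17.6 s⁻¹, Km 1.00 mM, 2% noise)
and refits it blind:

```
simulated 72 velocities under competitive inhibition
selected model: competitive
  kcat = 17.68 ± 0.08 s⁻¹  (truth 17.6)
  Km   = 1.010 ± 0.025 mM   (truth 1.00)
  Ki   = 1.68 ± 0.04 mM    (truth 1.7)
  global R² = 0.9975
double-reciprocal pattern (noiseless): competitive-pattern
catalytic efficiency kcat/Km = 17.5 s⁻¹ mM⁻¹
```

The mechanism is recovered by AICc, the three constants land on the
generating values within their standard errors, and the shared
1/v-intercept across inhibitor levels is the classical competitive
signature. The other examples cover pose triage (`01`), fingerprints
(`02`) and ΔΔG scans (`04`); each prints the numbers it computes and a
line on what they mean.

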