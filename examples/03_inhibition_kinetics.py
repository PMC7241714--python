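"""Fit and discriminate inhibition mechanisms from initial-velocity data.

Simulates a competitive inhibitor (Ki 1.7 mM at kcat 17.6 s⁻¹, Km
1.00 mM — the β-lysine regime) with 2% multiplicative noise over the
1.25–15 mM substrate grid, fits all candidate models globally, picks the
mechanism by AICc, and prints the Lineweaver–Burk intercept diagnostic.
"""

import malkit as mk

cfg = mk.KineticSimConfig(
    model="competitive", kcat=17.6, Km=1.0, Ki=1.7,
    I_levels=(0.0, 2.0, 5.0, 10.0), noise_cv=0.02, seed=1,
)
data, truth = mk.generate_kinetics(cfg)
print(f"simulated {len(data)} velocities under {truth['model']} inhibition")

fit = mk.classify_inhibition(data)
print(f"selected model: {fit.model}")
print(f"  kcat = {fit.kcat:.2f} ± {fit.kcat_se:.2f} s⁻¹  (truth 17.6)")
print(f"  Km   = {fit.Km:.3f} ± {fit.Km_se:.3f} mM   (truth 1.00)")
print(f"  Ki   = {fit.Ki:.2f} ± {fit.Ki_se:.2f} mM    (truth 1.7)")
print(f"  global R² = {fit.global_r_squared:.4f}")

# The intercept diagnostic is exact algebra, so run it on the noiseless
# curves; on noisy data the AICc-based classification above is the
# reliable discriminator.
noiseless, _ = mk.generate_kinetics(
    mk.KineticSimConfig(
        model="competitive", kcat=17.6, Km=1.0, Ki=1.7,
        I_levels=(0.0, 2.0, 5.0, 10.0), noise_cv=0.0,
    )
)
lb = mk.lineweaver_burk(noiseless)
print(f"double-reciprocal pattern (noiseless): {lb.pattern}")
# A shared 1/v-axis intercept across inhibitor levels is the classical
# competitive signature: the inhibitor raises the apparent Km only.

# Derived constants: catalytic efficiency and a fold comparison.
eff = mk.efficiency(fit.kcat, fit.Km)
print(f"catalytic efficiency kcat/Km = {eff:.1f} s⁻¹ mM⁻¹")
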