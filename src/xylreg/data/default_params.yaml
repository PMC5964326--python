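# Default parameter set of the GAL-type regulon model (versioned data).
#
# Units: rates nM/min, bimolecular constants per nM per min, first-order
# rates per min, Hill constants nM, Ks in % w/v inducer.
#
# The set was tuned so that the shipped defaults exhibit the qualitative
# behaviours the package analyses: bistability with hysteresis of the
# dual-feedback design at the default kf83, dual-feedback dominance of the
# sensitivity factor across the five-decade kf83 sweep, and saturation of
# both sensitivity-factor curves at strong binding.
alpha3: 0.3        # basal GAL3-promoter sensor production (weak, high-basal promoter)
beta3: 1.2         # Gal4p-activated GAL3-promoter production
K3: 2.0
n3: 2.0
alphaG1: 0.005     # basal GAL1-promoter production (strong, low-basal promoter)
betaG1: 0.15       # Gal4p-activated GAL1-promoter sensor production (dual loop only)
K1: 0.65
n1: 3.0
alpha80: 0.8       # basal Gal80p production
beta80: 0.5
K80: 4.0
n80: 1.0
alpha4: 0.4        # constitutive Gal4p supply (total pool ~40 nM)
kf83: 0.25         # lumped sensor-Gal80p forward binding (the swept parameter)
kr83: 0.35
kf84: 0.1          # Gal80p-Gal4p binding (Kd = 0.2 nM, tight repression)
kr84: 0.02
gamma: 0.01        # dilution, ~70 min doubling time
Ks: 1.0            # inducer half-saturation of sensor activation, % w/v
betaGFP: 1.0       # GFP synthesis capacity (RFU-equivalent scale)
constitutive_rate: 1.536   # matches dual-feedback fully induced sensor pool
inducer_mode: saturating
s_ref: 1.0
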