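# Synthetic benchmark parameter set, EXPONENTIAL competence  (kg / MJ / year / skill-unit)
#
# SYNTHETIC RECONSTRUCTION: not transcribed from any published estimation of
# this model family.  The physiological constants below are assembled from
# standard human-female physiology; the skill/environment block was calibrated
# by trial and error so that the optimized allocation strategy roughly
# reproduces observed human-female ontogenetic body and brain mass.  See
# docs/methods.md for provenance and derivations.

# --- newborn tissue masses (P1) ---
x_b0 = 0.35
x_r0 = 0.001
x_s0 = 3.05

# --- tissue metabolism (P2) ---
K = 125.5
beta = 0.75
B_b = 336.0
B_r = 2000.0
B_s = 31.5
E_b = 42.0
E_r = 50.0
E_s = 13.0

# --- demography (P3) ---
f0 = 1.0
mu = 0.02
T = 50.0

# --- newborn skill (P4) ---
x_k0 = 1.0

# --- skill metabolism (P5) ---
s_k = 0.5
B_k = 160.0
E_k = 400.0

# --- maternal care (P6) ---
phi0 = 0.6
phi_r = 0.15

# --- energy extraction (P7) ---
alpha = 2.0
gamma = 2.5

competence_form = "exponential"
C = 1.0
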