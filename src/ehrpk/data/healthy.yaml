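# Population parameter set: healthy control subjects (162 mg oral ER dose).
group: healthy
dose_mg: 162.0

# Parent clearances (L/h)
cl_int_h: 322.0
cl_nh: 4.14
cl_gi_multiplier: 0.25        # biliary secretory CL as a multiple of cl_int_h

# Fractions of parent hepatic intrinsic clearance forming each primary metabolite
f_m3: 0.5
f_m4: 0.1
f_m5: 0.4

# Sequential metabolism (L/h)
cl_int_m3_to_m1: 60.0
cl_int_m4_to_m4g: 5.0

# Volumes of distribution (L)
v_nal: 267.0
v_m1: 53.0
v_m3: 214.0
v_m4: 214.0
v_m5: 15.0
v_m4g: 15.0

# Metabolite elimination clearances (L/h)
cl_elim_m1: 20.0
cl_elim_m3: 4.0
cl_elim_m4: 40.0
cl_elim_m5: 17.0

# Blood:plasma ratios
bp_nal: 1.15
bp_m1: 0.7
bp_m3: 0.9
bp_m4: 0.9
bp_m5: 0.56
bp_m4g: 0.56

# Tablet release (1/h)
k_rel: 0.25

# Impairment scaling factor (not applicable for the reference group)
factor_a: null

# Observed apparent oral clearance, dose/AUC (L/h)
clf_observed: 465.0
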