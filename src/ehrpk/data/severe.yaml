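# Population parameter set: severe hepatic impairment (27 mg oral ER dose).
group: severe
dose_mg: 27.0

cl_int_h: 42.0
cl_nh: 4.14
cl_gi_multiplier: 0.1

f_m3: 0.3
f_m4: 0.1
f_m5: 0.6

cl_int_m3_to_m1: 30.0
cl_int_m4_to_m4g: 5.0

v_nal: 267.0
v_m1: 53.0
v_m3: 214.0
v_m4: 214.0
v_m5: 15.0
v_m4g: 15.0

cl_elim_m1: 20.0
cl_elim_m3: 4.0
cl_elim_m4: 40.0
cl_elim_m5: 17.0

bp_nal: 1.15
bp_m1: 0.7
bp_m3: 0.9
bp_m4: 0.9
bp_m5: 0.56
bp_m4g: 0.56

k_rel: 0.25

factor_a: 1.7

clf_observed: 58.0
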