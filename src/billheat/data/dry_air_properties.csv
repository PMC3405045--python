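# Published dry-air properties at 1 atm (standard engineering property
# tables; the 26.85 degC row is the canonical 300 K reference point).
# Used as the tolerance oracle for billheat.air.
temperature_c,thermal_conductivity_w_m_k,kinematic_viscosity_m2_s
0,0.02436,1.338e-5
10,0.02512,1.426e-5
20,0.02587,1.516e-5
26.85,0.02630,1.568e-5
30,0.02662,1.608e-5
40,0.02735,1.702e-5
50,0.02808,1.798e-5
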