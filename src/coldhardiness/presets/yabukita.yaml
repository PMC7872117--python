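# Published parameter set for the tea cultivar 'Yabukita'
name: yabukita
lt10_ini: -2.0
t_th_ac: 17.4
h_ac: 0.051
csm_ac: -489.8
k: 18.7
c: 3.4
t_th_de: -4.0
h_de: 0.032
csm_de: -605.0
p_de: 661.0
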