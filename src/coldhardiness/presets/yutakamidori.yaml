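# Published parameter set for the tea cultivar 'Yutakamidori'
name: yutakamidori
lt10_ini: -2.0
t_th_ac: 16.1
h_ac: 0.038
csm_ac: -594.3
k: 10.6
c: 2.5
t_th_de: -17.1
h_de: 0.015
csm_de: -491.0
p_de: 654.0
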