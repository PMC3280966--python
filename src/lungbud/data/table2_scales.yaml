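# Dimensional anchors: characteristic length L = inner bud radius rc,
# characteristic time T derived by matching the dimensionless Ptc
# diffusivity 0.02 to its dimensional estimate 0.05 um^2/s.
L_um: 50.0
T_s: 1000.0
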