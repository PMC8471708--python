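# label=L-FF
# method=PM3-RHF
# source=individual L-FF molecule dipole moment, Debye
i	Dx	Dy	Dz	Di
1	11.645	1.115	0.899	11.733
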