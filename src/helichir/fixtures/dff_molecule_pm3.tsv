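# label=D-FF
# method=PM3-RHF
# source=individual D-FF molecule dipole moment, Debye
i	Dx	Dy	Dz	Di
1	-11.630	1.052	1.113	11.730
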