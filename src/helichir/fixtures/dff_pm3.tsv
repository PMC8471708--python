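# label=D-FF
# method=PM3-RHF
# source=one coil (6 molecules) of the D-FF peptide nanotube; dipoles in Debye
i	Dx	Dy	Dz	Di
1	-12.228	-15.267	-11.167	22.523
2	7.302	-18.014	-11.072	22.340
3	19.234	-2.597	-11.125	22.372
4	11.905	15.905	-11.290	22.475
5	-6.613	17.478	-12.761	22.629
6	-19.820	4.382	-12.531	23.855
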