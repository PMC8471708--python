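# label=L-FF
# method=Amber
# source=one coil (6 molecules) of the L-FF peptide nanotube; dipoles in Debye
i	Dx	Dy	Dz	Di
1	14.901	-15.250	-9.781	23.458
2	-6.280	-18.879	-8.748	21.734
3	-18.698	-3.629	-10.070	21.545
4	-11.695	14.495	-10.801	21.530
5	7.397	17.408	-10.384	21.578
6	18.581	2.745	-10.742	21.638
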