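# label=D-FF
# method=Amber
# source=one coil (6 molecules) of the D-FF peptide nanotube; dipoles in Debye
i	Dx	Dy	Dz	Di
1	-12.299	-15.170	-9.475	21.707
2	7.210	-17.995	-9.360	21.527
3	19.168	-2.656	-9.416	21.520
4	11.914	15.274	-9.612	21.625
5	-6.487	17.386	-11.256	21.703
6	-19.893	4.727	-11.112	23.271
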