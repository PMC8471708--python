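# label=L-FF
# method=PM3-RHF
# source=one coil (6 molecules) of the L-FF peptide nanotube; dipoles in Debye
i	Dx	Dy	Dz	Di
1	14.576	-15.421	-11.261	24.022
2	-6.313	-18.923	-10.513	22.549
3	-18.646	-3.636	-11.849	22.389
4	-11.564	14.461	-12.573	22.381
5	7.555	17.308	-12.123	22.441
6	18.767	2.568	-12.303	22.587
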