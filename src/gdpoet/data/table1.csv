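source,group,engine,epoch,sequence,r1_ratio,absolute_r1
CaBM,natural,,,DKDGNGYISAAE,0.93,14
GdCl3,reference,,,,1.00,35
POET regex 1,poet,regex,1,NSAMADQADDDP,1.12,16
Lanthanide binding,natural,,,DKDGDTIDEREI,1.31,28
EF1,natural,,,DPDKDGTIDLKE,1.51,23
POET motif 1,poet,motif,1,DMMHDKTDCNDT,1.71,21
EF3,natural,,,DPDNDGTLDKKE,1.86,19
POET regex 2,poet,regex,2,SDDNHSDLGDDL,2.14,34.6
POET regex 2,poet,regex,2,TQDSDDGMEDED,2.16,35.7
POET motif 2,poet,motif,2,GDDEDDQCHQDG,2.17,26.6
POET regex 1,poet,regex,1,IDCRGTEDDDPN,2.30,32.8
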