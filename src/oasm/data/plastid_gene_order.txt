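psbA
matK
rps16
psbK
psbI
atpA
atpF
atpH
atpI
rps2
rpoC2
rpoC1
rpoB
petN
psbM
psbD
psbC
psbZ
rps14
psaB
psaA
rps4
ndhJ
ndhK
ndhC
atpE
atpB
rbcL
accD
psaI
cemA
petA
psbJ
psbL
psbF
psbE
petL
petG
psaJ
rpl33
rps18
rpl20
clpP
psbB
psbT
psbN
psbH
petB
petD
rpoA
rps11
rpl36
rps8
rpl14
rpl16
rps3
rpl22
rps19
rpl2
rpl23
ndhB
rps7
ndhF
rpl32
ccsA
ndhD
psaC
ndhE
ndhG
ndhI
ndhA
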