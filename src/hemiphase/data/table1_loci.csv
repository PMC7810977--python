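locus,lessonae_specific,ridibundus_specific
RICA2a34,144,-
RICA5,262,-
Rrid013A,301,287/293
Ga1a19,197,203/207/211/224/245/249/251
RICA18,188,-
RICA1b5,120,134/136/140
Res14,140,146/150
Res20,124,-
Re1Caga10,-,106/108/110/113/115/117/119/122/127/133/137
Re2Caga3,-,173/204/212/223/232/234/236/239
RICA1b6,-,77/80/83/88/90/96/98/103
Res22,-,85/106/108/113/130
Rrid059A,-,129/131/135/137/142
Rrid082A,-,163/169/178/182/184
Rrid169A,-,187/189/192/195/197/204/208
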