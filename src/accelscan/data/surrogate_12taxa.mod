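ALPHABET: A C G T
ORDER: 0
SUBST_MOD: REV
BACKGROUND: 0.295 0.205 0.205 0.295
RATE_MAT:
  -0.848439733710042  0.16102349311617  0.569775437180294  0.117640803413577
   0.23171673399644 -1.27157201224383  0.148637070568772  0.891218207678615
   0.819920751064326  0.148637070568772 -1.14680146316882  0.178243641535723
   0.117640803413577  0.619321127369885  0.123864225473977 -0.86082615625744
TREE: (((((((hg19:0.06,panTro4:0.064):0.022,gorGor3:0.09):0.07,ponAbe2:0.18):0.035,nomLeu3:0.22):0.11,rheMac3:0.36):0.25,calJac3:0.52):0.4,(mm10:1.6,rn5:1.7):0.9,((canFam3:0.9,felCat5:0.85):0.35,monDom5:1.4):0.2);
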