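srna,mrna,rank,category,binding
SroE,yieH,3,Top-ranked,no
SroE,yeaG,5,Top-ranked,no
SroE,yahN,9,Top-ranked,no
SroE,mdtA,10,Top-ranked,no
SroE,creA,12,Top-ranked,no
SroE,arcC,18,INTERFACE,no
SroE,pdxY,32,INTERFACE,no
SroE,marC,38,INTERFACE,no
SroE,ligB,46,INTERFACE,weak
SroE,fadH,61,INTERFACE,no
SroG,cdsA,4,Both,yes
SroG,cysJ,5,Both,yes
SroG,yfbR,7,Both,yes
SroG,yncD,10,Both,yes
SroG,mepM,12,Both,yes
SroG,potA,64,INTERFACE,yes
SroG,dosP,65,INTERFACE,no
SroG,pgl,75,INTERFACE,yes
SroG,fecE,76,INTERFACE,weak
Tpke70,agaS,3,Top-ranked,weak
Tpke70,dkgB,6,Both,no
Tpke70,mcrA,7,Both,yes
Tpke70,mdoB,12,Both,no
Tpke70,dbpA,13,Both,no
Tpke70,degS,14,Both,no
Tpke70,torT,19,INTERFACE,yes
Tpke70,glnK,29,INTERFACE,yes
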