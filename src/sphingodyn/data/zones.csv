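# sphingodyn zone annotation v1
# zone colours refer to the pathway-map grouping of enzymes by the shape of
# their inferred heat-stress activity change; "peripheral" marks enzymes whose
# individual pink-vs-tan panel assignment is not resolved in the sources
# bundled with this package.
index,name,zone,figure
X57,serine palmitoyltransferase (SPT),red,3
X27,3-KDHS reductase,red,3
X34,ceramide synthase,blue,4
X36,sphingoid base kinase,blue,4
X41,sphingoid-1-phosphate phosphatase,blue,4
X54,4-hydroxylase,blue,4
X50,sphingosine-phosphate lyase,blue,4
X43,GPI remodelase,blue,4
X59,very long chain fatty acid synthase / elongase (ELO1p),blue,4
X29,dihydroceramide alkaline ceramidase (dihydro-CDase),blue,5
X53,phytoceramide alkaline ceramidase (phyto-CDase),blue,5
X33,IPC synthase,green,6
X35,MIPC synthase,green,6
X55,M(IP)2C synthase,green,6
X51,inositol phosphosphingolipid phospholipase C (IPCase/ISC1),green,6
X52,fatty acid synthase,yellow,7
X60,acetyl-CoA carboxylase,yellow,7
X63,synthase,yellow,7
X26,unassigned periphery enzyme,peripheral,8
X31,unassigned periphery enzyme,peripheral,8
X32,unassigned periphery enzyme,peripheral,8
X38,unassigned periphery enzyme,peripheral,8
X39,unassigned periphery enzyme,peripheral,8
X40,unassigned periphery enzyme,peripheral,8
X42,unassigned periphery enzyme,peripheral,8
X44,unassigned periphery enzyme,peripheral,8
X45,unassigned periphery enzyme,peripheral,8
X46,unassigned periphery enzyme,peripheral,8
X49,unassigned periphery enzyme,peripheral,8
X56,unassigned periphery enzyme,peripheral,8
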