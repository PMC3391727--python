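HEAD: eye pubescence; ocelli; width of frons (male); width of frons (female); outer vertical setae (male); outer vertical setae (female); length of ocellar setae; inclination of ocellar setae; frontal setae; fronto-orbital plate; upper reclinate orbital setae; proclinate orbital setae (male); proclinate orbital setae (female); parafacial setae; width of parafacial; parafacial ratio; shape of facial ridge (head in lateral view); setae of facial ridge; type of setae on facial ridge; vibrissa; face; lower facial margin; genal dilation; ventral part of occiput; dorsal part of occiput; height of gena.
ANTENNAE: colour of antennal pedicel; length of antenna; length of first flagellomere; apex of first flagellomere; pubescence of arista; thickness of arista; length of first aristomere; lenght of second aristomere.
MOUTHPARTS: length of prementum; labella; colour of palpus; size and shape of palpus.
THORAX: presutural dark vittae of scutum; prosternal setulae; shape of prosternum; proepisternum; postpronotum; presutural acrostichal setae; presutural dorsocentral setae; postsutural dorsocentral setae; postsutural intra-alar setae; supra-alar setae; katepisternal setae; katepimeron; anepimeral seta; colour of scutellum; number of marginal setae of scutellum; lateral setae of scutellum; length of subapical setae of scutellum; apical scutellar setae; preapical scutellar setae; anatergite; posterior spiracle; postmetacoxal area.
WING: position of lower calypter; marginal shape of lower calypter; setulae on lower calypter surface; wing colour; tegula colour; basicosta colour; second costal segment; costal spine; vein R1; basal seta on vein R4+5; setae on vein R4+5; vein CuA1; bend of vein M; stub and prolongation of vein M; fourth costal sector (CS4); ratios of sections of vein M; crossvein DM-Cu; petiole.
LEGS: colour of legs; fore coxa; fore tibia; mid tibia; number of preapical setae on hind tibia; length of preapical setae on hind tibia; anterodorsal setae on hind tibia; hind coxa.
ABDOMEN: ground colour of abdomen; abdominal microtomentum (pattern); fusion of abdominal tergites; mid-dorsal depression on syntergite 1+2; marginal setae on syntergite 1+2; median marginal setae on tergites 3 and 4; median discal setae on tergites 3 and 4; tergite 5 length; sternite 4; male abdominal patches of setulae (pattern); female ovipositor.
COLOUR: general body ground colour.
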