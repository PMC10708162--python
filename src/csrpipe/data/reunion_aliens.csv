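# Ten alien woody species surveyed along a 0-2100 m rainforest elevational
# transect on Reunion Island (Mascarene archipelago): the elevations (m) at
# which each species occurred, its relative abundance (%) at each of those
# elevations (near-trail and off-trail plots pooled), its C:S:R coordinates
# and the assigned ternary strategy class.
species,elevations_m,relative_abundance_pct,c,s,r,strategy_class
Adenanthera pavonina,0,38,58,17,25,C/CSR
Aleurites moluccanus,0,5,65,29,6,C/CS
Artocarpus heterophyllus,0,2,53,36,11,CS/CSR
Mangifera indica,0,23,51,47,2,CS
Syzygium jambos,0,3,42,58,0,CS
Litsea glutinosa,300,1,27,73,0,S/CS
Schinus terebinthifolia,300,1,45,48,6,CS
Ardisia crenata,900,1,29,71,0,S/CS
Rubus alceifolius,900,5,53,42,5,CS
Psidium cattleyanum,0;300;600;900,16;18;8;10,43,57,0,CS
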